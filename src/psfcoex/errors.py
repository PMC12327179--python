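"""Exception types shared across the package."""


class PSFError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(PSFError):
    """A model configuration is structurally invalid.

    Raised with the offending parameter address(es) in the message so that
    config authors can locate the problem; multiple validation failures are
    reported together.
    """


class UnboundedGrowthError(PSFError):
    """A resident species lacks self-limitation (alpha_ii >= 0).

    Without negative intraspecific feedback there is no stable resident
    monoculture, so invasion analysis and outcome classification are
    meaningless.
    """


class IntegrationError(PSFError):
    """The ODE integrator failed; carries the last good state."""

    def __init__(self, message, last_state=None, last_time=None):
        super().__init__(message)
        self.last_state = last_state
        self.last_time = last_time
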