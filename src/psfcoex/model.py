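"""Parameter data model for plant-soil-feedback competition systems.

Two plant species compete directly through microbe-independent per-capita
coefficients ``c_ij`` (competition encoded as negative values) and indirectly
through any number of microbial taxa.  Each taxon X is described by its effect
``sigma_iX`` on each plant's per-capita growth (negative = pathogen, positive
= mutualist) and the cultivation rate ``phi_Xi`` by which each plant
contributes to the taxon's carrying capacity.

Any ``c``, ``sigma`` or ``phi`` parameter may be tied to a scalar
environmental variable ``v`` through a :class:`ScalingRule`; resolving a model
at a given ``v`` yields a :class:`ResolvedParameters` snapshot from which the
effective 2x2 competition matrix ``alpha_ij = c_ij + sum_X sigma_iX phi_Xj``
is computed.  Matrix orientation throughout: row = affected plant *i*,
column = acting plant *j*.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "PlantParams",
    "MicrobeTaxon",
    "ScalingRule",
    "PSFModel",
    "ResolvedParameters",
    "AlphaMatrix",
    "resolve_parameters",
    "effective_alpha",
    "apply_feedback_term",
    "parse_address",
]


@dataclass(frozen=True)
class PlantParams:
    """The two competing plant populations.

    Parameters
    ----------
    labels : pair of str
        Identifiers for plants A and B (row/column order of ``c``).
    r : pair of float
        Intrinsic growth rates (time^-1); must be positive.  Equilibria and
        coexistence metrics do not depend on ``r`` when the two rates are
        equal, so the default is 1 for both.
    c : 2x2 array-like
        Microbe-independent per-capita interaction coefficients ``c_ij``
        (effect of plant j on plant i).  Competition is ``c_ij < 0``.
    """

    labels: tuple[str, str] = ("A", "B")
    r: tuple[float, float] = (1.0, 1.0)
    c: np.ndarray = field(default_factory=lambda: np.full((2, 2), -0.05))

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "r", tuple(float(x) for x in self.r))
        c = np.asarray(self.c, dtype=float)
        if c.shape != (2, 2):
            raise ConfigurationError(f"c must be 2x2, got shape {c.shape}")
        object.__setattr__(self, "c", c)
        if len(self.labels) != 2 or len(set(self.labels)) != 2:
            raise ConfigurationError("exactly two distinct plant labels required")
        if any(r <= 0 for r in self.r):
            raise ConfigurationError("intrinsic growth rates r must be positive")


@dataclass(frozen=True)
class MicrobeTaxon:
    """One microbial taxon with per-plant effect and cultivation parameters.

    ``sigma`` is the per-unit-microbe effect on each plant's per-capita growth
    (any sign); ``phi`` is each plant's contribution to the taxon's carrying
    capacity and must be non-negative once scaling is resolved.
    """

    label: str
    g: float = 1.0
    sigma: tuple[float, float] = (0.0, 0.0)
    phi: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "sigma", tuple(float(x) for x in self.sigma))
        object.__setattr__(self, "phi", tuple(float(x) for x in self.phi))
        if float(self.g) <= 0:
            raise ConfigurationError(f"microbe {self.label!r}: g must be positive")


def _linear(v: float, intercept: float, slope: float) -> float:
    return intercept + v * slope


@dataclass(frozen=True)
class ScalingRule:
    """Ties one parameter to the environmental variable ``v``.

    The resolved value *replaces* the static value in the config (the scaling
    function defines the full parameter, not a perturbation).  The built-in
    form is linear, ``intercept + v * slope``; an arbitrary monotone function
    of ``v`` may be supplied through ``function`` (it receives ``v``,
    ``intercept`` and ``slope`` and returns the raw value, which is then
    clamped if requested).

    ``clamp_nonnegative`` truncates the resolved value at zero and is
    mandatory for ``phi`` targets: cultivation rates cannot be negative, so a
    linear rule becomes piecewise-linear, following the line where it is >= 0
    and staying at 0 otherwise.
    """

    target: str
    intercept: float
    slope: float
    clamp_nonnegative: bool = False
    function: Callable[[float, float, float], float] = _linear

    def __call__(self, v: float) -> float:
        raw = self.function(float(v), self.intercept, self.slope)
        if self.clamp_nonnegative:
            return max(raw, 0.0)
        return raw


def parse_address(address: str) -> tuple[str, str, str]:
    """Split a parameter address into (kind, first, second).

    Addresses are dotted string paths: ``c.<i>.<j>`` (affected plant,
    acting plant), ``sigma.<plant>.<microbe>``, ``phi.<microbe>.<plant>``,
    and ``m.<i>.<j>`` for composite feedback terms in sensitivity sweeps.
    """
    parts = address.split(".")
    if len(parts) != 3 or parts[0] not in {"c", "sigma", "phi", "m"}:
        raise ConfigurationError(
            f"invalid parameter address {address!r}: expected "
            "'c.<i>.<j>', 'sigma.<plant>.<microbe>', 'phi.<microbe>.<plant>' "
            "or 'm.<i>.<j>'"
        )
    return parts[0], parts[1], parts[2]


@dataclass(frozen=True)
class PSFModel:
    """Full parameter set: plants, microbes and environmental scaling rules."""

    plants: PlantParams
    microbes: tuple[MicrobeTaxon, ...] = ()
    scaling: tuple[ScalingRule, ...] = ()
    env_name: str = "v"
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "microbes", tuple(self.microbes))
        object.__setattr__(self, "scaling", tuple(self.scaling))
        self.validate()

    # -- address resolution -------------------------------------------------

    def plant_index(self, label: str) -> int:
        try:
            return self.plants.labels.index(label)
        except ValueError:
            raise ConfigurationError(
                f"unknown plant label {label!r}; have {self.plants.labels}"
            ) from None

    def microbe_index(self, label: str) -> int:
        for k, taxon in enumerate(self.microbes):
            if taxon.label == label:
                return k
        raise ConfigurationError(
            f"unknown microbe label {label!r}; have "
            f"{[t.label for t in self.microbes]}"
        )

    def validate(self) -> None:
        problems = []
        labels = [t.label for t in self.microbes]
        if len(set(labels)) != len(labels):
            problems.append(f"duplicate microbe labels in {labels}")
        seen_targets = set()
        for rule in self.scaling:
            if rule.target in seen_targets:
                problems.append(f"multiple scaling rules for {rule.target!r}")
            seen_targets.add(rule.target)
            try:
                kind, a, b = parse_address(rule.target)
                if kind == "m":
                    raise ConfigurationError(
                        f"scaling target {rule.target!r}: feedback terms are "
                        "sweep-only, not model parameters"
                    )
                if kind == "c":
                    self.plant_index(a), self.plant_index(b)
                elif kind == "sigma":
                    self.plant_index(a), self.microbe_index(b)
                elif kind == "phi":
                    self.microbe_index(a), self.plant_index(b)
                if kind == "phi" and not rule.clamp_nonnegative:
                    problems.append(
                        f"scaling rule for {rule.target!r}: clamp_nonnegative "
                        "is mandatory for phi targets"
                    )
            except ConfigurationError as exc:
                problems.append(f"scaling target {rule.target!r}: {exc}")
        # static phi values must be non-negative unless a rule overrides them
        for taxon in self.microbes:
            for j, plant in enumerate(self.plants.labels):
                addr = f"phi.{taxon.label}.{plant}"
                if taxon.phi[j] < 0 and addr not in seen_targets:
                    problems.append(f"negative cultivation rate at {addr!r}")
        if problems:
            raise ConfigurationError("; ".join(problems))

    def scaled_addresses(self) -> set[str]:
        return {rule.target for rule in self.scaling}


@dataclass(frozen=True)
class ResolvedParameters:
    """A :class:`PSFModel` evaluated at a single environment value."""

    plants: PlantParams
    microbes: tuple[MicrobeTaxon, ...]
    env_value: float
    env_name: str = "v"
    model_name: str = ""

    @property
    def n_microbes(self) -> int:
        return len(self.microbes)

    def sigma_matrix(self) -> np.ndarray:
        """(2, n) array of sigma_iX, row = plant, column = taxon."""
        if not self.microbes:
            return np.zeros((2, 0))
        return np.array([t.sigma for t in self.microbes]).T

    def phi_matrix(self) -> np.ndarray:
        """(n, 2) array of phi_Xi, row = taxon, column = plant."""
        if not self.microbes:
            return np.zeros((0, 2))
        return np.array([t.phi for t in self.microbes])


@dataclass(frozen=True)
class AlphaMatrix:
    """Effective 2x2 competition matrix alpha_ij (effect of j on i)."""

    alpha: np.ndarray
    labels: tuple[str, str] = ("A", "B")
    env_value: float | None = None
    model_name: str = ""

    def __post_init__(self):
        a = np.asarray(self.alpha, dtype=float)
        if a.shape != (2, 2):
            raise ConfigurationError(f"alpha must be 2x2, got {a.shape}")
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "labels", tuple(self.labels))

    def swapped(self) -> "AlphaMatrix":
        """Exchange the two plant labels (rows and columns)."""
        perm = np.array([[self.alpha[1, 1], self.alpha[1, 0]],
                         [self.alpha[0, 1], self.alpha[0, 0]]])
        return AlphaMatrix(perm, (self.labels[1], self.labels[0]),
                           self.env_value, self.model_name)


def resolve_parameters(model: PSFModel, v: float) -> ResolvedParameters:
    """Evaluate every scaling rule at environment value ``v``.

    Parameters carrying a rule take the value ``rule(v)`` (the static value in
    the model is ignored, with a warning when they differ); parameters without
    rules are passed through unchanged.  All cultivation rates are clamped to
    be non-negative by their rules, so the result never contains ``phi < 0``.
    """
    v = float(v)
    c = model.plants.c.copy()
    sigma = [list(t.sigma) for t in model.microbes]
    phi = [list(t.phi) for t in model.microbes]

    for rule in model.scaling:
        kind, a, b = parse_address(rule.target)
        value = rule(v)
        if kind == "c":
            i, j = model.plant_index(a), model.plant_index(b)
            if c[i, j] != rule.intercept and c[i, j] != 0.0:
                logger.warning(
                    "static value %g at %s shadowed by scaling rule",
                    c[i, j], rule.target,
                )
            c[i, j] = value
        elif kind == "sigma":
            i, x = model.plant_index(a), model.microbe_index(b)
            sigma[x][i] = value
        elif kind == "phi":
            x, i = model.microbe_index(a), model.plant_index(b)
            phi[x][i] = value

    plants = replace(model.plants, c=c)
    microbes = tuple(
        replace(t, sigma=tuple(sigma[k]), phi=tuple(phi[k]))
        for k, t in enumerate(model.microbes)
    )
    return ResolvedParameters(
        plants=plants, microbes=microbes, env_value=v,
        env_name=model.env_name, model_name=model.name,
    )


def effective_alpha(resolved: ResolvedParameters) -> AlphaMatrix:
    """Reduce a resolved model to effective competition coefficients.

    ``alpha_ij = c_ij + sum_X sigma_iX phi_Xj``: the direct per-capita effect
    of plant j on plant i plus the indirect effect routed through every
    microbial taxon at its quasi-equilibrium abundance (the taxon's carrying
    capacity, which is linear in plant abundances).  With no microbes this is
    exactly the microbe-independent matrix ``c``.
    """
    alpha = resolved.plants.c + resolved.sigma_matrix() @ resolved.phi_matrix()
    return AlphaMatrix(alpha, resolved.plants.labels,
                       resolved.env_value, resolved.model_name)


def alpha_at(model: PSFModel, v: float) -> AlphaMatrix:
    """Convenience composition of :func:`resolve_parameters` and
    :func:`effective_alpha`."""
    return effective_alpha(resolve_parameters(model, v))


def get_parameter(model: PSFModel, address: str) -> float:
    """Read the static value at a dotted parameter address."""
    kind, a, b = parse_address(address)
    if kind == "c":
        return float(model.plants.c[model.plant_index(a), model.plant_index(b)])
    if kind == "sigma":
        return model.microbes[model.microbe_index(b)].sigma[model.plant_index(a)]
    if kind == "phi":
        return model.microbes[model.microbe_index(a)].phi[model.plant_index(b)]
    raise ConfigurationError(f"{address!r} is not a static model parameter")


def with_parameter(model: PSFModel, address: str, value: float) -> PSFModel:
    """Return a copy of ``model`` with one static parameter replaced."""
    kind, a, b = parse_address(address)
    value = float(value)
    if kind == "c":
        c = model.plants.c.copy()
        c[model.plant_index(a), model.plant_index(b)] = value
        return replace(model, plants=replace(model.plants, c=c))
    if kind in ("sigma", "phi"):
        if kind == "sigma":
            x, i = model.microbe_index(b), model.plant_index(a)
        else:
            x, i = model.microbe_index(a), model.plant_index(b)
        taxon = model.microbes[x]
        vals = list(getattr(taxon, kind))
        vals[i] = value
        microbes = list(model.microbes)
        microbes[x] = replace(taxon, **{kind: tuple(vals)})
        return replace(model, microbes=tuple(microbes))
    raise ConfigurationError(f"{address!r} is not a static model parameter")


def apply_feedback_term(c: np.ndarray | PlantParams, m: np.ndarray,
                        labels: Sequence[str] = ("A", "B")) -> AlphaMatrix:
    """Build alpha from microbe-independent c plus composite feedback terms.

    ``m_ij = sigma_iX * phi_Xj`` is the plant-microbe feedback: the indirect
    effect of plant j on plant i via cultivation of a shared taxon.  Treating
    ``m`` as a directly manipulable 2x2 quantity supports sensitivity sweeps
    that are agnostic to how the product splits between sigma and phi.
    """
    if isinstance(c, PlantParams):
        labels = c.labels
        c = c.c
    c = np.asarray(c, dtype=float)
    m = np.asarray(m, dtype=float)
    if m.shape != (2, 2):
        raise ConfigurationError(f"feedback term m must be 2x2, got {m.shape}")
    return AlphaMatrix(c + m, tuple(labels))
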