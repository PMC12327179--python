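import numpy as np
import pytest

from psfcoex import (
    AlphaMatrix,
    MicrobeTaxon,
    PlantParams,
    PSFModel,
    builtin_scenario,
)


@pytest.fixture
def sterile_model():
    return builtin_scenario("ThSi-I").model


@pytest.fixture
def one_mutualist_model():
    return builtin_scenario("ThSi-II").model


@pytest.fixture
def two_mutualist_model():
    return builtin_scenario("ThSi-III").model


@pytest.fixture
def sean_model():
    return builtin_scenario("SeAn").model


def random_negative_alpha(rng: np.random.Generator) -> AlphaMatrix:
    """A random all-competitive alpha matrix on realistic scales."""
    return AlphaMatrix(-rng.uniform(0.01, 0.12, size=(2, 2)))


def random_full_model(rng: np.random.Generator,
                      require_outcome: str | None = None,
                      min_margin: float = 0.0) -> PSFModel:
    """A random plant+microbe model whose effective alpha is all-negative.

    ``min_margin`` demands both invasion margins |1 - a_ij/a_jj| exceed the
    given relative size, keeping samples away from classification
    boundaries.
    """
    from psfcoex import alpha_at, classify_outcome

    while True:
        c = -rng.uniform(0.02, 0.1, size=(2, 2))
        microbe = MicrobeTaxon(
            "X",
            g=float(rng.uniform(0.5, 2.0)),
            sigma=tuple(rng.uniform(-0.003, 0.003, size=2)),
            phi=tuple(rng.uniform(0.0, 10.0, size=2)),
        )
        model = PSFModel(PlantParams(c=c), microbes=(microbe,))
        a = alpha_at(model, 0.0).alpha
        if not np.all(a < 0):
            continue
        margins = [abs(1 - a[0, 1] / a[1, 1]), abs(1 - a[1, 0] / a[0, 0])]
        if min(margins) < min_margin:
            continue
        if require_outcome is not None:
            if classify_outcome(alpha_at(model, 0.0)).label != require_outcome:
                continue
        return model
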