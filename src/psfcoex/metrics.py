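"""Niche overlap, fitness ratio and competition-outcome classification.

Given the effective competition matrix of a two-species Lotka-Volterra
system, modern coexistence theory summarises the interaction with two axes:

* niche overlap ``rho = sqrt((a_AB * a_BA) / (a_AA * a_BB))`` and the niche
  difference ``1 - rho`` (stabilisation through stronger intra- than
  interspecific limitation);
* the fitness ratio ``f_B / f_A = sqrt((a_AA * a_AB) / (a_BB * a_BA))``
  (the average competitive advantage of B over A).

Both are defined only when all four coefficients are competitive
(``alpha_ij < 0``); any facilitative entry makes the square roots meaningless
and the metrics are flagged undefined.  The predicted outcome, by contrast,
is computed from the mutual-invasibility inequalities directly on alpha, so
it remains available under facilitation as long as both species self-limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import UnboundedGrowthError
from .model import AlphaMatrix

__all__ = [
    "CoexistenceMetrics",
    "OutcomeLabel",
    "OUTCOMES",
    "niche_overlap",
    "fitness_ratio",
    "fitness_inequality",
    "compute_metrics",
    "classify_outcome",
]

#: the closed set of outcome labels
OUTCOMES = (
    "coexistence",
    "exclusion_of_A",
    "exclusion_of_B",
    "priority_effects",
    "undefined",
)

#: default relative tolerance for boundary detection
DEFAULT_TOL = 1e-9


@dataclass(frozen=True)
class CoexistenceMetrics:
    rho: float
    niche_difference: float
    fitness_ratio_BA: float
    fitness_inequality: float
    defined: bool

    @classmethod
    def undefined(cls) -> "CoexistenceMetrics":
        nan = float("nan")
        return cls(nan, nan, nan, nan, False)


@dataclass(frozen=True)
class OutcomeLabel:
    label: str
    boundary: bool = False

    def __post_init__(self):
        if self.label not in OUTCOMES:
            raise ValueError(f"unknown outcome label {self.label!r}")

    def swapped(self) -> "OutcomeLabel":
        swap = {"exclusion_of_A": "exclusion_of_B",
                "exclusion_of_B": "exclusion_of_A"}
        return OutcomeLabel(swap.get(self.label, self.label), self.boundary)


def _all_competitive(alpha: np.ndarray) -> bool:
    return bool(np.all(alpha < 0))


def niche_overlap(alpha: AlphaMatrix) -> float:
    """rho; NaN when any alpha_ij >= 0 (facilitation -> undefined)."""
    a = alpha.alpha
    if not _all_competitive(a):
        return float("nan")
    return math.sqrt((a[0, 1] * a[1, 0]) / (a[0, 0] * a[1, 1]))


def fitness_ratio(alpha: AlphaMatrix) -> float:
    """f_B / f_A; NaN when any alpha_ij >= 0."""
    a = alpha.alpha
    if not _all_competitive(a):
        return float("nan")
    return math.sqrt((a[0, 0] * a[0, 1]) / (a[1, 1] * a[1, 0]))


def fitness_inequality(metrics_or_ratio) -> float:
    """max(f_B/f_A, f_A/f_B): the advantage of the fitter species, >= 1."""
    if isinstance(metrics_or_ratio, CoexistenceMetrics):
        if not metrics_or_ratio.defined:
            return float("nan")
        f = metrics_or_ratio.fitness_ratio_BA
    else:
        f = float(metrics_or_ratio)
    if not math.isfinite(f) or f <= 0:
        return float("nan")
    return max(f, 1.0 / f)


def compute_metrics(alpha: AlphaMatrix) -> CoexistenceMetrics:
    rho = niche_overlap(alpha)
    if math.isnan(rho):
        return CoexistenceMetrics.undefined()
    f = fitness_ratio(alpha)
    return CoexistenceMetrics(
        rho=rho,
        niche_difference=1.0 - rho,
        fitness_ratio_BA=f,
        fitness_inequality=max(f, 1.0 / f),
        defined=True,
    )


def _invades(a_ij: float, a_jj: float, tol: float) -> tuple[bool, bool]:
    """Can species i invade resident j?  Returns (invades, at_boundary).

    The resident monoculture sits at N_j* = -1/a_jj; the invader's per-capita
    growth there is r_i (1 - a_ij / a_jj), positive iff a_ij > a_jj.  For
    competitive a_ij this is |a_ij| < |a_jj|; a facilitative a_ij >= 0 always
    permits invasion.
    """
    scale = max(abs(a_ij), abs(a_jj), 1e-300)
    margin = (a_ij - a_jj) / scale
    return margin > 0, abs(margin) <= tol


def classify_outcome(alpha: AlphaMatrix, tol: float = DEFAULT_TOL) -> OutcomeLabel:
    """Predict the competition outcome by mutual invasibility.

    A invades B's resident equilibrium iff ``|alpha_AB| < |alpha_BB|`` and
    vice versa: both invade -> coexistence; neither -> priority effects (the
    winner is set by arrival order); exactly one -> exclusion of the
    non-invader.  When all alpha are competitive this is equivalent to the
    band rule ``rho < f_B/f_A < 1/rho`` for coexistence.

    ``boundary`` is True when either invasion margin is within ``tol``
    (relative) of zero, or when rho is defined and within ``tol`` of 1 (the
    degenerate edge of the coexistence/priority band).
    """
    a = alpha.alpha
    if a[0, 0] >= 0 or a[1, 1] >= 0:
        raise UnboundedGrowthError(
            "no stable resident equilibrium: requires alpha_AA < 0 and "
            f"alpha_BB < 0, got diag ({a[0, 0]:g}, {a[1, 1]:g})"
        )
    a_inv, a_bnd = _invades(a[0, 1], a[1, 1], tol)  # A into resident B
    b_inv, b_bnd = _invades(a[1, 0], a[0, 0], tol)  # B into resident A
    boundary = a_bnd or b_bnd
    rho = niche_overlap(alpha)
    if math.isfinite(rho) and abs(rho - 1.0) <= tol:
        boundary = True
    if a_inv and b_inv:
        label = "coexistence"
    elif a_inv:
        label = "exclusion_of_B"
    elif b_inv:
        label = "exclusion_of_A"
    else:
        label = "priority_effects"
    return OutcomeLabel(label, boundary)


def metrics_row(alpha: AlphaMatrix, tol: float = DEFAULT_TOL) -> dict:
    """One flat record: alpha entries, metrics and outcome.

    The serialization shared by gradient tables, sweeps and the CLI.  When a
    diagonal entry is non-negative the outcome is reported as ``undefined``
    rather than raising, so gradient scans can cross such regions.
    """
    a = alpha.alpha
    m = compute_metrics(alpha)
    try:
        outcome = classify_outcome(alpha, tol)
    except UnboundedGrowthError:
        outcome = OutcomeLabel("undefined")
    return {
        "env_value": alpha.env_value,
        "alpha_AA": a[0, 0],
        "alpha_AB": a[0, 1],
        "alpha_BA": a[1, 0],
        "alpha_BB": a[1, 1],
        "rho": m.rho,
        "niche_difference": m.niche_difference,
        "fitness_ratio_BA": m.fitness_ratio_BA,
        "fitness_inequality": m.fitness_inequality,
        "outcome": outcome.label,
        "boundary": outcome.boundary,
        "defined": m.defined,
    }
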