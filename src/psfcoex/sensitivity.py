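"""Sensitivity of niche differences and fitness ratios to model parameters.

Four complementary views:

* :func:`oat_sweep` — one-at-a-time sweeps: the focal parameter runs from its
  minimum to its maximum while everything else is held at baseline, and the
  coexistence metrics are recorded at each grid point.
* :func:`feedback_sweep` — the same, but over a composite feedback term
  ``m_ij = sigma_iX phi_Xj`` treated as a directly manipulable quantity, which
  is agnostic to how the product splits between effect and cultivation.
* :func:`local_derivatives` — closed-form partial derivatives of the niche
  difference and fitness ratio at the baseline (log-differentiation of the
  metric definitions through the alpha reduction), verified against central
  finite differences.
* :func:`global_screen` — a sampling-based variance decomposition: Latin
  hypercube samples over per-parameter boxes, first-order importance of each
  parameter estimated from binned conditional means of the metric.

Default sweep boxes: competition coefficients in [-0.1, 0], microbial
effects on plants in [-0.01, 0.01], cultivation rates in [0, 20], feedback
terms in [-0.2, 0.2].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .errors import ConfigurationError, PSFError
from .metrics import compute_metrics, metrics_row
from .model import (
    AlphaMatrix,
    PSFModel,
    apply_feedback_term,
    alpha_at,
    get_parameter,
    parse_address,
    with_parameter,
)

__all__ = [
    "SweepSpec",
    "SensitivityIndex",
    "default_boxes",
    "oat_sweep",
    "feedback_sweep",
    "local_derivatives",
    "global_screen",
]

#: parameter boxes used throughout the sensitivity analyses, by kind
DEFAULT_BOX_BY_KIND = {
    "c": (-0.1, 0.0),
    "sigma": (-0.01, 0.01),
    "phi": (0.0, 20.0),
    "m": (-0.2, 0.2),
}

DEFAULT_N_POINTS = 201


@dataclass(frozen=True)
class SweepSpec:
    """One-at-a-time sweep definition over a single parameter address."""

    target: str
    baseline: PSFModel
    min: float | None = None
    max: float | None = None
    n_points: int = DEFAULT_N_POINTS
    env_value: float = 0.0

    def __post_init__(self):
        kind, _, _ = parse_address(self.target)
        lo, hi = DEFAULT_BOX_BY_KIND[kind]
        object.__setattr__(self, "min", lo if self.min is None else float(self.min))
        object.__setattr__(self, "max", hi if self.max is None else float(self.max))
        if not self.min < self.max:
            raise ConfigurationError(
                f"sweep over {self.target!r}: need min < max, "
                f"got [{self.min}, {self.max}]"
            )
        if self.n_points < 2:
            raise ConfigurationError("sweep needs n_points >= 2")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.min, self.max, self.n_points)


@dataclass(frozen=True)
class SensitivityIndex:
    """Per-target summary: local slope and swept range of each metric."""

    target: str
    d_niche_difference: float = math.nan
    d_fitness_ratio: float = math.nan
    range_niche_difference: float = math.nan
    range_fitness_ratio: float = math.nan
    importance: float = math.nan


def primitive_targets(model: PSFModel) -> list[str]:
    """All c, sigma and phi addresses of a model, c first."""
    a, b = model.plants.labels
    targets = [f"c.{i}.{j}" for i in (a, b) for j in (a, b)]
    for taxon in model.microbes:
        targets += [f"sigma.{p}.{taxon.label}" for p in (a, b)]
        targets += [f"phi.{taxon.label}.{p}" for p in (a, b)]
    return targets


def default_boxes(model: PSFModel) -> dict[str, tuple[float, float]]:
    """The standard sweep box for every primitive parameter of ``model``."""
    return {
        t: DEFAULT_BOX_BY_KIND[parse_address(t)[0]]
        for t in primitive_targets(model)
    }


def _baseline_feedback(model: PSFModel, env_value: float) -> np.ndarray:
    """Baseline m matrix: summed sigma_iX phi_Xj contributions."""
    from .model import effective_alpha, resolve_parameters

    resolved = resolve_parameters(model, env_value)
    return resolved.sigma_matrix() @ resolved.phi_matrix()


def _alpha_for(spec: SweepSpec, value: float) -> AlphaMatrix:
    kind, a, b = parse_address(spec.target)
    model = spec.baseline
    if kind == "m":
        m = _baseline_feedback(model, spec.env_value)
        i = model.plant_index(a)
        j = model.plant_index(b)
        m[i, j] = value
        return apply_feedback_term(model.plants, m)
    return alpha_at(with_parameter(model, spec.target, value), spec.env_value)


def oat_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Metrics along the sweep grid, with the baseline row as reference.

    Rows where any alpha is non-negative keep their alpha values and outcome
    but carry ``defined=False`` for the metric columns (the curves are
    truncated there, not dropped, so plots can show where truncation occurs).
    Baseline metrics are attached in ``DataFrame.attrs['baseline']``.
    """
    kind, a, b = parse_address(spec.target)
    rows = []
    for value in spec.grid:
        row = metrics_row(_alpha_for(spec, value))
        row.pop("env_value")
        row = {
            "target": spec.target,
            "value": value,
            "standardized_position": (value - spec.min) / (spec.max - spec.min),
            **row,
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    if kind == "m":
        m = _baseline_feedback(spec.baseline, spec.env_value)
        baseline_alpha = apply_feedback_term(spec.baseline.plants, m)
        baseline_value = m[spec.baseline.plant_index(a),
                          spec.baseline.plant_index(b)]
    else:
        baseline_alpha = alpha_at(spec.baseline, spec.env_value)
        baseline_value = get_parameter(spec.baseline, spec.target)
    df.attrs["baseline"] = {
        "value": baseline_value,
        **{k: v for k, v in metrics_row(baseline_alpha).items()
           if k != "env_value"},
    }
    return df


def feedback_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Sweep a composite feedback term ``m.<i>.<j>``; other m entries stay at
    their baseline products."""
    if parse_address(spec.target)[0] != "m":
        raise ConfigurationError(
            f"feedback_sweep requires an m.<i>.<j> target, got {spec.target!r}"
        )
    return oat_sweep(spec)


def sweep_range(df: pd.DataFrame, column: str = "fitness_ratio_BA") -> float:
    """max - min of a metric over the defined portion of a sweep."""
    vals = df.loc[df["defined"], column].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return math.nan
    return float(vals.max() - vals.min())


# -- local (derivative-based) sensitivity -----------------------------------


def _dalpha(model: PSFModel, target: str, env_value: float) -> np.ndarray:
    """d alpha / d target: 2x2 matrix of partials of the alpha entries."""
    from .model import resolve_parameters

    kind, a, b = parse_address(target)
    d = np.zeros((2, 2))
    if kind in ("c", "m"):
        d[model.plant_index(a), model.plant_index(b)] = 1.0
    elif kind == "sigma":
        resolved = resolve_parameters(model, env_value)
        i = model.plant_index(a)
        x = model.microbe_index(b)
        d[i, :] = resolved.microbes[x].phi           # alpha_i. varies via phi_Xj
    elif kind == "phi":
        resolved = resolve_parameters(model, env_value)
        x = model.microbe_index(a)
        j = model.plant_index(b)
        d[:, j] = resolved.microbes[x].sigma         # alpha_.j varies via sigma_iX
    return d


def local_derivatives(
    model: PSFModel,
    targets: list[str] | None = None,
    env_value: float = 0.0,
    check: bool = True,
    fd_rel_step: float = 1e-6,
    fd_rtol: float = 1e-4,
) -> list[SensitivityIndex]:
    """Closed-form partials of niche difference and fitness ratio.

    From the log forms ``2 ln rho = ln|a_AB| + ln|a_BA| - ln|a_AA| - ln|a_BB|``
    and ``2 ln f = ln|a_AA| + ln|a_AB| - ln|a_BB| - ln|a_BA|``, the chain rule
    through the alpha reduction gives each partial as a weighted sum of
    ``(d alpha_ij / d p) / alpha_ij``.  With ``check=True`` each partial is
    verified against a central finite difference with step
    ``fd_rel_step * box width``; disagreement raises ``PSFError``.
    """
    if targets is None:
        targets = primitive_targets(model)
    alpha0 = alpha_at(model, env_value)
    a = alpha0.alpha
    base = compute_metrics(alpha0)
    if not base.defined:
        raise PSFError(
            "baseline metrics are undefined (some alpha >= 0); "
            "use oat_sweep to map the defined region instead"
        )
    rho, f = base.rho, base.fitness_ratio_BA

    out = []
    for target in targets:
        d = _dalpha(model, target, env_value)
        # signs: + for numerator entries of each metric, - for denominator
        drho = 0.5 * rho * (d[0, 1] / a[0, 1] + d[1, 0] / a[1, 0]
                            - d[0, 0] / a[0, 0] - d[1, 1] / a[1, 1])
        dfit = 0.5 * f * (d[0, 0] / a[0, 0] + d[0, 1] / a[0, 1]
                          - d[1, 1] / a[1, 1] - d[1, 0] / a[1, 0])
        d_nd = -drho
        if check:
            kind = parse_address(target)[0]
            lo, hi = DEFAULT_BOX_BY_KIND[kind]
            h = fd_rel_step * (hi - lo)
            spec_like = SweepSpec(target, model, min=-1.0, max=1.0,
                                  env_value=env_value)
            p0 = (get_parameter(model, target) if kind != "m"
                  else _baseline_feedback(model, env_value)[
                      model.plant_index(parse_address(target)[1]),
                      model.plant_index(parse_address(target)[2])])
            m_hi = compute_metrics(_alpha_for(spec_like, p0 + h))
            m_lo = compute_metrics(_alpha_for(spec_like, p0 - h))
            if not (m_hi.defined and m_lo.defined):
                raise PSFError(
                    f"finite-difference check for {target!r} crossed the "
                    "definedness boundary; use oat_sweep instead"
                )
            for closed, fd in (
                (d_nd, (m_hi.niche_difference - m_lo.niche_difference) / (2 * h)),
                (dfit, (m_hi.fitness_ratio_BA - m_lo.fitness_ratio_BA) / (2 * h)),
            ):
                scale = max(abs(closed), abs(fd), 1e-12)
                if abs(closed - fd) > fd_rtol * scale:
                    raise PSFError(
                        f"closed-form partial for {target!r} disagrees with "
                        f"finite difference: {closed:.6g} vs {fd:.6g}"
                    )
        out.append(SensitivityIndex(target, d_niche_difference=d_nd,
                                    d_fitness_ratio=dfit))
    return out


# -- global (sampling-based) screen -----------------------------------------


def global_screen(
    model: PSFModel,
    boxes: dict[str, tuple[float, float]] | None = None,
    n_samples: int = 8192,
    seed: int = 0,
    metric: str = "fitness_ratio_BA",
    n_bins: int = 20,
    env_value: float = 0.0,
) -> pd.DataFrame:
    """Variance-based first-order importance of each parameter.

    Latin hypercube samples are drawn jointly over the boxes; for each target
    the samples are split into ``n_bins`` equal-width bins of that parameter
    and the first-order index is Var(binned conditional means) / Var(metric).
    Samples whose metrics are undefined are excluded and their fraction is
    reported in ``attrs['undefined_fraction']``.  Deterministic given
    ``seed``.  The binned-conditional-means estimator is an implementer
    choice (recorded in ``attrs['method']``).

    The fitness ratio is heavy-tailed near the definedness boundary (it
    diverges as an interspecific coefficient approaches zero), so index
    estimates need several thousand samples to stabilise; the default
    ``n_samples`` is chosen accordingly.
    """
    if n_samples < 100:
        raise ConfigurationError("global_screen needs n_samples >= 100")
    if boxes is None:
        boxes = default_boxes(model)
    targets = list(boxes)
    lo = np.array([boxes[t][0] for t in targets])
    hi = np.array([boxes[t][1] for t in targets])
    sampler = qmc.LatinHypercube(d=len(targets), seed=int(seed))
    unit = sampler.random(n_samples)
    samples = lo + unit * (hi - lo)

    values = np.empty(n_samples)
    for s in range(n_samples):
        m = model
        for t, x in zip(targets, samples[s]):
            m = with_parameter(m, t, x)
        met = compute_metrics(alpha_at(m, env_value))
        values[s] = getattr(met, {
            "rho": "rho",
            "niche_difference": "niche_difference",
            "fitness_ratio_BA": "fitness_ratio_BA",
            "fitness_inequality": "fitness_inequality",
        }[metric]) if met.defined else math.nan

    ok = np.isfinite(values)
    if not ok.any():
        raise PSFError("all samples produced undefined metrics")
    y = values[ok]
    total_var = float(np.var(y))
    rows = []
    for k, t in enumerate(targets):
        x = samples[ok, k]
        if hi[k] == lo[k] or total_var == 0.0:
            rows.append({"target": t, "first_order_index": 0.0})
            continue
        edges = np.linspace(lo[k], hi[k], n_bins + 1)
        idx = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
        means, weights = [], []
        for b in range(n_bins):
            mask = idx == b
            if mask.any():
                means.append(y[mask].mean())
                weights.append(mask.sum())
        means = np.array(means)
        weights = np.array(weights, dtype=float)
        grand = np.average(means, weights=weights)
        between = float(np.average((means - grand) ** 2, weights=weights))
        rows.append({"target": t, "first_order_index": between / total_var})
    df = pd.DataFrame(rows).sort_values(
        "first_order_index", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    df.attrs["undefined_fraction"] = float(1.0 - ok.mean())
    df.attrs["metric"] = metric
    df.attrs["method"] = (
        "Latin hypercube + variance of binned conditional means "
        f"({n_bins} bins); implementer-chosen protocol"
    )
    return df
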