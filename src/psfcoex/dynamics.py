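"""Coupled plant-microbe ODE dynamics and invasion analysis.

The full system couples two competing plant populations to any number of
microbial taxa:

    dN_i/dt = r_i N_i (1 + c_ii N_i + c_ij N_j + sum_X sigma_iX S_X)
    dS_X/dt = g_X S_X (1 - S_X / k_X),   k_X = phi_XA N_A + phi_XB N_B

Each microbe grows logistically towards a carrying capacity set by the
plants that cultivate it.  When the microbes are at quasi-equilibrium
(S_X = k_X) the plant equations collapse to plain Lotka-Volterra with
effective coefficients alpha_ij = c_ij + sum_X sigma_iX phi_Xj, which is why
equilibria and invasion growth rates depend on alpha only and never on g_X.
This module provides the numerical half of that argument: integrating the
full system and checking it against the algebraic predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import IntegrationError, UnboundedGrowthError
from .model import AlphaMatrix, PSFModel, ResolvedParameters, resolve_parameters

__all__ = [
    "CommunityState",
    "Trajectory",
    "EquilibriumResult",
    "derivatives",
    "integrate",
    "coexistence_equilibrium",
    "invasion_growth_rate",
]

#: below this carrying capacity the logistic term degenerates to pure decay
K_EPSILON = 1e-12


@dataclass(frozen=True)
class CommunityState:
    """Plant and microbe abundances at one time point."""

    N: np.ndarray
    S: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "N", np.asarray(self.N, dtype=float))
        object.__setattr__(self, "S", np.atleast_1d(np.asarray(self.S, dtype=float)))

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.N, self.S])


@dataclass
class Trajectory:
    """Integrated states on an output grid, with provenance metadata."""

    times: np.ndarray
    N: np.ndarray                      # (n_times, 2)
    S: np.ndarray                      # (n_times, n_microbes)
    plant_labels: tuple[str, str]
    microbe_labels: tuple[str, ...]
    env_value: float | None = None
    model_name: str = ""
    converged: bool | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def final_state(self) -> CommunityState:
        return CommunityState(self.N[-1], self.S[-1], float(self.times[-1]))

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.times}
        for j, lab in enumerate(self.plant_labels):
            data[f"N_{lab}"] = self.N[:, j]
        for k, lab in enumerate(self.microbe_labels):
            data[f"S_{lab}"] = self.S[:, k]
        return pd.DataFrame(data)


def _rhs(y: np.ndarray, r, c, g, sigma, phi) -> np.ndarray:
    N = y[:2]
    S = y[2:]
    # trial steps of adaptive solvers may probe extreme states; overflow
    # there is resolved by step-size control, not an error
    with np.errstate(over="ignore", invalid="ignore"):
        dN = r * N * (1.0 + c @ N + sigma @ S)
        k = phi @ N if len(S) else np.zeros(0)
        dS = np.empty_like(S)
        small = k <= K_EPSILON
        # logistic towards plant-set capacity; pure decay when capacity vanishes
        dS[~small] = g[~small] * S[~small] * (1.0 - S[~small] / k[~small])
        dS[small] = -g[small] * S[small]
    return np.concatenate([dN, dS])


def derivatives(state: CommunityState, resolved: ResolvedParameters) -> np.ndarray:
    """Rate of change (dN_A, dN_B, dS_X...) at the given state."""
    r = np.array(resolved.plants.r)
    c = resolved.plants.c
    g = np.array([t.g for t in resolved.microbes])
    return _rhs(state.as_vector(), r, c, g,
                resolved.sigma_matrix(), resolved.phi_matrix())


def integrate(
    model: PSFModel,
    v: float,
    init: CommunityState,
    t_end: float,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "Radau",
) -> Trajectory:
    """Integrate the full plant-microbe system from ``init`` to ``t_end``.

    The default integrator is the implicit adaptive Radau method: extinction
    trajectories drive a microbe's carrying capacity towards zero, which
    makes its logistic term arbitrarily stiff, and explicit or
    auto-switching methods can step over the decay and blow up there.  Any
    ``scipy.integrate.solve_ivp`` method name may be passed instead.  Tiny
    negative overshoots below the absolute tolerance are clipped to zero so
    reported abundances are always non-negative.  ``converged`` reports
    whether max|dy/dt| < 1e-8 at the final state.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    resolved = resolve_parameters(model, v)
    if len(init.S) != len(resolved.microbes):
        raise ValueError(
            f"init has {len(init.S)} microbe abundances, model has "
            f"{len(resolved.microbes)}"
        )
    r = np.array(resolved.plants.r)
    c = resolved.plants.c
    g = np.array([t.g for t in resolved.microbes])
    sigma = resolved.sigma_matrix()
    phi = resolved.phi_matrix()

    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 201)
    sol = solve_ivp(
        lambda t, y: _rhs(y, r, c, g, sigma, phi),
        (0.0, float(t_end)),
        init.as_vector(),
        t_eval=np.asarray(t_eval, dtype=float),
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        finite = np.all(np.isfinite(sol.y), axis=0) if sol.t.size else np.array([])
        idx = int(np.argmax(~finite)) - 1 if sol.t.size and not finite.all() else -1
        last_t = sol.t[idx] if sol.t.size else 0.0
        last_y = sol.y[:, idx] if sol.t.size else init.as_vector()
        reason = sol.message if not sol.success else "non-finite state"
        raise IntegrationError(
            f"integration failed at t={last_t:g}: {reason}",
            last_state=last_y, last_time=last_t,
        )
    y = sol.y.T.copy()
    y[(y < 0) & (y > -atol)] = 0.0
    final_rate = _rhs(y[-1], r, c, g, sigma, phi)
    return Trajectory(
        times=sol.t,
        N=y[:, :2],
        S=y[:, 2:],
        plant_labels=resolved.plants.labels,
        microbe_labels=tuple(t.label for t in resolved.microbes),
        env_value=float(v),
        model_name=model.name,
        converged=bool(np.max(np.abs(final_rate), initial=0.0) < 1e-8),
        metadata={"method": method, "rtol": rtol, "atol": atol},
    )


@dataclass(frozen=True)
class EquilibriumResult:
    feasible: bool
    N: np.ndarray | None = None
    reason: str = ""


def coexistence_equilibrium(alpha: AlphaMatrix,
                            tol: float = 1e-12) -> EquilibriumResult:
    """Interior fixed point of the reduced plant system, if feasible.

    Solves ``1 + alpha N* = 0``.  Infeasible when the matrix is singular
    (within ``tol`` on the scaled determinant) or when any component of the
    solution is non-positive.
    """
    a = alpha.alpha
    if a[0, 0] >= 0 or a[1, 1] >= 0:
        raise UnboundedGrowthError(
            "coexistence equilibrium requires self-limitation "
            f"(alpha diag ({a[0, 0]:g}, {a[1, 1]:g}))"
        )
    det = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
    scale = max(np.max(np.abs(a)) ** 2, 1e-300)
    if abs(det) <= tol * scale:
        return EquilibriumResult(False, None, "singular alpha matrix")
    N = np.linalg.solve(a, [-1.0, -1.0])
    if np.any(N <= 0):
        return EquilibriumResult(False, None,
                                 f"non-positive equilibrium abundance {N}")
    return EquilibriumResult(True, N)


def microbe_equilibrium(resolved: ResolvedParameters, N: np.ndarray) -> np.ndarray:
    """Quasi-equilibrium microbe abundances S*_X = phi_XA N_A + phi_XB N_B."""
    return resolved.phi_matrix() @ np.asarray(N, dtype=float)


def invasion_growth_rate(invader: int | str, alpha: AlphaMatrix,
                         r: tuple[float, float] = (1.0, 1.0)) -> float:
    """Per-capita growth of a rare invader against the other's monoculture.

    The resident j sits at ``N_j* = -1/alpha_jj`` with its microbes at
    quasi-equilibrium; a rare invader i then grows at
    ``r_i (1 - alpha_ij / alpha_jj)``.  Positive means i can invade.
    """
    if isinstance(invader, str):
        invader = list(alpha.labels).index(invader)
    if invader not in (0, 1):
        raise ValueError("invader must identify one of the two plants")
    j = 1 - invader
    a = alpha.alpha
    if a[j, j] >= 0:
        raise UnboundedGrowthError(
            f"resident {alpha.labels[j]!r} lacks self-limitation "
            f"(alpha_jj = {a[j, j]:g})"
        )
    return r[invader] * (1.0 - a[invader, j] / a[j, j])
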