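"""Optional figures: the coexistence plane and trajectory panels.

Plots are human aids only; nothing downstream depends on them.
"""

from __future__ import annotations

import numpy as np

__all__ = ["coexistence_plane", "plot_gradient", "plot_trajectory"]


def _axes(ax=None):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    return ax


def coexistence_plane(ax=None, nd_range=(-0.5, 1.0)):
    """Draw the niche-difference / fitness-ratio plane with region borders.

    Coexistence requires ``rho < f_B/f_A < 1/rho``; the two curves
    ``f = 1 - ND`` and ``f = 1/(1 - ND)`` bound the coexistence wedge for
    ND > 0 and the priority-effects wedge for ND < 0.
    """
    ax = _axes(ax)
    nd = np.linspace(*nd_range, 400)
    rho = 1.0 - nd
    with np.errstate(divide="ignore"):
        ax.plot(nd, rho, "k-", lw=1)
        ax.plot(nd, np.where(rho > 0, 1.0 / rho, np.nan), "k-", lw=1)
    ax.axhline(1.0, color="0.8", lw=0.5)
    ax.axvline(0.0, color="0.8", lw=0.5)
    ax.set_xlabel("niche difference (1 - rho)")
    ax.set_ylabel("fitness ratio f_B / f_A")
    ax.set_yscale("log")
    return ax


def plot_gradient(table, ax=None):
    """Metrics of a gradient table on the coexistence plane, colored by v."""
    ax = coexistence_plane(ax)
    ok = table["defined"]
    sc = ax.scatter(table.loc[ok, "niche_difference"],
                    table.loc[ok, "fitness_ratio_BA"],
                    c=table.loc[ok, "env_value"], s=12, cmap="viridis")
    ax.figure.colorbar(sc, ax=ax, label="environment value")
    return ax


def plot_trajectory(traj, ax=None):
    ax = _axes(ax)
    frame = traj.to_frame()
    for col in frame.columns[1:]:
        style = "-" if col.startswith("N_") else "--"
        ax.plot(frame["t"], frame[col], style, label=col)
    ax.set_xlabel("time")
    ax.set_ylabel("abundance")
    ax.legend(fontsize=8)
    return ax
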