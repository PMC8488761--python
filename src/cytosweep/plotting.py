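"""Optional plotting layer: trajectory line plots and sweep heatmaps.

Figures are conveniences rendered from the in-memory results (or their
CSVs); the tested artifacts are the CSV tables themselves.
"""

from __future__ import annotations

import numpy as np

from .experiments import Sweep, Trajectory

__all__ = ["plot_trajectory", "plot_sweep"]

_CYTOTYPE_LABELS = {
    "p": "resident mitotype + symbiont",
    "q": "resident mitotype, uninfected",
    "r": "novel mitotype + symbiont",
    "s": "novel mitotype, uninfected",
}


def plot_trajectory(traj: Trajectory, ax=None):
    """Four cytotype frequencies against time, with the pre-invasion symbiont
    equilibrium as a dashed reference line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for comp, label in _CYTOTYPE_LABELS.items():
        ax.plot(traj.frame["generation"], traj.frame[comp], label=label)
    ax.axhline(traj.baseline, ls="--", color="0.4", lw=1,
               label="baseline symbiont equilibrium")
    ax.set_xlabel("generation")
    ax.set_ylabel("frequency")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize="small")
    return ax


def plot_sweep(sweep: Sweep, value: str = "mutant_final", ax=None):
    """Heatmap of a per-cell quantity (default: final novel-mitotype
    frequency N* = r* + s*) over the sweep grid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    v1 = sweep.axis1.values()
    v2 = sweep.axis2.values()
    grid = np.asarray(sweep.frame[value], dtype=float).reshape(len(v1), len(v2))
    mesh = ax.pcolormesh(v1, v2, grid.T, shading="nearest", vmin=0.0, vmax=1.0)
    ax.figure.colorbar(mesh, ax=ax, label=value)
    ax.set_xlabel(sweep.axis1.name)
    ax.set_ylabel(sweep.axis2.name)
    return ax
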