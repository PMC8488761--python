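"""Figure-style data artifacts: time-course trajectories and phase-diagram
parameter sweeps, written as tidy CSV tables.

A *trajectory* records the four cytotype frequencies every generation while a
rare novel mitotype invades (or fails to invade) a population at the resident
symbiont equilibrium.  A *sweep* classifies the long-run invasion outcome on
a 2-D parameter grid — typically segregational loss ``mu`` against mitotype
benefit ``t`` — recording the pre-invasion symbiont equilibrium and the final
novel-mitotype frequency ``N* = r* + s*`` per cell.  Sweep cells are
independent; they are simulated in lockstep as NumPy arrays, with converged
cells retired from the active set as they settle, and the output is sorted by
the axes so results are order-stable and byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import __version__
from .equilibria import resident_equilibrium
from .invasion import (
    DEFAULT_EPSILON,
    EPS_EXTINCT,
    EPS_FIX,
    INDETERMINATE,
    MITOTYPE_FIXED_SYMBIONT_EXCLUDED,
    MITOTYPE_FIXED_SYMBIONT_RETAINED,
    MITOTYPE_LOST,
    COEXISTENCE_PARTITIONED,
    NEUTRAL_BAND,
    PRESENCE_FLOOR,
    introduce_mutant,
)
from .models import (
    ModelParams,
    model_name,
    params_to_dict,
    step,
    step_arrays,
)

__all__ = [
    "AxisSpec",
    "Trajectory",
    "Sweep",
    "SYMBIONT_ABSENT",
    "ORIGIN_EMPTY",
    "run_trajectory",
    "run_sweep",
    "write_trajectory_csv",
    "write_sweep_csv",
]

SYMBIONT_ABSENT = "symbiont_absent"  #: the symbiont cannot persist in this cell
ORIGIN_EMPTY = "origin_empty"  #: the origin compartment is empty at equilibrium

DEFAULT_SWEEP_HORIZON = 300_000


class AxisSpec(NamedTuple):
    """A sweep axis: parameter ``name`` swept over ``n`` evenly spaced values
    in [lo, hi]."""

    name: str
    lo: float
    hi: float
    n: int

    def values(self) -> np.ndarray:
        if self.n < 1:
            raise ValueError(f"axis {self.name!r} must have n >= 1, got {self.n}")
        if self.hi < self.lo:
            raise ValueError(f"axis {self.name!r} has hi < lo")
        return np.linspace(self.lo, self.hi, self.n)


@dataclass(frozen=True)
class Trajectory:
    """Per-generation cytotype frequencies of one invasion run."""

    frame: pd.DataFrame
    baseline: float  #: pre-invasion resident symbiont equilibrium (dashed line)
    params: ModelParams
    origin: str
    epsilon: float
    converged: bool


@dataclass(frozen=True)
class Sweep:
    """Invasion outcomes over a 2-D parameter grid."""

    frame: pd.DataFrame
    axis1: AxisSpec
    axis2: AxisSpec
    fixed: dict
    origin: str
    epsilon: float


def run_trajectory(
    params: ModelParams,
    origin: str,
    epsilon: float = DEFAULT_EPSILON,
    horizon: int = 10**6,
    tol: float = 1e-12,
) -> Trajectory:
    """Record every generation of an invasion run started from the resident
    equilibrium perturbed by ``introduce_mutant``.

    Recording stops once successive states differ by less than ``tol``
    (max-norm) or at ``horizon``.  With ``epsilon = 0`` the trajectory is flat
    at the resident equilibrium.
    """
    eq = resident_equilibrium(params)
    state = introduce_mutant(eq.point, origin, epsilon)
    rows = [(0, state.p, state.q, state.r, state.s)]
    converged = False
    for gen in range(1, horizon + 1):
        nxt = step(state, params)
        rows.append((gen, nxt.p, nxt.q, nxt.r, nxt.s))
        delta = max(
            abs(nxt.p - state.p),
            abs(nxt.q - state.q),
            abs(nxt.r - state.r),
            abs(nxt.s - state.s),
        )
        state = nxt
        if delta < tol:
            converged = True
            break
    frame = pd.DataFrame(rows, columns=["generation", "p", "q", "r", "s"])
    frame["symbiont_freq"] = frame["p"] + frame["r"]
    frame["mutant_freq"] = frame["r"] + frame["s"]
    return Trajectory(frame, eq.p_star, params, origin, epsilon, converged)


# ---------------------------------------------------------------------------
# Vectorised sweep machinery
# ---------------------------------------------------------------------------

def _equilibrium_arrays(model: str, f: dict[str, np.ndarray]):
    """Pre-invasion symbiont equilibrium and persistence mask, elementwise.

    Returns ``(p_eq, persist)``; ``p_eq`` is NaN where the symbiont cannot
    persist.  For the CI model the equilibrium is the upper stable point E3.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        if model == "i":
            B, mu = f["B"], f["mu"]
            persist = (B > 0) & (mu < B / (1.0 + B))
            p_eq = np.where(persist, 1.0 - (1.0 + B) * mu / np.where(B != 0, B, np.nan), np.nan)
        elif model == "ii":
            b, c, mu = f["b"], f["c"], f["mu"]
            net = b - c
            persist = (net > 0) & (mu < net / (1.0 + net)) & (b > 0)
            disc = c * c + b * mu * (4.0 + b * mu - 2.0 * c)
            p_eq = np.where(
                persist,
                (b * (2.0 - mu) - c - np.sqrt(np.maximum(disc, 0.0)))
                / np.where(b != 0, 2.0 * b, np.nan),
                np.nan,
            )
        else:
            h, mu = f["h"], f["mu"]
            disc = h * h - 4.0 * h * mu * (1.0 - mu)
            # strict feasibility of E3: mu below the tangency bound
            persist = (h > 0) & (mu < (1.0 - np.sqrt(1.0 - h)) / 2.0) & (disc > 0)
            p_eq = np.where(
                persist,
                (h + np.sqrt(np.maximum(disc, 0.0)))
                / np.where(h != 0, 2.0 * h * (1.0 - mu), np.nan),
                np.nan,
            )
    return p_eq, persist


def _growth_factor_arrays(model: str, f: dict, p_eq: np.ndarray, origin: str):
    """Linearised rare-mutant growth factor per cell (NaN where no
    equilibrium)."""
    t = f["t"]
    lam_r = 1.0 + t
    if model == "i":
        wbar = p_eq * (1.0 + f["B"]) + (1.0 - p_eq)
        lam_s = (1.0 + t) / wbar
    elif model == "ii":
        w = 1.0 + f["b"] * (1.0 - p_eq) - f["c"]
        lam_s = (1.0 + t) / (p_eq * w + (1.0 - p_eq))
    else:
        phi = 1.0 - f["h"] * p_eq * (1.0 - p_eq * (1.0 - f["mu"]))
        lam_s = (1.0 + t) * (1.0 - f["h"] * p_eq) / phi
    return lam_s if origin == "uninfected" else np.maximum(lam_r, lam_s)


def _simulate_cells(model, fields, p0, q0, r0, s0, horizon, tol):
    """Iterate all cells in lockstep until each settles (per-generation
    max-norm change < tol) or the horizon is hit.

    Converged cells are compacted out of the active arrays so a few slow
    near-boundary cells do not keep the whole grid stepping.
    """
    n = p0.size
    finals = np.empty((4, n))
    gens = np.full(n, horizon, dtype=np.int64)
    conv = np.zeros(n, dtype=bool)
    active = np.arange(n)
    p, q, r, s = p0.copy(), q0.copy(), r0.copy(), s0.copy()
    f = {k: np.asarray(v, dtype=float).copy() for k, v in fields.items()}
    gen = 0
    while active.size and gen < horizon:
        gen += 1
        p2, q2, r2, s2 = step_arrays(model, p, q, r, s, f)
        delta = np.abs(p2 - p)
        np.maximum(delta, np.abs(q2 - q), out=delta)
        np.maximum(delta, np.abs(r2 - r), out=delta)
        np.maximum(delta, np.abs(s2 - s), out=delta)
        p, q, r, s = p2, q2, r2, s2
        done = delta < tol
        if done.any():
            idx = active[done]
            finals[0, idx], finals[1, idx] = p[done], q[done]
            finals[2, idx], finals[3, idx] = r[done], s[done]
            gens[idx] = gen
            conv[idx] = True
            keep = ~done
            active = active[keep]
            p, q, r, s = p[keep], q[keep], r[keep], s[keep]
            f = {k: v[keep] for k, v in f.items()}
    if active.size:
        finals[0, active], finals[1, active] = p, q
        finals[2, active], finals[3, active] = r, s
    return finals, gens, conv


def _classify_cells(finals, conv) -> np.ndarray:
    floor = max(EPS_EXTINCT, EPS_FIX, PRESENCE_FLOOR)
    mutant = finals[2] + finals[3]
    symbiont = finals[0] + finals[2]
    out = np.full(mutant.size, INDETERMINATE, dtype=object)
    out[mutant < floor] = MITOTYPE_LOST
    fixed = (1.0 - mutant) < floor  # ancestral mitotype gone
    out[fixed & (symbiont < floor)] = MITOTYPE_FIXED_SYMBIONT_EXCLUDED
    out[fixed & (symbiont >= floor)] = MITOTYPE_FIXED_SYMBIONT_RETAINED
    middle = ~fixed & (mutant >= floor)
    out[middle & conv] = COEXISTENCE_PARTITIONED
    out[middle & ~conv] = INDETERMINATE
    return out


def run_sweep(
    params: ModelParams,
    axis1: AxisSpec,
    axis2: AxisSpec,
    origin: str,
    epsilon: float = DEFAULT_EPSILON,
    horizon: int = DEFAULT_SWEEP_HORIZON,
    tol: float = 1e-12,
) -> Sweep:
    """Classify invasion outcomes over a 2-D grid of parameter values.

    ``params`` supplies the fixed parameters; ``axis1``/``axis2`` name the two
    fields swept (e.g. ``mu`` and ``t``).  Cells where the symbiont cannot
    persist are marked ``symbiont_absent``; cells whose origin compartment is
    empty at equilibrium are marked ``origin_empty``; cells whose linearised
    growth factor sits within the neutral band of 1 are reported
    ``indeterminate``.  Rows are sorted by (axis1, axis2).
    """
    model = model_name(params)
    base = params_to_dict(params)
    for ax in (axis1, axis2):
        if ax.name not in base:
            raise ValueError(
                f"axis {ax.name!r} is not a parameter of model {model} "
                f"(expected one of {sorted(base)})"
            )
    if axis1.name == axis2.name:
        raise ValueError("the two sweep axes must name different parameters")
    v1, v2 = axis1.values(), axis2.values()
    a1, a2 = np.meshgrid(v1, v2, indexing="ij")
    a1, a2 = a1.ravel(), a2.ravel()
    n = a1.size
    fields = {k: np.full(n, v) for k, v in base.items()}
    fields[axis1.name] = a1
    fields[axis2.name] = a2
    # validate swept values through the parameter class (first/last suffice
    # for range checks on an affine grid)
    for i in (0, n - 1):
        replace(params, **{axis1.name: a1[i], axis2.name: a2[i]})

    p_eq, persist = _equilibrium_arrays(model, fields)
    q_eq = 1.0 - p_eq
    origin_comp = p_eq if origin == "infected" else q_eq
    empty = persist & ~(origin_comp >= epsilon)
    simulate = persist & ~empty

    gf = np.where(persist, _growth_factor_arrays(model, fields, p_eq, origin), np.nan)

    outcome = np.full(n, SYMBIONT_ABSENT, dtype=object)
    outcome[empty] = ORIGIN_EMPTY
    finals = np.full((4, n), np.nan)
    gens = np.zeros(n, dtype=np.int64)
    idx = np.flatnonzero(simulate)
    if idx.size:
        eps = epsilon
        p0 = p_eq[idx] - (eps if origin == "infected" else 0.0)
        q0 = q_eq[idx] - (eps if origin == "uninfected" else 0.0)
        r0 = np.full(idx.size, eps if origin == "infected" else 0.0)
        s0 = np.full(idx.size, eps if origin == "uninfected" else 0.0)
        sub_fields = {k: v[idx] for k, v in fields.items()}
        fin, g, conv = _simulate_cells(model, sub_fields, p0, q0, r0, s0, horizon, tol)
        finals[:, idx] = fin
        gens[idx] = g
        labels = _classify_cells(fin, conv)
        labels[np.abs(gf[idx] - 1.0) < NEUTRAL_BAND] = INDETERMINATE
        outcome[idx] = labels

    frame = pd.DataFrame(
        {
            axis1.name: a1,
            axis2.name: a2,
            "symbiont_eq": p_eq,
            "growth_factor": gf,
            "outcome": outcome,
            "mutant_final": finals[2] + finals[3],
            "symbiont_final": finals[0] + finals[2],
            "generations": gens,
        }
    )
    fixed = {k: v for k, v in base.items() if k not in (axis1.name, axis2.name)}
    return Sweep(frame, axis1, axis2, fixed, origin, epsilon)


# ---------------------------------------------------------------------------
# CSV output
# ---------------------------------------------------------------------------

def _header_lines(kind: str, params_dict: dict, origin: str, epsilon: float,
                  extra: dict) -> list[str]:
    lines = [
        f"# cytosweep {kind} v{__version__}",
        "# params: " + ", ".join(f"{k}={v:.12g}" for k, v in params_dict.items()),
        f"# origin: {origin}",
        f"# epsilon: {epsilon:.12g}",
        f"# thresholds: eps_extinct={EPS_EXTINCT:.12g}, eps_fix={EPS_FIX:.12g}",
    ]
    for k, v in extra.items():
        lines.append(f"# {k}: {v}")
    return lines


def _write_csv(path, header: list[str], frame: pd.DataFrame) -> None:
    try:
        with open(path, "w", newline="") as fh:
            fh.write("\n".join(header) + "\n")
            frame.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")
    except OSError as err:
        raise OSError(f"cannot write CSV to {path!r}: {err}") from err


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """Tidy CSV, one row per generation, with a commented header block."""
    header = _header_lines(
        f"trajectory model={model_name(traj.params)}",
        params_to_dict(traj.params),
        traj.origin,
        traj.epsilon,
        {"baseline_symbiont_eq": f"{traj.baseline:.12g}",
         "converged": traj.converged},
    )
    _write_csv(path, header, traj.frame)


def write_sweep_csv(sweep: Sweep, path) -> None:
    """Tidy CSV, one row per grid cell, sorted by (axis1, axis2)."""
    ax1, ax2 = sweep.axis1, sweep.axis2
    header = _header_lines(
        "sweep",
        sweep.fixed,
        sweep.origin,
        sweep.epsilon,
        {
            "axis1": f"{ax1.name} in [{ax1.lo:.12g}, {ax1.hi:.12g}] n={ax1.n}",
            "axis2": f"{ax2.name} in [{ax2.lo:.12g}, {ax2.hi:.12g}] n={ax2.n}",
        },
    )
    _write_csv(path, header, sweep.frame)
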