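"""Closed-form equilibria and persistence criteria of the resident subsystem.

With the novel mitotype absent (r = s = 0) each model reduces to a single
recursion in the symbiont frequency p.  The equilibria are:

* Model i  — p* = 0 and p* = 1 - (1 + B) mu / B; the interior point is
  stable iff mu < B / (1 + B) (the symbiont-persistence criterion).
* Model ii — p* = 0 and the polymorphic root
  p* = (b(2 - mu) - c - sqrt(c^2 + b mu (4 + b mu - 2 c))) / (2 b),
  stable iff mu < (b - c) / (1 + b - c).
* Model iii (CI) — E1: p* = 0 (always stable), and the pair
  E2/E3: p* = (h -/+ sqrt(h^2 - 4 h mu (1 - mu))) / (2 h (1 - mu)),
  real iff mu <= (1 - sqrt(1 - h)) / 2.  E2 is the unstable separatrix of the
  bistable CI dynamics: only initial frequencies above E2 reach the stable
  upper equilibrium E3.

`find_fixed_point` is the model-agnostic numerical oracle used throughout the
test-suite to confirm the closed forms by direct iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

from .models import (
    CIParams,
    CytotypeState,
    FixedBenefitParams,
    FreqDepParams,
    ModelParams,
    model_name,
)

__all__ = [
    "EquilibriumResult",
    "FixedPointResult",
    "ConvergenceError",
    "NoResidentEquilibriumError",
    "equilibrium_model_i",
    "equilibrium_model_ii",
    "equilibrium_model_iii",
    "equilibria",
    "resident_equilibrium",
    "persistence_mu_max",
    "find_fixed_point",
]

# Equilibria this close to 0 or 1 are snapped to the boundary to avoid
# spurious "polymorphic" classifications from roundoff.
_SNAP_TOL = 1e-9

TRIVIAL = "trivial"
INTERNAL_STABLE = "internal_stable"
INTERNAL_UNSTABLE = "internal_unstable"


class NoResidentEquilibriumError(Exception):
    """The symbiont cannot persist: no stable interior resident equilibrium."""


class ConvergenceError(Exception):
    """Fixed-point iteration did not converge; carries the last state."""

    def __init__(self, message: str, last_state: CytotypeState, generations: int):
        super().__init__(message)
        self.last_state = last_state
        self.generations = generations


@dataclass(frozen=True)
class EquilibriumResult:
    """A resident-subsystem equilibrium with feasibility/stability flags.

    ``stable`` is ``None`` when indeterminate (e.g. exactly on a stability
    boundary).
    """

    p_star: float
    feasible: bool
    stable: Optional[bool]
    kind: str

    @property
    def point(self) -> CytotypeState:
        return CytotypeState.resident(self.p_star)


def _snap(p: float) -> float:
    if abs(p) < _SNAP_TOL:
        return 0.0
    if abs(p - 1.0) < _SNAP_TOL:
        return 1.0
    return p


def persistence_mu_max(params: ModelParams) -> float:
    """Largest segregational-loss rate compatible with symbiont persistence.

    Model i: B/(1+B); Model ii: (b-c)/(1+b-c); Model iii: (1-sqrt(1-h))/2
    (for CI this bounds *feasibility* of E3; persistence additionally needs
    the initial frequency above the separatrix E2).
    """
    name = model_name(params)
    if name == "i":
        return params.B / (1.0 + params.B) if params.B > 0 else 0.0
    if name == "ii":
        net = params.b - params.c
        return net / (1.0 + net) if net > 0 else 0.0
    return (1.0 - math.sqrt(1.0 - params.h)) / 2.0


def equilibrium_model_i(params: FixedBenefitParams) -> list[EquilibriumResult]:
    """Both equilibria of the Model-i resident subsystem."""
    B, mu = params.B, params.mu
    crit = persistence_mu_max(params)
    interior_exists = B != 0.0
    # p* = 0 is stable exactly when the interior equilibrium is not.
    trivial_stable = None if (interior_exists and mu == crit) else (not interior_exists or mu > crit)
    out = [EquilibriumResult(0.0, True, trivial_stable, TRIVIAL)]
    if not interior_exists:
        return out
    p_star = _snap(1.0 - (1.0 + B) * mu / B)
    feasible = 0.0 <= p_star <= 1.0
    stable = None if mu == crit else mu < crit
    kind = INTERNAL_STABLE if stable else INTERNAL_UNSTABLE
    if p_star == 0.0:
        kind = TRIVIAL
    out.append(EquilibriumResult(p_star, feasible, stable, kind))
    return out


def equilibrium_model_ii(params: FreqDepParams) -> list[EquilibriumResult]:
    """Trivial and polymorphic equilibria of the Model-ii resident subsystem."""
    b, c, mu = params.b, params.c, params.mu
    crit = persistence_mu_max(params)
    trivial_stable = None if (b > 0 and mu == crit) else (b <= c or mu > crit)
    out = [EquilibriumResult(0.0, True, trivial_stable, TRIVIAL)]
    if b == 0.0:
        return out
    disc = c * c + b * mu * (4.0 + b * mu - 2.0 * c)
    root = math.sqrt(max(disc, 0.0))
    p_star = _snap((b * (2.0 - mu) - c - root) / (2.0 * b))
    feasible = 0.0 <= p_star <= 1.0
    stable = None if mu == crit else mu < crit
    kind = INTERNAL_STABLE if stable else INTERNAL_UNSTABLE
    if p_star == 0.0:
        kind = TRIVIAL
    out.append(EquilibriumResult(p_star, feasible, stable, kind))
    return out


def equilibrium_model_iii(params: CIParams) -> list[EquilibriumResult]:
    """E1, E2 (separatrix) and E3 (upper stable) of the CI resident subsystem.

    When the discriminant ``h^2 - 4 h mu (1 - mu)`` is negative the interior
    pair does not exist and only E1 is returned.
    """
    h, mu = params.h, params.mu
    out = [EquilibriumResult(0.0, True, True, TRIVIAL)]
    if h == 0.0 or mu >= 1.0:
        return out
    disc = h * h - 4.0 * h * mu * (1.0 - mu)
    if disc < 0.0:
        return out
    root = math.sqrt(disc)
    denom = 2.0 * h * (1.0 - mu)
    e2 = _snap((h - root) / denom)
    e3 = _snap((h + root) / denom)
    tangent = disc == 0.0
    out.append(
        EquilibriumResult(e2, 0.0 <= e2 <= 1.0, None if tangent else False,
                          TRIVIAL if e2 == 0.0 else INTERNAL_UNSTABLE)
    )
    out.append(
        EquilibriumResult(e3, 0.0 <= e3 <= 1.0, None if tangent else True,
                          INTERNAL_STABLE if not tangent else INTERNAL_UNSTABLE)
    )
    return out


def equilibria(params: ModelParams) -> list[EquilibriumResult]:
    """Resident-subsystem equilibria for whichever model ``params`` selects."""
    name = model_name(params)
    if name == "i":
        return equilibrium_model_i(params)
    if name == "ii":
        return equilibrium_model_ii(params)
    return equilibrium_model_iii(params)


def resident_equilibrium(params: ModelParams) -> EquilibriumResult:
    """The stable interior resident equilibrium (E3 for the CI model).

    Raises :class:`NoResidentEquilibriumError` when the symbiont cannot
    persist at these parameters.
    """
    best = None
    for eq in equilibria(params):
        if eq.kind == INTERNAL_STABLE and eq.feasible and eq.p_star > 0.0:
            best = eq
    if best is None:
        raise NoResidentEquilibriumError(
            f"symbiont cannot persist at {params!r} "
            f"(requires mu < {persistence_mu_max(params):.6g})"
        )
    return best


@dataclass(frozen=True)
class FixedPointResult:
    state: CytotypeState
    generations: int


def find_fixed_point(
    step: Callable[[CytotypeState], CytotypeState],
    initial: CytotypeState,
    tol: float = 1e-12,
    max_gen: int = 10**6,
) -> FixedPointResult:
    """Iterate a one-generation operator until successive states differ by
    less than ``tol`` in max-norm.

    Geometric convergence makes this cheap away from stability boundaries;
    near-tangent CI cases converge slowly, hence the large default
    ``max_gen``.  Raises :class:`ConvergenceError` (carrying the last state)
    on non-convergence.
    """
    if not tol > 0.0:
        raise ValueError("tol must be positive")
    state = initial
    for gen in range(1, max_gen + 1):
        nxt = step(state)
        delta = max(
            abs(nxt.p - state.p),
            abs(nxt.q - state.q),
            abs(nxt.r - state.r),
            abs(nxt.s - state.s),
        )
        state = nxt
        if delta < tol:
            return FixedPointResult(state, gen)
    raise ConvergenceError(
        f"no fixed point within {max_gen} generations (tol={tol})", state, max_gen
    )
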