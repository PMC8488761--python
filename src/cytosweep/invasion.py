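"""Invasion analysis of a rare novel mitotype at the resident equilibrium.

A beneficial mitochondrial mutation (benefit ``t``) arises in a single
individual that is either symbiont-infected (origin ``"infected"``, seeding
the r compartment) or uninfected (origin ``"uninfected"``, seeding s).  Near
the resident equilibrium the rare (r, s) subsystem is linear and triangular:
r feeds s through segregational loss but receives nothing back, so the two
per-generation multipliers are

    lambda_r = 1 + t                       (all three models)
    lambda_s = (1 + t) / W*                (Models i and ii)
    lambda_s = (1 + t)(1 - h p*) / Phi*    (Model iii, at E3)

where ``W*`` (resp. ``Phi*``) is the population mean fitness at the resident
equilibrium.  An infected-origin lineage therefore always invades when
``t > 0``; an uninfected-origin lineage invades only when its own multiplier
``lambda_s`` exceeds 1, which rearranges to the printed thresholds

    Model i  :  t > B (1 - mu) - mu
    Model ii :  t > (1 - mu)(1 + b (1 - p*) - c) - 1   (invasion)
                t > (1 + b - c)(1 - mu) - 1            (displacement)

`classify_invasion` runs the full nonlinear recursion and labels the long-run
outcome; the module also provides the two scans behind the headline claims:
the symbiont-prevalence bound below which a ``t = 0.02`` mitotype can exclude
the symbiont (Model i), and the largest CI strength at which such a mitotype
can invade from an uninfected host (Model iii).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equilibria import (
    ConvergenceError,
    NoResidentEquilibriumError,
    find_fixed_point,
    persistence_mu_max,
    resident_equilibrium,
)
from .models import (
    CIParams,
    CytotypeState,
    FixedBenefitParams,
    FreqDepParams,
    ModelParams,
    model_name,
    step,
)

__all__ = [
    "InvasionResult",
    "ImpossibleOriginError",
    "ORIGINS",
    "OUTCOMES",
    "introduce_mutant",
    "mutant_growth_factor",
    "threshold_t_model_i",
    "threshold_t_model_ii_displacement",
    "threshold_t_model_ii_invasion",
    "classify_invasion",
    "classify_outcome",
    "exclusion_prevalence_bound",
    "ci_invasion_ceiling",
]

ORIGINS = ("infected", "uninfected")

MITOTYPE_LOST = "mitotype_lost"
MITOTYPE_FIXED_SYMBIONT_EXCLUDED = "mitotype_fixed_symbiont_excluded"
MITOTYPE_FIXED_SYMBIONT_RETAINED = "mitotype_fixed_symbiont_retained"
COEXISTENCE_PARTITIONED = "coexistence_partitioned"
INDETERMINATE = "indeterminate"

OUTCOMES = (
    MITOTYPE_LOST,
    MITOTYPE_FIXED_SYMBIONT_EXCLUDED,
    MITOTYPE_FIXED_SYMBIONT_RETAINED,
    COEXISTENCE_PARTITIONED,
)

# Defaults for the deterministic invasion runs: the introduction frequency
# only sets transient length; extinction/fixation cutoffs sit well below it.
DEFAULT_EPSILON = 1e-5
EPS_EXTINCT = 1e-9
EPS_FIX = 1e-9
# A run is declared converged when the per-generation state change drops
# below tol, which can freeze a slowly decaying component at a residual of
# up to tol / decay-rate (~1e-8 for tol=1e-12 and rates down to 1e-4).  A
# compartment therefore only counts as occupied *at equilibrium* above this
# floor: two decades above the worst residual, two below the introduction
# frequency that any truly invading lineage must exceed.
PRESENCE_FLOOR = 1e-7
DEFAULT_HORIZON = 10**6
# Growth factors within this band of 1 are on the invasion boundary and the
# outcome is reported as indeterminate rather than forced into a class.
NEUTRAL_BAND = 1e-6


class ImpossibleOriginError(Exception):
    """The origin compartment is empty at the resident equilibrium."""


@dataclass(frozen=True)
class InvasionResult:
    """Outcome of introducing a rare novel mitotype at the resident
    equilibrium."""

    origin: str
    growth_factor: float
    outcome: str
    final_state: CytotypeState
    generations: int
    baseline: float  #: pre-invasion symbiont equilibrium frequency


def _check_origin(origin: str) -> None:
    if origin not in ORIGINS:
        raise ValueError(f"origin must be one of {ORIGINS}, got {origin!r}")


def introduce_mutant(
    resident_eq: CytotypeState, origin: str, epsilon: float = DEFAULT_EPSILON
) -> CytotypeState:
    """Move frequency ``epsilon`` from the origin compartment into the
    corresponding novel-mitotype compartment."""
    _check_origin(origin)
    if not 0.0 <= epsilon < 1.0:
        raise ValueError(f"epsilon must be in [0, 1), got {epsilon}")
    if resident_eq.r != 0.0 or resident_eq.s != 0.0:
        raise ValueError("resident equilibrium must have r = s = 0")
    if origin == "infected":
        if resident_eq.p < epsilon or (epsilon > 0 and resident_eq.p == 0.0):
            raise ImpossibleOriginError(
                f"no symbiont-infected hosts to mutate (p = {resident_eq.p})"
            )
        return CytotypeState(resident_eq.p - epsilon, resident_eq.q, epsilon, 0.0)
    if resident_eq.q < epsilon or (epsilon > 0 and resident_eq.q == 0.0):
        raise ImpossibleOriginError(
            f"no uninfected hosts to mutate (q = {resident_eq.q})"
        )
    return CytotypeState(resident_eq.p, resident_eq.q - epsilon, 0.0, epsilon)


def _rare_multipliers(params: ModelParams) -> tuple[float, float]:
    """(lambda_r, lambda_s) of the linearised rare subsystem at the resident
    equilibrium."""
    name = model_name(params)
    eq = resident_equilibrium(params)
    p = eq.p_star
    t = params.t
    if name == "i":
        wbar = p * (1.0 + params.B) + (1.0 - p)
        return 1.0 + t, (1.0 + t) / wbar
    if name == "ii":
        w = 1.0 + params.b * (1.0 - p) - params.c
        wbar = p * w + (1.0 - p)
        return 1.0 + t, (1.0 + t) / wbar
    phi = 1.0 - params.h * p * (1.0 - p * (1.0 - params.mu))
    return 1.0 + t, (1.0 + t) * (1.0 - params.h * p) / phi


def mutant_growth_factor(params: ModelParams, origin: str) -> float:
    """Dominant per-generation growth factor of the rare mutant lineage.

    Uninfected-origin lineages never re-enter the infected compartment, so
    their growth is the s-compartment multiplier alone; infected-origin
    lineages seed both compartments and grow at the dominant multiplier.
    """
    _check_origin(origin)
    lam_r, lam_s = _rare_multipliers(params)
    return lam_s if origin == "uninfected" else max(lam_r, lam_s)


def threshold_t_model_i(B: float, mu: float) -> float:
    """Uninfected-origin invasion threshold t = B(1 - mu) - mu (Model i)."""
    params = FixedBenefitParams(B=B, mu=mu)
    if mu >= persistence_mu_max(params):
        raise NoResidentEquilibriumError(
            f"symbiont cannot persist: mu={mu} >= B/(1+B)={persistence_mu_max(params):.6g}"
        )
    return B * (1.0 - mu) - mu


def threshold_t_model_ii_displacement(b: float, c: float, mu: float) -> float:
    """Symbiont-displacement threshold t = (1 + b - c)(1 - mu) - 1 (Model ii).

    Above it the novel mitotype outcompetes the symbiont even when the
    symbiont is rare (its benefit maximal), so the symbiont is excluded.
    """
    params = FreqDepParams(b=b, c=c, mu=mu)
    if mu >= persistence_mu_max(params):
        raise NoResidentEquilibriumError(
            f"symbiont cannot persist: mu={mu} >= (b-c)/(1+b-c)"
        )
    return (1.0 + b - c) * (1.0 - mu) - 1.0


def threshold_t_model_ii_invasion(b: float, c: float, mu: float) -> float:
    """Uninfected-origin invasion threshold of Model ii.

    The t at which the rare-mutant growth factor equals 1:
    t* = (1 - mu)(1 + b(1 - p*) - c) - 1 with p* the polymorphic resident
    equilibrium.  Lies below the displacement threshold whenever mu > 0,
    creating the invade-but-coexist band.
    """
    params = FreqDepParams(b=b, c=c, mu=mu)
    eq = resident_equilibrium(params)  # raises if symbiont cannot persist
    return (1.0 - mu) * (1.0 + b * (1.0 - eq.p_star) - c) - 1.0


def classify_outcome(
    final: CytotypeState,
    converged: bool,
    eps_extinct: float = EPS_EXTINCT,
    eps_fix: float = EPS_FIX,
) -> str:
    """Label a terminal state of an invasion run.

    mitotype_lost when the mutant is extinct (below the presence floor at
    the end of the run — a lineage that invaded would sit far above its
    introduction frequency); the two fixed classes when the mutant has
    swept, split on whether the symbiont survived; coexistence when both
    mitotypes persist at a converged polymorphic state.
    """
    floor = max(eps_extinct, eps_fix, PRESENCE_FLOOR)
    mutant = final.mutant_freq
    symbiont = final.symbiont_freq
    if mutant < floor:
        return MITOTYPE_LOST
    if 1.0 - mutant < floor:  # ancestral mitotype gone: mutant fixed
        if symbiont < floor:
            return MITOTYPE_FIXED_SYMBIONT_EXCLUDED
        return MITOTYPE_FIXED_SYMBIONT_RETAINED
    if converged:
        return COEXISTENCE_PARTITIONED
    return INDETERMINATE


def classify_invasion(
    params: ModelParams,
    origin: str,
    epsilon: float = DEFAULT_EPSILON,
    horizon: int = DEFAULT_HORIZON,
    tol: float = 1e-12,
) -> InvasionResult:
    """Introduce a rare mutant at the resident equilibrium, run the full
    recursion to convergence (or ``horizon``), and classify the outcome.

    For the CI model the resident equilibrium is the upper stable point E3;
    bistability means an uninfected-origin sweep can drag the symbiont below
    the separatrix E2 and collapse it — the label reflects the final
    frequencies, whichever route the transient took.
    """
    eq = resident_equilibrium(params)
    start = introduce_mutant(eq.point, origin, epsilon)
    gf = mutant_growth_factor(params, origin)
    stepper = lambda st: step(st, params)  # noqa: E731
    try:
        res = find_fixed_point(stepper, start, tol=tol, max_gen=horizon)
        final, gens, converged = res.state, res.generations, True
    except ConvergenceError as err:
        final, gens, converged = err.last_state, err.generations, False
    if abs(gf - 1.0) < NEUTRAL_BAND:
        outcome = INDETERMINATE
    else:
        outcome = classify_outcome(final, converged)
    return InvasionResult(origin, gf, outcome, final, gens, eq.p_star)


# ---------------------------------------------------------------------------
# Headline scans
# ---------------------------------------------------------------------------

def exclusion_prevalence_bound(
    t: float = 0.02, B_lo: float = 0.1, B_hi: float = 0.5, n: int = 401
) -> tuple[float, np.ndarray]:
    """Largest symbiont prevalence at which an uninfected-origin mitotype of
    benefit ``t`` still excludes the symbiont (Model i).

    For each B on the grid, the invasion boundary t = B(1 - mu) - mu is
    solved for mu, and the equilibrium prevalence p* = 1 - (1 + B) mu / B is
    evaluated there; analytically p* reduces to t/B on the boundary, so the
    maximum over B >= B_lo is attained at B_lo.  Returns the maximum
    prevalence and the (B, mu, prevalence) grid.
    """
    if not 0.0 < t:
        raise ValueError("t must be positive")
    B = np.linspace(B_lo, B_hi, n)
    mu = (B - t) / (1.0 + B)  # boundary: t = B(1 - mu) - mu
    valid = (mu > 0.0) & (mu < B / (1.0 + B))
    prev = np.where(valid, 1.0 - (1.0 + B) * mu / B, np.nan)
    table = np.column_stack([B, mu, prev])
    return float(np.nanmax(prev)), table


def ci_invasion_ceiling(
    t_max: float = 0.02,
    h_step: float = 0.005,
    h_max: float = 0.2,
    n_mu: int = 26,
    n_t: int = 26,
    epsilon: float = DEFAULT_EPSILON,
    horizon: int = 200_000,
):
    """Largest CI strength h at which a novel mitotype with benefit
    ``t <= t_max``, arising in an uninfected host at E3, invades for *any*
    feasible segregational-loss rate (Model iii).

    For each h on the scan, a grid of mu strictly inside
    (0, (1 - sqrt(1 - h)) / 2) is crossed with t in (0, t_max], the full
    recursion is run from E3 perturbed in the s compartment, and the cell
    counts as invading when the outcome is anything other than loss of the
    mutant.  Returns ``(h_ceiling, per_h_table)`` where the table rows are
    (h, invading-cell count); ``h_ceiling`` is 0.0 when no h invades.
    """
    from .experiments import AxisSpec, run_sweep  # local: avoid import cycle

    h_values = np.arange(h_step, h_max + h_step / 2, h_step)
    rows = []
    ceiling = 0.0
    for h in h_values:
        h = round(float(h), 10)
        mu_max = (1.0 - np.sqrt(1.0 - h)) / 2.0
        mu_grid = np.linspace(0.0, mu_max, n_mu + 2)[1:-1]
        t_grid = np.linspace(0.0, t_max, n_t + 1)[1:]
        sweep = run_sweep(
            CIParams(h=h, mu=mu_grid[0], t=t_grid[0]),
            AxisSpec("mu", mu_grid[0], mu_grid[-1], n_mu),
            AxisSpec("t", t_grid[0], t_grid[-1], n_t),
            origin="uninfected",
            epsilon=epsilon,
            horizon=horizon,
        )
        invaded = sweep.frame["outcome"].isin(
            [
                MITOTYPE_FIXED_SYMBIONT_EXCLUDED,
                MITOTYPE_FIXED_SYMBIONT_RETAINED,
                COEXISTENCE_PARTITIONED,
            ]
        )
        count = int(invaded.sum())
        rows.append((h, count))
        if count > 0:
            ceiling = h
    return ceiling, np.array(rows)
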