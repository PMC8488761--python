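"""Cytotype state and one-generation recursion operators.

A host individual is characterised by its *cytotype*: the joint maternally
inherited combination of mitochondrial haplotype (resident vs. novel) and
heritable-symbiont infection status.  The population state is the frequency
vector of the four cytotypes,

    p : resident mitotype, symbiont-infected
    q : resident mitotype, uninfected
    r : novel mitotype,    symbiont-infected
    s : novel mitotype,    uninfected

with p + q + r + s = 1.  Three discrete-generation mean-field models describe
how selection on the symbiont and on the novel mitotype (benefit ``t``) moves
this vector from one generation to the next:

* **Model i** — the symbiont confers a fixed net benefit ``1 + B`` on the
  offspring of infected mothers and is lost segregationally at rate ``mu``.
* **Model ii** — the symbiont's benefit declines linearly with its overall
  frequency, ``B_T = b (1 - (p_T + r_T))``, against a fixed carriage cost
  ``c`` (negative frequency dependence, e.g. a defensive symbiont).
* **Model iii** — cytoplasmic incompatibility (CI): offspring of uninfected
  mothers fertilised by infected males survive with probability ``1 - h``
  (positive frequency dependence, e.g. *Wolbachia*).

The step operators are pure functions mapping a :class:`CytotypeState` and a
parameter set to the next-generation state.  The same arithmetic kernels
accept NumPy arrays elementwise, which is what the sweep machinery in
:mod:`cytosweep.experiments` uses to run thousands of parameter cells in
lockstep.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "CytotypeState",
    "FixedBenefitParams",
    "FreqDepParams",
    "CIParams",
    "ModelError",
    "DegenerateStateError",
    "ConservationError",
    "step",
    "step_model_i",
    "step_model_ii",
    "step_model_iii",
    "resident_map",
    "resident_map_i",
    "resident_map_ii",
    "resident_map_iii",
]

# Numerical policy for the state vector after a step: components within
# _CLAMP_TOL below zero are treated as roundoff and clamped; the four
# components must sum to 1 within _SUM_HARD_TOL (else the step operator has a
# genuine bug and we refuse to renormalise it away); sums off by more than
# _SUM_RENORM_TOL but less than _SUM_HARD_TOL are renormalised.
_CLAMP_TOL = 1e-15
_SUM_RENORM_TOL = 1e-12
_SUM_HARD_TOL = 1e-9


class ModelError(Exception):
    """Base class for model-layer errors."""


class DegenerateStateError(ModelError):
    """The normalising denominator of a recursion was non-positive."""


class ConservationError(ModelError):
    """State components left the simplex by more than roundoff allows."""


@dataclass(frozen=True)
class CytotypeState:
    """Frequencies of the four cytotypes ``(p, q, r, s)``.

    ``p``/``q`` carry the resident mitotype with/without the symbiont;
    ``r``/``s`` carry the novel mitotype with/without the symbiont.
    """

    p: float
    q: float
    r: float = 0.0
    s: float = 0.0

    def validate(self, atol: float = _SUM_HARD_TOL) -> None:
        comps = (self.p, self.q, self.r, self.s)
        for name, x in zip("pqrs", comps):
            if x < -_CLAMP_TOL or x > 1.0 + atol or not np.isfinite(x):
                raise ConservationError(f"component {name}={x!r} outside [0, 1]")
        total = sum(comps)
        if abs(total - 1.0) > atol:
            raise ConservationError(f"components sum to {total!r}, not 1")

    @property
    def symbiont_freq(self) -> float:
        """Overall symbiont prevalence, p + r."""
        return self.p + self.r

    @property
    def mutant_freq(self) -> float:
        """Overall novel-mitotype frequency, r + s."""
        return self.r + self.s

    def as_array(self) -> np.ndarray:
        return np.array([self.p, self.q, self.r, self.s], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "CytotypeState":
        p, q, r, s = (float(x) for x in arr)
        return cls(p, q, r, s)

    @classmethod
    def resident(cls, p_star: float) -> "CytotypeState":
        """Resident-subsystem state (r = s = 0) at symbiont frequency ``p_star``."""
        return cls(float(p_star), 1.0 - float(p_star), 0.0, 0.0)


def _validated(value: float, name: str, lo=None, hi=None, lo_strict=None):
    value = float(value)
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if lo is not None and value < lo:
        raise ValueError(f"{name} must be >= {lo}, got {value}")
    if lo_strict is not None and value <= lo_strict:
        raise ValueError(f"{name} must be > {lo_strict}, got {value}")
    if hi is not None and value > hi:
        raise ValueError(f"{name} must be <= {hi}, got {value}")
    return value


@dataclass(frozen=True)
class FixedBenefitParams:
    """Model i: fixed symbiont benefit ``B``, segregational loss ``mu``,
    novel-mitotype benefit ``t``.

    ``B`` is the net composite of benefit and carriage cost and may be
    negative as long as fitness ``1 + B`` stays positive.
    """

    B: float
    mu: float
    t: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "B", _validated(self.B, "B", lo_strict=-1.0))
        object.__setattr__(self, "mu", _validated(self.mu, "mu", lo=0.0, hi=1.0))
        object.__setattr__(self, "t", _validated(self.t, "t", lo_strict=-1.0))


@dataclass(frozen=True)
class FreqDepParams:
    """Model ii: maximum rare-symbiont benefit ``b``, fixed carriage cost
    ``c``, segregational loss ``mu``, novel-mitotype benefit ``t``.

    The realised benefit each generation is ``B_T = b (1 - (p_T + r_T))``;
    infected-mother fitness is ``1 + B_T - c`` and must stay positive at every
    symbiont frequency, hence the requirement ``1 + b - c > 0`` is implied by
    ``c < 1`` together with ``b >= 0`` (we require the sharper ``1 - c > 0``).
    """

    b: float
    c: float
    mu: float
    t: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "b", _validated(self.b, "b", lo=0.0))
        object.__setattr__(self, "c", _validated(self.c, "c", lo=0.0))
        object.__setattr__(self, "mu", _validated(self.mu, "mu", lo=0.0, hi=1.0))
        object.__setattr__(self, "t", _validated(self.t, "t", lo_strict=-1.0))
        if 1.0 + self.b - self.c <= 0.0 or 1.0 - self.c <= 0.0:
            raise ValueError(
                f"infected fitness must stay positive: b={self.b}, c={self.c}"
            )


@dataclass(frozen=True)
class CIParams:
    """Model iii: CI strength ``h`` (incompatible-cross offspring survive at
    ``1 - h``), segregational loss ``mu``, novel-mitotype benefit ``t``."""

    h: float
    mu: float
    t: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "h", _validated(self.h, "h", lo=0.0, hi=1.0))
        object.__setattr__(self, "mu", _validated(self.mu, "mu", lo=0.0, hi=1.0))
        object.__setattr__(self, "t", _validated(self.t, "t", lo_strict=-1.0))


ModelParams = FixedBenefitParams | FreqDepParams | CIParams

MODEL_NAMES = {FixedBenefitParams: "i", FreqDepParams: "ii", CIParams: "iii"}
PARAM_TYPES = {"i": FixedBenefitParams, "ii": FreqDepParams, "iii": CIParams}


def model_name(params: ModelParams) -> str:
    """Roman-numeral model label ('i', 'ii' or 'iii') for a parameter set."""
    try:
        return MODEL_NAMES[type(params)]
    except KeyError:
        raise TypeError(f"unknown parameter type {type(params).__name__}")


def params_to_dict(params: ModelParams) -> dict:
    return {f.name: getattr(params, f.name) for f in fields(params)}


# ---------------------------------------------------------------------------
# Arithmetic kernels.  These operate on scalars or NumPy arrays elementwise
# and return the four *unnormalised* next-generation weights plus their sum
# (the normaliser).  Division and simplex checks happen in the callers.
# ---------------------------------------------------------------------------

def _weights_i(p, q, r, s, B, mu, t):
    w = 1.0 + B
    np_ = p * w * (1.0 - mu)
    nq = p * w * mu + q
    nr = r * w * (1.0 - mu) * (1.0 + t)
    ns = (r * w * mu + s) * (1.0 + t)
    return np_, nq, nr, ns


def _weights_ii(p, q, r, s, b, c, mu, t):
    # Realised benefit uses the generation-T (pre-update) symbiont frequency.
    w = 1.0 + b * (1.0 - (p + r)) - c
    np_ = p * w * (1.0 - mu)
    nq = p * w * mu + q
    nr = r * w * (1.0 - mu) * (1.0 + t)
    ns = (r * w * mu + s) * (1.0 + t)
    return np_, nq, nr, ns


def _weights_iii(p, q, r, s, h, mu, t):
    # Uninfected mothers' offspring survive incompatible crosses at (1 - h);
    # with male cytotype frequencies equal to overall frequencies the
    # compatibility factor is (p + r)(1 - h) + q + s.  Segregant offspring of
    # infected mothers (the p*mu and r*mu terms) are *not* CI-protected.
    compat = (p + r) * (1.0 - h) + q + s
    np_ = p * (1.0 - mu)
    nq = (p * mu + q) * compat
    nr = r * (1.0 - mu) * (1.0 + t)
    ns = (r * mu + s) * (1.0 + t) * compat
    return np_, nq, nr, ns


_KERNELS = {
    "i": lambda p, q, r, s, pr: _weights_i(p, q, r, s, pr["B"], pr["mu"], pr["t"]),
    "ii": lambda p, q, r, s, pr: _weights_ii(
        p, q, r, s, pr["b"], pr["c"], pr["mu"], pr["t"]
    ),
    "iii": lambda p, q, r, s, pr: _weights_iii(
        p, q, r, s, pr["h"], pr["mu"], pr["t"]
    ),
}


def step_arrays(model: str, p, q, r, s, param_arrays: dict):
    """Vectorised one-generation update on component arrays.

    ``param_arrays`` maps field names to scalars or arrays broadcastable
    against the state arrays.  No simplex policing beyond clipping roundoff
    negatives: the kernels conserve total frequency to machine precision.
    """
    np_, nq, nr, ns = _KERNELS[model](p, q, r, s, param_arrays)
    tot = np_ + nq + nr + ns
    if np.any(tot <= 0.0):
        raise DegenerateStateError("non-positive normaliser in vectorised step")
    inv = 1.0 / tot
    return (
        np.maximum(np_ * inv, 0.0),
        np.maximum(nq * inv, 0.0),
        np.maximum(nr * inv, 0.0),
        np.maximum(ns * inv, 0.0),
    )


def _finalize(np_, nq, nr, ns, tot) -> CytotypeState:
    if not tot > 0.0:
        raise DegenerateStateError(f"normaliser {tot!r} is not positive")
    comps = [np_ / tot, nq / tot, nr / tot, ns / tot]
    for i, x in enumerate(comps):
        if x < 0.0:
            if x < -_CLAMP_TOL:
                raise ConservationError(f"negative frequency {x!r} after step")
            comps[i] = 0.0
    total = sum(comps)
    err = abs(total - 1.0)
    if err > _SUM_HARD_TOL:
        raise ConservationError(f"frequencies sum to {total!r} after step")
    if err > _SUM_RENORM_TOL:
        comps = [x / total for x in comps]
    return CytotypeState(*comps)


def step_model_i(state: CytotypeState, params: FixedBenefitParams) -> CytotypeState:
    """One generation of the fixed-benefit model (Model i)."""
    state.validate()
    np_, nq, nr, ns = _weights_i(
        state.p, state.q, state.r, state.s, params.B, params.mu, params.t
    )
    return _finalize(np_, nq, nr, ns, np_ + nq + nr + ns)


def step_model_ii(state: CytotypeState, params: FreqDepParams) -> CytotypeState:
    """One generation of the frequency-dependent-benefit model (Model ii)."""
    state.validate()
    np_, nq, nr, ns = _weights_ii(
        state.p, state.q, state.r, state.s, params.b, params.c, params.mu, params.t
    )
    return _finalize(np_, nq, nr, ns, np_ + nq + nr + ns)


def step_model_iii(state: CytotypeState, params: CIParams) -> CytotypeState:
    """One generation of the cytoplasmic-incompatibility model (Model iii)."""
    state.validate()
    np_, nq, nr, ns = _weights_iii(
        state.p, state.q, state.r, state.s, params.h, params.mu, params.t
    )
    return _finalize(np_, nq, nr, ns, np_ + nq + nr + ns)


_STEPS = {"i": step_model_i, "ii": step_model_ii, "iii": step_model_iii}


def step(state: CytotypeState, params: ModelParams) -> CytotypeState:
    """One generation of whichever model ``params`` belongs to."""
    return _STEPS[model_name(params)](state, params)


# ---------------------------------------------------------------------------
# Resident-subsystem maps: with r = s = 0 each model collapses to a single
# recursion in the symbiont frequency p (q = 1 - p).
# ---------------------------------------------------------------------------

def resident_map_i(p, B, mu):
    """p' = p (1 - mu)(1 + B) / (1 + B p)."""
    return p * (1.0 - mu) * (1.0 + B) / (1.0 + B * p)


def resident_map_ii(p, b, c, mu):
    """p' = p (1 - mu)(1 + b(1 - p) - c) / (p (1 + b(1 - p) - c) + 1 - p)."""
    w = 1.0 + b * (1.0 - p) - c
    return p * (1.0 - mu) * w / (p * w + 1.0 - p)


def resident_map_iii(p, h, mu):
    """p' = p (1 - mu) / (1 - h p (1 - p (1 - mu)))."""
    return p * (1.0 - mu) / (1.0 - h * p * (1.0 - p * (1.0 - mu)))


def resident_map(params: ModelParams):
    """Scalar map ``p -> p'`` of the resident (r = s = 0) subsystem."""
    name = model_name(params)
    if name == "i":
        return lambda p: resident_map_i(p, params.B, params.mu)
    if name == "ii":
        return lambda p: resident_map_ii(p, params.b, params.c, params.mu)
    return lambda p: resident_map_iii(p, params.h, params.mu)
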