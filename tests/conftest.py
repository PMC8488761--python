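import numpy as np
import pytest

from cytosweep import CIParams, FixedBenefitParams, FreqDepParams


@pytest.fixture
def fig1_params():
    """Fixed-benefit model at the published trajectory parameters."""
    return FixedBenefitParams(B=0.075, mu=0.05, t=0.02)


@pytest.fixture
def fig4_params():
    """Frequency-dependent-benefit model at the published trajectory parameters."""
    return FreqDepParams(b=0.1, c=0.05, mu=0.02, t=0.02)


@pytest.fixture
def fig6_params():
    """CI model at the published trajectory parameters."""
    return CIParams(h=0.25, mu=0.05, t=0.02)


def random_params(model: str, rng: np.random.Generator, margin: float = 0.9):
    """Draw a valid parameter set with the symbiont comfortably persistent.

    ``margin`` keeps mu away from the persistence boundary so fixed-point
    iteration converges quickly (rates scale with the distance to the
    boundary).
    """
    t = float(rng.uniform(0.0, 0.05))
    if model == "i":
        B = float(rng.uniform(0.02, 0.5))
        mu = float(rng.uniform(0.0, margin * B / (1 + B)))
        return FixedBenefitParams(B=B, mu=mu, t=t)
    if model == "ii":
        b = float(rng.uniform(0.05, 0.5))
        c = float(rng.uniform(0.0, 0.6 * b))
        net = b - c
        mu = float(rng.uniform(0.0, margin * net / (1 + net)))
        return FreqDepParams(b=b, c=c, mu=mu, t=t)
    h = float(rng.uniform(0.05, 0.9))
    mu_max = (1 - np.sqrt(1 - h)) / 2
    mu = float(rng.uniform(0.0, margin * mu_max))
    return CIParams(h=h, mu=mu, t=t)
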