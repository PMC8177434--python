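import numpy as np
import pytest

from languse import EmpiricalParams, PayoffSpec, SyntheticConfig, generate_localities


@pytest.fixture
def simple_spec():
    """Constant payoffs m=2, c=0.4, n=1: p* = 0.6 at alpha = 0.5."""
    return PayoffSpec.from_constants(m=2.0, c=0.4, n=1.0)


@pytest.fixture
def family_spec():
    """Admissible parametric family on a mid-range alpha grid."""
    return PayoffSpec.from_family(mu=1.0, kappa=0.1, n=1.0, alpha_star=0.9)


@pytest.fixture
def street_params():
    return EmpiricalParams(beta1=0.9, beta2=1.4, beta3=0.3, model_kind="street")


@pytest.fixture
def street_table(street_params):
    """One synthetic street-use survey year at realistic survey scale."""
    cfg = SyntheticConfig(
        true_params=street_params,
        n_localities=100,
        obs_counts=200,
        seed=42,
    )
    return generate_localities(cfg)


def random_admissible(rng):
    """Draw a random admissible (spec, alpha) pair: constant payoffs with
    the frustration cost placed strictly inside (0, weighted benefit)."""
    alpha = rng.uniform(0.15, 0.75)
    m = 1.0 + rng.uniform(0.5, 3.0)
    n = 1.0
    b = (m - n) * alpha / (1.0 - alpha)
    c = rng.uniform(0.1, 0.9) * min(b, n)
    spec = PayoffSpec.from_constants(m=m, c=c, n=n)
    return spec, alpha
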