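import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import credsurv as cs

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return cs.default_grid()


@pytest.fixture(scope="session")
def ph_fit():
    """One fitted PH replicate (n=120, gamma=(1,1,1)) shared across tests."""
    cfg = cs.PHSimConfig(n=120, beta=(0.0, 0.0), gamma=(1.0, 1.0, 1.0), seed=42)
    ds = cs.simulate_ph(cfg)
    res = cs.GammaProcessCox(ds).fit(n_iter=1500, burn_in=500, seed=7)
    return cfg, ds, res


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_pte(rng, M=400, G=12, measure="log_hr", loc=0.0, scale=1.0):
    """Synthetic posterior PTE draws: Gaussian around a random mean surface."""
    mean = rng.normal(loc, 1.0, G)
    sd = rng.uniform(0.3, 1.5, G) * scale
    values = mean + sd * rng.standard_normal((M, G))
    g = cs.CovariateGrid(points=np.c_[np.ones(G), np.arange(G, dtype=float)])
    if measure == "log_hr":
        return cs.PTEDraws(values, "log_hr", g, 0.0, "below")
    return cs.PTEDraws(values, "rmstd", g, 0.0, "above")
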