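import mpmath
import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from crabfate.beinf import beinf_density, beinf_shapes
from crabfate.synthetic import SimulationConfig, simulate_fate_tracking

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def beinf_total_probability(mu, sigma, nu, tau, edge=1e-8):
    """Oracle: total probability of the inflated-beta mixture.

    Sums the point masses, tanh-sinh quadrature of the package's density over
    the interior, and high-precision incomplete-beta tails near the endpoints
    (where shape parameters below one put non-negligible mass inside a strip
    narrower than float quadrature can resolve).
    """
    mass = beinf_density(0.0, mu, sigma, nu, tau) + beinf_density(1.0, mu, sigma, nu, tau)
    bulk = float(
        mpmath.quad(
            lambda y: beinf_density(float(y), mu, sigma, nu, tau),
            [edge, 0.5, 1.0 - edge],
        )
    )
    a, b = beinf_shapes(mu, sigma)
    with mpmath.workdps(40):
        tails = mpmath.betainc(a, b, 0, edge, regularized=True) + mpmath.betainc(
            a, b, 1.0 - edge, 1.0, regularized=True
        )
    return mass + bulk + (1.0 - nu) * (1.0 - tau) * float(tails)


@pytest.fixture(scope="session")
def study_dataset():
    """One full-size simulated campaign (4 sites x 3 transects x 43 colonies)."""
    return simulate_fate_tracking(SimulationConfig(seed=20240901))


@pytest.fixture
def small_config():
    """A quick two-site configuration for fast per-test simulations."""
    return SimulationConfig(
        n_sites=2,
        transects_per_site=2,
        colonies_per_transect=15,
        seed=5,
    )


COLONY_COLS = [
    "colony_id",
    "site",
    "transect",
    "time_point",
    "genus",
    "max_diameter_cm",
    "fragment_class",
    "health_state",
    "mortality_state",
]
DWELLING_COLS = ["dwelling_id", "colony_id", "time_point", "status"]


def make_colonies(rows):
    """Build a colony table from (colony_id, site, transect, tp, mortality) tuples."""
    if not rows:
        return pd.DataFrame(columns=COLONY_COLS)
    return pd.DataFrame(
        [
            {
                "colony_id": cid,
                "site": site,
                "transect": tr,
                "time_point": tp,
                "genus": "Pocillopora",
                "max_diameter_cm": 12.0,
                "fragment_class": "none",
                "health_state": "healthy",
                "mortality_state": mort,
            }
            for cid, site, tr, tp, mort in rows
        ]
    )


def make_dwellings(rows):
    """Build a dwelling table from (dwelling_id, colony_id, tp, status) tuples."""
    if not rows:
        return pd.DataFrame(columns=DWELLING_COLS)
    return pd.DataFrame(
        [
            {"dwelling_id": d, "colony_id": c, "time_point": tp, "status": s}
            for d, c, tp, s in rows
        ]
    )
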