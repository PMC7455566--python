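import logging

import numpy as np
import pytest

from featdiag.cohort import CohortConfig, random_feature_bank, simulate_experiment
from featdiag.geometry import ImageGeometry

logging.getLogger("featdiag").setLevel(logging.ERROR)

#: small geometry with the standard pixels-per-degree (250/22.5) so ladder
#: frequencies stay representable
SMALL_GEOM = ImageGeometry(side_px=125, extent_dva=11.25)


@pytest.fixture(scope="session")
def small_geom():
    return SMALL_GEOM


@pytest.fixture(scope="session")
def small_banks():
    """Two 300-feature simulated banks (one cat, one dog image)."""
    rng = np.random.default_rng(91)
    return {name: random_feature_bank(name, SMALL_GEOM, n_features=300, rng=rng)
            for name in ("cat1", "dog1")}


@pytest.fixture(scope="session")
def small_cohort_run(small_banks):
    """A 12-participant simulated experiment on the small banks
    (2 sessions -> 100 trials/image), with planted couplings at defaults."""
    cfg = CohortConfig(n_participants=12, rng_seed=5, fixed_sessions=2)
    rng = np.random.default_rng(5)
    trials, profiles, weights = simulate_experiment(cfg, small_banks, rng)
    return trials, profiles, weights
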