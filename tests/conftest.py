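import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from earlychange.grids import build_loading_matrix, early_change_grid
from earlychange.simulate import default_study_config, generate

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

# sklearn KMeans emits an environment hint about thread counts on some
# platforms; irrelevant to correctness
warnings.filterwarnings("ignore", message=".*KMeans.*")
warnings.filterwarnings("ignore", message=".*physical cores.*")


@pytest.fixture(scope="session")
def early_lam():
    return build_loading_matrix(early_change_grid())


@pytest.fixture(scope="session")
def default_draw():
    """One default-condition synthetic study sample (n=409, seed fixed)."""
    cfg = default_study_config()
    return generate(cfg, seed=20260926)


@pytest.fixture(scope="session")
def early_scores(default_draw):
    ds, _ = default_draw
    return ds.restrict_occasions(["screening", "registration", "wk2", "wk4"]).scores


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
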