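import warnings

import numpy as np
import pytest

from flexforage.atn_simulator import ATNParameters, Community
from flexforage.synthetic_data import SurveyConfig, generate_survey

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_survey():
    """A compact survey with the default (study-condition) generator."""
    cfg = SurveyConfig(n_sites=2, n_dates=6, n_fish_per_sample=5, seed=42)
    return generate_survey(cfg)


@pytest.fixture(scope="session")
def preferences(small_survey):
    from flexforage.preference_estimation import estimate_preferences

    tables, _ = small_survey
    return estimate_preferences(tables["stomachs"], tables["environment"])


@pytest.fixture
def two_species_community():
    """One consumer (index 1) on one basal prey (index 0), mass ratio at
    the Ricker optimum so the niche value is exactly 1."""
    L = np.array([[0.0, 0.0], [1.0, 0.0]])
    return Community(
        masses=np.array([1.0, 71.68]),
        is_basal=np.array([True, False]),
        beta_cons=np.array([0.47, 0.47]),
        beta_res=np.array([0.15, 0.15]),
        eta_cons=np.array([-0.48, -0.48]),
        eta_res=np.array([-0.66, -0.66]),
        c0_i=np.array([0.8, 0.8]),
        L=L,
        link=L > 0,
        K=np.array([[0.15, 0.15]]),
    )


def random_community(rng, n_species_max=5):
    """Small random community for oracle comparisons."""
    from flexforage.synthetic_data import generate_community

    n_basal = int(rng.integers(1, 3))
    n_cons = int(rng.integers(1, n_species_max - n_basal + 1))
    return generate_community(n_cons, n_basal, ATNParameters(),
                              seed=int(rng.integers(2**31 - 1)))
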