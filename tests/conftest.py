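import numpy as np
import pytest
from hypothesis import settings

import credsub as cs

settings.register_profile("default", deadline=None, max_examples=60)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    return cs.generate_cohort(cs.CohortGenConfig(n_subjects=800, seed=11))


@pytest.fixture(scope="session")
def small_design(small_cohort):
    cc, _ = cs.complete_cases(small_cohort)
    return cs.build_design(cc)


@pytest.fixture(scope="session")
def short_draws(small_design):
    cfg = cs.MCMCConfig(iterations=1500, burn_in=150, seed=3)
    return cs.sample_posterior(small_design, cs.PriorSpec(), cfg)


@pytest.fixture(scope="session")
def small_grid(small_design, small_cohort):
    cc, _ = cs.complete_cases(small_cohort)
    return cs.make_grid(small_design.std, cs.default_ranges(cc), resolution=5)


@pytest.fixture(scope="session")
def small_pte(short_draws, small_grid):
    return cs.compute_pte(short_draws, small_grid)


@pytest.fixture
def identity_std():
    return cs.StandardizationParams(
        center={"sf36_gh": 0.0, "age": 0.0, "hba1c": 0.0},
        scale={"sf36_gh": 1.0, "age": 1.0, "hba1c": 1.0},
    )


def make_toy_pte(values, threshold=0.0):
    return cs.PTEDraws.from_values(np.asarray(values, dtype=float), threshold=threshold)
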