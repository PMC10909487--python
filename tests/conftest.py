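import numpy as np
import pytest

from isolag import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Migratory cohort with zero grass and analytical noise: hair δ³⁴S is
    exactly the lag-shifted environmental mean plus the fractionation."""
    cfg = SimConfig(seed=0, movement_mode="migratory",
                    grass_sd_permil=0.0, analytical_sd_permil=0.0)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def standard_cohort():
    """Migratory cohort under the default study conditions (grass SD 1.21‰,
    analytical SD 0.65‰, rates Normal(0.511, 0.062), ~25 segments each)."""
    return simulate_cohort(SimConfig(seed=0, movement_mode="migratory"))


@pytest.fixture(scope="session")
def full_cohort():
    """Default cohort: 5 migratory plus 6 resident animals."""
    return simulate_cohort(SimConfig(seed=0))


def true_rates(cohort):
    return {a: cohort.truth["animals"][a]["rate_mm_per_day"]
            for a in cohort.hairs}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
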