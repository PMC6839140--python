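import numpy as np
import pytest

from methcap.methio import BetaMatrix
from methcap.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Standard planted cohort: 40/group, 1000 probes, 50 TN + 50 luminal-only."""
    return generate_cohort(
        CohortConfig(
            n_samples_per_subtype=(40, 40, 40),
            n_probes=1000,
            n_planted_tn=50,
            n_planted_luminal_only=50,
            effect_delta=0.25,
            noise_sd=0.05,
            n_prognostic=20,
            hazard_log_hr=1.0,
            censor_rate=0.3,
            seed=0,
        )
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Small, fast cohort for smoke-level tests."""
    return generate_cohort(
        CohortConfig(
            n_samples_per_subtype=(15, 15, 15),
            n_probes=200,
            n_planted_tn=20,
            n_planted_luminal_only=20,
            effect_delta=0.25,
            noise_sd=0.05,
            n_prognostic=10,
            hazard_log_hr=1.0,
            censor_rate=0.3,
            seed=11,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_beta_matrix(rng, n_probes=20, n_samples=8, prefix=""):
    vals = rng.uniform(0.05, 0.95, size=(n_probes, n_samples))
    return BetaMatrix(
        [f"{prefix}cg{i:05d}" for i in range(n_probes)],
        [f"{prefix}s{j}" for j in range(n_samples)],
        vals,
    )
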