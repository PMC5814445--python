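import numpy as np
import pytest

from lesionscope.simulate import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """One modest synthetic bundle shared across read-only tests."""
    cfg = CohortConfig(
        seed=7, n_cases=30, n_wes_cases=20, n_gep_cases=25,
        n_genes=200, n_probes=120, n_plate_cases=2,
        burden_mean=40.0, planted_mdr=(10, 13), planted_mdr_freq=0.4)
    return simulate_cohort(cfg, tmp_path_factory.mktemp("cohort"))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
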