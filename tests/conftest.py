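import numpy as np
import pytest

from mindtrack import boldsim as bs


@pytest.fixture(scope="session")
def small_cohort():
    """High-SNR simulated cohort shared by feature-selection / MVPA /
    decoding / integration tests (10 subjects, 16x16x10 voxels)."""
    params = bs.CohortParams(n_subjects=10, shape=(16, 16, 10), snr=2.0,
                             seed=20260927)
    return bs.simulate_cohort(params)


@pytest.fixture(scope="session")
def truth_20():
    return bs.make_ground_truth(shape=(20, 20, 12), snr=1.0, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
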