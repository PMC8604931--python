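import numpy as np
import pytest

from psiscreen.preprocessing import preprocess_matrix
from psiscreen.sample_selection import split_train_test
from psiscreen.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def strong_cohort():
    """Default-design cohort: 10+10 subjects, triplicates, 950 bins,
    Delta=5 planted at m/z 118 and 77."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def strong_preprocessed(strong_cohort):
    m, truth = strong_cohort
    return preprocess_matrix(m), truth


@pytest.fixture(scope="session")
def strong_split(strong_preprocessed):
    pm, _ = strong_preprocessed
    return split_train_test(pm, 0.7)


@pytest.fixture(scope="session")
def small_cohort_cfg():
    """Reduced grid (120 bins) for fast orchestration tests; the planted
    variables stay at their canonical positions."""
    return CohortConfig(mz_min=50.0, mz_max=170.0, seed=7,
                        shared_peaks=((60.0, 80.0, 0.25), (95.0, 150.0, 0.25),
                                      (130.0, 50.0, 0.25), (155.0, 120.0, 0.25)))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
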