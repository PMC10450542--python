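from datetime import datetime

import pytest

from appmarker.event_model import ObservationWindow
from appmarker.markers import sparsity_filter
from appmarker.pipeline import matrix_from_cohort
from appmarker.synthetic import EffectConfig, generate, scale


@pytest.fixture(scope="session")
def window() -> ObservationWindow:
    # Monday 2020-08-03; weekend defaults to {Friday, Saturday}
    return ObservationWindow(start=datetime(2020, 8, 3))


@pytest.fixture(scope="session")
def small_cohort(window):
    return generate(20, window, scale(EffectConfig(), 0.1), seed=3)


@pytest.fixture(scope="session")
def small_matrix(small_cohort, window):
    """Sparsity-filtered matrix + hamming index for the 20-participant cohort."""
    fm, hidx = matrix_from_cohort(small_cohort, window)
    return sparsity_filter(fm), hidx, small_cohort.labels
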