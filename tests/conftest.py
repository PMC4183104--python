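import numpy as np
import pytest

from dyncomp.core_data import RatingScale, RatingSeries
from dyncomp.simulate import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def scale06() -> RatingScale:
    return RatingScale(0.0, 6.0)


@pytest.fixture
def make_series(scale06):
    """Factory for a RatingSeries with contiguous days starting at 0."""

    def _make(values, patient_id="p001", item_id="item_a", scale=scale06):
        values = np.asarray(values, dtype=float)
        return RatingSeries(patient_id, item_id, np.arange(values.size), values, scale)

    return _make


@pytest.fixture(scope="session")
def small_cohort():
    """Six synthetic patients shared across pipeline-level tests."""
    return simulate_cohort(CohortConfig(n_patients=6, seed=2024))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
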