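import numpy as np
import pytest

import wearaffect as wa


@pytest.fixture(scope="session")
def small_config() -> wa.CohortConfig:
    """Desk-scale cohort: 4 participants, 2 minutes each at 32 Hz."""
    return wa.CohortConfig(
        n_participants=4, sampling_rate=32.0, duration=120.0, seed=7
    )


@pytest.fixture(scope="session")
def small_cohort(small_config) -> wa.Cohort:
    return wa.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_ws(small_cohort) -> wa.WindowedDataset:
    return wa.prepare_cohort(small_cohort)


@pytest.fixture()
def uniform_recording():
    """Single-state recording for windowing arithmetic."""

    def make(n_samples: int, label: int = 0, n_modalities: int = 8):
        rng = np.random.default_rng(0)
        return wa.Recording(
            participant_id="U01",
            signals=rng.standard_normal((n_modalities, n_samples)),
            labels=np.full(n_samples, label, dtype=np.int64),
            sampling_rate=32.0,
        )

    return make
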