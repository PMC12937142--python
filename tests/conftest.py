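from __future__ import annotations

import numpy as np
import pytest

from neuroentropy import CohortSpec, EEGRecording, gen_cohort
from neuroentropy.recordings import MONTAGE_CHANNELS


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_recording(
    data: np.ndarray, fs: float = 1000.0, subject_id: str = "S000"
) -> EEGRecording:
    """Recording over the 12 lobe-mapped channels from a channels × samples
    matrix (rows beyond the matrix are filled with copies of the last row)."""
    n_ch = len(MONTAGE_CHANNELS)
    data = np.asarray(data, dtype=float)
    if data.shape[0] < n_ch:
        data = np.vstack([data] + [data[-1:]] * (n_ch - data.shape[0]))
    return EEGRecording(list(MONTAGE_CHANNELS), data[:n_ch], fs, subject_id)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale 9-subject cohort shared across test modules."""
    spec = CohortSpec(
        n_per_group={"non-user": 3, "low-frequency": 3, "frequent": 3},
        duration_s=21.0,
        fs=200.0,
        seed=42,
    )
    return gen_cohort(spec)
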