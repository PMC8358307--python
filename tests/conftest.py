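import numpy as np
import pytest

from nptnet.synthetic import CohortConfig, SubjectRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A cheap signal-path configuration (few ROIs/epochs, full rate)."""
    return CohortConfig(n_subjects=3, n_rois=3, n_epochs=2, seed=11)


@pytest.fixture
def neutral_record():
    return SubjectRecord(
        subject_id="T001", age=80.0, gender="F",
        severity_pre=0.0, severity_post=0.0,
        mmse_pre=15, mmse_post=16, dbd_pre=10, dbd_post=9,
    )


def make_spectrum(densities):
    """NormalizedSpectrum on the standard 0.5 Hz grid over [1, 70]."""
    from nptnet.spectral import NormalizedSpectrum

    d = np.asarray(densities, dtype=float)
    f = np.linspace(1.0, 70.0, d.size)
    return NormalizedSpectrum(f, d / d.sum())
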