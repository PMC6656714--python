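import numpy as np
import pytest

from dkimri import BValueScheme, DWISeries, ROIMask, dki_signal

#: The five-point b grid used throughout: 100..1700 s/mm².
STUDY_BVALUES = (100.0, 500.0, 900.0, 1300.0, 1700.0)


@pytest.fixture(scope="session")
def scheme() -> BValueScheme:
    return BValueScheme(STUDY_BVALUES)


@pytest.fixture(scope="session")
def kurtosis_signal(scheme):
    """Noiseless kurtosis-model signal at responder-like parameters."""

    def _make(s0=1000.0, d_app=1.44e-3, k_app=0.69):
        return dki_signal(scheme.as_array(), s0, d_app, k_app)

    return _make


@pytest.fixture()
def small_series(scheme) -> DWISeries:
    """A tiny 4x4x2 series: every voxel holds the same kurtosis decay."""
    sig = dki_signal(scheme.as_array(), 1000.0, 1.2e-3, 0.6)
    return DWISeries(np.broadcast_to(sig, (4, 4, 2, 5)).copy(), scheme)


@pytest.fixture()
def small_mask(small_series) -> ROIMask:
    labels = np.zeros(small_series.grid_shape, dtype=np.int16)
    labels[1:3, 1:3, :] = 1
    return ROIMask(labels)
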