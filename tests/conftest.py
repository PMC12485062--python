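import numpy as np
import pytest

from specdim import (
    CameraConfig,
    DispersionModel,
    ExcitationVolume,
    SpectrumModel,
    calibrate_from_frames,
    make_scan_pattern,
)

CAL_WAVELENGTHS = [470.0, 520.0, 570.0, 620.0, 670.0, 720.0]


@pytest.fixture(scope="session")
def camera():
    return CameraConfig()


@pytest.fixture(scope="session")
def dispersion():
    return DispersionModel()


@pytest.fixture(scope="session")
def calibration(camera, dispersion):
    """One well-exposed synthetic calibration shared across tests."""
    return calibrate_from_frames(camera, dispersion, CAL_WAVELENGTHS,
                                 photons=200_000, seed=12345)


@pytest.fixture(scope="session")
def scan():
    return make_scan_pattern()


@pytest.fixture(scope="session")
def volume():
    return ExcitationVolume()


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)


def render_peak_frames(n_frames, photons, peak_nm, camera, dispersion, seed,
                       width_nm=15.0, residual=(0.0, 0.0)):
    """Render a batch of static-emitter frame pairs for spectral tests."""
    from specdim import render_frame_pair

    spec = SpectrumModel(peaks=(peak_nm,), widths=(width_nm,))
    rng = np.random.default_rng(seed)
    return [
        render_frame_pair(np.asarray(residual), lambda n, r: spec.sample(np.zeros(n), r),
                          photons, camera, dispersion, rng, frame_index=i)
        for i in range(n_frames)
    ]
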