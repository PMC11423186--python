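import numpy as np
import pytest

import cardiomea as cm


@pytest.fixture(scope="session")
def layout_4x8():
    return cm.grid_layout(8, 4)


@pytest.fixture(scope="session")
def planar_wavefront():
    return cm.WavefrontParams(mode="planar", speed_mm_s=50.0,
                              direction_deg=30.0)


@pytest.fixture(scope="session")
def noiseless_planar_recording(layout_4x8, planar_wavefront):
    """2-s noiseless 32-channel recording of a 50 mm/s planar wave."""
    beats = cm.constant_rate_beats(5.7, 2.0)
    return cm.synthesize_recording(beats, planar_wavefront,
                                   cm.SpikeTemplate(), layout_4x8,
                                   noise_rms_uV=0.0, sample_rate_hz=25000.0,
                                   duration_s=2.0)


@pytest.fixture(scope="session")
def small_recording():
    """4-channel, 1-s noisy recording on a square layout."""
    lay = cm.grid_layout(2, 2)
    beats = cm.constant_rate_beats(5.0, 1.0)
    wf = cm.WavefrontParams(speed_mm_s=50.0, direction_deg=0.0)
    return cm.synthesize_recording(beats, wf, cm.SpikeTemplate(), lay,
                                   noise_rms_uV=7.0, sample_rate_hz=25000.0,
                                   duration_s=1.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
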