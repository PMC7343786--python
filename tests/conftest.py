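import numpy as np
import pytest

import plaquesync as ps


def make_series(values, fs=25.0, kind="wall_diameter", units="px"):
    return ps.TimeSeries(np.asarray(values, dtype=float), fs, kind=kind, units=units)


def sinusoid(freq, fs=25.0, duration=10.0, amp=1.0, phase=0.0, offset=0.0):
    t = np.arange(int(round(duration * fs))) / fs
    return make_series(offset + amp * np.sin(2 * np.pi * freq * t + phase), fs)


@pytest.fixture(scope="session")
def phantom_zero():
    """Speckle phantom with fully synchronous motion (no delays)."""
    model = ps.MotionModel(top_bottom_delay=0.0, seed=1)
    geom = ps.PhantomGeometry()
    seq, truth, contours = ps.generate_image_sequence(model, geom)
    return seq, truth, contours


@pytest.fixture(scope="session")
def phantom_delayed():
    """Speckle phantom whose plaque top surface lags the bottom by 0.3 s."""
    model = ps.MotionModel(top_bottom_delay=0.3, seed=1)
    geom = ps.PhantomGeometry()
    seq, truth, contours = ps.generate_image_sequence(model, geom)
    return seq, truth, contours


@pytest.fixture(scope="session")
def tracked_zero(phantom_zero):
    """Tracked trajectories of the synchronous phantom (plaque edges trimmed)."""
    seq, truth, contours = phantom_zero
    cs = {
        k: (ps.ROIContour(k, c.pixels[25:-25]) if k in ("PTS", "PBS") else c)
        for k, c in contours.items()
    }
    return ps.track_rois(seq, cs)


@pytest.fixture(scope="session")
def features_zero(phantom_zero):
    seq, _, contours = phantom_zero
    return ps.extract_plaque_features(seq, contours)


@pytest.fixture(scope="session")
def features_delayed(phantom_delayed):
    seq, _, contours = phantom_delayed
    return ps.extract_plaque_features(seq, contours)
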