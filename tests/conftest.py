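import numpy as np
import pytest

import plmotion as pm


@pytest.fixture(scope="session")
def sinusoid_spec():
    """Default-noise clip with a sub-pixel sinusoidal pleural slide."""
    return pm.SyntheticClipSpec(
        pleural_motion=pm.Waveform(kind="sinusoid", amplitude_mm=2.5, frequency_hz=0.5),
        seed=11,
    )


@pytest.fixture(scope="session")
def sinusoid_clip(sinusoid_spec):
    frames, truth = pm.generate_clip(sinusoid_spec)
    return sinusoid_spec, frames, truth


@pytest.fixture(scope="session")
def drift_clip():
    """Clip with common-mode probe drift added to both layers."""
    spec = pm.SyntheticClipSpec(
        width_px=384,  # wide view: landmarks stay in frame under the drift
        pleural_motion=pm.Waveform(kind="sinusoid", amplitude_mm=2.5, frequency_hz=0.5),
        probe_motion=pm.Waveform(kind="ramp", amplitude_mm=4.0),
        seed=7,
    )
    frames, truth = pm.generate_clip(spec)
    return spec, frames, truth


def make_curve(x, stage="raw", role="pleural_central", t=None):
    x = np.asarray(x, dtype=float)
    if t is None:
        t = np.arange(x.size, dtype=float)
    return pm.MotionCurve(role=role, t=t, x_mm=x, stage=stage)


@pytest.fixture
def curve_factory():
    return make_curve
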