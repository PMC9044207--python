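import numpy as np
import pytest

import pulsekit as pk


@pytest.fixture(scope="session")
def spec72():
    """30 s, 30 fps pulse at a constant 72 BPM with mild noise."""
    return pk.PulseSpec(duration_s=30, fs=30, bpm=72.0, noise_sd=0.2, seed=7)


@pytest.fixture(scope="session")
def trace72(spec72):
    trace, gt = pk.make_rgb_trace(spec72, n_patches=1)
    return trace, gt


@pytest.fixture(scope="session")
def windows72(trace72):
    return pk.window_signal(trace72[0], 6, 1)


@pytest.fixture(scope="session")
def video60():
    """20 s, 30 fps rendered video with a 40x40 skin box pulsing at 60 BPM."""
    spec = pk.PulseSpec(duration_s=20, fs=30, bpm=60.0, noise_sd=0.3, seed=3)
    return pk.render_face_video(spec, size=(48, 48), skin_box=(4, 4, 40, 40))


def pulse_window(bpm=72.0, fs=30.0, m=180, mixing=(0.3, 0.8, 0.4),
                 baseline=(140.0, 110.0, 95.0), noise=0.0, seed=0, P=1):
    """One (P, 3, M) synthetic trace window carrying a clean pulse."""
    rng = np.random.default_rng(seed)
    t = np.arange(m) / fs
    x = np.sin(2 * np.pi * bpm / 60.0 * t)
    C = (np.asarray(baseline)[None, :, None]
         + np.asarray(mixing)[None, :, None] * x[None, None, :])
    C = np.broadcast_to(C, (P, 3, m)).copy()
    if noise:
        C += rng.normal(0, noise, C.shape)
    return C, x
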