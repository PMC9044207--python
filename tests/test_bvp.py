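import numpy as np
import pytest

import pulsekit as pk
from pulsekit.bvp import (
    MethodSpec,
    chrom,
    estimate_bvp,
    green,
    ica,
    lgi,
    pbv,
    pca,
    pos,
    register_method,
    ssr,
    window_bvp,
)
from pulsekit.errors import ParameterError, RegistryError
from pulsekit.extraction import PixelWindowSeries

from conftest import pulse_window

TRACE_METHODS = {
    "green": green,
    "chrom": chrom,
    "pos": pos,
    "pbv": pbv,
    "pca": pca,
    "ica": ica,
    "lgi": lgi,
}


def peak_bpm_of(y, fs=30.0, nfft=8192):
    from scipy.signal import periodogram

    f, p = periodogram(y - y.mean(), fs=fs, nfft=nfft)
    band = (f * 60 >= 39) & (f * 60 <= 240)
    return f[band][np.argmax(p[band])] * 60.0


@pytest.mark.parametrize("name,fn", TRACE_METHODS.items(), ids=TRACE_METHODS.keys())
class TestTraceMethodsShared:
    def test_constant_input_maps_to_zeros(self, name, fn):
        C = np.full((2, 3, 64), 100.0)
        out = fn(C)
        assert out.shape == (2, 64)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_output_zero_mean_per_patch(self, name, fn):
        C, _ = pulse_window(noise=0.3, seed=1, P=3)
        out = fn(C)
        assert np.all(np.abs(out.mean(axis=-1)) < 1e-9)

    def test_spectral_recovery_72bpm(self, name, fn):
        C, _ = pulse_window(bpm=72.0, noise=0.2, seed=2)
        y = fn(C)[0]
        assert abs(peak_bpm_of(y) - 72.0) <= max(60 * 30 / 8192, 60 / 6.0)

    def test_peak_location_invariant_to_global_gain(self, name, fn):
        C, _ = pulse_window(bpm=66.0, noise=0.2, seed=3)
        y1 = fn(C)[0]
        y2 = fn(1.7 * C)[0]
        assert peak_bpm_of(y1) == peak_bpm_of(y2)

    def test_nan_patch_propagates_as_nan(self, name, fn):
        C, _ = pulse_window(noise=0.1, seed=4, P=2)
        C[1] = np.nan
        out = fn(C)
        assert np.isfinite(out[0]).all()
        assert np.isnan(out[1]).all()


@pytest.mark.parametrize("fn", [chrom, pos], ids=["chrom", "pos"])
def test_projection_methods_exactly_gain_invariant(fn):
    """Temporal-mean normalisation makes the output identical under gain."""
    C, _ = pulse_window(bpm=80.0, noise=0.2, seed=5)
    np.testing.assert_allclose(fn(3.0 * C), fn(C), atol=1e-9)


def test_green_pulse_only_in_g_perfect_correlation():
    C, x = pulse_window(mixing=(0, 1, 0), noise=0.0)
    assert np.corrcoef(green(C)[0], x)[0, 1] > 0.999


def test_pbv_beats_green_when_green_channel_noisiest():
    gains = []
    for s in range(50):
        rng = np.random.default_rng(s)
        t = np.arange(180) / 30.0
        x = np.sin(2 * np.pi * 1.2 * t)
        C = np.stack(
            [100 + x + rng.normal(0, sd, 180) for sd in (0.1, 0.5, 0.1)]
        )[None]
        gains.append(
            abs(np.corrcoef(pbv(C)[0], x)[0, 1])
            - abs(np.corrcoef(green(C)[0], x)[0, 1])
        )
    assert np.mean(gains) > 0


def test_pca_selects_pulse_component_over_orthogonal_drift():
    t = np.arange(300) / 30.0
    x = np.sin(2 * np.pi * 1.2 * t)
    drift = 0.4 * np.sin(2 * np.pi * 0.1 * t)
    direction = np.array([0.3, 0.8, 0.4])
    ortho = np.array([0.8, -0.3, 0.0])
    C = (100 + direction[:, None] * x + ortho[:, None] * drift)[None]
    y = pca(C, fps=30.0)[0]
    assert abs(np.corrcoef(y, x)[0, 1]) > 0.99


def test_ica_deterministic_and_selects_inband_source():
    rng = np.random.default_rng(10)
    t = np.arange(300) / 30.0
    s1 = np.sin(2 * np.pi * 1.2 * t)  # 72 BPM, strong
    s2 = 0.4 * np.sin(2 * np.pi * 0.3 * t)  # 18 BPM, outside the band
    A = np.array([[0.5, 0.8], [0.9, 0.3], [0.4, 0.6]])
    C = (100 + A @ np.stack([s1, s2]) + rng.normal(0, 0.05, (3, 300)))[None]
    y1 = ica(C, seed=3, fps=30.0)
    y2 = ica(C, seed=3, fps=30.0)
    np.testing.assert_array_equal(y1, y2)
    assert abs(peak_bpm_of(y1[0]) - 72.0) <= 1.0


def test_lgi_kills_rank_one_input():
    t = np.arange(64)
    base = 100 + np.sin(t / 5.0)
    C = np.stack([base, 0.5 * base, 2.0 * base])[None]  # channels proportional
    assert np.max(np.abs(lgi(C))) < 1e-8


class TestSSR:
    @staticmethod
    def _pixels_from_video(spec, **kwargs):
        vid = pk.render_face_video(spec, **kwargs)
        ext = pk.TruthMaskExtractor.for_video(vid)
        return pk.collect_skin_pixels(vid, ext)

    def test_constant_pixels_give_zero_output(self):
        V = np.tile(np.array([[120.0, 100.0, 80.0]]), (20, 1))
        pix = PixelWindowSeries(frames=tuple(V for _ in range(60)), fps=30)
        out = ssr(pix, l=30)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_rendered_video_recovers_60bpm(self):
        spec = pk.PulseSpec(duration_s=20, fs=30, bpm=60.0, noise_sd=0.3, seed=3)
        pix = self._pixels_from_video(spec, size=(48, 48), skin_box=(4, 4, 40, 40))
        out = ssr(pix)
        assert abs(peak_bpm_of(out, fs=30) - 60.0) <= 60 / 20.0

    def test_full_length_segment_is_boundary_case(self):
        spec = pk.PulseSpec(duration_s=4, fs=20, bpm=75.0, noise_sd=0.1, seed=1)
        pix = self._pixels_from_video(spec, size=(16, 16), skin_box=(2, 2, 12, 12))
        out = ssr(pix, l=pix.n_frames)  # single segment
        assert out.shape == (pix.n_frames,)
        assert np.isfinite(out).all()

    def test_too_few_pixels_rejected(self):
        V = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        pix = PixelWindowSeries(frames=tuple(V for _ in range(40)), fps=20)
        with pytest.raises(ParameterError):
            ssr(pix, l=10)


class TestDispatch:
    def test_named_spec_equals_direct_call(self, windows72):
        via_spec = estimate_bvp(windows72, MethodSpec(name="green"))
        for w_spec, w_raw in zip(via_spec.windows, windows72.windows):
            np.testing.assert_array_equal(w_spec, green(w_raw))

    def test_custom_registered_method_reproduces_green(self, windows72):
        register_method("PASSTHROUGH_G", lambda C: C[:, 1, :] - C[:, 1, :].mean(axis=-1, keepdims=True))
        custom = estimate_bvp(windows72, "PASSTHROUGH_G")
        builtin = estimate_bvp(windows72, "GREEN")
        for a, b in zip(custom.windows, builtin.windows):
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_window_bookkeeping_preserved(self, windows72):
        bvp = estimate_bvp(windows72, "POS")
        assert bvp.n_windows == windows72.n_windows == 25
        np.testing.assert_array_equal(bvp.timestamps, windows72.timestamps)
        assert all(w.shape == (1, 180) for w in bvp.windows)

    def test_unknown_method_lists_available(self, windows72):
        with pytest.raises(RegistryError, match="GREEN"):
            estimate_bvp(windows72, "NO_SUCH_METHOD")

    def test_kind_mismatch_rejected(self, windows72):
        with pytest.raises(ParameterError):
            estimate_bvp(windows72, "SSR")


def test_window_bvp_slices_series_like_trace_windowing():
    series = np.arange(900, dtype=float)
    bw = window_bvp(series, 30.0, 6, 1)
    assert bw.n_windows == 25
    np.testing.assert_array_equal(bw.windows[3][0], series[90:270])
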