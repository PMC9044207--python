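import numpy as np
import pytest

import pulsekit as pk
from pulsekit.errors import (
    ExtractionError,
    OverlapViolationError,
    WindowTooLongError,
)
from pulsekit.extraction import GridLandmarkProvider, PixelWindowSeries


class TestHolistic:
    def test_trace_equals_analytic_box_mean(self):
        spec = pk.PulseSpec(duration_s=5, fs=30, bpm=66.0, noise_sd=0.0)
        vid = pk.render_face_video(spec, size=(30, 30), skin_box=(5, 5, 20, 20),
                                   mixing=(0.2, 0.9, 0.4), baseline=(140, 110, 95))
        ext = pk.TruthMaskExtractor.for_video(vid)
        trace = pk.extract_holistic(vid, ext)
        x, _ = pk.make_bvp_waveform(spec)
        expected = (np.array([140, 110, 95])[:, None]
                    + np.array([0.2, 0.9, 0.4])[:, None] * x[None, :])
        assert trace.values.shape == (1, 3, 150)
        np.testing.assert_allclose(trace.values[0], expected, atol=1e-9)

    def test_uniform_frame_gives_uniform_value(self):
        frames = np.full((10, 8, 8, 3), 128.0)
        ext = pk.TruthMaskExtractor((0, 0, 8, 8))
        trace = pk.extract_holistic(frames, ext, fps=10)
        assert np.all(trace.values == 128.0)

    def test_all_empty_masks_raise_naming_extractor(self):
        frames = np.zeros((5, 8, 8, 3))

        class EmptyExtractor:
            def extract(self, frame):
                return np.zeros(frame.shape[:2], dtype=bool)

        with pytest.raises(ExtractionError, match="EmptyExtractor"):
            pk.extract_holistic(frames, EmptyExtractor(), fps=10)

    def test_rendered_video_recovers_bpm_downstream(self):
        spec = pk.PulseSpec(duration_s=20, fs=30, bpm=60.0, noise_sd=0.2, seed=4)
        vid = pk.render_face_video(spec, size=(30, 30), skin_box=(5, 5, 20, 20))
        trace = pk.extract_holistic(vid, pk.TruthMaskExtractor.for_video(vid))
        wt = pk.window_signal(trace, 6, 1)
        bpm = pk.estimate_bpm(pk.estimate_bvp(wt, "GREEN"))
        assert abs(np.median(bpm.bpm) - 60.0) <= 1.0

    def test_chroma_extractor_finds_skin_box(self):
        spec = pk.PulseSpec(duration_s=1, fs=10, bpm=70.0, noise_sd=0.0)
        vid = pk.render_face_video(spec, size=(24, 24), skin_box=(4, 4, 16, 16))
        mask = pk.ChromaThresholdExtractor().extract(vid.frames[0])
        np.testing.assert_array_equal(mask, vid.skin_mask())


class TestPatches:
    def _uniform_video(self, colour=(140, 110, 95), size=24, box=(4, 4, 16, 16), T=10):
        frames = np.zeros((T, size, size, 3))
        frames[..., :] = (40, 60, 90)
        r0, c0, h, w = box
        frames[:, r0:r0 + h, c0:c0 + w, :] = colour
        return frames, box

    def test_patches_in_uniform_box_equal_box_colour(self):
        frames, box = self._uniform_video()
        provider = GridLandmarkProvider(box, n=3)
        spec = pk.PatchSpec(landmark_indices=(0, 4, 8), side=4)
        trace = pk.extract_patches(frames, pk.TruthMaskExtractor(box), spec,
                                   provider, fps=10)
        assert trace.values.shape[0] == 3
        for i in range(3):
            np.testing.assert_allclose(trace.values[i, 0], 140)
            np.testing.assert_allclose(trace.values[i, 1], 110)
            np.testing.assert_allclose(trace.values[i, 2], 95)

    def test_patch_outside_skin_is_invalid_others_unaffected(self):
        frames, box = self._uniform_video()

        class FarProvider:
            def landmarks(self, t):
                return np.array([[12.0, 12.0], [1.0, 1.0]])  # inside, outside

        spec = pk.PatchSpec(landmark_indices=(0, 1), side=3)
        trace = pk.extract_patches(frames, pk.TruthMaskExtractor(box), spec,
                                   FarProvider(), fps=10)
        assert trace.valid[0].all()
        assert not trace.valid[1].any()
        np.testing.assert_allclose(trace.values[0, 1], 110)

    def test_patch_isolation(self):
        """Perturbing pixels of one patch changes only that patch's trace."""
        frames, box = self._uniform_video()
        provider = GridLandmarkProvider(box, n=2)  # corners of the box
        spec = pk.PatchSpec(landmark_indices=(0, 3), side=3)
        ext = pk.TruthMaskExtractor(box)
        base = pk.extract_patches(frames, ext, spec, provider, fps=10)
        frames2 = frames.copy()
        frames2[:, 5:7, 5:7, :] += 30  # inside patch 0 only
        pert = pk.extract_patches(frames2, ext, spec, provider, fps=10)
        assert not np.allclose(base.values[0], pert.values[0])
        np.testing.assert_array_equal(base.values[1], pert.values[1])

    def test_median_patch_bpm_recovers_truth(self):
        spec = pk.PulseSpec(duration_s=20, fs=30, bpm=72.0, noise_sd=0.5, seed=6)
        vid = pk.render_face_video(spec, size=(48, 48), skin_box=(4, 4, 40, 40))
        provider = GridLandmarkProvider(vid.skin_box, n=4)
        pspec = pk.PatchSpec(landmark_indices=tuple(range(16)), side=6)
        trace = pk.extract_patches(vid, pk.TruthMaskExtractor.for_video(vid),
                                   pspec, provider)
        wt = pk.window_signal(trace, 6, 1)
        bpm = pk.estimate_bpm(pk.estimate_bvp(wt, "GREEN"))
        assert abs(np.median(bpm.bpm) - 72.0) <= 1.0
        assert np.all(bpm.mad >= 0)

    def test_mean_bound_property(self):
        """Every trace value lies within the contributing pixel range."""
        spec = pk.PulseSpec(duration_s=2, fs=20, bpm=80.0, noise_sd=2.0, seed=8)
        vid = pk.render_face_video(spec, size=(24, 24), skin_box=(4, 4, 16, 16))
        trace = pk.extract_holistic(vid, pk.TruthMaskExtractor.for_video(vid))
        mask = vid.skin_mask()
        for t in range(vid.frames.shape[0]):
            pix = vid.frames[t][mask]
            for c in range(3):
                assert pix[:, c].min() - 1e-9 <= trace.values[0, c, t] <= pix[:, c].max() + 1e-9


class TestCollectPixels:
    def test_uniform_box_shapes_and_values(self):
        frames = np.full((6, 10, 10, 3), 99.0)
        ext = pk.TruthMaskExtractor((2, 2, 4, 5))
        pix = pk.collect_skin_pixels(frames, ext, fps=10)
        assert pix.n_frames == 6
        for V in pix.frames:
            assert V.shape == (20, 3)
            assert np.all(V == 99.0)

    def test_shrinking_mask_series(self):
        frames = np.full((5, 10, 10, 3), 50.0)

        class ShrinkingExtractor:
            def __init__(self):
                self.t = 0

            def extract(self, frame):
                m = np.zeros(frame.shape[:2], dtype=bool)
                m[: 8 - self.t, : 8 - self.t] = True
                self.t += 1
                return m

        pix = pk.collect_skin_pixels(frames, ShrinkingExtractor(), fps=10)
        sizes = [V.shape[0] for V in pix.frames]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_frames_dropped_with_warning(self):
        frames = np.full((4, 6, 6, 3), 50.0)

        class Alternating:
            def __init__(self):
                self.t = 0

            def extract(self, frame):
                m = np.zeros(frame.shape[:2], dtype=bool)
                if self.t % 2 == 0:
                    m[:3, :3] = True
                self.t += 1
                return m

        with pytest.warns(UserWarning, match="dropped"):
            pix = pk.collect_skin_pixels(frames, Alternating(), fps=10)
        assert pix.n_frames == 2


class TestWindowing:
    @staticmethod
    def _trace(T=900, fps=30.0, P=1):
        rng = np.random.default_rng(0)
        return pk.RGBTrace(
            values=rng.uniform(50, 200, (P, 3, T)),
            fps=fps,
            pixel_counts=np.ones((P, T), dtype=int),
            valid=np.ones((P, T), dtype=bool),
        )

    def test_window_count_arithmetic(self):
        wt = pk.window_signal(self._trace(900, 30), 6, 1)
        assert wt.n_windows == 25
        assert wt.windows[0].shape == (1, 3, 180)

    def test_single_window_when_signal_length_equals_window(self):
        wt = pk.window_signal(self._trace(180, 30), 6, 1)
        assert wt.n_windows == 1

    @pytest.mark.parametrize("stride", [6, 7])
    def test_stride_not_less_than_window_rejected(self, stride):
        with pytest.raises(OverlapViolationError):
            pk.window_signal(self._trace(900, 30), 6, stride)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(WindowTooLongError):
            pk.window_signal(self._trace(100, 30), 6, 1)

    def test_reconstruction_windows_are_exact_slices(self):
        trace = self._trace(300, 30, P=2)
        wt = pk.window_signal(trace, 6, 2)
        step = int(2 * 30)
        for k, w in enumerate(wt.windows):
            np.testing.assert_array_equal(
                w, trace.values[:, :, k * step : k * step + 180]
            )

    def test_timestamps_at_window_centres(self):
        wt = pk.window_signal(self._trace(900, 30), 6, 1)
        np.testing.assert_allclose(wt.timestamps, 3.0 + np.arange(25) * 1.0)

    def test_mostly_invalid_patch_becomes_nan_in_window(self):
        trace = self._trace(300, 30, P=2)
        valid = trace.valid.copy()
        valid[1, :100] = False  # >20% of the first windows invalid
        trace = pk.RGBTrace(values=trace.values, fps=30,
                            pixel_counts=trace.pixel_counts, valid=valid)
        wt = pk.window_signal(trace, 6, 1)
        assert np.isnan(wt.windows[0][1]).all()
        assert np.isfinite(wt.windows[0][0]).all()
        assert np.isfinite(wt.windows[-1][1]).all()


def test_png_sequence_round_trip(tmp_path):
    spec = pk.PulseSpec(duration_s=0.5, fs=10, bpm=80.0, noise_sd=0.0)
    vid = pk.render_face_video(spec, size=(16, 16))
    from pulsekit.synthgen import export_png_sequence

    export_png_sequence(vid, tmp_path / "seq")
    frames = list(pk.extraction.iter_frames(tmp_path / "seq"))
    assert len(frames) == 5
    np.testing.assert_allclose(frames[0], np.rint(vid.frames[0]), atol=0.5)
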