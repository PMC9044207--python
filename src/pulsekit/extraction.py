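"""Stages 1-2: from video frames to per-patch RGB traces and analysis windows.

A *holistic* run averages all skin pixels into a single trace (P = 1); a
*patch-based* run tracks an ensemble of small square regions centred on
landmarks, one trace per patch.  Either way the traces q_i(t) are the
channel-wise means of the pixels contributing to region i at frame t, and
are then sliced into K overlapping rectangular windows of M = Ws*fps frames
with stride tau (the overlap inequality tau < Ws must hold).

Skin extraction is a *contract*, not an implementation: real deployments
plug in a face-mesh or face-parsing engine; this package ships a truth-mask
extractor for synthetic videos and a reference chroma-threshold detector.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Protocol, Sequence, runtime_checkable

import numpy as np

from .errors import (
    ExtractionError,
    OverlapViolationError,
    ParameterError,
    SignalLengthError,
    WindowTooLongError,
)
from .synthgen import SyntheticVideo

__all__ = [
    "SkinExtractor",
    "TruthMaskExtractor",
    "ChromaThresholdExtractor",
    "PatchSpec",
    "RGBTrace",
    "PixelWindowSeries",
    "WindowedTraces",
    "iter_frames",
    "extract_holistic",
    "extract_patches",
    "collect_skin_pixels",
    "window_signal",
]


# --------------------------------------------------------------------------
# Skin-extractor contract and reference implementations
# --------------------------------------------------------------------------


@runtime_checkable
class SkinExtractor(Protocol):
    """Anything with ``extract(frame) -> bool mask`` of the frame's shape."""

    def extract(self, frame: np.ndarray) -> np.ndarray: ...


class TruthMaskExtractor:
    """Skin extractor that returns the known pulse-carrying rectangle.

    Used with synthetic videos, where the generating spec records which
    pixels carry the pulse; it makes extraction exact so downstream stages
    can be tested in isolation.
    """

    def __init__(self, skin_box: tuple[int, int, int, int]):
        self.skin_box = skin_box

    @classmethod
    def for_video(cls, video: SyntheticVideo) -> "TruthMaskExtractor":
        return cls(video.skin_box)

    def extract(self, frame: np.ndarray) -> np.ndarray:
        r0, c0, h, w = self.skin_box
        mask = np.zeros(frame.shape[:2], dtype=bool)
        mask[r0 : r0 + h, c0 : c0 + w] = True
        return mask


class ChromaThresholdExtractor:
    """Reference rule-based skin detector on raw RGB values.

    Implements the classic explicit RGB skin-colour rule (bright, red
    dominant over blue, sufficient red-green spread).  Adequate for frontal
    faces under neutral illumination; a pluggable face-parsing engine
    should replace it in harder settings.
    """

    def __init__(self, min_r: float = 95, min_g: float = 40, min_b: float = 20,
                 min_spread: float = 15, min_rg_gap: float = 10):
        self.min_r, self.min_g, self.min_b = min_r, min_g, min_b
        self.min_spread, self.min_rg_gap = min_spread, min_rg_gap

    def extract(self, frame: np.ndarray) -> np.ndarray:
        r = frame[..., 0].astype(float)
        g = frame[..., 1].astype(float)
        b = frame[..., 2].astype(float)
        spread = frame.max(axis=-1).astype(float) - frame.min(axis=-1)
        return (
            (r > self.min_r)
            & (g > self.min_g)
            & (b > self.min_b)
            & (spread > self.min_spread)
            & (r > b)
            & (np.abs(r - g) > self.min_rg_gap)
        )


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PatchSpec:
    """Square patches centred on landmark points.

    ``landmark_indices`` select points from the landmark provider (up to
    468 in face-mesh conventions); ``side`` is the square side in pixels at
    native video resolution; pixels of each patch intersected with the skin
    mask are aggregated with the channel-wise mean.
    """

    landmark_indices: tuple[int, ...]
    side: int = 28
    aggregation: str = "mean"

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ParameterError("patch side must be positive")
        if len(set(self.landmark_indices)) != len(self.landmark_indices):
            raise ParameterError("landmark indices must be unique")
        if self.aggregation != "mean":
            raise ParameterError("only 'mean' aggregation is supported")


@dataclass(frozen=True)
class RGBTrace:
    """Per-patch, per-channel mean-intensity series q_i(t).

    Attributes
    ----------
    values : (P, 3, T) float array, channel order R, G, B, units [0, 255]
    fps : frame rate Fs in Hz
    pixel_counts : (P, T) int array N_i(t) of contributing pixels
    valid : (P, T) bool array; False where the region was unavailable and
        the value was interpolated (or is meaningless)
    """

    values: np.ndarray
    fps: float
    pixel_counts: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3 or v.shape[1] != 3:
            raise ParameterError("values must have shape (P, 3, T)")
        if self.fps <= 0:
            raise ParameterError("fps must be positive")
        if self.pixel_counts.shape != (v.shape[0], v.shape[2]):
            raise ParameterError("pixel_counts must have shape (P, T)")
        if self.valid.shape != (v.shape[0], v.shape[2]):
            raise ParameterError("valid must have shape (P, T)")

    @property
    def n_patches(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]


@dataclass(frozen=True)
class PixelWindowSeries:
    """Raw skin-pixel colour matrices, one (N_t, 3) matrix per frame.

    The pixel count N_t may vary over time (masks grow and shrink); this is
    the input form required by subspace-rotation pulse extraction, which
    needs the pixel population rather than its mean.
    """

    frames: tuple[np.ndarray, ...]
    fps: float

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ParameterError("fps must be positive")
        for V in self.frames:
            if V.ndim != 2 or V.shape[1] != 3:
                raise ParameterError("each frame matrix must be (N_t, 3)")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class WindowedTraces:
    """K overlapping (P, 3, M) slices of an RGB trace.

    ``timestamps`` mark window centres in seconds.  Rectangular windowing:
    window k covers frames [k*stride*fps, k*stride*fps + M).
    """

    windows: tuple[np.ndarray, ...]
    timestamps: np.ndarray
    window_s: float
    stride_s: float
    fps: float

    @property
    def n_windows(self) -> int:
        return len(self.windows)


# --------------------------------------------------------------------------
# Video input
# --------------------------------------------------------------------------


def iter_frames(video) -> Iterator[np.ndarray]:
    """Iterate (H, W, 3) RGB frames from any supported video representation.

    Accepts a :class:`SyntheticVideo`, a (T, H, W, 3) array, a directory of
    PNG/ordered image files, or a container file readable by imageio.
    """
    if isinstance(video, SyntheticVideo):
        yield from video.frames
        return
    if isinstance(video, np.ndarray):
        if video.ndim != 4 or video.shape[-1] != 3:
            raise ParameterError("frame array must have shape (T, H, W, 3)")
        yield from video
        return
    if isinstance(video, (list, tuple)):
        yield from video
        return
    path = os.fspath(video)
    if os.path.isdir(path):
        import imageio.v3 as iio

        names = sorted(
            f for f in os.listdir(path)
            if f.lower().endswith((".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"))
        )
        if not names:
            raise ExtractionError(f"no image frames found in {path!r}")
        for name in names:
            frame = iio.imread(os.path.join(path, name))
            if frame.ndim == 2:
                frame = np.stack([frame] * 3, axis=-1)
            yield frame[..., :3]
        return
    if not os.path.exists(path):
        raise IOError(f"video file not found: {path!r}")
    import imageio

    reader = imageio.get_reader(path)
    try:
        for frame in reader:
            yield np.asarray(frame)[..., :3]
    finally:
        reader.close()


def video_fps(video, default: float | None = None) -> float:
    """Best-effort frame rate of a video input."""
    if isinstance(video, SyntheticVideo):
        return video.fps
    if default is not None:
        return default
    path = os.fspath(video) if not isinstance(video, np.ndarray) else None
    if path and os.path.isfile(path):
        import imageio

        reader = imageio.get_reader(path)
        try:
            meta = reader.get_meta_data()
        finally:
            reader.close()
        if "fps" in meta:
            return float(meta["fps"])
    raise ParameterError("frame rate unknown; pass fps explicitly")


# --------------------------------------------------------------------------
# Trace extraction
# --------------------------------------------------------------------------


def _interpolate_invalid(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linearly interpolate invalid frames of a (3, T) series in place."""
    T = values.shape[1]
    if valid.all():
        return values
    idx = np.arange(T)
    good = np.flatnonzero(valid)
    if good.size == 0:
        return values
    for c in range(3):
        values[c] = np.interp(idx, good, values[c, good])
    return values


def extract_holistic(video, extractor: SkinExtractor, fps: float | None = None) -> RGBTrace:
    """Average all skin pixels of each frame into a single RGB trace (P=1).

    Frames on which the extractor returns an empty mask are flagged invalid
    and filled by linear interpolation from neighbouring valid frames; if
    every frame is empty an :class:`ExtractionError` is raised.
    """
    fps = video_fps(video, fps)
    means, counts, valid = [], [], []
    for frame in iter_frames(video):
        frame = np.asarray(frame, dtype=float)
        mask = extractor.extract(frame)
        if mask.shape != frame.shape[:2]:
            raise ExtractionError(
                f"{type(extractor).__name__} returned mask of shape {mask.shape} "
                f"for frame of shape {frame.shape[:2]}"
            )
        n = int(mask.sum())
        if n == 0:
            means.append(np.zeros(3))
            counts.append(0)
            valid.append(False)
        else:
            means.append(frame[mask].mean(axis=0))
            counts.append(n)
            valid.append(True)
    if not means:
        raise ExtractionError("video contains no frames")
    valid_arr = np.asarray(valid, dtype=bool)
    if not valid_arr.any():
        raise ExtractionError(
            f"{type(extractor).__name__} produced an empty mask on every frame"
        )
    values = np.asarray(means, dtype=float).T  # (3, T)
    values = _interpolate_invalid(values, valid_arr)
    return RGBTrace(
        values=values[None, :, :],
        fps=fps,
        pixel_counts=np.maximum(np.asarray(counts, dtype=int), 1)[None, :],
        valid=valid_arr[None, :],
    )


class GridLandmarkProvider:
    """Synthetic landmark provider: a regular grid inside a rectangle.

    Emulates the face-mesh fiducial points for synthetic videos by laying
    an ``n x n`` grid of points inside the known skin box; landmark ids are
    row-major grid indices.
    """

    def __init__(self, skin_box: tuple[int, int, int, int], n: int = 22):
        r0, c0, h, w = skin_box
        rows = np.linspace(r0 + 1, r0 + h - 2, n)
        cols = np.linspace(c0 + 1, c0 + w - 2, n)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        self._points = np.column_stack([rr.ravel(), cc.ravel()])

    def landmarks(self, frame_index: int) -> np.ndarray:
        """(N, 2) array of (row, col) fiducial points for a frame."""
        return self._points


def extract_patches(
    video,
    extractor: SkinExtractor,
    patch_spec: PatchSpec,
    landmark_provider,
    fps: float | None = None,
) -> RGBTrace:
    """Per-patch RGB traces from square regions centred on landmarks.

    Patch i at frame t is the ``side x side`` square centred on landmark
    ``landmark_indices[i]`` (clipped to the frame), intersected with the
    skin mask; its trace value is the channel mean over that intersection.
    Frames with an empty intersection are flagged invalid and interpolated.
    """
    fps = video_fps(video, fps)
    P = len(patch_spec.landmark_indices)
    if P < 1:
        raise ParameterError("at least one landmark index required")
    half = patch_spec.side / 2.0
    means, counts, valid = [], [], []
    for t, frame in enumerate(iter_frames(video)):
        frame = np.asarray(frame, dtype=float)
        H, W = frame.shape[:2]
        mask = extractor.extract(frame)
        pts = np.asarray(landmark_provider.landmarks(t), dtype=float)
        m_t = np.zeros((P, 3))
        c_t = np.zeros(P, dtype=int)
        v_t = np.zeros(P, dtype=bool)
        for i, li in enumerate(patch_spec.landmark_indices):
            if li >= len(pts):
                continue
            r, c = pts[li]
            r0 = max(0, int(round(r - half)))
            r1 = min(H, int(round(r + half)))
            c0 = max(0, int(round(c - half)))
            c1 = min(W, int(round(c + half)))
            if r1 <= r0 or c1 <= c0:
                continue
            sub = mask[r0:r1, c0:c1]
            n = int(sub.sum())
            if n == 0:
                continue
            m_t[i] = frame[r0:r1, c0:c1][sub].mean(axis=0)
            c_t[i] = n
            v_t[i] = True
        means.append(m_t)
        counts.append(c_t)
        valid.append(v_t)
    if not means:
        raise ExtractionError("video contains no frames")
    values = np.stack(means, axis=-1)  # (P, 3, T)
    counts_arr = np.stack(counts, axis=-1)
    valid_arr = np.stack(valid, axis=-1)
    if not valid_arr.any():
        raise ExtractionError("no patch intersected the skin mask in any frame")
    for i in range(values.shape[0]):
        if valid_arr[i].any():
            _interpolate_invalid(values[i], valid_arr[i])
    return RGBTrace(
        values=values,
        fps=fps,
        pixel_counts=np.maximum(counts_arr, 1),
        valid=valid_arr,
    )


def collect_skin_pixels(video, extractor: SkinExtractor, fps: float | None = None) -> PixelWindowSeries:
    """Raw masked pixel matrices per frame (input for subspace rotation).

    Frames with an empty mask are dropped (with a warning); if all frames
    are dropped an :class:`ExtractionError` is raised.
    """
    import warnings

    fps = video_fps(video, fps)
    mats = []
    dropped = 0
    for frame in iter_frames(video):
        frame = np.asarray(frame, dtype=float)
        mask = extractor.extract(frame)
        if mask.any():
            mats.append(frame[mask])
        else:
            dropped += 1
    if not mats:
        raise ExtractionError("skin mask empty on every frame")
    if dropped:
        warnings.warn(f"dropped {dropped} frames with empty skin mask", stacklevel=2)
    return PixelWindowSeries(frames=tuple(mats), fps=fps)


# --------------------------------------------------------------------------
# Windowing
# --------------------------------------------------------------------------

#: Minimum fraction of valid frames for a patch to be used in a window.
PATCH_VALIDITY_THRESHOLD = 0.8


def window_signal(trace: RGBTrace, window_s: float, stride_s: float) -> WindowedTraces:
    """Slice a trace into K overlapping rectangular windows.

    K = floor((T - M) / (stride*fps)) + 1 with M = window_s * fps frames;
    window k covers frames [k*stride*fps, k*stride*fps + M) and its
    timestamp is the window centre.  The stride must satisfy the overlap
    inequality stride < window_s.

    Within a window, a patch is kept only if at least 80% of its frames are
    valid (tracked regions may vanish for a few frames); kept patches keep
    their interpolated values, dropped patches are marked by NaN rows so
    downstream aggregation can exclude them.
    """
    if stride_s <= 0:
        raise ParameterError("stride must be positive")
    if stride_s >= window_s:
        raise OverlapViolationError(
            f"stride ({stride_s}s) must be strictly smaller than the window "
            f"length ({window_s}s) for successive windows to overlap"
        )
    T = trace.n_frames
    M = int(round(window_s * trace.fps))
    if M > T:
        raise WindowTooLongError(
            f"window of {M} frames exceeds the signal length ({T} frames)"
        )
    if M < 2:
        raise SignalLengthError("window must span at least 2 frames")
    step = stride_s * trace.fps
    K = int(np.floor((T - M) / step)) + 1
    windows = []
    timestamps = np.empty(K)
    for k in range(K):
        start = int(round(k * step))
        sl = trace.values[:, :, start : start + M].copy()
        frac_valid = trace.valid[:, start : start + M].mean(axis=1)
        sl[frac_valid < PATCH_VALIDITY_THRESHOLD] = np.nan
        windows.append(sl)
        timestamps[k] = start / trace.fps + window_s / 2.0
    return WindowedTraces(
        windows=tuple(windows),
        timestamps=timestamps,
        window_s=window_s,
        stride_s=stride_s,
        fps=trace.fps,
    )
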