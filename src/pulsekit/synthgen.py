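"""Synthetic pulsatile signals, RGB traces and rendered face-patch videos.

Every downstream stage of the pipeline (extraction, pulse estimation,
spectral BPM recovery, metrics, statistics) is testable against these
generators without any dataset download: the generated data carry their own
ground truth (the BPM trajectory and the contact-style reference waveform).

The pulse model is deliberately simple — a fundamental sinusoid at the
instantaneous heart frequency plus an optional first harmonic — because
that is exactly the structure the spectral estimator and the projection
algorithms rely on.  Noise is i.i.d. Gaussian per sample; slow motion /
illumination drift can be added as a low-frequency additive component to
exercise detrending and band-pass filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ParameterError

__all__ = [
    "PulseSpec",
    "GroundTruthPPG",
    "SyntheticVideo",
    "make_bvp_waveform",
    "make_rgb_trace",
    "render_face_video",
]

#: Feasible heart-rate band in beats per minute.
BPM_MIN, BPM_MAX = 39.0, 240.0


@dataclass(frozen=True)
class GroundTruthPPG:
    """Contact-sensor style reference waveform g(t).

    Attributes
    ----------
    samples : np.ndarray
        The sampled waveform.
    sample_rate : float
        Sampling frequency in Hz.
    """

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass(frozen=True)
class PulseSpec:
    """Specification of a synthetic cardiac pulse.

    Parameters
    ----------
    duration_s : float
        Signal duration in seconds (> 0).
    fs : float
        Sampling / frame rate in Hz (> 0).
    bpm : float | sequence of (time_s, bpm) | callable
        Heart-rate trajectory.  A scalar gives a constant rate; a sequence
        of ``(time, bpm)`` breakpoints is linearly interpolated (held
        constant outside the breakpoints); a callable is evaluated at each
        sample time.  Every value must lie in the open feasible band so the
        fundamental stays below Nyquist.
    harmonic_weights : sequence of float
        Relative amplitudes of the fundamental and successive harmonics,
        ``weights[m]`` multiplying ``sin(2π (m+1) φ(t))``.
    noise_sd : float
        Standard deviation of additive white Gaussian noise, in the same
        (intensity) units as the waveform amplitude.
    drift_amplitude, drift_freq_hz : float
        Optional slow additive drift (default off).  ``drift_freq_hz`` must
        stay below 0.3 Hz — it emulates motion / illumination trends, not
        pulse.
    seed : int
        RNG seed; all generators are deterministic given the seed.
    """

    duration_s: float
    fs: float
    bpm: float | Sequence[tuple[float, float]] | Callable[[np.ndarray], np.ndarray] = 72.0
    harmonic_weights: tuple[float, ...] = (1.0, 0.0)
    noise_sd: float = 0.0
    drift_amplitude: float = 0.0
    drift_freq_hz: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be > 0")
        if self.fs <= 0:
            raise ParameterError("fs must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.drift_freq_hz >= 0.3 and self.drift_amplitude != 0:
            raise ParameterError("drift is restricted to < 0.3 Hz")
        # validate the whole trajectory up front: fundamental below Nyquist
        bpm = self.bpm_at(self.times())
        nyquist_bpm = self.fs * 30.0  # fs*60/2 in BPM terms
        if np.any(bpm <= 0) or np.any(bpm >= nyquist_bpm):
            raise ParameterError(
                f"BPM trajectory must lie in (0, {nyquist_bpm}) for fs={self.fs}"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) / self.fs

    def bpm_at(self, t: np.ndarray) -> np.ndarray:
        """Instantaneous BPM evaluated at times ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        if callable(self.bpm):
            return np.asarray(self.bpm(t), dtype=float)
        if np.isscalar(self.bpm):
            return np.full_like(t, float(self.bpm))
        pts = np.asarray(self.bpm, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ParameterError("bpm breakpoints must be (time, bpm) pairs")
        return np.interp(t, pts[:, 0], pts[:, 1])


def _phase(spec: PulseSpec) -> np.ndarray:
    """Integrated cardiac phase (cycles) at each sample time.

    φ(t) = ∫ BPM(u)/60 du, integrated by the cumulative trapezoid so a
    piecewise-linear trajectory produces the exact chirp phase.
    """
    t = spec.times()
    f_hz = spec.bpm_at(t) / 60.0
    phase = np.concatenate(
        [[0.0], np.cumsum(0.5 * (f_hz[1:] + f_hz[:-1]) * np.diff(t))]
    )
    return phase


def _clean_waveform(spec: PulseSpec) -> np.ndarray:
    """Noise-free pulse waveform (harmonic sum plus optional drift)."""
    phase = _phase(spec)
    x = np.zeros(spec.n_samples)
    for m, w in enumerate(spec.harmonic_weights, start=1):
        if w != 0:
            x += w * np.sin(2.0 * np.pi * m * phase)
    if spec.drift_amplitude != 0:
        t = spec.times()
        x += spec.drift_amplitude * np.sin(2.0 * np.pi * spec.drift_freq_hz * t)
    return x


def make_bvp_waveform(spec: PulseSpec) -> tuple[np.ndarray, GroundTruthPPG]:
    """Generate a sampled pulse waveform and its paired reference PPG.

    Returns
    -------
    waveform : np.ndarray of shape (T,)
        x(t) = Σ_m w_m sin(2π m φ(t)) + noise, with φ the integrated
        heart-frequency phase.
    truth : GroundTruthPPG
        The same samples packaged as a contact-style ground-truth waveform
        at the same sampling rate.
    """
    rng = np.random.default_rng(spec.seed)
    x = _clean_waveform(spec)
    if spec.noise_sd > 0:
        x = x + rng.normal(0.0, spec.noise_sd, size=x.shape)
    return x, GroundTruthPPG(samples=x.copy(), sample_rate=spec.fs)


@dataclass(frozen=True)
class SyntheticVideo:
    """A rendered face-patch video with known pulse content.

    Attributes
    ----------
    frames : np.ndarray, (T, H, W, 3), float64 in [0, 255]
        Frame stack, channel order R, G, B.
    fps : float
        Frame rate.
    skin_box : tuple (row0, col0, height, width)
        Rectangle of pixels carrying the pulse.
    truth : PulseSpec
        The generating specification.
    """

    frames: np.ndarray
    fps: float
    skin_box: tuple[int, int, int, int]
    truth: PulseSpec = field(repr=False)

    def skin_mask(self) -> np.ndarray:
        """Boolean (H, W) mask of the pulse-carrying rectangle."""
        h, w = self.frames.shape[1:3]
        r0, c0, bh, bw = self.skin_box
        mask = np.zeros((h, w), dtype=bool)
        mask[r0 : r0 + bh, c0 : c0 + bw] = True
        return mask


def _check_mixing_baseline(mixing, baseline) -> tuple[np.ndarray, np.ndarray]:
    mixing = np.asarray(mixing, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if mixing.shape != (3,) or baseline.shape != (3,):
        raise ParameterError("mixing and baseline must be 3-vectors (R, G, B)")
    if np.any(baseline <= 0) or np.any(baseline >= 255):
        raise ParameterError("baseline channels must lie in (0, 255)")
    return mixing, baseline


def make_rgb_trace(
    spec: PulseSpec,
    n_patches: int = 1,
    mixing: Sequence[float] = (0.3, 0.8, 0.4),
    baseline: Sequence[float] = (140.0, 110.0, 95.0),
):
    """Generate a per-patch RGB trace carrying the pulse.

    Stands in for the output of the video extraction stage:
    ``trace[i, c, t] = baseline[c] + mixing[c] * x(t) + noise`` with
    independent noise per patch and channel.  The default mixing puts the
    strongest pulse in the green channel, as observed for real skin.

    Returns an :class:`~pulsekit.extraction.RGBTrace` of shape
    ``(n_patches, 3, T)`` together with the paired ground truth.
    """
    from .extraction import RGBTrace  # local import to avoid a cycle

    if n_patches < 1:
        raise ParameterError("n_patches must be >= 1")
    mixing, baseline = _check_mixing_baseline(mixing, baseline)
    rng = np.random.default_rng(spec.seed)
    x = _clean_waveform(spec)
    T = spec.n_samples
    values = baseline[None, :, None] + mixing[None, :, None] * x[None, None, :]
    values = np.broadcast_to(values, (n_patches, 3, T)).copy()
    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, size=values.shape)
    np.clip(values, 0.0, 255.0, out=values)
    trace = RGBTrace(
        values=values,
        fps=spec.fs,
        pixel_counts=np.ones((n_patches, T), dtype=int),
        valid=np.ones((n_patches, T), dtype=bool),
    )
    truth = GroundTruthPPG(samples=x.copy(), sample_rate=spec.fs)
    return trace, truth


#: Flat background colour for pixels outside the skin box (non-skin).
BACKGROUND_RGB = (40.0, 60.0, 90.0)


def render_face_video(
    spec: PulseSpec,
    size: tuple[int, int] = (64, 64),
    skin_box: tuple[int, int, int, int] | None = None,
    mixing: Sequence[float] = (0.3, 0.8, 0.4),
    baseline: Sequence[float] = (140.0, 110.0, 95.0),
) -> SyntheticVideo:
    """Render a minimal face-patch video: a pulsing skin rectangle.

    Pixels inside ``skin_box`` are modulated exactly as in
    :func:`make_rgb_trace` with independent per-pixel noise; pixels outside
    take a constant non-skin colour.  The returned object records the
    generating spec so extraction stages can be checked against the truth.

    Parameters
    ----------
    size : (H, W)
        Frame dimensions in pixels.
    skin_box : (row0, col0, height, width), optional
        Pulse-carrying rectangle; default is a centred box covering ~1/4 of
        the frame.  Its area must be at least 9 pixels.
    """
    H, W = size
    if skin_box is None:
        bh, bw = max(3, H // 2), max(3, W // 2)
        skin_box = ((H - bh) // 2, (W - bw) // 2, bh, bw)
    r0, c0, bh, bw = skin_box
    if bh * bw < 9:
        raise ParameterError("skin_box area must be at least 9 pixels")
    if r0 < 0 or c0 < 0 or r0 + bh > H or c0 + bw > W:
        raise ParameterError("skin_box must lie inside the frame")
    mixing, baseline = _check_mixing_baseline(mixing, baseline)

    rng = np.random.default_rng(spec.seed)
    x = _clean_waveform(spec)
    T = spec.n_samples
    frames = np.empty((T, H, W, 3), dtype=np.float64)
    frames[..., 0] = BACKGROUND_RGB[0]
    frames[..., 1] = BACKGROUND_RGB[1]
    frames[..., 2] = BACKGROUND_RGB[2]
    # skin block: baseline + mixing * x(t) + per-pixel noise
    block = (
        baseline[None, None, None, :]
        + mixing[None, None, None, :] * x[:, None, None, None]
    )
    block = np.broadcast_to(block, (T, bh, bw, 3)).copy()
    if spec.noise_sd > 0:
        block += rng.normal(0.0, spec.noise_sd, size=block.shape)
    np.clip(block, 0.0, 255.0, out=block)
    frames[:, r0 : r0 + bh, c0 : c0 + bw, :] = block
    return SyntheticVideo(frames=frames, fps=spec.fs, skin_box=skin_box, truth=spec)


def export_png_sequence(video: SyntheticVideo, directory) -> list[str]:
    """Write a video as a lossless zero-padded PNG sequence; returns paths."""
    import os

    import imageio.v3 as iio

    os.makedirs(directory, exist_ok=True)
    paths = []
    for i, frame in enumerate(np.rint(video.frames).astype(np.uint8)):
        p = os.path.join(directory, f"frame_{i:06d}.png")
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def export_waveform_csv(gt: GroundTruthPPG, path) -> None:
    """Write a ground-truth waveform as a two-column (time, value) CSV."""
    t = np.arange(len(gt.samples)) / gt.sample_rate
    np.savetxt(
        path,
        np.column_stack([t, gt.samples]),
        delimiter=",",
        header="time_s,value",
        comments="",
    )


def load_waveform_csv(path, sample_rate: float | None = None) -> GroundTruthPPG:
    """Read a (time, value) CSV back into a ground-truth waveform.

    If ``sample_rate`` is omitted it is inferred from the median time step.
    """
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    if data.ndim == 1:
        data = data[None, :]
    if sample_rate is None:
        dt = np.median(np.diff(data[:, 0]))
        if not np.isfinite(dt) or dt <= 0:
            raise ParameterError("cannot infer sample rate from time column")
        sample_rate = 1.0 / dt
    return GroundTruthPPG(samples=data[:, 1], sample_rate=float(sample_rate))
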