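"""Stage 6: from pulse estimates to beats per minute.

Per analysis window and per patch, the power spectral density of the pulse
estimate y_i^k is computed with Welch's averaged-periodogram method and the
dominant frequency inside the feasible band Omega = [39, 240] BPM is taken
as the patch's BPM prediction h_i^k.  With P patches, the window estimate
is the median of the P predictions and its uncertainty is their median
absolute deviation (MAD), which drops to 0 when P = 1.

The same machinery derives the reference BPM series from a contact-sensor
PPG waveform, windowed identically to the video so the two series align.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .bvp import BVPWindows
from .errors import AggregationError, ParameterError, SignalLengthError
from .synthgen import GroundTruthPPG

__all__ = [
    "OMEGA_BPM",
    "PSD",
    "BPMSeries",
    "welch_psd",
    "peak_bpm",
    "aggregate_bpm",
    "estimate_bpm",
    "reference_bpm",
]

#: Feasible heart-rate band in BPM (inclusive endpoints).
OMEGA_BPM = (39.0, 240.0)

#: Minimum samples for a meaningful Welch estimate.
MIN_WINDOW_SAMPLES = 32


@dataclass(frozen=True)
class PSD:
    """Welch power spectral density restricted to the feasible BPM band."""

    freqs_bpm: np.ndarray
    power: np.ndarray  # (P, nbins), zero rows mark invalid patches
    nfft: int
    fps: float

    @property
    def resolution_bpm(self) -> float:
        """Frequency-grid spacing in BPM (60*fps/nfft)."""
        return 60.0 * self.fps / self.nfft


@dataclass(frozen=True)
class BPMSeries:
    """Windowed BPM estimates with robust uncertainty.

    ``bpm[k]`` is the median of the per-patch predictions of window k,
    ``mad[k]`` their median absolute deviation, ``per_patch[k]`` the raw
    (possibly NaN-padded) P-vector, ``timestamps[k]`` the window-centre
    time in seconds.
    """

    bpm: np.ndarray
    mad: np.ndarray
    per_patch: np.ndarray  # (K, P), NaN where a patch was invalid
    timestamps: np.ndarray

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.timestamps, self.bpm, self.mad]),
            delimiter=",",
            header="time_s,bpm,mad",
            comments="",
        )


def _next_pow2(n: int) -> int:
    return 1 << (int(n - 1).bit_length())


def welch_psd(
    window: np.ndarray,
    fps: float,
    nfft: int | None = None,
    seg_len: int | None = None,
    seg_overlap: float = 0.5,
) -> PSD:
    """Welch periodogram of one pulse window, restricted to Omega.

    Hann segments of ``seg_len`` samples (default min(M, 256)) with
    ``seg_overlap`` fractional overlap, averaged and zero-padded to
    ``nfft`` (default max(2048, next power of two >= M)) so the BPM grid
    resolution is at most ~1 BPM at ordinary frame rates.

    ``window`` is (P, M) or (M,); patches with non-finite samples get an
    all-zero power row (treated as invalid downstream).
    """
    y = np.atleast_2d(np.asarray(window, dtype=float))
    P, M = y.shape
    if M < MIN_WINDOW_SAMPLES:
        raise SignalLengthError(
            f"window of {M} samples is too short for spectral estimation "
            f"(need >= {MIN_WINDOW_SAMPLES})"
        )
    if seg_len is None:
        seg_len = min(M, 256)
    if nfft is None:
        # large enough that the BPM grid spacing 60*fps/nfft stays <= 1 BPM
        nfft = max(2048, _next_pow2(M), _next_pow2(int(np.ceil(60.0 * fps))))
    if nfft < M:
        raise ParameterError("nfft must be at least the window length")
    noverlap = int(seg_len * seg_overlap)
    finite = np.all(np.isfinite(y), axis=1)
    safe = np.where(finite[:, None], y, 0.0)
    freqs, pxx = welch(
        safe,
        fs=fps,
        window="hann",
        nperseg=seg_len,
        noverlap=noverlap,
        nfft=nfft,
        detrend="constant",
        axis=-1,
    )
    pxx[~finite] = 0.0
    freqs_bpm = freqs * 60.0
    band = (freqs_bpm >= OMEGA_BPM[0]) & (freqs_bpm <= OMEGA_BPM[1])
    return PSD(freqs_bpm=freqs_bpm[band], power=pxx[:, band], nfft=nfft, fps=fps)


def peak_bpm(psd: PSD) -> tuple[np.ndarray, np.ndarray]:
    """Per-patch argmax of the PSD over Omega, in BPM.

    Returns ``(values, valid)``; ties break toward the lower frequency
    (argmax returns the first maximum) and a patch whose power is all zero
    is flagged invalid rather than given a spurious 39 BPM.
    """
    vals = psd.freqs_bpm[np.argmax(psd.power, axis=1)]
    valid = psd.power.max(axis=1) > 0
    return vals, valid


def aggregate_bpm(per_patch: np.ndarray) -> tuple[float, float]:
    """Median and MAD of the per-patch BPM predictions of one window.

    The median follows the order-statistic definition (odd P: central
    element; even P: mean of the two central elements); the MAD is
    median(|H - median|).  With a single prediction the estimate is that
    value and the MAD is exactly 0.
    """
    H = np.sort(np.asarray(per_patch, dtype=float))
    H = H[np.isfinite(H)]
    P = H.size
    if P == 0:
        raise AggregationError("no valid per-patch BPM prediction in this window")
    if P == 1:
        return float(H[0]), 0.0
    if P % 2 == 1:
        med = H[(P - 1) // 2]
    else:
        med = 0.5 * (H[P // 2 - 1] + H[P // 2])
    mad = float(np.median(np.abs(H - med)))
    return float(med), mad


def estimate_bpm(
    bvp: BVPWindows,
    nfft: int | None = None,
    seg_len: int | None = None,
    seg_overlap: float = 0.5,
) -> BPMSeries:
    """Welch-peak BPM per patch and window, aggregated to median +/- MAD."""
    K = bvp.n_windows
    if K == 0:
        raise ParameterError("no windows to estimate from")
    P = max(w.shape[0] for w in bvp.windows)
    bpm = np.empty(K)
    mad = np.empty(K)
    per_patch = np.full((K, P), np.nan)
    for k, w in enumerate(bvp.windows):
        psd = welch_psd(w, bvp.fps, nfft=nfft, seg_len=seg_len, seg_overlap=seg_overlap)
        vals, valid = peak_bpm(psd)
        per_patch[k, : len(vals)] = np.where(valid, vals, np.nan)
        bpm[k], mad[k] = aggregate_bpm(per_patch[k])
    return BPMSeries(bpm=bpm, mad=mad, per_patch=per_patch, timestamps=bvp.timestamps)


def reference_bpm(
    gt: GroundTruthPPG,
    window_s: float,
    stride_s: float,
    nfft: int | None = None,
) -> BPMSeries:
    """Reference BPM from a contact PPG waveform, windowed like the video.

    The waveform g(t) is sliced with the same window length and stride as
    the video pipeline (timestamps align when the sample rate matches the
    frame rate) and each window's BPM is the Welch-PSD peak over Omega.
    """
    from .bvp import window_bvp

    samples = np.asarray(gt.samples, dtype=float)
    M = int(round(window_s * gt.sample_rate))
    if M > samples.size:
        raise SignalLengthError(
            f"ground-truth waveform ({samples.size} samples) shorter than one "
            f"window ({M} samples)"
        )
    windows = window_bvp(samples, gt.sample_rate, window_s, stride_s)
    return estimate_bpm(windows, nfft=nfft)
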