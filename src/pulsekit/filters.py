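"""Stages 3 and 5: pre-filtering of RGB traces, post-filtering of pulse signals.

Three canonical filters: a zero-phase Butterworth band-pass restricted to
the feasible heart-rate band, detrending (least-squares line removal or a
smoothness-priors trend regularised by second differences), and DC removal.
All operate along the last axis and preserve shape, so they apply equally
to (T,), (P, T) and (P, 3, T) arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .errors import ParameterError, SignalLengthError

__all__ = ["FilterParams", "bandpass", "detrend", "zero_mean", "apply_filter"]


@dataclass(frozen=True)
class FilterParams:
    """Butterworth band-pass parameters.

    Defaults follow the conventional pulse band: 0.65-4.0 Hz (39-240 BPM),
    6th order, which brackets physiologically plausible heart rates.
    """

    minHz: float = 0.65
    maxHz: float = 4.0
    fps: float = 30.0
    order: int = 6

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ParameterError("filter order must be >= 1")
        if not (0.0 < self.minHz < self.maxHz < self.fps / 2.0):
            raise ParameterError(
                f"band edges must satisfy 0 < minHz < maxHz < fps/2 "
                f"(got {self.minHz}, {self.maxHz} at fps={self.fps})"
            )


def bandpass(x: np.ndarray, params: FilterParams) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass along time.

    Filtering forward and backward doubles the effective order and cancels
    group delay, so window timestamps stay aligned with the filtered
    samples.
    """
    x = np.asarray(x, dtype=float)
    T = x.shape[-1]
    if T <= 3 * params.order:
        raise SignalLengthError(
            f"signal of length {T} too short for an order-{params.order} band-pass"
        )
    sos = sps.butter(
        params.order,
        [params.minHz, params.maxHz],
        btype="bandpass",
        fs=params.fps,
        output="sos",
    )
    out = sps.sosfiltfilt(sos, x, axis=-1)
    if not np.all(np.isfinite(out)):
        raise ParameterError("band-pass produced non-finite values")
    return out


def _smoothness_priors_trend(x: np.ndarray, lam: float) -> np.ndarray:
    """Trend of each series via second-difference regularisation.

    Solves (I + lam^2 D2'D2) z = x for the smooth trend z, the standard
    smoothness-priors detrending operator for photoplethysmography.
    """
    T = x.shape[-1]
    eye = sparse.identity(T, format="csc")
    data = np.ones((3, T - 2))
    data[1] *= -2.0
    D2 = sparse.spdiags(data, [0, 1, 2], T - 2, T, format="csc")
    A = (eye + (lam**2) * (D2.T @ D2)).tocsc()
    flat = x.reshape(-1, T)
    trend = np.empty_like(flat)
    for i, row in enumerate(flat):
        trend[i] = spsolve(A, row)
    return trend.reshape(x.shape)


def detrend(x: np.ndarray, method: str = "linear", lam: float = 300.0) -> np.ndarray:
    """Remove offsets and slow trends from each series.

    ``linear`` subtracts the least-squares line; ``smoothness_priors``
    subtracts a second-difference-regularised trend with weight ``lam``
    (default 300, conventional for pulse waveforms at ~30 Hz).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 3:
        raise SignalLengthError("detrend requires at least 3 samples")
    if method == "linear":
        return sps.detrend(x, axis=-1, type="linear")
    if method == "smoothness_priors":
        if lam <= 0:
            raise ParameterError("lambda must be positive")
        return x - _smoothness_priors_trend(x, lam)
    raise ParameterError(f"unknown detrend method {method!r}")


def zero_mean(x: np.ndarray) -> np.ndarray:
    """Subtract the temporal mean of each series (DC removal)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 1:
        raise SignalLengthError("empty signal")
    return x - x.mean(axis=-1, keepdims=True)


def apply_filter(windows, filt, **kwargs):
    """Apply a filter callable to every window of a windowed container.

    ``windows`` may be a WindowedTraces, a BVPWindows, or a plain sequence
    of arrays; returns the same container type with filtered slices.  NaN
    rows (dropped patches) pass through untouched.
    """
    from dataclasses import replace

    def _one(w: np.ndarray) -> np.ndarray:
        out = np.asarray(w, dtype=float).copy()
        flat = out.reshape(-1, out.shape[-1])
        ok = np.all(np.isfinite(flat), axis=1)
        if ok.any():
            flat[ok] = filt(flat[ok], **kwargs)
        return flat.reshape(out.shape)

    if hasattr(windows, "windows"):
        return replace(windows, windows=tuple(_one(w) for w in windows.windows))
    return [_one(w) for w in windows]
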