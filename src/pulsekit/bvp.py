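"""Stage 4: blood-volume-pulse estimation from windowed RGB traces.

Eight classical algorithms map a windowed trace C of shape (P, 3, M) to a
per-patch pulse estimate y of shape (P, M):

* GREEN  — the green channel itself (baseline).
* CHROM  — chrominance combination X = 3R-2G, Y = 1.5R+G-1.5B on
           temporally normalised channels, alpha-tuned difference.
* POS    — projection onto the plane orthogonal to the skin tone.
* PBV    — blood-volume-pulse signature regression.
* PCA    — principal component of the channel covariance, selected by
           in-band spectral concentration.
* ICA    — blind source separation (FastICA), source with the strongest
           in-band spectral peak.
* LGI    — local group invariance: project out the leading singular
           direction of the centred traces.
* SSR    — spatial subspace rotation; unlike the others it consumes the
           raw skin-pixel population per frame, not the averaged trace.

All trace methods return zero-mean rows.  Degenerate inputs (zero temporal
variance in a needed channel) never crash: any internal sd-ratio with zero
denominator evaluates to 0 and a zero-variance window maps to zeros.
Patches dropped by the windowing stage arrive as NaN rows and propagate as
NaN rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import ParameterError, RegistryError, SignalLengthError
from .extraction import PixelWindowSeries, WindowedTraces

__all__ = [
    "BVPWindows",
    "MethodSpec",
    "green",
    "chrom",
    "pos",
    "pbv",
    "pca",
    "ica",
    "lgi",
    "ssr",
    "estimate_bvp",
    "register_method",
    "available_methods",
    "window_bvp",
]

_EPS = 1e-12


@dataclass(frozen=True)
class BVPWindows:
    """Per-window pulse estimates y_i^k: K arrays of shape (P, M)."""

    windows: tuple[np.ndarray, ...]
    fps: float
    timestamps: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.windows)


@dataclass(frozen=True)
class MethodSpec:
    """A registered pulse-extraction method plus its parameters."""

    name: str
    params: dict = field(default_factory=dict)

    @property
    def input_kind(self) -> str:
        return _registry_entry(self.name)[1]


def _sd(x: np.ndarray, axis=-1) -> np.ndarray:
    return np.std(x, axis=axis)


def _sd_ratio(num: np.ndarray, den: np.ndarray):
    """sd(num)/sd(den), defined as 0 where the denominator vanishes."""
    sn, sd_ = _sd(num), _sd(den)
    return np.where(sd_ > _EPS, sn / np.maximum(sd_, _EPS), 0.0)


def _check_window(C: np.ndarray) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if C.ndim == 2:
        C = C[None, :, :]
    if C.ndim != 3 or C.shape[1] != 3:
        raise ParameterError("window must have shape (P, 3, M)")
    if C.shape[2] < 32:
        raise SignalLengthError("window must contain at least 32 frames")
    return C


def _normalise_channels(C: np.ndarray) -> np.ndarray:
    """Divide each channel by its temporal mean (1 where the mean is ~0)."""
    mu = C.mean(axis=-1, keepdims=True)
    safe = np.where(np.abs(mu) > _EPS, mu, 1.0)
    return C / safe


def _demean(y: np.ndarray) -> np.ndarray:
    return y - y.mean(axis=-1, keepdims=True)


def green(C: np.ndarray) -> np.ndarray:
    """Green-channel trace as the pulse estimate (baseline method)."""
    C = _check_window(C)
    return _demean(C[:, 1, :])


def chrom(C: np.ndarray) -> np.ndarray:
    """Chrominance-based pulse estimation.

    On temporally normalised channels Rn, Gn, Bn build the chrominance
    signals Xs = 3Rn - 2Gn and Ys = 1.5Rn + Gn - 1.5Bn and combine them as
    y = Xs - alpha*Ys with alpha = sd(Xs)/sd(Ys), which cancels specular /
    intensity variation under the standardised skin-tone assumption.
    """
    C = _check_window(C)
    Cn = _normalise_channels(C)
    Rn, Gn, Bn = Cn[:, 0], Cn[:, 1], Cn[:, 2]
    Xs = 3.0 * Rn - 2.0 * Gn
    Ys = 1.5 * Rn + Gn - 1.5 * Bn
    alpha = _sd_ratio(Xs, Ys)[:, None]
    return _demean(Xs - alpha * Ys)


# Fixed projection onto the plane orthogonal to the (1,1,1) intensity axis.
_POS_PM = np.array([[0.0, 1.0, -1.0], [-2.0, 1.0, 1.0]])


def pos(C: np.ndarray) -> np.ndarray:
    """Plane-orthogonal-to-skin pulse estimation.

    Projects the temporally normalised channels onto two directions
    orthogonal to the mean skin tone and alpha-tunes their sum:
    y = S1 + (sd(S1)/sd(S2)) * S2.
    """
    C = _check_window(C)
    Cn = _normalise_channels(C)
    S = np.einsum("dc,pct->pdt", _POS_PM, Cn)
    S1, S2 = S[:, 0], S[:, 1]
    alpha = _sd_ratio(S1, S2)[:, None]
    return _demean(S1 + alpha * S2)


def pbv(C: np.ndarray, ridge: float = 1e-9) -> np.ndarray:
    """Blood-volume-pulse signature method.

    The per-window channel standard deviations of the normalised traces
    form the pulse signature s; solving (Cn Cn' + ridge*I) w = s gives the
    weighting that distinguishes pulse-induced colour changes from motion
    noise.  The signature is data-driven (computed per window).
    """
    C = _check_window(C)
    Cn = _normalise_channels(C)
    P, _, M = Cn.shape
    out = np.empty((P, M))
    for i in range(P):
        X = Cn[i]
        if not np.all(np.isfinite(X)):
            out[i] = np.nan
            continue
        s = X.std(axis=-1)
        norm = np.linalg.norm(s)
        if norm < _EPS:
            out[i] = 0.0
            continue
        s = s / norm
        # centre the normalised channels before the solve: the shared DC
        # component would otherwise dominate the Gram matrix and force the
        # weights orthogonal to (1,1,1), cancelling a pulse present in all
        # channels
        Xc = X - X.mean(axis=-1, keepdims=True)
        Q = Xc @ Xc.T + ridge * np.eye(3)
        w = np.linalg.solve(Q, s)
        out[i] = w @ Xc
    return _demean(out)


def _inband_mask(freqs_hz: np.ndarray, lo: float = 0.65, hi: float = 4.0) -> np.ndarray:
    return (freqs_hz >= lo) & (freqs_hz <= hi)


def _periodogram(y: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    from scipy.signal import periodogram

    f, p = periodogram(y, fs=fs, detrend="constant")
    return f, p


def _spectral_concentration(y: np.ndarray, fs: float) -> float:
    """Ratio of the in-band (0.65-4 Hz) peak power to total in-band power."""
    f, p = _periodogram(y, fs)
    band = _inband_mask(f)
    total = p[band].sum()
    if total < _EPS:
        return -np.inf
    return float(p[band].max() / total)


def pca(C: np.ndarray, fps: float = 30.0) -> np.ndarray:
    """Principal-component pulse estimation.

    Eigendecomposes the 3x3 covariance of the mean-centred channels and
    returns the projection whose periodogram is most concentrated at a
    single in-band (0.65-4 Hz) peak.
    """
    C = _check_window(C)
    P, _, M = C.shape
    out = np.empty((P, M))
    for i in range(P):
        X = C[i]
        if not np.all(np.isfinite(X)):
            out[i] = np.nan
            continue
        Xc = X - X.mean(axis=-1, keepdims=True)
        cov = Xc @ Xc.T / M
        if np.trace(cov) < _EPS:
            out[i] = 0.0
            continue
        _, vecs = np.linalg.eigh(cov)
        sources = vecs.T @ Xc  # (3, M)
        scores = [_spectral_concentration(sources[j], fps) for j in range(3)]
        out[i] = sources[int(np.argmax(scores))]
    return _demean(out)


def ica(C: np.ndarray, seed: int = 0, fps: float = 30.0) -> np.ndarray:
    """Blind-source-separation pulse estimation via FastICA.

    Channels are standardised, three sources are unmixed with a
    deflationary FastICA (fixed seed for determinism), and the source whose
    Welch spectrum peaks highest inside the feasible band is returned, with
    its sign fixed so the peak-bin phase matches the green channel's.
    """
    from sklearn.decomposition import FastICA

    C = _check_window(C)
    P, _, M = C.shape
    out = np.empty((P, M))
    for i in range(P):
        X = C[i]
        if not np.all(np.isfinite(X)):
            out[i] = np.nan
            continue
        sd = X.std(axis=-1, keepdims=True)
        if np.all(sd < _EPS):
            out[i] = 0.0
            continue
        Z = (X - X.mean(axis=-1, keepdims=True)) / np.where(sd > _EPS, sd, 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            transformer = FastICA(
                n_components=3,
                algorithm="deflation",
                fun="logcosh",
                random_state=np.random.RandomState(seed),
                whiten="unit-variance",
                max_iter=500,
            )
            sources = transformer.fit_transform(Z.T).T  # (3, M)
        # pick the source with the largest in-band spectral peak
        best, best_peak, best_bin = 0, -np.inf, 0
        for j in range(3):
            f, p = _periodogram(sources[j], fps)
            band = _inband_mask(f, 39.0 / 60.0, 240.0 / 60.0)
            if not band.any():
                continue
            peak = p[band].max()
            if peak > best_peak:
                best, best_peak = j, peak
                best_bin = np.flatnonzero(band)[int(np.argmax(p[band]))]
        y = sources[best]
        # sign: align the phase at the peak DFT bin with the green channel
        spec_y = np.fft.rfft(y)[best_bin]
        spec_g = np.fft.rfft(Z[1] - Z[1].mean())[best_bin]
        if np.real(spec_y * np.conj(spec_g)) < 0:
            y = -y
        out[i] = y
    return _demean(out)


def lgi(C: np.ndarray) -> np.ndarray:
    """Local-group-invariance pulse estimation.

    Projects the raw traces onto the complement of their leading singular
    direction and keeps the green row of the residual.  On raw (not
    centred) windows the leading direction is the quasi-static skin-tone
    axis, so the projection removes the DC level and intensity/motion
    variation along it while pulse components off that axis survive.
    """
    C = _check_window(C)
    P, _, M = C.shape
    out = np.empty((P, M))
    for i in range(P):
        X = C[i]
        if not np.all(np.isfinite(X)):
            out[i] = np.nan
            continue
        if np.linalg.norm(X) < _EPS or np.std(X) < _EPS:
            out[i] = 0.0
            continue
        U, _, _ = np.linalg.svd(X, full_matrices=False)
        u1 = U[:, 0:1]
        out[i] = ((np.eye(3) - u1 @ u1.T) @ X)[1]
    return _demean(out)


def ssr(pixels: PixelWindowSeries, l: int | None = None) -> np.ndarray:
    """Spatial subspace rotation on raw skin-pixel populations.

    Per frame t the 3x3 pixel correlation matrix C_t = V_t' V_t / N_t is
    eigendecomposed (descending eigenvalues; eigenvector signs fixed so the
    largest-magnitude entry is positive).  Over each sliding segment of
    ``l`` frames ending at t, the rotation of the leading eigenvector
    against the current subspace gives

        r1(tau) = sqrt(lam1(tau)/lam2(t)) * u1(tau).u2(t)
        r2(tau) = sqrt(lam1(tau)/lam3(t)) * u1(tau).u3(t)

    and the segment pulse p = r1 - (sd(r1)/sd(r2)) * r2 (mean-subtracted)
    is overlap-added into the output series.

    Parameters
    ----------
    l : int
        Segment length in frames; defaults to round(fps) (about one
        second).

    Returns
    -------
    np.ndarray of shape (T,): the pulse series over the whole input.
    """
    T = pixels.n_frames
    if l is None:
        l = int(round(pixels.fps))
    if l < 2:
        raise ParameterError("segment length l must be at least 2 frames")
    if T < l:
        raise SignalLengthError(f"need at least l={l} frames, got {T}")
    lams = np.empty((T, 3))
    us = np.empty((T, 3, 3))  # us[t, :, j] = eigenvector j at frame t
    for t, V in enumerate(pixels.frames):
        if V.shape[0] < 3:
            raise ParameterError(f"frame {t} has fewer than 3 skin pixels")
        Ct = V.T @ V / V.shape[0]
        w, vecs = np.linalg.eigh(Ct)  # ascending
        order = np.argsort(w)[::-1]
        w, vecs = w[order], vecs[:, order]
        # fix signs: largest-magnitude entry of each eigenvector positive
        for j in range(3):
            k = np.argmax(np.abs(vecs[:, j]))
            if vecs[k, j] < 0:
                vecs[:, j] = -vecs[:, j]
        lams[t], us[t] = w, vecs
    out = np.zeros(T)
    counts = np.zeros(T)
    for t in range(l - 1, T):
        sl = slice(t - l + 1, t + 1)
        lam2_t, lam3_t = lams[t, 1], lams[t, 2]
        if lam2_t <= _EPS or lam3_t <= _EPS:
            warnings.warn(
                f"degenerate pixel-correlation spectrum at frame {t}; segment skipped",
                stacklevel=2,
            )
            continue
        lam1 = lams[sl, 0]
        u1 = us[sl, :, 0]  # (l, 3)
        r1 = np.sqrt(lam1 / lam2_t) * (u1 @ us[t, :, 1])
        r2 = np.sqrt(lam1 / lam3_t) * (u1 @ us[t, :, 2])
        p = r1 - _sd_ratio(r1, r2) * r2
        p = p - p.mean()
        out[sl] += p
        counts[sl] += 1.0
    if not counts.any():
        return out
    return out


def window_bvp(series: np.ndarray, fps: float, window_s: float, stride_s: float) -> BVPWindows:
    """Slice a full-length pulse series into overlapping windows.

    Mirrors the trace windowing so pulse estimates produced on the whole
    video (subspace rotation, external deep estimators) feed the same BPM
    stage as the per-window methods.
    """
    from .extraction import RGBTrace, window_signal

    series = np.atleast_2d(np.asarray(series, dtype=float))  # (P, T)
    P, T = series.shape
    fake = RGBTrace(
        values=np.repeat(series[:, None, :], 3, axis=1),
        fps=fps,
        pixel_counts=np.ones((P, T), dtype=int),
        valid=np.ones((P, T), dtype=bool),
    )
    wt = window_signal(fake, window_s, stride_s)
    return BVPWindows(
        windows=tuple(w[:, 0, :] for w in wt.windows),
        fps=fps,
        timestamps=wt.timestamps,
    )


# --------------------------------------------------------------------------
# Registry and dispatch
# --------------------------------------------------------------------------

_TRACE_METHODS: dict[str, Callable] = {}
_PIXEL_METHODS: dict[str, Callable] = {}


def register_method(name: str, func: Callable, input_kind: str = "trace") -> None:
    """Register a pulse-extraction method under a config-usable name.

    A trace method must accept a (P, 3, M) array (plus keyword parameters)
    and return (P, M); a pixels method must accept a PixelWindowSeries and
    return a 1-D series.
    """
    table = {"trace": _TRACE_METHODS, "pixels": _PIXEL_METHODS}.get(input_kind)
    if table is None:
        raise ParameterError("input_kind must be 'trace' or 'pixels'")
    table[name.upper()] = func


def _registry_entry(name: str) -> tuple[Callable, str]:
    key = name.upper()
    if key in _TRACE_METHODS:
        return _TRACE_METHODS[key], "trace"
    if key in _PIXEL_METHODS:
        return _PIXEL_METHODS[key], "pixels"
    raise RegistryError(
        f"unknown method {name!r}; available: {sorted(available_methods())}"
    )


def available_methods() -> list[str]:
    return sorted(_TRACE_METHODS) + sorted(_PIXEL_METHODS)


for _name, _fn in [
    ("GREEN", green),
    ("CHROM", chrom),
    ("POS", pos),
    ("PBV", pbv),
    ("PCA", pca),
    ("ICA", ica),
    ("LGI", lgi),
]:
    register_method(_name, _fn, "trace")
register_method("SSR", ssr, "pixels")


def estimate_bvp(windowed, spec: MethodSpec | str) -> BVPWindows:
    """Dispatch a windowed trace (or pixel series) to a registered method.

    Trace methods run once per analysis window; the pixels method runs on
    the whole series and returns a single full-length window (slice it with
    :func:`window_bvp` before BPM estimation).
    """
    if isinstance(spec, str):
        spec = MethodSpec(name=spec)
    func, kind = _registry_entry(spec.name)
    params = dict(spec.params)
    if kind == "trace":
        if not isinstance(windowed, WindowedTraces):
            raise ParameterError(
                f"method {spec.name!r} requires windowed RGB traces"
            )
        if spec.name.upper() in ("ICA", "PCA"):
            params.setdefault("fps", windowed.fps)
        outs = tuple(np.atleast_2d(func(w, **params)) for w in windowed.windows)
        return BVPWindows(windows=outs, fps=windowed.fps, timestamps=windowed.timestamps)
    if not isinstance(windowed, PixelWindowSeries):
        raise ParameterError(f"method {spec.name!r} requires raw skin pixels")
    series = func(windowed, **params)
    T = len(series)
    return BVPWindows(
        windows=(np.atleast_2d(series),),
        fps=windowed.fps,
        timestamps=np.array([T / (2.0 * windowed.fps)]),
    )
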