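"""Agreement metrics between predicted and reference BPM series.

Five metrics: MAE, RMSE, Pearson correlation (PCC), Lin's concordance
correlation (CCC) and a spectral signal-to-noise ratio (SNR).  PCC and CCC
use population (1/K) moments, matching the CCC denominator

    CCC = 2*cov / ((mu_pred - mu_ref)^2 + var_pred + var_ref),

so |CCC| <= |PCC| always holds (the concordance penalises location and
scale shifts that leave PCC untouched).

The SNR compares, per window, the estimated pulse's spectral power within
+/-12 BPM of the reference rate and of its first harmonic against all
remaining power, in dB, averaged over windows.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import welch

from .bvp import BVPWindows
from .errors import ParameterError

__all__ = ["mae", "rmse", "pcc", "ccc", "snr_db", "MetricsResult", "compute_all"]

#: Half-width of the SNR pass band around the reference rate, in BPM.
SNR_HALF_BAND_BPM = 12.0

#: Floor for the out-of-band power (caps the SNR for pure tones).
SNR_POWER_FLOOR = 1e-12


def _pair(pred, ref) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float).ravel()
    r = np.asarray(ref, dtype=float).ravel()
    if p.size != r.size:
        raise ParameterError(f"series lengths differ: {p.size} vs {r.size}")
    if p.size < 1:
        raise ParameterError("empty series")
    return p, r


def mae(pred, ref) -> float:
    """Mean absolute error (1/K) * sum |pred_k - ref_k|."""
    p, r = _pair(pred, ref)
    return float(np.mean(np.abs(p - r)))


def rmse(pred, ref, strict_paper: bool = False) -> float:
    """Root-mean-square error.

    Default is the conventional sqrt of the mean squared difference.  With
    ``strict_paper=True`` the normalisation 1/K multiplies the square root
    of the *sum* of squares instead (an occasionally printed variant that
    scales as 1/sqrt(K) relative to the conventional one).
    """
    p, r = _pair(pred, ref)
    sq = (p - r) ** 2
    if strict_paper:
        return float(np.sqrt(sq.sum()) / sq.size)
    return float(np.sqrt(sq.mean()))


def _moments(p: np.ndarray, r: np.ndarray):
    mu_p, mu_r = p.mean(), r.mean()
    var_p = np.mean((p - mu_p) ** 2)
    var_r = np.mean((r - mu_r) ** 2)
    cov = np.mean((p - mu_p) * (r - mu_r))
    return mu_p, mu_r, var_p, var_r, cov


def pcc(pred, ref) -> float:
    """Pearson correlation coefficient (population moments)."""
    p, r = _pair(pred, ref)
    if p.size < 2:
        raise ParameterError("correlation requires at least 2 samples")
    _, _, var_p, var_r, cov = _moments(p, r)
    if var_p == 0 or var_r == 0:
        raise ParameterError("correlation undefined for a constant series")
    return float(cov / np.sqrt(var_p * var_r))


def ccc(pred, ref) -> float:
    """Lin's concordance correlation coefficient.

    2*cov / ((mu_pred - mu_ref)^2 + var_pred + var_ref) with population
    moments; equals PCC only under exact location/scale agreement.
    """
    p, r = _pair(pred, ref)
    if p.size < 2:
        raise ParameterError("concordance requires at least 2 samples")
    mu_p, mu_r, var_p, var_r, cov = _moments(p, r)
    denom = (mu_p - mu_r) ** 2 + var_p + var_r
    if denom == 0:
        raise ParameterError("concordance undefined for identical constant series")
    return float(2.0 * cov / denom)


def snr_db(
    bvp: BVPWindows,
    ref_bpm,
    fps: float | None = None,
    nfft: int | None = None,
) -> float:
    """Spectral SNR of the pulse estimate against the reference rate.

    For window k with reference rate h_k, a binary mask U selects the
    frequency bins within +/-12 BPM of h_k and of its first harmonic 2*h_k
    on the full Welch grid; the window's SNR is

        10 * log10( sum(U * S) / sum((1 - U) * S) )

    with S the (squared-magnitude) power spectral density averaged over
    valid patches; the out-of-band power is floored at 1e-12 so a pure
    on-reference tone yields a large capped value rather than infinity.
    Windows whose mask covers no bin are skipped with a warning.  Returns
    the average over windows.
    """
    ref = np.asarray(ref_bpm, dtype=float).ravel()
    if ref.size != bvp.n_windows:
        raise ParameterError(
            f"reference has {ref.size} windows, pulse estimate has {bvp.n_windows}"
        )
    fps = fps or bvp.fps
    vals = []
    for k, w in enumerate(bvp.windows):
        y = np.atleast_2d(np.asarray(w, dtype=float))
        M = y.shape[1]
        n = nfft or max(2048, 1 << int(M - 1).bit_length())
        finite = np.all(np.isfinite(y), axis=1)
        if not finite.any():
            continue
        freqs, pxx = welch(
            y[finite],
            fs=fps,
            window="hann",
            nperseg=min(M, 256),
            noverlap=min(M, 256) // 2,
            nfft=n,
            detrend="constant",
            axis=-1,
        )
        S = pxx.mean(axis=0)
        f_bpm = freqs * 60.0
        mask = (np.abs(f_bpm - ref[k]) <= SNR_HALF_BAND_BPM) | (
            np.abs(f_bpm - 2.0 * ref[k]) <= SNR_HALF_BAND_BPM
        )
        if not mask.any():
            warnings.warn(
                f"window {k}: reference rate {ref[k]:.1f} BPM outside the "
                "spectral grid; window skipped",
                stacklevel=2,
            )
            continue
        sig = S[mask].sum()
        noise = max(S[~mask].sum(), SNR_POWER_FLOOR)
        vals.append(10.0 * np.log10(max(sig, SNR_POWER_FLOOR) / noise))
    if not vals:
        raise ParameterError("no window produced a valid SNR")
    return float(np.mean(vals))


class MetricsResult(dict):
    """Scalar metric values for one (video, method) pair.

    A thin dict with keys MAE, RMSE, PCC, CCC, SNR; attribute access is
    provided for convenience.
    """

    def __getattr__(self, key):
        try:
            return self[key]
        except KeyError as e:  # pragma: no cover
            raise AttributeError(key) from e


def compute_all(
    pred_bpm,
    ref_bpm,
    bvp: BVPWindows | None = None,
    fps: float | None = None,
) -> MetricsResult:
    """All five metrics for one prediction/reference pair.

    A metric that is undefined for the pair at hand (correlations of a
    constant series; SNR when ``bvp`` is not supplied) is reported as NaN
    rather than aborting the batch.
    """
    out = MetricsResult(
        MAE=mae(pred_bpm, ref_bpm),
        RMSE=rmse(pred_bpm, ref_bpm),
        PCC=np.nan,
        CCC=np.nan,
        SNR=np.nan,
    )
    for key, fn in (("PCC", pcc), ("CCC", ccc)):
        try:
            out[key] = fn(pred_bpm, ref_bpm)
        except ParameterError:
            pass
    if bvp is not None:
        try:
            out["SNR"] = snr_db(bvp, ref_bpm, fps=fps)
        except ParameterError:
            pass
    return out
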