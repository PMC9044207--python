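"""Waveform-complexity features for real-vs-fake video discrimination.

Face-swapping disrupts the subtle pulse-related colour signal, so pulse
estimates from manipulated videos behave like noise: higher waveform
complexity and less agreement across patches.  Two per-video features
capture this:

* ``FD_vid`` — the Katz fractal dimension of the estimated pulse, averaged
  over patches and windows;
* ``MAD_vid`` — the average across windows of the per-window MAD of the
  patch BPM predictions.

A genuine video clusters at low FD / low MAD; a swapped one drifts toward
high FD / high MAD, and a linear decision boundary in this plane already
separates the two classes well.
"""

from __future__ import annotations

import numpy as np

from .bvp import BVPWindows
from .errors import ParameterError, SignalLengthError
from .spectral import BPMSeries

__all__ = ["katz_fd", "video_features", "fit_linear_detector"]


def katz_fd(signal, normalize: bool = False) -> float:
    """Katz fractal dimension of a sampled waveform.

    The waveform is treated as the planar curve (t, x_t) with unit index
    spacing (abscissa in the same units as the amplitude).  With L the sum
    of Euclidean distances between successive points, a = L/(n-1) the mean
    step and d the maximum Euclidean distance from the first point,

        D = log10(L/a) / log10(d/a).

    A straight line gives exactly 1; rougher waveforms give larger values.
    A constant signal (or any curve with d = a) is defined to have D = 1,
    the straight-line limit.

    With ``normalize=True`` the amplitude is first scaled to unit standard
    deviation, making D independent of the waveform's physical units.
    """
    x = np.asarray(signal, dtype=float).ravel()
    n = x.size
    if n < 3:
        raise SignalLengthError("Katz FD requires at least 3 samples")
    if not np.all(np.isfinite(x)):
        raise ParameterError("signal contains non-finite values")
    if normalize:
        s = x.std()
        if s > 0:
            x = x / s
    dx = np.diff(x)
    if np.all(dx == 0):
        return 1.0
    L = float(np.sum(np.sqrt(1.0 + dx**2)))
    a = L / (n - 1)
    idx = np.arange(n, dtype=float)
    d = float(np.max(np.sqrt(idx**2 + (x - x[0]) ** 2)))
    ratio = d / a
    if ratio <= 1.0:
        return 1.0
    return float(np.log10(L / a) / np.log10(ratio))


def video_features(
    bvp: BVPWindows,
    bpm: BPMSeries,
    normalize_fd: bool = False,
) -> tuple[float, float]:
    """Per-video (FD_vid, MAD_vid) feature pair.

    ``FD_vid`` averages the Katz fractal dimension over every valid
    (patch, window) pulse estimate; ``MAD_vid`` averages the per-window MAD
    of the BPM predictions.  Patches dropped by the windowing stage (NaN
    rows) are excluded from the FD average.
    """
    if bvp.n_windows == 0:
        raise ParameterError("no pulse windows")
    if bpm.mad.size == 0:
        raise ParameterError("no BPM windows")
    fds = []
    for w in bvp.windows:
        for row in np.atleast_2d(w):
            if np.all(np.isfinite(row)):
                fds.append(katz_fd(row, normalize=normalize_fd))
    if not fds:
        raise ParameterError("every patch in every window was invalid")
    return float(np.mean(fds)), float(np.mean(bpm.mad))


def fit_linear_detector(features: np.ndarray, labels, seed: int = 0):
    """Convenience linear-SVM detector over (FD_vid, MAD_vid) pairs.

    Features are standardised and a linear support-vector classifier is
    fitted; returns the fitted sklearn Pipeline.  This is a thin wrapper —
    cross-validation protocols belong in analysis scripts, not here.
    """
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import LinearSVC

    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ParameterError("features must be (n_videos, 2): FD_vid, MAD_vid")
    clf = make_pipeline(StandardScaler(), LinearSVC(random_state=seed))
    clf.fit(X, np.asarray(labels))
    return clf
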