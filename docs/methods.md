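# Methods

## Signal model

The package assumes the standard rPPG observation model: within a skin
region, the camera sees a quasi-static baseline colour plus a small
pulse-synchronous modulation and sensor noise,

    p(t) = b + m · x(t) + ε(t),

with `b` the per-channel baseline in [0, 255], `m` the per-channel pulse
amplitude (strongest in green for real skin), `x(t)` the cardiac waveform
and `ε` zero-mean noise. Spatial averaging over N pixels reduces the noise
by √N, which is why both the holistic region and per-patch means are taken
before any temporal processing.

## Synthetic generator

The generator emulates exactly this model. The cardiac waveform is a
fundamental sinusoid at the instantaneous heart frequency plus an optional
first harmonic; the instantaneous phase is the trapezoidal integral of the
BPM trajectory (scalar, piecewise-linear breakpoints, or a callable), so
chirps have the exact analytic phase. Noise is i.i.d. Gaussian per sample
(and per pixel in rendered videos); slow motion/illumination trends can be
added as a < 0.3 Hz additive drift to exercise detrending and band-pass.
Intensities are clipped to [0, 255]; with the default baseline
(140, 110, 95), mixing (0.3, 0.8, 0.4) and noise at the levels used in the
tests, clipping probability is negligible.

Defaults used throughout the tests: 30 fps, 6 s windows with 1 s stride
(20–30 s clips), pulse amplitude of order 1 intensity unit against noise
of 0.2–0.5 — chosen to match the regime where classical rPPG methods are
expected to work cleanly, so failures indicate implementation defects
rather than hopeless inputs.

What the generator does **not** emulate: PPG morphology (dicrotic notch),
specular highlights, subject motion with occlusion, compression artefacts,
or channel-correlated sensor noise. Passing tests therefore demonstrate
algorithmic correctness, not field robustness on real faces.

One consequence worth noting: rendered videos use *isotropic* per-pixel
noise, so the second and third eigenvectors of the per-frame pixel
correlation matrix — the rotation reference used by SSR — are nearly
degenerate and rotate freely frame to frame. SSR is therefore noisier on
these synthetic videos than on real skin (whose noise is anisotropic);
the 20 s clips used in the tests average this out.

## Windowing

K = ⌊(T − M)/(τ·F_s)⌋ + 1 rectangular windows of M = W_s·F_s frames;
window k covers frames [k·τ·F_s, k·τ·F_s + M) and is stamped at its centre
time. The stride must satisfy τ < W_s (overlap inequality); violating it
raises an error rather than silently producing gapped coverage. A tracked
patch that is present in at least 80% of a window's frames is kept (its
missing frames linearly interpolated); below that it is dropped from the
window (NaN row) and excluded from the BPM median — tracking dropouts
should widen the uncertainty, not bias the estimate.

## Pulse-extraction methods

All trace methods receive one (P, 3, M) window and return (P, M), zero-mean
per patch. Degenerate inputs never crash: any internal sd-ratio with a
vanishing denominator evaluates to 0, and a zero-variance window maps to
zeros.

* **GREEN** — the mean-subtracted G row; the baseline method.
* **CHROM** — channels are divided by their temporal means; the
  chrominance pair X = 3R − 2G, Y = 1.5R + G − 1.5B is combined as
  X − (σ_X/σ_Y)·Y, cancelling intensity variation under a standardised
  skin tone.
* **POS** — the normalised channels are projected on the plane orthogonal
  to (1,1,1) via [[0,1,−1],[−2,1,1]] and alpha-tuned: S₁ + (σ₁/σ₂)·S₂.
* **PBV** — the per-window channel standard deviations of the normalised
  traces form the pulse signature s (unit length); the weights solve
  (C̃C̃' + 1e-9·I) w = s on the *centred* normalised channels C̃. Centring
  matters: the uncentred Gram matrix is dominated by the shared DC
  direction (1,1,1), which forces w orthogonal to it and cancels any pulse
  present equally in all channels. The signature is data-driven rather
  than a fixed literature vector, trading some optimality for freedom from
  calibration constants.
* **PCA** — eigendecomposition of the 3×3 channel covariance; the
  component whose periodogram is most concentrated at a single in-band
  (0.65–4 Hz) peak is returned.
* **ICA** — channels standardised, three sources unmixed by FastICA
  (deflation, logcosh, fixed seed — deterministic); the source with the
  largest in-band Welch peak is selected and its sign aligned with the
  green channel's phase at the peak bin. Solver variant and seed are
  exposed parameters.
* **LGI** — SVD of the *raw* (uncentred) window; the leading left singular
  vector tracks the quasi-static skin-tone axis, and the G row of the
  projection onto its complement is the pulse estimate. Using the raw
  window is deliberate: after centring, a clean pulse becomes the leading
  direction and would be projected out.
* **SSR** — operates on the raw (N_t, 3) skin-pixel matrices. Per frame
  the correlation matrix V'V/N is eigendecomposed (descending eigenvalues,
  eigenvector signs fixed by the largest-magnitude entry); over each
  sliding ℓ-frame segment the rotation of the leading eigenvector against
  the current subspace gives r₁, r₂ and the segment pulse
  r₁ − (σ₁/σ₂)·r₂, overlap-added into the output. Default ℓ = round(fps)
  (~1 s), exposed as a parameter. Segments with a numerically degenerate
  spectrum (λ₂ or λ₃ ≤ 1e-12, e.g. noise-free synthetic frames) are
  skipped with a warning.

CHROM and POS are applied once per analysis window without the original
short-stride overlap-add refinement — the pipeline windowing already
provides sliding estimates; this is a deliberate simplification.

## Filters

Band-pass: Butterworth, applied forward-backward (`sosfiltfilt`) so there
is no group delay and window timestamps stay aligned; the defaults
(0.65–4 Hz ≙ 39–240 BPM, order 6) bracket plausible heart rates.
Detrending: least-squares line removal (default) or smoothness priors —
the second-difference-regularised trend with weight λ = 300, conventional
for pulse waveforms around 30 Hz. The smoothness-priors operator is less
regularised at the series edges, so a few seconds at each boundary carry
artefacts; tests evaluate its interior. Zero-mean removes DC per series.

## Spectral estimation

Welch's method with Hann segments of min(M, 256) samples, 50% overlap,
zero-padded to nfft = the next power of two above max(2048, M, 60·fps) so
the BPM grid spacing 60·fps/nfft never exceeds 1 BPM. The peak is taken
over the inclusive band Ω = [39, 240] BPM; ties break to the lower
frequency; a patch with an all-zero spectrum is marked invalid and
excluded from aggregation rather than contributing a spurious value.
Aggregation uses the order-statistic median (even P averages the two
central values) and MAD^k = median(|H^k − ĥ^k|), which is exactly 0 for
P = 1. Reference BPM from a contact waveform uses the identical windowing
and estimator so prediction and reference align window for window.

## Metrics

PCC and CCC use population (1/K) moments, consistent with the CCC
denominator ((μ̂−μ)² + σ₁² + σ₂²); hence |CCC| ≤ |PCC| holds identically.
RMSE is the conventional √(mean of squares); a variant normalising the
root of the *sum* by 1/K is available as `strict_paper=True`.
The SNR mask selects bins within ±12 BPM of the reference rate and of its
first harmonic on the full Welch grid; with a binary mask the squared
forms of numerator and denominator coincide, so Welch power enters both
sides directly, and the out-of-band power is floored at 1e-12 so a pure
on-reference tone yields a large capped value instead of infinity.

## Statistical engine

Shapiro–Wilk per group at the chosen α; homogeneity via Bartlett when all
groups are normal, Levene otherwise (the standard convention). Two groups:
paired t if normal, Wilcoxon signed-rank otherwise. More than two:
repeated-measures ANOVA (subject-blocked two-way decomposition, no
sphericity correction — a documented limitation) if normal and
homoskedastic, else Friedman. Post hoc on rejection: Tukey with the
repeated-measures error term (studentized range on df_error) after ANOVA;
Nemenyi (studentized range at infinite df on mean-rank differences) after
Friedman. The critical difference is CD = q_α·√(k(k+1)/(6N)) with
q_α the α-level studentized-range quantile over √2; methods within one CD
are joined into the groups a CD diagram draws. Effect sizes: paired
Cohen's d under normality, otherwise Akinshin's γ = (MD₁ − MD₂)/pooled
robust scale with s = 1.4826·MAD; magnitudes labelled at the conventional
0.2/0.5/0.8 cut points (configurable). Videos missing any method's value
are dropped (complete-case pairing); all-constant groups yield an explicit
"no variance" report instead of a meaningless test.

## Forensic features

Katz fractal dimension treats the sampled waveform as the planar curve
(t, x_t) with unit index spacing — the abscissa convention is documented
because D depends on it; an amplitude-normalised variant (unit standard
deviation before the computation) is available. Constant signals and any
curve with d ≤ a are defined to have D = 1, the straight-line limit.
FD_vid averages D over all valid (patch, window) pulse estimates; MAD_vid
averages the per-window BPM dispersion. The linear-SVM detector is a thin
convenience wrapper; cross-validation protocols belong in analysis
scripts.

## Orchestration

The INI configuration mirrors the block structure used in the field
(DATASET / filter blocks / SIG / BVP / per-method blocks); `device_type`
keys are accepted and ignored — there is a single CPU implementation.
`cpu_`/`gpu_`-prefixed implementation names are accepted and stripped.
Results persist as HDF5 (primary, with a format version attribute checked
on load) or CSV; the HDF5 layout is this package's own. Dataset access is
a two-method adapter contract (`load_filenames`, `read_sigfile`) pairing
videos with ground-truth waveforms by index; `PairedListAdapter` covers
both file paths and in-memory synthetic objects. Per-video failures in a
dataset run are logged and recorded as missing rather than aborting the
run. Video input accepts frame arrays, PNG-sequence directories, synthetic
video objects, and any container imageio can decode; decoding of
compressed containers depends on the available imageio plugins.

## Problem sizes in tests

The suite runs on 12–30 s clips at 20–30 fps, frames up to 48×48, up to
100 patches, 50-pair forensic batches and 1000-replicate null simulations
for the type-I calibration — sizes chosen so the full suite completes in
well under a minute while every statistical assertion retains comfortable
Monte-Carlo margins (thresholds sit ≥ 3 binomial standard deviations from
their expected values).

## Known limitations

* No face detection/landmarking models ship with the package; real-video
  patch runs require an external landmark provider.
* The chroma-threshold skin detector is a reference rule, not a
  segmentation model.
* SSR on isotropic-noise synthetic video is noisier than on real skin
  (see above).
* Repeated-measures ANOVA applies no sphericity correction.
* No time-frequency HR tracking or inter-beat-interval analysis.
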