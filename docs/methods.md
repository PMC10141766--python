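# Methods

This note records the models the package implements, the parameters that
matter, the design choices made where several constructions were
defensible, and what the synthetic-data tests do and do not establish
about real EEG.

## Signal model and preprocessing

Recordings are treated as linear instantaneous mixtures, x(t) = A s(t),
of zero-mean sources. Conventional filtering uses a second-order IIR
notch (quality factor 30, default 50 Hz) and a 4th-order Butterworth
band-pass (default 8–30 Hz, the mu/beta band), both applied
forward–backward (`filtfilt`) so the net phase response is zero — trial
timing is never skewed by filtering. Neither filter design nor order is
canonical for this problem; these are ordinary engineering defaults, and
the test suite pins their measurable behaviour (stop-band depth,
pass-band flatness, zero phase) rather than their coefficients.

Sources are estimated by SOBI: the EEG channels are zero-meaned and
whitened by PCA, symmetrised time-lagged covariance matrices at lags
1..100 are jointly diagonalised by Jacobi rotations (Givens-angle
updates on all index pairs until no rotation exceeds 1e−8), and the
unmixing matrix is the rotation composed with the whitener. The lag
range covers 4–400 ms of autocorrelation structure at 250 Hz, standard
SOBI practice. Rank-deficient channel covariance reduces the
decomposition to the numerical rank with a warning; sources without
temporal structure (all lagged covariances ≈ 0) violate SOBI's
identifiability assumption, so the result is returned but flagged
low-confidence.

A component is called ocular when the magnitude of its zero-lag
Pearson-form cross-correlation with any EOG channel reaches a threshold
(default 0.5; the metric is fixed, the cutoff is not, so it is a
parameter). Flagged source rows are zeroed and the EEG is reconstructed
as x̂ = A ŝ; EOG channels pass through untouched. Cleaning refuses to
run if every component is flagged, because that would null the data.

**Ordering.** The chain is notch → SOBI zeroing → band-pass. Running the
band-pass first was measured to strip nearly all ocular energy (blink
spectra lie mostly below 8 Hz), leaving the EOG-correlation criterion
without signal to key on; zeroing on the wideband data and band-passing
afterwards keeps the criterion effective and is the standard order in
EEG artifact practice. EOG channels never enter the decomposition; they
are references only.

## CompEn features

All four features are computed on fixed windows of 1500 samples (6 s at
250 Hz) per trial and channel.

**Higuchi fractal dimension.** Curve lengths L_m(k) of k-decimated
sub-series with the normalisation (N−1)/(⌊(N−m)/k⌋·k), averaged over
offsets, and the least-squares slope of ln L(k) against ln(1/k) for
k = 1..kmax. kmax defaults to 20, the plateau region for these window
lengths (estimates at kmax = 20 and 40 differ by < 0.05 on fGn).
Degenerate intervals with zero curve length (e.g. a pure alternating
series decimated at even k) are excluded from the fit with a warning; a
constant window raises. Estimates are never clipped to [1, 2] — finite
noise lands a hair above 2 — and excursions beyond ±0.05 warn.

**Rescaled-range Hurst exponent.** For block lengths n on a dyadic grid
(16, 32, ... ≤ N/2), the window is split into ⌊N/n⌋ adjacent blocks,
each reduced to R/S (range of cumulative mean-deviations over standard
deviation), and the estimate is the log–log slope of the block-averaged
R/S against n. Remainder samples are discarded; zero-variance blocks
are excluded with a warning. The classical log-returns pre-transform is
available behind `use_log_returns` but defaults off: band-passed EEG
crosses zero, where a ratio-logarithm is undefined. Plain R/S carries a
known small-sample bias (measured here: about +0.08 at H = 0.3, +0.04
at H = 0.5, ≈0 at H = 0.7 for N = 1500); the slope itself is reported,
uncorrected, since relative ordering between classes is what the
pipeline consumes. A separate rescaled-range "correction" formula of
the form (2^{2H−1}−1)·n^H circulates in the literature; it conflates the
lag-one autocorrelation identity of fGn with the R/S scaling law and is
internally inconsistent with the slope definition, so it is documented
here and not computed.

**Tsallis entropy.** The q-family S_T = (1 − Σ pᵢ^q)/(q − 1) with the
Shannon limit at q = 1 is provided on probability vectors. On signals
the default is Sneddon's critical-point approximation for q = 2:
critical points are samples where the discrete derivative is zero or
changes sign (scanning left to right against the last nonzero
derivative; Δt cancels since only the sign pattern matters), the window
is partitioned into bins between consecutive critical points (window
edges as outer boundaries), and S_T ≈ 1 − (1/N)·Σ sᵢ²/σ². This form is
bounded above by 1: it reaches 1 when every bin is internally constant
and 0 when each bin's variance equals the global variance. A histogram
mode (Tsallis entropy of the amplitude histogram, default 16 bins)
is retained because the two forms live on different scales — published
per-channel values around 3 are impossible under the Sneddon bound and
can only arise from the probability-vector form on a finer partition —
and neither tabulation is treated as ground truth here.

**Dispersion entropy.** Samples are mapped to c classes through the
normal CDF of the standardised signal, z = round(c·Φ((x−μ)/σ) + 0.5)
clipped to [1, c]; this makes the pattern distribution invariant to
positive affine transforms of the signal. Length-m patterns at delay d
are counted over the N − (m−1)d embedded vectors and entropied with the
natural log, giving a value in [0, ln c^m]. Defaults m = 2, c = 2,
d = 1: d = 1 is the standard recommendation, and the 4-pattern alphabet
(upper bound ln 4 ≈ 1.386) matches the scale on which per-channel
values of this feature are conventionally reported for this task; both
are configurable, and c^m ≥ N triggers an undersampling warning. A
pre-classified integer series can bypass the mapping
(`mapping="identity"`), which is also how the exhaustive
pattern-enumeration oracle in the tests drives the implementation.

## Screening

Each feature gets a balanced fixed-effects two-way ANOVA with factors
class and channel, one observation per (trial, channel). Sums of
squares are computed directly from cell means — not delegated to a
model-fitting package — so the decomposition is verifiable against an
independent reference (the test suite checks F agreement with
statsmodels to 1e−8 and SS conservation to 1e−8 relative). Unbalanced
tables are down-sampled to the minority class with a seeded RNG, since
the classical decomposition is ambiguous when unbalanced and the
experimental design is balanced anyway. Zero error mean square is
reported as a degenerate-data warning rather than an exception. The
screening output is descriptive — it names the class driving each
feature's significance via the largest standardised cell-mean deviation
— and does not gate which features reach the classifier: all four
always proceed to the combined CompEn set. Normality and
homoscedasticity checks and post-hoc comparisons are out of scope.

## Laplacian Eigenmap

Features are standardised before distances (a dimension living in
[1, 2] must not be drowned by a raw-scale one), a k-NN graph
(Euclidean, OR-symmetrised, default k = 5) is built with binary or heat
weights, and the embedding solves Ly = λDy with L = D − W. The solver
returns D-orthonormal eigenvectors, so YᵀDY = I holds by construction
and tr(YᵀLY) equals the sum of retained eigenvalues. Only the first
zero eigenvector (the constant direction) is dropped; additional zero
eigenvectors of a disconnected graph are component indicators that
carry real cluster structure and are kept as coordinates, with a
warning (strict mode errors instead). Default r = 10, capped at
feature-count − 1.

Inside cross-validation the eigenmap is fit on training folds only;
test trials are mapped by a Nyström-style extension — the
inverse-distance-weighted average of the coordinates of the k nearest
training points. This keeps test data out of every fitted statistic at
the cost of a first-order approximation for out-of-sample points.

## Classification harness

10-fold stratified CV (stratification preserves class balance per
fold). Per fold: standardiser fit on the training rows, optional
eigenmap fit on the training rows, then KNN (k = 5, Euclidean), SVM
(RBF, C = 10, kernel width σ = 0.5 read as k(x,y) =
exp(−‖x−y‖²/(2σ²)), i.e. gamma = 2 — "smoothing value" names no
convention, so this one is fixed explicitly) and a 100-tree random
forest. An optional tuning mode grid-searches C over 10^−4..10^4 by
nested 10-fold CV; default runs use the fixed C for determinism and
speed. Metrics: accuracy, macro precision/recall (zero-division
contributes 0 with a warning) and a confusion matrix in the fixed class
order (left hand, right hand, foot, tongue). A master seed fans out to
per-stage seeds via `numpy.random.SeedSequence`, so identical configs
give bit-identical reports and stages can be re-run in isolation.

## Synthetic generator

The generator emulates the study conditions the pipeline targets, with
exact ground truth:

- **Trial schedule**: fixation 0–2 s, cue at 2 s, imagery 2–6 s, then a
  1.5 s inter-trial gap (the gap has no canonical published value and
  is a parameter). One Graz-style event code (769–772) per trial;
  classes are balanced and shuffled.
- **Class signatures**: during the imagery window the class's channel
  group carries fGn with a class-specific Hurst exponent (defaults
  0.35/0.50/0.65/0.80 on disjoint quarters of the 22-channel montage)
  plus a 10 Hz mu oscillation attenuated by the class's ERD depth
  (0.6/0.5/0.4/0.3); background is H = 0.5 fGn at 8 µV RMS with the
  oscillation at full amplitude.
- **fGn/fBm**: exact-autocovariance circulant embedding (Davies–Harte),
  so γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}) holds by
  construction and the estimators can be scored against a known H. The
  fBm trace (cumulative sum) is the ground-truth process for the
  fractal-dimension relation FD = 2 − H; raw fGn has FD ≈ 2 for every H
  (its spectral exponent lies outside the regime where curve dimension
  tracks H), which is why dimension checks run on fBm while R/S checks
  run on fGn.
- **Artifacts**: blinks as Gaussian-windowed biphasic pulses (300 ms
  extent, opposite-sign lobes of σ = 30 ms spaced 60 ms) at 12/min and
  80 µV, written to the EOG channels and propagated to frontal EEG
  channels at gain 0.35 (0.02 elsewhere); the lobe sharpness is chosen
  so roughly a third of the pulse's RMS lies in 8–30 Hz, as for real
  blinks, leaving the rejection criterion something to key on both
  before and after band-passing. Line interference is a 50 Hz sinusoid
  on all channels. EEG sources are mixed by a near-identity random
  full-rank matrix recorded in the ground truth.

What passing tests show: every stage's contract holds on data whose
generating process is exactly known — estimator bias bounds, separation
quality, artifact-flag sensitivity, leakage-free CV, planted-effect
recovery. What they do not show: performance on real EEG, whose sources
are non-stationary, whose artifacts include muscle and electrode events
this generator never produces, and whose class differences are far
subtler than the planted Hurst gaps. The generator contains no head
model or forward solution; mixing is statistical, not biophysical.

## Problem sizes and numerical choices

Default desk-scale runs use 8–160 trials (the full experimental
protocol uses 288 per session; the pipeline is O(trials) in features
and O(trials²–³) only in the small embedding eigenproblem, so it scales
to that directly). Dense `eigh` is used for the embedding (trial counts
are a few hundred at most), circulant embedding uses real FFTs of
length 2N−2, and the EDF writer stores int16 with per-channel physical
scaling parsed back from the header so quantisation is exactly the
written range / 65535. Ties in k-NN graph construction follow argsort
order (stable); ties in the NCDF class mapping round half away from the
lower class edge via `round(c·y + 0.5)`. Degenerate inputs (constant
windows, zero-variance correlation operands, empty ANOVA cells,
isolated graph vertices) raise typed errors rather than propagating
NaNs.

## Known limitations

- The EDF writer supports continuous 16-bit EDF+C with one annotation
  stream and integer sampling rates; GDF is read but not written.
- Plain R/S bias near small H is inherited from the estimator
  definition; ordering across classes is preserved, absolute values
  near H = 0.3 sit high by ≈ 0.08.
- The Nyström extension maps far-outlying test points to the convex
  hull of training coordinates; with k = 5 this is a coarse
  approximation when a test trial is unlike all training trials.
- SOBI assumes temporally coloured, second-order-separable sources; it
  is the only BSS algorithm provided (no FastICA/AMICA baselines).
- The cross-correlation criterion is zero-lag only; lagged ocular
  propagation is not modelled.
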