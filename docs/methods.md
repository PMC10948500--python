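# Methods

## Problem setting

`itdeeg` decodes which of six conditions — imagined flexion of one of the
five fingers of a hand, or a passive no-mental-task (NoMT) state — produced
a one-second, multichannel EEG epoch. Modelling the idle state as a sixth
class matters for brain–computer interfaces: without it, spontaneous
activity is forced onto a movement class and every idle moment becomes a
potential false activation. The working geometry is 19 channels sampled at
1000 Hz, 100 trials per class (600 per subject), hardware-style filtering
of 0.53–100 Hz with a 50 Hz notch.

## Intrinsic time-scale decomposition

Each channel of each epoch is decomposed by ITD into proper rotation
components (PRCs) plus a monotonic trend. One level splits the signal
X_t into a baseline L_t and a residual H_t = X_t − L_t. Between successive
local extrema τ_k the baseline is piecewise defined from knot values

    L_{k+1} = α [X_k + (τ_{k+1} − τ_k)/(τ_{k+2} − τ_k) · (X_{k+2} − X_k)]
              + (1 − α) X_{k+1},     0 < α < 1,

i.e. an α-contraction of each extremum toward the chord of its neighbours
(α = 1/2 by default), and on each inter-extrema segment L_t is the affine
image of the monotone signal segment onto its knot interval,
L_t = L_k + (L_{k+1} − L_k)/(X_{k+1} − X_k) · (X_t − X_k). Iterating on
successive baselines yields PRC1, PRC2, … ordered from highest to lowest
frequency content, with exact additive reconstruction
X = Σ_j H^(j) + L^(D).

Numerical choices:

* **Boundaries.** The baseline is only defined between extrema, so virtual
  knots carrying the signal values are pinned at the first and last
  samples. This keeps reconstruction exact at the edges.
* **Stopping.** Iteration stops when the current baseline has fewer than 3
  interior extrema (it is then the monotonic trend) or after
  `max_components` (default 10) levels. The classification pipeline uses
  only PRC1–PRC3; an epoch whose decomposition is shallower has the
  missing components zero-padded and the trial flagged.
* **Ties and plateaus.** A plateau of equal samples flanked by opposite
  slopes contributes one extremum at its midpoint (rounded down), which
  keeps maxima and minima strictly alternating and the result
  deterministic.
* **Degenerate segments.** If the segment contraction denominator
  |X_{k+1} − X_k| falls below 1e-12 the baseline degrades to linear
  interpolation of its knots, avoiding division blow-up.
* α = 0 is permitted in `compute_baseline` for diagnostics (the PRC then
  vanishes at interior knots) but the iterated decomposition requires
  0 < α < 1.

## Features

Ten features per signal (a PRC or the raw channel):

| feature | definition |
|---|---|
| mean | arithmetic mean |
| power | S_T = Σ_k S(w_k), S(w_k) = \|DFT(x)[k]\|²/N over all N bins |
| M1–M4 | Σ_k w_k^p S(w_k), w_k = 2πk/N in radians/sample |
| activity | sample variance (N−1 denominator) |
| mobility | SD(Δx) / SD(x) |
| complexity | mobility(Δx) / mobility(x) |
| sampen | −ln(A/B), Richman–Moorman sample entropy |

The periodogram is two-sided (rectangular window, no detrending, all N
bins) so that Parseval gives S_T = Σ x[n]² exactly; a one-sided spectrum
would halve the printed sums. Spectral moments stay in radians/sample —
they are used as discriminative statistics, not physical quantities, and
this keeps them independent of the sampling rate. Hjorth parameters are
computed on the signal itself (an `autocorr=True` flag applies them to the
biased autocorrelation sequence instead, for comparison with texts that
define them that way); the first difference stands in for the derivative,
and the sampling interval cancels in both ratios. Sample entropy uses
embedding dimension m = 2 and tolerance r = 0.2·SD by default — the
customary choice for short physiological series — with Chebyshev distance
and self-matches excluded; both match counts are computed over the N − m
templates. A constant signal returns 0; zero extended-match counts return
+inf from the scalar API and are emitted as 0 with a per-cell flag in
matrix builds, as are the mobility/complexity of zero-variance signals, so
a degenerate channel never aborts a build.

A trial's feature vector concatenates channels (channel-major) ×
components × the fixed feature order, giving 10 · 19 · 3 = 570 columns for
the PRC1-to-3 selection and 190 for raw EEG. The eight component
selections are PRC1, PRC2, PRC3, the pairs {1,2}, {1,3}, {2,3}, the triple
{1,2,3}, and EEG (no decomposition).

The O(N²) sample-entropy pair count and the ITD inner loops are
numba-compiled; a 600-trial, 19-channel feature build takes tens of
seconds on one CPU.

## ANOVA screening

Each feature column is screened with classical equal-variance one-way
ANOVA across the six classes; columns with p < 0.05 are kept. No
multiple-testing correction is applied by default (a Bonferroni option
exists): the screen is a pre-filter for classifiers, not an inferential
claim, and the chance-level tests confirm the α-rate behaviour. The screen
runs on training rows only — inside every CV fold it is refit on that
fold's training part — so held-out rows never influence the mask; a
whole-data mode exists for comparison with analyses that did not guard
against this. If nothing passes, the bench falls back to all features and
flags the fact.

## Classifier bench

Eight families with 27 named variants (trees fine/medium/coarse; linear
and quadratic discriminants; Gaussian and kernel naive Bayes; SVM linear,
quadratic, cubic and three Gaussian widths; cubic and cosine k-NN; five
ensembles; five MLP shapes; kernel-approximation SVM and logistic
regression). The variant names follow common GUI-toolbox presets whose
exact hyperparameters are not standardised; `registry.py` pins each to an
explicit configuration — tree leaf budgets 100/20/4, k-NN k = 10, Gaussian
SVM kernel scales √F/4, √F, 4√F for F features, 30 learners per ensemble,
MLP widths 10/25/100 and 10-10 / 10-10-10, random-Fourier expansion 2F —
all overridable per spec. Families whose presets standardise inputs (SVM,
k-NN, MLP, kernel approximation) include a StandardScaler; binary-native
learners use one-vs-one. RUS-boosting is implemented as fit-time random
undersampling to the minority count followed by AdaBoost, a near no-op on
the balanced design.

Protocol: stratified 80/20 train/test split, stratified 5-fold CV on the
training rows, both seeded. Reported per variant: mean CV accuracy and
held-out test accuracy — published tables of this kind often blur which
of the two they print, so both are always emitted, clearly labelled —
plus the 6×6 confusion matrix. Multi-class accuracy is trace/total, the
micro-averaged form of the binary (TP+TN)/(TP+TN+FP+FN). A variant that
fails to fit (e.g. a quadratic discriminant on singular covariances) is
recorded as not-available and the bench continues. Subject-dependent
analysis benches each subject's trials separately; subject-independent
pools all trials under the same protocol.

`MovementDecoder` wraps the whole pipeline: one ITD pass per scope serves
all PRC rows via column subsetting, `fit()` returns `DecoderResults` with
the component-set × scope accuracy tables, `summary()`, confusion
accessors and a bar-chart plot.

## Synthetic data generator

The generator emulates the study's acquisition geometry so the pipeline is
testable without any recordings. Background: per-channel independent
Gaussian 1/f^β noise (β = 1), unit SD, spectrally shaped. Classes 1–5 add
an amplitude-modulated sinusoid — frequency drawn uniformly in a 4 Hz band
centred at 8/12/16/20/24 Hz, random phase, raised-cosine envelope — on
overlapping 4-channel subsets; class 6 (NoMT) is background only. The band
centres mimic mu/beta motor-band modulation; the overlapping subsets keep
classes confusable. Everything is then zero-phase band-pass filtered
0.53–100 Hz (4th-order Butterworth) and notch filtered at 50 Hz (Q = 30),
emulating the hardware chain without phase distortion.

The class-signal RMS is snr × amplitude × background SD. The default
modulation depth (amplitude 0.3 at snr 1, i.e. class band power ≈ 9% of
background power) was chosen to place the task in a realistic mid-range
regime: movement-band modulations in real EEG are a small fraction of
ongoing activity, and at this depth the ensemble bench scores roughly
60–75% rather than saturating. `generate_null_set` empties every profile
and assigns labels round-robin, giving an exact chance-level control;
`spectral_ground_truth` returns the analytic per-(class, channel, band)
expected power for Monte-Carlo checks.

What the generator does **not** emulate: volume conduction and spatial
correlation (available as nothing more than independent channels by
default), non-stationarity across a session, eye/muscle artifacts,
event-related potentials, or any biophysical forward model. Passing tests
therefore demonstrate that the pipeline recovers band-limited spectral
class structure against 1/f background at realistic depths — not that it
attains any particular accuracy on recorded EEG.

## Problem sizes used in the checks

The end-to-end checks run at the full study geometry (600 trials × 19
channels × 1000 samples). The chance-level control benches six
representative variants (one per major family) on three component rows;
the signal-recovery check runs the ensemble family as its bagged-trees
variant over 20 generator seeds, comparing ANOVA-screened PRC1-to-3
against PRC2-only. `scripts/acceptance.py` repeats these computations
from scratch (three generator seeds for the discriminative comparison)
and writes the resulting numbers as JSON.

## Known limitations

* ITD is sensitive to sampling of extrema; heavily oversampled smooth
  signals produce long plateau runs whose midpoint convention, while
  deterministic, is one of several defensible choices.
* The preset registry is a reconstruction of undocumented GUI presets;
  absolute accuracies depend on it, though family orderings are stable.
* The kernel naive Bayes evaluates per-feature KDEs densely and is the
  slowest variant on wide feature sets.
* EDF export writes plain EDF (not EDF+); epoch onsets travel in a
  sidecar TSV event table rather than embedded annotations.
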