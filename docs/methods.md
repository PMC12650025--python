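# Methods

## Overview

`microfuse` implements a complete EEG group-classification pipeline built
around microstate dynamics. A recording is reduced to two feature blocks —
a 28-dimensional microstate block describing the temporal organisation of
four canonical scalp topographies, and a 40-dimensional statistical block
of time/frequency/nonlinear descriptors — which are z-scored, concatenated
and fed to a two-branch separable-convolution / GRU network trained under a
validation-feedback loop with feature-level augmentation. Every stage is
testable against ground truth because the package ships its own synthetic
cohort generator, whose generating parameters (topographies, state
durations, transition matrix, noise level) are known exactly.

## Microstate model

The global field power `GFP(t) = sqrt((1/N) Σ_i (V_i(t) − V̄(t))²)` is the
spatial standard deviation of the instantaneous scalp map. Local GFP
maxima (minimum separation 10 ms by default) supply high-SNR frames for
clustering. Clustering is a polarity-invariant modified K-means (K = 4):
frames are assigned to the template maximising the squared spatial
correlation, and each template update is the dominant eigenvector of the
assigned frames' scatter matrix. The best of `n_init = 10` seeded restarts
by GFP²-weighted explained variance is kept; convergence is declared when
assignments stop changing (cap 100 iterations). Templates are fitted in
two levels — per subject first, then a second clustering of the pooled
subject templates — and the group-level maps are ordered A–D by optimal
assignment (Hungarian algorithm on |spatial correlation|, provably equal
to the exhaustive K! search) against a reference set, with signs flipped
to positive correlation.

The packaged reference maps
(`data/reference_templates_synthetic_1020_19ch.json`) are *synthetic*
approximations of the canonical A–D topographies, constructed from
idealised 10–20 electrode geometry (two diagonal gradients, an
anterior–posterior gradient, a fronto-central extremum). Published
normative maps are not redistributable here; any `(4, n_ch)` array can be
substituted, and on synthetic data the generating templates themselves are
the natural reference.

Backfitting labels every sample with the template of maximal squared
correlation (scale- and polarity-invariant; ties → lowest index). Label
smoothing by minimum run duration is available but **off by default**: the
semi-Markov generator produces genuine 1-sample runs, and smoothing would
bias duration recovery. Per labelled segment the feature vector is

    [duration(4) | coverage(4) | occurrence rate(4) | transitions(12) | GEV(4)]

with durations in ms, coverage as time fractions (sums to 1), occurrence
in runs/s, transition probabilities counted at run boundaries (the
diagonal is structurally zero, so 12 off-diagonal entries remain;
row-normalised where the state occurs), and per-state global explained
variance `GEV_k = Σ_{t∈S_k} corr²(V_t, T_k)·GFP(t)² / Σ_t GFP(t)²`. The
"12-D temporal statistics" are read as duration + coverage + occurrence;
occurrence rate is the field-standard third statistic. Absent states get
zeroed entries and an `occurred` flag. Transition counting at run
boundaries (rather than per sample) is a deliberate choice: it makes the
zero diagonal structural and the row normalisation exact.

## Statistical feature block

40 scalars in 26 descriptor categories, computed per channel and averaged
across channels (median or no aggregation are config options). The
multi-valued categories are expanded as: quantiles {0.25, 0.5, 0.75};
relative band powers δ, θ, α, β, low-γ (0.5–4–8–13–30–45 Hz, Welch PSD);
absolute band energies δ, θ, α, β (log1p-compressed); six db4 wavelet
detail-level relative energies. This expansion to exactly 40 is the
package's documented default manifest — the inventory is config-driven.

Three information-theoretic descriptors get first-class treatment:

* **Sample entropy** `−ln(A/B)` (m = 2, r = 0.2·SD, Chebyshev distance,
  self-matches excluded, identical template populations at both lengths).
  Neighbour counting uses a k-d tree; the test suite proves exact
  agreement with an O(n²) brute-force count. A series with no
  length-(m+1) match returns `inf`; in the aggregated manifest this is
  replaced by the Richman–Moorman estimable upper bound
  `−ln(2/((N−m−1)(N−m)))`.
* **SVD entropy**: Shannon entropy of the sum-normalised singular values
  of the (order 3, delay 1) delay embedding; bounded by `ln(order)`.
* **SVD Fisher information**: `Σ_{i≥2} (p_i − p_{i−1})²/(p_i + ε)` with
  `ε = 1e−8` guarding the division.

Feature selection fits a random-forest importance estimator (impurity
based, importances sum to 1) on **training folds only** and drops features
with importance below 0.002; the three information-theoretic features are
always retained regardless of score.

## Preprocessing

Order: band-pass → artifact correction → average reference. The band-pass
is a zero-phase 4th-order Butterworth, 0.5–45 Hz by default. Artifact
correction is a sliding-window robust amplitude method: per channel, RMS
over 0.5 s windows at 50% overlap; windows exceeding
`median + k·(q₀.₇₅ − q₀.₂₅ quantile spread)` (k = 5) are attenuated onto
that envelope via Hann-windowed overlap-add, which is an exact identity
wherever no window is flagged. The (0.25, 0.75) quantile pair defines the
robust spread; the multiplier, window length and overlap are configurable.
The slot where an ICA-based component classifier would run is a
pass-through callback defaulting to identity — training such a classifier
is out of scope, and the hook lets users plug in their own.

## Synthetic cohorts

The generator inverts the microstate model: a first-order semi-Markov
chain with geometric run lengths (the maximum-entropy run-length law
consistent with a first-order chain) selects one of K templates per
sample; the map is scaled by a rectified smoothed Gaussian amplitude
process (mean ≈ 1, SD 0.3, 50 ms correlation length — nonconstant
amplitude is required for GFP peaks to exist) and per-channel Gaussian
sensor noise is added after projection to zero channel mean, so the
average-reference invariant holds exactly. Default conditions: 19-channel
10–20 montage at 128 Hz, two groups, near-orthogonal zero-mean unit-norm
templates, 80 ms mean durations and uniform transitions for controls, and
`noise_sd = 0.05` (per-channel signal RMS ≈ 1/√19 at unit amplitude, i.e.
SNR ≈ 5).

Group differences follow the case/control pattern reported for
attention-deficit cohorts: state B lengthened (110 ms) and over-targeted
(transitions into B raised from A and D), state C shortened (55 ms) and
under-targeted (transitions into C lowered from A, B and D). These
overrides roughly preserve the overall switching rate, so group
information lives in the *state-specific* dynamics rather than in gross
signal statistics — which is what makes the no-microstate ablation arm
informative.

What the generator does **not** emulate: volume-conducted source
geometry, 1/f spectral shaping, non-stationary artifacts, inter-subject
template variability. Passing tests therefore demonstrate correctness of
the machinery and recoverability of the encoded dynamics, not clinical
performance on real EEG.

## Network and training

The fused vector (68-D with the default blocks: 28 + 40) enters as a
length-T sequence with one channel. Note the described blocks total 68
while some reports of comparable pipelines quote 71 inputs; the fused
dimension here is always data-driven (it also shrinks when selection drops
statistical features) and never hard-coded. Convolutional branch:
SeparableConv1D(k=3) → BatchNorm → ReLU → SeparableConv1D(k=5) →
BatchNorm, a 1×1-convolution residual from the input added before the
final ReLU, then max-pool (2), flatten, dropout. Recurrent branch: a
standard GRU (h₀ = 0), last hidden state, dropout. The concatenated
branches pass through a ReLU dense layer with dropout into a single
sigmoid unit. Defaults (32/64 filters, 64 GRU units, 64 dense units,
dropout 0.5) put the parameter count near 1.6 × 10⁵ at T ≈ 70; exact
counts come from `count_params`. Forward, backward (including batch-norm
and backprop-through-time) and Adam are implemented in NumPy and verified
against central finite differences.

Training: Adam, initial learning rate 1e−4, batch 64, up to 500 epochs
with early stopping (patience 50, best-validation weights restored).
Each epoch the closed feedback loop computes `R = val_acc − val_loss`
(the loss is the *unweighted* validation BCE, keeping rewards comparable
across loss weights), updates `w ← clip(w + η·R, 0.5, 2.0)` (η = 0.1) and
scales the training BCE by `w`. Stagnation — `val_acc ≤ best + ε`
(ε = 0.001) for T = 10 consecutive epochs — escalates: first a loss-weight
perturbation `w ~ U(0.7, 1.3)`, then after another T stagnant epochs a
uniform resample of (dropout, learning rate, L2) from the preset grids
with full weight re-initialisation and a fresh optimiser (clean-restart
semantics; the resampled dropout applies to every dropout site, the
resampled learning rate replaces any schedule, and the early-stopping
counter resets). η, ε and T have no canonical values; the defaults here
are configurable and logged. Augmentation triples the training split
(original + Gaussian σ = 0.05 copy + contiguous-10%-cutout copy) and
never touches validation or test rows.

## Evaluation protocol

Cross-validation partitions *subjects* (stratified by group) into k = 5
test folds, with a stratified 80/20 train/validation subject split inside
each fold's remainder; fold plans are validated for leakage on
construction. With fixed-window epoching (one feature row per epoch), a
test subject's epoch probabilities are averaged into one subject-level
prediction. Metrics (accuracy, precision, recall, F1, Cohen's κ, RMSE of
probabilities) come from definitional formulas; zero-denominator ratios
are flagged NaN rather than coerced to 0, so averages are never silently
inflated. Results report both the pooled confusion over folds and the
per-fold mean ± SD. Group comparison of microstate features uses a
two-sided Mann–Whitney U per feature at α = 0.05 (no multiple-testing
correction by default, BH-FDR optional); the reported direction is the
sign of the case-minus-control mean difference.

## Problem sizes and numerical choices

The shipped acceptance computations use scaled study conditions chosen as
the package's standard desk-scale experiment: parameter recovery on
20 + 20 subjects × 60 s records (whole-record features), classification on
20 + 20 subjects × 30 s records split into 7.5 s epochs (4 rows/subject,
training capped at 60 epochs with patience 25). Epoch length trades
feature-estimate variance against sample count; 7.5 s ≈ 90 state runs per
epoch keeps transition-row estimates usable. Other numerical choices:
probabilities are clamped to [1e−7, 1 − 1e−7] before logs and at the
sigmoid output; batch-norm uses momentum 0.99 and ε = 1e−3; L2 applies to
kernels/matrices only; empty K-means clusters are reseeded with the
worst-fit frame; template signs are fixed by making the largest-magnitude
channel positive; ties in backfitting and peak selection resolve to the
lowest index / earlier sample. All randomness flows from one seed through
`numpy.random.SeedSequence.spawn`, making cohorts, fold plans and training
runs bit-reproducible.

## Known limitations

* The statistical manifest's expansion of multi-valued categories to
  exactly 40 scalars is a documented convention, not a canonical list.
* The synthetic reference topographies are geometric idealisations; on
  real data users should substitute digitised normative maps.
* Recovery tolerances hold at the stated conditions (SNR ≥ 5, ≥ 60 s);
  shorter records or heavier noise degrade duration estimates first
  (misassigned samples split runs).
* The NumPy network is single-threaded and CPU-bound; it is sized for
  desk-scale feature vectors, not raw-EEG end-to-end learning.
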