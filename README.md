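# microfuse

EEG microstate + statistical feature fusion for two-group classification,
with a feedback-trained CNN–GRU classifier and synthetic cohorts that make
the whole pipeline testable against known ground truth.

## Who this is for

Researchers analysing multichannel EEG (e.g. 19-channel 10–20 recordings of
clinical and control groups) who want to (a) extract microstate dynamics
and standard statistical descriptors, (b) fuse them into a compact vector,
and (c) train and evaluate a subject-independent classifier — all with a
reproducible, seedable pipeline that can be validated end to end on
synthetic data before touching real recordings.

## The model in brief

**Microstates.** Spontaneous EEG is segmented into brief periods of
quasi-stable scalp topography. From the global field power

    GFP(t) = sqrt( (1/N) Σᵢ (Vᵢ(t) − V̄(t))² )

peak frames are clustered by a polarity-invariant modified K-means
(assignment maximises squared spatial correlation; K = 4), pooled across
subjects in a second clustering, aligned A–D against reference maps by
optimal |correlation| assignment, and backfitted to label every sample.
Each labelled segment yields a 28-D vector: per-state mean duration,
coverage, occurrence rate, the 12 off-diagonal run-boundary transition
probabilities, and the per-state global explained variance

    GEV_k = Σ_{t∈S_k} corr²(V_t, T_k) · GFP(t)² / Σ_t GFP(t)².

**Statistical block.** 40 descriptors in 26 categories per record (moments,
quantiles, Hjorth parameters, fractal dimensions, band powers/energies,
spectral slope/entropy/edge, db4 wavelet energies, Hurst, decorrelation
time) including sample entropy `−ln(A/B)`, SVD entropy `−Σ pᵢ ln pᵢ` of the
delay-embedding singular spectrum, and SVD Fisher information
`Σ (pᵢ−pᵢ₋₁)²/(pᵢ+ε)`. Random-forest Gini importances (fitted on training
folds only) drop features below 0.002; the three entropy features are
always kept.

**Classifier.** The z-scored concatenation `[x_micro, x_stat]` feeds a
two-branch network: SeparableConv1D(3) → BN → ReLU → SeparableConv1D(5) →
BN with a 1×1 residual, max-pool/flatten/dropout, in parallel with a GRU
whose last hidden state is taken; branches are concatenated into a dense
ReLU layer and a sigmoid output. Training uses Adam with a closed feedback
loop: reward `R = val_acc − val_loss` updates a loss weight
`w ← clip(w + ηR, 0.5, 2.0)`; stagnation triggers first a loss-weight
perturbation `w ~ U(0.7, 1.3)` and then hyperparameter resampling
(dropout ∈ {0.4,…,0.7}, lr ∈ {1e−3, 1e−4, 5e−5}, L2 ∈ {1e−3, 5e−4, 1e−4})
with full re-initialisation. The training split is tripled by augmentation
(Gaussian σ = 0.05 copy + contiguous 10%-cutout copy). Evaluation is
subject-independent 5-fold CV with accuracy, precision, recall, F1,
Cohen's κ and probability RMSE.

The network (forward, backprop through time, Adam) is implemented in NumPy
and verified against finite-difference gradients in the test suite.

## Worked example

```python
import numpy as np
from microfuse import synth, microstate as ms

gt = synth.default_control_ground_truth(seed=0)
gt0 = synth.MicrostateGroundTruth(          # noiseless variant
    templates=gt.templates, transition_matrix=gt.transition_matrix,
    mean_durations_ms=gt.mean_durations_ms, noise_sd=0.0)
fs, n = 128.0, int(60 * 128)
labels = synth.simulate_state_sequence(gt0, n, fs, seed=1)
amps = synth.amplitude_series(n, fs, seed=2)
rec = synth.synthesize_eeg(gt0, labels, amps, seed=3, fs_hz=fs)

recovered = ms.backfit(rec, gt0.templates)
summary = ms.summarize(recovered, fs)
gev = ms.compute_gev(rec, recovered, gt0.templates)

print(f"label agreement: {(recovered == labels).mean():.3f}")
print(f"mean durations (ms): {np.round(summary.duration_ms, 1)}")
print(f"coverage:            {np.round(summary.coverage, 3)}")
print(f"total GEV:           {gev.sum():.6f}")
```

prints

```
label agreement: 1.000
mean durations (ms): [87.9 75.6 86.6 78.9]
coverage:            [0.284 0.226 0.264 0.226]
total GEV:           1.000000
```

Backfitting a noiseless record recovers every generated state label, so
the empirical durations/coverages differ from the generating values
(80 ms each, uniform transitions) only by the sampling variability of one
60-second realisation, and the four templates explain all of the
topographic variance (ΣGEV = 1).

The same study runs end to end from the shell:

```bash
microfuse run out/demo --seed 11          # synthesize → … → metrics
microfuse report out/demo/metrics        # human-readable summary
```

`out/demo/metrics/metrics.json` holds pooled and per-fold (mean ± SD)
metrics; `out/demo/logs/training.jsonl` logs every epoch's validation
accuracy/loss, reward, loss weight and any perturbation/reinit events.

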