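# Methods

## The decoding model

The classifier is a compact convolutional network of the EEGNet family,
implemented in numpy with hand-written backpropagation. The architecture
factorizes the EEG epoch (channels × samples) into *when* and *where*:

* **Block 1** — a temporal convolution with `f1` kernels of length
  `temporal_kernel_len` (default 64 samples ≈ fs/4, same-padding, shared
  across electrodes) extracts frequency-selective features; a depthwise
  spatial convolution spanning the full electrode axis learns
  `depth_multiplier` spatial filters per temporal filter and collapses the
  channel dimension; a pointwise convolution mixes the `f1·D` maps into
  `f2`. Batch normalization, ELU, temporal average pooling and channel-wise
  (2-D) dropout follow.
* **Block 2** (and an optional **Block 3**) — a separable convolution:
  depthwise temporal kernels per feature map plus a pointwise mix, with the
  same normalization/activation/pool/dropout tail. Two blocks are the
  default; three are supported via `n_blocks`.
* **Head** — flatten and a dense layer to one logit per class; argmax with
  ties resolved toward the lowest output index.

Because every stage of Block 1 before batch normalization is linear, and a
channel-shared temporal convolution commutes with channel mixing, the block
is evaluated spatial-first (project 61 electrodes down to `f1·D` maps, then
convolve in time). This is an exact algebraic rearrangement — outputs and
parameter gradients are identical to the sequential form, which is asserted
by a unit test — and removes the electrode axis from the expensive temporal
convolution, making CPU training of the full pipeline practical.

Convolutions carry no biases (batch norm supplies affine terms). Weights
initialize from a seeded generator at scale 1/√fan-in. Training minimizes
class-weighted cross-entropy with w_k = N/(K·N_k) (so Σ N_k·w_k = N),
using Adam with decoupled weight decay applied to convolution/dense weights
only. Early stopping monitors validation loss with a patience counter and
restores the best epoch's weights; when no validation set is supplied, a
stratified fraction (default 0.15) is carved from the training pool. All
computation is single-threaded numpy, so a fixed seed reproduces training
bit-for-bit.

Default sizes: `f1=8`, `D=2`, `f2=16`, pools (4, 8), separable kernel 16,
dropout 0.25, input 61 × 251. The reduced "desk" profile used by the test
bed sets `f1=4`, kernel 32, `f2=16`, 30 epochs maximum with patience 5 and
learning rate 2·10⁻³.

## Evaluation protocol

A single network is trained on 80% of the pooled cohort, split stratified
by subject × class so every stratum contributes to both partitions
(rounding within ±1 trial). The held-out 20% is scored per subject with
five-fold cross-validation that *re-scores* the trained network on each
fold (no refitting — one pooled model is the object under study), yielding
one accuracy per participant. Per-subject normalization (z-scoring each
channel) is fit on the training partition only and applied unchanged to
held-out and cross-task data; an audit asserts train/test trial-identifier
sets are disjoint in every experiment.

## Chance-level inference

Accuracies are tested against a Binomial(n, 1/k) null, where n is the
average number of predictions per participant. The significance threshold
is the smallest correct count m with P(X ≥ m) ≤ α (exact tail, no normal
approximation; if even m = n cannot reach α the sentinel n+1 marks the
bound unattainable). The bootstrap (default 100,000 iterations) resamples
*subjects* with replacement and pairs each resampled subject with a fresh
null draw; the statistic is mean(observed) − mean(null), summarized by a
percentile 95% CI and a one-sided p-value floored at 1/n_iter. Subject-level
resampling is a design choice: the accuracy list is one value per
participant, and participants are the exchangeable unit. Two decoders are
compared with a pooled-variance two-sample t-test (df = n₁+n₂−2), with an
exact-equality fast path when the pooled variance is zero.

The type-I-error calibration check feeds the bootstrap per-subject
accuracies drawn directly from Binomial(n, 1/k)/n — exactly the
distribution a chance-level decoder's holdout accuracies follow — rather
than training hundreds of networks on null data; this isolates the
statistical procedure, which is what calibration is about.

## Grad-CAM attribution

For each trial the gradient of the *predicted* class's logit (an option
switches to true-class logits) is taken with respect to the second block's
post-ELU feature maps. Each map's weight is the temporal mean of its
gradient; the weighted sum is rectified (negative evidence zeroed). Because
Block 1 collapses the electrode axis, the maps have no native channel
dimension: the map-to-electrode projection chains the *squared* pointwise
and spatial convolution weights, normalized per map. Squared weights are
used because a channel's contribution to a spatial filter's output variance
scales with w²; the energy projection concentrates attribution on the
electrodes that actually drive each feature map, where an absolute-weight
chain is visibly more diffuse. The time axis is linearly interpolated from
the pooled grid back to the 251-sample input grid (bin centers at
(j+0.5)·pool−0.5). Maps are min–max normalized per trial, averaged within
participants, then across participants (each participant weighted equally),
re-normalized, and the element-wise median over repeated runs (default 5)
is reported. `window_mass` quantifies concentration as the fraction of
total importance inside a channel-group × latency window, compared against
the uniform expectation (window cells / total cells).

## Synthetic cohorts

The generator reproduces the study design's bookkeeping exactly: 7 door
configurations (non-empty subsets of three wall positions) × n_colors wall
colors (7 by default; the color-decoding preset uses 8, matching its 1/8
chance level); 6 blocks per participant with scene-memory trials strictly
before spatial-memory trials in each; 770 trials per task per participant
at full scale (110 per configuration), with remainders of non-divisible
counts spread deterministically and never dropped; a per-subject
color→goal-direction map drawn once; spatial-memory responses correct with
probability 0.93.

Epochs are background noise plus planted components:

* **Background** — per-channel Gaussian 1/f^β noise (β default 1.0,
  synthesized in the frequency domain, unit variance, scaled to `noise_sd`,
  default 6 µV), mixed with a shared per-trial trace as
  √(1−ρ)·own + √ρ·shared so the pairwise channel correlation is ρ
  (`spatial_mixing`, default 0.3).
* **Components** — Gaussian bumps in time on a fixed channel topography
  (max |w| = 1), with per-class amplitudes keyed to a metadata field, a
  per-subject lognormal gain (SD 0.2) and Gaussian latency jitter
  (SD 10 ms). Scenario presets place the effects where evoked scene
  responses are observed empirically: occipitoparietal channels at
  50–250 ms, frontal channels near 190 ms, late central (motor) activity
  after 600 ms. Preset amplitudes (8 µV three-channel occipitoparietal
  patches for the 7-affordance and 8-color scenarios; 6 µV for the 3-goal
  scenario; 2–6 µV task differences) were chosen once so that reduced
  cohorts decode in the accuracy regime such analyses report, and are part
  of the fixed study conditions.
* **Artifacts** — with probability `artifact_rate`, a 150 µV rectangular
  100 ms excursion on two random channels, exercising the 100 µV rejection
  rule.

`remap_condition_patterns` derives the cross-task dissociation condition:
spatial-memory trials express each class through another class's
topography/latency (a seeded derangement; an explicit permutation can be
passed, and the identity returns the config unchanged), while scene-memory
trials and the marginal amplitude distribution are untouched.

All randomness flows from one master seed through named sub-streams
(schedule, noise, gains, artifacts, balance, split, init, train,
bootstrap), so identical seeds give bit-identical epochs, trainings and
reports, and modules can be re-run independently.

What the generator does *not* emulate: ocular/muscular artifact
morphology, electrode drift or re-referencing effects, volume-conduction
topographies from a head model (topographies are abstract weight vectors),
non-stationary noise, or realistic between-subject topographic variability.
Passing tests therefore demonstrate that the pipeline recovers planted
effects of plausible magnitude under EEG-like noise — not that the same
accuracies would be obtained on real recordings.

## Preprocessing

Zero-phase 4th-order Butterworth band-pass (0.3–50 Hz; forward–backward,
preserving latencies), baseline correction over −200..0 ms, cropping to
the 0..1000 ms model window with inclusive endpoints (251 samples at
250 Hz), rejection of any trial exceeding 100 µV at any channel/sample,
and mastoid (M1/M2) removal leaving 61 data channels. Baseline correction
runs before cropping because its window lies in the discarded pre-stimulus
segment. Amplitude-threshold rejection is the only artifact control:
synthetic data carry no physiological artifacts, so an ICA/ASR chain would
have nothing to act on.

## Experiments and problem sizes

Each experiment repeats `n_runs` times (default 5) with fresh
balance/split/training per run and reports medians. The scale profiles fix
the simulated problem sizes: `smoke` (3 subjects × 112 trials/task, 1 run,
2,000 bootstrap iterations) exercises everything in well under two
minutes; `desk` (5 × 399, 5 runs, 10,000 iterations) is the reduced
default for interactive work; `full` (30 × 770, 100,000 iterations)
mirrors the complete design and is proportionally slower. The acceptance
suites run single-run experiments at 5 subjects × 224 trials/task
(parameter recovery, with a cohort whose only planted signal is the
occipitoparietal 50–250 ms effect) and 4 subjects × 280 trials/task
(generalization dissociation, 2,000 bootstrap iterations); these sizes are
the package's chosen reduced conditions and are asserted with the pass
fractions stated in the test suite (≥9/10 and ≥8/10 seeds).

## Numerical and design choices

* Epoch windows: simulation defaults to (−1 s, +2 s) at full scale;
  reduced profiles simulate (−0.3, +1.1 s), the minimal span containing
  the baseline and model windows.
* Zero-variance channels in normalization receive ε = 10⁻⁸ with a warning.
* Pooling uses floor division; trailing samples that do not fill a bin are
  dropped (251 → 62 → 7 with pools 4 and 8).
* Batch-norm running statistics (momentum 0.1) are used in evaluation
  mode; Grad-CAM backward passes run in evaluation mode, so no batch
  coupling enters the gradients.
* The binomial threshold uses scipy's exact binomial survival function;
  the test suite checks it against explicit tail summation for
  k ∈ {2,3,7,8}, n ∈ 10..2000.
* Hyperparameter search is seeded random sampling with successive halving
  (candidates train for increasing epoch budgets; the better half survives
  each rung), replacing Bayesian/TPE approaches out of scope here.
* The per-subject five-fold evaluation re-scores one pooled model; fold
  sizes differ by at most one trial.
* The affordance generalization decoder uses k = 7 classes in both
  directions; reports can optionally flag a different k for the chance
  test without resolving that inconsistency.

## Known limitations

* The CNN is CPU-bound numpy; full-scale cohorts (30 subjects × 1,540
  trials) train in minutes-to-tens-of-minutes, not seconds.
* Grad-CAM's electrode projection is a model-derived heuristic — the
  channel axis genuinely no longer exists at Block 2 — so channel
  attributions inherit the spatial filters' smoothness and should be read
  as relative, not anatomical, localization.
* The generator's subject variability (scalar gain + latency jitter) is
  far simpler than real inter-subject topographic variability; cross-task
  transfer results on synthetic data are best-case.
* EDF import requires mne and expects an `onset_sample` metadata sidecar;
  no other acquisition formats are supported.
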