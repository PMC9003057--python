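# Methods

## The estimator

`gsconn` measures directed functional connectivity between brain areas
through the lens of *generalized synchronization*: two systems are
functionally related when the state of the response system is a
function of the state of the drive system,

```
y(t) = F(x(t)).
```

Each area is represented by three sensors whose band-limited series are
taken as the coordinates of a 3-D state trajectory,

```
x(t) = (x1(t), x2(t), x3(t))^T,   y(t) = (y1(t), y2(t), y3(t))^T.
```

A small feed-forward network — 3 linear inputs, two hidden layers of 10
units with a softmax activation across each layer, 3 linear outputs —
is trained to predict y(t) from x(t). The quality of the approximation
y'(t) on held-out samples is the connectivity value, scored with the
pooled multivariate coefficient of determination

```
R2 = 1 - [ Σ_d Σ_i (y_d(t_i) - y'_d(t_i))² ] / [ Σ_d Σ_i (y_d(t_i) - ȳ_d)² ],
```

one ratio pooled over all D·N points (D = 3), *not* an average of
per-dimension scores. R2 is at most 1 and unbounded below; predicting
each dimension's mean scores exactly 0.

### Directionality caveat

Cross-prediction detects functional *interdependence*. When F is
invertible (any non-degenerate affine map), the reverse direction
x = F⁻¹(y) is equally predictable, and both directed entries of a
coupled pair score high. Simulations with a single strength-1 affine
link show forward R2 ≈ 0.996, reverse ≈ 0.98, and ≤ 0.04 for every pair
with no link in either direction. Asymmetry between the two directions
is therefore informative only for non-invertible couplings; the matrix
as a whole should be read as a dependence graph with directional
annotations, not as proof of causal direction.

## Pipeline

1. **Notch filter** (zero-phase IIR, default 50 Hz, Q = 30) on the
   continuous recording.
2. **Band-pass** into the band of interest — theta 4–8 Hz and mu
   8–14 Hz by default — with a Butterworth filter applied
   forward–backward (`sosfiltfilt`), order 4 per pass. Zero-phase
   filtering preserves the latency of event-locked features; a single
   causal pass would shift them. Filtering precedes epoching so edge
   transients never fall inside an epoch.
3. **Epoching** around each stimulus event, −1 s to +2 s by default.
   Events without full margins are dropped with a warning rather than
   zero-padded (padding would corrupt trajectory statistics).
4. **Window slicing** into five frames: (−1,0), (0,0.5), (0.5,1),
   (1,1.5), (1.5,2) s. Windows are half-open `[start, end)` in samples
   so the five frames tile the epoch without duplicated samples.
5. **Trajectory extraction** per area: the three channel rows in the
   region's declared order, trials concatenated along time
   (N = trials × window samples). One model is trained per
   subject/band/window over all epochs pooled; the learned mapping is
   instantaneous, so concatenation introduces no cross-trial leakage.
   Channel lookup is by label, case-insensitive (EDF headers vary in
   capitalisation).
6. **Normalization** of each trajectory row to (0, 1) by min–max
   scaling, computed per window-level trajectory.
7. **Training**: the paired samples are jointly shuffled with a seeded
   generator and split 50/50 into training and validation halves; Adam
   (lr 0.001, β₁ = 0.9, β₂ = 0.999, ε = 1e-8) minimizes the MSE over
   the three output components for 1000 iterations. The **validation**
   R2 is the stored connectivity value — the defensible reading of a
   protocol that holds out half the data; the training score is also
   reported in `TrainOutcome`.
8. **Matrix assembly**: all 20 ordered pairs of the 5 areas, diagonal
   masked (self-prediction is trivially near-perfect and would distort
   statistics). Each fit's seed derives from
   (base seed, subject, band, window index, drive, response) — see
   "Seeding" below.
9. **Baseline correction**: the prestimulus matrix is subtracted
   entrywise from every window's matrix (its own included, which
   becomes exactly zero). The operation is idempotent.

### Sensor groups

Five 3-sensor areas over the 10–10 montage: parietal P = {P4, Pz, P3},
frontal F = {F4, Fz, F3}, and left/right/midline motor cortex
MCL = {Fc3, C3, Cp3}, MCR = {Fc4, C4, Cp4}, MCZ = {Fcz, Cz, Cpz} — 15
distinct sensors. (Published descriptions of this montage occasionally
quote "18 selected channels"; the five 3-sensor groups above are the
consistent reading, since the state space is fixed at D = 3.) Custom
groups can be configured, but must have exactly three channels each and
share no channel.

## What "1000 iterations" means

An Adam update moves each weight by at most ≈ the learning rate, so
1000 *single-step full-batch* passes at lr 0.001 cannot move weights
more than ~1 unit — not enough to fit even a strength-1 affine coupling
(measured validation R2 ≈ 0.13). Mainstream MLP implementations count
`max_iter`/epochs as passes over shuffled minibatches; with the default
minibatch size of 200 (capped at the training-set size), 1000
iterations means ~10⁴ Adam updates and the same affine task reaches
R2 ≈ 0.997. `gsconn` therefore reads an iteration as one pass over the
training split in seeded minibatches of `batch_size` (default 200);
`batch_size: null` selects strict one-step-per-iteration full-batch
training for comparison. The softmax hidden activation is implemented
literally (softmax across each hidden layer's 10 units), with sigmoid
and tanh as configurable alternatives.

## Seeding and determinism

Everything stochastic — weight initialization (Glorot-uniform), the
shuffle-split, minibatch order, and all simulation noise — flows from
explicit integer seeds through `numpy` SeedSequences. Identical
(data, config, seed) reproduce bit-identical results on one platform;
a pipeline rerun from the same config produces byte-identical archives.

Per-fit seeds are hashed from (base seed, subject id, band, window
index, drive index, response index). Including the subject is
essential, not cosmetic: if all subjects of a group share
initialization and split seeds, the estimator's finite-sample bias is
common across subjects, and the paired within-group test flags that
common bias as an effect. With subject-dependent seeds the null
simulation calibrates at the nominal level.

Many independent fits (the 20 pairs of a matrix; all subjects × pairs
of a simulation repetition) are advanced through a single loop of
stacked batched matmuls; the stacked path produces the same numbers as
one-at-a-time fits and is asserted equivalent in the tests.

## Group statistics

Within a group, each post-stimulus window is contrasted against the
prestimulus window by a paired t-test per directed link, on
*uncorrected* matrices — baseline subtraction is common to both
operands of the paired difference, so the test is identical either way
(asserted as a test). Between groups, each link is contrasted with
Welch's unequal-variance t-test (groups are small and variances
unknown). Both are two-sided with α = 0.05 by default.

Bonferroni correction uses the family of links tested together; the
default family is the 20 directed links of one window × band
(`stats.family: per_window`), with `per_band` and `global` as
configurable alternatives. Links with zero variance of differences are
flagged degenerate with t = 0 and p = 1. Significance is strict:
`p_corrected < α` with corrected p capped at 1.

## The synthetic generator

`simulate_subject` builds a continuous 15-channel recording in which
each region's three channels carry unit-variance Gaussian noise
band-limited with the same Butterworth code the pipeline uses
(guaranteeing spectral consistency; ≥ 90 % of channel power falls in
the configured band). A directed coupling makes each response channel

```
y_d(t) = c(t) · F_d(x(t)) + (1 − c(t)) · η_d(t) + σ · ν_d(t),
```

with F a seeded random affine, tanh-saturating or quadratic map of the
drive region's standardized 3-D state, η and ν fresh band-limited
noise, and c(t) a piecewise-constant schedule: per analysis window
relative to each event, `baseline_strength` elsewhere. The (1 − c)
mixing keeps response variance roughly independent of c, so estimated
R2 tracks coupling rather than amplitude. Defaults mirror the study
conditions: 250 Hz, 30 trials, events 6–8 s apart, measurement noise
σ = 0.05, between-subject strength jitter s.d. 0.05 in groups.

Constraints: the coupling graph must be feed-forward with at most one
incoming link per region (cycles and multi-parent nodes raise errors);
couplings are instantaneous, matching the estimator's memoryless model.
What the generator does **not** emulate — neural mass dynamics, volume
conduction, 1/f background, artifacts — bounds what passing tests
show: they validate the estimator's statistical machinery and its
sensitivity to known functional dependence, not its behaviour on every
property of real EEG. One realistic caveat is visible even here:
because band-limited signals are strongly autocorrelated, the random
shuffle-split places validation samples between temporally adjacent
training samples, which mildly inflates small-sample validation R2
(≈ 0.07 at N = 1250 for independent signals, ≈ 0.0 at N = 3750). This
is inherent to the shuffle-split protocol itself.

## Problem sizes of the simulation studies

Chosen as the package's own defaults for desk-scale verification:

- **Detectability**: 10 seeded subjects at full study conditions
  (30 trials, 0.5 s window → N = 3750), full 5×5 matrix each.
- **Monotonicity**: strengths {0, 0.25, 0.5, 0.75, 1} × 10 seeds,
  two-region network, 10 trials (N = 1250), one fit per cell.
- **Type-I calibration**: 100 repetitions × 10 subjects, 2 trials,
  0.25 s windows, reduced model (200 iterations, full-batch). The null
  distribution of the t statistic does not depend on estimator quality,
  so the cheapest consistent settings suffice.
- **Power**: 5 runs × 10 subjects, 10 trials, 0.5 s windows, reduced
  model (200 iterations, minibatch 50) — the power arm needs enough
  data and updates for the 0.1 → 0.9 step to surface in R2.

## Known limitations

- No artifact handling: input is assumed cleaned (ICA, epoch rejection
  happen upstream).
- Lagged couplings are invisible to the instantaneous cross-predictor;
  the generator offers them only as realistic negatives.
- Direction of an invertible coupling is not identified (see above).
- The Bonferroni family is a configuration choice; per-window
  correction (the default) is anti-conservative relative to a global
  family if many windows/bands are screened.
- EDF export is not implemented; recordings are written in the
  delimited-text dialect (EDF reading is supported via `mne`).
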