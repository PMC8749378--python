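# Methods

This note records the model as implemented, the defaults and why they are
what they are, what the synthetic data does and does not emulate, and the
numerical and design choices made where the published description of this
family of models is ambiguous or silent.

## Model

`pgsom` trains a competitive-learning network whose output layer lives on
an unbounded 2-D integer lattice with von Neumann (4-) connectivity.
Three variants share one presentation pipeline:

* **som** — fixed `som_rows × som_cols` grid; weights adapt, topology is
  frozen.
* **gsom** — starts from a 2×2 seed at (0,0),(0,1),(1,0),(1,1) and adds
  neurons dynamically. Each neuron accumulates CEQ += η·d on the
  presentations it wins (d the squared Euclidean distance to the input).
  When a winner's CEQ reaches the growth threshold GT = −D·ln(SF) it
  either grows — if it has at least one free neighbor slot, a new neuron
  is created in *every* free slot and the winner's CEQ, spent on growth,
  resets to 0 — or, if interior, keeps CEQ/2 and distributes the removed
  half equally over its occupied neighbors (total CEQ is conserved
  exactly in this branch).
* **pgsom** — gsom plus age-based pruning: ages count presentations since
  a neuron last won (winner and newborns reset to 0, everyone else +1),
  and any neuron with age > M is deleted immediately after the growth
  step. M = round(RF · batch_size); an explicit `m=inf` disables pruning,
  in which case pgsom is field-identical to gsom (tested).

Squared Euclidean distance is used consistently: for winner search, for
CEQ accumulation, and inside the neighbor-damping factor.

### Weight updates

The winner moves toward the input at the plain learning rate,
w ← w + η(x − w). Its occupied lattice neighbors move toward the
winner's *pre-update* weight, damped by their own distance to the input:
wᵢ ← wᵢ + η (w_winner − wᵢ) e^(−dᵢ/τ). A literal reading of the update
rule in this model family leaves the winner fixed (its self-difference is
zero) while the surrounding prose says the winner is updated; moving the
winner at plain rate η and the neighbors by the damped rule is the
minimal repair that honors both.

The neighborhood of the update is the direct 4-neighbors only, consistent
with growth and redistribution, which also act on direct neighbors.

### Growth-slot weight interpolation

New neurons get deterministic interpolated weights, in a fixed case
ladder: (a) if the slot opposite the new position across the winner is
occupied, linear extrapolation 2·w_winner − w_opp; (b) else the midpoint
with the winner's lowest-id occupied neighbor; (c) else (lone neuron)
w_winner plus a seeded perturbation uniform within ±1 % of the
per-dimension data range.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| SF | 0.8 | spread factor in (0,1); GT = −D·ln(SF). 0.8 is the best cell of the reference grid. |
| RF | 1.5 | ratio factor; M = round(RF·batch). 1.5 is the best reference cell. |
| eta0 | 0.3 | initial learning rate. |
| R | 1.0 | decay constant in η ← (1 − R/\|Φ\|)·η. Decay contracts only while R < \|Φ\|; degenerate configs clamp to eta_min with a warning. |
| eta_min | 1e-4 | floor keeping η positive. |
| eta_decay | "iteration" | decay cadence; see below. |
| tau | auto (= D) | neighbor-damping bandwidth; see below. |
| batch_size | 4000 | samples per training iteration (seeded; without replacement when the pool suffices). |
| calib_size | 2000 | labeled samples used for calibration. |
| max_iter | 50 | training iterations; the reference protocol converges by ~45. |

**Decay cadence.** η is decayed once per *iteration* (batch), not per
sample. The decay factor (1 − R/|Φ|) is a per-iteration contraction: the
defining description ties the decrease of η to iterations, and a
per-presentation reading drives η to the floor within a few dozen samples
of a 4-neuron start (0.75 per presentation), after which no
self-organization is possible at any realistic scale. The per-presentation
cadence remains available as `eta_decay="presentation"`. η is never reset
between iterations.

**Damping bandwidth τ.** The factor e^(−dᵢ/τ) acts on *squared* distances,
whose typical magnitude for standardized D-dimensional data is ≈ D
(E‖x − w‖² = D for a well-placed neuron). With τ = 1 the factor
underflows to zero for any D beyond a handful, neighbors never move, and
a single interior winner halves-and-redistributes forever while the map
deadlocks at a few neurons. τ therefore defaults to D; τ = 1 reproduces
the undamped-by-dimension form for low-dimensional data.

**Tie-breaks** (all deterministic): winner-distance ties go to the lowest
neuron id; neighbor enumeration is always [up, down, left, right];
calibration majority ties go to the smallest class label; dead-neuron
label propagation ties go to the smallest labeled neuron id; M uses
half-up rounding; a prune that would empty the network retains the single
youngest neuron (lowest id on ties) and warns.

## Features

Raw input is a 30 Hz, 7-channel table (wrist x/y/z, hip x/y/z, piezo
ventilation). Two synthetic acceleration channels — the per-sample norm
√(x²+y²+z²) of each tri-axial triple — give 9 signals. Non-overlapping
500-sample windows (step configurable; "sliding" length 500 is the
reference) each yield 11 statistics per signal plus
corr(hip-synthetic, piezo) and corr(wrist-synthetic, piezo):
11·9 + 2 = 101 features, in a fixed documented column order.

Statistic conventions are pinned because dialects differ: population
variance (÷ n); RMS = √(mean of squares); Fisher *excess* kurtosis and
Fisher–Pearson g₁ skewness (both defined as 0 for a zero-variance
signal); energy = mean of squares (scale-free in window length; plain sum
is selectable); percentiles by linear interpolation; Pearson correlation,
defined 0 when either series is constant. Feature scaling (z-score fitted
on training data, constant columns passed through) lives in the feature
module; the training core never rescales.

## Synthetic data

The reference wearable dataset is not public, so the generator reproduces
its statistical shape:

* **Feature-space generator** (primary): 9 isotropic unit-variance
  Gaussian clusters in 101-D, centroids seeded on a sphere of radius
  `separation` (default 8, in within-class standard deviations), class
  sizes by largest-remainder rounding of the reference proportions
  1635 : 807 : 794 : 840 : 1549 : 1646 : 494 : 359 : 462 (total 8586).
  The pair (4, 6) — emulating walking vs low-speed running — is pulled to
  separation/4 apart, making it genuinely confusable: at the default
  separation its Bayes error is ≈ 16 % within the pair, so even an ideal
  classifier tops out near 95 % overall. Tests confirm that essentially
  all residual errors concentrate on this pair.
* **Raw-signal generator**: per-class sinusoids (0.5–4 Hz fundamentals)
  with seeded per-channel amplitude/phase and Gaussian noise at 30 Hz,
  used to integration-test the windowing/feature pipeline.

What passing tests on this data do *not* show: isotropic Gaussians have
none of the heavy tails, autocorrelation, inter-subject variability, or
scale heterogeneity of real accelerometer features, and winner distances
concentrate tightly (relative sd ≈ √(2/D)), which makes growth dynamics
more regular than on real data (see the limitation below).

## Evaluation

Confusion-matrix metrics are computed from first principles (accuracy =
trace/total; Cohen's kappa with chance agreement from the marginals;
macro recall and macro F1 excluding classes absent from the truth) and
cross-checked against scikit-learn in the tests. Cross-validation is
seeded stratified k-fold (round-robin within class; fold sizes differ by
≤ 1); each fold trains unsupervised on the fold-train portion, calibrates
on a fixed seeded subset, and scores the held-out fold. Inference time is
reported but is hardware-bound and excluded from any assertion.

## Problem sizes

The test suite exercises training at n = 2000 samples, batches of 1000,
10 iterations (and 500-presentation runs at D = 5 for the structural
equivalence checks); the acceptance script runs the full protocol scale —
8586 samples, 9:1 split, batches of 4000, 2000-sample calibration, 50
iterations — for both GSOM and PGSOM. These sizes keep a complete run in
the minutes range on a single CPU while reproducing the reference
protocol's proportions.

## Known limitations

* **Pruning does not shrink the standing network on this data.** Pruning
  reliably deletes inactive neurons, and `m=inf` reproduces growth-only
  training exactly. But on the synthetic clusters, boundary winners
  re-cross GT on nearly every win (η·d̄ ≳ GT), so a pruned slot is
  refilled almost immediately, and deleting a dead neighbor also converts
  interior winners back into boundary winners — turning redistribution
  events into growth events. The standing PGSOM population therefore
  tracks, and can slightly exceed, the GSOM population (measured ≈ +4 %
  at the 10-iteration test scale and ≈ +15 % at protocol scale), instead
  of showing the substantial net reduction reported for the original
  private dataset, whose error landscape is plausibly in the gradual
  regime (growth driven by rare large-error events, leaving pruned slots
  empty for long stretches). Accuracy behaves as reported — PGSOM matches
  or exceeds GSOM — but the model-size benefit of pruning should not be
  expected on data whose winner distances are as concentrated as
  isotropic Gaussians make them.
* Single-threaded, in-memory training; no batch-SOM, conscience, or
  connection-based (SOINN-style) pruning variants.
* The calibration step assumes every class present in the labeled subset;
  missing classes warn and are excluded from macro averages.
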