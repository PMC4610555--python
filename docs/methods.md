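# Methods

This note records the scientific and numerical choices behind `gaitphase`:
what is modelled, what the synthetic data do and do not emulate, and where
the design was genuinely open.

## Signals and preprocessing

A trial couples the sagittal angular velocity of foot and shank (gyroscope,
50 Hz, deg/s) with a four-channel binary footswitch trace (200 Hz; heel,
5th metatarsus, 1st metatarsus, toe). Angular velocity is low-pass filtered
with a Butterworth filter, cut-off 15 Hz. The filter order (default 4) and
the forward–backward (zero-phase) application are package choices: the
transition-timing evaluation uses a ±30 ms window, and a causal filter's
group delay would bias every detected transition late by several samples.
Both knobs sit in `TrainConfig`.

The footswitch trace is aligned to the gyro clock by taking the state of
the nearest original sample at each gyro tick (no majority vote). This is
deterministic and keeps phase-onset timing within ±2.5 ms, below the
evaluation resolution. When the three signals disagree in span, the
intersecting span is used with a warning.

## Footswitch partitioning

The reference phase sequence comes from the switch combination at each
sample. Rules per phase: a required-active set (all pressed, all unmarked
switches released) and, for stance in 2P and heel-off in 4P, an any-of set
(at least one pressed). The tabulated combinations do not cover all 16
physically possible ones (e.g. all four pressed), so classification is
tiered:

1. exact rule match;
2. most-specific subset: the phase whose non-empty required set is the
   largest subset of the active set, if that maximum is unique — this is
   what resolves "all four pressed" to mid stance and "three forefoot
   switches" to terminal stance; a tie is broken toward the immediate
   successor of the previous phase when that successor is among the tied
   candidates;
3. otherwise the previous phase is held;
4. with no history at all, the heel-contact phase.

Whether unmarked switches should be read as don't-care or required-inactive
is not derivable from the rule table alone; required-inactive (with the
tiered fallback) was chosen because it keeps the exact tier unambiguous.
The rule is total and deterministic, which the test suite verifies by
exhaustion over all combinations, models and histories.

Stride boundaries are transitions into the phase that cyclically follows
swing — the heel-contact phase (SP, HS or IC). For the 4P vocabulary this
deliberately differs from the first listed phase (FF): heel contact, not
foot-flat, is the stride event.

## HMM core

Emissions are univariate Gaussian mixtures with `n_mix = 1` by default. The
parameter set nominally carries mixture weights `w`; with one component
they are degenerate at 1. This is the minimal reading consistent with the
parameterisation; `n_mix` is configurable.

The transition matrix is cyclic left–right: `a_ii = 1 − 1/d_i`,
`a_{i,i+1 mod n} = 1/d_i`, everything else exactly zero, with `d_i`
initialised from the mean phase durations measured on the training
reference. Cyclicity is required because trials contain tens of strides; a
terminating chain cannot re-enter the first phase. The initial distribution
is uniform (the phase at recording onset is unknown).

Numerics: forward–backward runs in scaled linear space (per-step max-shift
of the log emission densities, per-step normalisation of the forward
variable), which is exact for the log-likelihood and substantially faster
than per-step log-sum-exp at these state counts; Viterbi runs in log space.
Probability floors keep zero-likelihood samples from producing NaNs.
Baum–Welch preserves the structural zeros of `A` (a zero entry accrues zero
expected transitions), clamps emission SDs at a floor (default 1% of the
pooled training-signal SD) and stops at a relative log-likelihood change
below 1e-6 or at `max_iter`. The per-iteration log-likelihood is
non-decreasing up to 1e-8 slack, and this is asserted in tests on every
training run they perform.

Decoding defaults to exact offline Viterbi. A fixed-lag variant (commit the
best-path state `lag` samples behind the frontier) is provided for online
use; for `lag ≥ T` it coincides with the offline decoder, and on
well-separated data a 100 ms lag agrees with it on ≥ 99% of samples. Which
decoder "modified Viterbi" should denote is not reconstructable; both are
exposed and selected by `TrainConfig.decoder`.

## Distributed (fused) classification

The distributed classifier combines the two scalar members' per-sample
state posteriors as a convex combination (uniform weights by default; an
optional performance weighting `w_k ∝ √2 − G_k` from training-set goodness
is available), renormalises per sample, and decodes the fused scores as
emission likelihoods through a fusion matrix `A_dc` that permits self, next
and previous phase (`a_ii = 0.9` by default). The backward step lets the
fusion chain retract a member's premature transition. The precise fusion
rule of the original hierarchical-decision scheme is not specified at this
level of detail anywhere reachable; the convex-posterior reconstruction is
the package's own and is recorded in model metadata.

## Training protocols

**SST.** Per subject and walking condition: partition repetition 1 by its
footswitches, initialise emissions phase-wise, build `A` from measured
durations, refine by Baum–Welch on the filtered repetition-1 signal
(default 10 iterations — supervised initialisation leaves little for EM to
do), test on repetition 2. Repetition 2 is never touched during training;
the training-trial keys are recorded in classifier metadata.

**Phase-wise initialisation.** Every occurrence of a phase is resampled to
`L_norm = 100` points by linear interpolation so short and long occurrences
weigh equally; mean and ML (ddof = 0) standard deviation are taken over the
pooled normalised ensemble. The normalisation length is a package choice
(only the fact of normalisation is prescribed); means are invariant to it,
which is tested.

**SPT.** The standardized parameter set is built from the healthy (TD)
group only, per condition: each included subject's repetition-1 strides
(heel-contact to heel-contact on the 6P reference) are resampled to
`L_cycle = 200` points, averaged within subject, then across subjects.
Emission means come from the template waveform under a majority-vote phase
script; emission SDs pool the within-phase variation of the template with
the per-point cross-subject dispersion — the dispersion term matters
because averaging alone shrinks variance and would produce an overconfident
model. Durations scale the script's phase fractions by the mean cycle
length. Baum–Welch then refines on ten concatenated template cycles.
Evaluated TD subjects are excluded from their own template (leave-one-out);
HC subjects are tested against the full TD template. Whether the original
procedure averaged before or after phase partitioning is open; this package
averages whole normalised cycles and partitions the template afterwards.

**The factorial study** crosses {SST, SPT} × {2P, 4P, 6P} × {ft SC, sh SC,
ftsh DC} — 18 configurations — over every subject and condition, always
training on repetition 1 and testing on repetition 2, and reports confusion
counts, TPR, TNR, G and the ROC category per cell. Scalar trainings and
member posteriors are cached and shared between SC and DC cells, which
keeps the full 20-subject study under two minutes on one CPU.

## Evaluation

The positive event is a phase transition. The tolerance window is 60 ms
centred on each reference transition; its half-width in samples is
`floor(tol/2 · fs/1000)` — ±1 sample at 50 Hz (the rounding rule is
configurable). Matching requires the identical (from, to) phase pair and is
greedy nearest-first, one-to-one — the strictest reading of "accordingly
detected". Unmatched reference transitions are FN, unmatched predicted
transitions FP, and remaining non-transition samples TN. Degenerate
denominators yield missing rates and a missing G, never a silent zero.

`G = sqrt((1−TPR)² + (1−TNR)²)`; bands: optimum ≤ 0.25, good < 0.70,
random at 0.70, bad above. By this definition the supremum of G is
√2 ≈ 1.414 (both rates zero). Aggregation reports mean and SD (n−1) of G
per (group, condition, model, signal, procedure) cell.

## Synthetic cohorts

The generator is the package's test bed, not a biomechanical simulation.
Each stride follows a six-phase script whose footswitch progression
`{H} → {H,5} → {H,5,1} → {H,5,1,T} → {5,1,T} → {T} → {}` traverses the
tabulated combinations plus the two off-table ones that the specificity
tier resolves (all-four → MS, three-forefoot → TS). Footswitch, phase
script and gyro waveform are derived from the same stride-edge floats, so
partitioning a noise-free trial reproduces the emitted script exactly — an
oracle the test suite leans on heavily. The strict (table-only) progression
exists for exact-rule tests; it has no all-four segment, hence no 4P
flat-foot phase, and cannot support 4P training.

Waveforms are per-segment plateaus (deg/s) joined by 40 ms cosine ramps at
segment boundaries, with sinusoidal swing bumps (double-peaked for the
shank). Plateau levels were chosen once to mimic the qualitative shape of
sagittal foot/shank angular velocity: strong features at heel strike,
heel-off, push-off and swing; nearly equal levels across the
loading/mid-stance boundaries, where real recordings also carry little
information. That last property is what makes the finer vocabularies
genuinely harder — boundaries without a kinematic event (first-metatarsal
contact, forefoot loading) are resolvable only through duration structure —
and reproduces the qualitative ordering of difficulty (2P easiest, finer
models and inter-subject training harder, shank worse than foot under SPT)
rather than assuming it.

Default study conditions: cadence 42 strides/min; 6P phase fractions
(IC, LR, MS, TS, PS, SW) = (0.04, 0.07, 0.28, 0.13, 0.08, 0.40) with 75% of
MS forefoot-loaded; conditions modify cadence (speed) and shank amplitude
(incline); inter-subject SD 6% on timing/amplitude/fractions;
stride-to-stride SD 3% for TD and 8% for HC (hemiplegic gait is the more
variable); additive gyro noise 12 deg/s. Trials default to 60 s; the
acceptance study uses 30 s trials to keep the 1440-cell factorial fast —
fractions and levels are free parameters of the template, and none of the
package's checks depend on their realism beyond separability.

What the generator does **not** emulate: soft-tissue artifact, sensor
drift, asymmetric or festinating gait patterns, spasticity-related
waveform distortions, footswitch bounce, or any validated biomechanics.
Passing tests therefore demonstrate the correctness of the pipeline and
the achievable behaviour under controlled variability, not clinical
performance on real recordings.

A three-axis mode adds proportional off-sagittal components so that fixed
IMU-misalignment rotations (e.g. 2° about the frontal and/or transverse
axis) can be applied and the sagittal channel re-extracted, mirroring the
usual sensor-placement sensitivity check; with zero off-sagittal content a
pure rotation scales the sagittal trace by the cosine of the angle, which
is tested.

## Known limitations

* Emissions are univariate per member; multivariate fusion happens only at
  the posterior level.
* The G categories make the "random" band a measure-zero point at 0.70; it
  is reported only when hit within 1e-9.
* The tolerance half-width at 50 Hz truncates 1.5 samples to 1; with the
  "nearest" rounding rule results shift slightly in the permissive
  direction.
* Synthetic 2P classifiers routinely reach G = 0 — stance/swing boundaries
  coincide with the sharpest waveform features by construction; real data
  would not be this clean.
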