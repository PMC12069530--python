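# Methods

This note documents the models and procedures implemented in `oipr`, the
parameters that matter and their defaults, the numerical choices, and what
the synthetic-data generator does and does not emulate.

## Task structure and data model

A session is a sequence of blocks; a block is 30 completed trials — five
scenes presented in a fixed order, repeated for six runs. Each scene is
bound for the whole block to one correct object (of two) and one reward size
(small / medium / large, nominally 0.15 / 0.3 / 0.6 ml). Within a block all
three sizes are present and no size is assigned to three scenes, so the
composition over the five scenes is always 2+2+1. A *stay* trial repeats the
choice made for the same scene in the previous run; a *switch* trial takes
the alternative object; run-1 trials are undefined. All times are integer-
friendly milliseconds on one session clock; event times (scene onset,
go-signal, feedback onset) live in the trial table, spike times per neuron
in an HDF5 store. Incomplete trailing blocks are excluded from block-level
analyses (`complete_blocks`) but usable for epoch-level decoding.

Binning is half-open: a bin covers `[start, start + width)` and a spike on
the boundary belongs to the later bin. The bin count for a span is
`floor((span − width)/step) + 1`; the package default span of −500 to
+1300 ms around an alignment event gives 63 bins at the standard
250 ms / 25 ms binning, which together with 20 label shuffles yields the
1260-value null pool and the Bonferroni threshold 0.05/1260 ≈ 3.97 × 10⁻⁵.
The span itself is an analysis choice (it includes a pre-event baseline and
the shortest delay duration) and is configurable per epoch.

## Synthetic-data generator

The generator exists so that every downstream analysis can be validated
against a known ground truth; its defaults define the study conditions used
throughout the tests.

**Design.** Scene order is drawn once per block and reused across the six
runs; the scene→reward map obeys the 2+2+1 rule; scene identities are fresh
each block. Delay (scene onset → go) is 800 or 1200 ms and the feedback
display 400 or 600 ms, drawn per trial; the inter-trial interval (2 s)
leaves room for pre-event baseline bins.

**Agent.** Learning is modeled phenomenologically rather than with a
reinforcement-learning rule: run-1 choices hit the correct object with
probability 0.5; from run 2 the agent repeats its previous choice for that
scene with a probability conditional on reward size and on whether that
choice was correct. Defaults: stay after a correct choice 0.70 (small) /
0.95 (medium, large); stay after an incorrect choice 0.15 / 0.25 / 0.25.
These four numbers per size are the minimal mechanism that reproduces the
behavioral pattern of interest — fast learning and exploitation for medium
and large reward, a slower learning curve and an elevated switch rate for
small reward in *both* outcome branches. Reaction times are log-normal with
medians 400 / 320 / 300 ms (σ = 0.2) so small-reward trials are slower;
movement times are size-independent (median 250 ms, σ = 0.15).

**Spiking.** Each neuron is a Poisson process: a constant baseline (10 Hz)
plus additive rate gains inside event-locked windows, realized exactly by
superposing extra Poisson spikes (positive gains) or thinning the baseline
train (negative gains; rates clip at zero with a warning). Default gains:
feedback window (0–400 ms after feedback onset) 0 / 4 / 8 Hz for
small/medium/large, active from the first trial of a block; delay window
(400 ms after scene onset until the go-signal) 0 / 4 / 4 Hz — a *merged*
medium/large representation — active only when the within-block trial index
reaches the learning gate (default trial 15); action window (800–1000 ms
after scene onset) 0 Hz stay / 4 Hz switch. Each neuron is independently a
coder of each feature (probabilities 0.6 / 0.5 / 0.4) and coders scale the
population gain by a per-neuron multiplier U(0.5, 1.5). With all gains zero
the generator is condition-blind, which is the configuration used for
chance-level checks. The learning gate is a hard trial-index threshold, not
coupled to the agent's actual learning — this makes the late-block onset of
delay coding a controllable ground truth.

What the generator does **not** emulate: trial-to-trial gain correlations or
shared noise (pseudo-populations destroy them anyway), individual-subject
differences, eye movements, non-Poisson spiking statistics, drift or
non-stationarity across a session. Tests passing on this generator therefore
demonstrate that the analysis chain recovers the statistical structure it is
designed for, not that real cortical data contain that structure.

## Pseudo-population decoding

Neurons recorded in different sessions are combined by drawing, per neuron
and condition, the same number of trials (default 60; 25 for stay/switch
decoding; eligibility requires at least that many trials per condition) and
stacking the draws as pseudo-simultaneous columns. Sampling is without
replacement within a resample and independent across resamples. Folds
(default k = 10) are stratified by condition so every fold has equal label
counts and the chance level is unbiased. Per fold, each neuron is z-scored
with the mean and SD of its *training* columns only; a zero-variance neuron
maps to 0 rather than being dropped, keeping the population size fixed. The
classifier is a linear SVM with C = 1 (one-vs-rest by default, one-vs-one
available); the per-bin accuracy is the fold average, averaged over 50
resamples (configurable), with the resample SD retained as the spread.

**Null model and significance.** The whole procedure is repeated
`n_shuffles` (default 20) times with condition labels permuted within each
assembled sample; per shuffle and bin the resample-averaged accuracy is
kept, and all `n_shuffles × n_bins` values are pooled into one null
distribution (a per-bin mode is available through slicing, but the pooled
form is the default). The observed accuracy is z-scored against the pool.
Two one-sided p-values are computed: the normal upper tail of the z-score,
and the empirical exceedance `(1 + #{null ≥ obs})/(1 + N)`. The
*significance decision* uses the normal-tail p by construction: the
Bonferroni-corrected alpha `0.05/(n_bins · n_shuffles)` is strictly smaller
than the empirical p-value's resolution `1/(1 + n_bins · n_shuffles)`, so an
empirical criterion could never fire at any signal strength. Both values are
reported so the choice is auditable. Significant bins must form runs of at
least five consecutive bins.

**Sliding trial windows.** To track learning within a block, window *w*
pools trials with within-block index in `[w, w+9]` across blocks (21 windows
for 30-trial blocks at step 1) and the full decode-plus-null procedure runs
per window with 20 trials per condition (the eligibility minimum per
window). The Bonferroni alpha and consecutive-bin rule apply along the time
axis of each window.

**Balanced two-variable decoding.** Reward (small vs medium+large) and
action (stay vs switch) labels are correlated in behavior. For each neuron
with at least 10 trials in every cell of the 2×2 cross-table, the same
number of trials is drawn from each cell, so within either variable's
classes the other variable is exactly balanced and cannot carry information.
Each variable is decoded in a chosen bin (default the 200 ms window
800–1000 ms after scene onset) with 10 stratified 70/30 train/test splits
per resample — the natural reading of "a 70–30 split with tenfold
cross-validation", which cannot be a single standard k-fold — averaged over
resamples. Significance is the exceedance p against 25 label shuffles,
`p = (1 + #{null ≥ obs})/26`, with conventional stars.

## Discriminant projections and the overlap index

Per bin and resample, 60 trials per condition are drawn per neuron and
leave-one-out folds hold out one trial of every condition. Training means
per condition are z-scored with statistics computed from the *small and
large training trials only* (so the normalization is blind to the medium
condition being tested for its position); the coding direction is
`mean(large) − mean(small)`, unnormalized; the held-out population vector of
each condition is projected by dot product, and projections are averaged
over folds. Collected over 100 resamples this gives a projection
distribution per condition per bin. Pairs are compared with the overlap
index: Gaussian-kernel densities (Silverman bandwidth) on one shared
512-point grid, overlap = ∫ min(f̂_A, f̂_B). The index is symmetric and in
[0, 1]; zero-variance samples degenerate to a point-mass rule (1 if equal,
else 0, with a warning). A pair is "different" in a bin when overlap < 0.05,
sustained over at least five consecutive bins.

**Limitation worth knowing.** If a neuron's per-condition trial pool equals
the number of trials drawn per resample, every resample contains the same
trials and the leave-one-out-averaged projection is deterministic — the
projection "distribution" collapses to a point and any pair of conditions
looks separated. Resampling is only meaningful when pools exceed the draw;
the synthetic sessions used in the tests keep pools at roughly twice the
sample (e.g. 20 blocks for 60 trials per condition). The same caveat applies
to real neurons recorded for exactly the eligibility minimum.

## Per-neuron models

**Variance partitioning.** For each neuron and epoch, ordinary least squares
fits `rate ~ RT_mov + size + RT_mov:size`, where RT_mov is the
reaction–movement time (go-signal to target touch, ms). Sequential (Type I)
sums of squares are used with the motor covariate entered *first*, so reward
size is only credited variance beyond what the motor term explains —
conservative for the claim that reward size dominates; Type II is available.
Formula-level ANOVA in statsmodels always orders categorical terms first, so
the sequential partition is computed from explicit nested OLS fits.
Percentages are term SS over total SS; the full-vs-null comparison is the
model F-test. Constant rates or a degenerate design are flagged rank-
deficient rather than raising.

**Feedback-property ANOVA.** One-way ANOVA of feedback-window rates
(default feedback onset to +400 ms) across levels of a feedback stimulus
property, separately in correct and incorrect trials; the summary is the
fraction of neurons with p < 0.05, which should sit at the nominal 5% rate
when the population is property-blind.

## Behavioral statistics

Exact one-sided binomial tests against the 0.5 chance level per (run, size);
2×2 chi-square without continuity correction between proportions (Yates
available via flag); two-sided two-sample KS tests on reaction times
(asymptotic p, exact when both samples are below 50); switch proportions per
(run 2–6, size) under three outcome filters (all, after-correct,
after-incorrect) that partition the trials; and a per-day aggregation
variant that evaluates any statistic per session and averages the
per-session values unweighted.

## Problem sizes and reproducibility

Everything stochastic takes an explicit seed (numpy `SeedSequence` spawning
for independent stages) and fixed seeds give byte-identical outputs,
including the pipeline's CSV files. The test and recovery suites run the
full algorithms at reduced problem sizes chosen once: recovery sessions use
12–20 blocks and 20–80 neurons; sliding-window recovery uses 20 resamples,
5 shuffles × 5 null resamples, k = 5, and 12 time bins per epoch (delay
200–1000 ms, feedback −100 to +700 ms, step 50 ms — spans bracketing the
generator's coding windows); geometry recovery uses the full 100 resamples
and 60 trials per condition. Full-scale defaults (63 bins, 50 resamples,
20 shuffles, k = 10, 160 neurons) remain the package defaults and are what
the pipeline config documents.
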