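# Methods

## Model

The package implements an additive, factor-based sequential model of
action switching. A task is a stream of discrete time bins (a game turn, a
5-second telemetry window, a text clause); each bin carries the action in
force, optionally a performance score in [0, 1], and a nonnegative
environmental-change magnitude supplied by the task coding. The model
emits, per bin, the probability that the person switches away from their
current action, as the sum of the factor contributions that are active at
that moment, clamped to [0, 1].

Two factors describe the structure of the unfolding events. *Environmental
change* enters directly as the coded magnitude of recent situational
change (for text and game material, 0.1 per changed dimension — new
entities, time, location, goals; configurable via `env_increment`). *Time
on task*, `1 − 1.001^−(A+1)` with `A` the cumulative trial count, is a
slow-moving power function expressing that the longer a task has been
underway, the more likely an eventual change.

Five factors describe the person's running experience. *Just shifted*,
`−0.01·R^−(R+1)` for `R` bins since the last shift, is a fast-decaying
inhibition that gives a freshly adopted action a chance to work; it is
gated out whenever an environmental change is present, which is taken to
drive the behaviour instead. *Number of shifts*, `1.001^−S − 1`, is a
slowly accumulating inhibition. *Performance dip*, `1 − 1.1^−(C+1)`, reacts
to a recent score decrease of magnitude `C`; *bad shift* duplicates the dip
term when the dip immediately followed a shift (an additive copy, i.e. a
doubling of the dip's effect). *Flexibility* is a per-person running bias
updated by a delta rule from the previous bin's prediction error,
`F ← F + 0.1·(H₋₁ − P(H)₋₁)`.

Assumptions worth making explicit: trials within a task share one
cumulative experience (shift and trial counts and flexibility carry across
a participant's conditions unless `reset_between_conditions` is set); the
model predicts only *whether* a switch occurs, never which action follows;
and the constants are fixed properties of the model, identical across
tasks, not fitted quantities.

## Sequencing and edge conventions

Within a bin the order is: detect the shift (action differs from the
previous bin's; the stream's first bin scores 0), apply the flexibility
update from the previous bin's `(H, P)`, assemble factors from the pre-bin
state plus the current environmental change, emit the clamped sum, then
commit the observation. The first bin of every stream is forced to
probability zero — with no prior action there is nothing to compare — and
consequently the first effective flexibility update lands at the third bin
(the update entering bin 2 would use the forced zero prediction and a zero
shift). Factor activity is bookkept independently of magnitude: a factor
whose trigger holds counts as active even if its value rounds to zero,
which is what the trace's component count reports.

A dip detected between bins `t−2` and `t−1` contributes at bin `t`. Two
dip-magnitude modes exist. The default, `raw_decrease`, takes `C` as the
lag-1 score drop whenever positive; it is the behaviour the bundled
reference trace exhibits and therefore the default. The alternative,
`normalized_window`, takes `C = (S_min − S_{t−1}) / (S_max − S_min)` over
the up-to-10 scores preceding the previous one and activates only when the
previous score falls below the recent minimum; the two modes genuinely
disagree (the normalized form is inactive whenever the previous score sits
inside the recent range), so both are provided and the choice is a config
switch rather than a silent correction. Streams without scores (reading,
segmentation) simply never activate the dip or bad-shift factors.

## Print-precision convention

The reference trace bundled in `fluidevents.datasets` prints every value
to four decimals, and its prediction column is consistent with summing the
*rounded* factor cells rather than the full-precision ones (three of its
rows differ from the full-precision sum by more than 1e-4, none from the
rounded sum by more than 1e-4). The model therefore computes in full
precision throughout, and `printed_trace` reproduces the print convention:
factors rounded half-up to four decimals, prediction recomputed as the
clamped, rounded sum. Comparisons against printed values are made on that
view at ±0.0001; all downstream analysis uses full precision.

## Synthetic cohorts

The generator emulates the statistical shape of behavioural streams, not
their semantics. Scores follow a reflected ±0.1 random walk on [0, 1]
starting at 0.5, matching the granularity of the reference trace's score
column. Environmental change is drawn from a band mixture with the pooled
proportions observed across tasks: 38% of bins in (0, 0.1), 10% in
(0.4, 0.5), 1% above 0.6 (upper edge set to 0.8, a choice — only "greater
than 0.6" is specified), the remaining 51% exactly zero, uniform within
bands. Switch decisions come from a policy: `model_driven` (the default)
draws each switch as Bernoulli with the model's own prediction, starting
from flexibility 0 (the model's stated initialization for a person with no
prior task experience); `bernoulli(rate)` reproduces a fixed empirical
switch rate (0.39 is the pooled mean rate across the original tasks);
`calibration` cycles explicit known probabilities. A switch draws a
uniformly random *different* action. Cohorts derive per-participant seeds
from the master seed via `numpy` seed sequences, so a cohort is a pure
function of its parameters.

Model-driven data are perfectly calibrated by construction (the realized
switch is a draw from the predicted probability), which makes them the
strongest available ground truth for the evaluation pipeline: calibration
slope must approach 1, the summed predictor must dominate a trial-number
null, and permuting outcomes must destroy the correlation. What such data
cannot show is how the model fares on behaviour it did not generate —
real data violate the model's independence and stationarity idealizations
in ways the walk-plus-mixture generator does not represent — so passing
these tests validates the implementation and the pipeline, not the
psychological adequacy of the model. Note also that the model's own
closed-loop dynamics settle into higher switch rates (≈0.5) than the
original behavioural mean of 0.39; the delta rule has fixed points where
prediction matches behaviour, including saturated ones.

## Evaluation pipeline

The summed prediction is scored directly by point-biserial correlation
(identically Pearson on the 0/1 coding) with a seeded permuted baseline,
and by an 11-bin calibration table: bin k (k = 0…10) collects predictions
in [k/10 − 0.05, k/10 + 0.05), so the edge bins are half-width by
construction; a least-squares line is fitted to (bin centre, observed
rate) over non-empty bins and left undefined, with a note, when fewer than
two bins are occupied.

Five logistic variants regress the realized switch on different feature
sets: trial number only (null), the summed prediction (sum), all factors
individually (individual; the bad-shift duplicate is kept as its own
feature by default, with a config option to fold it into the dip), the two
event-structure factors, and the four experience factors. Fits are
unpenalized maximum likelihood with an intercept (Newton, tolerance 1e-8,
at most 100 iterations); separation or non-convergence raises a reported
error, and in cross-validation such folds are skipped with a warning
rather than silently dropped. Leave-one-participant-out cross-validation
holds each participant out once and pools all held-out predictions before
computing metrics (pooled, not averaged per fold). Accuracy is summarized
by ROC AUC (rank probability, ties half-weighted), precision and recall
from the 2×2 table at an inclusive 0.5 threshold, and the Pearson
correlation across participants between predicted-switch rate and observed
switch rate. Any metric undefined on its inputs (single outcome class, no
predicted switches, zero variance) is reported as missing with its reason.

## Problem sizes and numerical choices

The regression surface is the 20-bin reference trace (full factor-level
agreement at ±0.0001). Distributional generator checks use 10,000-bin
streams; the calibration-slope and correlation properties use a
model-driven cohort of 20 participants × 5,000 bins (100,000 bins), and
cross-validated variant comparisons use 10 × 400; these sizes give the
stochastic assertions comfortable margins while keeping the suite quick.
Closed-form factor implementations are checked against direct evaluation
of their power-function definitions at 10⁶ random arguments (tolerance
1e-12). Rounding for printed comparisons is half-up (away from zero on
ties), matching the reference table's printing; internal arithmetic is
IEEE double throughout, and factor sums use compensated summation.

## Known limitations

The generator's scores are a symmetric walk and its environmental changes
are i.i.d.; real tasks have autocorrelated difficulty and event structure.
The model's constants are taken as given — no fitting, no per-task
adjustment — so systematic miscalibration on real data is expected and is
precisely what the logistic refit (individual variant) measures. Reading
regime changes between any two categories count as one shift (fast→slow is
not decomposed through normal). How a participant's initial flexibility
should be seeded when a record begins mid-experience is task knowledge the
caller must supply (`initial_flexibility`), as in the bundled demo.
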