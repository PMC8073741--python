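# Methods

## Problem and scope

Penned beef cattle wearing tri-axial accelerometers (neck-collar and
ear-tag, 25 Hz, values in g) perform four mutually exclusive behaviours —
licking a mineral block, eating, standing, lying — annotated from video as
timestamped events during a daily 10:00–16:00 observation window. The
package turns raw traces plus annotations into per-epoch movement features,
trains four classifiers over three ethogram granularities, and evaluates
them with confusion-matrix metrics. Because no public recording of such a
study exists, a synthetic generator reproduces the statistical structure
the analysis relies on; the generator is first-class, tested code.

## Signal model of the generator

For each behaviour × deployment a regime defines

    a(t) = m + j  +  v·A ⊙ sin(2πft + φ)  +  ε(t),   ε ~ N(0, diag(σ²))

with static gravity orientation `m` (3-vector, g), oscillation amplitude
`A` and frequency `f` (head/jaw movement), and per-axis noise SD `σ`. Per
event, one random phase vector `φ`, one posture offset `j ~ N(0, 0.05² I)`
and one vigour factor `v = 1 + N(0, 0.15²)` are drawn: animals do not
repeat a posture identically between bouts, and this bout-level variability
is what makes neighbouring classes genuinely overlap. Eating alternates two
static orientations (head-down biting / head-up chewing, 5 s substate
period), mirroring its two-posture definition and creating the
licking↔eating confusion channel. Transitions between events are abrupt; no
gradual posture change is modelled (a known generator limitation).

Schedules draw behaviours i.i.d. from a categorical distribution (default
uniform over the four behaviours) with uniform durations per regime
(licking 20–180 s, others 30–240 s), tiling the observation window; the
final event is truncated at the window end.

### Calibration

Default regimes target the movement-variation levels observed on penned
cattle — collar: eating ≈ 0.20, licking ≈ 0.18, lying ≈ 0.04,
standing ≈ 0.03 g; ear-tag: 0.30 / 0.17 / 0.09 / 0.07 g — as soft targets
only. Because oscillation and noise do not add linearly in a mean absolute
first difference, realised epoch means sit somewhat below the naive sum
(e.g. collar licking ≈ 0.13 g); only the ordering
eating > licking ≫ lying ≥ standing is asserted anywhere, and it holds
robustly for both deployments. Head-down classes (licking, eating) keep
their static X component at least 3 noise SDs away from head-up classes
(standing, lying), so AVG_X separates head position. Ear-tag regimes are
noisier throughout (looser attachment, independent ear movement).

### What the generator does not emulate

Drift, temperature effects, sensor saturation, ear-flick transients,
rumination sub-structure, inter-animal variability beyond the per-event
jitter, and diurnal behaviour patterns. Synthetic classes are therefore
cleaner than real ones: the random forest reaches ~100 % test accuracy on
default studies, whereas real deployments reported 87–98 %. Passing the
pipeline acceptance thresholds (≥ 85–90 %) demonstrates that the plumbing —
labelling, epoching, features, splitting, training, evaluation — preserves
class signal; it says nothing about field accuracy. A further caveat shared
with the original pooled design: epochs from the same bout can land in both
train and test, so pooled test accuracy is optimistic relative to
animal-wise or bout-wise hold-out (`synthio.scaled_regimes` therefore
switches per-event jitter off when probing pure class separability).

## Trace handling

Timestamps are naive local time; clock synchronisation between sensor and
annotator is assumed done upstream. Windows and event intervals are
half-open `[start, end)`, which makes trimming and labelling commute and
prevents double-labelling at abutting events. Events shorter than 10 s are
discarded, boundary inclusive — an event of exactly 10 s yields exactly one
epoch, consistent with the rule's purpose of keeping one behaviour per
epoch. Samples outside every event are tagged `unlabelled` and excluded
downstream rather than erroring (sensors record continuously; only
annotated periods are analysed). Timestamp jitter below half a sample
period is tolerated; gaps above 1.5 sample periods split an epoching run so
a dropout cannot smear across a window.

## Features

Epoch windows restart at each annotated-event boundary (not a wall-clock
grid), guaranteeing single-label epochs; trailing partial windows are
discarded. Numerical conventions, chosen where the common typeset
definitions are ambiguous:

* Magnitude = mean Euclidean norm; energy = mean squared norm by default
  (`energy_mode="squared_norm_sq"` gives the alternative mean
  squared-squared-norm reading).
* Per-axis SD uses the sample divisor (n−1); at n = 250 the difference from
  the population divisor is < 0.3 %.
* Entropy terms with 1 + (x+y+z) = 0 contribute 0 (the t·ln t limit) and
  are logged as degenerate.
* Angles are computed per sample, then averaged. Pitch uses
  `atan2(−x, √(y²+z²))`, defined (±90°) when y = z = 0; inclination uses
  `atan2(√(x²+y²), z)` so z ≤ 0 maps into [90°, 180°] instead of dividing
  by zero; an all-zero sample contributes 0° to all angles.
* Epochs with any non-finite sample are dropped and logged.

Every feature is validated against an independent loop-based reference
implementation to 1e-9 relative tolerance, plus closed-form cases.

## Classification

Animals are pooled before the split, as in the original study design. The
70/30 split is stratified per class with train size `floor(0.7·n + 0.5)`.
Feature ranking uses random-forest mean-decrease-in-impurity importances
(ntree = 500, mtry = 5); these are normalised to sum to one, unlike R's
unnormalised MeanDecreaseGini, which is immaterial since only the ordering
is used (ties break by canonical feature order). The ranking forest and the
RF classifier are fitted separately with the same settings.

Tuning grids (10-fold stratified CV, accuracy scoring):

| model | inputs | tuned |
| --- | --- | --- |
| DT (CART) | top-3 features, raw | cost-complexity α ∈ {0, 1e-4, 5e-4, 1e-3, 5e-3, 1e-2} |
| RF | all 20, raw | none (ntree = 500, mtry = 5 fixed) |
| kNN | top-3, standardised | k ∈ {3, 5, …, 15}, Euclidean |
| SVM (RBF, one-vs-one) | all 20, standardised | C ∈ {1, 10, 100}, γ ∈ {scale, 0.01, 0.1} |

Standardisation uses training-set statistics only. All estimators are
seeded; identical configuration and seed give byte-identical feature
tables, rankings, predictions and reports.

## Evaluation

Confusion matrices store predicted classes as rows and observed classes as
columns. Multi-class overall accuracy is trace/total — the only reading of
the two-class `(TP+TN)/(TP+TN+FP+FN)` formula consistent with the reference
matrices (e.g. 656/710 = 92.4 %). Per-class metrics with an empty row or
column are reported as undefined (`None`), never as 0, to avoid silently
deflating averages. Kappa is the standard unweighted form from the matrix
margins; it reproduces every reference kappa, so no weighted variant is
considered. Display rounding is one decimal, half away from zero; the
embedded reference tables additionally round the proportion to four
decimals before converting to percent (`reference.printed_percent`), a
convention recovered from the tables themselves — four reported values
differ from single-step rounding by exactly this mechanism.

Band boundaries interpret the printed integer ranges as [90, 100],
[80, 90), [70, 80), [0, 70) for accuracy-like percentages, and for kappa:
≤ 0.20 none, < 0.40 minimal, < 0.60 weak, < 0.80 moderate, ≤ 0.90 strong,
> 0.90 almost perfect.

## Problem sizes

The acceptance script and acceptance tests run the default study — 4
animals × 1 day × 6 h at 25 Hz (≈ 540,000 samples per trace, ≈ 8,400 epochs
per deployment) — the condition under which the pipeline properties are
stated. Unit and property tests use 10–45 minute windows with 1–2 animals,
which already give every behaviour dozens to hundreds of epochs.

## Known limitations

* Sinusoid-plus-noise signals, not recorded-waveform replay: realistic at
  the feature level, not the waveform level.
* Abrupt behaviour transitions; no transition epochs exist.
* No animal-wise hold-out (pooled split replicates the original design and
  inflates accuracy estimates).
* The exact tuning grids of the original analysis are unknown; the grids
  above are reasonable defaults, not a reconstruction.
* `.cwa` binary sensor files are out of scope; the pipeline consumes CSV.
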