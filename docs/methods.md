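# Methods

## Windowing and labeling

A recording is a `[n_channels × n_samples]` matrix in µV with seizure
onsets in seconds. The labeling scheme is driven by four parameters
(`WindowingConfig`):

| parameter | default | meaning |
|---|---|---|
| `sph_minutes` | 10 | seizure prediction horizon: the pre-ictal period before each onset |
| `window_seconds` | 2.8 | analysis-window length, both classes |
| `postictal_minutes` | 30 | time after an onset excluded from "normal" |
| `max_normal_to_preictal_ratio` | 10 | cap on class imbalance |

Decisions where the scheme left room:

- **Window length in samples** is `round(window_seconds × fs)`; at 256 Hz,
  2.8 s is 716.8 samples and is rounded to 717. Deterministic and
  configurable.
- **Pre-ictal tiling** anchors at the onset and tiles backward without
  overlap, discarding the fractional leftover at the far end of the
  horizon: the window adjacent to onset is the clinically critical one.
  The onset sample is `floor(onset × fs)`, so windows never extend past
  the onset. Horizons are truncated at the recording start and at the
  previous seizure's post-ictal boundary rather than dropping the seizure.
- **Normal sampling** draws the window start uniformly among admissible
  integer sample positions within each complete clock hour — positions
  whose window fits in the hour and touches no
  `[onset − SPH, onset + post-ictal]` zone. Hours with no admissible
  position contribute nothing. A `per_hour` parameter (default 1, the
  clinical rule) densifies sampling for short synthetic recordings;
  windows drawn within one hour are sampled independently and may overlap.
- **Chronological split**: the earliest `n_train` seizures (and their
  pre-ictal windows) train, the rest test. Normal windows split by time at
  the start of the first test seizure's horizon, so training data strictly
  precedes the test period; the 10:1 cap is re-applied per partition.
  Consequence: a recording whose normal windows all precede that boundary
  yields a test set with no normal windows, and specificity is then
  undefined (reported as NaN, see below).

Times are seconds from recording start; sample indices are 0-based with
half-open intervals.

## Permutation entropy

For embedding dimension `m` (default 3) and delay `tau` (default 1), every
overlapping delay vector is mapped to the permutation sorting it ascending,
ties broken by order of appearance (stable ranking — the standard
convention for sampled data, and deterministic). Entropy is Shannon
entropy in base 2 over the empirical pattern distribution, with the
`0·log 0 := 0` convention and probabilities computed over observed vectors
(`n − (m−1)·tau` of them). `normalize=True` (default) divides by
`log2(m!)` so values lie in [0, 1] and iid noise reads ≈ 1.

`m = 3, tau = 1` keeps the pattern space (6 patterns) well covered by a
717-sample window (> 100 vectors per pattern) — larger orders would need
longer windows than the 2.8-s scheme provides. A warning is emitted when a
series covers the pattern space less than 10× over.

Since patterns depend only on ranks, PE is exactly invariant under strictly
monotone transforms; the test suite asserts this bit-for-bit.

## Synthetic generator

`SyntheticCohortSpec` defines one synthetic patient. Background on every
channel is iid Gaussian noise (sd 15 µV, a realistic scalp amplitude).
During each `[onset − SPH, onset)` interval, the designated informative
channels become `x = (1−λ)·noise + λ·regular`, where λ is
`preictal_regularity` and the regular component is a sinusoid whose
instantaneous frequency performs a slow reflected random walk in 3–12 Hz,
scaled to the noise RMS. Onsets sit at 3/4 of equal blocks of the
recording, which guarantees spacing greater than SPH + post-ictal and a
full horizon before the first onset; infeasible requests raise.

What the generator does and does not emulate: it reproduces exactly the
statistical contract the selector assumes — an ordinal-regularity drop on
informative channels during the SPH, statistically identical classes on all
other channels — and nothing else. No 1/f spectrum, artifacts, electrode
drift, or sleep-stage structure. Passing recovery tests therefore shows the
pipeline finds channels that carry ordinal pre-ictal structure; it does not
show that clinical pre-ictal EEG has such structure.

An interaction worth noting: per-window PE of the mixture at λ = 0.8 drops
only ~0.02–0.03 below the noise ceiling (at 256 Hz the sample-to-sample
noise increments still dominate local ordering), but window-level PE spread
is ~0.001, so planted channels are strongly separable while feature
*standardization* (below) keeps the 20 noise channels genuinely harmful to
the classifier — which is what gives the selection problem its gradient.

## Channel selection (KNN-GA)

Chromosomes are binary channel masks with ≥ 1 gene on; invalid offspring
are repaired by switching on one uniformly chosen gene. Defaults:
population 20, ≤ 30 generations, uniform crossover with probability 1.0,
per-gene mutation 0.01, reproductive fraction 0.9 (90% of each new
generation is bred by fitness-proportionate parent selection and
crossover; the rest is copied from the current fittest, subsuming
elitism ≥ 1), convergence after 5 generations without best-fitness
improvement (within 1e−12). The best-ever chromosome is returned, so the
reported history is non-decreasing. An optional restarts mode
(`select-channels --restarts`) runs independent searches and keeps the
best.

Fitness is stratified 5-fold CV accuracy of KNN (k = 5, Euclidean) on the
masked feature columns — not training-set accuracy, which is degenerately
1.0 at k = 1. Features are standardized per fold with training-fold
statistics. KNN tie rules are fixed so every prediction is reproducible:
equal distances rank by training index; tied votes go to the nearest
neighbor's class. Initial chromosomes set each gene on with probability ½.
All randomness flows from one seeded generator recorded in the result.

## SVM validation

Features (selected columns or all) are standardized with training-set
statistics; the transform is part of the fitted model. Variants:

- `lm`: one RBF dual solve at C = 1, γ = 1/n_features;
- `evolutionary`: differential evolution (rand/1/bin, 6×2-D population,
  F = 0.8, CR = 0.9) over log2 C ∈ [−5, 15], log2 γ ∈ [−15, 3], 30
  candidate evaluations;
- `pso`: particle swarm (6 particles, inertia 0.7, cognitive/social 1.5)
  over the same space and budget.

Candidates are scored by stratified 5-fold CV accuracy on the training
partition, and the adopted variant is likewise chosen on training CV —
never on test performance, which would leak. The paired selected-vs-all
comparison reuses bit-identical windows and seeds.

Metrics follow the four confusion quadrants (I pre-ictal hits, II false
alarms, III misses, IV true normals): accuracy (I+IV)/total, sensitivity
I/(I+III), specificity IV/(II+IV), each ×100. A zero denominator yields
NaN, never 0: a printed 0.00 sensitivity means every pre-ictal window was
missed, not that none existed. The event-level prediction rate flags a
seizure as predicted when ≥ 1 of its SPH windows is classified pre-ictal
(the most permissive consistent rule); per-seizure flags are stored so the
stricter majority rule can be recomputed, and `--event-rule` exposes both.

## Cohort statistics

`summarize` reports N, sum, mean and *sample* SD (n−1) — the sample form
is what reproduces the reference table's printed SDs (population SD gives
15.01 where 15.36 is printed for selected-channel accuracy).
`rm_anova_paired` is a two-condition repeated-measures ANOVA with patient
as the blocking factor (statsmodels `AnovaRM`); with two conditions its F
on (1, n−1) df equals the squared paired t, asserted to 1e−9 against an
independent scipy implementation. An independent one-way ANOVA would give
F ≈ 1.96 on the reference accuracy columns instead of the reproduced
11.5588, which is why the repeated-measures reading is adopted. Identical
conditions return F = 0, p = 1 by convention (the ratio is otherwise 0/0).

The shipped reference table has 22 patients (two excluded upstream as
unusable recordings). One patient's selection includes "CP2-Ref", a
reference-derivation channel outside the 23-channel bipolar montage; it is
carried as a labeled extra and excluded from per-index frequency counts.
The table's own prediction-rate columns average 91.51% (selected) and
72.65% (all channels); the summary stage reports these recomputed means.

## Benchmark and problem sizes

The standard benchmark (`eegselect.benchmark`) is one synthetic patient:
23 channels, 256 Hz, 4 h, 4 seizures, informative channels {4, 7, 16},
regularity 0.8, normal sampling densified to 110 windows/hour, 2 training
seizures. The genetic search consumes a balanced 200-windows-per-class
training subset; validation uses the full train/test partitions
(758/538 windows). Ten seeded searches and ten paired validations
constitute the recovery and end-to-end-benefit experiments run by the test
suite and `scripts/acceptance.py`. A 200-per-class *normal* sample under
the strict one-per-hour rule would require a multi-hundred-hour recording;
densified sampling preserves the class-conditional window distributions
while keeping recordings simulable.

## EDF handling

Reading uses MNE (EDF/EDF+ headers, scaling, annotation parsing), with
channels reordered to the requested montage; labels are matched case- and
whitespace-insensitively, and duplicate montage labels (the standard
23-channel bipolar montage repeats T8-P8) are matched to distinct file
channels in order, accommodating MNE's `-0`/`-1` de-duplication renames.
Writing is a minimal in-package 16-bit EDF writer (uniform rate, single
physical range, 1-s records) used to export synthetic recordings and for
round-trip tests; quantization error at the default ±1000 µV range is
< 0.02 µV. Seizure onsets travel in a JSON sidecar, not inside the EDF.

## Known limitations

- The generator's noise is white; PE of real EEG background sits well
  below 1 and varies with vigilance state, so absolute PE levels here are
  optimistic even though the *contrast* mechanism is the same.
- Fitness-proportionate selection degenerates when all fitnesses are equal
  (uniform fallback, logged); accuracy-valued fitness keeps the scale in
  [0, 1] by construction.
- The SVM optimizer searches are tiny fixed-budget metaheuristics; they
  are not tuned global optimizers, and on easy problems all variants tie.
- `chronological_split` can produce a test partition without normal
  windows on short recordings (see above); callers wanting balanced test
  sets should densify normal sampling or extend the recording.
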