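# Methods

## Clinical setting and outcome definition

The package models 1-year outcome of pallidal deep brain stimulation (DBS)
in children with dystonia from six pre-surgical features: sex, etiology
(six groups: isolated genetic, complex genetic, and four acquired groups —
cerebral palsy, metabolic, other, degenerative), baseline severity on the
BFMDRS-m motor scale (0–120, higher = more severe), cranial MRI class, and
two neurophysiological statuses, CMCT and SEP.

CMCT/SEP are recorded per limb (≤4 limbs). Patient-level coding is binary:
*abnormal* if at least one limb is abnormal, *NA* if no limb produced a
technically satisfactory recording, *normal* otherwise. A child with some
untestable limbs but no abnormal tested limb is coded normal — the coding
rule triggers only on positive evidence of abnormality, and NA is reserved
for the absence of any usable recording. NA is carried as an ordinary
categorical level into the feature-subset search (it is informative: it
encodes that the test could not be completed), but records with NA are
excluded from the fixed-tree Monte Carlo analysis, which requires a
definite CMCT status.

Outcome is percentage improvement, `100·(baseline − followup)/baseline`,
positive = dystonia reduction. `baseline = 0` raises an error rather than
returning 0%: the ratio is undefined and a zero baseline is clinically
implausible in a DBS candidate. Binarization supports two comparison modes,
matching the two conventions in use: strict `> t` for the any-improvement
analyses and the 0–5% robustness sweep, and `≥ t` for the literature's 20%
cut-off. A COPM change of ≥ 2 points is the alternative,
occupational-performance outcome binarization.

## Tree induction

Plain greedy binary CART. Splits maximize weighted impurity decrease (Gini
by default; entropy available); continuous candidate thresholds are the
midpoints between consecutive distinct sorted values, with `value ≤
threshold` routed left; categorical splits enumerate all 2^(m−1) − 1 binary
partitions of the levels present at the node (m ≤ 6 here, so enumeration is
exact and cheap) — no numeric re-encoding of categories anywhere. A split
is admissible only if both children retain `min_leaf` rows (default 10, the
end-node constraint used throughout the search); induction stops on purity,
size, the optional depth limit, or when no admissible split has strictly
positive gain.

Determinism: among equal-gain candidates (equality at 1e-12) the learner
prefers the lowest schema feature index, then the lowest threshold, then the
lexicographically smallest left-level set (each categorical partition is
canonically oriented so its lexicographically smaller side is the left
child). Leaf-label ties go to the unfavorable class — a deliberately
conservative prognosis, configurable via `TreeParams.tie_label`. At predict
time, a categorical level outside the schema routes with the majority child
and emits a warning, so prediction is total.

Requiring strictly positive gain means a perfectly balanced XOR pattern
stops at the root (every marginal split has zero gain); any asymmetry in the
cell counts restores a positive first-split gain and the interaction is then
captured exactly at depth 2. Hyperparameters are fixed defaults
(`min_leaf = 10`) rather than searched; an inner-CV grid over
`min_leaf ∈ {5, 10, 20}` and `max_depth ∈ {1, 2, 3, ∞}` can be run by the
caller but is not part of any reported analysis, keeping every result
exactly reproducible from one seed.

## Feature-subset search and cross-validation

All 2^k − 1 non-empty subsets (63 for the six features; 31 with CMCT
removed) are enumerated in binary-counter order over the schema. Each is
scored by repeated k-fold cross-validation: per iteration, an *unstratified*
uniform random partition into k near-equal folds (a stratified option
exists but is off by default, matching the plain random-allocation design);
per fold, a tree is fit on the other k − 1 folds and evaluated on the
held-out fold. The iteration's accuracy pools correct predictions across
folds (correct/n) rather than averaging fold accuracies — insensitive to
unequal fold sizes; fold-mean aggregation is available as an option. The
subset's score is the mean and standard error (sd/√iterations) over
iterations (default 100 iterations, k = 10).

Per-subset seeds derive deterministically from (master seed, subset index)
via `numpy` `SeedSequence`, so subsets are comparable across runs and the
whole search reproduces bit-identically. Ranking is by mean accuracy, ties
broken toward fewer features then enumeration order; the report records the
majority-class baseline, the top-10 subsets, and each feature's frequency
among them. A training partition whose labels are single-class (or admits
no positive-gain split) degenerates to a single-leaf majority predictor —
the correct fallback, equal to the majority-class classifier.

The outcome-threshold sweep re-binarizes the same cohort at thresholds
0–5% and reruns the search, reporting class counts and the features
appearing in more than half of the top-10 subsets. A threshold leaving
fewer than `2·min_leaf` members in either class is flagged as performance
degradation and skipped: no admissible first split exists, so every tree
collapses to the baseline.

## Fixed tree, Monte Carlo sweep, and node-1 bounds

The counseling tree is fixed, not learned: abnormal CMCT ⇒ unfavorable;
otherwise favorable iff baseline BFMDRS-m strictly exceeds the cutoff
(equality ⇒ unfavorable; the boundary case is unaddressed in the usual
">80 favorable / <80 less favorable" phrasing, so the strict rule is a
documented convention). The cutoff grid spans floor(min baseline) to
ceil(max baseline) in 0.5 steps.

The sweep draws `n_sample = 100` records uniformly with replacement,
`reps = 1000` times, computing per-rep sensitivity and specificity at every
cutoff. A rep that draws no positives (or no negatives) has that metric
undefined; such reps are excluded from that metric's mean/SE and counted in
a diagnostics field — exclusion avoids arbitrary imputation. Reported error
is ±1 standard error (across-rep sd/√defined-reps). The ROC is the locus of
per-cutoff mean points; no AUC is reported.

Node-1 bounds: `sens_upper = 1 − P(abnormal CMCT | positive)` and
`spec_lower = P(abnormal CMCT | negative)`. These hold exactly within every
resample (the tree can only predict positive for CMCT-normal cases), which
the implementation asserts per rep, and the full-cohort bounds are reported
alongside the sweep.

## Synthetic cohort generator

Real cohorts of this kind are access-restricted, so the generator is a
first-class module emulating the published marginals. Defaults
(the study conditions; `default_params("acquired")`):

| parameter | default | meaning |
|---|---|---|
| n | 96 | acquired-dystonia analysis cohort size |
| etiology_probs | (0, 0, 82/148, 19/148, 35/148, 12/148) | acquired groups, referral-cohort ratios |
| p_cmct_na | 18/96 | CMCT not available |
| p_cmct_abnormal | 0.154 | unconditional; ≈0.19 of the CMCT-available pool |
| p_sep_na, p_sep_abnormal | 42/96, 0.20 | SEP availability/abnormality |
| baseline_mean, baseline_sd | 70, 25 | BFMDRS-m, truncated normal on [5, 120] |
| mu0 | +5 % | mean change, normal CMCT, baseline ≤ s₀ |
| beta_cmct | −25 % | shift for abnormal CMCT |
| beta_sev, s₀ | +0.5 %/point, 80 | hinge severity effect above s₀ |
| noise_sd | 15 % | Gaussian outcome noise |

The outcome model is
`pct = μ₀ + β_cmct·1[abnormal] + β_sev·max(0, baseline − s₀) + N(0, σ²)`.
The hinge plants a recoverable severity threshold for the fixed-tree
machinery; sex and MRI are drawn independently of outcome so the subset
search *should not* select them. A normal-approximation calculation under
these defaults gives ≈61% positive outcomes at the >0% threshold,
P(positive | abnormal CMCT) ≈ 0.17 vs ≈ 0.69 given normal CMCT — abnormal
CMCT rates of roughly 12% among responders and 29% among non-responders,
consistent with the intended node-1 structure. `default_params("full")`
gives a 133-child whole cohort with the referral cohort's etiology mix
(genetic groups included).

Generation details: follow-up BFMDRS-m is derived from the planted % change
and clipped to the scale range [0, 120]; the stored % change is then
recomputed from the clipped score so every record is internally consistent
(this truncates extreme simulated worsenings — a bounded scale cannot
express them). CMCT/SEP statuses are expanded to 4-limb recording lists
that re-code exactly to the drawn status; NA children carry β_cmct = 0
(their true conduction status is unobserved, a simplification). COPM has no
generative model; longitudinal structure beyond 1 year and CMCT–SEP
correlation are not modelled. Passing tests on these cohorts demonstrates
that the *pipeline* recovers planted structure under realistic marginals —
not that any particular feature predicts outcome in real patients, nor that
real effect sizes match the planted ones.

## Problem sizes used in tests and the acceptance script

Unit and property suites run at n = 96–500 with 5–20 CV iterations;
the planted-effect recovery check uses n = 500, 10-fold × 20 iterations;
Monte Carlo checks use the full 1,000 × 100 resampling design on a
~78-record pool. The acceptance script runs the full 63-subset search at
the study's own design point (n = 96, 10-fold × 100 iterations) plus the
1,000-rep sweep. These sizes are the package's chosen reporting conditions;
all are reproducible from a single seed.

## Known limitations

- Accuracy values on real data are not reproducible here: the patient
  dataset is restricted, and the original hyperparameter optimization
  search space is unspecified. Only counting/arithmetic anchors and
  structural properties are reproduction targets.
- Unstratified folds can occasionally produce single-class training
  partitions on small cohorts; the majority-class fallback handles this but
  adds variance at extreme class imbalance (hence the degradation flag).
- The CV standard error measures partition-allocation variability on a
  fixed cohort, not sampling variability of the cohort itself.
- No cost-complexity pruning, surrogate splits, multiclass outcomes,
  ensembles, or decision-curve/utility analysis.
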