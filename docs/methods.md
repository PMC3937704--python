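# Methods

## The analysis problem

In prodromal Huntington disease (prHD), gene-expansion carriers show striatal
atrophy and cortical thinning years before motor diagnosis, and performance
declines across several cognitive domains.  The scientific question this
package operationalizes is *which* regional morphometric measures co-vary
with performance in each domain, given that (a) regional measures are
numerous and strongly inter-correlated, (b) age and sex have nonlinear and
interacting effects on morphometry, and (c) regions may relate to cognition
nonlinearly and jointly.  Ordinary multiple regression handles none of these
well; ensembles of regression trees handle all three, at the cost of needing
a ranking-and-selection protocol instead of coefficients and p-values.

The pipeline has two stages.

### Stage 1 — normative adjustment and atrophy screening

For each region *r*, a random-forest regression of the measure on {age, sex}
is fitted on **controls only**.  Residuals are formed for both groups against
this control-derived norm:

* residual 1 = observed − predicted, controls;
* residual 2 = observed − predicted, cases.

Because in-sample forest predictions are shrunken toward the training
observations, control residuals are predicted **out-of-bag** by default
(`prediction_mode="oob"`); the in-sample mode is retained and demonstrably
biases |residual 1| toward zero (a test asserts this), which would
artificially inflate group differences.  Case predictions always use the full
forest.

Each region is then tested with a one-sided two-sample Wilcoxon rank-sum
test (H1: control residuals stochastically larger, i.e. atrophy), exact by
enumeration when both groups have ≤ 10 tie-free observations, otherwise the
normal approximation with continuity and tie corrections.  The
Benjamini–Hochberg step-up procedure at FDR 0.05 is applied across all
regions (cortical and striatal as one family); survivors form the sMRI
predictor set.

### Stage 2 — importance ranking and parsimonious selection

For one cognitive outcome, a forest is fitted on the screened regions plus
the four covariates {age, sex, education, visit count} (cases only;
covariates adjust for confounding on cognition but never compete in the
ranking).  Variable importance is the **out-of-bag permutation importance**:
for each tree, its OOB observations are predicted before and after permuting
one predictor's values within the OOB set, and the increase in MSE is
averaged over trees (raw units: outcome²; a `scaled` mode divides by the
between-tree standard error).  Since a single forest's ranking is itself
noisy, the whole fit is repeated with fresh bootstrap draws and permutations,
and each sMRI variable's rank (midranks on ties) is averaged over
repetitions.

Model size is chosen by nested top-k curves: for k = 1..m, forests on the
top-k regions (+ covariates) are fitted `n_runs` times and the mean OOB MSE
per k is recorded.  `strict_min` picks the argmin; the default `one_se`
rule picks the smallest k whose mean MSE is within one standard error of the
minimum.  The one-SE rule is a reproducible formalization of the judgment
call of preferring a clearly smaller model whose error is "very close" to
the technical minimum; it can never pick a larger k than `strict_min`.

A final report lists the selected regions in mean-rank order with the
Spearman correlation between each region's morphometry and the outcome:
atrophy semantics imply thinner/smaller ↔ worse performance, i.e. positive
ρ; |ρ| below a threshold (default 0.1) is flagged `indeterminate`, negative
beyond it `inconsistent`.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| trees, ranking/selection forests | 5000 (full) / 300–500 (reduced) | — | full scale matches the emulated analysis; reduced for desk-scale runs |
| ranking repetitions | 1000 (full) / 15–50 (reduced) | — | rank stability |
| selection runs per k | 200 (full) / 10–50 (reduced) | — | curve precision |
| mtry | max(1, ⌊p/3⌋) | predictors | regression-forest default; p counts covariates too |
| min samples per leaf | 5 | subjects | R `randomForest` regression default (`nodesize=5`); leaf size 1 overfits the 2-predictor normative design and inflates residual noise |
| normative trees | 500 (200 in bulk simulations) | — | per-region univariate fit |
| FDR α | 0.05 | — | screening target |
| extrapolation guard | training age range ± 10 | years | warn on normative extrapolation |
| direction threshold | 0.1 | \|ρ\| | below: indeterminate |

Every run records seed, configuration hash and package version; per-repetition
forest seeds derive from `SeedSequence([master, repetition])` and permutation
streams from `SeedSequence([master, repetition, crc32(variable), tree])`, so
results are independent of predictor column order and of the worker count.

## The synthetic cohort generator

There is no public cohort with this structure, so the generator is
first-class, tested code with serialized ground truth.  It emulates:

* two groups (defaults 119 controls / 325 cases), ages uniform 18–75,
  ~65% women, education ~N(14, 2.8²) clipped to [8, 20], visit count ∈ {1, 3};
* 72 regions: 34 Desikan–Killiany cortical parcels per hemisphere
  (thickness, mm) plus bilateral caudate and putamen as volume/ICV ratios
  (ratio scale 0.002 relative to the mm scale);
* age effect: monotone decreasing, mildly quadratic
  (−0.004·(age−40) − 3·10⁻⁵·(age−40)², mm) — a realistic thinning rate;
  sex offset −0.06 mm (male) and a small age×sex interaction (0.0015 mm/yr);
* block-correlated noise: regions within a hemisphere×lobe block share an
  equicorrelation ρ (default 0.4), emulating the strong inter-regional
  correlation that motivates forests over linear regression;
* atrophy: cases lose `atrophy_effect_sd` × noise-SD × severity in a known
  region subset, where severity is gamma(2, 0.5) (mean 1, right-skewed),
  emulating heterogeneous proximity to onset;
* outcomes: five scores driven by a known subset of the atrophied regions
  (weights uniform 0.7–1.0, all positive, so thinner ↔ worse by
  construction) plus small covariate effects, with noise sized so the region
  signal explains `outcome_r2` (default 0.6) of latent variance; linear,
  saturating-nonlinear and interaction outcome models are available.  Count
  scores are rounded and clipped at 0; timing precision is a lognormal-style
  transform, keeping it positive.

Defaults were calibrated once by pilot simulation so that every inference
stage has detectable but not trivial signal (e.g. at the original draft's
age slope of 0.010 mm/yr, shared age variance correlated all regions at
~0.7 and region-specific recovery was impossible; the realistic slope fixes
this).  What the generator does **not** emulate: scanner/site effects,
CAG-length–age interactions, measurement floors/ceilings of real
instruments, missingness mechanisms, longitudinal structure.  Passing tests
therefore demonstrate statistical correctness of the machinery under a
plausible data-generating process, not clinical validity on PREDICT-style
data.

## Numerical and design choices

* **Exact vs asymptotic rank-sum p**: exact enumeration only when both
  n ≤ 10 and no ties; the one-sided p is P(rank sum ≥ observed), the
  standard convention, validated against exhaustive enumeration in tests.
* **Degenerate inputs**: all-identical samples → p = 1 with a warning;
  constant predictors → importance exactly 0 with a warning; all-identical
  intertap intervals → error (precision undefined); empty predictor set
  after screening → pipeline halts with an explanatory status.
* **Ties in mean rank** are broken by higher mean importance, then variable
  name — output order is fully deterministic.
* **OOB bookkeeping**: each tree's OOB set is reconstructed from its stored
  random state (validated against the bootstrap complement in tests); OOB
  MSE for the selection curve is computed over subjects with at least one
  OOB prediction.
* **Missingness**: subjects missing any of {age, sex, education, visit
  count} are excluded with a logged count; outcomes are excluded
  per-analysis.  Mixed training/held-out subject sets are rejected in
  residualization because their residual distributions are incomparable.
* **ANCOVA**: ordinary least squares with sex as an indicator; with one
  two-level factor and continuous covariates the group test is identical
  under Type I/III sums of squares.  The five outcomes are deliberately
  tested without multiplicity correction, mirroring the descriptive use of
  these comparisons.

## Problem sizes used in tests and the acceptance script

Monte-Carlo experiments are sized for a single CPU.  The package's own
choices: FDR-null check 12–16 cohorts (study-scale n, 72 regions, 200-tree
normative stage); screening sensitivity 10–15 cohorts (10 regions atrophied
at 0.5 SD; pilot mean 0.956 ± 0.013 over 25 cohorts); importance recovery
8–12 cohorts at 300 trees × 15 repetitions with the 40 ground-truth
atrophied regions as the predictor set; selection curves at 150 trees × 10
runs, k ≤ 20.  Full-scale settings (5000 trees, 1000 repetitions, 200 runs)
remain available via `RunConfig(scale="full")`.

## Known limitations

* Permutation importance shares credit among correlated predictors; with
  strong block correlation the ranking separates *sets* of correlated
  regions better than individual members (tested: duplicated predictors get
  statistically indistinguishable mean ranks).
* The normative stage assumes controls are a valid norm (no disease signal);
  it does not model site effects.
* The selection curve inherits forest randomness; with few runs the one-SE
  rule is conservative by design.
* `oob_prediction_` requires enough trees that every subject is OOB at least
  once; the pipeline uses ≥ 40 trees everywhere and masks uncovered subjects
  in curve MSEs.
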