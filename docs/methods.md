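# Methods

## The statistic

For a binary screening test with sensitivity SEN and specificity SPE in a
population with disease prevalence *p*, the expected fraction of correct
classifications is

    Accuracy(p) = p · SEN + (1 − p) · SPE.

This is affine in *p*, bounded by [min(SEN, SPE), max(SEN, SPE)], equals
(SEN + SPE)/2 at *p* = ½, and is strictly decreasing in *p* iff SEN < SPE.
The package evaluates it on the observed (questionnaire) prevalence, on a
simulated ladder (default 20/30/40/50%), and on a 1–50% sweep in 1-point
steps — the sweep's low end covers the prevalence range where population
screening actually operates.

## Test construction

FeNO is an integer-ppb biomarker with a device detection floor
(default 5 ppb, typical of electrochemical analysers). The screening test
is the strict-greater rule `value > c` for c ∈ {19, 24, 34}; on integer
data this is identical to ≥20/≥25/≥35, so both labellings of the cutoffs
describe the same rule. Records with a missing measurement are excluded
from each contrast and counted in the log; observed prevalence is computed
from the questionnaire over the full cohort.

Per outcome, the positive group is contrasted against a comparator and the
2×2 table yields SEN = TP/(TP+FN), SPE = TN/(TN+FP), PPV = TP/(TP+FP),
NPV = TN/(TN+FN). A zero denominator yields an explicitly undefined metric
(`None`), which propagates; accuracy rows with undefined SEN or SPE are
dropped rather than half-filled. Metrics live on the [0, 1] scale
throughout; conversion to percent (one decimal, round half away from zero,
with a 1e-9 pre-round absorbing binary floating-point dust) happens once,
at render time.

**Comparator choice.** The default negative class is the *symptom-free*
comparator: children with every panel indicator 0. This is the design the
source tables describe, and it makes SPE identical across outcomes by
construction. The published predictive-value denominators, however, are
only consistent with the *complement of the outcome group* (e.g. ≈410 =
447 − 37 negatives for the asthma contrast, impossible for a symptom-free
group when 234 of 447 children report night cough); passing
`comparator="outcome_complement"` to `run_study` reproduces that reading.
The choice moves PPV/NPV and the AUC subset, not the accuracy formula.

**Structural lint.** Under a strict-greater rule on a single dataset, SEN
is non-increasing and SPE non-decreasing in the cutoff. `run_study` checks
this and warns on violation — the published any-asthma row (SPE 98.5% at
>24 but 94.6% at >34) fails this lint and is treated as a table error, not
a behaviour to emulate.

## Real-prevalence reconciliation

The package computes the real-prevalence accuracy column from the exact
observed proportion (e.g. 37/447). The published column is reproducible
only when each prevalence is first *truncated to a whole percent* (8%, 1%,
52%, 46%, 23%, 3%, 2% for the seven outcomes); with that convention every
published cell agrees to 0.1 points, while exact prevalences differ by up
to ≈0.8 points (cough during the day). `truncate_prevalence_percent`
exposes the convention for reconciliation; the exact computation remains
the default because the truncation discards real information.

## AUC

The reported AUC is the Mann–Whitney rank-concordance statistic with
half-credit for ties — the appropriate estimator for integer ppb scores,
where ties are frequent. It is computed from midranks; the tie-pair count
is reported alongside. The empirical ROC staircase (tied scores move
diagonally in a single step) has trapezoidal area identical to the
concordance statistic, and the suite asserts this identity to 1e-12 on
random tied instances.

The univariate logistic model logit P(y=1) = a + b·FeNO is fitted by
Newton–Raphson IRLS on a centred/scaled covariate (coefficients mapped
back), convergence on log-likelihood change < 1e-8, at most 50 iterations.
Complete or quasi-complete separation is flagged (`separated=True`,
`converged=False`) when the linear predictor exceeds ±30 — beyond which
fitted probabilities are 0/1 to machine precision — rather than returning
divergent coefficients. Because the fitted probability is a strictly
increasing transform of FeNO whenever b > 0, the logistic route and raw
concordance give the same AUC; the suite asserts this invariance, and the
fitter is cross-checked against direct likelihood maximization and
statsmodels to 1e-6.

## Synthetic cohorts

FeNO is modelled per status group as lognormal — the standard family for
exhaled nitric oxide (positive, right-skewed). A two-parameter lognormal
is solved exactly from two exceedance anchors via
ln c_i = μ + σ·Φ⁻¹(1 − p_i); the two extreme cutoffs (>19, >34) are the
anchors and the middle cutoff (>24) is an out-of-sample check. Because
values are rounded to integer ppb, the empirical exceedance of cutoff *c*
equals the continuous survival at *c* + 0.5; calibration targets the
rounded variable through this half-step correction (`rounded=True`), which
removes an ≈1-point bias at these scales. Anchors implying σ > 20 log-ppb
(near-equal exceedances) are rejected as degenerate.

Default study conditions (the generator's fixed defaults, not dials):
cohort n = 447; asthma prevalence 37/447; symptom marginals matching the
published per-outcome counts (night cough 234, day cough 210, rhinitis
106, night dyspnoea 17, day dyspnoea 12). Symptoms are independent
Bernoulli given asthma status. Given asthma, cough and rhinitis rates are
set at their marginal values and dyspnoea mildly enriched (8%/6%); the
wheeze rate given asthma (no published count) is then solved from the
isolated-asthma constraint — asthma with no coexisting symptom — so the
expected isolated count is the published 5 of 447 (giving ≈0.19); wheeze
given no asthma is set to 10%, a plausible childhood rate. Three FeNO
groups are calibrated from the published table: any-asthma children from
the asthma SEN anchors, symptom-free children from 1 − SPE, and the
remaining symptomatic non-asthmatics from the night-cough SEN anchors
(an intermediate inflammation level).

What the generator does *not* emulate: corticosteroid suppression of FeNO,
age/sex/smoke-exposure effects, within-child correlation between symptom
reports beyond shared asthma status, and measurement repeats. Passing
tests therefore demonstrate the *pipeline's* correctness and calibration
consistency, not distributional claims about real cohorts. Notably, the
calibrated group distributions imply a two-group AUC of ≈0.55 for the
any-asthma contrast, below the published 0.628 — the published SEN/SPE
anchors and the published AUC are not jointly attainable by any
single-biomarker data set of this form, one of several internal
inconsistencies in the source tables (with the SPE non-monotonicity and
the real-column rounding above). AUC values are therefore validated by
estimator identities and closed-form convergence, not against the
published numbers.

## Numerical and design choices

- Proportions are never rounded until render time; report rounding is one
  decimal, half away from zero.
- Determinism: cohorts are byte-identical under a fixed spec and seed
  (`numpy.random.default_rng`); the analysis itself is deterministic, so
  re-running on the same input yields byte-identical reports.
- Problem sizes: parameter-recovery checks use 200,000 draws per group
  (Monte-Carlo SE ≈ 0.1 points on a proportion); the closed-form AUC
  convergence check uses 100,000 per group; pipeline tests use cohorts of
  3,000–60,000.
- Empty inputs: an empty confusion table is valid (all metrics undefined);
  an empty prevalence grid or cohort is an error; an outcome with no
  positives is skipped with a warning; a cohort with no symptom-free child
  is a degenerate analysis (CLI exit code 3).
- No confidence intervals, multiple-testing adjustment, multivariable
  models or cost-weighted accuracy extensions: the analysis mirrors the
  unadjusted single-predictor design it reproduces.
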