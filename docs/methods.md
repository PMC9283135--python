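# Methods

## Demographic adjustment and ES=0 classification

Three Italian normative systems correct the raw MoCA total (0–30) for age
and years of education:

| dataset | equation (adjusted = raw + correction) | ES=0 cut-off | normative ages |
|---|---|---|---|
| Conti | `+ 0.175·(age − 70.08) + 24.3·(1/edu − 0.126)` | 17.36 | 60–80 |
| Santangelo | `− 4.228·(log10(100 − age) − 1.58) − 3.201·(√edu − 3.25)` | 15.50 | 21–95 |
| Aiello | `+ 0.000008·(age³ − 297697.184801) − 3.331407·(ln(edu) − 2.325648)` | 18.58 | 21–96 |

The coefficients ship as a read-only JSON resource
(`moca_psci/data/normative_datasets.json`) so their provenance is auditable
in one place. Conventions and degenerate-input handling:

- **Strict cut-off.** Impaired iff adjusted < cut-off; a tie at the cut-off
  is normal, consistent with "below" the tolerance limit defining ES = 0.
- **No clamping of outputs.** Adjusted values may exceed 30 or drop below
  0; the corrections are additive and clamping would distort the score
  ordering the ROC analysis depends on. Reports round to two decimals;
  full precision is kept internally.
- **Education 0.** `1/edu` (Conti) and `ln(edu)` (Aiello) are undefined at
  zero; education is clamped to a configurable minimum (default 1 year),
  the result flagged `clamped_inputs`, and a warning logged. The normative
  samples contain no illiterate subjects, so no principled extrapolation
  exists; clamping preserves totality without inventing norms.
- **Age ≥ 100.** Santangelo's `log10(100 − age)` is undefined; age is
  clamped to 99 with the same flag.
- **Ages outside a dataset's normative range** (e.g. < 60 for Conti) are
  evaluated anyway but flagged `extrapolated`; stroke cohorts routinely
  span wider ages than the norming samples and the caveat should be
  visible rather than fatal.
- Logarithms are exactly as published: base-10 in Santangelo, natural in
  Aiello. Each equation has a fixed point — adjusted = raw at the
  centering demographics (e.g. Conti: age 70.08, education 1/0.126 years)
  — which the tests assert to 1e-9.

Only the impaired/normal dichotomy is implemented. The full 5-level ES
grading needs the normative studies' tolerance-limit tables, which are not
part of this package's sources; the borderline (ES = 1) category is
therefore out of scope.

## Outcome adjudication

A followed-up patient is cognitively impaired when **at least one** test in
the follow-up battery is impaired (per-test norming happens upstream; the
package consumes booleans meaning "adjusted score below the 5th centile").
Dementia requires, in addition, functional dependence in ADL **or** IADL
(logical OR of the two flags) that is *not* attributable to motor/sensory
sequelae of the stroke or to another disease; cognitive impairment without
qualifying dependence is MCI. The modified Rankin Scale is carried as
descriptive metadata only. The instrument-level thresholds that define
"dependence" (number of lost ADL/IADL functions) are not modelled; the
package consumes pre-computed booleans, which is the only faithful
granularity available. Patients with an empty test battery raise a
"not assessable" error and fall out of the analyzable set.

## Accuracy, association and the per-point risk model

- Se = tp/(tp+fn), Sp = tn/(tn+fp), PPV = tp/(tp+fp), NPV = tn/(tn+fn);
  a zero denominator yields "undefined" (None), never 0 or 1. Percent
  rendering rounds **half-up** (46.75 → 47, 97.56 → 98), the convention
  that reproduces clinical tables; Python's default banker's rounding
  would not.
- Chi-square is Pearson's without Yates continuity correction (the common
  default at these sample sizes); the correction is available through
  `scipy` directly if wanted. p-values render as `<0.001` below 0.001.
- The logistic risk model `logit P(PSCI) = a + b·adjusted` is fit by
  maximum likelihood (statsmodels). Because lower MoCA means higher risk,
  `b` is negative; the package exposes `exp(−b)` as the **odds ratio per
  point lost** with a Wald 95 % CI, avoiding sign confusion. Separation is
  flagged (|b| > 50, a huge standard error, or non-convergence) and
  reported as `converged=False` rather than raised.
- Two-group baseline comparisons use the pooled-variance Student t-test
  (Welch selectable) for numeric variables and Pearson chi-square for
  binary ones.

## ROC analysis and cut-off selection

Candidate thresholds are the midpoints between consecutive distinct
observed adjusted values, plus sentinels at (min − 1) and (max + 1); a
patient tests positive iff adjusted score **< threshold** (lower MoCA =
worse). Midpoint thresholds are what make non-observed cut-off values
(e.g. 22.82) appear in screening tables: the reported cut-off lies between
two patients' scores. The AUC is the trapezoid over (1 − Sp, Se) with ties
in FPR ordered by TPR, which equals the Mann–Whitney concordance
probability `P(score_case < score_control) + ½·P(tie)`; the tests assert
this identity to 1e-12 against an O(n²) pairwise oracle and cross-check
against scikit-learn.

The optimal cut-off maximizes Youden's J among thresholds meeting the
screening adequacy rule **Se ≥ 0.80 and Sp ≥ 0.60**; ties prefer higher
sensitivity (in screening, a missed future PSCI case is the costlier
error), then the lower threshold. If no threshold is adequate the global
Youden maximizer is returned flagged `adequate=False`. The adequacy-
constrained-Youden criterion is this package's design choice for "optimal":
the adequacy rule itself is standard, but no single selection algorithm is
canonical, and maximum J under the constraint is the natural one.

No bootstrap CI on the AUC is computed by default; DeLong comparisons and
cost-weighted cut-points are out of scope.

## Synthetic cohort generator

`SimulationConfig` defaults encode the emulated study conditions: n = 207;
age 76 ± 9.6 years truncated to [45, 95]; education 9.1 ± 4.5 years
truncated to [1, 21] and rounded to integers; 34 % female; event mix
TIA/ischemic/hemorrhagic = 6/84/10 %; NIHSS 2.1 ± 3.1 (≥ 0); raw MoCA
17.1 ± 6.9 on [0, 30]; follow-up rate 57 % at 7.4 ± 1.7 months; PSCI
prevalence 65 % among the followed with dementia share 22/77; risk OR 1.39
per adjusted point lost.

Structure and numerical choices:

- **Latent ability.** A single continuous factor with loadings −0.35 (age,
  z-scale) and +0.25 (education) plus idiosyncratic noise drives the raw
  MoCA. The loadings are a free parameter of the generator — the real
  cohort's age/education–MoCA correlations are unknown — chosen once as a
  moderate value (realized age–MoCA correlation ≈ −0.3) and not tuned.
- **Truncated normals** are drawn by vectorized rejection sampling;
  integer rounding happens after truncation. The raw-MoCA channel clips
  the latent-driven value to [0, 30] before rounding (the bounds are
  2.5 SD and 1.9 SD from the mean, so the clipped mass is small).
- **Informative drop-out.** Retention follows
  `logit P(retained) = c − 0.05·(age − mean) + 0.07·(moca − mean)`;
  the intercept `c` is found by bisection (tolerance 1e-4) so the mean
  retention probability over the realized cohort equals the configured
  follow-up rate. Drop-outs are therefore older and lower-scoring in
  expectation, with the marginal rate hit regardless of the covariate
  draws. `followup_rate = 1` disables attrition.
- **Outcome model.** `logit P(PSCI) = α + β·(Aiello-adjusted baseline)`,
  β = −ln(OR per point lost), α calibrated by the same bisection to the
  target prevalence among the followed. Conditioning on the
  Aiello-adjusted score makes the configured OR the directly recoverable
  generative parameter; age/education affect the outcome only through the
  adjustment.
- **Assessments.** Per-test latent scores are ability + N(0, 0.8²) noise,
  impaired below −0.4; flags are then coerced consistent with the drawn
  status (a PSCI patient with no impaired draw gets their weakest test
  impaired; a no-PSCI patient screens normal on every test). Functional
  dependence is assigned so dementia cases are ADL/IADL-dependent for
  cognitive reasons, and a 15 % share of MCI carries dependence marked
  motor/sensory. Consequently outcome adjudication round-trips the
  generated labels **exactly**, which the tests assert.
- **Determinism.** One `numpy.random.Generator` (PCG64) with a fixed draw
  order, pinned in the run metadata; identical seed ⇒ bit-identical
  cohorts.

What the generator does **not** emulate: lesion location and stroke-subtype
effects on cognition, centre effects beyond a label, per-domain impairment
structure (one latent factor, not four), partial ADL/IADL dependence, and
measurement error in the baseline MoCA beyond integer rounding. Passing
tests on synthetic cohorts therefore demonstrate the statistical machinery
and its calibration, not clinical validity on real patients; the
data-dependent published quantities (group means, exact AUCs, exact optimal
cut-off values) are reproducible only qualitatively.

## Pipeline conventions

- Patients without a baseline MoCA stay in the cohort description but are
  excluded (and counted in the logs) from every score analysis; a cohort
  with no scores at all aborts.
- `--exclude-tia` removes TIA patients from every denominator, supporting
  the sensitivity analysis that repeats the study on strokes only.
- Reports are byte-reproducible from the same inputs and configuration
  (asserted by test); the effective configuration and a hash are embedded
  in `meta.json`.
- Percentages render at the precision clinical tables use (integers, one
  decimal where informative).

## Problem sizes used in the checks

The automated checks run the oracle suites at n ≤ 50 over 1000 random
instances, parameter recovery at n = 2000 over 100 seeded replicates
(Wald-CI coverage of the generative OR asserted ≥ 90 %), and the
structural-replication run at n = 4000 — sizes chosen so the stochastic
assertions are stable at standard Monte-Carlo tolerances.
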