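# Methods

## The index

The TCRAD score is a binary median-cutoff adherence index in the
tradition of the Mediterranean Diet Score family: each of 14 food-group
components contributes one point, awarded at or above the sex-specific
median intake for the 6 healthy components and strictly below the median
for the 8 unhealthy components (inverse scoring). Totals of 0–14 are
banded low (< 6), moderate (6–7) and high (8–14); SES points (0–100) are
classed ≤ 29 / 30–84 / ≥ 85.

Two conventions deserve note:

* **Tie at the cutoff.** The published rule is explicit for healthy
  components (meeting the median earns the point). For unhealthy
  components we take the strict logical inverse — an intake exactly at
  the cutoff scores 0 — so that for every component exactly one of the
  two directions earns the point at any intake.
* **Cutoff provenance.** Cutoffs may be supplied (the bundled reference
  table, for scoring against the original population's medians) or
  derived from the cohort being scored (the right choice for a new
  population). The `ScoredCohort` records which was used. Derived
  cutoffs of 0 (possible for episodically consumed foods such as
  tortillas) make the corresponding healthy component a free point; the
  deriver warns when this happens.

Whether the reference cutoffs were computed on raw or energy-adjusted
intakes is not documented; the pipeline exposes both (`score_on:
raw|adjusted`, default `raw`) and records the choice.

## Preprocessing

**Energy-outlier screen.** Per sex, participants whose mean daily energy
falls strictly below the 1st or strictly above the 99th percentile of
the pre-exclusion distribution are removed. Percentiles use linear
interpolation between order statistics (the numpy default); values
exactly at a threshold are retained. Both choices are configurable
because the verbal rule ("in the 1st percentile or above the 99th") does
not pin them down. Sexes with fewer than 10 participants are left
unscreened — extreme percentiles of tiny samples are noise.

**Usual intake.** The default estimator is the mean over available
recorded days (1–3; participants with fewer than 3 days are flagged).
The alternative is a one-way random-effects shrinkage estimator:
û_i = μ̂ + λ_i (x̄_i − μ̂) with λ_i = σ̂²_b / (σ̂²_b + σ̂²_w / k_i),
where σ̂²_w is the pooled within-person day-to-day variance, σ̂²_b =
var(person means) − σ̂²_w · mean(1/k_i) truncated at zero, and k_i the
days observed. λ ∈ [0, 1] always, so the estimate interpolates between
the person mean and the population mean. This is a deliberately simple
stand-in for full usual-intake methodology (e.g. the Multiple Source
Method): it shrinks on the raw scale, ignores covariates and consumption
probability, and applies one λ per component. On the synthetic cohorts
it beats the raw 3-day mean in mean-squared error in every tested seed.

**Energy adjustment (residual method).** Each variable is regressed on
mean daily energy (closed-form single-regressor OLS) and replaced by its
residual plus the value predicted at the sample-mean energy:
a_i = y_i − b(e_i − ē). This preserves the variable's mean exactly,
annihilates its correlation with energy (|r| < 1e-10 numerically), and
keeps original units. Negative adjusted intakes can occur and are
retained: scoring and category medians operate on ranks of the adjusted
distribution, where re-truncation would distort.

Pipeline order is exclusion → usual intake → adjustment.

## Validation statistics

* Spearman rank correlation (average ranks for ties) of each nutrient
  with the total score; constant inputs yield an undefined (NaN)
  correlation with a note, never 0. Stars at p < 0.05 / 0.01 / 0.001.
* Component medians (min–max) within each score category, a
  Kruskal–Wallis test across categories, and pairwise Wilcoxon rank-sum
  comparisons. The rank-sum test uses the exact null distribution when
  both groups have n < 20 and no ties, otherwise the normal
  approximation with tie correction. Pairwise comparisons are
  uncorrected by default (a Bonferroni option exists) — multiplicity
  handling in this literature is typically left implicit, and the
  default mirrors that practice.
* Means (SD) of the score and components per stratum of sex, area, SES
  class, age group (12–15 / 16–19) and school type, with per-factor
  Kruskal–Wallis tests; chi-square (no Yates correction by default) and
  Student's t are provided for categorical / two-level characteristics.
* Row-normalised low/moderate/high percentages per stratum, one decimal.

All tests are two-tailed at α = 0.05.

## The synthetic cohort generator

The generator emulates a cross-sectional adolescent dietary survey with
3-day food records. What it models:

* **Strata.** Sex (36% boys / 64% girls), area (50/50 urban/rural),
  school type (80/20 public/private), SES class (32/40/28 low/medium/
  high, with points drawn uniformly within each class band), age 13–18.
  Proportions follow the study population the package emulates.
* **Usual intakes.** Per component, log-normal around the sex-specific
  reference median with multiplicative area and SES effects taken from
  the published stratum mean ratios (rural ↑ beans/vegetables/white
  rice, urban ↑ sugary drinks/fast food/solid fats; high-SES ↑ fast
  food/dairy, ↓ beans/white rice). Effect multipliers are normalised in
  log space by the stratum proportions so the configured sex medians
  remain the overall anchors. Between-person SD on the log scale
  defaults to σ_b = 0.5 — a realistic right-skew for food-group intakes.
* **Day-to-day variation.** x_{icd} = T_{ic} · exp(σ_w ε − σ_w²/2) with
  σ_w = 0.45, so E[x | T] = T and the 3-day mean is unbiased for the
  usual intake. The −σ_w²/2 term corrects the mean, not the median, of
  the daily values; the *usual-intake* median equals the configured
  median exactly, which is what the anchor-recovery tests check.
* **Energy and nutrients.** Energy is a composition-weighted sum of the
  day's food groups (approximate kcal/g densities) plus a basal term
  (650 kcal, for foods outside the 14 groups) and N(0, 130²) noise.
  Nutrients are linear combinations of food groups plus basal and noise,
  with fiber/folate/magnesium/potassium loading on legumes, vegetables
  and fruits and saturated fat on the fatty unhealthy groups — the sign
  structure a traditional-diet score should recover.
* **Bookkeeping.** Days 1–2 are labelled weekday and day 3 weekend, with
  no distributional effect (record days are balanced by design, not by
  model). Optional per-component zero-inflation (default 0) can emulate
  episodic consumers. All draws come from one seeded generator in a
  fixed order, so cohorts are bit-reproducible.

An outlier injector scales the energy of a chosen fraction of
participants (capped at 5%) by m, alternating with 1/m, so injected
participants land strictly outside both contaminated percentile
thresholds; because thresholds are sex-specific, the "all injected are
flagged" guarantee holds within a sex.

What the generator does **not** model — and hence what passing tests do
not establish about real data: reporting error and selective
misreporting, school-level clustering and the survey's three-stage
sampling design, seasonality, weekday/weekend intake differences,
correlated food-group consumption beyond the stratum effects (e.g. rice
with beans), and the measurement-error deattenuation of correlations.
The validation battery's effect directions are built in by construction;
the tests verify that the pipeline *recovers* them, not that they hold
in any real population.

## Problem sizes and numerical choices

Simulation-based checks use cohorts of 1,000–10,000 participants and
10–100 seeds, sizes at which the checked quantities (medians,
percentile exclusion rates, MSE orderings, rejection rates, stratum
sign patterns) are stable. Test calibration uses groups of 100, where
the asymptotic null distributions of the rank tests are accurate.
Percentiles and medians interpolate linearly between order statistics.
Kruskal–Wallis on wholly-tied data returns NaN rather than raising.
Scoring is a total function on finite inputs; missing component intakes
raise a scoring error naming the component rather than imputing.

## Known limitations

* The shrinkage usual-intake estimator is a teaching-grade stand-in, not
  a replacement for full measurement-error modelling.
* Binary median-cutoff scoring discards within-half information; the
  package deliberately does not implement graded components.
* The reference cutoff table applies to the population it was estimated
  in; scoring other populations against it answers a different question
  than scoring against their own medians.
* Score–nutrient correlations are attenuated by day-to-day variance;
  no deattenuation is applied.
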