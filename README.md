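# tcrad

Construction and validation of the **Traditional Costa Rican Adolescents
Diet (TCRAD) score**, a 14-component binary adherence index for
adolescent 3-day food-record data, together with the preprocessing steps
such an analysis needs (energy-outlier screening, usual-intake
estimation, energy adjustment by the residual method), a battery of
validation statistics, and a synthetic cohort generator so the whole
pipeline is testable without access to survey microdata.

It is aimed at nutritional epidemiologists who want a reproducible,
scriptable implementation of a median-cutoff traditional-diet score —
for scoring new cohorts, for methodological experiments, or as a
template for building similar culture-specific indices.

## The score

Fourteen food groups are scored against **sex-specific median cutoffs**
m<sub>c,s</sub> (g/day). Six groups are *healthy* (legumes, vegetables,
fruits, vegetable oils, dairy, corn tortillas) and eight *unhealthy*
(white rice, red/processed meat, solid fats, desserts, sugary drinks,
snacks, fast food, refined bread). For participant *i* of sex *s* with
usual intake x<sub>i,c</sub>:

- healthy component: p<sub>i,c</sub> = 1 if x<sub>i,c</sub> ≥ m<sub>c,s</sub>, else 0
- unhealthy component (inverse scoring): p<sub>i,c</sub> = 1 if x<sub>i,c</sub> < m<sub>c,s</sub>, else 0

The total S<sub>i</sub> = Σ<sub>c</sub> p<sub>i,c</sub> ranges 0–14 and is
banded **low** (S < 6), **moderate** (6–7), **high** (8–14). Household
socioeconomic status on the 0–100 point scale is classed low (≤ 29),
medium (30–84), high (≥ 85). The published reference cutoffs ship with
the package (`load_cutoffs("table1_fixture")`); cutoffs can also be
derived as the within-sex sample medians of any cohort.

Preprocessing mirrors standard survey practice: participants with mean
daily energy strictly outside the sex-specific 1st–99th percentile band
are excluded; usual intakes are estimated from the 3 recorded days (mean,
or a one-way shrinkage estimator that pulls noisy person means toward the
population mean by λ = σ²_b / (σ²_b + σ²_w/k)); and nutrients/components
are energy-adjusted by the residual method (OLS residual re-centred at
the mean-energy prediction).

## Worked example

```python
from tcrad import (GeneratorConfig, generate_cohort, exclude_energy_outliers,
                   estimate_usual_intake, score_cohort,
                   correlate_score_nutrients, DEFAULT_INDEX)

cfg = GeneratorConfig(n_participants=818, seed=42)
cohort = generate_cohort(cfg)
records, report = exclude_energy_outliers(cohort.records, cohort.participants)
print(f"excluded {len(report.excluded_ids)} energy outliers, {report.n_after} remain")

usual = estimate_usual_intake(records, method="mean")
scored = score_cohort(usual.values[list(DEFAULT_INDEX.component_names)],
                      cohort.participants, cutoffs="derive")
print(f"mean TCRAD score: {scored.frame['tcrad_score'].mean():.2f}")
print(scored.frame['category'].value_counts().to_dict())

corr = correlate_score_nutrients(scored, usual.values[["fiber", "saturated_fat"]])
print(corr[["rho", "p", "stars"]].round(3))
```

prints

```
excluded 18 energy outliers, 800 remain
mean TCRAD score: 7.00
{'high': 316, 'moderate': 307, 'low': 177}
                 rho    p stars
nutrient
fiber          0.298  0.0   ***
saturated_fat -0.332  0.0   ***
```

The ~2% exclusion is what a two-sided 1%/99% screen removes from
continuous data; the mean score of 7.0 is the median-anchored expectation
(each of 14 components contributes ≈ 0.5 points when scored against its
own sex median); and the correlations show the construct-validity sign
pattern — fiber tracks the traditional diet positively, saturated fat
negatively.

The same pipeline is available from the shell:

```bash
tcrad run --seed 42 --out-dir out/          # simulate → preprocess → score → validate
tcrad fixtures --out-dir fixtures/          # dump reference cutoffs + worked examples
tcrad score --records usual.csv --participants roster.csv --cutoffs table1 --out scored.csv
```

The estimator classes (`EnergyOutlierFilter`, `UsualIntakeEstimator`,
`EnergyAdjuster`, `TcradScorer`) follow the scikit-learn
fit/transform/get_params protocol and compose with sklearn tooling.

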