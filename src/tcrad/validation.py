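"""Validation statistics for a scored cohort.

Four report tables mirror the usual construct-validation battery for a
diet-quality index:

* score-nutrient Spearman rank correlations (with significance stars),
* component medians across score categories with Kruskal-Wallis and
  pairwise Wilcoxon rank-sum comparisons,
* mean component intakes and total score across sociodemographic strata
  with Kruskal-Wallis tests,
* score-category proportions by stratum.

All tests are two-tailed at alpha = 0.05. Pairwise comparisons default
to no multiplicity correction (a Bonferroni option is provided). The
rank-sum test uses the normal approximation with tie correction, or the
exact null distribution when both groups have fewer than 20
observations and no ties are present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError
from .scoring import ScoredCohort

__all__ = [
    "significance_stars",
    "rank_sum_test",
    "chi_square_test",
    "correlate_score_nutrients",
    "medians_by_category",
    "compare_by_strata",
    "category_proportions",
]

CATEGORY_ORDER = ("low", "moderate", "high")
DEFAULT_FACTORS = ("sex", "area", "ses_class", "age_group", "school_type")


def significance_stars(p: float) -> str:
    """Stars at the 0.05 / 0.01 / 0.001 thresholds; empty when p >= 0.05."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def rank_sum_test(a: np.ndarray, b: np.ndarray, method: str = "auto") -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    ``method="auto"`` uses the exact null distribution when both samples
    have n < 20 and there are no ties, otherwise the standardized normal
    approximation with tie correction. Returns (statistic, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if method == "auto":
        no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
        method = "exact" if (len(a) < 20 and len(b) < 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chi_square_test(table: np.ndarray, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a contingency table (no Yates correction by
    default). Returns (statistic, p)."""
    stat, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=correction)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Score-nutrient correlations
# ---------------------------------------------------------------------------


def correlate_score_nutrients(
    cohort: ScoredCohort, nutrients: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rank correlation of each nutrient with the total score.

    Ties are handled by average ranks. A constant score or nutrient makes
    rho undefined; such rows report NaN rho with an explanatory note
    rather than 0.

    Returns a DataFrame indexed by nutrient with columns: median,
    mean, sd, q1, q3, rho, p, stars, note.
    """
    if cohort.n < 3:
        raise DegenerateDataError("correlation needs >= 3 participants")
    nutrients = nutrients.loc[cohort.frame.index]
    score = cohort.frame["tcrad_score"].to_numpy(dtype=float)
    rows = []
    score_constant = np.ptp(score) == 0
    for name in nutrients.columns:
        v = nutrients[name].to_numpy(dtype=float)
        note = ""
        if score_constant or np.ptp(v) == 0:
            rho, p = float("nan"), float("nan")
            note = "undefined: constant " + ("score" if score_constant else "nutrient")
        else:
            res = stats.spearmanr(v, score)
            rho, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "nutrient": name,
                "median": float(np.median(v)),
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)),
                "q1": float(np.percentile(v, 25)),
                "q3": float(np.percentile(v, 75)),
                "rho": rho,
                "p": p,
                "stars": significance_stars(p),
                "note": note,
            }
        )
    return pd.DataFrame(rows).set_index("nutrient")


# ---------------------------------------------------------------------------
# Component medians by score category
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CategoryMedianTable:
    """Per-component category medians plus group and pairwise tests."""

    table: pd.DataFrame  # per component: overall/category median, min, max
    counts: dict  # category -> n
    pairwise: pd.DataFrame  # per component x contrast: p, significant
    multiplicity: str


def medians_by_category(
    cohort: ScoredCohort,
    adjusted: pd.DataFrame,
    multiplicity: str = "none",
    alpha: float = 0.05,
) -> CategoryMedianTable:
    """Median (min-max) of each (energy-adjusted) component within each
    score category, with a Kruskal-Wallis test across categories and
    pairwise rank-sum comparisons.

    ``multiplicity`` is ``"none"`` (default) or ``"bonferroni"``.
    """
    if multiplicity not in ("none", "bonferroni"):
        raise ValueError(f"unknown multiplicity rule {multiplicity!r}")
    adjusted = adjusted.loc[cohort.frame.index]
    cat = cohort.frame["category"]
    present = [c for c in CATEGORY_ORDER if (cat == c).any()]
    if len(present) < 2:
        raise DegenerateDataError("need >= 2 non-empty score categories")
    counts = {c: int((cat == c).sum()) for c in present}
    underpowered = min(counts.values()) < 2

    contrasts = [
        (a, b)
        for i, a in enumerate(CATEGORY_ORDER)
        for b in CATEGORY_ORDER[i + 1 :]
        if a in present and b in present
    ]
    n_contrasts = max(len(contrasts), 1)

    comp_cols = [c for c in cohort.index.component_names if c in adjusted.columns]
    rows = []
    pw_rows = []
    for comp in comp_cols:
        v = adjusted[comp]
        row: dict = {"component": comp}
        row["overall_median"] = float(v.median())
        row["overall_min"] = float(v.min())
        row["overall_max"] = float(v.max())
        groups = []
        for c in CATEGORY_ORDER:
            sel = v[cat == c]
            if len(sel) == 0:
                row[f"{c}_median"] = np.nan
                row[f"{c}_min"] = np.nan
                row[f"{c}_max"] = np.nan
                continue
            groups.append(sel.to_numpy(dtype=float))
            row[f"{c}_median"] = float(sel.median())
            row[f"{c}_min"] = float(sel.min())
            row[f"{c}_max"] = float(sel.max())
        try:
            _, kw_p = stats.kruskal(*groups)
        except ValueError:  # all values identical
            kw_p = float("nan")
        row["kw_p"] = float(kw_p)
        row["underpowered"] = underpowered
        rows.append(row)
        for a, b in contrasts:
            ga = v[cat == a].to_numpy(dtype=float)
            gb = v[cat == b].to_numpy(dtype=float)
            if len(ga) < 2 or len(gb) < 2:
                p = float("nan")
            else:
                _, p = rank_sum_test(ga, gb)
            p_adj = min(p * n_contrasts, 1.0) if multiplicity == "bonferroni" else p
            pw_rows.append(
                {
                    "component": comp,
                    "contrast": f"{a}-{b}",
                    "p": p,
                    "p_adjusted": p_adj,
                    "significant": bool(p_adj < alpha) if np.isfinite(p_adj) else False,
                }
            )
    return CategoryMedianTable(
        table=pd.DataFrame(rows).set_index("component"),
        counts=counts,
        pairwise=pd.DataFrame(pw_rows),
        multiplicity=multiplicity,
    )


# ---------------------------------------------------------------------------
# Stratum summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StratumSummaryTable:
    """Means/SDs of score and components per stratum, with per-factor
    Kruskal-Wallis p-values."""

    summaries: pd.DataFrame  # rows: variable; columns: (factor, level, stat)
    tests: pd.DataFrame  # rows: variable; columns: factor -> KW p
    counts: dict  # factor -> {level: n}


def compare_by_strata(
    cohort: ScoredCohort,
    values: pd.DataFrame | None = None,
    factors: Sequence[str] = DEFAULT_FACTORS,
) -> StratumSummaryTable:
    """Mean (SD) of the total score and each component within each level of
    each sociodemographic factor, with a Kruskal-Wallis test per factor.

    ``values`` defaults to the intakes attached to the cohort (the same
    table that was scored); the total score column is always included.
    Single-level factors are skipped with a warning.
    """
    if values is None:
        if cohort.intakes is None:
            values = pd.DataFrame(index=cohort.frame.index)
        else:
            values = cohort.intakes
    values = values.loc[cohort.frame.index]
    data = values.copy()
    data["tcrad_score"] = cohort.frame["tcrad_score"].to_numpy(dtype=float)
    variables = ["tcrad_score"] + [c for c in values.columns]

    usable: list[str] = []
    counts: dict[str, dict] = {}
    for f in factors:
        if f not in cohort.frame.columns:
            warnings.warn(f"factor {f!r} not present; skipped", stacklevel=2)
            continue
        levels = cohort.frame[f].dropna().unique()
        if len(levels) < 2:
            warnings.warn(f"factor {f!r} has a single level; skipped", stacklevel=2)
            continue
        usable.append(f)
        counts[f] = cohort.frame[f].value_counts().to_dict()

    summary_cols: dict[tuple, list] = {}
    test_rows: dict[str, dict] = {v: {} for v in variables}
    for f in usable:
        levels = sorted(cohort.frame[f].unique())
        for v in variables:
            groups = [
                data.loc[(cohort.frame[f] == lv).to_numpy(), v].to_numpy(dtype=float)
                for lv in levels
            ]
            for lv, g in zip(levels, groups):
                summary_cols.setdefault((f, lv, "mean"), []).append(float(np.mean(g)))
                summary_cols.setdefault((f, lv, "sd"), []).append(
                    float(np.std(g, ddof=1)) if len(g) > 1 else float("nan")
                )
            try:
                _, p = stats.kruskal(*groups)
            except ValueError:
                p = float("nan")
            test_rows[v][f] = float(p)
    summaries = pd.DataFrame(summary_cols, index=variables)
    summaries.columns = pd.MultiIndex.from_tuples(
        summaries.columns, names=["factor", "level", "stat"]
    )
    tests = pd.DataFrame(test_rows).T.reindex(variables)
    return StratumSummaryTable(summaries=summaries, tests=tests, counts=counts)


def t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample Student's t-test (equal variances), for two-level
    continuous characteristics. Returns (statistic, p)."""
    res = stats.ttest_ind(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Category proportions
# ---------------------------------------------------------------------------


def category_proportions(cohort: ScoredCohort, factor: str) -> pd.DataFrame:
    """Row-normalised percentages of low/moderate/high score per stratum of
    *factor*, rounded to one decimal, with the stratum n."""
    if factor not in cohort.frame.columns:
        raise KeyError(f"factor {factor!r} not in cohort")
    rows = []
    for level, grp in cohort.frame.groupby(factor, sort=True):
        n = len(grp)
        if n == 0:
            warnings.warn(f"empty stratum {level!r} omitted", stacklevel=2)
            continue
        row = {"stratum": level, "n": n}
        for c in CATEGORY_ORDER:
            row[f"pct_{c}"] = round(100.0 * float((grp["category"] == c).sum()) / n, 1)
        rows.append(row)
    return pd.DataFrame(rows).set_index("stratum")
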