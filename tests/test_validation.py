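"""Validation statistics: correlations, category medians, stratum tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tcrad import (
    DEFAULT_INDEX,
    category_proportions,
    chi_square_test,
    compare_by_strata,
    correlate_score_nutrients,
    medians_by_category,
    rank_sum_test,
    score_cohort,
)
from tcrad.validation import significance_stars, t_test

COMPONENTS = list(DEFAULT_INDEX.component_names)


def _cohort_from_scores(scores, table1, sexes=None, areas=None):
    """Build a scored cohort whose totals are exactly `scores` by setting
    that many healthy components to their male cutoff."""
    n = len(scores)
    healthy = list(DEFAULT_INDEX.healthy_names)
    unhealthy = list(DEFAULT_INDEX.unhealthy_names)
    rows = []
    for s in scores:
        profile = {}
        for j, c in enumerate(healthy):
            profile[c] = table1.get(c, "male") if j < min(s, 6) else 0.0
        extra = max(s - 6, 0)  # remaining points from unhealthy (intake below cutoff)
        for j, c in enumerate(unhealthy):
            profile[c] = 0.0 if j < extra else table1.get(c, "male")
        rows.append(profile)
    intakes = pd.DataFrame(
        rows, index=pd.Index([f"p{i}" for i in range(n)], name="participant_id")
    )
    roster = pd.DataFrame(
        {
            "participant_id": intakes.index,
            "sex": sexes if sexes is not None else ["male"] * n,
            "age": [15] * n,
            "area": areas if areas is not None else ["urban"] * n,
            "school_type": ["public"] * n,
            "ses_points": [50] * n,
        }
    )
    return score_cohort(intakes, roster, cutoffs=table1)


def brute_force_spearman(x, y):
    """Average-rank Spearman written out by hand."""

    def avg_ranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sv = np.array(v, dtype=float)[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestCorrelations:
    def test_monotone_nutrient_gives_rho_one(self, table1):
        cohort = _cohort_from_scores([2, 4, 6, 8, 10, 12], table1)
        nutrients = pd.DataFrame(
            {"fiber": np.exp(cohort.frame["tcrad_score"].to_numpy(dtype=float))},
            index=cohort.frame.index,
        )
        out = correlate_score_nutrients(cohort, nutrients)
        assert out.loc["fiber", "rho"] == pytest.approx(1.0)

    def test_anti_monotone_gives_minus_one(self, table1):
        cohort = _cohort_from_scores([2, 4, 6, 8, 10], table1)
        nutrients = pd.DataFrame(
            {"satfat": -cohort.frame["tcrad_score"].to_numpy(dtype=float)},
            index=cohort.frame.index,
        )
        out = correlate_score_nutrients(cohort, nutrients)
        assert out.loc["satfat", "rho"] == pytest.approx(-1.0)

    def test_tied_values_match_average_rank_oracle(self, table1):
        scores = [2, 5, 5, 8, 11]
        cohort = _cohort_from_scores(scores, table1)
        nut = np.array([3.0, 1.0, 4.0, 4.0, 2.0])
        nutrients = pd.DataFrame({"x": nut}, index=cohort.frame.index)
        out = correlate_score_nutrients(cohort, nutrients)
        expected = brute_force_spearman(nut, np.array(scores, dtype=float))
        assert out.loc["x", "rho"] == pytest.approx(expected, abs=1e-12)

    def test_constant_nutrient_undefined_not_zero(self, table1):
        cohort = _cohort_from_scores([2, 4, 6, 8], table1)
        nutrients = pd.DataFrame({"x": [5.0] * 4}, index=cohort.frame.index)
        out = correlate_score_nutrients(cohort, nutrients)
        assert np.isnan(out.loc["x", "rho"])
        assert "constant" in out.loc["x", "note"]

    def test_stars_monotone_in_p(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == ""


class TestGroupTests:
    def test_chi_square_closed_form(self):
        """2x2 table {{10,20},{20,10}} has X^2 = 6.6667 without continuity
        correction (all expected counts are 15)."""
        stat, p = chi_square_test([[10, 20], [20, 10]])
        assert stat == pytest.approx(20.0 / 3.0, abs=1e-4)
        assert p == pytest.approx(stats.chi2.sf(20.0 / 3.0, 1), abs=1e-12)

    def test_t_test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        stat, p = t_test(a, a.copy())
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_rank_sum_exact_for_small_untied_samples(self):
        a = [1.0, 3.0, 5.0]
        b = [2.0, 4.0, 6.0]
        _, p_auto = rank_sum_test(a, b)
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert p_auto == pytest.approx(float(res.pvalue))


class TestMediansByCategory:
    def test_shifted_component_detected(self, table1):
        rng = np.random.default_rng(3)
        scores = [2] * 120 + [6] * 120 + [10] * 120
        cohort = _cohort_from_scores(scores, table1)
        adjusted = pd.DataFrame(
            {c: rng.lognormal(3, 0.4, size=360) for c in COMPONENTS},
            index=cohort.frame.index,
        )
        high = (cohort.frame["category"] == "high").to_numpy()
        adjusted.loc[high, "legumes"] *= 1.5
        out = medians_by_category(cohort, adjusted)
        assert out.table.loc["legumes", "kw_p"] < 0.05
        pw = out.pairwise.set_index(["component", "contrast"])
        assert pw.loc[("legumes", "low-high"), "significant"]
        assert out.table.loc["legumes", "high_median"] > out.table.loc[
            "legumes", "low_median"
        ]

    def test_single_participant_per_category_underpowered(self, table1):
        cohort = _cohort_from_scores([2, 6, 10], table1)
        adjusted = pd.DataFrame(
            {c: [1.0, 2.0, 3.0] for c in COMPONENTS}, index=cohort.frame.index
        )
        out = medians_by_category(cohort, adjusted)
        assert bool(out.table["underpowered"].all())
        assert out.table.loc["legumes", "low_median"] == 1.0
        assert out.table.loc["legumes", "high_median"] == 3.0

    def test_bonferroni_not_smaller_than_raw(self, table1):
        rng = np.random.default_rng(8)
        scores = list(rng.integers(0, 15, size=90))
        cohort = _cohort_from_scores(scores, table1)
        adjusted = pd.DataFrame(
            {c: rng.lognormal(3, 0.4, size=90) for c in COMPONENTS},
            index=cohort.frame.index,
        )
        raw = medians_by_category(cohort, adjusted, multiplicity="none")
        bonf = medians_by_category(cohort, adjusted, multiplicity="bonferroni")
        assert (
            bonf.pairwise["p_adjusted"].to_numpy()
            >= raw.pairwise["p_adjusted"].to_numpy() - 1e-12
        ).all()


class TestStrataAndProportions:
    def test_means_match_pandas_and_counts_sum(self, table1):
        rng = np.random.default_rng(5)
        scores = list(rng.integers(0, 15, size=60))
        areas = ["urban"] * 30 + ["rural"] * 30
        cohort = _cohort_from_scores(scores, table1, areas=areas)
        out = compare_by_strata(cohort)
        rural = cohort.frame.loc[cohort.frame["area"] == "rural", "tcrad_score"]
        assert out.summaries.loc["tcrad_score", ("area", "rural", "mean")] == (
            pytest.approx(rural.mean())
        )
        assert sum(out.counts["area"].values()) == 60

    def test_single_level_factor_skipped(self, table1):
        cohort = _cohort_from_scores([2, 6, 10, 12], table1)  # all male, all urban
        with pytest.warns(UserWarning):
            out = compare_by_strata(cohort, factors=("sex",))
        assert "sex" not in out.counts

    def test_all_high_scores_give_100_percent_high(self, table1):
        cohort = _cohort_from_scores([14] * 10, table1, areas=["urban"] * 5 + ["rural"] * 5)
        props = category_proportions(cohort, "area")
        for _, row in props.iterrows():
            assert (row["pct_low"], row["pct_moderate"], row["pct_high"]) == (0, 0, 100)

    def test_rows_sum_to_100(self, table1):
        rng = np.random.default_rng(11)
        scores = list(rng.integers(0, 15, size=200))
        areas = list(rng.choice(["urban", "rural"], size=200))
        cohort = _cohort_from_scores(scores, table1, areas=areas)
        props = category_proportions(cohort, "area")
        for _, row in props.iterrows():
            assert row[["pct_low", "pct_moderate", "pct_high"]].sum() == (
                pytest.approx(100.0, abs=0.1)
            )

    def test_uniform_scores_high_fraction_near_expected(self, table1):
        """Uniform scores 0..14 put 7/15 = 46.7% of participants in the
        high band."""
        rng = np.random.default_rng(17)
        scores = list(rng.integers(0, 15, size=10_000))
        cohort = _cohort_from_scores(scores, table1)
        props = category_proportions(cohort, "sex")
        assert props.loc["male", "pct_high"] == pytest.approx(100 * 7 / 15, abs=2.0)
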