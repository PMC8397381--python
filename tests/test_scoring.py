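"""Scoring rules: component points, totals, cutoff derivation, cohort scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrad import (
    DEFAULT_INDEX,
    TcradScorer,
    compute_tcrad,
    derive_cutoffs,
    score_cohort,
    score_component,
)
from tcrad.components import ComponentSpec, IndexDefinition
from tcrad.errors import CompletenessError, ScoringError

COMPONENTS = list(DEFAULT_INDEX.component_names)
HEALTHY = set(DEFAULT_INDEX.healthy_names)


def brute_force_score(intakes, sex, cutoffs):
    """Independent scorer: explicit 14-term loop with hand-written
    comparisons, one branch per direction."""
    total = 0
    for name in COMPONENTS:
        cut = cutoffs.get(name, sex)
        x = intakes[name]
        if name in HEALTHY:
            if x >= cut:
                total += 1
        else:
            if x < cut:
                total += 1
    return total


class TestScoreComponent:
    @pytest.mark.parametrize(
        "intake, cutoff, direction, expected",
        [
            (42.9, 42.9, "healthy", 1),  # meeting the median earns the point
            (42.8, 42.9, "healthy", 0),  # strictly below does not
            (230.10, 230.10, "unhealthy", 0),  # inverse scoring at the tie
            (0.0, 230.10, "unhealthy", 1),
            (1000.0, 42.9, "healthy", 1),
            (1000.0, 42.9, "unhealthy", 0),
        ],
    )
    def test_tie_and_direction_rules(self, intake, cutoff, direction, expected):
        assert score_component(intake, cutoff, direction) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ScoringError):
            score_component(float("nan"), 10.0, "healthy")


class TestComputeTcrad:
    def test_worked_profiles(self, table1):
        """Best male profile scores 14, worst scores 0, all-at-cutoff scores 6
        (6 healthy ties earn the point, 8 unhealthy ties do not)."""
        best = {
            c: (table1.get(c, "male") if c in HEALTHY else 0.0) for c in COMPONENTS
        }
        worst = {
            c: (0.0 if c in HEALTHY else table1.get(c, "male")) for c in COMPONENTS
        }
        ties = {c: table1.get(c, "male") for c in COMPONENTS}
        assert compute_tcrad(best, "male", table1) == 14
        assert compute_tcrad(worst, "male", table1) == 0
        assert compute_tcrad(ties, "male", table1) == 6

    def test_missing_component_named(self, table1):
        profile = {c: 10.0 for c in COMPONENTS if c != "dairy"}
        with pytest.raises(ScoringError, match="dairy"):
            compute_tcrad(profile, "male", table1)

    def test_matches_brute_force_on_random_profiles(self, table1):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            sex = "male" if rng.random() < 0.5 else "female"
            profile = {c: float(rng.uniform(0, 400)) for c in COMPONENTS}
            assert compute_tcrad(profile, sex, table1) == brute_force_score(
                profile, sex, table1
            )

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        base=st.floats(0, 300),
        delta=st.floats(0, 100),
        comp=st.sampled_from(COMPONENTS),
    )
    def test_monotonicity(self, table1, base, delta, comp):
        """Raising a healthy intake never lowers the score; raising an
        unhealthy intake never raises it."""
        profile = {c: 50.0 for c in COMPONENTS}
        profile[comp] = base
        before = compute_tcrad(profile, "female", table1)
        profile[comp] = base + delta
        after = compute_tcrad(profile, "female", table1)
        if comp in HEALTHY:
            assert after >= before
        else:
            assert after <= before

    def test_component_order_irrelevant(self, table1):
        rng = np.random.default_rng(7)
        shuffled = list(DEFAULT_INDEX.components)
        rng.shuffle(shuffled)
        permuted = IndexDefinition(components=tuple(shuffled))
        for _ in range(50):
            profile = {c: float(rng.uniform(0, 400)) for c in COMPONENTS}
            assert compute_tcrad(profile, "male", table1) == compute_tcrad(
                profile, "male", table1, index=permuted
            )


class TestDeriveCutoffs:
    def _frame(self, values, sexes):
        intakes = pd.DataFrame(
            {c: values for c in COMPONENTS},
            index=pd.Index([f"p{i}" for i in range(len(values))], name="participant_id"),
        )
        roster = pd.DataFrame(
            {"participant_id": intakes.index, "sex": sexes}
        )
        return intakes, roster

    def test_odd_n_median(self):
        intakes, roster = self._frame([10, 20, 30, 40, 50], ["male"] * 5)
        roster2 = pd.concat(
            [roster, pd.DataFrame({"participant_id": ["f0", "f1"], "sex": ["female"] * 2})]
        )
        intakes2 = pd.concat(
            [intakes, pd.DataFrame({c: [7.0, 7.0] for c in COMPONENTS}, index=["f0", "f1"])]
        )
        cuts = derive_cutoffs(intakes2, roster2)
        assert cuts.get("legumes", "male") == 30
        assert cuts.get("legumes", "female") == 7.0  # constant intake

    def test_even_n_midpoint(self):
        intakes, roster = self._frame([10, 20, 30, 40], ["male"] * 4)
        roster2 = pd.concat(
            [roster, pd.DataFrame({"participant_id": ["f0", "f1"], "sex": ["female"] * 2})]
        )
        intakes2 = pd.concat(
            [intakes, pd.DataFrame({c: [1.0, 3.0] for c in COMPONENTS}, index=["f0", "f1"])]
        )
        cuts = derive_cutoffs(intakes2, roster2)
        assert cuts.get("legumes", "male") == 25

    def test_absent_sex_is_completeness_error(self):
        intakes, roster = self._frame([10, 20, 30], ["male"] * 3)
        with pytest.raises(CompletenessError):
            derive_cutoffs(intakes, roster)

    def test_zero_cutoff_warns(self):
        intakes, roster = self._frame([0.0, 0.0, 5.0], ["male", "male", "female"])
        roster.loc[2, "sex"] = "female"
        with pytest.warns(UserWarning, match="free points"):
            derive_cutoffs(intakes, roster)


class TestScoreCohort:
    def test_composition_of_worked_examples(self, table1):
        best = {c: (table1.get(c, "male") if c in HEALTHY else 0.0) for c in COMPONENTS}
        worst = {c: (0.0 if c in HEALTHY else table1.get(c, "male")) for c in COMPONENTS}
        ties = {c: table1.get(c, "male") for c in COMPONENTS}
        intakes = pd.DataFrame(
            [best, worst, ties], index=pd.Index(["a", "b", "c"], name="participant_id")
        )
        roster = pd.DataFrame(
            {
                "participant_id": ["a", "b", "c"],
                "sex": ["male"] * 3,
                "age": [14, 15, 17],
                "area": ["urban"] * 3,
                "school_type": ["public"] * 3,
                "ses_points": [10, 50, 90],
            }
        )
        cohort = score_cohort(intakes, roster, cutoffs=table1)
        assert list(cohort.frame["tcrad_score"]) == [14, 0, 6]
        assert list(cohort.frame["category"]) == ["high", "low", "moderate"]
        assert list(cohort.frame["ses_class"]) == ["low", "medium", "high"]

    def test_empty_cohort_no_error(self, table1):
        intakes = pd.DataFrame(columns=COMPONENTS)
        intakes.index.name = "participant_id"
        roster = pd.DataFrame(
            columns=["participant_id", "sex", "age", "area", "school_type", "ses_points"]
        )
        cohort = score_cohort(intakes, roster, cutoffs=table1)
        assert cohort.n == 0

    def test_derived_cutoff_prevalence_near_half(self):
        """Scored against their own sex medians, continuous intakes give
        each component a point prevalence close to 50%."""
        rng = np.random.default_rng(21)
        n = 4000  # 2000 per sex
        intakes = pd.DataFrame(
            rng.lognormal(3.0, 0.6, size=(n, 14)),
            columns=COMPONENTS,
            index=pd.Index([f"p{i}" for i in range(n)], name="participant_id"),
        )
        roster = pd.DataFrame(
            {
                "participant_id": intakes.index,
                "sex": ["male"] * (n // 2) + ["female"] * (n // 2),
                "age": [15] * n,
                "area": ["urban"] * n,
                "school_type": ["public"] * n,
                "ses_points": [50] * n,
            }
        )
        cohort = score_cohort(intakes, roster, cutoffs="derive")
        for c in COMPONENTS:
            assert 0.45 <= cohort.frame[f"p_{c}"].mean() <= 0.55
        assert cohort.cutoff_source == "derived"


class TestSklearnProtocol:
    def test_get_set_params_and_clone(self, table1):
        from sklearn.base import clone

        scorer = TcradScorer(cutoffs=table1)
        params = scorer.get_params()
        assert params["cutoffs"] is table1
        cloned = clone(scorer)
        assert dict(cloned.cutoffs.values) == dict(table1.values)

    def test_fitted_attribute_convention(self, table1):
        scorer = TcradScorer(cutoffs=table1)
        X = pd.DataFrame(
            {**{c: [10.0, 20.0] for c in COMPONENTS}, "sex": ["male", "female"]}
        )
        scorer.fit(X)
        assert scorer.cutoffs_ is table1
        out = scorer.transform(X)
        assert "tcrad_score" in out.columns
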