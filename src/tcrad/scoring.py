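"""TCRAD scoring: cutoff derivation, binary component points, totals,
score categories, and SES classification.

Scoring rule
------------
For a healthy component, a participant earns 1 point when their intake
meets or exceeds the sex-specific median cutoff, else 0. For an
unhealthy component the scoring is inverted: 1 point strictly below the
cutoff, 0 at or above it. An intake exactly at the cutoff therefore
scores 1 when healthy and 0 when unhealthy. The 14 component points sum
to the total score (0-14), banded low (<6), moderate (6-7), high (8-14).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .components import (
    DEFAULT_CATEGORY_RULE,
    DEFAULT_INDEX,
    DEFAULT_SES_RULE,
    Direction,
    IndexDefinition,
    ScoreCategoryRule,
    Sex,
    SesRule,
)
from .cutoffs import CutoffTable
from .errors import CompletenessError, ScoringError

__all__ = [
    "derive_cutoffs",
    "score_component",
    "compute_tcrad",
    "categorize_score",
    "classify_ses",
    "TcradScorer",
    "ScoredCohort",
    "score_cohort",
    "write_scored_cohort",
    "read_scored_cohort",
]


def derive_cutoffs(
    intakes: pd.DataFrame,
    participants: pd.DataFrame,
    index: IndexDefinition = DEFAULT_INDEX,
) -> CutoffTable:
    """Sex-specific sample medians of each component intake.

    Parameters
    ----------
    intakes : DataFrame
        Participant x component usual (or energy-adjusted) intakes,
        indexed by participant id.
    participants : DataFrame
        Roster with ``participant_id`` and ``sex``.
    """
    missing = [c for c in index.component_names if c not in intakes.columns]
    if missing:
        raise CompletenessError(f"intake table missing components: {missing}")
    sex = participants.set_index("participant_id")["sex"]
    sex = sex.reindex(intakes.index)
    values: dict[tuple[str, str], float] = {}
    for s in (Sex.MALE.value, Sex.FEMALE.value):
        mask = (sex == s).to_numpy()
        if mask.sum() == 0:
            raise CompletenessError(f"no participants of sex {s!r}; cannot derive cutoffs")
        for c in index.component_names:
            values[(c, s)] = float(intakes.loc[mask, c].median())
    zeroes = [k for k, v in values.items() if v == 0]
    if zeroes:
        warnings.warn(
            f"derived cutoff is 0 for {zeroes}; the corresponding healthy "
            "components become free points",
            stacklevel=2,
        )
    return CutoffTable(values=values, source="derived")


def score_component(intake: float, cutoff: float, direction: Direction | str) -> int:
    """Binary point for one component.

    Healthy: 1 iff intake >= cutoff. Unhealthy (inverse scoring): 1 iff
    intake < cutoff.
    """
    if not (np.isfinite(intake) and np.isfinite(cutoff)):
        raise ScoringError(f"non-finite intake/cutoff: {intake}, {cutoff}")
    if Direction(direction) is Direction.HEALTHY:
        return 1 if intake >= cutoff else 0
    return 1 if intake < cutoff else 0


def compute_tcrad(
    intakes: Mapping[str, float],
    sex: str,
    cutoffs: CutoffTable,
    index: IndexDefinition = DEFAULT_INDEX,
) -> int:
    """Total score for one participant; no imputation of missing components."""
    total = 0
    for comp in index.components:
        if comp.name not in intakes:
            raise ScoringError(f"missing intake for component {comp.name!r}")
        total += score_component(
            float(intakes[comp.name]), cutoffs.get(comp.name, sex), comp.direction
        )
    return total


def categorize_score(
    score: int,
    rule: ScoreCategoryRule = DEFAULT_CATEGORY_RULE,
    max_score: int = DEFAULT_INDEX.max_score,
) -> str:
    return rule.categorize(int(score), max_score)


def classify_ses(points: int, rule: SesRule = DEFAULT_SES_RULE) -> str:
    return rule.classify(int(points))


class TcradScorer(BaseEstimator, TransformerMixin):
    """Vectorised scorer following the scikit-learn transformer protocol.

    Parameters
    ----------
    cutoffs : CutoffTable or None
        If None, sex-specific median cutoffs are derived from the data
        seen at ``fit`` time; otherwise the supplied table (e.g. the
        published reference cutoffs) is used as-is.
    index : IndexDefinition
    category_rule : ScoreCategoryRule

    ``fit`` expects a DataFrame with one row per participant containing
    the component columns and a ``sex`` column; ``transform`` returns a
    DataFrame with per-component points (``p_<component>``), the total
    ``tcrad_score`` and its ``category``. Fitted cutoffs live in
    ``cutoffs_``.
    """

    def __init__(
        self,
        cutoffs: CutoffTable | None = None,
        index: IndexDefinition = DEFAULT_INDEX,
        category_rule: ScoreCategoryRule = DEFAULT_CATEGORY_RULE,
    ):
        self.cutoffs = cutoffs
        self.index = index
        self.category_rule = category_rule

    def fit(self, X: pd.DataFrame, y=None) -> "TcradScorer":
        if self.cutoffs is not None:
            self.cutoffs.validate_against(self.index)
            self.cutoffs_ = self.cutoffs
        else:
            if len(X) == 0:
                raise CompletenessError("cannot derive cutoffs from an empty cohort")
            roster = pd.DataFrame(
                {"participant_id": X.index, "sex": X["sex"].to_numpy()}
            )
            intakes = X[list(self.index.component_names)]
            self.cutoffs_ = derive_cutoffs(intakes, roster, self.index)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.index.component_names if c not in X.columns]
        if missing:
            raise ScoringError(f"missing intake for components: {missing}")
        out = pd.DataFrame(index=X.index)
        sex = X["sex"].to_numpy()
        total = np.zeros(len(X), dtype=int)
        for comp in self.index.components:
            cut = np.where(
                sex == Sex.MALE.value,
                self.cutoffs_.get(comp.name, Sex.MALE.value),
                self.cutoffs_.get(comp.name, Sex.FEMALE.value),
            )
            v = X[comp.name].to_numpy(dtype=float)
            if comp.direction is Direction.HEALTHY:
                pts = (v >= cut).astype(int)
            else:
                pts = (v < cut).astype(int)
            out[f"p_{comp.name}"] = pts
            total += pts
        out["tcrad_score"] = total
        out["category"] = [
            self.category_rule.categorize(int(s), self.index.max_score) for s in total
        ]
        return out


@dataclass
class ScoredCohort:
    """A scored cohort: per-participant strata, component points, total
    score, score category and SES class, plus the cutoffs used."""

    frame: pd.DataFrame  # indexed by participant_id
    cutoffs: CutoffTable
    cutoff_source: str
    index: IndexDefinition = DEFAULT_INDEX
    intakes: pd.DataFrame | None = None  # the intakes that were scored

    def __post_init__(self) -> None:
        pts = self.frame[[f"p_{c}" for c in self.index.component_names]]
        if len(self.frame) and not (pts.sum(axis=1) == self.frame["tcrad_score"]).all():
            raise ScoringError("total score does not equal the sum of component points")

    @property
    def n(self) -> int:
        return len(self.frame)

    def summary(self) -> dict:
        return {
            "n": self.n,
            "cutoff_source": self.cutoff_source,
            "mean_score": float(self.frame["tcrad_score"].mean()) if self.n else None,
            "category_counts": self.frame["category"].value_counts().to_dict(),
        }


def _age_group(age: float) -> str:
    return "12-15" if age <= 15 else "16-19"


def score_cohort(
    intakes: pd.DataFrame,
    participants: pd.DataFrame,
    cutoffs: CutoffTable | str = "derive",
    index: IndexDefinition = DEFAULT_INDEX,
    category_rule: ScoreCategoryRule = DEFAULT_CATEGORY_RULE,
    ses_rule: SesRule = DEFAULT_SES_RULE,
) -> ScoredCohort:
    """Score every participant and attach strata, categories and SES class.

    ``cutoffs`` may be a :class:`CutoffTable` or the string ``"derive"``
    to compute sex-specific medians from *intakes* (recorded in the
    output for provenance).
    """
    roster = participants.set_index("participant_id")
    roster = roster.loc[[pid for pid in intakes.index if pid in roster.index]]
    intakes = intakes.loc[roster.index]

    if len(intakes) == 0:
        cols = (
            ["sex", "age", "age_group", "area", "school_type", "ses_points", "ses_class"]
            + [f"p_{c}" for c in index.component_names]
            + ["tcrad_score", "category"]
        )
        empty = pd.DataFrame(columns=cols)
        empty.index.name = "participant_id"
        table = cutoffs if isinstance(cutoffs, CutoffTable) else CutoffTable(values={})
        return ScoredCohort(empty, table, "empty", index, intakes)

    X = intakes[list(index.component_names)].copy()
    X["sex"] = roster["sex"].to_numpy()
    if isinstance(cutoffs, CutoffTable):
        scorer = TcradScorer(cutoffs=cutoffs, index=index, category_rule=category_rule)
        source = cutoffs.source
    elif cutoffs == "derive":
        scorer = TcradScorer(cutoffs=None, index=index, category_rule=category_rule)
        source = "derived"
    else:
        raise ValueError(f"cutoffs must be a CutoffTable or 'derive', got {cutoffs!r}")
    scored = scorer.fit(X).transform(X)

    frame = pd.DataFrame(index=intakes.index)
    frame.index.name = "participant_id"
    frame["sex"] = roster["sex"].to_numpy()
    frame["age"] = roster["age"].to_numpy()
    frame["age_group"] = [_age_group(a) for a in frame["age"]]
    frame["area"] = roster["area"].to_numpy()
    frame["school_type"] = roster["school_type"].to_numpy()
    frame["ses_points"] = roster["ses_points"].to_numpy()
    frame["ses_class"] = [ses_rule.classify(int(p)) for p in frame["ses_points"]]
    for c in scored.columns:
        frame[c] = scored[c].to_numpy()
    return ScoredCohort(frame, scorer.cutoffs_, source, index, intakes)


def write_scored_cohort(cohort: ScoredCohort, path: str | Path) -> None:
    """One CSV row per participant with a deterministic column order."""
    cols = (
        ["sex", "age", "age_group", "area", "school_type", "ses_points", "ses_class"]
        + [f"p_{c}" for c in cohort.index.component_names]
        + ["tcrad_score", "category"]
    )
    cohort.frame[cols].to_csv(path, index=True, index_label="participant_id")


def read_scored_cohort(
    path: str | Path,
    cutoffs: CutoffTable,
    index: IndexDefinition = DEFAULT_INDEX,
) -> ScoredCohort:
    frame = pd.read_csv(path).set_index("participant_id")
    return ScoredCohort(frame, cutoffs, cutoffs.source, index)
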