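"""Pre-scoring computations: energy-outlier exclusion, usual-intake
estimation, and energy adjustment by the residual method.

The three stages are scikit-learn-style transformers so they compose with
``sklearn.pipeline`` machinery; the module-level functions
(:func:`exclude_energy_outliers`, :func:`estimate_usual_intake`,
:func:`energy_adjust`) are thin wrappers that return the richer report
objects the pipeline records.

Pipeline order is exclusion -> usual intake -> adjustment. Re-running the
exclusion on already-filtered data with the same thresholds is a no-op.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DataValidationError, DegenerateDataError
from .records import ENERGY_COL, FoodRecordTable

__all__ = [
    "ExclusionReport",
    "EnergyOutlierFilter",
    "exclude_energy_outliers",
    "UsualIntakeTable",
    "UsualIntakeEstimator",
    "estimate_usual_intake",
    "AdjustedIntakeTable",
    "EnergyAdjuster",
    "energy_adjust",
]


# ---------------------------------------------------------------------------
# Energy-outlier exclusion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExclusionReport:
    """Sex-specific thresholds and the participants they excluded."""

    thresholds: dict  # sex -> {"lower": kcal, "upper": kcal} (None if skipped)
    excluded_ids: tuple
    n_before: int
    n_after: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "thresholds": self.thresholds,
            "excluded_ids": list(self.excluded_ids),
            "n_before": self.n_before,
            "n_after": self.n_after,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


class EnergyOutlierFilter(BaseEstimator):
    """Flag participants with extreme mean daily energy, per sex.

    Within each sex, the 1st and 99th percentiles of the per-participant
    mean daily energy are computed on the pre-exclusion distribution
    (linear interpolation between order statistics by default);
    participants strictly below the lower or strictly above the upper
    threshold are outliers. Values exactly equal to a threshold are
    retained. Sexes with fewer than ``min_group`` participants are left
    unfiltered with a warning, since extreme percentiles are unstable.

    Follows the scikit-learn outlier-detector convention: ``fit`` learns
    the thresholds, ``predict`` returns +1 (inlier) / -1 (outlier).
    """

    def __init__(
        self,
        lower_pct: float = 1.0,
        upper_pct: float = 99.0,
        min_group: int = 10,
        interpolation: str = "linear",
    ):
        self.lower_pct = lower_pct
        self.upper_pct = upper_pct
        self.min_group = min_group
        self.interpolation = interpolation

    def fit(self, X: pd.DataFrame, y=None) -> "EnergyOutlierFilter":
        """X: DataFrame with columns ``sex`` and ``energy`` (one row per
        participant, mean daily energy)."""
        if not {"sex", "energy"}.issubset(X.columns):
            raise DataValidationError("expected columns 'sex' and 'energy'")
        thresholds: dict[str, dict | None] = {}
        for sex, grp in X.groupby("sex", sort=True):
            e = grp["energy"].to_numpy(dtype=float)
            if len(e) < self.min_group:
                warnings.warn(
                    f"sex {sex!r} has only {len(e)} participants; "
                    "percentile thresholds unstable, no exclusion applied",
                    stacklevel=2,
                )
                thresholds[str(sex)] = None
                continue
            lo = float(np.percentile(e, self.lower_pct, method=self.interpolation))
            hi = float(np.percentile(e, self.upper_pct, method=self.interpolation))
            thresholds[str(sex)] = {"lower": lo, "upper": hi}
        self.thresholds_ = thresholds
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """+1 for retained participants, -1 for outliers."""
        out = np.ones(len(X), dtype=int)
        for i, (sex, energy) in enumerate(zip(X["sex"], X["energy"])):
            th = self.thresholds_.get(str(sex))
            if th is None:
                continue
            if energy < th["lower"] or energy > th["upper"]:
                out[i] = -1
        return out

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).predict(X)


def exclude_energy_outliers(
    table: FoodRecordTable,
    participants: pd.DataFrame,
    lower_pct: float = 1.0,
    upper_pct: float = 99.0,
    min_group: int = 10,
    interpolation: str = "linear",
) -> tuple[FoodRecordTable, ExclusionReport]:
    """Remove participants whose mean daily energy lies strictly outside the
    sex-specific [P1, P99] band, returning the filtered table and a report."""
    mean_energy = table.mean_daily_energy()
    roster = participants.set_index("participant_id")
    missing = [pid for pid in mean_energy.index if pid not in roster.index]
    if missing:
        raise DataValidationError(f"participants without roster entry: {missing[:5]}")
    X = pd.DataFrame(
        {
            "participant_id": mean_energy.index,
            "sex": roster.loc[mean_energy.index, "sex"].to_numpy(),
            "energy": mean_energy.to_numpy(),
        }
    )
    filt = EnergyOutlierFilter(
        lower_pct=lower_pct,
        upper_pct=upper_pct,
        min_group=min_group,
        interpolation=interpolation,
    )
    flags = filt.fit_predict(X)
    excluded = tuple(X.loc[flags == -1, "participant_id"])
    kept = X.loc[flags == 1, "participant_id"]
    report = ExclusionReport(
        thresholds=filt.thresholds_,
        excluded_ids=excluded,
        n_before=len(X),
        n_after=len(kept),
    )
    return table.subset(kept), report


# ---------------------------------------------------------------------------
# Usual-intake estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UsualIntakeTable:
    """Per-participant usual intakes and, for the shrinkage method, the
    variance components used."""

    values: pd.DataFrame  # participant x variable
    method: str
    variance_components: pd.DataFrame | None = None  # per variable: sigma2_b, sigma2_w
    flagged_ids: tuple = ()  # participants with fewer than 3 day rows


class UsualIntakeEstimator(BaseEstimator, TransformerMixin):
    """Estimate each participant's usual (long-run) daily intake from up
    to three recorded days.

    method="mean"
        The mean over available days — unbiased but noisy.
    method="shrinkage"
        A one-way random-effects shrinkage estimator: person means are
        pulled toward the population mean by
        ``lambda_i = s2_b / (s2_b + s2_w / k_i)`` where ``s2_w`` is the
        pooled within-person day-to-day variance, ``s2_b`` the
        between-person variance (``var(person means) - s2_w * mean(1/k_i)``,
        truncated at 0), and ``k_i`` the number of observed days. This is
        a deliberately simple usual-intake model: it shrinks on the raw
        scale and ignores covariates and consumption probability.
    """

    def __init__(self, method: str = "mean", columns: Sequence[str] | None = None):
        self.method = method
        self.columns = columns

    def _cols(self, table: FoodRecordTable) -> list[str]:
        if self.columns is not None:
            return list(self.columns)
        cols = list(table.components)
        if ENERGY_COL in table.frame.columns:
            cols.append(ENERGY_COL)
        cols.extend(table.nutrients)
        return cols

    def fit(self, X: FoodRecordTable, y=None) -> "UsualIntakeEstimator":
        if self.method not in ("mean", "shrinkage"):
            raise ValueError(f"unknown method {self.method!r}")
        cols = self._cols(X)
        if self.method == "shrinkage":
            df = X.frame
            k = df.groupby("participant_id", sort=False)[cols[0]].size()
            if (k < 2).all():
                raise DegenerateDataError(
                    "shrinkage needs at least some participants with >= 2 days"
                )
            vc = {}
            means = df.groupby("participant_id", sort=False)[cols].mean()
            inv_k = (1.0 / k).mean()
            for c in cols:
                within = df.groupby("participant_id", sort=False)[c].var(ddof=1)
                s2w = float(within.dropna().mean()) if within.notna().any() else 0.0
                s2b = float(means[c].var(ddof=1)) - s2w * float(inv_k)
                vc[c] = {"sigma2_b": max(s2b, 0.0), "sigma2_w": s2w}
            self.variance_components_ = pd.DataFrame(vc).T
            self.grand_means_ = means.mean()
        self.columns_ = cols
        return self

    def transform(self, X: FoodRecordTable) -> pd.DataFrame:
        cols = self.columns_
        means = X.frame.groupby("participant_id", sort=False)[cols].mean()
        if self.method == "mean":
            return means
        k = X.frame.groupby("participant_id", sort=False)[cols[0]].size()
        out = means.copy()
        for c in cols:
            s2b = float(self.variance_components_.loc[c, "sigma2_b"])
            s2w = float(self.variance_components_.loc[c, "sigma2_w"])
            denom = s2b + s2w / k.to_numpy(dtype=float)
            with np.errstate(invalid="ignore", divide="ignore"):
                lam = np.where(denom > 0, s2b / denom, 0.0)
            mu = float(self.grand_means_[c])
            out[c] = mu + lam * (means[c].to_numpy() - mu)
        return out


def estimate_usual_intake(
    table: FoodRecordTable,
    method: str = "mean",
    columns: Sequence[str] | None = None,
) -> UsualIntakeTable:
    """Per-participant usual intakes over food groups, energy and nutrients."""
    est = UsualIntakeEstimator(method=method, columns=columns)
    values = est.fit(table).transform(table)
    days = table.days_per_participant()
    flagged = tuple(days.index[days < 3])
    vc = getattr(est, "variance_components_", None)
    return UsualIntakeTable(
        values=values, method=method, variance_components=vc, flagged_ids=flagged
    )


# ---------------------------------------------------------------------------
# Energy adjustment (residual method)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdjustedIntakeTable:
    """Energy-adjusted values plus the regression coefficients used."""

    values: pd.DataFrame  # participant x variable, original units
    slopes: pd.Series
    intercepts: pd.Series
    energy_mean: float


class EnergyAdjuster(BaseEstimator, TransformerMixin):
    """Energy adjustment by the residual method.

    For each variable y, fit the ordinary least-squares regression
    y = a + b * energy across participants and replace y_i by its
    residual re-centred at the value predicted for the sample-mean
    energy: ``adj_i = y_i - b * (energy_i - mean(energy))``. Adjusted
    values keep the variable's original units and sample mean, and are
    uncorrelated with energy by construction. Negative adjusted values
    can occur and are retained — ranking and medians of the adjusted
    distribution are what downstream scoring uses.
    """

    def __init__(self, energy_col: str = ENERGY_COL):
        self.energy_col = energy_col

    def fit(self, X: pd.DataFrame, y=None) -> "EnergyAdjuster":
        """X: participant-level DataFrame containing ``energy_col`` and the
        variables to adjust (all numeric columns except energy)."""
        if self.energy_col not in X.columns:
            raise DataValidationError(f"missing energy column {self.energy_col!r}")
        if len(X) < 3:
            raise DegenerateDataError("energy adjustment needs >= 3 participants")
        e = X[self.energy_col].to_numpy(dtype=float)
        var_e = float(np.var(e))
        if var_e == 0:
            raise DegenerateDataError("energy is constant; residual method undefined")
        self.energy_mean_ = float(e.mean())
        cols = [c for c in X.columns if c != self.energy_col]
        ec = e - self.energy_mean_
        slopes = {}
        intercepts = {}
        for c in cols:
            v = X[c].to_numpy(dtype=float)
            b = float(ec @ (v - v.mean()) / (ec @ ec))
            slopes[c] = b
            intercepts[c] = float(v.mean() - b * self.energy_mean_)
        self.slopes_ = pd.Series(slopes)
        self.intercepts_ = pd.Series(intercepts)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        e = X[self.energy_col].to_numpy(dtype=float)
        out = {}
        for c in self.slopes_.index:
            v = X[c].to_numpy(dtype=float)
            out[c] = v - self.slopes_[c] * (e - self.energy_mean_)
        return pd.DataFrame(out, index=X.index)


def energy_adjust(
    values: pd.DataFrame, energy: pd.Series | np.ndarray
) -> AdjustedIntakeTable:
    """Adjust every column of *values* for total energy by the residual
    method; *energy* is aligned positionally with the rows of *values*."""
    X = values.copy()
    X["__energy__"] = np.asarray(energy, dtype=float)
    adj = EnergyAdjuster(energy_col="__energy__")
    adjusted = adj.fit(X).transform(X)
    return AdjustedIntakeTable(
        values=adjusted,
        slopes=adj.slopes_,
        intercepts=adj.intercepts_,
        energy_mean=adj.energy_mean_,
    )
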