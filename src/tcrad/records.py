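"""Food-record tables, participant rosters, and their CSV readers/writers.

A :class:`FoodRecordTable` holds long-run dietary records in "wide day"
form: one row per participant per recorded day, one column per food-group
component (g/day), a total-energy column (kcal/day), and optional nutrient
columns (units as supplied). Up to three days per participant are allowed,
mirroring a 3-day food record; participants with fewer recorded days are
retained and flagged downstream.

Two CSV dialects are supported:

* ``wide``: ``participant_id, day, <component columns>, energy_kcal,
  <nutrient columns>``
* ``long``: ``participant_id, day, component, grams`` (energy may appear
  as a pseudo-component named ``energy_kcal``)

All intakes are g/day and energy kcal/day; no unit inference is done.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .components import DEFAULT_INDEX, IndexDefinition, Sex
from .errors import DataValidationError, SchemaError

__all__ = [
    "FoodRecordTable",
    "read_food_records",
    "write_food_records",
    "read_participants",
    "validate_participants",
    "ENERGY_COL",
]

ID_COL = "participant_id"
DAY_COL = "day"
ENERGY_COL = "energy_kcal"
VALID_DAYS = (1, 2, 3)


@dataclass
class FoodRecordTable:
    """Validated per-participant-per-day intake table.

    Attributes
    ----------
    frame : pandas.DataFrame
        Columns: ``participant_id``, ``day``, the component columns,
        ``energy_kcal``, then nutrient columns.
    components : tuple of str
        Names of the food-group columns (g/day).
    nutrients : tuple of str
        Names of the nutrient columns.
    """

    frame: pd.DataFrame
    components: tuple[str, ...]
    nutrients: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.components = tuple(self.components)
        self.nutrients = tuple(self.nutrients)
        self._validate()

    def _validate(self) -> None:
        df = self.frame
        needed = [ID_COL, DAY_COL, *self.components]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise SchemaError(f"food record table missing columns: {missing}")
        if df.duplicated(subset=[ID_COL, DAY_COL]).any():
            dup = df[df.duplicated(subset=[ID_COL, DAY_COL], keep=False)]
            raise DataValidationError(
                f"duplicated (participant, day) rows: {dup[[ID_COL, DAY_COL]].head().to_dict('records')}"
            )
        bad_days = ~df[DAY_COL].isin(VALID_DAYS)
        if bad_days.any():
            raise DataValidationError(
                f"day index must be in {VALID_DAYS}; offending rows "
                f"{df.loc[bad_days, [ID_COL, DAY_COL]].head().to_dict('records')}"
            )
        value_cols = list(self.components)
        if ENERGY_COL in df.columns:
            value_cols.append(ENERGY_COL)
        vals = df[value_cols].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise DataValidationError("non-finite intake or energy values present")
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise DataValidationError(
                f"negative value in column {value_cols[c]!r}, row participant "
                f"{df.iloc[int(r)][ID_COL]!r} day {int(df.iloc[int(r)][DAY_COL])}"
            )
        counts = df.groupby(ID_COL, sort=False)[DAY_COL].size()
        if (counts > len(VALID_DAYS)).any():
            raise DataValidationError("a participant has more than 3 day rows")

    # -- convenience accessors -------------------------------------------------

    @property
    def participant_ids(self) -> list:
        return list(self.frame[ID_COL].drop_duplicates())

    @property
    def n_participants(self) -> int:
        return self.frame[ID_COL].nunique()

    def days_per_participant(self) -> pd.Series:
        return self.frame.groupby(ID_COL, sort=False)[DAY_COL].size()

    def mean_daily_energy(self) -> pd.Series:
        """Per-participant mean of daily total energy (kcal/day)."""
        if ENERGY_COL not in self.frame.columns:
            raise SchemaError(f"table has no {ENERGY_COL!r} column")
        return self.frame.groupby(ID_COL, sort=False)[ENERGY_COL].mean()

    def person_means(self, columns: Sequence[str] | None = None) -> pd.DataFrame:
        """Per-participant mean over available days for the given columns."""
        cols = list(columns) if columns is not None else list(self.components)
        return self.frame.groupby(ID_COL, sort=False)[cols].mean()

    def subset(self, participant_ids: Iterable) -> "FoodRecordTable":
        ids = set(participant_ids)
        sub = self.frame[self.frame[ID_COL].isin(ids)].reset_index(drop=True)
        return FoodRecordTable(sub, self.components, self.nutrients)


def _ordered_columns(table: FoodRecordTable) -> list[str]:
    cols = [ID_COL, DAY_COL]
    if "day_type" in table.frame.columns:
        cols.append("day_type")
    cols.extend(table.components)
    if ENERGY_COL in table.frame.columns:
        cols.append(ENERGY_COL)
    cols.extend(table.nutrients)
    return cols


def write_food_records(table: FoodRecordTable, path: str | Path) -> None:
    """Write a food-record table as a wide CSV with deterministic columns."""
    table.frame[_ordered_columns(table)].to_csv(path, index=False)


def read_food_records(
    path: str | Path,
    dialect: str = "wide",
    index: IndexDefinition = DEFAULT_INDEX,
) -> FoodRecordTable:
    """Read a food-record CSV in the ``wide`` or ``long`` dialect.

    Component columns are matched against *index*; any other numeric
    column (besides ``energy_kcal``) is treated as a nutrient and a
    warning lists columns not recognised as index components.
    """
    if dialect not in ("wide", "long"):
        raise SchemaError(f"unknown dialect {dialect!r}; expected 'wide' or 'long'")
    df = pd.read_csv(path)
    if dialect == "long":
        required = {ID_COL, DAY_COL, "component", "grams"}
        if not required.issubset(df.columns):
            raise SchemaError(
                f"long dialect requires columns {sorted(required)}, got {list(df.columns)}"
            )
        if df.duplicated(subset=[ID_COL, DAY_COL, "component"]).any():
            raise DataValidationError("duplicated (participant, day, component) cell")
        df = (
            df.pivot(index=[ID_COL, DAY_COL], columns="component", values="grams")
            .reset_index()
            .rename_axis(columns=None)
        )
    required = {ID_COL, DAY_COL}
    if not required.issubset(df.columns):
        raise SchemaError(f"missing mandatory columns {sorted(required - set(df.columns))}")

    known = set(index.component_names)
    components = [c for c in index.component_names if c in df.columns]
    missing_components = sorted(known - set(components))
    if missing_components:
        raise SchemaError(f"missing component columns: {missing_components}")
    extra = [
        c
        for c in df.columns
        if c not in known and c not in (ID_COL, DAY_COL, ENERGY_COL, "day_type")
    ]
    if extra:
        warnings.warn(
            f"columns not in the index treated as nutrients: {extra}", stacklevel=2
        )
    df[DAY_COL] = df[DAY_COL].astype(int)
    return FoodRecordTable(df, tuple(components), tuple(extra))


PARTICIPANT_COLS = ["participant_id", "sex", "age", "area", "school_type", "ses_points"]


def validate_participants(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a participant roster (id, sex, age, area, school_type,
    ses_points) and return it with normalised dtypes."""
    missing = [c for c in PARTICIPANT_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"participant table missing columns: {missing}")
    if df[ID_COL].duplicated().any():
        raise DataValidationError("duplicate participant ids")
    bad_sex = ~df["sex"].isin([s.value for s in Sex])
    if bad_sex.any():
        raise DataValidationError(f"unknown sex values: {df.loc[bad_sex, 'sex'].unique()}")
    if not df["area"].isin(["urban", "rural"]).all():
        raise DataValidationError("area must be 'urban' or 'rural'")
    if not df["school_type"].isin(["public", "private"]).all():
        raise DataValidationError("school_type must be 'public' or 'private'")
    pts = df["ses_points"].to_numpy()
    if ((pts < 0) | (pts > 100)).any():
        raise DataValidationError("ses_points must lie in [0, 100]")
    out = df.copy()
    out["ses_points"] = out["ses_points"].astype(int)
    out["age"] = out["age"].astype(float)
    return out


def read_participants(path: str | Path) -> pd.DataFrame:
    return validate_participants(pd.read_csv(path))
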