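"""Sex-specific median cutoff tables.

A :class:`CutoffTable` maps ``(component, sex)`` to a median cutoff in
g/day. The package bundles the published reference cutoffs for the 14
TCRAD components ("table1_fixture"); cutoffs can also be loaded from a
CSV or derived from a cohort (see :func:`tcrad.scoring.derive_cutoffs`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .components import DEFAULT_INDEX, IndexDefinition, Sex
from .errors import CompletenessError, DataValidationError

__all__ = ["CutoffTable", "load_cutoffs", "TABLE1_FIXTURE"]

TABLE1_FIXTURE = "table1_fixture"

SEXES = (Sex.MALE.value, Sex.FEMALE.value)


@dataclass(frozen=True)
class CutoffTable:
    """Mapping (component, sex) -> cutoff in g/day."""

    values: Mapping[tuple[str, str], float]
    source: str = "custom"

    def __post_init__(self) -> None:
        for (comp, sex), v in self.values.items():
            if sex not in SEXES:
                raise DataValidationError(f"unknown sex {sex!r} for component {comp!r}")
            if not (v >= 0):
                raise DataValidationError(f"cutoff for ({comp}, {sex}) must be >= 0, got {v}")

    def __getitem__(self, key: tuple[str, str]) -> float:
        return float(self.values[key])

    def get(self, component: str, sex: str) -> float:
        try:
            return float(self.values[(component, str(Sex(sex).value))])
        except KeyError:
            raise CompletenessError(f"no cutoff for ({component}, {sex})") from None

    def components(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for comp, _ in self.values:
            seen.setdefault(comp, None)
        return tuple(seen)

    def validate_against(self, index: IndexDefinition) -> None:
        """Every (component, sex) pair of *index* must be present."""
        missing = [
            (c, s)
            for c in index.component_names
            for s in SEXES
            if (c, s) not in self.values
        ]
        if missing:
            raise CompletenessError(f"cutoff table missing pairs: {missing}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"component": c, "sex": s, "cutoff_g_per_day": float(v)}
            for (c, s), v in self.values.items()
        ]
        return pd.DataFrame(rows, columns=["component", "sex", "cutoff_g_per_day"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, source: str = "custom") -> "CutoffTable":
        required = {"component", "sex", "cutoff_g_per_day"}
        if not required.issubset(frame.columns):
            raise DataValidationError(
                f"cutoff table needs columns {sorted(required)}, got {list(frame.columns)}"
            )
        values = {
            (str(r.component), str(r.sex)): float(r.cutoff_g_per_day)
            for r in frame.itertuples()
        }
        if len(values) != len(frame):
            raise DataValidationError("duplicate (component, sex) rows in cutoff table")
        return cls(values=values, source=source)


def load_cutoffs(
    source: str | Path = TABLE1_FIXTURE, index: IndexDefinition = DEFAULT_INDEX
) -> CutoffTable:
    """Load a cutoff table and check it covers every (component, sex) pair.

    Parameters
    ----------
    source : str or Path
        Either the sentinel ``"table1_fixture"`` for the bundled published
        cutoffs, or a path to a CSV with columns
        ``component, sex, cutoff_g_per_day``.
    index : IndexDefinition
        The index whose components must all be covered.
    """
    if str(source) == TABLE1_FIXTURE:
        ref = resources.files("tcrad.data").joinpath("table1_cutoffs.csv")
        with resources.as_file(ref) as p:
            frame = pd.read_csv(p)
        table = CutoffTable.from_frame(frame, source=TABLE1_FIXTURE)
    else:
        frame = pd.read_csv(source)
        table = CutoffTable.from_frame(frame, source=str(source))
    table.validate_against(index)
    return table
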