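"""Synthetic 3-day food-record cohorts.

The generator emulates the data structure of a cross-sectional adolescent
dietary survey: each participant has a sex, age (13-18 y), area of
residence, school type, and a 0-100 socioeconomic (SES) point score; each
contributes up to three recorded days (two weekdays and one weekend day)
of food-group intakes (g/day), total energy (kcal/day), and nutrient
intakes.

Model
-----
Per participant *i* and component *c* the true usual intake is

    T[i, c] = median[c, sex(i)] * m_area[c, area(i)] * m_ses[c, ses(i)]
              * exp(sigma_b[c] * z[i, c]),          z ~ N(0, 1)

so component medians within a sex anchor exactly to the configured
medians (stratum multipliers are normalised in log space by the stratum
proportions). Daily intakes add mean-corrected multiplicative
within-person noise,

    x[i, c, d] = T[i, c] * exp(sigma_w[c] * eps - sigma_w[c]^2 / 2),

which leaves E[x | T] = T so the 3-day mean is unbiased for T. Energy is
a composition-weighted sum of the day's food groups plus a basal term and
Gaussian noise; nutrients are linear combinations of food groups plus
basal and noise. Nutrient loadings concentrate fiber, folate, magnesium
and potassium on legumes/vegetables/fruits and saturated fat on the
fatty unhealthy groups, reproducing the sign structure expected of a
traditional-diet score.

Default medians are the published sex-specific medians; default area and
SES multipliers follow the published stratum mean ratios (rural higher
beans/vegetables/white rice, urban higher sugary drinks/fast food,
high-SES higher fast food and lower beans).

All randomness flows from one :class:`numpy.random.Generator` seeded by
``config.seed``; draw order is fixed (strata, SES points, age, person
effects, day effects, energy noise, nutrient noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .components import DEFAULT_INDEX, IndexDefinition
from .errors import ConfigError
from .records import ENERGY_COL, FoodRecordTable

__all__ = [
    "GeneratorConfig",
    "TrueParameters",
    "SyntheticCohort",
    "generate_cohort",
    "inject_energy_outliers",
    "TABLE1_MEDIANS",
]

# Published sex-specific median usual intakes (g/day) used as anchors.
TABLE1_MEDIANS: dict[str, dict[str, float]] = {
    "legumes": {"male": 42.9, "female": 25.6},
    "vegetables": {"male": 32.6, "female": 41.6},
    "fruits": {"male": 48.0, "female": 57.2},
    "vegetable_oils": {"male": 7.4, "female": 5.6},
    "dairy": {"male": 69.2, "female": 68.9},
    "tortillas": {"male": 0.9, "female": 0.3},
    "white_rice": {"male": 165.7, "female": 116.0},
    "red_meat": {"male": 43.7, "female": 28.3},
    "solid_fats": {"male": 4.2, "female": 4.3},
    "desserts": {"male": 29.3, "female": 35.3},
    "sugary_drinks": {"male": 308.4, "female": 230.1},
    "snacks": {"male": 8.9, "female": 11.4},
    "fast_food": {"male": 23.7, "female": 14.1},
    "refined_bread": {"male": 47.4, "female": 43.3},
}

# rural/urban mean ratios per component (published stratum means).
AREA_RATIOS: dict[str, float] = {
    "legumes": 1.422,
    "vegetables": 1.506,
    "fruits": 1.096,
    "vegetable_oils": 1.283,
    "dairy": 0.808,
    "tortillas": 1.061,
    "white_rice": 1.355,
    "red_meat": 0.915,
    "solid_fats": 0.657,
    "desserts": 1.108,
    "sugary_drinks": 0.743,
    "snacks": 0.866,
    "fast_food": 0.822,
    "refined_bread": 0.827,
}

# (low, medium, high) SES multipliers relative to medium (published ratios).
SES_RATIOS: dict[str, tuple[float, float, float]] = {
    "legumes": (1.252, 1.0, 0.746),
    "vegetables": (1.016, 1.0, 0.879),
    "fruits": (1.177, 1.0, 1.047),
    "vegetable_oils": (1.182, 1.0, 0.924),
    "dairy": (0.760, 1.0, 1.101),
    "tortillas": (0.760, 1.0, 0.933),
    "white_rice": (1.278, 1.0, 0.731),
    "red_meat": (1.035, 1.0, 1.119),
    "solid_fats": (0.991, 1.0, 1.045),
    "desserts": (0.961, 1.0, 1.023),
    "sugary_drinks": (0.930, 1.0, 1.067),
    "snacks": (1.012, 1.0, 1.017),
    "fast_food": (0.844, 1.0, 1.480),
    "refined_bread": (0.839, 1.0, 0.951),
}

# Approximate energy densities of the food groups, kcal per gram as consumed.
ENERGY_DENSITY: dict[str, float] = {
    "legumes": 1.3,
    "vegetables": 0.3,
    "fruits": 0.5,
    "vegetable_oils": 8.8,
    "dairy": 0.6,
    "tortillas": 2.2,
    "white_rice": 1.3,
    "red_meat": 2.5,
    "solid_fats": 7.2,
    "desserts": 3.5,
    "sugary_drinks": 0.4,
    "snacks": 5.0,
    "fast_food": 2.8,
    "refined_bread": 3.0,
}

# Nutrient loadings: units of nutrient per gram of food group.
NUTRIENT_LOADINGS: dict[str, dict[str, float]] = {
    "fiber": {  # g
        "legumes": 0.08,
        "vegetables": 0.025,
        "fruits": 0.02,
        "tortillas": 0.04,
        "white_rice": 0.005,
        "refined_bread": 0.01,
    },
    "folate": {  # mcg (white rice and bread fortified)
        "legumes": 1.5,
        "vegetables": 0.6,
        "fruits": 0.2,
        "white_rice": 0.5,
        "refined_bread": 0.4,
    },
    "magnesium": {  # mg
        "legumes": 0.5,
        "vegetables": 0.15,
        "fruits": 0.1,
        "dairy": 0.1,
        "white_rice": 0.12,
    },
    "potassium": {  # mg
        "legumes": 4.0,
        "vegetables": 3.0,
        "fruits": 2.0,
        "dairy": 1.5,
        "fast_food": 2.0,
    },
    "saturated_fat": {  # g
        "solid_fats": 0.45,
        "red_meat": 0.08,
        "dairy": 0.02,
        "desserts": 0.06,
        "fast_food": 0.05,
        "snacks": 0.05,
    },
    "protein": {  # g
        "legumes": 0.09,
        "dairy": 0.033,
        "red_meat": 0.26,
        "white_rice": 0.024,
        "fast_food": 0.12,
    },
    "carbohydrate": {  # g
        "legumes": 0.2,
        "fruits": 0.12,
        "tortillas": 0.45,
        "white_rice": 0.28,
        "desserts": 0.45,
        "sugary_drinks": 0.10,
        "snacks": 0.55,
        "refined_bread": 0.5,
    },
    "vitamin_c": {  # mg
        "fruits": 0.45,
        "vegetables": 0.25,
    },
}

NUTRIENT_BASAL: dict[str, float] = {
    "fiber": 7.0,
    "folate": 280.0,
    "magnesium": 160.0,
    "potassium": 1450.0,
    "saturated_fat": 7.0,
    "protein": 33.0,
    "carbohydrate": 135.0,
    "vitamin_c": 55.0,
}

NUTRIENT_NOISE_SD: dict[str, float] = {
    "fiber": 1.2,
    "folate": 60.0,
    "magnesium": 20.0,
    "potassium": 180.0,
    "saturated_fat": 1.8,
    "protein": 6.0,
    "carbohydrate": 25.0,
    "vitamin_c": 15.0,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic-cohort generator.

    Defaults reproduce the study conditions: 818 enrolled adolescents,
    36/64 boy/girl split, a balanced urban/rural split, SES class
    proportions 0.32/0.40/0.28 (points drawn uniformly within each class
    band), and Table-anchored component medians and stratum multipliers.
    """

    n_participants: int = 818
    sex_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.36, "female": 0.64}
    )
    area_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"urban": 0.5, "rural": 0.5}
    )
    school_type_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"public": 0.8, "private": 0.2}
    )
    ses_class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.32, "medium": 0.40, "high": 0.28}
    )
    medians: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: TABLE1_MEDIANS
    )
    area_ratios: Mapping[str, float] = field(default_factory=lambda: AREA_RATIOS)
    ses_ratios: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: SES_RATIOS
    )
    sigma_b: float | Mapping[str, float] = 0.5
    sigma_w: float | Mapping[str, float] = 0.45
    zero_inflation: Mapping[str, float] = field(default_factory=dict)
    energy_density: Mapping[str, float] = field(default_factory=lambda: ENERGY_DENSITY)
    energy_basal: float = 650.0
    energy_noise_sd: float = 130.0
    nutrient_loadings: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: NUTRIENT_LOADINGS
    )
    nutrient_basal: Mapping[str, float] = field(default_factory=lambda: NUTRIENT_BASAL)
    nutrient_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: NUTRIENT_NOISE_SD
    )
    n_days: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ConfigError("n_participants must be positive")
        for name, props in (
            ("sex_proportions", self.sex_proportions),
            ("area_proportions", self.area_proportions),
            ("ses_class_proportions", self.ses_class_proportions),
            ("school_type_proportions", self.school_type_proportions),
        ):
            total = float(sum(props.values()))
            if abs(total - 1.0) > 1e-9 or any(p < 0 for p in props.values()):
                raise ConfigError(f"{name} must be nonnegative and sum to 1")
        for comp, by_sex in self.medians.items():
            if any(v < 0 for v in by_sex.values()):
                raise ConfigError(f"median for {comp} must be >= 0")
        for s in self._sigma_map(self.sigma_b).values():
            if s < 0:
                raise ConfigError("sigma_b must be >= 0")
        for s in self._sigma_map(self.sigma_w).values():
            if s < 0:
                raise ConfigError("sigma_w must be >= 0")
        if not 1 <= self.n_days <= 3:
            raise ConfigError("n_days must be 1..3")

    def _sigma_map(self, sigma: float | Mapping[str, float]) -> dict[str, float]:
        comps = list(self.medians)
        if isinstance(sigma, Mapping):
            return {c: float(sigma.get(c, 0.0)) for c in comps}
        return {c: float(sigma) for c in comps}


@dataclass(frozen=True)
class TrueParameters:
    """Ground truth recorded exactly as drawn.

    ``usual_intakes`` is participant x component (true usual intake T);
    ``multipliers`` records the per-component stratum multipliers after
    log-space normalisation.
    """

    usual_intakes: pd.DataFrame
    multipliers: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        self.usual_intakes.to_csv(path)


@dataclass(frozen=True)
class SyntheticCohort:
    participants: pd.DataFrame
    records: FoodRecordTable
    truth: TrueParameters

    def __iter__(self):  # allows: records, truth = cohort
        return iter((self.records, self.truth))


def _normalised_multipliers(
    raw: Mapping[str, float], proportions: Mapping[str, float]
) -> dict[str, float]:
    """Scale multipliers so the proportion-weighted mean log-multiplier is 0,
    keeping between-stratum ratios while preserving the overall median."""
    levels = list(proportions)
    logs = np.array([np.log(raw[lv]) for lv in levels])
    w = np.array([proportions[lv] for lv in levels])
    centred = logs - float(w @ logs)
    return {lv: float(np.exp(c)) for lv, c in zip(levels, centred)}


def _draw_categorical(rng, levels, probs, n):
    return rng.choice(np.array(levels, dtype=object), size=n, p=np.asarray(probs, dtype=float))


SES_BANDS = {"low": (10, 29), "medium": (30, 84), "high": (85, 100)}


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a synthetic cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    comps = list(config.medians)
    n_comp = len(comps)

    sex = _draw_categorical(
        rng, list(config.sex_proportions), list(config.sex_proportions.values()), n
    )
    area = _draw_categorical(
        rng, list(config.area_proportions), list(config.area_proportions.values()), n
    )
    school = _draw_categorical(
        rng,
        list(config.school_type_proportions),
        list(config.school_type_proportions.values()),
        n,
    )
    ses_class = _draw_categorical(
        rng,
        list(config.ses_class_proportions),
        list(config.ses_class_proportions.values()),
        n,
    )
    ses_points = np.empty(n, dtype=int)
    for cls, (lo, hi) in SES_BANDS.items():
        mask = ses_class == cls
        ses_points[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    age = rng.integers(13, 19, size=n).astype(float)

    participants = pd.DataFrame(
        {
            "participant_id": [f"P{i:05d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "area": area,
            "school_type": school,
            "ses_points": ses_points,
        }
    )

    sb = config._sigma_map(config.sigma_b)
    sw = config._sigma_map(config.sigma_w)

    # Per-component stratum multipliers, normalised to preserve sex medians.
    area_levels = list(config.area_proportions)
    ses_levels = list(config.ses_class_proportions)
    mult_rows = []
    area_mult: dict[str, dict[str, float]] = {}
    ses_mult: dict[str, dict[str, float]] = {}
    for c in comps:
        ratio = float(config.area_ratios.get(c, 1.0))
        raw_area = {"urban": 1.0, "rural": ratio}
        area_mult[c] = _normalised_multipliers(raw_area, config.area_proportions)
        low, med, high = config.ses_ratios.get(c, (1.0, 1.0, 1.0))
        raw_ses = {"low": low, "medium": med, "high": high}
        ses_mult[c] = _normalised_multipliers(raw_ses, config.ses_class_proportions)
        mult_rows.append(
            {
                "component": c,
                **{f"area_{lv}": area_mult[c][lv] for lv in area_levels},
                **{f"ses_{lv}": ses_mult[c][lv] for lv in ses_levels},
            }
        )

    base = np.empty((n, n_comp))
    for j, c in enumerate(comps):
        med = np.where(
            sex == "male",
            float(config.medians[c]["male"]),
            float(config.medians[c]["female"]),
        )
        am = np.vectorize(area_mult[c].get)(area).astype(float)
        sm = np.vectorize(ses_mult[c].get)(ses_class).astype(float)
        base[:, j] = med * am * sm

    z = rng.standard_normal((n, n_comp))
    sb_vec = np.array([sb[c] for c in comps])
    truth_T = base * np.exp(sb_vec[None, :] * z)

    # Optional zero inflation for episodically consumed foods (default off).
    for j, c in enumerate(comps):
        p0 = float(config.zero_inflation.get(c, 0.0))
        if p0 > 0:
            nonconsumer = rng.random(n) < p0
            truth_T[nonconsumer, j] = 0.0

    k = config.n_days
    sw_vec = np.array([sw[c] for c in comps])
    eps = rng.standard_normal((n, n_comp, k))
    daily = truth_T[:, :, None] * np.exp(
        sw_vec[None, :, None] * eps - (sw_vec**2)[None, :, None] / 2.0
    )

    kcal = np.array([float(config.energy_density.get(c, 0.0)) for c in comps])
    energy = (
        np.tensordot(daily, kcal, axes=([1], [0]))
        + config.energy_basal
        + rng.normal(0.0, config.energy_noise_sd, size=(n, k))
    )
    energy = np.clip(energy, 1.0, None)

    nutrients = list(config.nutrient_loadings)
    nut_vals = {}
    for nut in nutrients:
        load = np.array([float(config.nutrient_loadings[nut].get(c, 0.0)) for c in comps])
        vals = (
            np.tensordot(daily, load, axes=([1], [0]))
            + float(config.nutrient_basal.get(nut, 0.0))
            + rng.normal(0.0, float(config.nutrient_noise_sd.get(nut, 0.0)), size=(n, k))
        )
        nut_vals[nut] = np.clip(vals, 0.0, None)

    ids = np.repeat(participants["participant_id"].to_numpy(), k)
    days = np.tile(np.arange(1, k + 1), n)
    day_type = np.where(days == 3, "weekend", "weekday")
    data = {
        "participant_id": ids,
        "day": days,
        "day_type": day_type,
    }
    for j, c in enumerate(comps):
        data[c] = daily[:, j, :].reshape(-1)
    data[ENERGY_COL] = energy.reshape(-1)
    for nut in nutrients:
        data[nut] = nut_vals[nut].reshape(-1)
    records = FoodRecordTable(pd.DataFrame(data), tuple(comps), tuple(nutrients))

    truth = TrueParameters(
        usual_intakes=pd.DataFrame(
            truth_T, index=participants["participant_id"], columns=comps
        ),
        multipliers=pd.DataFrame(mult_rows).set_index("component"),
    )
    return SyntheticCohort(participants=participants, records=records, truth=truth)


def inject_energy_outliers(
    table: FoodRecordTable,
    fraction: float,
    magnitude: float,
    seed: int,
) -> tuple[FoodRecordTable, list]:
    """Scale the energy of a random fraction of participants by *magnitude*
    (alternating with 1/magnitude) and return the new table plus the
    injected ids.

    The fraction is capped at 0.05 so the 1st/99th-percentile outlier
    screen retains its meaning.
    """
    if not 0 <= fraction <= 0.05:
        raise ConfigError("outlier fraction must lie in [0, 0.05]")
    if magnitude <= 0:
        raise ConfigError("magnitude must be positive")
    if fraction == 0:
        return table, []
    rng = np.random.default_rng(seed)
    ids = np.array(table.participant_ids, dtype=object)
    n_inject = int(round(fraction * len(ids)))
    if n_inject == 0:
        return table, []
    chosen = rng.choice(ids, size=n_inject, replace=False)
    factors = {
        pid: (magnitude if i % 2 == 0 else 1.0 / magnitude)
        for i, pid in enumerate(chosen)
    }
    df = table.frame.copy()
    fac = df["participant_id"].map(factors).fillna(1.0)
    df[ENERGY_COL] = df[ENERGY_COL] * fac
    return FoodRecordTable(df, table.components, table.nutrients), list(chosen)
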