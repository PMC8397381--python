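"""Definition of the TCRAD index: components, directions, and banding rules.

The Traditional Costa Rican Adolescents Diet (TCRAD) score is a binary
adherence index over 14 food groups. Six groups are scored as healthy
(a point is earned at or above the sex-specific median intake) and eight
as unhealthy (a point is earned below the median, i.e. inverse scoring).
The total therefore ranges from 0 to 14 points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .errors import ConfigError

__all__ = [
    "Direction",
    "Sex",
    "ComponentSpec",
    "IndexDefinition",
    "ScoreCategoryRule",
    "SesRule",
    "DEFAULT_INDEX",
    "DEFAULT_CATEGORY_RULE",
    "DEFAULT_SES_RULE",
    "COMPONENT_LABELS",
]


class Direction(str, Enum):
    HEALTHY = "healthy"
    UNHEALTHY = "unhealthy"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


@dataclass(frozen=True)
class ComponentSpec:
    """One scored food group.

    Parameters
    ----------
    name : str
        Canonical snake_case identifier (e.g. ``"legumes"``).
    direction : Direction
        ``healthy`` components score 1 at/above the cutoff, ``unhealthy``
        components score 1 strictly below it.
    """

    name: str
    direction: Direction

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction(self.direction))


@dataclass(frozen=True)
class IndexDefinition:
    """An ordered set of components defining a binary adherence index."""

    components: tuple[ComponentSpec, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ConfigError("component names must be unique within an index")

    @property
    def max_score(self) -> int:
        return len(self.components)

    @property
    def component_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)

    @property
    def healthy_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components if c.direction is Direction.HEALTHY)

    @property
    def unhealthy_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components if c.direction is Direction.UNHEALTHY)

    def direction_of(self, name: str) -> Direction:
        for c in self.components:
            if c.name == name:
                return c.direction
        raise KeyError(name)


# Canonical component identifiers mapped to the human-readable food-group
# labels used in reports. "Legumes" covers beans, lentils and chickpeas;
# "tortillas" is corn tortilla; "refined_bread" covers breads and cookies.
COMPONENT_LABELS: dict[str, str] = {
    "legumes": "Legumes",
    "vegetables": "Vegetables",
    "fruits": "Fruits",
    "vegetable_oils": "Vegetable oils",
    "dairy": "Dairy",
    "tortillas": "Tortillas",
    "white_rice": "White rice",
    "red_meat": "Red/processed meat",
    "solid_fats": "Solid fats",
    "desserts": "Desserts",
    "sugary_drinks": "Sugary drinks",
    "snacks": "Snacks",
    "fast_food": "Fast food",
    "refined_bread": "Refined bread",
}

_HEALTHY = ("legumes", "vegetables", "fruits", "vegetable_oils", "dairy", "tortillas")
_UNHEALTHY = (
    "white_rice",
    "red_meat",
    "solid_fats",
    "desserts",
    "sugary_drinks",
    "snacks",
    "fast_food",
    "refined_bread",
)

DEFAULT_INDEX = IndexDefinition(
    components=tuple(
        [ComponentSpec(n, Direction.HEALTHY) for n in _HEALTHY]
        + [ComponentSpec(n, Direction.UNHEALTHY) for n in _UNHEALTHY]
    )
)


@dataclass(frozen=True)
class ScoreCategoryRule:
    """Score bands: low (< moderate_min), moderate (moderate_min..high_min-1),
    high (high_min..max_score). Defaults reproduce low <6, moderate 6-7,
    high 8-14."""

    moderate_min: int = 6
    high_min: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.moderate_min < self.high_min:
            raise ConfigError("category bands must satisfy 0 < moderate_min < high_min")

    def categorize(self, score: int, max_score: int = 14) -> str:
        if not 0 <= score <= max_score:
            raise ValueError(f"score {score} outside [0, {max_score}]")
        if score < self.moderate_min:
            return "low"
        if score < self.high_min:
            return "moderate"
        return "high"


@dataclass(frozen=True)
class SesRule:
    """Socioeconomic-status bands on the 0-100 point household score:
    low <= low_max, high >= high_min, medium in between."""

    low_max: int = 29
    high_min: int = 85

    def __post_init__(self) -> None:
        if not 0 <= self.low_max < self.high_min <= 100:
            raise ConfigError("SES bands must satisfy 0 <= low_max < high_min <= 100")

    def classify(self, points: int) -> str:
        if not 0 <= points <= 100:
            raise ValueError(f"SES points {points} outside [0, 100]")
        if points <= self.low_max:
            return "low"
        if points >= self.high_min:
            return "high"
        return "medium"


DEFAULT_CATEGORY_RULE = ScoreCategoryRule()
DEFAULT_SES_RULE = SesRule()
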