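"""Structure of the second-order well-being measurement model.

A single second-order factor (the Well-Being Index, WBI) loads on four
first-order components — Lifestyle habits (L), Social context (S),
Emotional status (E) and Mental skills (MS) — and each of the 14 observed
indicators loads on exactly one component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: Canonical factor order used everywhere (matrices, serialisation).
FACTORS: tuple[str, ...] = ("L", "S", "E", "MS")

FACTOR_LABELS = {
    "L": "Lifestyle habits",
    "S": "Social context",
    "E": "Emotional status",
    "MS": "Mental skills",
}

#: Canonical indicator -> first-order factor mapping. Five lifestyle
#: indicators, four social, three emotional, two mental-skill.
DEFAULT_INDICATOR_MAP: dict[str, str] = {
    "physical_wellbeing": "L",
    "autonomy": "L",
    "financial_resources": "L",
    "kidmed": "L",
    "paqc": "L",
    "parent_relations": "S",
    "peers": "S",
    "school_environment": "S",
    "bullying": "S",
    "psychological_wellbeing": "E",
    "moods_emotions": "E",
    "self_perception": "E",
    "stroop_interference": "MS",
    "school_performance": "MS",
}

INDICATORS: tuple[str, ...] = tuple(DEFAULT_INDICATOR_MAP)


@dataclass(frozen=True)
class ModelSpec:
    """Indicator-to-factor structure of the hierarchical measurement model.

    Identification convention: the second-order factor variance is fixed to
    1 and every first-order factor is kept at unit total variance (its
    disturbance variance is ``1 - beta**2``), so all reported loadings are
    standardized.
    """

    indicator_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_INDICATOR_MAP)
    )

    def __post_init__(self) -> None:
        if not self.indicator_map:
            raise ValueError("indicator_map must not be empty")

    @property
    def indicators(self) -> tuple[str, ...]:
        return tuple(self.indicator_map)

    @property
    def factors(self) -> tuple[str, ...]:
        """Factors in canonical order (custom factor names keep first-appearance order)."""
        used = list(dict.fromkeys(self.indicator_map.values()))
        if set(used) <= set(FACTORS):
            return tuple(f for f in FACTORS if f in used)
        return tuple(used)

    @property
    def n_indicators(self) -> int:
        return len(self.indicator_map)

    def factor_of(self, indicator: str) -> str:
        return self.indicator_map[indicator]

    def indicators_of(self, factor: str) -> tuple[str, ...]:
        return tuple(j for j, f in self.indicator_map.items() if f == factor)

    def factor_index(self, indicator: str) -> int:
        return FACTORS.index(self.indicator_map[indicator])

    # -- serialisation -----------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({"indicator_map": self.indicator_map}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(indicator_map=dict(data["indicator_map"]))


DEFAULT_MODEL = ModelSpec()
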