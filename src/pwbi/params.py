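"""Population parameters of the generating model for synthetic cohorts.

The defaults encode the study conditions the package emulates: a cohort of
early adolescents (mean age 12, SD 0.81 years, 52% male) whose 14 scored
indicators arise from the second-order well-being factor model, with the
published standardized second-order loadings (0.954 lifestyle, 0.972 social,
0.949 emotional, -0.1417 mental skills) and first-order loadings of 0.60
except for the three weak indicators (diet, physical activity, executive
function) at 0.20.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import yaml

from .model import FACTORS, INDICATORS

#: Standardized second-order loadings (component on the global WBI factor).
DEFAULT_SECOND_ORDER = {"L": 0.954, "S": 0.972, "E": 0.949, "MS": -0.1417}

#: Standardized first-order loadings (indicator on its component). 0.60 for
#: all indicators except the three with weak published coefficients.
DEFAULT_FIRST_ORDER = {
    j: (0.20 if j in ("kidmed", "paqc", "stroop_interference") else 0.60)
    for j in INDICATORS
}

#: Native-scale location/scale per indicator, chosen so that the latent
#: Gaussian draws essentially never leave the instrument's admissible range
#: (KIDSCREEN dimension scores 0-100, KIDMED 0-12, PAQ-C 1-5, school 1-10;
#: Stroop interference is unbounded).
DEFAULT_INDICATOR_MEANS = {
    **{j: 65.0 for j in INDICATORS if j not in
       ("kidmed", "paqc", "stroop_interference", "school_performance")},
    "kidmed": 6.0,
    "paqc": 2.9,
    "stroop_interference": 1.5,
    "school_performance": 6.8,
}
DEFAULT_INDICATOR_SDS = {
    **{j: 12.0 for j in INDICATORS if j not in
       ("kidmed", "paqc", "stroop_interference", "school_performance")},
    "kidmed": 2.2,
    "paqc": 0.75,
    "stroop_interference": 6.5,
    "school_performance": 1.3,
}

DEFAULT_DEMOGRAPHICS = {"prop_male": 0.52, "age_mean": 12.0, "age_sd": 0.81}

#: Per-reason exclusion probabilities matching the enrolment arithmetic
#: 57 / 169 / 185 out of 1,659.
DEFAULT_EXCLUSION_PROBS = {
    "diagnosed_condition": 57 / 1659,
    "no_consent": 169 / 1659,
    "incomplete": 185 / 1659,
}


@dataclass(frozen=True)
class PopulationParams:
    """Generating parameters for a synthetic adolescent cohort."""

    second_order_loadings: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SECOND_ORDER)
    )
    first_order_loadings: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FIRST_ORDER)
    )
    indicator_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INDICATOR_MEANS)
    )
    indicator_sds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INDICATOR_SDS)
    )
    demographics: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DEMOGRAPHICS)
    )
    exclusion_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXCLUSION_PROBS)
    )

    def validate(self) -> None:
        for k in FACTORS:
            b = self.second_order_loadings[k]
            if not -1.0 <= b <= 1.0:
                raise ValueError(f"second-order loading for {k} outside [-1, 1]: {b}")
        for j in INDICATORS:
            lam = self.first_order_loadings[j]
            if not -1.0 <= lam <= 1.0:
                raise ValueError(
                    f"first-order loading for {j} implies negative residual "
                    f"variance: {lam}"
                )
            if self.indicator_sds[j] <= 0:
                raise ValueError(f"indicator SD for {j} must be > 0")
        if not 0.0 <= self.demographics["prop_male"] <= 1.0:
            raise ValueError("prop_male must be in [0, 1]")
        for reason, p in self.exclusion_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"exclusion probability {reason} outside [0, 1]: {p}")
        if not math.isfinite(self.demographics["age_sd"]) or self.demographics["age_sd"] < 0:
            raise ValueError("age_sd must be a nonnegative finite number")

    def with_overrides(self, **kwargs) -> "PopulationParams":
        """Return a copy with dict-valued fields shallowly updated."""
        updates = {}
        for name, override in kwargs.items():
            current = getattr(self, name)
            if isinstance(current, dict) and isinstance(override, dict):
                merged = dict(current)
                merged.update(override)
                updates[name] = merged
            else:
                updates[name] = override
        return replace(self, **updates)

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "second_order_loadings": dict(self.second_order_loadings),
            "first_order_loadings": dict(self.first_order_loadings),
            "indicator_means": dict(self.indicator_means),
            "indicator_sds": dict(self.indicator_sds),
            "demographics": dict(self.demographics),
            "exclusion_probs": dict(self.exclusion_probs),
        }

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "PopulationParams":
        base = cls()
        return base.with_overrides(**{k: v for k, v in data.items() if v is not None})

    @classmethod
    def from_yaml(cls, path) -> "PopulationParams":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
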