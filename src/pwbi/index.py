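"""Personalised Well-Being Index: lambda/theta-weighted factor scores.

The per-student raw index is the Bartlett-style weighted sum

    PWBI = sum_j (lambda_j / theta_j) * (x_j - mean(x_j)) / sd(x_j)

over the 14 indicators, with loadings and residual variances taken from the
fitted (standardized) measurement model and means/SDs from a reference
cohort. Cohort scores are min-max rescaled to 0-100; the observed extremes
are persisted so new students can be placed on an existing cohort's scale.
Component sub-scores restrict the sum to one component's indicators and are
rescaled per component; the component composite additionally applies the
second-order loadings to the standardized component scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DEFAULT_MODEL, ModelSpec
from .sem import ParameterSet


@dataclass
class CohortStats:
    """Reference means/SDs per indicator, and persisted rescaling extremes."""

    means: dict[str, float]
    sds: dict[str, float]
    scale_min: dict[str, float] = field(default_factory=dict)
    scale_max: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_indicators(cls, indicators: pd.DataFrame,
                        spec: ModelSpec = DEFAULT_MODEL) -> "CohortStats":
        data = indicators[list(spec.indicators)].astype(float).dropna()
        means = data.mean().to_dict()
        sds = data.std(ddof=1).to_dict()
        for j, s in sds.items():
            if not s > 0:
                raise ValueError(f"indicator {j} has zero variance in reference cohort")
        return cls(means=means, sds=sds)

    def to_dict(self) -> dict:
        return {
            "means": dict(self.means),
            "sds": dict(self.sds),
            "scale_min": dict(self.scale_min),
            "scale_max": dict(self.scale_max),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CohortStats":
        return cls(
            means=dict(data["means"]), sds=dict(data["sds"]),
            scale_min=dict(data.get("scale_min", {})),
            scale_max=dict(data.get("scale_max", {})),
        )


@dataclass
class WellBeingReport:
    """Per-student index report: global score, components, contributions."""

    student_id: str
    pwbi_raw: float
    pwbi_scaled: float
    component_raw: dict[str, float]
    component_scores: dict[str, float]
    composite: float
    indicator_contributions: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "student_id": self.student_id,
            "pwbi_raw": self.pwbi_raw,
            "pwbi_scaled": self.pwbi_scaled,
            "component_raw": dict(self.component_raw),
            "component_scores": dict(self.component_scores),
            "composite": self.composite,
            "indicator_contributions": dict(self.indicator_contributions),
        }


def index_weights(params: ParameterSet, spec: ModelSpec = DEFAULT_MODEL) -> dict[str, float]:
    """Per-indicator weights lambda_j / theta_j from a fitted solution."""
    weights = {}
    for j in spec.indicators:
        theta = params.residuals[j]
        if theta <= 0:
            raise ValueError(f"nonpositive residual variance for {j}")
        weights[j] = params.loadings[j] / theta
    return weights


def pwbi_raw(
    indicators: dict[str, float],
    stats: CohortStats,
    params: ParameterSet,
    spec: ModelSpec = DEFAULT_MODEL,
    subset: tuple[str, ...] | None = None,
) -> tuple[float, dict[str, float]]:
    """Raw index for one student: weighted sum of standardized indicators.

    Returns the raw score and the per-indicator signed contributions
    (lambda_j/theta_j * z_j), which sum to it. Raises KeyError on a missing
    indicator (students with incomplete indicator vectors are skipped at
    cohort level, mirroring the complete-case rule).
    """
    weights = index_weights(params, spec)
    names = subset if subset is not None else spec.indicators
    contributions = {}
    for j in names:
        x = indicators[j]
        if x is None or (isinstance(x, float) and np.isnan(x)):
            raise KeyError(f"missing indicator {j}")
        sd = stats.sds[j]
        if sd <= 0:
            raise ValueError(f"nonpositive reference SD for {j}")
        z = (float(x) - stats.means[j]) / sd
        contributions[j] = weights[j] * z
    return float(sum(contributions.values())), contributions


def rescale(
    raw: np.ndarray,
    low: float | None = None,
    high: float | None = None,
) -> tuple[np.ndarray, float, float]:
    """Min-max rescale raw scores to 0-100: 100 * (x - min) / (max - min).

    Cohort extremes are used unless reference ``low``/``high`` are given
    (values beyond a stored reference range are clipped). A degenerate
    all-equal cohort maps to the midpoint 50 with a warning.
    """
    raw = np.asarray(raw, dtype=float)
    lo = float(np.min(raw)) if low is None else float(low)
    hi = float(np.max(raw)) if high is None else float(high)
    if hi == lo:
        warnings.warn("degenerate rescaling: all raw scores equal; mapping to 50")
        return np.full(raw.shape, 50.0), lo, hi
    scaled = 100.0 * (raw - lo) / (hi - lo)
    return np.clip(scaled, 0.0, 100.0), lo, hi


def wbi_composite(component_scores: dict[str, float], betas: dict[str, float]) -> float:
    """Second-order composite: sum of beta_k * component_k."""
    missing = [k for k in betas if k not in component_scores]
    if missing:
        raise KeyError(f"missing component scores: {missing}")
    return float(sum(betas[k] * component_scores[k] for k in betas))


def score_index(
    indicators: pd.DataFrame,
    params: ParameterSet,
    stats: CohortStats | None = None,
    spec: ModelSpec = DEFAULT_MODEL,
) -> tuple[pd.DataFrame, CohortStats, list[str]]:
    """Compute raw and 0-100 indices for a cohort of indicator vectors.

    When ``stats`` carries persisted rescaling extremes the cohort is scored
    against that reference scale; otherwise the observed cohort extremes
    define the 0-100 range and are stored in the returned ``CohortStats``.
    Students with any missing indicator are skipped (returned as the third
    element).

    Returns ``(scores, stats, skipped_ids)`` where ``scores`` has per-student
    rows: ``pwbi_raw``, ``pwbi_scaled``, per-component raw and 0-100 scores,
    and the beta-weighted composite of standardized component scores.
    """
    cols = list(spec.indicators)
    data = indicators.set_index("student_id")[cols].astype(float)
    complete = data.dropna()
    skipped = [str(s) for s in data.index[data.isna().any(axis=1)]]
    if stats is None:
        stats = CohortStats.from_indicators(indicators, spec)
    reference = bool(stats.scale_min)

    weights = index_weights(params, spec)
    w = np.array([weights[j] for j in cols])
    mu = np.array([stats.means[j] for j in cols])
    sd = np.array([stats.sds[j] for j in cols])
    Z = (complete.to_numpy() - mu) / sd
    contrib = Z * w
    raw = contrib.sum(axis=1)

    out = pd.DataFrame({"student_id": complete.index.astype(str), "pwbi_raw": raw})
    scaled, lo, hi = rescale(
        raw,
        stats.scale_min.get("pwbi") if reference else None,
        stats.scale_max.get("pwbi") if reference else None,
    )
    out["pwbi_scaled"] = scaled
    stats.scale_min["pwbi"], stats.scale_max["pwbi"] = lo, hi

    comp_std = {}
    for k in spec.factors:
        jdx = [cols.index(j) for j in spec.indicators_of(k)]
        comp_raw = contrib[:, jdx].sum(axis=1)
        out[f"{k}_raw"] = comp_raw
        comp_scaled, lo_k, hi_k = rescale(
            comp_raw,
            stats.scale_min.get(k) if reference else None,
            stats.scale_max.get(k) if reference else None,
        )
        out[f"{k}_scaled"] = comp_scaled
        stats.scale_min[k], stats.scale_max[k] = lo_k, hi_k
        s = comp_raw.std(ddof=1) if len(comp_raw) > 1 else 1.0
        comp_std[k] = (comp_raw - comp_raw.mean()) / s if s > 0 else comp_raw * 0.0

    out["composite"] = sum(
        params.betas[k] * comp_std[k] for k in spec.factors
    )
    return out.reset_index(drop=True), stats, skipped


def student_reports(
    indicators: pd.DataFrame,
    params: ParameterSet,
    stats: CohortStats | None = None,
    spec: ModelSpec = DEFAULT_MODEL,
) -> list[WellBeingReport]:
    """Per-student reports with indicator-level contributions."""
    scores, stats, skipped = score_index(indicators, params, stats, spec)
    by_id = indicators.set_index("student_id")
    reports = []
    for _, row in scores.iterrows():
        sid = row["student_id"]
        ind = by_id.loc[sid, list(spec.indicators)].astype(float).to_dict()
        _, contributions = pwbi_raw(ind, stats, params, spec)
        reports.append(WellBeingReport(
            student_id=str(sid),
            pwbi_raw=float(row["pwbi_raw"]),
            pwbi_scaled=float(row["pwbi_scaled"]),
            component_raw={k: float(row[f"{k}_raw"]) for k in spec.factors},
            component_scores={k: float(row[f"{k}_scaled"]) for k in spec.factors},
            composite=float(row["composite"]),
            indicator_contributions={j: float(c) for j, c in contributions.items()},
        ))
    return reports


def reports_to_json(reports: list[WellBeingReport], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=2, sort_keys=True)
        fh.write("\n")
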