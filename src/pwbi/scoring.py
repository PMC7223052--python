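"""Convert raw instrument responses into the 14 observed indicator scores.

Each scorer implements the published convention of its instrument:

* KIDSCREEN-52 dimensions: reverse-key negatively worded items, average the
  items of a dimension, and map the mean linearly from [1, 5] to [0, 100].
  Up to two missing items per dimension are tolerated (mean imputation);
  more make the dimension missing.
* KIDMED: +1 per affirmed diet-positive item, -1 per affirmed negative
  item, floored at zero so the index spans exactly 0-12.
* PAQ-C: arithmetic mean of the nine five-point items.
* Stroop interference: colour-word score minus the predicted score
  word*colour/(word+colour) (Golden's convention); higher values mean
  better executive function.
* School performance: mean of the three subject grades.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
import pandas as pd

from .instruments import (
    GRADE_COLS,
    KIDMED_COLS,
    KIDMED_NEGATIVE,
    KIDSCREEN_COLS,
    KIDSCREEN_DIMENSIONS,
    KIDSCREEN_MAX_MISSING,
    KIDSCREEN_REVERSED,
    PAQC_COLS,
    STROOP_COLS,
)
from .model import INDICATORS


@dataclass
class IndicatorVector:
    """The 14 observed variables feeding the measurement model.

    KIDSCREEN dimensions are 0-100 scores, ``kidmed`` an integer 0-12,
    ``paqc`` a 1-5 mean, ``stroop_interference`` unbounded, and
    ``school_performance`` a 1-10 mean. Missing values are NaN.
    """

    physical_wellbeing: float
    autonomy: float
    financial_resources: float
    kidmed: float
    paqc: float
    parent_relations: float
    peers: float
    school_environment: float
    bullying: float
    psychological_wellbeing: float
    moods_emotions: float
    self_perception: float
    stroop_interference: float
    school_performance: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @property
    def complete(self) -> bool:
        return all(not math.isnan(v) for v in self.as_dict().values())


def _check_range(values, low, high, instrument):
    arr = np.asarray(values, dtype=float)
    bad = (arr < low) | (arr > high)
    if np.any(bad & ~np.isnan(arr)):
        raise ValueError(
            f"{instrument}: response outside {low}..{high}: "
            f"{arr[bad & ~np.isnan(arr)][0]!r}"
        )
    return arr


def score_kidscreen(
    items: Sequence[float],
    reversed_items: frozenset[int] = KIDSCREEN_REVERSED,
    max_missing: int = KIDSCREEN_MAX_MISSING,
) -> dict[str, float]:
    """Score the 52 KIDSCREEN items into ten 0-100 dimension scores.

    ``items`` holds responses 1..5 in form order; missing responses are NaN.
    """
    arr = _check_range(items, 1, 5, "kidscreen")
    if arr.shape != (52,):
        raise ValueError(f"kidscreen: expected 52 items, got {arr.shape}")
    keyed = arr.copy()
    rev = [i - 1 for i in reversed_items]
    keyed[rev] = 6.0 - keyed[rev]
    out: dict[str, float] = {}
    for dim, item_nums in KIDSCREEN_DIMENSIONS.items():
        vals = keyed[[i - 1 for i in item_nums]]
        n_missing = int(np.isnan(vals).sum())
        if n_missing > max_missing:
            out[dim] = float("nan")
        else:
            out[dim] = (float(np.nanmean(vals)) - 1.0) / 4.0 * 100.0
    return out


def score_kidmed(items: Sequence, floor_at_zero: bool = True) -> int:
    """Mediterranean-diet index from the 16 yes/no items.

    Affirmed positives add one point, affirmed negatives subtract one; the
    paper-stated 0-12 range is enforced by flooring negative totals at zero
    (set ``floor_at_zero=False`` for the raw -4..12 instrument range).
    """
    if len(items) != 16:
        raise ValueError(f"kidmed: expected 16 items, got {len(items)}")
    total = 0
    for i, v in enumerate(items, start=1):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"kidmed: item {i} missing")
        affirmed = bool(v)
        if affirmed:
            total += -1 if i in KIDMED_NEGATIVE else 1
    return max(total, 0) if floor_at_zero else total


def score_paqc(items: Sequence[float]) -> float:
    """Physical-activity score: mean of nine 1..5 items."""
    arr = _check_range(items, 1, 5, "paqc")
    if arr.shape != (9,):
        raise ValueError(f"paqc: expected 9 items, got {arr.shape}")
    if np.isnan(arr).any():
        raise ValueError("paqc: missing item")
    return float(arr.mean())


def score_stroop(word: float, color: float, color_word: float) -> float:
    """Stroop interference: colour-word count minus Golden's predicted score.

    ``interference = CW - W*C/(W+C)``; positive values mean the child named
    incongruent colour-words faster than the single-task baselines predict.
    """
    if word < 0 or color < 0 or color_word < 0:
        raise ValueError("stroop: counts must be nonnegative")
    if word + color <= 0:
        raise ValueError("stroop: word + color baselines must be positive")
    predicted = word * color / (word + color)
    return float(color_word - predicted)


def score_school(grades: Sequence[float]) -> float:
    """School performance: mean of the three subject grades (1..10)."""
    arr = _check_range(grades, 1, 10, "school")
    if arr.shape != (3,):
        raise ValueError(f"school: expected 3 grades, got {arr.shape}")
    if np.isnan(arr).any():
        raise ValueError("school: missing grade")
    return float(arr.mean())


def _get(row, cols) -> np.ndarray:
    return np.asarray(
        [np.nan if pd.isna(row[c]) else float(row[c]) for c in cols], dtype=float
    )


def score_all(record, kidmed_floor: bool = True) -> IndicatorVector:
    """Score one student record (mapping or pandas row) into indicators.

    Instruments with missing responses yield NaN fields; out-of-range
    responses raise with the instrument named.
    """
    ks = score_kidscreen(_get(record, KIDSCREEN_COLS))

    km_raw = _get(record, KIDMED_COLS)
    if np.isnan(km_raw).any():
        kidmed = float("nan")
    else:
        kidmed = float(score_kidmed(km_raw.astype(bool), floor_at_zero=kidmed_floor))

    pq = _get(record, PAQC_COLS)
    paqc = float("nan") if np.isnan(pq).any() else score_paqc(pq)

    st = _get(record, STROOP_COLS)
    stroop = (
        float("nan") if np.isnan(st).any() else score_stroop(st[0], st[1], st[2])
    )

    gr = _get(record, GRADE_COLS)
    school = float("nan") if np.isnan(gr).any() else score_school(gr)

    return IndicatorVector(
        physical_wellbeing=ks["physical_wellbeing"],
        autonomy=ks["autonomy"],
        financial_resources=ks["financial_resources"],
        kidmed=kidmed,
        paqc=paqc,
        parent_relations=ks["parent_relations"],
        peers=ks["peers"],
        school_environment=ks["school_environment"],
        bullying=ks["bullying"],
        psychological_wellbeing=ks["psychological_wellbeing"],
        moods_emotions=ks["moods_emotions"],
        self_perception=ks["self_perception"],
        stroop_interference=stroop,
        school_performance=school,
    )


def score_cohort(cohort: pd.DataFrame, kidmed_floor: bool = True) -> pd.DataFrame:
    """Vectorised scoring of a whole cohort.

    Returns a frame with ``student_id`` plus the 14 indicator columns in
    canonical order; unscorable instruments yield NaN.
    """
    ks = cohort[list(KIDSCREEN_COLS)].astype(float).to_numpy()
    _check_range(ks, 1, 5, "kidscreen")
    keyed = ks.copy()
    rev = [i - 1 for i in KIDSCREEN_REVERSED]
    keyed[:, rev] = 6.0 - keyed[:, rev]

    out = pd.DataFrame({"student_id": cohort["student_id"].to_numpy()})
    for dim, item_nums in KIDSCREEN_DIMENSIONS.items():
        block = keyed[:, [i - 1 for i in item_nums]]
        n_missing = np.isnan(block).sum(axis=1)
        with np.errstate(invalid="ignore"):
            means = np.nanmean(
                np.where(n_missing[:, None] <= KIDSCREEN_MAX_MISSING, block, np.nan),
                axis=1,
            )
        out[dim] = (means - 1.0) / 4.0 * 100.0

    km = cohort[list(KIDMED_COLS)].astype(float).to_numpy()
    signs = np.array([-1 if i in KIDMED_NEGATIVE else 1 for i in range(1, 17)])
    km_total = (km * signs).sum(axis=1)  # NaN propagates for missing items
    if kidmed_floor:
        km_total = np.maximum(km_total, 0)
    out["kidmed"] = km_total

    pq = cohort[list(PAQC_COLS)].astype(float).to_numpy()
    _check_range(pq, 1, 5, "paqc")
    out["paqc"] = pq.mean(axis=1)

    w, c, cw = (cohort[col].astype(float).to_numpy() for col in STROOP_COLS)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["stroop_interference"] = cw - w * c / (w + c)

    gr = cohort[list(GRADE_COLS)].astype(float).to_numpy()
    _check_range(gr, 1, 10, "school")
    out["school_performance"] = gr.mean(axis=1)

    return out[["student_id", *INDICATORS]]
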