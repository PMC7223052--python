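"""Seeded synthetic adolescent cohorts with the assumed latent structure.

Generation follows the hierarchical factor model top-down: a standard-normal
global well-being score per student, component scores ``beta_k * WBI +
disturbance``, standardized indicator draws ``lambda_j * component +
residual``, each mapped to its native instrument scale and then inverted
through the scoring conventions back to item-level responses. Item
discretisation uses the coarsest grid each instrument allows (the item mean
grid for Likert scales, integers for counts), so re-scoring a generated
record recovers the intended indicator value up to discretisation error.

Exclusion mechanisms (no consent, diagnosed condition, incomplete
questionnaires) can be injected either stochastically with per-reason
probabilities or deterministically with exact counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .instruments import (
    GRADE_COLS,
    ITEM_COLS,
    KIDMED_COLS,
    KIDMED_NEGATIVE,
    KIDSCREEN_COLS,
    KIDSCREEN_DIMENSIONS,
    KIDSCREEN_REVERSED,
    PAQC_COLS,
    STROOP_COLS,
)
from .model import DEFAULT_MODEL, INDICATORS, ModelSpec
from .params import PopulationParams

#: Fixed Stroop single-task baselines used when inverting the interference
#: score into a colour-word count (word and colour-naming raw scores).
STROOP_WORD_BASELINE = 100
STROOP_COLOR_BASELINE = 75
_STROOP_PREDICTED = (
    STROOP_WORD_BASELINE * STROOP_COLOR_BASELINE
    / (STROOP_WORD_BASELINE + STROOP_COLOR_BASELINE)
)

META_COLS = ("student_id", "age", "sex", "consent", "diagnosed_condition")
COHORT_COLS = META_COLS + ITEM_COLS

_KIDMED_POSITIVE = [i for i in range(1, 17) if i not in KIDMED_NEGATIVE]


def _distribute(total: np.ndarray, k: int, low: int, high: int) -> np.ndarray:
    """Spread integer row totals over k items as evenly as possible.

    Returns an (n, k) integer array with row sums equal to ``total`` (after
    clipping totals into [k*low, k*high]); the first ``total mod k`` items
    carry the extra unit.
    """
    total = np.clip(np.asarray(total, dtype=int), k * low, k * high)
    base = total // k
    remainder = total - base * k
    items = base[:, None] + (np.arange(k)[None, :] < remainder[:, None])
    return items


def latent_indicator_draws(
    params: PopulationParams, n: int, rng: np.random.Generator,
    spec: ModelSpec = DEFAULT_MODEL,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (wbi, indicators) from the second-order model on native scales.

    ``indicators`` is an (n, 14) array in canonical indicator order; the
    global factor scores are returned for factor-score validity checks.
    """
    wbi = rng.standard_normal(n)
    components = {}
    for k in spec.factors:
        beta = params.second_order_loadings[k]
        psi = 1.0 - beta**2
        if psi < 0:
            raise ValueError(f"second-order loading for {k} exceeds 1 in magnitude")
        components[k] = beta * wbi + np.sqrt(psi) * rng.standard_normal(n)
    x = np.empty((n, len(spec.indicators)))
    for j, name in enumerate(spec.indicators):
        lam = params.first_order_loadings[name]
        resid = 1.0 - lam**2
        if resid < 0:
            raise ValueError(f"loading for {name} implies negative residual variance")
        z = lam * components[spec.factor_of(name)] + np.sqrt(resid) * rng.standard_normal(n)
        x[:, j] = params.indicator_means[name] + params.indicator_sds[name] * z
    return wbi, x


def _back_map(ind: dict[str, np.ndarray], n: int, rng: np.random.Generator) -> dict:
    """Invert indicator values into item-level responses."""
    cols: dict[str, np.ndarray] = {}

    # KIDSCREEN: per dimension, spread the implied item-mean over the items.
    for dim, item_nums in KIDSCREEN_DIMENSIONS.items():
        k = len(item_nums)
        score = np.clip(ind[dim], 0.0, 100.0)
        target_sum = np.rint((1.0 + score / 25.0) * k)
        items = _distribute(target_sum, k, 1, 5)
        for pos, item_num in enumerate(item_nums):
            vals = items[:, pos]
            if item_num in KIDSCREEN_REVERSED:
                vals = 6 - vals
            cols[f"ks{item_num:02d}"] = vals

    # KIDMED: affirm as many diet-positive items as the target index.
    km_target = np.clip(np.rint(ind["kidmed"]), 0, 12).astype(int)
    for i in range(1, 17):
        if i in KIDMED_NEGATIVE:
            cols[f"km{i:02d}"] = np.zeros(n, dtype=int)
        else:
            rank = _KIDMED_POSITIVE.index(i)
            cols[f"km{i:02d}"] = (rank < km_target).astype(int)

    paqc_sum = np.rint(np.clip(ind["paqc"], 1.0, 5.0) * 9)
    pq_items = _distribute(paqc_sum, 9, 1, 5)
    for pos, col in enumerate(PAQC_COLS):
        cols[col] = pq_items[:, pos]

    cols["stroop_word"] = np.full(n, STROOP_WORD_BASELINE, dtype=int)
    cols["stroop_color"] = np.full(n, STROOP_COLOR_BASELINE, dtype=int)
    cols["stroop_color_word"] = np.maximum(
        np.rint(ind["stroop_interference"] + _STROOP_PREDICTED), 0
    ).astype(int)

    grade_sum = np.rint(np.clip(ind["school_performance"], 1.0, 10.0) * 3)
    grades = _distribute(grade_sum, 3, 1, 10)
    for pos, col in enumerate(GRADE_COLS):
        cols[col] = grades[:, pos]

    return cols


def generate_cohort(
    params: PopulationParams,
    n: int,
    seed: int,
    spec: ModelSpec = DEFAULT_MODEL,
    return_latent: bool = False,
):
    """Generate ``n`` synthetic student records (deterministic given seed).

    With ``return_latent=True`` also returns the true global well-being
    factor scores, for validity studies of the computed index.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    params.validate()
    rng = np.random.default_rng(seed)

    wbi, x = latent_indicator_draws(params, n, rng, spec)
    ind = {name: x[:, j] for j, name in enumerate(spec.indicators)}

    age = np.clip(
        rng.normal(params.demographics["age_mean"], params.demographics["age_sd"], n),
        10.0, 14.0,
    ).round(1)
    sex = np.where(rng.random(n) < params.demographics["prop_male"], "M", "F")

    data: dict[str, object] = {
        "student_id": [f"S{i + 1:05d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "consent": np.ones(n, dtype=bool),
        "diagnosed_condition": np.zeros(n, dtype=bool),
    }
    data.update(_back_map(ind, n, rng))
    cohort = pd.DataFrame(data, columns=list(COHORT_COLS))
    for col in ITEM_COLS:
        cohort[col] = cohort[col].astype("Int64")
    if return_latent:
        return cohort, wbi
    return cohort


# ---------------------------------------------------------------------------
# Exclusion mechanisms
# ---------------------------------------------------------------------------

#: Questionnaire item columns a study coordinator would flag as "not filled
#: out completely" (per-student tests and grades are recorded separately).
_QUESTIONNAIRE_COLS = KIDSCREEN_COLS + KIDMED_COLS + PAQC_COLS


def inject_exclusions(
    cohort: pd.DataFrame, params: PopulationParams, seed: int
) -> pd.DataFrame:
    """Stochastically flag students for exclusion (independent draws).

    Each reason is drawn independently per student, so a record may carry
    several disqualifiers; precedence is resolved downstream by the
    inclusion filter. Incomplete questionnaires are materialised by blanking
    one to three randomly chosen questionnaire items.
    """
    for reason, p in params.exclusion_probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"exclusion probability {reason} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    n = len(out)
    diagnosed = rng.random(n) < params.exclusion_probs["diagnosed_condition"]
    no_consent = rng.random(n) < params.exclusion_probs["no_consent"]
    incomplete = rng.random(n) < params.exclusion_probs["incomplete"]
    out["diagnosed_condition"] = out["diagnosed_condition"].to_numpy() | diagnosed
    out["consent"] = out["consent"].to_numpy() & ~no_consent
    inc_rows = np.flatnonzero(incomplete)
    if inc_rows.size:
        # blank 1-3 questionnaire items per incomplete student
        n_blank = rng.integers(1, 4, size=inc_rows.size)
        picks = rng.integers(0, len(_QUESTIONNAIRE_COLS), size=(inc_rows.size, 3))
        for j, col in enumerate(_QUESTIONNAIRE_COLS):
            hit = (picks[:, 0] == j)
            hit |= (n_blank >= 2) & (picks[:, 1] == j)
            hit |= (n_blank == 3) & (picks[:, 2] == j)
            rows = inc_rows[hit]
            if rows.size:
                out.iloc[rows, out.columns.get_loc(col)] = pd.NA
    return out


def inject_exclusions_exact(
    cohort: pd.DataFrame,
    n_diagnosed: int,
    n_no_consent: int,
    n_incomplete: int,
) -> pd.DataFrame:
    """Deterministically flag disjoint blocks of students for exclusion.

    The first ``n_diagnosed`` records are marked diagnosed, the next
    ``n_no_consent`` lose consent, and the next ``n_incomplete`` have their
    first KIDSCREEN item blanked. Useful to reproduce a published exclusion
    cascade exactly.
    """
    total = n_diagnosed + n_no_consent + n_incomplete
    if total > len(cohort):
        raise ValueError("exclusion counts exceed cohort size")
    out = cohort.copy()
    idx = out.index
    out.loc[idx[:n_diagnosed], "diagnosed_condition"] = True
    out.loc[idx[n_diagnosed:n_diagnosed + n_no_consent], "consent"] = False
    out.loc[idx[n_diagnosed + n_no_consent:total], "ks01"] = pd.NA
    return out


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

_ITEM_RANGES: dict[str, tuple[int, int]] = {
    **{c: (1, 5) for c in KIDSCREEN_COLS},
    **{c: (0, 1) for c in KIDMED_COLS},
    **{c: (1, 5) for c in PAQC_COLS},
    **{c: (0, 10**9) for c in STROOP_COLS},
    **{c: (1, 10) for c in GRADE_COLS},
}


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV (UTF-8, header row, missing as empty field)."""
    out = cohort.copy()
    out["consent"] = out["consent"].astype(int)
    out["diagnosed_condition"] = out["diagnosed_condition"].astype(int)
    out.to_csv(path, index=False, lineterminator="\n", float_format="%.1f")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV, raising with row/column context."""
    df = pd.read_csv(path, dtype={"student_id": str})
    missing_cols = [c for c in COHORT_COLS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"malformed cohort header: missing columns {missing_cols}")
    df = df[list(COHORT_COLS)]
    for col in ("consent", "diagnosed_condition"):
        df[col] = df[col].astype(bool)
    for col in ITEM_COLS:
        df[col] = df[col].astype("Int64")
        low, high = _ITEM_RANGES[col]
        vals = df[col]
        bad = vals.notna() & ((vals < low) | (vals > high))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"out-of-range value in column {col!r}, row {row + 2} "
                f"(1-based with header): {vals.iloc[row]} not in {low}..{high}"
            )
    if df["student_id"].duplicated().any():
        dup = df["student_id"][df["student_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate student_id {dup!r}")
    return df
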