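"""Instrument layouts: item columns, dimension structure, scoring keys.

Covers the four questionnaires and tests feeding the well-being model:

* KIDSCREEN-52 — 52 five-point items in 10 health-related quality-of-life
  dimensions, scored 0-100 per dimension.
* KIDMED — 16 yes/no Mediterranean-diet items, index 0-12.
* PAQ-C — 9 five-point physical-activity items, mean score 1-5.
* Stroop Colour and Word Test (children's version) — word / colour /
  colour-word counts, summarised as an interference score.
* School achievement — three subject grades on a 1-10 scale.

The reverse-keying of negatively worded KIDSCREEN items and the set of
diet-negative KIDMED items follow the published conventions of the cited
instruments; both are module-level constants so deployments using a
different key can override them.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# KIDSCREEN-52
# ---------------------------------------------------------------------------

KIDSCREEN_COLS = tuple(f"ks{i:02d}" for i in range(1, 53))

#: dimension -> 1-based global item numbers within the 52-item form.
KIDSCREEN_DIMENSIONS: dict[str, tuple[int, ...]] = {
    "physical_wellbeing": tuple(range(1, 6)),        # 5 items
    "psychological_wellbeing": tuple(range(6, 12)),  # 6 items
    "moods_emotions": tuple(range(12, 19)),          # 7 items
    "self_perception": tuple(range(19, 24)),         # 5 items
    "autonomy": tuple(range(24, 29)),                # 5 items
    "parent_relations": tuple(range(29, 35)),        # 6 items
    "financial_resources": tuple(range(35, 38)),     # 3 items
    "peers": tuple(range(38, 44)),                   # 6 items
    "school_environment": tuple(range(44, 50)),      # 6 items
    "bullying": tuple(range(50, 53)),                # 3 items
}

#: Negatively worded items, recoded as 6 - response before averaging:
#: all moods-and-emotions items, the negative self-perception items, and the
#: three bullying items (so that higher always means better, including
#: "less bullied" for the social-acceptance dimension).
KIDSCREEN_REVERSED: frozenset[int] = frozenset(
    list(range(12, 19)) + [21, 22, 23] + [50, 51, 52]
)

#: Per dimension, at most this many missing items are tolerated (the mean of
#: the observed items then stands in, i.e. within-dimension mean imputation).
KIDSCREEN_MAX_MISSING = 2

# ---------------------------------------------------------------------------
# KIDMED
# ---------------------------------------------------------------------------

KIDMED_COLS = tuple(f"km{i:02d}" for i in range(1, 17))

#: 1-based numbers of the four diet-negative items (fast food, skipped
#: breakfast, commercially baked breakfast goods, daily sweets); each scores
#: -1 when affirmed, the remaining twelve score +1.
KIDMED_NEGATIVE: frozenset[int] = frozenset({6, 12, 14, 16})

# ---------------------------------------------------------------------------
# PAQ-C, Stroop, school grades
# ---------------------------------------------------------------------------

PAQC_COLS = tuple(f"pq{i}" for i in range(1, 10))

STROOP_COLS = ("stroop_word", "stroop_color", "stroop_color_word")

GRADE_COLS = ("grade_literature", "grade_language", "grade_science")

#: Every per-item response column, in canonical CSV order.
ITEM_COLS: tuple[str, ...] = (
    KIDSCREEN_COLS + KIDMED_COLS + PAQC_COLS + STROOP_COLS + GRADE_COLS
)

assert len(KIDSCREEN_COLS) == 52 and sum(
    len(v) for v in KIDSCREEN_DIMENSIONS.values()
) == 52
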