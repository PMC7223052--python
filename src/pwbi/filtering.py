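"""Inclusion/exclusion cascade with an auditable log.

A student is excluded for the first matching reason in fixed precedence:
diagnosed condition, then missing consent, then incomplete questionnaires,
then age outside the inclusion range. Counting each student under exactly
one reason makes the per-reason counts sum to the total number excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .instruments import ITEM_COLS

#: Precedence order of exclusion reasons.
REASONS = ("diagnosed_condition", "no_consent", "incomplete", "age_out_of_range")


@dataclass
class ExclusionLog:
    """Accounting of one pass of the inclusion filter."""

    n_enrolled: int
    n_diagnosed: int
    n_no_consent: int
    n_incomplete: int
    n_age: int
    n_final: int
    excluded_ids: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return self.n_diagnosed + self.n_no_consent + self.n_incomplete + self.n_age

    def to_dict(self) -> dict:
        return {
            "n_enrolled": self.n_enrolled,
            "n_diagnosed": self.n_diagnosed,
            "n_no_consent": self.n_no_consent,
            "n_incomplete": self.n_incomplete,
            "n_age_out_of_range": self.n_age,
            "n_excluded": self.n_excluded,
            "n_final": self.n_final,
            "excluded_ids": self.excluded_ids,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def apply_inclusion(
    cohort: pd.DataFrame, age_range: tuple[float, float] = (10.0, 14.0)
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Filter a cohort to eligible students and log every exclusion.

    Incompleteness means any missing item response. The returned cohort
    contains exactly the students with no disqualifier; every enrolled
    student lands either there or in exactly one exclusion list.
    """
    diagnosed = cohort["diagnosed_condition"].astype(bool).to_numpy()
    no_consent = ~cohort["consent"].astype(bool).to_numpy()
    incomplete = cohort[list(ITEM_COLS)].isna().any(axis=1).to_numpy()
    age = cohort["age"].astype(float).to_numpy()
    age_out = (age < age_range[0]) | (age > age_range[1])

    reason_masks = {}
    assigned = pd.Series(False, index=cohort.index).to_numpy()
    for reason, mask in (
        ("diagnosed_condition", diagnosed),
        ("no_consent", no_consent),
        ("incomplete", incomplete),
        ("age_out_of_range", age_out),
    ):
        first_match = mask & ~assigned
        reason_masks[reason] = first_match
        assigned = assigned | mask

    ids = cohort["student_id"].astype(str)
    excluded_ids = {r: ids[m].tolist() for r, m in reason_masks.items()}
    kept = cohort[~assigned].reset_index(drop=True)
    log = ExclusionLog(
        n_enrolled=len(cohort),
        n_diagnosed=int(reason_masks["diagnosed_condition"].sum()),
        n_no_consent=int(reason_masks["no_consent"].sum()),
        n_incomplete=int(reason_masks["incomplete"].sum()),
        n_age=int(reason_masks["age_out_of_range"].sum()),
        n_final=len(kept),
        excluded_ids=excluded_ids,
    )
    assert log.n_final == log.n_enrolled - log.n_excluded
    return kept, log
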