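"""Modified Neurological Severity Score (mNSS) scoring and cohort exclusions.

The mNSS composite covers three subtests (higher = worse deficit):

* raising the rat by the tail -- three binary items (forelimb flexion,
  hindlimb flexion, head movement > 10 degrees off the vertical axis within
  30 s), subtotal 0-3;
* sensory battery -- four ordinal items scored 0-3 each (visual placement
  of forelimbs, tactile placement of forelimbs, proprioceptive adduction of
  hindlimbs, tactile placement of hindlimbs), subtotal 0-12;
* beam balance -- a single ordinal category 0-6, from steady posture (0) to
  falling off with no attempt to balance within 20 s (6).

The total is the arithmetic sum of the subtotals. Note the published scale
is described as 0-18 while the printed subtotal bounds sum to 21; this
scorer returns the arithmetic sum and warns when a total exceeds 18 rather
than silently rescaling. The scorer consumes pre-judged item values; it
performs no video or angle measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "MNSSRecord",
    "MNSSScore",
    "score_mnss",
    "apply_exclusions",
    "TAIL_ITEMS",
    "SENSORY_ITEMS",
    "EXCLUSION_FLAGS",
]

TAIL_ITEMS = ("tail_forelimb_flexion", "tail_hindlimb_flexion", "tail_head_movement")
SENSORY_ITEMS = (
    "sensory_visual_forelimb",
    "sensory_tactile_forelimb",
    "sensory_proprioceptive_hindlimb",
    "sensory_tactile_hindlimb",
)
BEAM_ITEM = "beam_balance"
EXCLUSION_FLAGS = ("none", "died_24h", "no_deficit", "SAH")


@dataclass(frozen=True)
class MNSSRecord:
    """One animal x timepoint set of rubric item responses."""

    subject: str
    timepoint: str
    tail_forelimb_flexion: int
    tail_hindlimb_flexion: int
    tail_head_movement: int
    sensory_visual_forelimb: int
    sensory_tactile_forelimb: int
    sensory_proprioceptive_hindlimb: int
    sensory_tactile_hindlimb: int
    beam_balance: int

    def __post_init__(self) -> None:
        for item in TAIL_ITEMS:
            v = getattr(self, item)
            if v not in (0, 1):
                raise ValueError(f"item {item!r} must be 0 or 1, got {v}")
        for item in SENSORY_ITEMS:
            v = getattr(self, item)
            if not 0 <= v <= 3:
                raise ValueError(f"item {item!r} must be in 0..3, got {v}")
        if not 0 <= self.beam_balance <= 6:
            raise ValueError(f"item 'beam_balance' must be in 0..6, got {self.beam_balance}")


@dataclass(frozen=True)
class MNSSScore:
    tail_subtotal: int     # 0-3
    sensory_subtotal: int  # 0-12
    beam_subtotal: int     # 0-6
    total: int


def score_mnss(record: MNSSRecord) -> MNSSScore:
    """Subtotal and total mNSS for one record (normal = 0; higher = worse)."""
    tail = sum(getattr(record, item) for item in TAIL_ITEMS)
    sensory = sum(getattr(record, item) for item in SENSORY_ITEMS)
    beam = record.beam_balance
    total = tail + sensory + beam
    if total > 18:
        warnings.warn(
            f"mNSS total {total} exceeds the published 0-18 scale (the printed "
            "subtotal bounds allow up to 21); reporting the arithmetic sum",
            stacklevel=2,
        )
    return MNSSScore(tail_subtotal=tail, sensory_subtotal=sensory,
                     beam_subtotal=beam, total=total)


def score_mnss_frame(mnss: pd.DataFrame) -> pd.DataFrame:
    """Score every row of an item-level mNSS table; adds subtotal/total columns."""
    out = mnss.copy()
    scores = [
        score_mnss(MNSSRecord(
            subject=str(row.get("animal", row.get("subject", ""))),
            timepoint=str(row["timepoint"]),
            **{item: int(row[item]) for item in (*TAIL_ITEMS, *SENSORY_ITEMS, BEAM_ITEM)},
        ))
        for _, row in mnss.iterrows()
    ]
    out["tail_subtotal"] = [s.tail_subtotal for s in scores]
    out["sensory_subtotal"] = [s.sensory_subtotal for s in scores]
    out["beam_subtotal"] = [s.beam_subtotal for s in scores]
    out["mnss_total"] = [s.total for s in scores]
    return out


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop flagged animals; report per-group, per-reason counts.

    ``cohort`` needs ``animal``, ``group`` and ``exclusion`` columns with
    flags from {none, died_24h, no_deficit, SAH}. Idempotent: the included
    table carries only ``none`` flags.
    """
    required = {"animal", "group", "exclusion"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing column(s): {sorted(missing)}")
    bad = set(cohort["exclusion"]) - set(EXCLUSION_FLAGS)
    if bad:
        raise ValueError(f"unknown exclusion flag(s): {sorted(bad)}; allowed {EXCLUSION_FLAGS}")
    included = cohort[cohort["exclusion"] == "none"].reset_index(drop=True)
    excluded = cohort[cohort["exclusion"] != "none"]
    by_reason = excluded["exclusion"].value_counts().to_dict()
    by_group_reason = {
        g: sub["exclusion"].value_counts().to_dict()
        for g, sub in excluded.groupby("group")
    }
    report = {
        "enrolled": int(len(cohort)),
        "excluded": int(len(excluded)),
        "included": int(len(included)),
        "by_reason": {k: int(v) for k, v in by_reason.items()},
        "by_group_reason": {
            g: {k: int(v) for k, v in d.items()} for g, d in by_group_reason.items()
        },
    }
    return included, report
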