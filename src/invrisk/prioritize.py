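"""Combine invasiveness category and projected habitat change into a
priority ranking.

Species are ordered lexicographically: invasiveness category tier first
(Extremely Invasive highest), then the change in suitable high-risk
habitat area (descending), then species name for determinism.  Each
species also gets a coarse management tier:

* ``high``  -- Extremely or Highly Invasive AND habitat projected to
  grow (positive delta, or habitat appearing where there was none);
* ``low``   -- at most Modestly Invasive AND no projected growth;
* ``watch`` -- everything else (e.g. a highly invasive species whose
  habitat is shrinking, or a weak invader that is expanding).

``comparison_table`` emits the three orderings -- risk score alone,
habitat change alone, and the combined rule -- side by side, which is
where single-axis prioritisation visibly disagrees with the combined
one.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .habitat_change import HabitatChange
from .risk_assessment import RiskResult, category_rank


class PrioritizeError(ValueError):
    pass


@dataclass
class PriorityRecord:
    species: str
    category: str
    risk_score: float
    change: HabitatChange
    priority_rank: int
    priority_tier: str


def _tier(category: str, change: HabitatChange) -> str:
    rank = category_rank(category)
    growing = change.delta > 0 or change.new_habitat_flag
    if rank >= 4 and growing:  # Highly or Extremely Invasive
        return "high"
    if rank <= 2 and not growing:  # Modestly Invasive or below
        return "low"
    return "watch"


def prioritize(
    entries: list[tuple[str, RiskResult, HabitatChange]]
) -> list[PriorityRecord]:
    """Rank species by (category tier desc, high-risk area delta desc, name)."""
    if not entries:
        raise PrioritizeError("no species to prioritise")
    names = [e[0] for e in entries]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise PrioritizeError(f"duplicate species: {', '.join(dupes)}")
    ordered = sorted(
        entries,
        key=lambda e: (-category_rank(e[1].category), -e[2].delta, e[0]),
    )
    return [
        PriorityRecord(
            species=name,
            category=risk.category,
            risk_score=risk.score,
            change=change,
            priority_rank=i + 1,
            priority_tier=_tier(risk.category, change),
        )
        for i, (name, risk, change) in enumerate(ordered)
    ]


def priority_frame(records: list[PriorityRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "priority_rank": r.priority_rank,
            "species": r.species,
            "category": r.category,
            "risk_score": r.risk_score,
            "priority_tier": r.priority_tier,
        }
        row.update(r.change.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def comparison_table(
    entries: list[tuple[str, RiskResult, HabitatChange]]
) -> pd.DataFrame:
    """Three ranked species lists: risk score alone, habitat-change alone,
    and the combined rule."""
    if not entries:
        raise PrioritizeError("no species to compare")
    by_risk = sorted(entries, key=lambda e: (-e[1].score, e[0]))
    by_change = sorted(entries, key=lambda e: (-e[2].delta, e[0]))
    combined = prioritize(entries)
    return pd.DataFrame(
        {
            "rank": range(1, len(entries) + 1),
            "risk_assessment_only": [e[0] for e in by_risk],
            "habitat_change_only": [e[0] for e in by_change],
            "combined": [r.species for r in combined],
        }
    )
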