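"""Schema-driven invasiveness risk scoring.

The scoring engine implements the structure of criterion-based
invasiveness ranking systems: a fixed set of criteria (the shipped
default has 21) grouped under four attributes -- ecological impact,
invasive characteristics, dispersal ability, and feasibility of
control.  Each criterion awards points up to its maximum; the risk
score is the percentage of the achievable maximum actually earned,

    score = 100 * sum(earned over answered) / sum(max over answered),

so criteria answered "unknown" drop out of both numerator and
denominator and the score remains comparable across species with
different knowledge gaps.  The fraction of criteria answered is
reported, and a result below a configurable minimum answered fraction
is flagged as having insufficient information.

Scores map onto six categories: >= 80 Extremely Invasive, 70-79 Highly,
60-69 Moderately, 50-59 Modestly, 40-49 Weakly, < 40 Very Weakly
Invasive.  Band edges are half-open so non-integer scores always fall
in exactly one category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml


class SchemaError(ValueError):
    pass


class ScoringError(ValueError):
    pass


ATTRIBUTE_GROUPS = (
    "ecological impact",
    "invasive characteristics",
    "dispersal ability",
    "feasibility of control",
)

UNKNOWN = "unknown"

CATEGORIES = (
    "Very Weakly Invasive",
    "Weakly Invasive",
    "Modestly Invasive",
    "Moderately Invasive",
    "Highly Invasive",
    "Extremely Invasive",
)

# lower score bound of each category, aligned with CATEGORIES
_CATEGORY_BOUNDS = (0.0, 40.0, 50.0, 60.0, 70.0, 80.0)


@dataclass
class Criterion:
    id: str
    prompt: str
    group: str
    max_points: float
    levels: dict[str, float]  # answer label -> points

    def points_for(self, answer) -> float:
        """Resolve an answer (level label or number) to points earned."""
        if isinstance(answer, str):
            if answer not in self.levels:
                raise ScoringError(
                    f"criterion {self.id!r}: unknown answer level {answer!r} "
                    f"(allowed: {', '.join(self.levels)})"
                )
            return self.levels[answer]
        pts = float(answer)
        if not 0 <= pts <= self.max_points:
            raise ScoringError(
                f"criterion {self.id!r}: points {pts} outside [0, {self.max_points}]"
            )
        return pts


@dataclass
class CriteriaSchema:
    name: str
    criteria: list[Criterion]

    def __post_init__(self) -> None:
        ids = [c.id for c in self.criteria]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SchemaError(f"duplicate criterion id(s): {', '.join(sorted(dupes))}")
        bad_groups = sorted({c.group for c in self.criteria} - set(ATTRIBUTE_GROUPS))
        if bad_groups:
            raise SchemaError(
                f"unknown attribute group(s): {', '.join(bad_groups)}; "
                f"allowed: {', '.join(ATTRIBUTE_GROUPS)}"
            )
        if len({c.group for c in self.criteria}) != 4:
            raise SchemaError("schema must use exactly 4 attribute groups")
        offenders = [c.id for c in self.criteria if c.max_points < 0]
        if offenders:
            raise SchemaError(f"negative max_points for: {', '.join(offenders)}")
        over = [
            f"{c.id}:{lvl}"
            for c in self.criteria
            for lvl, pts in c.levels.items()
            if pts > c.max_points or pts < 0
        ]
        if over:
            raise SchemaError(f"answer level points outside [0, max]: {', '.join(over)}")

    def __len__(self) -> int:
        return len(self.criteria)

    @property
    def groups(self) -> list[str]:
        return sorted({c.group for c in self.criteria}, key=ATTRIBUTE_GROUPS.index)

    def criterion(self, cid: str) -> Criterion:
        for c in self.criteria:
            if c.id == cid:
                return c
        raise ScoringError(f"no criterion with id {cid!r}")

    @property
    def total_max_points(self) -> float:
        return sum(c.max_points for c in self.criteria)


@dataclass
class Scorecard:
    """One species' answers: criterion id -> level label, points, or 'unknown'."""

    species: str
    answers: dict[str, object]
    notes: str = ""


@dataclass
class RiskResult:
    species: str
    score: float
    category: str
    answered_fraction: float
    group_subtotals: dict[str, tuple[float, float]]  # group -> (earned, max)
    insufficient_information: bool = False


def load_schema(path: str | Path | None = None) -> CriteriaSchema:
    """Load a criteria schema from YAML; with no path, the shipped default
    (21 criteria in the four standard attribute groups)."""
    if path is None:
        text = resources.files("invrisk.data").joinpath("invasiveness_schema.yml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "criteria" not in raw:
        raise SchemaError("schema file must be a mapping with a 'criteria' list")
    criteria = []
    for entry in raw["criteria"]:
        try:
            criteria.append(
                Criterion(
                    id=str(entry["id"]),
                    prompt=str(entry.get("prompt", "")),
                    group=str(entry["group"]),
                    max_points=float(entry["max_points"]),
                    levels={str(k): float(v) for k, v in entry.get("levels", {}).items()},
                )
            )
        except KeyError as exc:
            raise SchemaError(f"criterion entry missing key {exc}") from exc
    return CriteriaSchema(name=str(raw.get("name", "unnamed")), criteria=criteria)


def load_scorecard(path: str | Path) -> Scorecard:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "species" not in raw or "answers" not in raw:
        raise ScoringError(f"{path}: scorecard must have 'species' and 'answers'")
    return Scorecard(
        species=str(raw["species"]),
        answers=dict(raw["answers"]),
        notes=str(raw.get("notes", "")),
    )


def total_score(
    card: Scorecard,
    schema: CriteriaSchema,
    min_answered_fraction: float = 0.8,
) -> RiskResult:
    """Score a scorecard against a schema.

    Unknown answers are excluded from both sides of the ratio; a card
    with no answered criteria cannot be scored.
    """
    unknown_ids = set(card.answers) - {c.id for c in schema.criteria}
    if unknown_ids:
        raise ScoringError(f"answers reference unknown criterion id(s): {', '.join(sorted(unknown_ids))}")
    earned_total = 0.0
    max_total = 0.0
    n_answered = 0
    groups: dict[str, tuple[float, float]] = {g: (0.0, 0.0) for g in schema.groups}
    for c in schema.criteria:
        answer = card.answers.get(c.id, UNKNOWN)
        if isinstance(answer, str) and answer.lower() == UNKNOWN:
            continue
        pts = c.points_for(answer)
        earned_total += pts
        max_total += c.max_points
        n_answered += 1
        e, m = groups[c.group]
        groups[c.group] = (e + pts, m + c.max_points)
    if n_answered == 0 or max_total == 0:
        raise ScoringError(f"scorecard for {card.species!r} has no scorable answers")
    score = 100.0 * earned_total / max_total
    answered_fraction = n_answered / len(schema)
    return RiskResult(
        species=card.species,
        score=score,
        category=categorize(score),
        answered_fraction=answered_fraction,
        group_subtotals=groups,
        insufficient_information=answered_fraction < min_answered_fraction,
    )


def categorize(score: float) -> str:
    """Map a 0-100 risk score onto its invasiveness category band."""
    if not 0.0 <= score <= 100.0:
        raise ScoringError(f"score {score} outside [0, 100]")
    for cat, bound in zip(reversed(CATEGORIES), reversed(_CATEGORY_BOUNDS)):
        if score >= bound:
            return cat
    raise AssertionError("unreachable")


def category_rank(category: str) -> int:
    """0 = Very Weakly Invasive ... 5 = Extremely Invasive."""
    try:
        return CATEGORIES.index(category)
    except ValueError:
        raise ScoringError(f"unknown category {category!r}") from None
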