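"""Hierarchical herd-welfare scoring and the high-welfare-farm gate.

The integrated welfare score is a weighted pooled mean over a hierarchy of
clusters → components → aspects → indicators, with only the cluster level
fixed by the model: environment 0.3, feeding 0.3, animal 0.4.  Lower levels
are user-definable via ScoreNode trees (e.g. from YAML config).  A herd is
high-welfare when its total score strictly exceeds 70% and every cluster
strictly exceeds 65%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .core import ValidationError
from .registry import FARM_TABLE, PHASE_ORDER

CLUSTER_WEIGHTS = {"environment": 0.3, "feeding": 0.3, "animal": 0.4}

_WEIGHT_TOL = 1e-9


@dataclass
class ScoreNode:
    """A node of the welfare hierarchy: a leaf score or a weighted group."""

    name: str
    weight: float = 1.0
    score: Optional[float] = None            # percent, leaves only
    children: list["ScoreNode"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.weight <= 1):
            raise ValidationError(f"{self.name}: weight must lie in [0,1]")
        if self.score is not None and self.children:
            raise ValidationError(f"{self.name}: a node is a leaf or a group, not both")
        if self.score is not None and not (0 <= self.score <= 100):
            raise ValidationError(f"{self.name}: leaf score must lie in [0,100]")

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreNode":
        children = [cls.from_dict(c) for c in d.get("children", [])]
        return cls(name=d["name"], weight=d.get("weight", 1.0),
                   score=d.get("score"), children=children)


def aggregate_score(node: ScoreNode) -> float:
    """Bottom-up weighted mean of a well-formed score tree, in [0,100]."""
    if not node.children:
        if node.score is None:
            raise ValidationError(f"{node.name}: leaf without a score")
        return float(node.score)
    total_w = sum(c.weight for c in node.children)
    if abs(total_w - 1.0) > _WEIGHT_TOL:
        raise ValidationError(
            f"{node.name}: child weights sum to {total_w}, expected 1")
    return sum(c.weight * aggregate_score(c) for c in node.children)


def total_idsw(env: float, feed: float, animal: float) -> float:
    """Total welfare score: 0.3·environment + 0.3·feeding + 0.4·animal.

    Returns the unrounded percentage; use :func:`display_score` for the
    integer display value.
    """
    for name, v in (("env", env), ("feed", feed), ("animal", animal)):
        if not (0 <= v <= 100):
            raise ValidationError(f"{name} score must lie in [0,100], got {v}")
    return 0.3 * env + 0.3 * feed + 0.4 * animal


def display_score(score: float) -> int:
    """Integer display rounding (round-half-to-even) of a percent score."""
    return round(score)


def is_high_welfare(total: float, env: float, feed: float, animal: float) -> bool:
    """True iff total > 70 and every cluster > 65 (both strict)."""
    for name, v in (("total", total), ("env", env), ("feed", feed), ("animal", animal)):
        if not (0 <= v <= 100):
            raise ValidationError(f"{name} score must lie in [0,100], got {v}")
    return total > 70 and min(env, feed, animal) > 65


def ecm_305(milk_kg: float, fat_pct: float, protein_pct: float) -> float:
    """Energy-corrected milk for a 305-d lactation.

    ECM = milk × (0.383·fat% + 0.242·protein% + 0.7832) / 3.1138, normalised
    so that milk at 4.0% fat and 3.30% protein maps to itself.
    """
    if milk_kg < 0:
        raise ValidationError(f"milk_kg must be >= 0, got {milk_kg}")
    for name, v in (("fat_pct", fat_pct), ("protein_pct", protein_pct)):
        if not (0 < v < 15):
            raise ValidationError(f"{name} must lie in (0,15), got {v}")
    return milk_kg * (0.383 * fat_pct + 0.242 * protein_pct + 0.7832) / 3.1138


@dataclass
class FarmProfile:
    """Welfare cluster scores and herd descriptors for one farm."""

    farm_id: str
    env_score: float
    feed_score: float
    animal_score: float
    lactating_cows: int = 0
    milking_frequency: float = 2.0
    days_open: float = 0.0
    ecm_305: float = 0.0
    enrolled: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("env_score", "feed_score", "animal_score"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValidationError(f"{name} must lie in [0,100], got {v}")
        if self.lactating_cows < 0 or any(v < 0 for v in self.enrolled.values()):
            raise ValidationError("counts must be >= 0")

    @property
    def total_score(self) -> float:
        return total_idsw(self.env_score, self.feed_score, self.animal_score)

    @property
    def high_welfare(self) -> bool:
        return is_high_welfare(self.total_score, self.env_score,
                               self.feed_score, self.animal_score)


def packaged_farms() -> list[FarmProfile]:
    """The 11 packaged high-welfare herd profiles."""
    return [FarmProfile(
        farm_id=f["farm_id"], env_score=f["env_score"], feed_score=f["feed_score"],
        animal_score=f["animal_score"], lactating_cows=f["lactating_cows"],
        milking_frequency=f["milking_frequency"], days_open=f["days_open"],
        ecm_305=f["ecm_305"], enrolled=dict(f["enrolled"]),
    ) for f in FARM_TABLE]


def read_farms(path) -> list[FarmProfile]:
    """Read farm profiles from farms.csv."""
    df = pd.read_csv(path, dtype={"farm_id": str})
    farms = []
    for row in df.itertuples(index=False):
        enrolled = {p: int(getattr(row, f"enrolled_{p}"))
                    for p in PHASE_ORDER if hasattr(row, f"enrolled_{p}")}
        farms.append(FarmProfile(
            farm_id=row.farm_id, env_score=float(row.env_score),
            feed_score=float(row.feed_score), animal_score=float(row.animal_score),
            lactating_cows=int(getattr(row, "lactating_cows", 0)),
            milking_frequency=float(getattr(row, "milking_frequency", 2.0)),
            days_open=float(getattr(row, "days_open", 0.0)),
            ecm_305=float(getattr(row, "ecm_305", 0.0)),
            enrolled=enrolled,
        ))
    return farms


def write_farms(farms: Sequence[FarmProfile], path) -> None:
    rows = []
    for f in farms:
        row = {"farm_id": f.farm_id, "env_score": f.env_score,
               "feed_score": f.feed_score, "animal_score": f.animal_score,
               "lactating_cows": f.lactating_cows,
               "milking_frequency": f.milking_frequency,
               "days_open": f.days_open, "ecm_305": f.ecm_305}
        for p in PHASE_ORDER:
            row[f"enrolled_{p}"] = f.enrolled.get(p, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def high_welfare_farms(farms: Sequence[FarmProfile]) -> list[FarmProfile]:
    """Apply the high-welfare gate, returning the farms that pass."""
    return [f for f in farms if f.high_welfare]
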