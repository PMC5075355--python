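"""Summed-score clinical staging engines.

Classical liver staging systems assign each of a fixed set of markers
an integer point value according to physician-chosen cutoffs, sum the
points, and diagnose by comparing the total against a cutoff score.
The engine here is generic — any point table expressed as per-marker
(condition, points) lists can be loaded from YAML/JSON — and the Tokyo
Score ships as a packaged default (four markers: serum albumin, total
bilirubin, largest tumor size, number of tumors; total >= 2 flags
possible recurrence).

Unlike the discrete Bayes classifier, these systems require their
specific markers: a missing value is a hard error, not something the
engine can route around.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path
from typing import Mapping

import yaml

from .domain_model import (
    NONRECURRENCE,
    RECURRENCE,
    MissingMarkerError,
    PatientRecord,
    Rule,
)


@dataclass(frozen=True)
class ScoreItem:
    """One scored marker: ordered (condition, points) bands."""

    marker: str
    bands: tuple[tuple[Rule, int], ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError(f"marker {self.marker!r} has no point bands")
        if any(p < 0 or int(p) != p for _, p in self.bands):
            raise ValueError("points must be nonnegative integers")

    def points_for(self, raw: object) -> int:
        hits = [p for rule, p in self.bands if rule.matches(raw)]
        if len(hits) == 1:
            return int(hits[0])
        if not hits:
            raise ValueError(
                f"value {raw!r} matches no condition of marker {self.marker!r}"
            )
        raise ValueError(
            f"value {raw!r} matches multiple conditions of {self.marker!r}"
        )


@dataclass(frozen=True)
class ScoreTable:
    """A staging system: name, per-marker point bands, diagnosis cutoff
    and comparison direction (``ge``: score >= cutoff means possible
    recurrence; ``gt`` available for strict systems)."""

    name: str
    items: tuple[ScoreItem, ...]
    cutoff: int
    direction: str = "ge"

    def __post_init__(self) -> None:
        if self.direction not in ("ge", "gt"):
            raise ValueError("direction must be 'ge' or 'gt'")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "cutoff": self.cutoff,
            "direction": self.direction,
            "markers": [
                {
                    "name": it.marker,
                    "points": [
                        {"rule": rule.to_dict(), "points": p}
                        for rule, p in it.bands
                    ],
                }
                for it in self.items
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoreTable":
        return cls(
            name=str(d["name"]),
            cutoff=int(d["cutoff"]),
            direction=str(d.get("direction", "ge")),
            items=tuple(
                ScoreItem(
                    marker=str(md["name"]),
                    bands=tuple(
                        (Rule.from_dict(b["rule"]), int(b["points"]))
                        for b in md["points"]
                    ),
                )
                for md in d["markers"]
            ),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoreTable":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def tokyo_score_table() -> ScoreTable:
    """The packaged Tokyo Score point table (editable config; only the
    marker set and the standard point bands are assumed)."""
    text = files("hccbayes").joinpath("data/tokyo_score.yaml").read_text()
    return ScoreTable.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Operations


def total_score(record: PatientRecord, table: ScoreTable) -> int:
    """Sum of the matched per-marker points.

    Raises :class:`MissingMarkerError` naming the first absent marker —
    point systems cannot be applied with incomplete marker data.
    """
    total = 0
    for item in table.items:
        raw = record.get(item.marker)
        if raw is None:
            raise MissingMarkerError(
                f"record has no value for scored marker {item.marker!r}"
            )
        total += item.points_for(raw)
    return total


def diagnose(score: int, table: ScoreTable) -> str:
    """Compare a total score against the table's cutoff."""
    flagged = score >= table.cutoff if table.direction == "ge" else score > table.cutoff
    return RECURRENCE if flagged else NONRECURRENCE


def classify_record(record: PatientRecord, table: ScoreTable) -> str:
    """Score then diagnose in one step."""
    return diagnose(total_score(record, table), table)
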