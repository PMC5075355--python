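"""Markers, divisions, patients, datasets and division-count tables.

Continuous and discrete laboratory values are converted to categorical
data by per-marker cutoff rules ("divisions"); natively categorical
values are kept as is.  A patient is then a *pattern*: the tuple of
division indices of the selected markers.  The entire fitted state of
the downstream classifier is a :class:`DivisionCountTable` — per class,
per marker, per division patient counts.

Conventions
-----------
* Division indices are 1-based, mirroring the r_j subscript notation
  common in the discrete-pattern-recognition literature.
* The positive class (index 0) is recurrence within one year; the
  negative class (index 1) is nonrecurrence.
* Patient files are delimited text with a header row naming markers and
  an outcome column (default ``"outcome"``) holding the literal strings
  ``"recurrence"`` / ``"nonrecurrence"`` (case-insensitive).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

RECURRENCE = "recurrence"
NONRECURRENCE = "nonrecurrence"
#: Class labels in index order: class 0 = recurrence (positive class).
CLASSES = (RECURRENCE, NONRECURRENCE)

_OUTCOME_ALIASES = {RECURRENCE: RECURRENCE, NONRECURRENCE: NONRECURRENCE}


class DomainError(ValueError):
    """A raw value matches no division of its marker."""


class MissingMarkerError(KeyError):
    """A requested marker has no (non-missing) value in the record."""


def normalize_outcome(value: object) -> str:
    """Map a raw outcome cell to a canonical class label."""
    s = str(value).strip().lower()
    if s not in _OUTCOME_ALIASES:
        raise ValueError(
            f"unknown outcome {value!r}; expected one of {CLASSES}"
        )
    return _OUTCOME_ALIASES[s]


# ---------------------------------------------------------------------------
# Discretization rules


_NUMERIC_OPS = frozenset({"gt", "ge", "lt", "le", "between"})


@dataclass(frozen=True)
class Rule:
    """A discretization predicate for one division.

    ``op`` is one of

    ``gt``/``ge``/``lt``/``le``
        threshold on a continuous value, ``value`` is the boundary;
        strictness follows the operator (``gt`` excludes the boundary,
        ``ge`` includes it, ...).
    ``between``
        closed interval ``[low, high]`` (both endpoints included).
    ``eq``
        exact categorical match against ``value``.
    """

    op: str
    value: object = None
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        if self.op not in _NUMERIC_OPS | {"eq"}:
            raise ValueError(f"unknown rule op {self.op!r}")
        if self.op == "between" and (self.low is None or self.high is None):
            raise ValueError("'between' rule needs low and high")
        if self.op in _NUMERIC_OPS - {"between"} and self.value is None:
            raise ValueError(f"{self.op!r} rule needs a boundary value")

    def matches(self, raw: object) -> bool:
        if self.op == "eq":
            return str(raw) == str(self.value)
        try:
            x = float(raw)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            return False
        if self.op == "gt":
            return x > float(self.value)  # type: ignore[arg-type]
        if self.op == "ge":
            return x >= float(self.value)  # type: ignore[arg-type]
        if self.op == "lt":
            return x < float(self.value)  # type: ignore[arg-type]
        if self.op == "le":
            return x <= float(self.value)  # type: ignore[arg-type]
        return float(self.low) <= x <= float(self.high)  # between

    def to_dict(self) -> dict:
        if self.op == "between":
            return {"op": "between", "low": self.low, "high": self.high}
        return {"op": self.op, "value": self.value}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Rule":
        return cls(**dict(d))


@dataclass(frozen=True)
class Division:
    """One category of a discretized marker."""

    label: str
    index: int  # 1-based
    rule: Rule


@dataclass(frozen=True)
class Marker:
    """A laboratory or pathology feature with its ordered divisions."""

    id: int
    name: str
    divisions: tuple[Division, ...]

    def __post_init__(self) -> None:
        if len(self.divisions) < 2:
            raise ValueError(f"marker {self.name!r} needs >= 2 divisions")
        labels = [d.label for d in self.divisions]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate division labels in {self.name!r}")
        expected = tuple(range(1, len(self.divisions) + 1))
        if tuple(d.index for d in self.divisions) != expected:
            raise ValueError(
                f"divisions of {self.name!r} must be indexed 1..k in order"
            )

    @property
    def n_divisions(self) -> int:
        return len(self.divisions)

    @property
    def is_categorical(self) -> bool:
        return all(d.rule.op == "eq" for d in self.divisions)

    def discretize(self, raw: object) -> int:
        """Return the 1-based index of the division ``raw`` falls in."""
        hits = [d.index for d in self.divisions if d.rule.matches(raw)]
        if len(hits) == 1:
            return hits[0]
        if not hits:
            raise DomainError(
                f"value {raw!r} matches no division of marker {self.name!r}"
            )
        raise DomainError(  # rules are declared mutually exclusive
            f"value {raw!r} matches divisions {hits} of marker {self.name!r}"
        )


@dataclass(frozen=True)
class CutoffScheme:
    """An ordered set of markers with their physician-defined cutoffs."""

    markers: tuple[Marker, ...]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        ids = [m.id for m in self.markers]
        if len(set(names)) != len(names) or len(set(ids)) != len(ids):
            raise ValueError("marker names and ids must be unique")

    @property
    def marker_ids(self) -> tuple[int, ...]:
        return tuple(m.id for m in self.markers)

    def marker(self, key: int | str) -> Marker:
        for m in self.markers:
            if m.id == key or m.name == key:
                return m
        raise KeyError(f"no marker {key!r} in scheme")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "markers": [
                {
                    "id": m.id,
                    "name": m.name,
                    "divisions": [
                        {"label": d.label, "rule": d.rule.to_dict()}
                        for d in m.divisions
                    ],
                }
                for m in self.markers
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CutoffScheme":
        markers = tuple(
            Marker(
                id=int(md["id"]),
                name=str(md["name"]),
                divisions=tuple(
                    Division(
                        label=str(dd["label"]),
                        index=i + 1,
                        rule=Rule.from_dict(dd["rule"]),
                    )
                    for i, dd in enumerate(md["divisions"])
                ),
            )
            for md in d["markers"]
        )
        return cls(markers=markers, version=str(d.get("version", "unversioned")))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CutoffScheme":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def validate_scheme(
    scheme: CutoffScheme,
    grid: Sequence[float] | None = None,
) -> None:
    """Check mutual exclusivity + exhaustiveness of every numeric marker
    over a dense value grid (categorical markers are checked over their
    declared categories).  Raises :class:`DomainError` on violation."""
    for m in scheme.markers:
        if m.is_categorical:
            values: Iterable[object] = [d.rule.value for d in m.divisions]
        elif grid is not None:
            values = grid
        else:
            bounds = []
            for d in m.divisions:
                r = d.rule
                if r.op == "between":
                    bounds += [float(r.low), float(r.high)]
                else:
                    bounds.append(float(r.value))
            lo, hi = min(bounds) - 10.0, max(bounds) + 10.0
            values = np.concatenate(
                [np.linspace(lo, hi, 2001), np.asarray(bounds, float)]
            )
        for v in values:
            m.discretize(v)  # raises on 0 or >1 matches


# ---------------------------------------------------------------------------
# Patients and datasets


@dataclass(frozen=True)
class PatientRecord:
    """Raw per-marker values (possibly missing) and an outcome label.

    ``values`` maps marker *name* to a number or category string; a
    value of ``None`` (or NaN) is missing.  ``outcome`` is one of the
    :data:`CLASSES` or ``None`` (allowed only at classification time).
    """

    values: Mapping[str, object]
    outcome: str | None = None

    def __post_init__(self) -> None:
        if self.outcome is not None and self.outcome not in CLASSES:
            raise ValueError(f"outcome must be one of {CLASSES} or None")

    def get(self, marker_name: str):
        v = self.values.get(marker_name)
        if v is None:
            return None
        if isinstance(v, float) and math.isnan(v):
            return None
        return v


@dataclass(frozen=True)
class DiscretizedPattern:
    """A patient as the ordered tuple of division indices of the
    selected markers: marker id -> 1-based division index."""

    divisions: tuple[tuple[int, int], ...]

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, int]) -> "DiscretizedPattern":
        return cls(tuple(mapping.items()))

    @property
    def marker_ids(self) -> tuple[int, ...]:
        return tuple(j for j, _ in self.divisions)

    def division_of(self, marker_id: int) -> int:
        for j, r in self.divisions:
            if j == marker_id:
                return r
        raise KeyError(f"marker {marker_id} not in pattern")

    def __len__(self) -> int:
        return len(self.divisions)


@dataclass
class LabeledDataset:
    """A list of patient records with known outcomes."""

    records: list[PatientRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.outcome is None:
                raise ValueError("labeled datasets require known outcomes")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def class_sizes(self) -> tuple[int, int]:
        """(n recurrence, n nonrecurrence)."""
        n1 = sum(1 for r in self.records if r.outcome == RECURRENCE)
        return n1, len(self.records) - n1

    def by_class(self, label: str) -> "LabeledDataset":
        return LabeledDataset([r for r in self.records if r.outcome == label])

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset([self.records[i] for i in indices])

    def to_frame(self, outcome_column: str = "outcome") -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = dict(rec.values)
            row[outcome_column] = rec.outcome
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Operations


def discretize_record(
    record: PatientRecord,
    scheme: CutoffScheme,
    marker_ids: Sequence[int] | None = None,
) -> DiscretizedPattern:
    """Convert a record's raw values to the pattern of division indices.

    Raises :class:`MissingMarkerError` naming the marker if a requested
    value is missing, and :class:`DomainError` if a value matches no
    division.
    """
    if marker_ids is None:
        marker_ids = scheme.marker_ids
    out: dict[int, int] = {}
    for j in marker_ids:
        m = scheme.marker(j)
        raw = record.get(m.name)
        if raw is None:
            raise MissingMarkerError(
                f"record has no value for marker {m.name!r} (id {m.id})"
            )
        out[j] = m.discretize(raw)
    return DiscretizedPattern.from_mapping(out)


@dataclass(frozen=True)
class DivisionCountTable:
    """Per class, per marker, per division patient counts.

    ``counts[marker_id]`` is an integer array of shape
    ``(2, n_divisions)``; row 0 is the recurrence class.  For every
    marker and class the division counts sum to that class's total
    ``n^i`` — the table is a complete set of within-class marginals.
    """

    counts: Mapping[int, np.ndarray]
    class_sizes: tuple[int, int]

    def __post_init__(self) -> None:
        for j, arr in self.counts.items():
            a = np.asarray(arr)
            if a.shape[0] != 2 or a.ndim != 2:
                raise ValueError(f"marker {j}: counts must be (2, k)")
            if (a < 0).any():
                raise ValueError(f"marker {j}: negative count")
            sums = a.sum(axis=1)
            if tuple(sums) != tuple(self.class_sizes):
                raise ValueError(
                    f"marker {j}: per-class sums {tuple(sums)} != "
                    f"class sizes {self.class_sizes}"
                )

    @property
    def marker_ids(self) -> tuple[int, ...]:
        return tuple(self.counts.keys())

    def count(self, class_index: int, marker_id: int, division: int) -> int:
        """Count of class ``class_index`` patients in 1-based ``division``."""
        return int(self.counts[marker_id][class_index, division - 1])

    def restrict(self, marker_ids: Sequence[int]) -> "DivisionCountTable":
        return DivisionCountTable(
            {j: np.array(self.counts[j]) for j in marker_ids},
            self.class_sizes,
        )

    def equals(self, other: "DivisionCountTable") -> bool:
        if self.class_sizes != other.class_sizes:
            return False
        if set(self.marker_ids) != set(other.marker_ids):
            return False
        return all(
            np.array_equal(self.counts[j], other.counts[j])
            for j in self.marker_ids
        )

    def to_dict(self) -> dict:
        return {
            "class_sizes": list(self.class_sizes),
            "counts": {
                int(j): np.asarray(a).astype(int).tolist()
                for j, a in self.counts.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DivisionCountTable":
        return cls(
            counts={
                int(j): np.asarray(a, dtype=np.int64)
                for j, a in d["counts"].items()
            },
            class_sizes=tuple(int(n) for n in d["class_sizes"]),  # type: ignore[arg-type]
        )


def count_divisions(
    data: LabeledDataset,
    scheme: CutoffScheme,
    marker_ids: Sequence[int] | None = None,
) -> DivisionCountTable:
    """Tally each class's patients into each marker's divisions.

    Records missing a value for any requested marker are excluded from
    the tally (with a warning) so that the per-marker column sums equal
    the retained per-class totals.  Raises if either class ends empty.
    """
    if marker_ids is None:
        marker_ids = scheme.marker_ids
    markers = [scheme.marker(j) for j in marker_ids]
    tallies = {
        m.id: np.zeros((2, m.n_divisions), dtype=np.int64) for m in markers
    }
    n = [0, 0]
    dropped = 0
    for idx, rec in enumerate(data.records):
        try:
            pattern = discretize_record(rec, scheme, marker_ids)
        except MissingMarkerError:
            dropped += 1
            continue
        except DomainError as e:
            raise DomainError(f"record {idx}: {e}") from e
        i = 0 if rec.outcome == RECURRENCE else 1
        n[i] += 1
        for j, r in pattern.divisions:
            tallies[j][i, r - 1] += 1
    if dropped:
        logger.warning(
            "count_divisions: dropped %d record(s) with missing marker values",
            dropped,
        )
    if n[0] == 0 or n[1] == 0:
        raise ValueError(
            f"both classes must be nonempty for counting; got sizes {tuple(n)}"
        )
    return DivisionCountTable(tallies, (n[0], n[1]))


def discretize_dataset(
    data: LabeledDataset,
    scheme: CutoffScheme,
    marker_ids: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Discretize every record into an integer matrix.

    Returns ``(X, y)`` where ``X[n, k]`` is the 0-based division index
    of record ``n`` in the ``k``-th requested marker and ``y[n]`` is the
    class index (0 = recurrence).  Strict: missing values raise.
    """
    if marker_ids is None:
        marker_ids = scheme.marker_ids
    X = np.empty((len(data), len(marker_ids)), dtype=np.int64)
    y = np.empty(len(data), dtype=np.int64)
    for n, rec in enumerate(data.records):
        pattern = discretize_record(rec, scheme, marker_ids)
        for k, (_, r) in enumerate(pattern.divisions):
            X[n, k] = r - 1
        y[n] = 0 if rec.outcome == RECURRENCE else 1
    return X, y


# ---------------------------------------------------------------------------
# Delimited-text I/O


def read_dataset(
    path: str | Path,
    scheme: CutoffScheme | None = None,
    outcome_column: str = "outcome",
    sep: str | None = None,
) -> LabeledDataset:
    """Read a patient table from delimited text.

    The header row names markers; unknown columns are preserved in the
    records but ignored by discretization.  ``sep=None`` sniffs comma
    vs tab from the suffix.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if outcome_column not in df.columns:
        raise ValueError(
            f"{path}: no outcome column {outcome_column!r} in header"
        )
    if scheme is not None:
        numeric = {
            m.name for m in scheme.markers if not m.is_categorical
        } & set(df.columns)
        for col in numeric:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as e:
                raise ValueError(
                    f"{path}: unparseable numeric value in column {col!r}: {e}"
                ) from e
    records = []
    for line_no, (_, row) in enumerate(df.iterrows(), start=2):
        try:
            outcome = normalize_outcome(row[outcome_column])
        except ValueError as e:
            raise ValueError(f"{path}:{line_no}: {e}") from e
        values = {
            c: (None if pd.isna(row[c]) else row[c])
            for c in df.columns
            if c != outcome_column
        }
        records.append(PatientRecord(values=values, outcome=outcome))
    return LabeledDataset(records)


def write_dataset(
    data: LabeledDataset,
    path: str | Path,
    outcome_column: str = "outcome",
    sep: str | None = None,
) -> None:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    data.to_frame(outcome_column).to_csv(path, sep=sep, index=False)
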