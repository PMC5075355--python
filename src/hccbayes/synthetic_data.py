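"""Synthetic two-class categorical cohorts.

Real patient-level data for this problem are not publicly deposited, so
every stochastic procedure in the package is exercised on generated
cohorts.  The generator draws each record's division in each marker
independently from a per-class categorical distribution — exactly the
independence assumption under which the discrete Bayes rule factorizes
the joint conditional — and can emit raw continuous values sampled
inside each division's interval so that discretization round-trips.

What the generator does NOT emulate: between-marker correlation within
a class (real laboratory markers of liver function are correlated),
missingness, and measurement drift around cutoffs.  A green test on
synthetic cohorts therefore establishes correctness of the procedures,
not clinical performance.

`materialize_exact_counts` is the deterministic counterpart: it realizes
a division-count table exactly, shuffling each marker's division
assignments independently within each class (marginals carry no joint
information, so any consistent joint is a valid realization).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from typing import Mapping, Sequence

import numpy as np
import yaml

from .domain_model import (
    CLASSES,
    CutoffScheme,
    DivisionCountTable,
    LabeledDataset,
    PatientRecord,
    Rule,
)


def reference_scheme() -> CutoffScheme:
    """The packaged 10-marker cutoff scheme of the reference cohort."""
    text = files("hccbayes").joinpath("data/reference_scheme.yaml").read_text()
    return CutoffScheme.from_dict(yaml.safe_load(text))


def reference_counts() -> DivisionCountTable:
    """The packaged reference division-count table (29 recurrence / 89
    nonrecurrence training patients over the 10 reference markers)."""
    text = files("hccbayes").joinpath("data/reference_counts.yaml").read_text()
    return DivisionCountTable.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorSpec:
    """A stated cohort: sizes and per-class per-marker division laws.

    ``probabilities[i][j]`` is the division-probability vector of marker
    ``j`` in class ``i`` (0 = recurrence); each vector must sum to 1
    within 1e-9 and match the marker's division count.
    """

    scheme: CutoffScheme
    class_sizes: tuple[int, int]
    probabilities: Mapping[int, Mapping[int, Sequence[float]]]
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.class_sizes) < 0:
            raise ValueError("class sizes must be nonnegative")
        for i in (0, 1):
            for m in self.scheme.markers:
                p = np.asarray(self.probabilities[i][m.id], dtype=float)
                if p.shape != (m.n_divisions,):
                    raise ValueError(
                        f"class {i}, marker {m.name!r}: need "
                        f"{m.n_divisions} probabilities, got {p.shape}"
                    )
                if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                    raise ValueError(
                        f"class {i}, marker {m.name!r}: probabilities must "
                        "be nonnegative and sum to 1"
                    )


def probabilities_from_counts(
    counts: DivisionCountTable,
) -> dict[int, dict[int, np.ndarray]]:
    """Per-class division frequencies of a count table (counts / n^i)."""
    out: dict[int, dict[int, np.ndarray]] = {0: {}, 1: {}}
    for j in counts.marker_ids:
        arr = np.asarray(counts.counts[j], dtype=float)
        for i in (0, 1):
            out[i][j] = arr[i] / counts.class_sizes[i]
    return out


def single_informative_spec(
    scheme: CutoffScheme,
    informative_marker: int,
    class_sizes: tuple[int, int] = (29, 89),
    strength: tuple[float, float] = (0.9, 0.1),
    seed: int = 0,
) -> GeneratorSpec:
    """A cohort with one informative two-division marker among noise.

    The informative marker's division probabilities are ``strength`` in
    the recurrence class and reversed in the nonrecurrence class; every
    other marker is uniform over its divisions in both classes.  The
    default sizes mirror the reference training cohort (29/89); the
    default strength (0.9, 0.1) is a strong, clearly recoverable effect.
    """
    m = scheme.marker(informative_marker)
    if m.n_divisions != 2:
        raise ValueError("informative marker must have exactly 2 divisions")
    probs: dict[int, dict[int, list[float]]] = {0: {}, 1: {}}
    for mk in scheme.markers:
        u = [1.0 / mk.n_divisions] * mk.n_divisions
        probs[0][mk.id] = list(u)
        probs[1][mk.id] = list(u)
    probs[0][m.id] = [strength[0], strength[1]]
    probs[1][m.id] = [strength[1], strength[0]]
    return GeneratorSpec(scheme, class_sizes, probs, seed)


# ---------------------------------------------------------------------------
# Raw-value emission


def _sample_raw(rule: Rule, rng: np.random.Generator) -> object:
    """Draw a raw value satisfying ``rule``.

    Thresholded divisions are unbounded on one side; values are drawn
    from a window of width max(1, |c|/2) next to the cutoff, nudged off
    the boundary when the rule is strict.
    """
    if rule.op == "eq":
        return rule.value
    if rule.op == "between":
        lo, hi = float(rule.low), float(rule.high)
        return rng.uniform(lo, hi)
    c = float(rule.value)  # type: ignore[arg-type]
    span = max(1.0, abs(c) / 2.0)
    eps = 1e-9 * max(1.0, abs(c))
    if rule.op == "gt":
        return rng.uniform(c + eps, c + span)
    if rule.op == "ge":
        return rng.uniform(c, c + span)
    if rule.op == "lt":
        return rng.uniform(c - span, c - eps)
    return rng.uniform(c - span, c)  # le


def _records_from_divisions(
    divisions: np.ndarray,
    outcome: str,
    scheme: CutoffScheme,
    rng: np.random.Generator,
    emit_raw: bool,
) -> list[PatientRecord]:
    """Build records from an (n, n_markers) array of 0-based divisions."""
    records = []
    for row in divisions:
        values: dict[str, object] = {}
        for m, r in zip(scheme.markers, row):
            rule = m.divisions[int(r)].rule
            values[m.name] = _sample_raw(rule, rng) if emit_raw else (
                rule.value if rule.op == "eq" else None
            )
            if not emit_raw and rule.op != "eq":
                # keep a representative in-division value even without
                # random emission, so discretization stays total
                values[m.name] = _midpoint(rule)
        records.append(PatientRecord(values=values, outcome=outcome))
    return records


def _midpoint(rule: Rule) -> float:
    if rule.op == "between":
        return (float(rule.low) + float(rule.high)) / 2.0
    c = float(rule.value)  # type: ignore[arg-type]
    span = max(1.0, abs(c) / 2.0)
    if rule.op in ("gt", "ge"):
        return c + span / 2.0
    return c - span / 2.0


# ---------------------------------------------------------------------------
# Operations


def generate(spec: GeneratorSpec, emit_raw: bool = True) -> LabeledDataset:
    """Draw a cohort: each record's division in each marker sampled
    independently from its class's probability vector.  Reproducible
    under the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    # draw every division index before any raw-value emission so the
    # drawn cohort is identical whether or not raw values are emitted
    per_class: list[np.ndarray] = []
    for i in (0, 1):
        n = spec.class_sizes[i]
        cols = [
            rng.choice(
                m.n_divisions,
                size=n,
                p=np.asarray(spec.probabilities[i][m.id], dtype=float),
            )
            for m in spec.scheme.markers
        ]
        per_class.append(np.stack(cols, axis=1) if n else np.empty((0, 0), int))
    records: list[PatientRecord] = []
    for i, label in enumerate(CLASSES):
        records.extend(
            _records_from_divisions(per_class[i], label, spec.scheme, rng, emit_raw)
        )
    return LabeledDataset(records)


def materialize_exact_counts(
    counts: DivisionCountTable,
    scheme: CutoffScheme,
    seed: int = 0,
    emit_raw: bool = True,
) -> LabeledDataset:
    """A dataset whose per-class per-marker division tallies equal
    ``counts`` exactly.

    Within each class, each marker's division assignments are shuffled
    independently across records, so the joint structure is an arbitrary
    consistent realization of the given marginals.
    """
    rng = np.random.default_rng(seed)
    marker_ids = counts.marker_ids
    markers = [scheme.marker(j) for j in marker_ids]
    records: list[PatientRecord] = []
    for i, label in enumerate(CLASSES):
        n = counts.class_sizes[i]
        cols = []
        for m in markers:
            col = np.repeat(
                np.arange(m.n_divisions),
                np.asarray(counts.counts[m.id][i], dtype=np.int64),
            )
            rng.shuffle(col)
            cols.append(col)
        divisions = np.stack(cols, axis=1) if n else np.empty((0, 0), int)
        sub = CutoffScheme(markers=tuple(markers), version=scheme.version)
        records.extend(
            _records_from_divisions(divisions, label, sub, rng, emit_raw)
        )
    return LabeledDataset(records)
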