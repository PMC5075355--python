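"""Optimal-marker selection by resampling over virtual samples.

Small training cohorts make wrapper feature selection prone to
overfitting, so each candidate marker combination is scored not on the
training set itself but on *virtual* samples: the training set is
repeatedly split (stratified, default in half) into virtual training
and virtual test halves, a discrete Bayes classifier is fitted on the
former and applied to the latter, and the combination's score is the
mean sensitivity and mean specificity over N such trials (default
N = 100).  For each combination size d the size-d subsets of the
candidate pool are enumerated exhaustively; among those whose mean
specificity clears the constraint (default 0.5) the one with maximal
mean sensitivity becomes that size's candidate, and the overall optimum
is the candidate with the highest mean sensitivity (ties go to fewer
markers).

The virtual-split sequence is a function of the seed, the data and the
split fraction only — not of the combination — so all combinations of
one search are scored on the same N splits (common random numbers).
This makes scores directly comparable across combinations and means
``search_per_size`` is exactly reproducible by calling
``evaluate_combination`` subset by subset with the same seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .domain_model import (
    CutoffScheme,
    LabeledDataset,
    RECURRENCE,
    discretize_dataset,
)

logger = logging.getLogger(__name__)

DEFAULT_SPECIFICITY_THRESHOLD = 0.5
#: float guard so a mean specificity of exactly 0.50 qualifies
_THRESHOLD_TOL = 1e-9


@dataclass(frozen=True)
class CombinationScore:
    """Resampling score of one marker combination."""

    markers: tuple[int, ...]
    mean_sensitivity: float
    mean_specificity: float
    n_trials: int

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("need at least one trial")

    @property
    def size(self) -> int:
        return len(self.markers)

    @property
    def youden(self) -> float:
        """Youden index of the two means."""
        return self.mean_sensitivity + self.mean_specificity - 1.0


@dataclass(frozen=True)
class SelectionResult:
    """Per-size candidates and the overall optimal combination."""

    per_size: Mapping[int, CombinationScore | None]
    optimal: CombinationScore | None
    threshold: float = DEFAULT_SPECIFICITY_THRESHOLD


# ---------------------------------------------------------------------------
# Stratified virtual splits


def _stratified_split_indices(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random per-class split; the larger half goes to (virtual)
    training via ceiling on odd counts."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("split fraction must be in (0, 1)")
    train_parts, test_parts = [], []
    for i in (0, 1):
        idx = np.flatnonzero(y == i)
        if len(idx) == 0:
            raise ValueError(f"class {i} is empty; cannot split")
        k = int(np.ceil(len(idx) * fraction))
        if k == len(idx):
            raise ValueError(
                f"fraction {fraction} leaves class {i} with an empty "
                "(virtual) test half"
            )
        perm = rng.permutation(idx)
        train_parts.append(perm[:k])
        test_parts.append(perm[k:])
    return np.concatenate(train_parts), np.concatenate(test_parts)


def resample_split(
    training: LabeledDataset,
    fraction: float = 0.5,
    seed: int = 0,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Split a training set into virtual training / virtual test halves,
    stratified by class, reproducibly under ``seed``."""
    y = np.array(
        [0 if r.outcome == RECURRENCE else 1 for r in training.records]
    )
    rng = np.random.default_rng(seed)
    tr, te = _stratified_split_indices(y, fraction, rng)
    return training.subset(tr.tolist()), training.subset(te.tolist())


def _virtual_splits(
    y: np.ndarray, n_trials: int, fraction: float, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """The N virtual splits of a search: a pure function of
    (seed, class labels, fraction) so that every combination sees the
    same split sequence."""
    rng = np.random.default_rng(seed)
    splits = []
    while len(splits) < n_trials:
        tr, te = _stratified_split_indices(y, fraction, rng)
        if len(set(y[tr])) < 2:  # defensive; cannot occur stratified
            logger.warning("virtual training lacks a class; resampling trial")
            continue
        splits.append((tr, te))
    return splits


# ---------------------------------------------------------------------------
# Vectorized trial kernel


def _trial_numerators(
    X: np.ndarray,
    y: np.ndarray,
    n_divisions: Sequence[int],
    split: tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial lookup table of division counts for the test records.

    Returns ``(NUM, y_test)`` where ``NUM[i, m, t]`` is the virtual
    training count of class ``i`` in the division that test record
    ``t`` occupies in marker column ``m``.
    """
    tr, te = split
    ytr = y[tr]
    Xte = X[te]
    num_rows = []
    for i in (0, 1):
        rows_i = []
        tri = tr[ytr == i]
        for m in range(X.shape[1]):
            c = np.bincount(X[tri, m], minlength=n_divisions[m])
            rows_i.append(c[Xte[:, m]])
        num_rows.append(np.stack(rows_i))
    return np.stack(num_rows).astype(np.float64), y[te]


def _combo_decisions(
    NUM: np.ndarray,
    cols: Sequence[int],
    priors: tuple[float, float],
) -> np.ndarray:
    """Max-posterior decisions (0/1) for one combination in one trial.

    Ties — including the degenerate case of zero likelihood in both
    classes — go to class 0 (recurrence), the default tie-break.
    """
    sub = NUM[:, cols, :]  # (2, d, n_test)
    d = sub.shape[1]
    denom = sub.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        joint = np.where(denom > 0, sub.prod(axis=1) / denom**d, 0.0)
    s0 = priors[0] * joint[0]
    s1 = priors[1] * joint[1]
    return np.where(s0 >= s1, 0, 1)


def _score_trial(pred: np.ndarray, y_test: np.ndarray) -> tuple[float, float]:
    pos = y_test == 0
    sens = float(np.mean(pred[pos] == 0))
    spec = float(np.mean(pred[~pos] == 1))
    return sens, spec


# ---------------------------------------------------------------------------
# Operations


def evaluate_combination(
    training: LabeledDataset,
    scheme: CutoffScheme,
    markers: Sequence[int],
    n_trials: int = 100,
    fraction: float = 0.5,
    seed: int = 0,
    priors: tuple[float, float] = (0.5, 0.5),
) -> CombinationScore:
    """Mean sensitivity/specificity of one combination over N virtual
    splits (fit on the virtual training half, classify every virtual
    test record, tally; average the per-trial rates)."""
    markers = tuple(markers)
    X, y = discretize_dataset(training, scheme, markers)
    ndiv = [scheme.marker(j).n_divisions for j in markers]
    sens_sum = spec_sum = 0.0
    for split in _virtual_splits(y, n_trials, fraction, seed):
        NUM, y_test = _trial_numerators(X, y, ndiv, split)
        sens, spec = _score_trial(
            _combo_decisions(NUM, range(len(markers)), priors), y_test
        )
        sens_sum += sens
        spec_sum += spec
    return CombinationScore(
        markers=markers,
        mean_sensitivity=sens_sum / n_trials,
        mean_specificity=spec_sum / n_trials,
        n_trials=n_trials,
    )


def _search_sizes(
    training: LabeledDataset,
    scheme: CutoffScheme,
    candidates: Sequence[int],
    sizes: Sequence[int],
    n_trials: int,
    fraction: float,
    threshold: float,
    seed: int,
    priors: tuple[float, float],
) -> dict[int, CombinationScore | None]:
    """Exhaustive search over all sizes, sharing splits and per-trial
    count lookups across every combination."""
    candidates = tuple(candidates)
    for d in sizes:
        if not 1 <= d <= len(candidates):
            raise ValueError(f"size {d} out of range for {len(candidates)} candidates")
    X, y = discretize_dataset(training, scheme, candidates)
    ndiv = [scheme.marker(j).n_divisions for j in candidates]
    combos: list[tuple[int, ...]] = []
    combo_sizes: list[int] = []
    for d in sizes:
        for cols in itertools.combinations(range(len(candidates)), d):
            combos.append(cols)
            combo_sizes.append(d)
    sens_sum = np.zeros(len(combos))
    spec_sum = np.zeros(len(combos))
    for split in _virtual_splits(y, n_trials, fraction, seed):
        NUM, y_test = _trial_numerators(X, y, ndiv, split)
        pos = y_test == 0
        neg = ~pos
        for ci, cols in enumerate(combos):
            pred = _combo_decisions(NUM, cols, priors)
            sens_sum[ci] += np.mean(pred[pos] == 0)
            spec_sum[ci] += np.mean(pred[neg] == 1)
    scores = [
        CombinationScore(
            markers=tuple(candidates[c] for c in cols),
            mean_sensitivity=sens_sum[ci] / n_trials,
            mean_specificity=spec_sum[ci] / n_trials,
            n_trials=n_trials,
        )
        for ci, cols in enumerate(combos)
    ]
    out: dict[int, CombinationScore | None] = {}
    for d in sizes:
        of_size = [s for s, sd in zip(scores, combo_sizes) if sd == d]
        out[d] = _best_of(of_size, threshold)
    return out


def _best_of(
    scores: Iterable[CombinationScore], threshold: float
) -> CombinationScore | None:
    """Best qualifying score: maximal mean sensitivity among those with
    mean specificity >= threshold; sensitivity ties broken by higher
    specificity, then lexicographic marker ids."""
    qualifying = [
        s
        for s in scores
        if s.mean_specificity >= threshold - _THRESHOLD_TOL
    ]
    if not qualifying:
        return None
    return min(
        qualifying,
        key=lambda s: (-s.mean_sensitivity, -s.mean_specificity, s.markers),
    )


def search_per_size(
    training: LabeledDataset,
    scheme: CutoffScheme,
    candidates: Sequence[int],
    size: int,
    n_trials: int = 100,
    fraction: float = 0.5,
    threshold: float = DEFAULT_SPECIFICITY_THRESHOLD,
    seed: int = 0,
    priors: tuple[float, float] = (0.5, 0.5),
) -> CombinationScore | None:
    """Evaluate every size-``size`` subset of the candidates; return the
    best qualifying combination, or None if no subset clears the
    specificity constraint."""
    return _search_sizes(
        training, scheme, candidates, [size], n_trials, fraction,
        threshold, seed, priors,
    )[size]


def select_optimal(
    per_size: Mapping[int, CombinationScore | None],
    threshold: float = DEFAULT_SPECIFICITY_THRESHOLD,
) -> SelectionResult:
    """Pick the overall optimum among the per-size candidates: maximal
    mean sensitivity, ties resolved toward fewer markers."""
    present = [s for s in per_size.values() if s is not None]
    best = None
    if present:
        best = min(
            present,
            key=lambda s: (
                -s.mean_sensitivity,
                s.size,
                -s.mean_specificity,
                s.markers,
            ),
        )
    return SelectionResult(per_size=dict(per_size), optimal=best, threshold=threshold)


def select_markers(
    training: LabeledDataset,
    scheme: CutoffScheme,
    candidates: Sequence[int] | None = None,
    sizes: Sequence[int] | None = None,
    n_trials: int = 100,
    fraction: float = 0.5,
    threshold: float = DEFAULT_SPECIFICITY_THRESHOLD,
    seed: int = 0,
    priors: tuple[float, float] = (0.5, 0.5),
) -> SelectionResult:
    """Full search: per-size exhaustive candidate search followed by the
    overall choice.  Sizes default to 3..M-1 for M candidate markers."""
    if candidates is None:
        candidates = scheme.marker_ids
    if sizes is None:
        sizes = range(3, len(candidates))
    per_size = _search_sizes(
        training, scheme, candidates, list(sizes), n_trials, fraction,
        threshold, seed, priors,
    )
    return select_optimal(per_size, threshold)
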