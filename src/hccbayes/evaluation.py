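"""Holdout evaluation, diagnostic metrics, learning curves and ROC
operating points.

The evaluation protocol is a single stratified holdout: recurrence and
nonrecurrence patients are each randomly halved, the classifier is
designed on one half and evaluated on the other (odd class counts send
the larger half to training, so a 57/177 cohort yields 29+89 training
and 28+88 test patients).  Performance is summarized by sensitivity,
specificity, accuracy, the Youden index (sensitivity + specificity - 1),
the F1 measure and the diagnostic odds ratio TP*TN/(FN*FP), with the
recurrence class as positive.

`reconstruct_confusion` inverts published sensitivity/specificity pairs
back to integer confusion matrices (round half up), which lets printed
comparator results — staging systems whose internal point definitions
are not reimplemented here — be placed on the same metric scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .discrete_bayes import classify_dataset, fit
from .domain_model import (
    CLASSES,
    RECURRENCE,
    CutoffScheme,
    LabeledDataset,
    count_divisions,
)
from .marker_selection import resample_split


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (the tie rule used for reported tables)."""
    if math.isnan(x) or math.isinf(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Confusion matrices and metrics


@dataclass(frozen=True)
class ConfusionMatrix:
    """Two-class tally; positive class = recurrence."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn


def confusion(
    predictions: Sequence[str], truths: Sequence[str]
) -> ConfusionMatrix:
    """Exact tally of predicted vs true class labels."""
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths differ in length")
    tp = fn = fp = tn = 0
    for p, t in zip(predictions, truths):
        if p not in CLASSES or t not in CLASSES:
            raise ValueError(f"labels must be in {CLASSES}")
        if t == RECURRENCE:
            tp += p == RECURRENCE
            fn += p != RECURRENCE
        else:
            tn += p != RECURRENCE
            fp += p == RECURRENCE
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


@dataclass(frozen=True)
class MetricReport:
    sensitivity: float
    specificity: float
    accuracy: float
    youden: float
    f1: float
    diagnostic_odds_ratio: float

    def rounded(self, ndigits: int = 2) -> "MetricReport":
        """Half-up rounded copy, as reported in comparison tables."""
        return MetricReport(
            **{
                k: round_half_up(v, ndigits)
                for k, v in self.__dict__.items()
            }
        )

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """The six diagnostic metrics of a confusion matrix.

    The diagnostic odds ratio is infinite when FN*FP = 0 with
    TP*TN > 0, and NaN in the doubly degenerate 0/0 case.
    """
    if cm.n_positive == 0 or cm.n_negative == 0:
        raise ValueError("need at least one patient in each class")
    sens = cm.tp / cm.n_positive
    spec = cm.tn / cm.n_negative
    acc = (cm.tp + cm.tn) / (cm.n_positive + cm.n_negative)
    f1 = (
        2 * cm.tp / (2 * cm.tp + cm.fp + cm.fn)
        if (2 * cm.tp + cm.fp + cm.fn) > 0
        else 0.0
    )
    num, den = cm.tp * cm.tn, cm.fn * cm.fp
    if den > 0:
        dor = num / den
    elif num > 0:
        dor = math.inf
    else:
        dor = math.nan
    return MetricReport(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        youden=sens + spec - 1.0,
        f1=f1,
        diagnostic_odds_ratio=dor,
    )


def reconstruct_confusion(
    sensitivity: float,
    specificity: float,
    n_positive: int,
    n_negative: int,
) -> ConfusionMatrix:
    """Integer confusion matrix consistent with printed rates:
    TP = round(sensitivity * n_positive) half-up, TN likewise, FN/FP by
    complement."""
    tp = int(round_half_up(sensitivity * n_positive, 0))
    tn = int(round_half_up(specificity * n_negative, 0))
    return ConfusionMatrix(
        tp=tp, fn=n_positive - tp, fp=n_negative - tn, tn=tn
    )


# ---------------------------------------------------------------------------
# Holdout protocol


def holdout_split(
    data: LabeledDataset, seed: int = 0, fraction: float = 0.5
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified random halving into (training, test); odd class
    counts send the larger half to training."""
    return resample_split(data, fraction=fraction, seed=seed)


def evaluate_holdout(
    training: LabeledDataset,
    test: LabeledDataset,
    scheme: CutoffScheme,
    markers: Sequence[int],
    priors: tuple[float, float] = (0.5, 0.5),
    smoothing: float = 0.0,
    tie_break: str = RECURRENCE,
) -> tuple[ConfusionMatrix, MetricReport]:
    """Fit on the training half with the given markers and score the
    test half."""
    counts = count_divisions(training, scheme, markers)
    model = fit(counts, markers, priors=priors, smoothing=smoothing)
    preds = classify_dataset(model, test, scheme, tie_break=tie_break)
    cm = confusion(preds, [r.outcome for r in test.records])
    return cm, metrics(cm)


# ---------------------------------------------------------------------------
# Learning curves over nested training subsets


@dataclass(frozen=True)
class SubsetSchedule:
    """Strictly growing (recurrence, nonrecurrence) subset sizes; each
    step's records are a superset of the previous step's (nesting is
    realized by prefix sampling of one per-class permutation)."""

    steps: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for (a1, b1), (a2, b2) in zip(self.steps, self.steps[1:]):
            if a2 < a1 or b2 < b1 or (a2, b2) == (a1, b1):
                raise ValueError(
                    "subset sizes must increase componentwise"
                )


def default_schedule(full: tuple[int, int] = (29, 89)) -> SubsetSchedule:
    """Six nested subsets: (5, 15), then (6, 17), then four linearly
    interpolated steps up to the full training size.

    Only the first two steps and the nesting structure are fixed by the
    protocol; the interpolation is this package's default and the
    schedule is fully configurable.
    """
    first, second = (5, 15), (6, 17)
    steps = [first, second]
    for k in range(1, 5):
        steps.append(
            (
                int(round(second[0] + (full[0] - second[0]) * k / 4)),
                int(round(second[1] + (full[1] - second[1]) * k / 4)),
            )
        )
    return SubsetSchedule(tuple(steps))


def nested_chain(
    training: LabeledDataset,
    schedule: SubsetSchedule,
    rng: np.random.Generator,
) -> list[list[int]]:
    """One random nested chain of record-index subsets realizing the
    schedule: S_k is a prefix of S_{k+1} within each class."""
    pos = [i for i, r in enumerate(training.records) if r.outcome == RECURRENCE]
    neg = [i for i, r in enumerate(training.records) if r.outcome != RECURRENCE]
    n1, n2 = schedule.steps[-1]
    if n1 > len(pos) or n2 > len(neg):
        raise ValueError("schedule exceeds available training records")
    p = rng.permutation(pos)
    q = rng.permutation(neg)
    return [list(p[:a]) + list(q[:b]) for a, b in schedule.steps]


@dataclass(frozen=True)
class LearningCurvePoint:
    n_recurrence: int
    n_nonrecurrence: int
    mean_sensitivity: float
    ci_low: float
    ci_high: float


def learning_curve(
    training: LabeledDataset,
    test: LabeledDataset,
    scheme: CutoffScheme,
    markers: Sequence[int],
    schedule: SubsetSchedule | None = None,
    n_trials: int = 30,
    seed: int = 0,
    ci_method: str = "normal",
    priors: tuple[float, float] = (0.5, 0.5),
) -> list[LearningCurvePoint]:
    """Sensitivity on the fixed test set as the training subset grows.

    Each trial draws one nested chain, fits one classifier per subset
    and scores it on the test set; reported per subset are the mean
    sensitivity over trials and a 95% confidence interval (normal
    approximation by default, ``ci_method="percentile"`` for the
    bootstrap-percentile alternative).
    """
    if schedule is None:
        schedule = default_schedule(training.class_sizes)
    rng = np.random.default_rng(seed)
    truths = [r.outcome for r in test.records]
    sens = np.empty((n_trials, len(schedule.steps)))
    for t in range(n_trials):
        for k, idx in enumerate(nested_chain(training, schedule, rng)):
            counts = count_divisions(training.subset(idx), scheme, markers)
            model = fit(counts, markers, priors=priors)
            preds = classify_dataset(model, test, scheme)
            sens[t, k] = metrics(confusion(preds, truths)).sensitivity
    points = []
    z = stats.norm.ppf(0.975)
    for k, (a, b) in enumerate(schedule.steps):
        vals = sens[:, k]
        m = float(vals.mean())
        if ci_method == "normal":
            half = z * float(vals.std(ddof=1)) / math.sqrt(n_trials) if n_trials > 1 else 0.0
            lo, hi = m - half, m + half
        elif ci_method == "percentile":
            lo, hi = (float(v) for v in np.percentile(vals, [2.5, 97.5]))
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
        points.append(LearningCurvePoint(a, b, m, lo, hi))
    return points


# ---------------------------------------------------------------------------
# ROC operating points by marker count


def roc_points(
    training: LabeledDataset,
    test: LabeledDataset,
    scheme: CutoffScheme,
    combos: Mapping[int, Sequence[int]] | None = None,
    sizes: Sequence[int] = (3, 4, 5, 6),
    n_trials: int = 100,
    seed: int = 0,
    priors: tuple[float, float] = (0.5, 0.5),
) -> list[tuple[float, float]]:
    """One (1 - specificity, sensitivity) operating point per marker
    count, plus the (0, 0) and (1, 1) anchors, sorted by false-positive
    rate.

    ``combos`` maps marker count to the combination to use (e.g. the
    per-size candidates of a prior selection).  When omitted, the
    per-size search is re-run on the training half (the refit route).
    """
    if combos is None:
        from .marker_selection import search_per_size

        combos = {}
        for d in sizes:
            best = search_per_size(
                training, scheme, scheme.marker_ids, d,
                n_trials=n_trials, seed=seed, priors=priors,
            )
            if best is not None:
                combos[d] = best.markers
    points = [(0.0, 0.0), (1.0, 1.0)]
    for d in sorted(combos):
        _, rep = evaluate_holdout(
            training, test, scheme, combos[d], priors=priors
        )
        points.append((1.0 - rep.specificity, rep.sensitivity))
    return sorted(points)


# ---------------------------------------------------------------------------
# Balanced-resampling comparison (equal class sizes in the test set)


def balanced_resampled_metrics(
    predictions: Sequence[str],
    truths: Sequence[str],
    n_rounds: int = 100,
    seed: int = 0,
) -> dict[str, tuple[float, float, float]]:
    """Re-evaluate fixed test-set predictions on class-balanced
    subsamples.

    Each round draws, without replacement, min(n_pos, n_neg) patients
    from each class and recomputes the metric suite; reported per
    metric are the mean and a normal-approximation 95% CI over rounds.
    Rounds where the diagnostic odds ratio is infinite are excluded
    from its aggregate.
    """
    preds = np.asarray(predictions)
    ys = np.asarray(truths)
    pos = np.flatnonzero(ys == RECURRENCE)
    neg = np.flatnonzero(ys != RECURRENCE)
    k = min(len(pos), len(neg))
    if k == 0:
        raise ValueError("need patients of both classes")
    rng = np.random.default_rng(seed)
    samples: dict[str, list[float]] = {}
    for _ in range(n_rounds):
        take = np.concatenate(
            [rng.choice(pos, k, replace=False), rng.choice(neg, k, replace=False)]
        )
        rep = metrics(confusion(list(preds[take]), list(ys[take])))
        for name, v in rep.as_dict().items():
            samples.setdefault(name, []).append(v)
    out = {}
    z = stats.norm.ppf(0.975)
    for name, vals in samples.items():
        arr = np.asarray(vals)
        arr = arr[np.isfinite(arr)]
        m = float(arr.mean())
        half = z * float(arr.std(ddof=1)) / math.sqrt(len(arr)) if len(arr) > 1 else 0.0
        out[name] = (m, m - half, m + half)
    return out
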