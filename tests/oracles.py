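"""Independent brute-force oracles used only by the tests.

Everything here is written directly from the defining formulas with
exact rational arithmetic, deliberately sharing no code with the
package implementation.
"""

from __future__ import annotations

from fractions import Fraction

import hccbayes as hb


def bayes_oracle(
    table: hb.DivisionCountTable,
    pattern: hb.DiscretizedPattern,
    priors: tuple[Fraction, Fraction] = (Fraction(1, 2), Fraction(1, 2)),
):
    """Exact evaluation of the discrete Bayes rule.

    Returns (per-class division-conditional dicts, joints, posteriors,
    predicted class index); posteriors is None when both prior-weighted
    joints vanish (the degenerate case, decided by the w1 tie-break).
    """
    conds: list[dict[int, Fraction | None]] = []
    joints: list[Fraction] = []
    for i in (0, 1):
        denom = sum(
            table.count(i, j, r) for j, r in pattern.divisions
        )
        per_marker: dict[int, Fraction | None] = {}
        joint = Fraction(1)
        for j, r in pattern.divisions:
            if denom == 0:
                per_marker[j] = None
                joint = Fraction(0)
            else:
                p = Fraction(table.count(i, j, r), denom)
                per_marker[j] = p
                joint *= p
        conds.append(per_marker)
        joints.append(joint)
    s = [priors[0] * joints[0], priors[1] * joints[1]]
    total = s[0] + s[1]
    if total == 0:
        return conds, joints, None, 0  # tie-break: recurrence
    post = (s[0] / total, s[1] / total)
    pred = 0 if post[0] >= post[1] else 1
    return conds, joints, post, pred


def metrics_oracle(tp: int, fn: int, fp: int, tn: int) -> dict[str, Fraction | float]:
    """Textbook metric formulas with exact rationals."""
    sens = Fraction(tp, tp + fn)
    spec = Fraction(tn, tn + fp)
    acc = Fraction(tp + tn, tp + fn + fp + tn)
    precision = Fraction(tp, tp + fp) if tp + fp else None
    if precision is None or precision + sens == 0:
        f1 = Fraction(0)
    else:
        f1 = 2 * precision * sens / (precision + sens)
    if fn * fp > 0:
        dor: Fraction | float = Fraction(tp * tn, fn * fp)
    elif tp * tn > 0:
        dor = float("inf")
    else:
        dor = float("nan")
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "youden": sens + spec - 1,
        "f1": f1,
        "diagnostic_odds_ratio": dor,
    }


def recount_oracle(data: hb.LabeledDataset, scheme: hb.CutoffScheme):
    """Per-record tally loop, independent of count_divisions."""
    out: dict[int, list[list[int]]] = {
        m.id: [[0] * m.n_divisions for _ in range(2)] for m in scheme.markers
    }
    sizes = [0, 0]
    for rec in data.records:
        i = 0 if rec.outcome == hb.RECURRENCE else 1
        sizes[i] += 1
        for m in scheme.markers:
            r = m.discretize(rec.get(m.name))
            out[m.id][i][r - 1] += 1
    return out, tuple(sizes)
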