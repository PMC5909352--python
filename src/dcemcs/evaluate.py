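"""Performance metrics and the McNemar paired-classifier comparison.

Malignant is the positive class throughout: sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN),
accuracy = (TP+TN)/n, all reported as percentages. Metrics are kept at
full precision internally; display rounding is half-up to one decimal.

The McNemar test compares two classifiers on the same lesions through the
discordant counts b (A correct, B wrong) and c (A wrong, B correct): an
exact two-sided binomial p-value when b + c is small, otherwise the
continuity-corrected chi-square statistic (|b-c| - 1)^2/(b+c) on 1 df.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "metrics",
           "mcnemar", "round_half_up"]

VALID_LABELS = {"benign", "malignant"}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v < 0 or int(v) != v:
                raise ValueError(f"count {name} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Percentages at full precision; NaN where a denominator is zero
    (the corresponding flag in ``undefined`` is set)."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    undefined: tuple[str, ...] = ()

    def rounded(self, decimals: int = 1) -> dict:
        """Display form: half-up rounding to match printed tables."""
        return {name: (None if name in self.undefined
                       else round_half_up(getattr(self, name), decimals))
                for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy")}


def round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _check_labels(labels: Sequence[str], name: str) -> None:
    bad = set(labels) - VALID_LABELS
    if bad:
        raise ValueError(f"{name} contains labels outside benign/malignant: {sorted(bad)}")


def confusion(truth: Sequence[str], pred: Sequence[str]) -> ConfusionCounts:
    """Counts with malignant as the positive class."""
    if len(truth) != len(pred):
        raise ValueError("truth and prediction lists differ in length")
    _check_labels(truth, "truth")
    _check_labels(pred, "pred")
    tp = sum(t == "malignant" and p == "malignant" for t, p in zip(truth, pred))
    fn = sum(t == "malignant" and p == "benign" for t, p in zip(truth, pred))
    tn = sum(t == "benign" and p == "benign" for t, p in zip(truth, pred))
    fp = sum(t == "benign" and p == "malignant" for t, p in zip(truth, pred))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else np.nan


def metrics(c: ConfusionCounts) -> MetricReport:
    if c.n == 0:
        raise ValueError("empty confusion counts")
    values = {
        "sensitivity": _ratio(c.tp, c.tp + c.fn),
        "specificity": _ratio(c.tn, c.tn + c.fp),
        "ppv": _ratio(c.tp, c.tp + c.fp),
        "npv": _ratio(c.tn, c.tn + c.fn),
        "accuracy": _ratio(c.tp + c.tn, c.n),
    }
    undefined = tuple(k for k, v in values.items() if np.isnan(v))
    return MetricReport(**values, undefined=undefined)


def mcnemar(pred_a: Sequence[str], pred_b: Sequence[str], truth: Sequence[str],
            exact_cutoff: int = 25) -> float:
    """Two-sided McNemar p-value for paired classifiers A and B.

    Exact binomial when b + c < ``exact_cutoff``, else chi-square with
    continuity correction. b + c = 0 returns 1 by convention.
    """
    if not len(pred_a) == len(pred_b) == len(truth) or len(truth) == 0:
        raise ValueError("prediction and truth lists must be aligned and non-empty")
    for lst, name in ((pred_a, "pred_a"), (pred_b, "pred_b"), (truth, "truth")):
        _check_labels(lst, name)
    a_correct = np.asarray([p == t for p, t in zip(pred_a, truth)])
    b_correct = np.asarray([p == t for p, t in zip(pred_b, truth)])
    b = int((a_correct & ~b_correct).sum())
    c = int((~a_correct & b_correct).sum())
    n_disc = b + c
    if n_disc == 0:
        return 1.0
    if n_disc < exact_cutoff:
        p = 2.0 * stats.binom.cdf(min(b, c), n_disc, 0.5)
        return float(min(1.0, p))
    chi2 = (abs(b - c) - 1.0) ** 2 / n_disc
    return float(stats.chi2.sf(chi2, df=1))
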