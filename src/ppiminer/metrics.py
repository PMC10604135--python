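"""Precision / recall / F1 metrics shared by the classifier and the tagger.

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

Zero denominators yield 0 with a warning, matching the behavior of
scikit-learn's classification report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Sequence

__all__ = ["ConfusionCounts", "precision_recall_f1", "evaluate_binary", "weighted_f1"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    """Compute (precision, recall, F1) from confusion counts."""
    if c.TP + c.FP > 0:
        precision = c.TP / (c.TP + c.FP)
    else:
        warnings.warn("precision undefined (TP+FP=0); returning 0", stacklevel=2)
        precision = 0.0
    if c.TP + c.FN > 0:
        recall = c.TP / (c.TP + c.FN)
    else:
        warnings.warn("recall undefined (TP+FN=0); returning 0", stacklevel=2)
        recall = 0.0
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
    return precision, recall, f1


def _counts_for(y_true: Sequence, y_pred: Sequence, positive) -> ConfusionCounts:
    tp = fp = fn = tn = 0
    for t, p in zip(y_true, y_pred):
        if p == positive and t == positive:
            tp += 1
        elif p == positive:
            fp += 1
        elif t == positive:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


def evaluate_binary(y_true: Sequence[int], y_pred: Sequence[int]) -> dict:
    """Per-class precision/recall/F1 plus the macro (unweighted) average F1.

    Each class is treated as positive in turn; the macro average is the
    unweighted mean over the two classes.
    """
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    if not y_true:
        raise ValueError("empty evaluation set")
    report: dict = {"per_class": {}}
    f1s = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cls in (0, 1):
            p, r, f1 = precision_recall_f1(_counts_for(y_true, y_pred, cls))
            report["per_class"][cls] = {"precision": p, "recall": r, "f1": f1}
            f1s.append(f1)
    report["macro_f1"] = sum(f1s) / len(f1s)
    return report


def weighted_f1(
    gold: Sequence[Sequence[Hashable]], predicted: Sequence[Sequence[Hashable]]
) -> float:
    """Support-weighted mean of per-label F1 over tag sequences.

    Per-label F1 is computed treating each label in the gold tag set as
    positive in turn; weights are the label's gold support divided by the
    total number of tokens.
    """
    if len(gold) != len(predicted):
        raise ValueError("sequence count mismatch")
    flat_gold: list = []
    flat_pred: list = []
    for g, p in zip(gold, predicted):
        if len(g) != len(p):
            raise ValueError("tag sequence length mismatch")
        flat_gold.extend(g)
        flat_pred.extend(p)
    if not flat_gold:
        raise ValueError("empty tag sequences")
    total = len(flat_gold)
    score = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for label in sorted(set(flat_gold), key=str):
            support = sum(1 for t in flat_gold if t == label)
            _, _, f1 = precision_recall_f1(_counts_for(flat_gold, flat_pred, label))
            score += f1 * support / total
    return score
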