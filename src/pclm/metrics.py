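"""Evaluation statistics for residue-level binary and multi-label predictions.

Binary residue metrics (Sn, Sp, ACC, BACC, MCC), ROC/AUC with tie-corrected
steps, example-based multi-label metrics over label sets, the absolute
point-biserial correlation used for feature-quality scoring, and a seeded
random multi-label baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import FUNCTIONS

__all__ = ["BinaryEval", "MultiLabelEval", "confusion_metrics", "roc_auc",
           "multilabel_metrics", "pbc", "random_baseline",
           "evaluate_function", "harmonic_f1", "report_table"]


@dataclass
class BinaryEval:
    Sn: float
    Sp: float
    ACC: float
    BACC: float
    MCC: float
    AUC: float | None = None
    threshold: float | None = None
    mcc_undefined: bool = False

    def __post_init__(self):
        assert abs(self.BACC - 0.5 * (self.Sn + self.Sp)) < 1e-12


@dataclass
class MultiLabelEval:
    hamming_loss: float
    accuracy_exam: float
    precision_exam: float
    recall_exam: float
    f1_exam: float
    p: int
    q: int


def confusion_metrics(calls: np.ndarray, y: np.ndarray,
                      threshold: float | None = None) -> BinaryEval:
    """Sn/Sp/ACC/BACC/MCC from binary calls against binary truth.

    A zero MCC denominator (degenerate confusion table) is reported as
    MCC = 0 with ``mcc_undefined`` set, alongside a warning.
    """
    calls = np.asarray(calls, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if calls.shape != y.shape:
        raise ValueError("calls and labels must have equal length")
    tp = int(((calls == 1) & (y == 1)).sum())
    tn = int(((calls == 0) & (y == 0)).sum())
    fp = int(((calls == 1) & (y == 0)).sum())
    fn = int(((calls == 0) & (y == 1)).sum())
    pos, neg = tp + fn, tn + fp
    if pos == 0 or neg == 0:
        raise ValueError("both classes must be present in the labels")
    sn = tp / pos
    sp = tn / neg
    acc = (tp + tn) / (pos + neg)
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    undefined = denom == 0.0
    if undefined:
        warnings.warn("MCC denominator is zero; reporting MCC = 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / denom
    return BinaryEval(sn, sp, acc, 0.5 * (sn + sp), mcc,
                      threshold=threshold, mcc_undefined=undefined)


def roc_auc(scores: np.ndarray, y: np.ndarray,
            return_curve: bool = False):
    """Trapezoidal area under the ROC curve with tie groups stepped together.

    Equivalent to the tie-corrected Mann-Whitney statistic U/(n1*n0).
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present for ROC analysis")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = y[order]
    # collapse tie groups: cumulative TP/FP at each distinct score
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    ctp = np.cumsum(t)[distinct]
    cfp = np.cumsum(1 - t)[distinct]
    tpr = np.r_[0.0, ctp / n1]
    fpr = np.r_[0.0, cfp / n0]
    auc = float(np.trapezoid(tpr, fpr))
    if return_curve:
        return auc, np.column_stack([fpr, tpr])
    return auc


def multilabel_metrics(H: list[set[int]], Y: list[set[int]],
                       q: int) -> MultiLabelEval:
    """Example-based multi-label metrics over predicted/true label sets.

    Hamming loss, accuracy, precision and recall are means of per-example
    set comparisons; F1 is the harmonic mean of the *aggregate* precision
    and recall.  An empty predicted set contributes precision 0 for its
    example; an empty union counts as accuracy 1 (identical empty sets).
    """
    p = len(H)
    if p == 0 or len(Y) != p:
        raise ValueError("need equally many predicted and true label sets")
    ham = acc = prec = rec = 0.0
    for h, yset in zip(H, Y):
        if (h | yset) - set(range(1, q + 1)):
            raise ValueError(f"labels must be subsets of 1..{q}")
        ham += len(h ^ yset) / q
        union = len(h | yset)
        acc += (len(h & yset) / union) if union else 1.0
        prec += (len(h & yset) / len(h)) if h else 0.0
        rec += (len(h & yset) / len(yset)) if yset else 1.0
    ham, acc, prec, rec = ham / p, acc / p, prec / p, rec / p
    return MultiLabelEval(ham, acc, prec, rec, harmonic_f1(prec, rec), p, q)


def harmonic_f1(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def pbc(values: np.ndarray, labels: np.ndarray) -> float:
    """Absolute point-biserial correlation between a feature and a 0/1 label.

    |m1 - m0| / s_n * sqrt(n0 n1 / n^2) with the population (divide-by-n)
    standard deviation, which makes it exactly |Pearson| under 0/1 coding.
    """
    x = np.asarray(values, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if x.shape != y.shape:
        raise ValueError("feature and label vectors must have equal length")
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    sn = x.std()  # population sd
    if sn == 0.0:
        raise ValueError("feature has zero variance; PBC undefined")
    m1 = x[y == 1].mean()
    m0 = x[y == 0].mean()
    return float(abs(m1 - m0) / sn * np.sqrt(n0 * n1 / (y.size ** 2)))


def random_baseline(Y: list[set[int]], q: int, prob: float = 0.5,
                    seed: int = 0) -> list[set[int]]:
    """Predict each of the q labels independently with the given probability."""
    if not 0.0 <= prob <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    draws = rng.random((len(Y), q)) < prob
    return [{j + 1 for j in range(q) if draws[i, j]} for i in range(len(Y))]


def evaluate_function(scores: np.ndarray, y: np.ndarray,
                      threshold: float) -> BinaryEval:
    """One report row: AUC from scores plus confusion metrics at a threshold."""
    scores = np.asarray(scores, dtype=np.float64)
    auc = roc_auc(scores, y)
    ev = confusion_metrics((scores > threshold).astype(np.int64), y,
                           threshold=threshold)
    ev.AUC = auc
    return ev


def report_table(rows: dict[str, BinaryEval]) -> pd.DataFrame:
    """Per-function report (one row per function, fixed order)."""
    order = [f for f in FUNCTIONS if f in rows] + \
            [f for f in rows if f not in FUNCTIONS]
    data = [{"function": f, "AUC": rows[f].AUC, "Sn": rows[f].Sn,
             "Sp": rows[f].Sp, "ACC": rows[f].ACC, "BACC": rows[f].BACC,
             "MCC": rows[f].MCC, "threshold": rows[f].threshold}
            for f in order]
    return pd.DataFrame(data)
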