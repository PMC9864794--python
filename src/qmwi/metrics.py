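"""Segmentation performance metrics: Dice and Matthews coefficients.

Each class is scored one-vs-rest over pixels.  For a class c, TP counts pixels
correctly labelled c, TN pixels correctly labelled not-c, and FP/FN the two
disagreement kinds.  The Dice similarity coefficient

    DSC = 2·TP / (2·TP + FP + FN)

measures overlap of the predicted and true class regions; the Matthews
correlation coefficient

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

is the balanced correlation, more conservative under heavy class imbalance
(the background class dominates pixel counts).

Degenerate conventions (documented, chosen to avoid NaN-poisoning averages):
a class absent from both maps scores DSC = 1 (flagged ``degenerate``);
a zero factor in the MCC denominator scores MCC = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth.cylinders import ClassBinning


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest pixel counts for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def degenerate(self) -> bool:
        """Class absent from both prediction and truth."""
        return self.tp + self.fp + self.fn == 0


def confusion(pred: np.ndarray, truth: np.ndarray, class_id: int) -> ConfusionCounts:
    """One-vs-rest confusion counts over all pixels."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = pred == class_id
    t = truth == class_id
    return ConfusionCounts(
        tp=int((p & t).sum()),
        tn=int((~p & ~t).sum()),
        fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()),
    )


def dsc(c: ConfusionCounts) -> float:
    """Dice similarity coefficient; 1.0 by convention for an absent class."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2.0 * c.tp / denom


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0.0 when any denominator factor is 0."""
    factors = [c.tp + c.fp, c.tp + c.fn, c.tn + c.fp, c.tn + c.fn]
    if any(f == 0 for f in factors):
        return 0.0
    dm = np.sqrt(np.prod(np.asarray(factors, float)))
    return float((c.tp * c.tn - c.fp * c.fn) / dm)


def sample_metrics(pred: np.ndarray, truth: np.ndarray, n_classes: int) -> pd.DataFrame:
    """Per-class DSC/MCC for one predicted map."""
    rows = []
    for c in range(n_classes):
        cc = confusion(pred, truth, c)
        rows.append(
            {"class": c, "dsc": dsc(cc), "mcc": mcc(cc), "degenerate": cc.degenerate}
        )
    return pd.DataFrame(rows)


def evaluate_folds(
    predictions: dict[int, np.ndarray],
    truths: np.ndarray,
    fold_of_sample: dict[int, int],
    binning: ClassBinning,
    mode: str = "per-sample",
) -> pd.DataFrame:
    """Fold-averaged per-class metrics report.

    ``mode='per-sample'`` (default): metrics per sample, averaged within each
    fold, then across folds.  ``mode='pooled'``: confusion counts pooled over
    each fold's pixels before computing the metrics, then averaged across
    folds.  Rows are ordered by descending class with the contrast interval
    attached, mirroring the usual reporting layout.
    """
    if mode not in ("per-sample", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    missing = [i for i in fold_of_sample if i not in predictions]
    if missing:
        raise ValueError(f"missing predictions for samples {missing[:5]}")

    n_classes = binning.n_classes
    folds = sorted(set(fold_of_sample.values()))
    per_fold_dsc = np.zeros((len(folds), n_classes))
    per_fold_mcc = np.zeros((len(folds), n_classes))
    for fi, fold in enumerate(folds):
        idxs = [i for i, f in fold_of_sample.items() if f == fold]
        if mode == "per-sample":
            vals_d = np.zeros((len(idxs), n_classes))
            vals_m = np.zeros((len(idxs), n_classes))
            for row, i in enumerate(idxs):
                for c in range(n_classes):
                    cc = confusion(predictions[i], truths[i], c)
                    vals_d[row, c] = dsc(cc)
                    vals_m[row, c] = mcc(cc)
            per_fold_dsc[fi] = vals_d.mean(axis=0)
            per_fold_mcc[fi] = vals_m.mean(axis=0)
        else:
            for c in range(n_classes):
                agg = np.zeros(4, np.int64)
                for i in idxs:
                    cc = confusion(predictions[i], truths[i], c)
                    agg += [cc.tp, cc.tn, cc.fp, cc.fn]
                cc = ConfusionCounts(*[int(v) for v in agg])
                per_fold_dsc[fi, c] = dsc(cc)
                per_fold_mcc[fi, c] = mcc(cc)

    rows = []
    for c in reversed(range(n_classes)):
        rows.append(
            {
                "class": c,
                "contrast": binning.interval(c),
                "dsc": float(per_fold_dsc[:, c].mean()),
                "mcc": float(per_fold_mcc[:, c].mean()),
            }
        )
    return pd.DataFrame(rows)


def format_report(report: pd.DataFrame) -> str:
    """Plain-text table of the fold-averaged metrics."""
    lines = [f"{'Class':>5} {'Contrast':>12} {'DSC':>7} {'MCC':>7}"]
    for _, r in report.iterrows():
        lines.append(f"{int(r['class']):>5} {r['contrast']:>12} {r['dsc']:>7.3f} {r['mcc']:>7.3f}")
    return "\n".join(lines)
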