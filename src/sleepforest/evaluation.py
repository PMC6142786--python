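"""Confusion matrices and the seven staging performance indexes.

Rows of the confusion matrix are the expert (true) stage, columns the
classifier's prediction.  From the k x k counts the report derives:
overall accuracy, per-class sensitivity (TPR / recall), specificity
(TNR), precision, F-measure, one-vs-rest ROC area (Mann-Whitney rank
statistic, macro-averaged) and the kappa statistic — both multiclass
Cohen's kappa and the binary-formula variant
2(TN*TP - FP*FN) / ((TN+FN)(FN+TP) + (FP+TP)(TN+FP)) applied per
one-vs-rest reduction.  Binary definitions are aggregated one-vs-rest
with macro averaging.  Percentages round half-up to 2 decimals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, UnknownLabelError


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal rounding half away from zero, matching printed tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (k, k) ints, rows = true, cols = predicted
    classes: tuple

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise DegenerateInputError(
                f"counts shape {self.counts.shape} does not match {k} classes"
            )
        if (self.counts < 0).any():
            raise DegenerateInputError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, cls) -> tuple:
        """(TP, TN, FP, FN) for one class."""
        i = self.classes.index(cls)
        tp = self.counts[i, i]
        fn = self.counts[i].sum() - tp
        fp = self.counts[:, i].sum() - tp
        tn = self.total - tp - fn - fp
        return int(tp), int(tn), int(fp), int(fn)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def confusion_matrix(y_true, y_pred, classes) -> ConfusionMatrix:
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise DegenerateInputError("y_true and y_pred must have equal length")
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise UnknownLabelError(f"label {t if t not in index else p!r} not in classes")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise DegenerateInputError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def per_class_sensitivity(cm: ConfusionMatrix) -> dict:
    """Diagonal over row sum per class; classes absent from the truth get
    NaN (undefined)."""
    out = {}
    for i, cls in enumerate(cm.classes):
        row = cm.counts[i].sum()
        out[cls] = float(cm.counts[i, i] / row) if row > 0 else float("nan")
    return out


def one_vs_rest_metrics(cm: ConfusionMatrix, cls) -> dict:
    """Sensitivity, specificity, precision and F-measure of one class
    (one-vs-rest reduction).  F-measure is 0 when precision + recall = 0."""
    tp, tn, fp, fn = cm.one_vs_rest(cls)
    tpr = tp / (tp + fn) if tp + fn > 0 else float("nan")
    tnr = tn / (tn + fp) if tn + fp > 0 else float("nan")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    f = (
        2 * precision * tpr / (precision + tpr)
        if np.isfinite(tpr) and precision + tpr > 0
        else 0.0
    )
    return {"sensitivity": tpr, "specificity": tnr, "precision": precision,
            "f_measure": f}


def kappa(cm: ConfusionMatrix, mode: str = "multiclass_cohen"):
    """Chance-corrected agreement.

    ``multiclass_cohen``: (p_o - p_e) / (1 - p_e) with p_e from row/column
    marginals.  ``binary_per_class``: the binary formula
    2(TN*TP - FP*FN) / ((TN+FN)(FN+TP) + (FP+TP)(TN+FP)) per one-vs-rest
    reduction, returned as a dict.
    """
    if cm.total == 0:
        raise DegenerateInputError("empty confusion matrix")
    if mode == "multiclass_cohen":
        n = cm.total
        p_o = np.trace(cm.counts) / n
        p_e = float((cm.counts.sum(axis=1) * cm.counts.sum(axis=0)).sum()) / n ** 2
        if p_e >= 1.0:
            raise DegenerateInputError("chance agreement is 1: kappa undefined")
        return float((p_o - p_e) / (1 - p_e))
    if mode == "binary_per_class":
        out = {}
        for cls in cm.classes:
            tp, tn, fp, fn = cm.one_vs_rest(cls)
            denom = (tn + fn) * (fn + tp) + (fp + tp) * (tn + fp)
            out[cls] = 2 * (tn * tp - fp * fn) / denom if denom > 0 else float("nan")
        return out
    raise ValueError(f"unknown kappa mode {mode!r}")


def _binary_auc(scores: np.ndarray, positives: np.ndarray) -> float:
    """Mann-Whitney AUC with midranks for ties."""
    from scipy.stats import rankdata

    n_pos = int(positives.sum())
    n_neg = len(positives) - n_pos
    ranks = rankdata(scores)
    auc = (ranks[positives].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc)


def roc_area(scores: np.ndarray, y_true, classes) -> float:
    """Macro one-vs-rest ROC area from per-class score columns (e.g. vote
    fractions).  Classes absent from ``y_true`` are excluded with a
    warning."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    y_true = list(y_true)
    aucs = []
    for j, cls in enumerate(classes):
        positives = np.array([t == cls for t in y_true])
        if positives.all() or not positives.any():
            warnings.warn(f"class {cls!r} absent from y_true (or exhaustive); "
                          "excluded from macro ROC area")
            continue
        aucs.append(_binary_auc(scores[:, j], positives))
    if not aucs:
        raise DegenerateInputError("no class admits a one-vs-rest ROC area")
    return float(np.mean(aucs))


@dataclass
class EvalReport:
    """The seven indexes for one confusion matrix (macro aggregation)."""

    cm: ConfusionMatrix
    accuracy: float
    sensitivity: dict
    specificity: dict
    precision: dict
    f_measure: dict
    kappa_cohen: float
    kappa_binary: dict
    roc_area: float | None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in self.cm.classes:
            rows.append({
                "class": cls,
                "sensitivity": self.sensitivity[cls],
                "specificity": self.specificity[cls],
                "precision": self.precision[cls],
                "f_measure": self.f_measure[cls],
                "kappa_binary": self.kappa_binary[cls],
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"accuracy: {round_half_up(100 * self.accuracy)}%",
            f"kappa (Cohen): {self.kappa_cohen:.4f}",
        ]
        if self.roc_area is not None:
            lines.append(f"ROC area (macro OvR): {self.roc_area:.4f}")
        for cls in self.cm.classes:
            lines.append(
                f"  {cls}: sens {100 * self.sensitivity[cls]:.2f}%  "
                f"spec {100 * self.specificity[cls]:.2f}%  "
                f"prec {100 * self.precision[cls]:.2f}%  "
                f"F {self.f_measure[cls]:.4f}"
            )
        return "\n".join(lines)


def evaluate(
    y_true, y_pred, classes, scores: np.ndarray | None = None
) -> EvalReport:
    """Full report from labels (and optional per-class score columns)."""
    cm = confusion_matrix(y_true, y_pred, classes)
    return evaluate_cm(cm, scores=scores, y_true=y_true)


def evaluate_cm(
    cm: ConfusionMatrix, scores: np.ndarray | None = None, y_true=None
) -> EvalReport:
    per = {cls: one_vs_rest_metrics(cm, cls) for cls in cm.classes}
    area = None
    if scores is not None and y_true is not None:
        area = roc_area(scores, y_true, cm.classes)
    return EvalReport(
        cm=cm,
        accuracy=overall_accuracy(cm),
        sensitivity={c: per[c]["sensitivity"] for c in cm.classes},
        specificity={c: per[c]["specificity"] for c in cm.classes},
        precision={c: per[c]["precision"] for c in cm.classes},
        f_measure={c: per[c]["f_measure"] for c in cm.classes},
        kappa_cohen=kappa(cm, "multiclass_cohen"),
        kappa_binary=kappa(cm, "binary_per_class"),
        roc_area=area,
    )


def read_confusion_csv(path, classes=None) -> ConfusionMatrix:
    """Confusion matrix from CSV (header row + index column of class
    names), for standalone recomputation of published tables."""
    df = pd.read_csv(path, index_col=0)
    if classes is None:
        classes = tuple(df.columns)
    return ConfusionMatrix(counts=df.loc[list(classes), list(classes)].to_numpy(),
                           classes=tuple(classes))
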