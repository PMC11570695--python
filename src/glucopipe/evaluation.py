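"""Classifier validation: confusion-matrix metrics, ISO 15197 bands, R².

The classifier is scored three ways:

* one-vs-rest confusion-matrix metrics per class — accuracy
  ``(TP+TN)/(TP+TN+FP+FN)``, precision ``TP/(TP+FP)``, recall
  ``TP/(TP+FN)`` and F1 ``2PR/(P+R)`` — with macro averages over classes;
* ISO 15197 accuracy bands: a prediction counts as clinically acceptable
  when it falls within +/-15 mg/dL of the true value for true < 100 mg/dL,
  or within +/-15 % for true >= 100 mg/dL (boundaries inclusive; the two
  rules coincide at exactly 100);
* coefficients of determination against the identity line,
  ``R² = 1 - sum((pred-true)²)/sum((true-mean(true))²)``, stratified into
  the low (< 100) and high (>= 100 mg/dL) concentration ranges.

Zero-denominator metrics are defined as 0 rather than NaN so macro
averages stay computable; the fitted-line R² convention is available via
``compliance_report(..., r2_mode="fitted")``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: ISO 15197 band parameters.
ISO_ABSOLUTE_BAND = 15.0  # mg/dL, below the threshold
ISO_RELATIVE_BAND = 0.15  # fraction, at or above the threshold
ISO_THRESHOLD = 100.0  # mg/dL
ISO_PASS_FRACTION = 0.95


@dataclass(frozen=True)
class BinaryCounts:
    """One-vs-rest outcome counts for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_matrix(
    true_labels: Sequence[int], predicted_labels: Sequence[int], n_classes: int = 16
) -> np.ndarray:
    """Tally an ``n_classes`` x ``n_classes`` matrix, rows = true class."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("true and predicted label sequences differ in length")
    if len(t) and (
        t.min() < 0 or p.min() < 0 or t.max() >= n_classes or p.max() >= n_classes
    ):
        raise ValueError("label outside the 0..n_classes-1 alphabet")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (t, p), 1)
    return cm


def binary_counts(cm: np.ndarray, class_index: int) -> BinaryCounts:
    """Collapse a confusion matrix to one-vs-rest counts for one class."""
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if not 0 <= class_index < cm.shape[0]:
        raise IndexError(f"class index {class_index} out of range")
    tp = int(cm[class_index, class_index])
    fp = int(cm[:, class_index].sum()) - tp
    fn = int(cm[class_index, :].sum()) - tp
    tn = int(cm.sum()) - tp - fp - fn
    return BinaryCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def class_metrics(counts: BinaryCounts) -> tuple[float, float, float]:
    """(precision, recall, F1); zero-denominator metrics are 0."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    if p + r == 0:
        if counts.tp + counts.fp + counts.fn:
            logger.debug("zero-denominator metric defined as 0")
        return p, r, 0.0
    return p, r, 2 * p * r / (p + r)


def overall_accuracy(cm: np.ndarray) -> float:
    """Trace over total: the fraction of correctly classified items."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm) / total)


def metrics_report(cm: np.ndarray, class_values: Sequence[int] | None = None) -> pd.DataFrame:
    """Per-class precision/recall/F1 table plus accuracy and macro rows.

    Rows are indexed by class value (mg/dL) when ``class_values`` is given,
    otherwise by class index; the final ``macro`` row holds unweighted
    means over classes, alongside an ``accuracy`` column repeated for
    convenience.
    """
    cm = np.asarray(cm)
    n = cm.shape[0]
    labels = list(class_values) if class_values is not None else list(range(n))
    rows = []
    for i in range(n):
        p, r, f1 = class_metrics(binary_counts(cm, i))
        rows.append({"class": labels[i], "precision": p, "recall": r, "f1": f1})
    df = pd.DataFrame(rows).set_index("class")
    macro = df.mean(axis=0)
    df.loc["macro"] = macro
    df["accuracy"] = overall_accuracy(cm)
    return df


def iso15197_within(
    true_conc: float,
    pred_conc: float,
    *,
    absolute_band: float = ISO_ABSOLUTE_BAND,
    relative_band: float = ISO_RELATIVE_BAND,
    threshold: float = ISO_THRESHOLD,
) -> bool:
    """Whether a prediction meets the ISO 15197 accuracy band.

    True value below the 100 mg/dL threshold: |pred - true| <= 15 mg/dL.
    True value at or above it: |pred - true| <= 15 % of true.  Both bands
    inclusive; at exactly 100 mg/dL the two rules coincide.
    """
    if true_conc <= 0 or pred_conc <= 0:
        raise ValueError("concentrations must be positive")
    if true_conc < threshold:
        return abs(pred_conc - true_conc) <= absolute_band
    return abs(pred_conc - true_conc) <= relative_band * true_conc


def _r2_identity(true: np.ndarray, pred: np.ndarray) -> float | None:
    """R² of predictions against the identity line; None if undefined."""
    if len(np.unique(true)) < 2:
        return None
    ss_res = float(((pred - true) ** 2).sum())
    ss_tot = float(((true - true.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def _r2_fitted(true: np.ndarray, pred: np.ndarray) -> float | None:
    """Squared Pearson correlation (fitted-regression-line convention)."""
    if len(np.unique(true)) < 2 or len(np.unique(pred)) < 2:
        return None
    return float(np.corrcoef(true, pred)[0, 1] ** 2)


@dataclass
class ISOComplianceReport:
    """Per-pair ISO verdicts with the summary statistics of the run."""

    pairs: pd.DataFrame  # columns: true, predicted, within_band
    compliance_fraction: float
    passes_iso: bool
    r2_low: float | None
    r2_high: float | None
    absolute_band: float = ISO_ABSOLUTE_BAND
    relative_band: float = ISO_RELATIVE_BAND
    threshold: float = ISO_THRESHOLD


def compliance_report(
    pairs: Sequence[tuple[float, float]], r2_mode: str = "identity"
) -> ISOComplianceReport:
    """ISO 15197 compliance and stratified R² for (true, predicted) pairs.

    ``compliance_fraction`` is the fraction of pairs within band, with the
    pass indicator at the standard's 95 % level.  R² is computed separately
    over the low (< 100) and high (>= 100 mg/dL) strata; a stratum with
    fewer than two distinct true values reports None.
    """
    if len(pairs) == 0:
        raise ValueError("at least one (true, predicted) pair is required")
    arr = np.asarray(pairs, dtype=float)
    true, pred = arr[:, 0], arr[:, 1]
    within = np.array([iso15197_within(t, p) for t, p in arr])
    r2 = {"identity": _r2_identity, "fitted": _r2_fitted}[r2_mode]
    low = true < ISO_THRESHOLD
    frac = float(within.mean())
    return ISOComplianceReport(
        pairs=pd.DataFrame({"true": true, "predicted": pred, "within_band": within}),
        compliance_fraction=frac,
        passes_iso=frac >= ISO_PASS_FRACTION,
        r2_low=r2(true[low], pred[low]) if low.any() else None,
        r2_high=r2(true[~low], pred[~low]) if (~low).any() else None,
    )
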