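"""Confusion-matrix metrics, AUC, and TSS-optimal threshold selection.

The confusion matrix cells follow the standard presence/absence layout:
A true positives, B false positives, C false negatives, D true negatives,
N = A + B + C + D. From it:

    CCI   = (A + D) / N                      correctly classified instances
    Sn    = A / (A + C)                      sensitivity
    Sp    = D / (B + D)                      specificity
    TSS   = Sn + Sp - 1                      true skill statistic
    kappa = (Po - Pe) / (1 - Pe)             chance-corrected agreement,
            Po = CCI,  Pe = [(A+B)(A+C) + (C+D)(D+B)] / N^2

TSS is prevalence-insensitive, which is why it serves as the objective for
model selection on prevalence-balanced training sets. A metric whose
marginal is empty (e.g. Sn with no observed positives) is reported as NaN,
never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts A (TP), B (FP), C (FN), D (TN)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataError("confusion counts must be non-negative")
        if self.n < 1:
            raise DataError("confusion matrix must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def confusion(predictions, observations) -> ConfusionMatrix:
    """Tally the four agreement cells of binary predictions vs observations."""
    pred = np.asarray(predictions)
    obs = np.asarray(observations)
    if pred.shape != obs.shape or pred.ndim != 1 or pred.size < 1:
        raise DataError("predictions and observations must be equal-length 1-D, n >= 1")
    if not (np.isin(pred, (0, 1)).all() and np.isin(obs, (0, 1)).all()):
        raise DataError("predictions and observations must be binary (0/1)")
    pred = pred.astype(bool)
    obs = obs.astype(bool)
    return ConfusionMatrix(
        a=int((pred & obs).sum()),
        b=int((pred & ~obs).sum()),
        c=int((~pred & obs).sum()),
        d=int((~pred & ~obs).sum()),
    )


def compute_metrics(cm: ConfusionMatrix) -> dict:
    """kappa, CCI, Sn, Sp and TSS of one confusion matrix.

    Metrics whose denominator is zero are returned as NaN.
    """
    a, b, c, d = float(cm.a), float(cm.b), float(cm.c), float(cm.d)
    n = a + b + c + d
    cci = (a + d) / n
    sn = a / (a + c) if (a + c) > 0 else float("nan")
    sp = d / (b + d) if (b + d) > 0 else float("nan")
    tss = sn + sp - 1.0
    pe = ((a + b) * (a + c) + (c + d) * (d + b)) / n**2
    kappa = (cci - pe) / (1.0 - pe) if pe < 1.0 else float("nan")
    return {"kappa": kappa, "cci": cci, "sn": sn, "sp": sp, "tss": tss}


def compute_auc(scores, labels) -> float:
    """Area under the ROC curve in the rank (Mann-Whitney) form.

    The probability that a randomly chosen positive outscores a randomly
    chosen negative, ties counting one half. Undefined (NaN) when only one
    class is present.
    """
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def threshold_grid(grid_step: float = 0.01) -> np.ndarray:
    """The threshold scan grid {0, grid_step, ..., 1}."""
    if not 0.0 < grid_step <= 1.0:
        raise DataError("grid_step must be in (0, 1]")
    n = int(round(1.0 / grid_step))
    return np.linspace(0.0, 1.0, n + 1)


def tss_curve(scores, labels, grid_step: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """TSS at every grid threshold (vectorised scan).

    Returns ``(thresholds, tss)``. Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DataError("TSS scan requires at least one positive and one negative")
    thr = threshold_grid(grid_step)
    pred = scores[:, None] >= thr[None, :]
    tp = (pred & labels[:, None]).sum(axis=0)
    fp = (pred & ~labels[:, None]).sum(axis=0)
    sn = tp / n_pos
    sp = (n_neg - fp) / n_neg
    return thr, sn + sp - 1.0


def optimal_threshold(scores, labels, grid_step: float = 0.01) -> tuple[float, float]:
    """Smallest grid threshold maximising TSS, and the maximal TSS."""
    thr, tss = tss_curve(scores, labels, grid_step)
    best = int(np.argmax(tss))  # argmax returns the first (smallest) maximiser
    return float(thr[best]), float(tss[best])


@dataclass
class EvaluationReport:
    """One model's evaluation row."""

    kappa: float
    cci: float
    sn: float
    sp: float
    tss: float
    auc: float
    optimal_threshold: float

    def to_row(self) -> dict:
        return {
            "kappa": self.kappa, "cci": self.cci, "sn": self.sn, "sp": self.sp,
            "tss": self.tss, "auc": self.auc, "threshold": self.optimal_threshold,
        }


def evaluate_scores(scores, labels, grid_step: float = 0.01) -> EvaluationReport:
    """Full report at the TSS-optimal threshold."""
    thr, _ = optimal_threshold(scores, labels, grid_step)
    pred = (np.asarray(scores, dtype=float) >= thr).astype(int)
    m = compute_metrics(confusion(pred, np.asarray(labels).astype(int)))
    return EvaluationReport(
        kappa=m["kappa"], cci=m["cci"], sn=m["sn"], sp=m["sp"], tss=m["tss"],
        auc=compute_auc(scores, labels), optimal_threshold=thr,
    )


def classify_performance(kappa: float | None = None, auc: float | None = None) -> dict:
    """Qualitative labels used in river-management practice.

    kappa > 0.6 counts as well-performing. AUC bands: [0.5, 0.7) poor,
    [0.7, 0.9) reasonable, >= 0.9 very good (boundaries assigned upward).
    """
    if isinstance(kappa, EvaluationReport):
        report = kappa
        kappa, auc = report.kappa, report.auc
    labels: dict = {}
    if kappa is not None and not np.isnan(kappa):
        labels["kappa"] = "well-performing" if kappa > 0.6 else "below-standard"
    if auc is not None and not np.isnan(auc):
        if auc >= 0.9:
            labels["auc"] = "very good"
        elif auc >= 0.7:
            labels["auc"] = "reasonable"
        else:
            labels["auc"] = "poor"
    return labels
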