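"""Model evaluation: LOOCV regression metrics and culture-condition ROC.

Regression quality is reported as Pearson's R between observed and predicted
pseudo-time, RMSE, and the least-squares slope of predicted-on-observed
(slope 1 = unbiased scaling).  Classification treats predicted pseudo-time
as a score for separating the serum-like (higher pseudo-time, positive
class) from the 2i-like group: ROC over all score thresholds, trapezoidal
AUC, and accuracy at a chosen operating point (Youden's J by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .quant import MethylationMatrix
from .selection import ElasticNetConfig, PluripotencyModel, fit_elastic_net


@dataclass
class RegressionEval:
    pearson_R: float
    rmse: float
    slope: float
    pairs: pd.DataFrame  # columns y, y_hat


@dataclass
class ClassificationEval:
    roc_points: pd.DataFrame  # columns fpr, tpr, threshold
    auc: float
    accuracy: float | None
    threshold: float | None
    positive_label: str


def predict(model: PluripotencyModel, matrix: MethylationMatrix) -> pd.Series:
    """Predicted pseudo-time per sample: yhat = b0 + sum_i b_i x_i.

    The matrix must contain every marker interval of the model; missing
    intervals are an error (use the transfer path for partial coverage).
    """
    index = {iv: j for j, iv in enumerate(matrix.intervals)}
    missing = [iv.id for iv, _ in model.markers if iv not in index]
    if missing:
        raise KeyError(f"matrix lacks model marker intervals: {missing}")
    cols = [index[iv] for iv, _ in model.markers]
    yhat = model.intercept + matrix.values[:, cols] @ model.coefficients
    return pd.Series(yhat, index=matrix.samples, name="predicted_pseudo_time")


def loocv(
    X: np.ndarray,
    y: Sequence[float],
    fit: Callable[[np.ndarray, np.ndarray], tuple[float, np.ndarray]] | None = None,
    cfg: ElasticNetConfig | None = None,
    lam: float | None = None,
) -> np.ndarray:
    """Leave-one-out predictions with per-fold coefficient refits.

    The marker set (columns of X) is held fixed; for each sample the
    coefficients are refit on the other N-1 samples and the held-out sample
    is predicted.  ``fit`` may supply a custom procedure returning
    ``(intercept, coefficients)``; the default refits the elastic net at the
    given (or config) penalty.
    """
    X = np.asarray(X, float)
    t = np.asarray(y, float)
    n = len(t)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    if fit is None:
        cfg = cfg or ElasticNetConfig()

        def fit(Xtr: np.ndarray, ttr: np.ndarray) -> tuple[float, np.ndarray]:
            m = fit_elastic_net(Xtr, ttr, cfg, lam=lam)
            coef = np.zeros(Xtr.shape[1])
            # scatter nonzero coefficients back to column positions
            pos = [iv.start for iv, _ in m.markers]
            coef[pos] = m.coefficients
            return m.intercept, coef

    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        b0, b = fit(X[mask], t[mask])
        preds[i] = b0 + X[i] @ b
    return preds


def regression_metrics(y: Sequence[float], y_hat: Sequence[float]) -> RegressionEval:
    """Pearson R, RMSE and least-squares slope of predictions against truth."""
    t = np.asarray(y, float)
    p = np.asarray(y_hat, float)
    if t.shape != p.shape or t.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    rmse = float(np.sqrt(np.mean((t - p) ** 2)))
    if np.std(t) == 0:
        r = float("nan")
        slope = float("nan")
    else:
        r = float(stats.pearsonr(t, p).statistic) if np.std(p) > 0 else float("nan")
        tc = t - t.mean()
        slope = float((tc @ (p - p.mean())) / (tc @ tc))
    pairs = pd.DataFrame({"y": t, "y_hat": p})
    return RegressionEval(r, rmse, slope, pairs)


def _binary_labels(labels: Sequence[str], positive_label: str | None) -> tuple[np.ndarray, str]:
    lab = np.asarray(labels)
    classes = sorted(pd.unique(lab))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if positive_label is None:
        positive_label = "serum" if "serum" in classes else classes[1]
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} not among {classes}")
    return (lab == positive_label).astype(int), str(positive_label)


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[str],
    positive_label: str | None = None,
) -> ClassificationEval:
    """ROC over all score thresholds and trapezoidal AUC.

    Higher scores indicate the positive (serum-like, higher-pseudo-time)
    class.  The AUC equals the Mann-Whitney probability that a random
    positive outscores a random negative, ties counted half.
    """
    s = np.asarray(scores, float)
    ybin, pos = _binary_labels(labels, positive_label)
    fpr, tpr, thr = roc_curve(ybin, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return ClassificationEval(points, auc, None, None, pos)


def accuracy_at_threshold(
    scores: Sequence[float],
    labels: Sequence[str],
    rule: str = "youden",
    threshold: float | None = None,
    positive_label: str | None = None,
) -> ClassificationEval:
    """Classification accuracy at an operating point on the ROC.

    ``rule='youden'`` picks the threshold maximizing TPR - FPR (largest such
    threshold on ties); ``rule='fixed'`` uses the supplied ``threshold``.
    A sample is called positive when its score is >= the threshold.
    """
    s = np.asarray(scores, float)
    ybin, pos = _binary_labels(labels, positive_label)
    ev = roc_auc(s, labels, positive_label=pos)
    if rule == "youden":
        pts = ev.roc_points.iloc[1:]  # skip the synthetic (0,0) point at +inf
        j = pts["tpr"] - pts["fpr"]
        thr = float(pts["threshold"].iloc[int(np.argmax(j.to_numpy()))])
    elif rule == "fixed":
        if threshold is None:
            raise ValueError("rule='fixed' requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    calls = (s >= thr).astype(int)
    acc = float((calls == ybin).mean())
    return ClassificationEval(ev.roc_points, ev.auc, acc, thr, pos)


def evaluate_model(
    model: PluripotencyModel,
    X: np.ndarray,
    y: Sequence[float],
    groups: Sequence[str] | None = None,
    cfg: ElasticNetConfig | None = None,
) -> dict:
    """LOOCV regression metrics and (optionally) group-classification metrics.

    LOOCV refits coefficients per fold at the model's fitted penalty with the
    marker set fixed; the ROC uses the LOOCV predictions as scores.
    """
    preds = loocv(X, y, cfg=cfg or ElasticNetConfig(alpha=model.alpha), lam=model.lam)
    reg = regression_metrics(y, preds)
    out = {"regression": reg, "loocv_predictions": preds}
    if groups is not None:
        cls = accuracy_at_threshold(preds, groups)
        out["classification"] = cls
    return out
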