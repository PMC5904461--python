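"""Prediction-accuracy measures for presence/absence maps, classical and
spatially corrected.

A false prediction next to an observed presence arguably deserves more
credit than one far away, because on raster maps the assignment of values
to cells is partly arbitrary and nearby cells are not independent.  The
spatial variants therefore replace each binary actual value by its mean
over the 3x3 queen neighbourhood, and

* ``th_dep`` scores a 4x4 ordinal contingency table (classes from the cut
  points t/2, t, (1+t)/2) with a weighted Cohen's kappa whose agreement
  weights ``w_ij = 1 - |i-j|/3`` give partial credit to near-diagonal
  cells;
* ``th_indep`` builds a soft ROC curve in which a predicted presence
  contributes its neighbourhood presence fraction to the true positives.

With ``spatial=False`` both reduce exactly to the classical measures
(2x2 kappa, empirical ROC/AUC, maximum TSS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve


@dataclass
class ConfusionTable4:
    """4x4 spatially weighted contingency table (rows actual, cols predicted)."""

    counts: np.ndarray
    threshold: float
    weightmat: np.ndarray
    spatial: bool

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class ROCCurve:
    """ROC sweep with AUC (trapezoid) and maximum TSS."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    tss: float
    spatial: bool


def _as_arrays(actuals, predictions, coords):
    a = np.asarray(actuals, dtype=float)
    p = np.asarray(predictions, dtype=float) if predictions is not None else None
    c = np.asarray(coords)
    if a.ndim != 1 or c.shape != (a.size, 2):
        raise ValueError("actuals must be 1-D with matching (n, 2) coords")
    if not np.all(np.isin(a, (0.0, 1.0))):
        raise ValueError("actuals must be binary 0/1")
    if p is not None:
        if p.shape != a.shape:
            raise ValueError("predictions must match actuals")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("predictions must lie in [0, 1]")
    return a, p, c


def _neighbourhood_mean(values, coords, window: int = 3) -> np.ndarray:
    """Mean over the queen neighbourhood (window x window, incl. self),
    using observed cells only."""
    v = np.asarray(values, dtype=float)
    c = np.asarray(coords)
    ix = c - c.min(axis=0)
    cols, rows = ix[:, 0], ix[:, 1]
    H, W = rows.max() + 1, cols.max() + 1
    A = np.zeros((H, W))
    M = np.zeros((H, W))
    A[rows, cols] = v
    M[rows, cols] = 1.0
    kern = np.ones((window, window))
    num = convolve(A, kern, mode="constant", cval=0.0)
    den = convolve(M, kern, mode="constant", cval=0.0)
    return (num / den)[rows, cols]


def smooth_actuals(actuals, coords) -> np.ndarray:
    """Neighbourhood presence fraction: mean of the actual values over the
    3x3 queen neighbourhood of each cell (including the cell itself),
    using observed cells only."""
    a, _, c = _as_arrays(actuals, None, coords)
    return _neighbourhood_mean(a, c)


WEIGHTMAT4 = 1.0 - np.abs(np.subtract.outer(np.arange(4), np.arange(4))) / 3.0


def _classify4(v: np.ndarray, t: float) -> np.ndarray:
    """Ordinal class 0..3 from cut points t/2, t, (1+t)/2 (half-open up)."""
    cuts = np.array([t / 2.0, t, (1.0 + t) / 2.0])
    return np.searchsorted(cuts, v, side="right")


def _weighted_kappa(counts: np.ndarray, w: np.ndarray) -> float:
    n = counts.sum()
    po = float((w * counts).sum()) / n
    r = counts.sum(axis=1)
    c = counts.sum(axis=0)
    pe = float((w * np.outer(r, c)).sum()) / (n * n)
    if pe >= 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


def th_dep(actuals, predictions, coords, threshold: float = 0.5,
           spatial: bool = True) -> dict:
    """Threshold-dependent accuracy: kappa, sensitivity, specificity.

    spatial=True smooths both the binary actuals and the predicted
    probabilities over the queen neighbourhood, maps each into 4 ordinal
    classes and scores the 4x4 table with the near-diagonal weights
    (smoothing both sides keeps kappa = 1 for predictions identical to the
    actuals, which raw-vs-smoothed comparison cannot);  spatial=False is
    the classical 2x2 analysis at the same threshold.
    """
    a, p, c = _as_arrays(actuals, predictions, coords)
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    n = a.size
    if spatial:
        a_star = smooth_actuals(a, c)
        p_star = _neighbourhood_mean(p, c)
        ca = _classify4(a_star, threshold)
        cp = _classify4(p_star, threshold)
        counts = np.zeros((4, 4), dtype=int)
        np.add.at(counts, (ca, cp), 1)
        kappa = _weighted_kappa(counts, WEIGHTMAT4)
        pos_a = ca >= 2
        pos_p = cp >= 2
        cm = ConfusionTable4(counts=counts, threshold=threshold,
                             weightmat=WEIGHTMAT4.copy(), spatial=True)
    else:
        pos_a = a == 1.0
        pos_p = p >= threshold
        counts2 = np.array([
            [np.sum(~pos_a & ~pos_p), np.sum(~pos_a & pos_p)],
            [np.sum(pos_a & ~pos_p), np.sum(pos_a & pos_p)],
        ])
        po = counts2.trace() / n
        r = counts2.sum(axis=1)
        col = counts2.sum(axis=0)
        pe = float(np.sum(r * col)) / (n * n)
        kappa = 1.0 if pe >= 1.0 else (po - pe) / (1.0 - pe)
        cm = ConfusionTable4(counts=counts2, threshold=threshold,
                             weightmat=np.eye(2), spatial=False)
    tp = int(np.sum(pos_a & pos_p))
    fn = int(np.sum(pos_a & ~pos_p))
    tn = int(np.sum(~pos_a & ~pos_p))
    fp = int(np.sum(~pos_a & pos_p))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    return {"cm": cm, "kappa": float(kappa), "sensitivity": float(sens),
            "specificity": float(spec)}


def th_indep(actuals, predictions, coords, spatial: bool = True) -> ROCCurve:
    """Threshold-independent accuracy: ROC, AUC (trapezoid) and max TSS.

    Thresholds sweep the midpoints between consecutive distinct predicted
    probabilities (plus 0 and 1), so tied predictions share a threshold.
    spatial=True scores a soft confusion using the neighbourhood presence
    fraction a*: a predicted presence contributes a* to the true positives
    and 1-a* to the false positives.
    """
    a, p, c = _as_arrays(actuals, predictions, coords)
    if np.all(a == a[0]):
        raise ValueError("AUC undefined: actuals are all one class")
    weight = smooth_actuals(a, c) if spatial else a

    uniq = np.unique(p)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.array([])
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])

    pos_w = weight.sum()
    neg_w = (1.0 - weight).sum()
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred_pos = p > t
        tp = weight[pred_pos].sum()
        fp = (1.0 - weight[pred_pos]).sum()
        sens[i] = tp / pos_w if pos_w > 0 else np.nan
        spec[i] = (neg_w - fp) / neg_w if neg_w > 0 else np.nan

    # fpr falls as the threshold rises: reverse so the curve runs (0,0)->(1,1)
    fpr = (1.0 - spec)[::-1]
    tpr = sens[::-1]
    auc = float(np.trapezoid(tpr, fpr))
    tss = float(np.nanmax(sens + spec - 1.0))
    return ROCCurve(thresholds=thresholds, sensitivity=sens,
                    specificity=spec, auc=auc, tss=tss, spatial=spatial)
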