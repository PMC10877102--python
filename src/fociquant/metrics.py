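"""Segmentation evaluation metrics.

Pixelwise Dice similarity coefficient and intersection-over-union,

    DSC = 2·TP / (2·TP + FP + FN),     IoU = TP / (TP + FP + FN),

with TP/FP/FN counted over pixels, and the objectwise DSC for foci: objects
(8-connected components) of prediction and ground truth are matched
one-to-one by an optimal assignment over center pairs whose Euclidean
distance is strictly below the matching radius (default 3 px, the mean
focus size 2.53 px rounded up); matched pairs are TP, unmatched predictions
FP, unmatched truths FN.  Agreement between predicted and ground-truth
per-image quantities is summarized by ordinary least squares with R² equal
to the squared Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.optimize import linear_sum_assignment

from .io import SemanticMask

__all__ = [
    "MatchConfig",
    "PixelReport",
    "ObjectReport",
    "RegressionReport",
    "pixel_metrics",
    "object_dsc",
    "agreement_regression",
    "paired_dsc_comparison",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class MatchConfig:
    max_center_distance_px: float = 3.0

    def __post_init__(self) -> None:
        if self.max_center_distance_px <= 0:
            raise ValueError("max_center_distance_px must be > 0")


@dataclass(frozen=True)
class PixelReport:
    tp: int
    fp: int
    fn: int
    dsc_pixel: float
    iou_pixel: float


@dataclass(frozen=True)
class ObjectReport:
    tp: int
    fp: int
    fn: int
    dsc_object: float


@dataclass(frozen=True)
class RegressionReport:
    r_squared: float
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    pearson_r: float
    p_value: float


def pixel_metrics(pred: SemanticMask, truth: SemanticMask) -> PixelReport:
    """Pixelwise DSC and IoU; both-empty masks score 1 by convention."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = pred.raster > 0
    t = truth.raster > 0
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    if tp + fp + fn == 0:
        return PixelReport(0, 0, 0, 1.0, 1.0)
    return PixelReport(
        tp=tp,
        fp=fp,
        fn=fn,
        dsc_pixel=2 * tp / (2 * tp + fp + fn),
        iou_pixel=tp / (tp + fp + fn),
    )


def _component_centroids(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return np.empty((0, 2))
    return np.asarray(ndimage.center_of_mass(mask, labels, range(1, n + 1)), dtype=float)


def object_dsc(pred_mask: SemanticMask, truth_mask: SemanticMask, cfg: MatchConfig | None = None) -> ObjectReport:
    """Objectwise DSC by optimal one-to-one center matching.

    Among center pairs with distance strictly below the radius, the
    assignment maximizes the number of matches, breaking ties by smallest
    total distance; the metric is symmetric in prediction and truth.
    Both-empty masks score 1.
    """
    if pred_mask.shape != truth_mask.shape:
        raise ValueError(f"shape mismatch: {pred_mask.shape} vs {truth_mask.shape}")
    cfg = cfg or MatchConfig()
    pc = _component_centroids(pred_mask.raster > 0)
    tc = _component_centroids(truth_mask.raster > 0)
    n_pred, n_truth = len(pc), len(tc)
    if n_pred == 0 and n_truth == 0:
        return ObjectReport(0, 0, 0, 1.0)
    tp = 0
    if n_pred and n_truth:
        d = np.linalg.norm(pc[:, None, :] - tc[None, :, :], axis=2)
        eligible = d < cfg.max_center_distance_px
        # cost: large penalty for ineligible pairs so the assignment first
        # maximizes match count, then minimizes total distance
        big = cfg.max_center_distance_px * (n_pred + n_truth + 1)
        cost = np.where(eligible, d, big)
        rows, cols = linear_sum_assignment(cost)
        tp = int(np.count_nonzero(eligible[rows, cols]))
    fp = n_pred - tp
    fn = n_truth - tp
    return ObjectReport(tp=tp, fp=fp, fn=fn, dsc_object=2 * tp / (2 * tp + fp + fn))


def agreement_regression(per_image_pred: np.ndarray, per_image_truth: np.ndarray) -> RegressionReport:
    """OLS of predicted on ground-truth per-image values, with coefficient SEs."""
    pred = np.asarray(per_image_pred, dtype=float)
    truth = np.asarray(per_image_truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("inputs must be equal-length 1D arrays")
    n = pred.size
    if n < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(truth) == 0:
        raise ValueError("ground-truth values have zero variance")
    res = stats.linregress(truth, pred)
    return RegressionReport(
        r_squared=res.rvalue**2,
        slope=res.slope,
        intercept=res.intercept,
        slope_se=res.stderr,
        intercept_se=res.intercept_stderr,
        pearson_r=res.rvalue,
        p_value=res.pvalue,
    )


def paired_dsc_comparison(dsc_condition_a, dsc_condition_b) -> tuple[float, float]:
    """Two-sided paired t-test on per-sample DSC differences."""
    a = np.asarray(dsc_condition_a, dtype=float)
    b = np.asarray(dsc_condition_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length lists with n ≥ 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0) and not np.allclose(diff, 0):
        raise ValueError("zero-variance non-zero differences: t undefined")
    if np.allclose(diff, 0):
        return 0.0, 1.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
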