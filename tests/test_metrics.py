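import numpy as np
import pytest
from scipy import ndimage

from fociquant.io import SemanticMask
from fociquant.metrics import (
    MatchConfig,
    agreement_regression,
    object_dsc,
    paired_dsc_comparison,
    pixel_metrics,
)


def _mask(arr):
    return SemanticMask(np.asarray(arr, dtype=np.uint8), 1.0)


def _brute_pixel(pred, truth):
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    if tp + fp + fn == 0:
        return 1.0, 1.0
    return 2 * tp / (2 * tp + fp + fn), tp / (tp + fp + fn)


class TestPixelMetrics:
    def test_identical_masks_score_one(self):
        m = _mask(np.eye(8))
        r = pixel_metrics(m, m)
        assert r.dsc_pixel == 1.0 and r.iou_pixel == 1.0

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((8, 8)); a[:4] = 1
        r = pixel_metrics(_mask(a), _mask(1 - a))
        assert r.dsc_pixel == 0.0 and r.iou_pixel == 0.0

    def test_worked_counts_case(self):
        # TP=3, FP=3, FN=1 → DSC = 6/10, IoU = 3/7
        pred = np.zeros((10, 10)); truth = np.zeros((10, 10))
        pred[0, :6] = 1
        truth[0, 3:7] = 1
        r = pixel_metrics(_mask(pred), _mask(truth))
        assert (r.tp, r.fp, r.fn) == (3, 3, 1)
        assert r.dsc_pixel == pytest.approx(0.6)
        assert r.iou_pixel == pytest.approx(3 / 7)

    def test_both_empty_convention(self):
        r = pixel_metrics(_mask(np.zeros((4, 4))), _mask(np.zeros((4, 4))))
        assert r.dsc_pixel == 1.0 and r.iou_pixel == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_and_identity(self, seed):
        rng = np.random.default_rng(seed)
        pred = (rng.uniform(size=(24, 24)) > 0.6).astype(np.uint8)
        truth = (rng.uniform(size=(24, 24)) > 0.6).astype(np.uint8)
        r = pixel_metrics(_mask(pred), _mask(truth))
        dsc_b, iou_b = _brute_pixel(pred, truth)
        assert r.dsc_pixel == pytest.approx(dsc_b, abs=1e-12)
        assert r.iou_pixel == pytest.approx(iou_b, abs=1e-12)
        assert r.dsc_pixel == pytest.approx(2 * r.iou_pixel / (1 + r.iou_pixel), abs=1e-12)
        assert r.dsc_pixel >= r.iou_pixel


def _point_mask(shape, points):
    arr = np.zeros(shape, dtype=np.uint8)
    for r, c in points:
        arr[r, c] = 1
    return _mask(arr)


class TestObjectDsc:
    def test_close_pair_matches(self):
        pred = _point_mask((12, 12), [(5, 5)])
        truth = _point_mask((12, 12), [(6, 6)])
        r = object_dsc(pred, truth)
        assert r.tp == 1 and r.dsc_object == 1.0

    def test_distant_pair_no_match(self):
        r = object_dsc(_point_mask((12, 12), [(0, 0)]), _point_mask((12, 12), [(10, 10)]))
        assert r.dsc_object == 0.0

    def test_one_to_one_matching(self):
        # two predictions near one truth: only one TP allowed
        pred = _point_mask((12, 12), [(5, 5), (8, 5)])
        truth = _point_mask((12, 12), [(5, 6)])
        r = object_dsc(pred, truth)
        assert (r.tp, r.fp, r.fn) == (1, 1, 0)
        assert r.dsc_object == pytest.approx(2 / 3)

    def test_strict_inequality_at_radius(self):
        pred = _point_mask((12, 12), [(2, 2)])
        truth = _point_mask((12, 12), [(2, 5)])  # distance exactly 3.0
        assert object_dsc(pred, truth).tp == 0
        truth_close = _point_mask((12, 12), [(2, 4)])  # 2.0 < 3
        assert object_dsc(pred, truth_close).tp == 1

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(6)
        a = _mask((rng.uniform(size=(32, 32)) > 0.9).astype(np.uint8))
        b = _mask((rng.uniform(size=(32, 32)) > 0.9).astype(np.uint8))
        r1, r2 = object_dsc(a, b), object_dsc(b, a)
        assert r1.tp == r2.tp and r1.fp == r2.fn and r1.fn == r2.fp
        assert r1.dsc_object == pytest.approx(r2.dsc_object, abs=1e-12)

    def test_assignment_beats_greedy_pairing(self):
        # greedy from the nearest pair would strand one prediction
        pred = _point_mask((20, 20), [(5, 5), (5, 7)])
        truth = _point_mask((20, 20), [(5, 6), (5, 9)])
        r = object_dsc(pred, truth)
        assert r.tp == 2  # (5,5)->(5,6) and (5,7)->(5,9)

    def test_both_empty_scores_one(self):
        r = object_dsc(_mask(np.zeros((5, 5))), _mask(np.zeros((5, 5))))
        assert r.dsc_object == 1.0


class TestAgreementRegression:
    def test_perfect_identity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r = agreement_regression(x, x)
        assert r.r_squared == pytest.approx(1.0)
        assert r.slope == pytest.approx(1.0) and r.intercept == pytest.approx(0.0)

    def test_affine_exactness(self):
        t = np.array([1.0, 2.0, 3.0, 5.0])
        r = agreement_regression(2 * t + 1, t)
        assert r.r_squared == pytest.approx(1.0)
        assert r.slope == pytest.approx(2.0) and r.intercept == pytest.approx(1.0)

    def test_matches_closed_form_pearson(self):
        rng = np.random.default_rng(12)
        t = rng.uniform(0, 1, 50)
        p = 0.8 * t + rng.normal(0, 0.05, 50)
        r = agreement_regression(p, t)
        num = np.sum((t - t.mean()) * (p - p.mean()))
        den = np.sqrt(np.sum((t - t.mean()) ** 2) * np.sum((p - p.mean()) ** 2))
        assert r.r_squared == pytest.approx((num / den) ** 2, abs=1e-9)

    def test_zero_variance_truth_rejected(self):
        with pytest.raises(ValueError):
            agreement_regression(np.array([1.0, 2, 3]), np.array([5.0, 5, 5]))


class TestPairedComparison:
    def test_identical_lists(self):
        t, p = paired_dsc_comparison([0.8, 0.7, 0.9], [0.8, 0.7, 0.9])
        assert t == 0.0 and p == 1.0

    def test_constant_shift_detected(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.7, 0.9, 11)
        b = a - 0.1 + rng.normal(0, 0.005, 11)
        _, p = paired_dsc_comparison(a, b)
        assert p < 0.01

    def test_minimal_n_two(self):
        t, p = paired_dsc_comparison([0.8, 0.6], [0.7, 0.4])
        assert np.isfinite(t) and 0 <= p <= 1
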