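"""Overlap and boundary metrics against direct counting and brute force."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from vhucsnet.metrics import (MetricConfig, aggregate_report, assd,
                              confusion_counts, dice, dice_loss, hd95, iou)

EXACT = MetricConfig(epsilon=1e-12)


def brute_force_boundary(mask):
    """Oracle boundary: foreground pixels with a background 4-neighbour
    (image border counts as background)."""
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or not mask[ni, nj]:
                    out[i, j] = True
    return out


def brute_force_surface_distances(a, b):
    pa = np.argwhere(brute_force_boundary(a))
    pb = np.argwhere(brute_force_boundary(b))
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return d.min(axis=1), d.min(axis=0)


class TestDiceIoU:
    def test_identical_masks(self, rng):
        m = (rng.random((10, 10)) > 0.5).astype(np.uint8)
        m[0, 0] = 1
        assert dice(m, m, EXACT) == pytest.approx(1.0)
        assert iou(m, m, EXACT) == pytest.approx(1.0)

    def test_nested_masks_direct_count(self):
        gt = np.zeros((4, 4), dtype=np.uint8)
        gt[1:3, 1:3] = 1  # 4 pixels
        pred = np.zeros_like(gt)
        pred[1, 1:3] = 1  # 2 pixels inside
        assert dice(pred, gt, EXACT) == pytest.approx(2 * 2 / 6, abs=1e-9)
        assert iou(pred, gt, EXACT) == pytest.approx(2 / 4, abs=1e-9)

    def test_disjoint_masks(self):
        a = np.zeros((6, 6), dtype=np.uint8)
        b = np.zeros_like(a)
        a[0, 0] = 1
        b[5, 5] = 1
        assert dice(a, b, EXACT) == pytest.approx(0.0, abs=1e-9)
        assert iou(a, b, EXACT) == pytest.approx(0.0, abs=1e-9)

    def test_both_empty_equal_one_by_smoothing(self):
        z = np.zeros((5, 5), dtype=np.uint8)
        assert dice(z, z) == pytest.approx(1.0)
        assert iou(z, z) == pytest.approx(1.0)

    @settings(max_examples=100, derandomize=True)
    @given(hnp.arrays(np.int8, (7, 7), elements=st.integers(0, 1)),
           hnp.arrays(np.int8, (7, 7), elements=st.integers(0, 1)))
    def test_dice_iou_identity_and_symmetry(self, a, b):
        d, j = dice(a, b, EXACT), iou(a, b, EXACT)
        assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)
        assert dice(b, a, EXACT) == pytest.approx(d, abs=1e-12)
        assert iou(b, a, EXACT) == pytest.approx(j, abs=1e-12)

    @pytest.mark.parametrize("j,d", [(0.9441, 0.9712), (0.9285, 0.9629),
                                     (0.9107, 0.9532)])
    def test_published_iou_dice_pairs(self, j, d):
        # both sides are printed at 4 decimals, so agreement holds to ~1e-4
        assert 2 * j / (1 + j) == pytest.approx(d, abs=1e-4)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros((3, 3)), np.zeros((4, 4)))


class TestDiceLoss:
    def test_perfect_prediction_zero_loss(self, rng):
        g = (rng.random((8, 8)) > 0.5).astype(float)
        assert dice_loss(g, g) == pytest.approx(0.0, abs=1e-5)

    def test_loss_is_one_minus_soft_dice(self, rng):
        p = rng.random((8, 8))
        g = (rng.random((8, 8)) > 0.5).astype(float)
        cfg = MetricConfig()
        soft = (2 * (p * g).sum() + cfg.epsilon) / (p.sum() + g.sum() + cfg.epsilon)
        assert dice_loss(p, g, cfg) + soft == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("d,loss", [(0.9712, 0.0288), (0.9532, 0.0468),
                                        (0.9629, 0.0371)])
    def test_published_loss_dice_complements(self, d, loss):
        assert 1.0 - d == pytest.approx(loss, abs=1e-12)

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.full((3, 3), 1.5), np.ones((3, 3)))


class TestBoundaryMetrics:
    def test_identical_masks_zero(self):
        m = np.zeros((8, 8), dtype=np.uint8)
        m[2:6, 2:6] = 1
        assert hd95(m, m) == 0.0
        assert assd(m, m) == 0.0

    def test_single_pixels_three_apart(self):
        a = np.zeros((8, 8), dtype=np.uint8)
        b = np.zeros_like(a)
        a[4, 1] = 1
        b[4, 4] = 1
        assert hd95(a, b) == pytest.approx(3.0)
        assert assd(a, b) == pytest.approx(3.0)

    def test_empty_mask_raises_unless_sentinel(self):
        z = np.zeros((5, 5), dtype=np.uint8)
        m = z.copy()
        m[2, 2] = 1
        with pytest.raises(ValueError):
            hd95(m, z)
        assert hd95(z, z, MetricConfig(empty_sentinel=True)) == 0.0

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        a = (r.random((12, 12)) > 0.6).astype(np.uint8)
        b = (r.random((12, 12)) > 0.6).astype(np.uint8)
        if not a.any() or not b.any():
            return
        d_ab, d_ba = brute_force_surface_distances(a, b)
        pooled = np.concatenate([d_ab, d_ba])
        assert hd95(a, b, EXACT) == pytest.approx(np.percentile(pooled, 95))
        assert assd(a, b, EXACT) == pytest.approx(
            (d_ab.mean() + d_ba.mean()) / 2)

    def test_pixel_spacing_scales_distances(self):
        a = np.zeros((6, 6), dtype=np.uint8)
        b = np.zeros_like(a)
        a[2, 1] = 1
        b[2, 3] = 1
        cfg = MetricConfig(pixel_spacing=(1.0, 0.5))
        assert hd95(a, b, cfg) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a = (rng.random((10, 10)) > 0.5).astype(np.uint8)
        b = (rng.random((10, 10)) > 0.5).astype(np.uint8)
        a[0, 0] = b[0, 0] = 1
        assert hd95(a, b) == pytest.approx(hd95(b, a))
        assert assd(a, b) == pytest.approx(assd(b, a))


class TestConfusionAndAggregates:
    def test_perfect_and_inverted(self, rng):
        g = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        tp, fp, fn, tn = confusion_counts(g, g)
        assert fp == fn == 0 and tp + tn == 36
        tp, fp, fn, tn = confusion_counts(1 - g, g)
        assert tp == tn == 0 and fp + fn == 36

    def test_enumerated_2x2(self):
        pred = np.array([[1, 0], [0, 0]])
        gt = np.array([[1, 1], [0, 0]])
        assert confusion_counts(pred, gt) == (1, 0, 1, 2)

    def test_published_ci_arithmetic(self):
        mean, sd, lo, hi = aggregate_report([0.9712])
        assert sd == 0.0
        # the printed fused-model interval comes from mean 0.9712, sd 0.0088
        lo = 0.9712 - 1.96 * 0.0088
        hi = 0.9712 + 1.96 * 0.0088
        assert lo == pytest.approx(0.95395, abs=5e-6)
        assert hi == pytest.approx(0.98845, abs=5e-6)

    def test_aggregate_of_identical_values(self):
        mean, sd, lo, hi = aggregate_report([0.5] * 10)
        assert (mean, sd) == (0.5, 0.0)
        assert lo == hi == 0.5

    def test_aggregate_mean_sd_ci(self, rng):
        vals = rng.random(50)
        mean, sd, lo, hi = aggregate_report(vals)
        assert mean == pytest.approx(vals.mean())
        assert sd == pytest.approx(vals.std(ddof=0))
        assert lo == pytest.approx(mean - 1.96 * sd)
        assert hi == pytest.approx(mean + 1.96 * sd)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_report([])
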