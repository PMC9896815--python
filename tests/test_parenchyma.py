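"""Parenchyma segmentation: threshold fixed point, screening rule, morphology,
Dice, and the composed single-slice pipeline on phantoms."""

import numpy as np
import pytest

from nodulecad.parenchyma import (SegmentConfig, SegmentationError,
                                  apply_mask, binarize_parenchyma,
                                  dice_coefficient, fill_holes,
                                  iterative_threshold, repair_boundary,
                                  screen_components, segment_slice,
                                  split_left_right)
from nodulecad.preprocess import preprocess_slice

from conftest import MID


def brute_force_threshold(values, epsilon=1e-3):
    """Independent fixed-point oracle for the adaptive threshold."""
    g = np.asarray(values, float)
    t = (g.max() + g.min()) / 2.0
    while True:
        lo, hi = g[g < t], g[g >= t]
        if lo.size == 0 or hi.size == 0:
            return t
        t_new = (lo.mean() + hi.mean()) / 2.0
        if abs(t_new - t) < epsilon:
            return t_new
        t = t_new


class TestIterativeThreshold:
    def test_two_class_example(self):
        g = np.array([50] * 600 + [200] * 400, float)
        assert iterative_threshold(g) == pytest.approx(125.0)

    def test_three_class_example(self):
        g = np.array([0] * 100 + [100] * 100 + [255] * 100, float)
        assert iterative_threshold(g) == pytest.approx(152.5)

    def test_constant_image_rejected(self):
        with pytest.raises(SegmentationError):
            iterative_threshold(np.full((5, 5), 9))

    def test_matches_brute_force_on_random_histograms(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n1, n2 = rng.integers(50, 500, 2)
            g = np.concatenate([rng.normal(rng.uniform(10, 90), 8, n1),
                                rng.normal(rng.uniform(120, 240), 12, n2)])
            g = np.clip(g, 0, 255)
            assert iterative_threshold(g) == pytest.approx(
                brute_force_threshold(g), abs=2e-3)

    def test_result_is_fixed_point(self):
        rng = np.random.default_rng(3)
        g = np.clip(np.concatenate([rng.normal(40, 5, 300),
                                    rng.normal(180, 10, 200)]), 0, 255)
        t = iterative_threshold(g)
        lo, hi = g[g < t], g[g >= t]
        assert t == pytest.approx((lo.mean() + hi.mean()) / 2.0, abs=2e-3)


class TestBinarize:
    def test_strictly_below_threshold(self):
        img = np.array([[10, 50, 49, 51]])
        mask = binarize_parenchyma(img, 50)
        assert mask.tolist() == [[True, False, True, False]]


def _blob(canvas, r0, c0, area):
    """Place a solid rectangle of the given area (rows x cols heuristics)."""
    h = int(np.sqrt(area))
    w = area // h
    rem = area - h * w
    canvas[r0:r0 + h, c0:c0 + w] = True
    if rem:
        canvas[r0 + h, c0:c0 + rem] = True


class TestScreening:
    def build(self, areas, shape=(300, 300)):
        m = np.zeros(shape, bool)
        c0 = 5
        for a in areas:
            _blob(m, 120, c0, a)
            c0 += int(np.sqrt(a)) + 15
        return m

    def _areas_kept(self, areas):
        out, table = screen_components(self.build(areas))
        from scipy import ndimage
        lab, n = ndimage.label(out, ndimage.generate_binary_structure(2, 1))
        kept = sorted(ndimage.sum_labels(out, lab, np.arange(1, n + 1)).astype(int),
                      reverse=True)
        return kept, table

    def test_two_lungs_kept_trachea_dropped(self):
        kept, table = self._areas_kept([10000, 500, 400, 20])
        assert kept == [500, 400]
        assert table.sorted_areas.tolist() == [10000, 500, 400, 20]

    def test_lambda_branch_single_lung(self):
        kept, _ = self._areas_kept([10000, 600, 5])
        assert kept == [600]  # 600/5 = 120 > 50

    def test_two_components_keep_second(self):
        kept, _ = self._areas_kept([10000, 700])
        assert kept == [700]

    def test_single_component_is_error(self):
        m = np.zeros((50, 50), bool)
        m[10:20, 10:20] = True
        with pytest.raises(SegmentationError):
            screen_components(m)

    def test_border_touching_component_not_lung(self):
        m = np.zeros((100, 100), bool)
        m[0:50, 0:50] = True          # largest, touches border (air)
        m[60:70, 0:20] = True         # touches border: ineligible
        m[60:70, 40:50 + 10] = True   # interior lung candidate
        out, _ = screen_components(m)
        assert out.sum() == 200
        assert not out[60:70, 0:20].any()

    def test_area_conservation(self):
        out, table = screen_components(self.build([10000, 500, 400, 20]))
        assert out.sum() == 900  # sum of selected S entries


class TestFillHoles:
    def test_solid_disk_unchanged(self):
        yy, xx = np.mgrid[:30, :30]
        d = (yy - 15) ** 2 + (xx - 15) ** 2 <= 81
        assert np.array_equal(fill_holes(d), d)

    def test_annulus_becomes_disk(self):
        yy, xx = np.mgrid[:30, :30]
        r2 = (yy - 15) ** 2 + (xx - 15) ** 2
        annulus = (r2 <= 100) & (r2 >= 36)
        disk = r2 <= 100
        assert np.array_equal(fill_holes(annulus), disk)

    def test_hole_area_added_exactly(self):
        m = np.ones((40, 40), bool)
        m[0, :] = m[-1, :] = m[:, 0] = m[:, -1] = False
        m[5:10, 5:10] = False     # 25 px
        m[20:24, 20:24] = False   # 16 px
        m[30:34, 8:12] = False    # 16 px -> 57 px of interior holes
        filled = fill_holes(m)
        assert int(filled.sum()) == int(m.sum()) + 57

    def test_idempotent_and_extensive_on_random_blobs(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            m = rng.random((48, 48)) < 0.55
            f = fill_holes(m)
            assert (f | m).sum() == f.sum()          # extensive
            assert np.array_equal(fill_holes(f), f)  # idempotent


class TestRepair:
    def _disk(self, n=80, r=25):
        yy, xx = np.mgrid[:n, :n]
        return (yy - n // 2) ** 2 + (xx - n // 2) ** 2 <= r * r

    def test_zero_radii_identity(self):
        d = self._disk()
        out = repair_boundary(d, np.zeros_like(d), open_radius=0, erode_radius=0)
        assert np.array_equal(out, d)

    def test_notch_is_closed(self):
        d = self._disk()
        yy, xx = np.mgrid[:80, :80]
        bite = (yy - 40) ** 2 + (xx - 65) ** 2 <= 9  # 3-px-deep boundary bite
        notched = d & ~bite
        out = repair_boundary(notched, np.zeros_like(d),
                              open_radius=5, erode_radius=0)
        # the notch is re-incorporated up to the closing's boundary chord,
        # which can sag ~1-2 px inside the original convex contour
        from skimage.morphology import disk as _disk, erosion
        inner = d & bite & erosion(d, _disk(2)).astype(bool)
        assert inner.any() and out[inner].all()

    def test_close_lungs_stay_separate(self):
        m = np.zeros((60, 100), bool)
        yy, xx = np.mgrid[:60, :100]
        left = (yy - 30) ** 2 + (xx - 28) ** 2 <= 144
        right = (yy - 30) ** 2 + (xx - 56) ** 2 <= 144  # 4 px gap
        out = repair_boundary(left, right, open_radius=1, erode_radius=1)
        from scipy import ndimage
        _, n = ndimage.label(out, ndimage.generate_binary_structure(2, 1))
        assert n == 2

    def test_overlap_rejected(self):
        d = self._disk()
        with pytest.raises(SegmentationError):
            repair_boundary(d, d)


class TestSplit:
    def test_left_is_smaller_column(self):
        m = np.zeros((60, 100), bool)
        yy, xx = np.mgrid[:60, :100]
        m |= (yy - 30) ** 2 + (xx - 30) ** 2 <= 64
        m |= (yy - 30) ** 2 + (xx - 70) ** 2 <= 64
        s = split_left_right(m)
        assert not s.fused
        assert np.nonzero(s.left)[1].mean() < np.nonzero(s.right)[1].mean()

    def test_single_region_flagged(self):
        m = np.zeros((30, 30), bool)
        m[10:20, 10:20] = True
        s = split_left_right(m)
        assert s.fused and np.array_equal(s.left, s.right)

    def test_three_components_rejected(self):
        m = np.zeros((30, 90), bool)
        for c in (10, 40, 70):
            m[10:20, c:c + 10] = True
        with pytest.raises(SegmentationError):
            split_left_right(m)


class TestApplyMaskAndDice:
    def test_apply_mask_identity_and_zero(self):
        img = np.arange(25, dtype=np.uint8).reshape(5, 5)
        assert np.array_equal(apply_mask(img, np.ones((5, 5), bool)), img)
        assert apply_mask(img, np.zeros((5, 5), bool)).sum() == 0

    def test_apply_mask_counts(self):
        img = np.full((6, 6), 9, np.uint8)
        mask = np.zeros((6, 6), bool)
        mask[:3] = True
        assert (apply_mask(img, mask) > 0).sum() == mask.sum()

    def test_apply_mask_shape_mismatch(self):
        with pytest.raises(SegmentationError):
            apply_mask(np.zeros((3, 3)), np.zeros((4, 4), bool))

    def test_dice_identities(self):
        a = np.zeros((10, 10), bool)
        a[2:6, 2:6] = True
        assert dice_coefficient(a, a) == 1.0
        b = np.zeros_like(a)
        b[7:9, 7:9] = True
        assert dice_coefficient(a, b) == 0.0

    def test_dice_partial_overlap(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, :4] = True              # |A| = 4
        b[0, 2:] = b[1, :2] = True   # |B| = 4, overlap 2
        assert dice_coefficient(a, b) == 0.5

    def test_dice_symmetric(self):
        rng = np.random.default_rng(7)
        a = rng.random((20, 20)) < 0.4
        b = rng.random((20, 20)) < 0.4
        assert dice_coefficient(a, b) == dice_coefficient(b, a)

    def test_dice_both_empty_error(self):
        z = np.zeros((5, 5), bool)
        with pytest.raises(SegmentationError):
            dice_coefficient(z, z)


class TestSegmentSlice:
    def test_noise_free_phantom_dice(self, clean_phantom):
        _, vol, truth = clean_phantom
        seg = segment_slice(preprocess_slice(vol[MID]))
        assert dice_coefficient(seg.mask, truth.parenchyma[MID]) >= 0.98

    def test_masked_image_is_product(self, clean_phantom):
        _, vol, _ = clean_phantom
        pre = preprocess_slice(vol[MID])
        seg = segment_slice(pre)
        assert np.array_equal(seg.masked_image, pre * seg.mask)
        assert np.array_equal(seg.mask, seg.left | seg.right)

    def test_fused_lungs_take_single_region_path(self, fused_phantom):
        _, vol, _ = fused_phantom
        seg = segment_slice(preprocess_slice(vol[MID]))
        assert seg.fused
        assert seg.mask.any()

    def test_slice_without_lungs_raises_stage_error(self, clean_phantom):
        _, vol, _ = clean_phantom
        with pytest.raises(SegmentationError, match="empty|no lung"):
            segment_slice(preprocess_slice(vol[0]))

    def test_literal_repair_sequence_available(self, clean_phantom):
        _, vol, truth = clean_phantom
        cfg = SegmentConfig(repair_ops=("open", "erode"))
        seg = segment_slice(preprocess_slice(vol[MID]), cfg)
        assert dice_coefficient(seg.mask, truth.parenchyma[MID]) >= 0.95
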