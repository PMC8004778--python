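"""Extreme-point cropping, dihedral augmentation, and dataset splitting."""

import numpy as np
import pytest

from featfuse import (
    ExtremePoints,
    InvalidInputError,
    NoForegroundError,
    augment_dihedral,
    binarize,
    crop_pipeline,
    crop_to_extremes,
    find_extreme_points,
    largest_component_contour,
    morph_clean,
    resize_bicubic,
    split_dataset,
)
from featfuse.preprocessing import dihedral_transform


class TestBinarize:
    def test_nothing_exceeds_threshold(self):
        assert not binarize(np.zeros((8, 8)), threshold=10, smooth_radius=0).any()

    def test_foreground_exactly_on_bright_block(self):
        img = np.zeros((10, 10))
        img[3:7, 2:6] = 200.0
        mask = binarize(img, threshold=100, smooth_radius=0)
        expected = img > 100
        assert np.array_equal(mask, expected)

    def test_uniform_exceedance(self):
        assert binarize(np.full((5, 5), 255.0), threshold=254, smooth_radius=0).all()

    def test_empty_image_rejected(self):
        with pytest.raises(InvalidInputError):
            binarize(np.zeros((0, 0)), threshold=10)


class TestMorphClean:
    def test_zero_iterations_is_identity(self):
        rng = np.random.default_rng(0)
        mask = rng.random((12, 12)) > 0.5
        assert np.array_equal(morph_clean(mask, 0, 0), mask)

    def test_erosion_removes_singleton(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[3, 3] = True
        assert not morph_clean(mask, erode_iters=1, dilate_iters=0).any()

    def test_opening_recovers_solid_square(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:8, 2:8] = True
        assert np.array_equal(morph_clean(mask, 1, 1), mask)

    def test_opening_preserves_convex_area(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 8:22] = True
        for iters in (1, 2, 3):
            assert morph_clean(mask, iters, iters).sum() == mask.sum()

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            morph_clean(np.ones((3, 3), dtype=bool), -1, 0)


class TestLargestComponentContour:
    def test_block_boundary(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[2:7, 2:7] = True
        pts = largest_component_contour(mask)
        interior = {(r, c) for r in range(3, 6) for c in range(3, 6)}
        got = {tuple(p) for p in pts}
        border = {(r, c) for r in range(2, 7) for c in range(2, 7)} - interior
        assert got == border

    def test_larger_component_wins(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[1:7, 1:7] = True  # 6x6
        mask[9:11, 9:11] = True  # 2x2
        pts = largest_component_contour(mask)
        assert pts[:, 0].max() <= 6 and pts[:, 1].max() <= 6

    def test_single_pixel_degenerate(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 4] = True
        assert [tuple(p) for p in largest_component_contour(mask)] == [(2, 4)]

    def test_empty_mask_rejected(self):
        with pytest.raises(NoForegroundError):
            largest_component_contour(np.zeros((4, 4), dtype=bool))


class TestFindExtremePoints:
    def test_rectangle_extremes(self):
        pts = np.array([(r, c) for r in range(2, 8) for c in range(3, 10)
                        if r in (2, 7) or c in (3, 9)])
        ep = find_extreme_points(pts)
        assert ep.top[0] == 2 and ep.bottom[0] == 7
        assert ep.left[1] == 3 and ep.right[1] == 9

    def test_single_point_degenerate(self):
        ep = find_extreme_points(np.array([[4, 4]]))
        assert ep.left == ep.right == ep.top == ep.bottom == (4, 4)

    def test_disk_width_spans_two_radii(self):
        r = 9
        yy, xx = np.mgrid[0:41, 0:41]
        mask = (yy - 20) ** 2 + (xx - 20) ** 2 <= r * r
        ep = find_extreme_points(largest_component_contour(mask))
        assert ep.right[1] - ep.left[1] == 2 * r

    def test_matches_argmin_argmax_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pts = rng.integers(0, 50, size=(rng.integers(1, 40), 2))
            ep = find_extreme_points(pts)
            assert ep.left[1] == pts[:, 1].min()
            assert ep.right[1] == pts[:, 1].max()
            assert ep.top[0] == pts[:, 0].min()
            assert ep.bottom[0] == pts[:, 0].max()

    def test_empty_contour_rejected(self):
        with pytest.raises(InvalidInputError):
            find_extreme_points(np.empty((0, 2)))


class TestCropToExtremes:
    def test_full_span_identity(self):
        img = np.arange(36.0).reshape(6, 6)
        ep = ExtremePoints(left=(0, 0), right=(0, 5), top=(0, 0), bottom=(5, 0))
        assert np.array_equal(crop_to_extremes(img, ep, margin=0), img)

    def test_inclusive_index_arithmetic(self):
        img = np.zeros((20, 20))
        ep = ExtremePoints(left=(5, 6), right=(5, 12), top=(5, 6), bottom=(9, 6))
        assert crop_to_extremes(img, ep, margin=0).shape == (5, 7)

    def test_margin_clipped_at_border(self):
        img = np.zeros((10, 10))
        ep = ExtremePoints(left=(1, 1), right=(1, 8), top=(1, 1), bottom=(8, 1))
        assert crop_to_extremes(img, ep, margin=2).shape == (10, 10)

    def test_out_of_bounds_rejected(self):
        img = np.zeros((5, 5))
        ep = ExtremePoints(left=(0, 0), right=(0, 9), top=(0, 0), bottom=(4, 0))
        with pytest.raises(InvalidInputError):
            crop_to_extremes(img, ep)


class TestResizeBicubic:
    def test_constant_maps_to_constant(self):
        out = resize_bicubic(np.full((17, 23), 100.0), 32, 32)
        assert out.shape == (32, 32)
        assert np.allclose(out, 100.0)

    @pytest.mark.parametrize("size", [(224, 224), (299, 299)])
    def test_standard_backbone_input_sizes(self, size):
        out = resize_bicubic(np.random.default_rng(0).random((50, 60)), *size)
        assert out.shape == size

    def test_nonpositive_target_rejected(self):
        with pytest.raises(InvalidInputError):
            resize_bicubic(np.zeros((4, 4)), 0, 5)


class TestDihedralAugmentation:
    def test_rot90_four_times_is_identity(self, asymmetric_image):
        out = asymmetric_image
        for _ in range(4):
            out = dihedral_transform(out, 1, False)
        assert np.array_equal(out, asymmetric_image)

    def test_flip_twice_is_identity(self, asymmetric_image):
        out = dihedral_transform(dihedral_transform(asymmetric_image, 0, True), 0, True)
        assert np.array_equal(out, asymmetric_image)

    def test_exhaustive_gives_8_distinct_variants(self, asymmetric_image):
        variants = augment_dihedral(asymmetric_image, mode="exhaustive")
        assert len(variants) == 8
        for i in range(8):
            for j in range(i + 1, 8):
                assert not np.array_equal(variants[i], variants[j])

    def test_group_closure_under_composition(self, asymmetric_image):
        variants = augment_dihedral(asymmetric_image, mode="exhaustive")
        keys = {v.tobytes() for v in variants}
        for k in range(4):
            for flip in (False, True):
                for v in variants:
                    assert dihedral_transform(v, k, flip).tobytes() in keys

    def test_random_mode_is_seeded_and_in_group(self, asymmetric_image):
        a = augment_dihedral(asymmetric_image, mode="random", seed=5)
        b = augment_dihedral(asymmetric_image, mode="random", seed=5)
        assert len(a) == 1 and np.array_equal(a[0], b[0])
        keys = {v.tobytes() for v in augment_dihedral(asymmetric_image, "exhaustive")}
        assert a[0].tobytes() in keys


class TestCropPipeline:
    def test_recovers_known_rectangles(self):
        """The full crop chain returns exactly a bright rectangle's bounding
        box for 50 random placements and sizes (margin 0)."""
        rng = np.random.default_rng(123)
        for _ in range(50):
            h, w = 64, 64
            rh = int(rng.integers(8, 30))
            rw = int(rng.integers(8, 30))
            r0 = int(rng.integers(4, h - rh - 4))
            c0 = int(rng.integers(4, w - rw - 4))
            img = np.zeros((h, w))
            img[r0 : r0 + rh, c0 : c0 + rw] = 200.0
            out = crop_pipeline(img, threshold=45, smooth_radius=0, erode_iters=2, dilate_iters=2)
            assert out.shape == (rh, rw)
            assert np.all(out == 200.0)


class TestSplitDataset:
    @pytest.mark.parametrize(
        "n,expected_train,expected_test",
        [(3000, 2400, 600), (253, 202, 51), (10, 8, 2)],
    )
    def test_eighty_twenty_counts(self, n, expected_train, expected_test):
        part = split_dataset(list(range(n)), [i % 2 for i in range(n)], 0.8, seed=0)
        assert len(part.train_ids) == expected_train
        assert len(part.test_ids) == expected_test

    def test_partition_properties(self):
        ids = [f"s{i}" for i in range(97)]
        labels = [i % 3 for i in range(97)]
        part = split_dataset(ids, labels, 0.8, seed=9)
        assert set(part.train_ids) | set(part.test_ids) == set(ids)
        assert set(part.train_ids) & set(part.test_ids) == set()
        assert split_dataset(ids, labels, 0.8, seed=9) == part

    def test_stratified_preserves_class_proportions(self):
        ids = list(range(100))
        labels = [0] * 70 + [1] * 30
        part = split_dataset(ids, labels, 0.8, seed=1, stratified=True)
        train_labels = [labels[i] for i in part.train_ids]
        assert len(part.train_ids) == 80
        assert train_labels.count(0) == 56 and train_labels.count(1) == 24

    def test_too_small_rejected(self):
        with pytest.raises(InvalidInputError):
            split_dataset([1], [0], 0.8, seed=0)
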