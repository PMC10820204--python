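"""Component labeling, moment-ellipse fitting and crop standardization."""

import numpy as np
import pytest
from skimage.transform import rotate as sk_rotate

from colonycount import synthetic
from colonycount.components import (
    fit_ellipse,
    label_components,
    spatially_normalize,
    standardize_crop,
)


def bar_mask(h=6, w=20, canvas=40):
    m = np.zeros((canvas, canvas), dtype=bool)
    r0 = (canvas - h) // 2
    c0 = (canvas - w) // 2
    m[r0 : r0 + h, c0 : c0 + w] = True
    return m


class TestLabelComponents:
    def test_two_disjoint_squares(self):
        m = np.zeros((10, 10), dtype=bool)
        m[1:4, 1:4] = True
        m[6:9, 6:9] = True
        assert len(label_components(m, min_area=1)) == 2

    def test_empty_mask(self):
        assert label_components(np.zeros((5, 5), dtype=bool)) == []

    def test_diagonal_touch_is_one_component_under_8_connectivity(self):
        m = np.zeros((6, 6), dtype=bool)
        m[1:3, 1:3] = True
        m[3:5, 3:5] = True
        assert len(label_components(m, min_area=1)) == 1
        assert len(label_components(m, connectivity=1, min_area=1)) == 2

    def test_min_area_drops_speckle(self):
        m = np.zeros((12, 12), dtype=bool)
        m[0, 0] = True  # 1-px speckle
        m[4:8, 4:8] = True
        comps = label_components(m, min_area=9)
        assert len(comps) == 1
        assert comps[0].area == 16

    def test_sorted_by_bbox_origin_and_ids_sequential(self):
        m = np.zeros((20, 20), dtype=bool)
        m[10:14, 2:6] = True
        m[1:5, 8:12] = True
        comps = label_components(m, min_area=1)
        assert [c.id for c in comps] == [0, 1]
        assert comps[0].bbox[0] < comps[1].bbox[0]

    def test_matches_flood_fill_oracle_on_random_masks(self):
        """Label partitions equal an independent BFS flood fill (8-neighbour)."""

        def flood_partition(mask):
            seen = np.zeros_like(mask, dtype=bool)
            parts = []
            h, w = mask.shape
            for i in range(h):
                for j in range(w):
                    if mask[i, j] and not seen[i, j]:
                        stack, part = [(i, j)], set()
                        seen[i, j] = True
                        while stack:
                            r, c = stack.pop()
                            part.add((r, c))
                            for dr in (-1, 0, 1):
                                for dc in (-1, 0, 1):
                                    rr, cc = r + dr, c + dc
                                    if (
                                        0 <= rr < h
                                        and 0 <= cc < w
                                        and mask[rr, cc]
                                        and not seen[rr, cc]
                                    ):
                                        seen[rr, cc] = True
                                        stack.append((rr, cc))
                        parts.append(frozenset(part))
            return set(parts)

        rng = np.random.default_rng(23)
        for _ in range(100):
            mask = rng.random((16, 16)) < 0.35
            expected = flood_partition(mask)
            got = {
                frozenset(map(tuple, c.pixel_set))
                for c in label_components(mask, min_area=1)
            }
            assert got == expected


class TestFitEllipse:
    def test_horizontal_rectangle_is_90_degrees(self):
        comp = label_components(bar_mask(), min_area=1)[0]
        ell = fit_ellipse(comp)
        assert abs(ell.theta - 90.0) <= 1.0
        assert ell.major > ell.minor

    def test_vertical_rectangle_is_0_degrees(self):
        comp = label_components(bar_mask().T, min_area=1)[0]
        assert abs(fit_ellipse(comp).theta) <= 1.0

    def test_disk_axes_nearly_equal(self):
        yy, xx = np.mgrid[0:41, 0:41]
        disk = (yy - 20) ** 2 + (xx - 20) ** 2 <= 15**2
        ell = fit_ellipse(label_components(disk, min_area=1)[0])
        assert ell.minor / ell.major > 0.98

    @pytest.mark.parametrize("phi", [15, -30, 45, 70])
    def test_rotation_equivariance(self, phi):
        base = bar_mask(canvas=60)
        theta0 = fit_ellipse(label_components(base, min_area=1)[0]).theta
        rotated = sk_rotate(base.astype(float), phi, resize=True, order=0) > 0.5
        theta1 = fit_ellipse(label_components(rotated, min_area=1)[0]).theta
        delta = (theta1 - theta0 + 90) % 180 - 90
        # a counterclockwise display rotation by phi moves the fitted
        # from-vertical angle by +phi (modulo the 180-degree axis symmetry)
        err = (delta - phi + 90) % 180 - 90
        assert abs(err) <= 1.0

    def test_collinear_pixels_take_line_direction(self):
        pts = np.array([[i, 5] for i in range(3, 9)])
        ell = fit_ellipse(pts)
        assert ell.minor == 0.0
        assert abs(ell.theta) <= 1e-9

    def test_too_few_pixels_rejected(self):
        with pytest.raises(ValueError):
            fit_ellipse(np.array([[0, 0], [1, 1]]))


class TestSpatialNormalization:
    def test_vertical_component_unchanged_up_to_interpolation(self):
        rng = np.random.default_rng(0)
        img = rng.random((40, 40)) * 0.1
        mask = bar_mask().T
        img[mask] = 0.8
        comp = label_components(mask, min_area=1)[0]
        crop = spatially_normalize(comp, img)
        # same content: bright bar still vertical, same area within 5%
        refit = fit_ellipse(np.argwhere(crop > 0.4))
        assert abs(refit.theta) < 3.0
        assert abs((crop > 0.4).sum() - mask.sum()) / mask.sum() < 0.05

    def test_horizontal_bar_becomes_vertical(self):
        img = np.zeros((40, 40))
        mask = bar_mask()
        img[mask] = 1.0
        comp = label_components(mask, min_area=1)[0]
        crop, rmask = spatially_normalize(comp, img, return_mask=True)
        refit = fit_ellipse(np.argwhere(rmask))
        assert abs(refit.theta) < 3.0

    def test_area_preserved_across_rotation(self):
        img = np.zeros((60, 60))
        mask = sk_rotate(bar_mask(canvas=60).astype(float), 33, order=0) > 0.5
        img[mask] = 1.0
        comp = label_components(mask, min_area=1)[0]
        _crop, rmask = spatially_normalize(comp, img, return_mask=True)
        assert abs(rmask.sum() - mask.sum()) / mask.sum() < 0.05

    def test_near_circular_component_not_rotated(self):
        yy, xx = np.mgrid[0:31, 0:31]
        disk = (yy - 15) ** 2 + (xx - 15) ** 2 <= 10**2
        img = disk.astype(float)
        comp = label_components(disk, min_area=1)[0]
        crop = spatially_normalize(comp, img)
        # no interpolation happened: values stay exactly binary
        assert set(np.unique(crop)) <= {0.0, 1.0}

    def test_content_beyond_margin_radius_is_zeroed(self):
        img = np.zeros((30, 30))
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:12, 5:12] = True
        img[:] = 0.7  # bright background everywhere
        img[mask] = 1.0
        comp = label_components(mask, min_area=1)[0]
        crop = spatially_normalize(comp, img, rotate=False)
        # window corner lies within bbox+margin but beyond the 4-px
        # Euclidean margin around the pixel set, so it must be masked out
        assert crop[0, 0] == 0.0
        # pixels adjacent to the component (adhesion boundary) are kept
        assert crop.max() == 1.0
        assert (crop == 0.7).any()


class TestStandardizeCrop:
    def test_small_crop_zero_padded_and_centered(self):
        crop = np.ones((50, 40))
        out = standardize_crop(crop)
        assert out.shape == (128, 128)
        assert out.sum() == pytest.approx(50 * 40)
        rows = np.nonzero(out.any(axis=1))[0]
        assert rows[0] == (128 - 50) // 2

    def test_large_crop_rescaled_with_nearest_rounding(self):
        out = standardize_crop(np.ones((200, 60)))
        cols = np.nonzero(out.any(axis=0))[0]
        assert out.shape == (128, 128)
        assert len(cols) == 38  # 60 * 128/200 = 38.4 -> 38

    def test_exact_size_unchanged(self):
        crop = np.random.default_rng(0).random((128, 128)).astype(np.float32)
        assert np.array_equal(standardize_crop(crop), crop)

    def test_idempotent(self):
        crop = np.random.default_rng(1).random((73, 190))
        once = standardize_crop(crop)
        assert np.array_equal(standardize_crop(once), once)

    def test_color_crops_supported(self):
        out = standardize_crop(np.ones((30, 260, 3)))
        assert out.shape == (128, 128, 3)

    def test_empty_crop_rejected(self):
        with pytest.raises(ValueError):
            standardize_crop(np.zeros((0, 4)))


def test_count_conservation_on_synthetic_plates():
    """No colony is lost or double-assigned between generator and labeling."""
    cfg = synthetic.SynthConfig(
        image_size=(96, 96), n_components=8, colony_radius_range=(2.0, 4.0), seed=21
    )
    for index in range(5):
        s = synthetic.generate_plate(cfg, index=index)
        comps = label_components(s.colony_mask, min_area=1)
        stored = {tuple(sorted(map(tuple, px))): k for px, k in s.components}
        total = 0
        for c in comps:
            total += stored[tuple(sorted(map(tuple, c.pixel_set)))]
        assert total == s.total_count
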