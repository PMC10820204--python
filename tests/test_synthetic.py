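"""Synthetic plate generator: determinism, geometry and label statistics."""

import numpy as np
import pytest
from scipy import ndimage, stats

from colonycount import synthetic
from colonycount.components import label_components


def small_cfg(**kw):
    base = dict(image_size=(96, 96), n_components=6,
                colony_radius_range=(2.0, 4.0), seed=5)
    base.update(kw)
    return synthetic.SynthConfig(**base)


class TestConfigValidation:
    def test_count_distribution_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            small_cfg(count_distribution=[0.5] + [0.0] * 8)

    @pytest.mark.parametrize(
        "field,value",
        [
            ("edge_thickness_frac", 0.0),
            ("cluster_overlap_frac", 1.0),
            ("dish_radius_frac", 0.6),
            ("colony_radius_range", (0.0, 3.0)),
            ("n_components", -1),
        ],
    )
    def test_invalid_fields_rejected(self, field, value):
        with pytest.raises(ValueError):
            small_cfg(**{field: value})


class TestColonyCluster:
    def test_single_disk_area_close_to_circle(self):
        cfg = small_cfg(colony_radius_range=(6.0, 6.0))
        rng = np.random.default_rng(0)
        blob = synthetic.render_colony_cluster(1, (48, 48), cfg, rng)
        area = len(blob.pixels)
        assert np.pi * 36 * 0.7 <= area <= np.pi * 36 * 1.3

    @pytest.mark.parametrize("k", [1, 2, 3, 5, 9])
    def test_cluster_is_one_connected_component(self, k):
        cfg = small_cfg(image_size=(128, 128))
        rng = np.random.default_rng(k)
        blob = synthetic.render_colony_cluster(k, (64, 64), cfg, rng)
        mask = np.zeros((128, 128), dtype=bool)
        mask[blob.pixels[:, 0], blob.pixels[:, 1]] = True
        _, n = ndimage.label(mask, structure=np.ones((3, 3)))
        assert n == 1

    def test_two_disk_overlap_reduces_union_area(self):
        # two r=10 disks whose centres are 10 px apart (overlap 0.5) must
        # cover less than two disjoint disks; oracle: direct rasterization
        cfg = small_cfg(colony_radius_range=(10.0, 10.0),
                        cluster_overlap_frac=0.5, image_size=(128, 128))
        rng = np.random.default_rng(3)
        blob = synthetic.render_colony_cluster(2, (64, 64), cfg, rng)
        (y0, x0, r0), (y1, x1, r1) = blob.disks
        assert np.hypot(y1 - y0, x1 - x0) == pytest.approx(10.0, abs=1e-9)
        yy, xx = np.mgrid[0:128, 0:128]
        single = ((yy - y0) ** 2 + (xx - x0) ** 2 <= r0 * r0).sum()
        assert len(blob.pixels) < 2 * single

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            synthetic.render_colony_cluster(
                13, (10, 10), small_cfg(), np.random.default_rng(0)
            )


class TestPlateGeneration:
    def test_same_seed_gives_bitwise_identical_sample(self):
        cfg = small_cfg()
        a = synthetic.generate_plate(cfg)
        b = synthetic.generate_plate(cfg)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.edge_mask, b.edge_mask)
        assert np.array_equal(a.colony_mask, b.colony_mask)

    def test_different_index_gives_different_plate(self):
        cfg = small_cfg()
        a = synthetic.generate_plate(cfg, index=0)
        b = synthetic.generate_plate(cfg, index=1)
        assert not np.array_equal(a.image, b.image)

    def test_empty_plate_has_no_colonies(self):
        s = synthetic.generate_plate(small_cfg(n_components=0))
        assert not s.colony_mask.any()
        assert s.total_count == 0
        assert s.components == []

    def test_annulus_to_background_ratio_near_one_eighth(self):
        s = synthetic.generate_plate(small_cfg(image_size=(256, 256)))
        annulus = s.edge_mask.sum()
        ratio = annulus / (s.edge_mask.size - annulus)
        assert 1 / 8 * 0.5 <= ratio <= 1 / 8 * 1.5

    def test_colony_pixels_strictly_inside_dish_interior(self):
        s = synthetic.generate_plate(small_cfg(n_components=10, seed=9))
        interior = ndimage.binary_fill_holes(s.edge_mask) & ~s.edge_mask
        assert s.colony_mask.any()
        assert not (s.colony_mask & ~interior).any()

    def test_labeling_mask_recovers_components_and_counts(self):
        s = synthetic.generate_plate(small_cfg(n_components=8, seed=12))
        comps = label_components(s.colony_mask, min_area=1)
        assert len(comps) == len(s.components)
        assert sum(k for _, k in s.components) == s.total_count
        # each labeled region matches exactly one stored pixel set
        stored = {tuple(sorted(map(tuple, px))): k for px, k in s.components}
        for c in comps:
            key = tuple(sorted(map(tuple, c.pixel_set)))
            assert key in stored

    def test_singleton_share_matches_mix_within_ci(self):
        """Over many draws the 1-colony share converges to the configured mix."""
        cfg = small_cfg(seed=77)
        labels = synthetic.sample_crop_labels(1000, cfg)
        nonempty = labels[labels > 0]
        p_single = cfg.count_distribution[0]
        lo, hi = stats.binom.interval(0.99, len(nonempty), p_single)
        assert lo <= (nonempty == 1).sum() <= hi


class TestCropDataset:
    def test_reproducible_label_sequence(self, crop_cfg):
        a = synthetic.generate_crop_dataset(10, crop_cfg)
        b = synthetic.generate_crop_dataset(10, crop_cfg)
        assert [l for _, l in a] == [l for _, l in b]
        assert all(np.array_equal(x, y) for (x, _), (y, _) in zip(a, b))

    def test_labels_capped_at_nine(self):
        # a component rendered with more than nine colonies is labelled 9
        cfg = small_cfg(count_distribution=[0.0] * 8 + [1.0],
                        empty_crop_rate=0.0)
        rng = np.random.default_rng(0)
        assert synthetic._draw_label(rng, cfg) == 9
        blob = synthetic.render_colony_cluster(
            11, (64, 64), small_cfg(image_size=(160, 160)), rng
        )
        assert blob.k == 11  # renderable, but the label saturates at 9

    def test_empty_rate_matches_configuration(self):
        labels = synthetic.sample_crop_labels(
            10_000, small_cfg(seed=4)
        )
        assert abs((labels == 0).mean() - 0.109) < 0.01

    def test_crops_standardized_and_scaled(self, crop_cfg):
        data = synthetic.generate_crop_dataset(12, crop_cfg)
        for crop, label in data:
            assert crop.shape == (128, 128, 3)
            assert 0.0 <= crop.min() and crop.max() <= 1.0
            assert 0 <= label <= 9

    def test_unknown_rotation_mode_rejected(self, crop_cfg):
        with pytest.raises(ValueError, match="rotation"):
            synthetic.generate_crop_dataset(2, crop_cfg, rotation="diagonal")
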