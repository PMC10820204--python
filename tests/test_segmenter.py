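"""Segmentation network contracts: shapes, determinism, loss, training."""

import numpy as np
import pytest

from colonycount._nn.autograd import Tensor
from colonycount.segmenter import (
    SegmenterConfig,
    TrainConfig,
    build_segmenter,
    hflip_pair,
    load_checkpoint,
    predict_probability_map,
    save_checkpoint,
    train_segmenter,
    weighted_bce_loss,
)

RNG = np.random.default_rng(7)


@pytest.fixture(scope="module")
def small_model():
    return build_segmenter(SegmenterConfig(scale="small", seed=3))


class TestBuildAndPredict:
    def test_output_is_valid_probability_map(self, small_model):
        img = RNG.random((64, 64, 3))
        p = predict_probability_map(small_model, img)
        assert p.shape == (64, 64)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_constant_input_valid_map(self, small_model):
        p = predict_probability_map(small_model, np.full((64, 64, 3), 0.5))
        assert np.isfinite(p).all()
        assert ((0 <= p) & (p <= 1)).all()

    def test_same_seed_same_input_identical_output(self):
        cfg = SegmenterConfig(scale="small", seed=11)
        img = RNG.random((64, 64, 3))
        p1 = predict_probability_map(build_segmenter(cfg), img)
        p2 = predict_probability_map(build_segmenter(cfg), img)
        assert np.array_equal(p1, p2)

    def test_different_seed_different_parameters(self):
        a = build_segmenter(SegmenterConfig(scale="small", seed=0))
        b = build_segmenter(SegmenterConfig(scale="small", seed=1))
        pa = np.concatenate([p.data.ravel() for p in a.parameters()])
        pb = np.concatenate([p.data.ravel() for p in b.parameters()])
        assert not np.array_equal(pa, pb)

    def test_indivisible_input_raises_with_padding_hint(self, small_model):
        x = np.zeros((1, 3, 66, 64), dtype=np.float32)
        with pytest.raises(ValueError, match="pad"):
            small_model.forward(x)

    def test_offsize_image_resized_through_model(self, small_model):
        img = RNG.random((100, 90, 3))
        p = predict_probability_map(small_model, img)
        assert p.shape == (100, 90)

    def test_full_scale_topology_constructs_and_runs(self):
        cfg = SegmenterConfig(scale="full", base_channels=8, input_size=(64, 64))
        model = build_segmenter(cfg)
        assert len(cfg.stage_depths) == 6
        p = predict_probability_map(model, RNG.random((64, 64, 3)))
        assert p.shape == (64, 64)


class TestWeightedBceLoss:
    def test_perfect_logits_near_zero_loss(self):
        target = (RNG.random((1, 1, 8, 8)) > 0.5).astype(np.float32)
        logits = Tensor((target * 2 - 1) * 50.0)
        assert float(weighted_bce_loss(logits, target, 8.0).data) < 1e-6

    def test_matches_hand_computed_bce_at_weight_one(self):
        z = np.array([[[[0.5, -0.5], [1.0, 0.0]]]], dtype=np.float32)
        t = np.array([[[[1.0, 0.0], [0.0, 1.0]]]], dtype=np.float32)
        expected = np.mean(
            [
                -np.log(1 / (1 + np.exp(-0.5))),
                -np.log(1 - 1 / (1 + np.exp(0.5))),
                -np.log(1 - 1 / (1 + np.exp(-1.0))),
                -np.log(0.5),
            ]
        )
        got = float(weighted_bce_loss(Tensor(z), t, 1.0).data)
        assert got == pytest.approx(expected, rel=1e-5)

    def test_all_foreground_loss_linear_in_weight(self):
        z = Tensor(RNG.standard_normal((1, 1, 4, 4)).astype(np.float32))
        t = np.ones((1, 1, 4, 4), dtype=np.float32)
        l1 = float(weighted_bce_loss(z, t, 1.0).data)
        l8 = float(weighted_bce_loss(z, t, 8.0).data)
        assert l8 == pytest.approx(8 * l1, rel=1e-5)

    def test_sums_over_multiple_outputs(self):
        z = Tensor(np.zeros((1, 1, 2, 2), dtype=np.float32))
        t = np.ones((1, 1, 2, 2), dtype=np.float32)
        single = float(weighted_bce_loss(z, t, 1.0).data)
        triple = float(weighted_bce_loss([z, z, z], t, 1.0).data)
        assert triple == pytest.approx(3 * single, rel=1e-6)

    def test_nonbinary_target_rejected(self):
        z = Tensor(np.zeros((1, 1, 2, 2), dtype=np.float32))
        with pytest.raises(ValueError, match="binary"):
            weighted_bce_loss(z, np.full((1, 1, 2, 2), 0.3))


def test_hflip_mirrors_image_and_mask_together():
    x = RNG.random((1, 3, 4, 6)).astype(np.float32)
    m = (RNG.random((1, 1, 4, 6)) > 0.5).astype(np.float32)
    fx, fm = hflip_pair(x, m)
    assert np.array_equal(fx, x[:, :, :, ::-1])
    assert np.array_equal(fm, m[:, :, :, ::-1])
    fx2, fm2 = hflip_pair(fx, fm)
    assert np.array_equal(fx2, x) and np.array_equal(fm2, m)


class TestTraining:
    def test_history_has_one_entry_per_epoch(self, plate_corpus):
        ds = [(c["unit"], c["sample"].edge_mask) for c in plate_corpus[:3]]
        model = build_segmenter(SegmenterConfig(scale="small", seed=5))
        _m, history = train_segmenter(
            model, ds[:2], TrainConfig(epochs=1, seed=0), val_dataset=ds[2:]
        )
        assert len(history) == 1
        assert {"epoch", "train_loss", "val_f_score", "val_mae"} <= set(history[0])

    def test_empty_dataset_rejected(self):
        model = build_segmenter(SegmenterConfig(scale="small", seed=5))
        with pytest.raises(ValueError):
            train_segmenter(model, [], TrainConfig(epochs=1))

    def test_single_image_memorization(self, plate_corpus):
        """The small model must overfit one plate to F > 0.99 within 200 epochs.

        Unweighted loss: the 8:1 foreground weighting intentionally trades
        precision for recall, which caps the precision-weighted F-score;
        this test probes capacity, not the class-balance policy.
        """
        unit = plate_corpus[0]["unit"]
        mask = plate_corpus[0]["sample"].edge_mask
        model = build_segmenter(SegmenterConfig(scale="small", seed=0))
        _m, history = train_segmenter(
            model,
            [(unit, mask)],
            TrainConfig(epochs=200, fg_weight=1.0, seed=0),
            val_dataset=[(unit, mask)],
        )
        assert max(h["val_f_score"] for h in history) > 0.99


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path):
        model = build_segmenter(SegmenterConfig(scale="small", seed=9))
        img = RNG.random((64, 64, 3))
        before = predict_probability_map(model, img)
        path = tmp_path / "seg.npz"
        save_checkpoint(model, path, extra={"note": "test"})
        restored = load_checkpoint(path)
        assert np.array_equal(predict_probability_map(restored, img), before)

    def test_wrong_kind_rejected(self, tmp_path):
        from colonycount.counter import CounterConfig, build_counter, save_counter

        path = tmp_path / "counter.npz"
        save_counter(build_counter(CounterConfig()), path)
        with pytest.raises(ValueError, match="segmenter"):
            load_checkpoint(path)
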