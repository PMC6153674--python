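"""Backbone contracts: resizing, pooling heads (vs brute-force oracles),
model construction, and training behaviour."""

import warnings

import numpy as np
import pytest

import fetseg as fs
from fetseg.backbone import (
    BackboneConfig,
    TrainConfig,
    BinaryClassifier,
    build_model,
    pool_avg_full,
    pool_max_of_avg,
    resize_input,
    train,
)
from fetseg.data import AnnotatedDataset, random_rotation
from fetseg.types import Phase
from tests.test_data import make_frames


def brute_force_avg(fm):
    c = fm.shape[0]
    out = np.zeros(c)
    for ch in range(c):
        out[ch] = fm[ch].sum() / fm[ch].size
    return out


def brute_force_max_of_avg(fm, k=7):
    c, h, w = fm.shape
    out = np.full(c, -np.inf)
    for ch in range(c):
        for i in range(0, h, k):
            for j in range(0, w, k):
                out[ch] = max(out[ch], fm[ch, i : i + k, j : j + k].mean())
    return out


class TestResize:
    def test_downsample_to_224(self):
        f = fs.render_frame(fs.SceneParams(image_size=448), Phase.OTHER, 0)
        out = resize_input(f, "downsample224")
        assert out.shape == (224, 224, 3)
        out448 = resize_input(f, "avg448")
        assert out448.shape == (448, 448, 3)

    def test_same_size_passthrough(self):
        f = fs.render_frame(fs.SceneParams(image_size=64), Phase.OTHER, 0)
        out = resize_input(f, "small_cnn")
        assert np.array_equal(out, f.pixels.astype(np.float32) / 255.0)

    def test_constant_image_stays_constant(self):
        img = np.full((128, 128, 3), 77, dtype=np.uint8)
        out = resize_input(img, "small_cnn")
        assert np.allclose(out, 77 / 255.0, atol=1e-6)

    def test_rejects_non_square(self):
        with pytest.raises(ValueError):
            resize_input(np.zeros((64, 32, 3), dtype=np.uint8), "small_cnn")


class TestPoolingOracles:
    def test_avg_constant_and_small(self):
        assert pool_avg_full(np.full((3, 4, 4), 2.5))[0] == pytest.approx(2.5)
        fm = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        assert pool_avg_full(fm)[0] == pytest.approx(2.5)

    def test_max_of_avg_constant_and_block(self):
        assert pool_max_of_avg(np.full((2, 14, 14), 3.0))[0] == pytest.approx(3.0)
        fm = np.zeros((1, 14, 14))
        fm[0, :7, :7] = 1.0  # one 7x7 block all ones
        assert pool_max_of_avg(fm)[0] == pytest.approx(1.0)

    def test_avg_matches_brute_force_on_random_maps(self, rng):
        for _ in range(100):
            fm = rng.standard_normal((3, 14, 14))
            assert np.allclose(pool_avg_full(fm), brute_force_avg(fm), atol=1e-6)

    def test_max_of_avg_matches_brute_force_on_random_maps(self, rng):
        for _ in range(100):
            fm = rng.standard_normal((4, 14, 14))
            assert np.allclose(
                pool_max_of_avg(fm), brute_force_max_of_avg(fm), atol=1e-6
            )

    def test_pool_shape_errors(self):
        with pytest.raises(ValueError):
            pool_avg_full(np.zeros((3, 4, 5)))
        with pytest.raises(ValueError):
            pool_max_of_avg(np.zeros((3, 12, 12)))  # not divisible by 7


class TestBuildModel:
    def test_scores_normalised(self, quick_model):
        f = fs.render_frame(fs.SceneParams(image_size=160), Phase.ABLATION, 5)
        s = quick_model.score_frame(f)
        assert s.score_positive + s.score_negative == pytest.approx(1.0, abs=1e-6)
        assert 0.0 <= s.score_positive <= 1.0

    def test_untrained_model_refuses_scoring(self):
        model = build_model(BackboneConfig("small_cnn"))
        f = fs.render_frame(fs.SceneParams(image_size=64), Phase.OTHER, 0)
        with pytest.raises(RuntimeError, match="untrained"):
            model.score_frame(f)

    def test_maxavg_head_reproduces_pooling_op(self, rng):
        model = build_model(BackboneConfig("maxavg448"))
        fm = rng.standard_normal((model.n_channels, 14, 14)).astype(np.float32)
        via_head = model.head.forward(fm[None])[0]
        assert np.allclose(via_head, pool_max_of_avg(fm), atol=1e-5)
        avg_model = build_model(BackboneConfig("avg448"))
        via_avg = avg_model.head.forward(fm[None])[0]
        assert np.allclose(via_avg, pool_avg_full(fm), atol=1e-5)

    def test_feature_geometry_is_stride_32(self):
        model = build_model(BackboneConfig("downsample224"))
        x = np.zeros((1, 224, 224, 3), dtype=np.float32)
        fm = model.features.forward(x.transpose(0, 3, 1, 2))
        assert fm.shape[2:] == (7, 7)
        model448 = build_model(BackboneConfig("avg448"))
        fm = model448.features.forward(np.zeros((1, 3, 448, 448), dtype=np.float32))
        assert fm.shape[2:] == (14, 14)

    def test_two_outputs_enforced(self):
        with pytest.raises(ValueError):
            BackboneConfig("small_cnn", n_outputs=1000)
        with pytest.raises(ValueError):
            BackboneConfig("resnet152")

    def test_pretrained_weights_unavailable_is_explicit(self):
        with pytest.raises(RuntimeError, match="pretrained"):
            build_model(BackboneConfig("downsample224", pretrained=True))

    def test_save_load_round_trip(self, quick_model, tmp_path):
        path = tmp_path / "model.npz"
        quick_model.save(path)
        clone = BinaryClassifier.load(path)
        f = fs.render_frame(fs.SceneParams(image_size=160), Phase.TARGETING, 9)
        assert clone.score_frame(f) == quick_model.score_frame(f)


class TestTraining:
    def test_loss_decreases_on_separable_task(self):
        ds = AnnotatedDataset(make_frames(40, 40, seed=3))
        model = build_model(BackboneConfig("small_cnn"), init_seed=1)
        trace = train(model, ds, TrainConfig(iterations=200, seed=1))
        assert len(trace) == 200
        assert trace["loss"].iloc[-20:].mean() < trace["loss"].iloc[:20].mean()
        assert model.trained

    def test_single_class_rejected(self):
        ds = AnnotatedDataset(make_frames(10, 0))
        model = build_model(BackboneConfig("small_cnn"))
        with pytest.raises(ValueError, match="single class"):
            train(model, ds, TrainConfig(iterations=10))

    def test_empty_rejected(self):
        model = build_model(BackboneConfig("small_cnn"))
        with pytest.raises(ValueError, match="empty"):
            train(model, AnnotatedDataset([]), TrainConfig(iterations=10))

    def test_imbalance_warns(self):
        ds = AnnotatedDataset(make_frames(4, 40))
        model = build_model(BackboneConfig("small_cnn"))
        with pytest.warns(UserWarning, match="imbalanced"):
            train(model, ds, TrainConfig(iterations=5))

    def test_paper_scale_profile_preserved(self):
        assert fs.PAPER_TRAIN.iterations == 30000
        assert fs.PAPER_TRAIN.learning_rate == pytest.approx(1e-5)
        assert fs.PAPER_TRAIN.batch_size == 4

    def test_rotation_robustness_after_augmented_training(self, quick_model, study_ds):
        """Training with random rotations should make predictions stable
        under a 90-degree rotation for >= 90% of held-out frames."""
        held_out = study_ds.subset(["proc_04"]).frames[:40]
        stable = 0
        for f in held_out:
            s0 = quick_model.score_frame(f).score_positive >= 0.5
            s90 = quick_model.score_frame(random_rotation(f, angle=90.0)).score_positive >= 0.5
            stable += s0 == s90
        assert stable >= 0.9 * len(held_out)
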