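import numpy as np
import pandas as pd
import pytest

from embryostage.nn import (
    AugmentationPolicy,
    ModelConfig,
    TrainConfig,
    augment,
    build_model,
    combined_loss,
    exclude_transition_frames,
    load_checkpoint,
    make_blob_dataset,
    predict_probabilities,
    preprocess_image,
    save_checkpoint,
    train,
)
from embryostage.nn import autograd as ag
from embryostage.nn.layers import Conv2d, LayerNorm, Linear, TransformerEncoderLayer
from embryostage.nn.models import FusedStageClassifier


def finite_difference_check(build_loss, params, rng, eps=1e-6, n_checks=4):
    loss = build_loss()
    for p in params:
        p.grad = None
    loss.backward()
    for p in params:
        flat = p.data.ravel()
        grad = p.grad.ravel()
        for i in rng.choice(flat.size, size=min(n_checks, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            up = float(build_loss().data)
            flat[i] = orig - eps
            down = float(build_loss().data)
            flat[i] = orig
            numeric = (up - down) / (2 * eps)
            assert np.isclose(numeric, grad[i], rtol=1e-4, atol=1e-6)


class TestAutograd:
    def test_conv2d_gradients(self, rng):
        conv = Conv2d(2, 3, 3, rng, stride=2, padding=1)
        x = ag.Tensor(rng.normal(size=(2, 2, 8, 8)), requires_grad=True)
        targets = np.array([1, 2])

        def loss():
            return ag.cross_entropy(ag.mean(conv(x), axis=(2, 3)), targets)

        finite_difference_check(loss, [conv.weight, conv.bias, x], rng)

    def test_encoder_layer_gradients(self, rng):
        enc = TransformerEncoderLayer(8, 2, rng)
        head = Linear(8, 3, rng)
        x = ag.Tensor(rng.normal(size=(3, 2, 8)), requires_grad=True)
        targets = np.array([0, 1, 2])

        def loss():
            return ag.cross_entropy(head(ag.take_token(enc(x), 0)), targets)

        finite_difference_check(loss, [x] + enc.parameters(), rng, n_checks=2)

    def test_layer_norm_gradients(self, rng):
        ln = LayerNorm(6)
        head = Linear(6, 3, rng)
        x = ag.Tensor(rng.normal(size=(4, 6)), requires_grad=True)

        def loss():
            return ag.cross_entropy(head(ln(x)), np.array([0, 1, 2, 0]))

        finite_difference_check(loss, [x, ln.gamma, ln.beta], rng)

    def test_weighted_cross_entropy_gradients(self, rng):
        lin = Linear(4, 3, rng)
        x = ag.Tensor(rng.normal(size=(5, 4)))
        w = np.array([0.5, 2.0, 1.0])

        def loss():
            return ag.cross_entropy(lin(x), np.array([0, 1, 2, 0, 1]), w)

        finite_difference_check(loss, [lin.weight, lin.bias], rng)

    def test_backward_requires_scalar(self):
        t = ag.Tensor(np.zeros(3), requires_grad=True)
        with pytest.raises(ValueError):
            t.backward()


class TestPreprocess:
    def test_output_shape(self):
        img = np.zeros((50, 40), dtype=np.uint8)
        out = preprocess_image(img, 64)
        assert out.shape == (3, 64, 64)

    def test_constant_gray_closed_form_without_clahe(self):
        from embryostage.nn.preprocess import IMAGENET_MEAN, IMAGENET_STD

        img = np.full((32, 32), 128, dtype=np.uint8)
        out = preprocess_image(img, 32, clahe=False)
        v = 128 / 255
        for k in range(3):
            expected = (v - IMAGENET_MEAN[k]) / IMAGENET_STD[k]
            assert np.allclose(out[k], expected)

    def test_clahe_raises_contrast_of_gradient(self):
        # low-contrast horizontal ramp
        ramp = np.tile(np.linspace(100, 140, 64), (64, 1)).astype(np.uint8)
        with_clahe = preprocess_image(ramp, 64, clahe=True)
        without = preprocess_image(ramp, 64, clahe=False)
        assert with_clahe[0].std() > without[0].std()

    def test_multichannel_rejected(self):
        with pytest.raises(ValueError, match="single-channel"):
            preprocess_image(np.zeros((8, 8, 3)), 32)

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, (40, 40)).astype(np.uint8)
        assert np.array_equal(preprocess_image(img, 32), preprocess_image(img, 32))


class TestAugment:
    def test_zero_probabilities_identity(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, (24, 24)).astype(np.uint8)
        policy = AugmentationPolicy(p_rotate_shift=0, p_flip=0, p_noise_blur=0)
        assert np.allclose(augment(img, policy, seed=5), img)

    def test_flip_is_involution(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, (24, 24)).astype(np.uint8)
        policy = AugmentationPolicy(p_rotate_shift=0, p_flip=1.0, p_noise_blur=0)
        once = augment(img, policy, seed=3)
        twice = augment(once, policy, seed=3)
        assert np.allclose(twice, img)

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 255, (24, 24)).astype(np.uint8)
        assert np.allclose(augment(img, seed=7), augment(img, seed=7))

    def test_flip_frequency_within_3_sigma(self):
        img = np.arange(64, dtype=np.uint8).reshape(8, 8)
        policy = AugmentationPolicy(p_rotate_shift=0, p_flip=0.5, p_noise_blur=0)
        n = 2000
        flips = sum(
            not np.allclose(augment(img, policy, seed=s), img) for s in range(n)
        )
        sigma = np.sqrt(0.25 / n)
        assert abs(flips / n - 0.5) < 3 * sigma

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            AugmentationPolicy(p_flip=1.5)


class TestModels:
    def test_image_only_single_logit_set(self):
        model = build_model(ModelConfig(num_classes=5, image_size=32), seed=0)
        x = np.zeros((2, 3, 32, 32))
        logits = model(x)
        assert logits.shape == (2, 5)

    def test_fused_two_logit_sets(self):
        cfg = ModelConfig(num_classes=5, image_size=32, fused=True, fusion_hidden=32)
        model = build_model(cfg, seed=0)
        x = np.zeros((2, 3, 32, 32))
        t = np.zeros((2, 84))
        t[:, 3] = 1
        l1, l2 = model(x, t)
        assert l1.shape == (2, 5) and l2.shape == (2, 5)

    def test_gradient_reaches_backbone_from_each_head(self, rng):
        cfg = ModelConfig(num_classes=5, image_size=32, fused=True, fusion_hidden=32)
        model = build_model(cfg, seed=0)
        x = rng.normal(size=(2, 3, 32, 32))
        t = np.zeros((2, 84))
        t[:, 3] = 1
        targets = np.array([0, 1])
        for head in (0, 1):
            model.zero_grad()
            logits = model(x, t)[head]
            ag.cross_entropy(logits, targets).backward()
            grads = [p.grad for p in model.backbone.parameters()]
            assert all(g is not None and np.abs(g).sum() > 0 for g in grads)

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            ModelConfig(backbone="resnet")
        with pytest.raises(ValueError):
            ModelConfig(num_classes=1)
        with pytest.raises(ValueError):
            ModelConfig(fused=True, fusion_hidden=30, fusion_heads=4)

    def test_reference_backbone_buildable(self):
        model = build_model(ModelConfig(backbone="reference", image_size=64), seed=0)
        logits = model(np.zeros((1, 3, 64, 64)))
        assert logits.shape == (1, 17)


class TestCombinedLoss:
    def test_uniform_logits_twice_log_k(self):
        k = 5
        logits = ag.Tensor(np.zeros((3, k)))
        loss = combined_loss(logits, ag.Tensor(np.zeros((3, k))), np.array([0, 1, 2]))
        assert float(loss.data) == pytest.approx(2 * np.log(k))

    def test_identical_heads_double_single_loss(self, rng):
        logits = ag.Tensor(rng.normal(size=(4, 6)))
        targets = np.array([0, 1, 2, 3])
        single = float(ag.cross_entropy(logits, targets).data)
        double = float(combined_loss(logits, logits, targets).data)
        assert double == pytest.approx(2 * single)

    def test_unit_weights_match_unweighted(self, rng):
        l1 = ag.Tensor(rng.normal(size=(4, 6)))
        l2 = ag.Tensor(rng.normal(size=(4, 6)))
        targets = np.array([0, 1, 2, 3])
        a = float(combined_loss(l1, l2, targets).data)
        b = float(combined_loss(l1, l2, targets, np.ones(6)).data)
        assert a == pytest.approx(b)

    def test_near_perfect_logits_near_zero_loss(self):
        logits = np.full((2, 4), -50.0)
        logits[0, 1] = logits[1, 2] = 50.0
        loss = combined_loss(ag.Tensor(logits), ag.Tensor(logits), np.array([1, 2]))
        assert float(loss.data) < 1e-6

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            combined_loss(ag.Tensor(np.zeros((2, 3))), ag.Tensor(np.zeros((2, 4))), np.array([0, 0]))


class TestExcludeTransitionFrames:
    @staticmethod
    def annotations(labels, video="v"):
        return pd.DataFrame(
            {
                "video_id": [video] * len(labels),
                "frame_index": range(len(labels)),
                "time_minutes": [20.0 * i for i in range(len(labels))],
                "label": labels,
            }
        )

    def test_margin_two_drops_four_frames(self):
        ann = self.annotations(["t2"] * 5 + ["t3"] * 5)
        out = exclude_transition_frames(ann, margin=2)
        assert len(out) == 6
        assert out["frame_index"].tolist() == [0, 1, 2, 7, 8, 9]

    def test_margin_zero_identity(self):
        ann = self.annotations(["t2"] * 3 + ["t3"] * 3)
        assert len(exclude_transition_frames(ann, margin=0)) == 6

    def test_constant_video_untouched(self):
        ann = self.annotations(["t4"] * 8)
        assert len(exclude_transition_frames(ann)) == 8

    def test_multiple_videos_independent(self):
        ann = pd.concat(
            [
                self.annotations(["t2"] * 5 + ["t3"] * 5, video="a"),
                self.annotations(["t4"] * 6, video="b"),
            ],
            ignore_index=True,
        )
        out = exclude_transition_frames(ann)
        assert len(out[out.video_id == "a"]) == 6
        assert len(out[out.video_id == "b"]) == 6


@pytest.fixture(scope="module")
def tiny_dataset():
    return make_blob_dataset(videos_per_class=10, frames_per_video=4, seed=0)


class TestTraining:
    def test_zero_epochs_returns_initial_model(self, tiny_dataset):
        cfg = ModelConfig(num_classes=5, image_size=32)
        model, history = train(tiny_dataset, cfg, TrainConfig(epochs=0, seed=0))
        reference = build_model(cfg, seed=0)
        assert history.empty
        for a, b in zip(model.state_arrays(), reference.state_arrays()):
            assert np.array_equal(a, b)

    def test_loss_decreases_on_toy_task(self, tiny_dataset):
        _, history = train(
            tiny_dataset,
            ModelConfig(num_classes=5, image_size=32),
            TrainConfig(epochs=6, seed=0, batch_size=8),
        )
        assert history["train_loss"].iloc[5] < history["train_loss"].iloc[0]

    def test_lr_never_increases(self, tiny_dataset):
        _, history = train(
            tiny_dataset,
            ModelConfig(num_classes=5, image_size=32),
            TrainConfig(epochs=6, seed=0, batch_size=8),
        )
        assert (np.diff(history["lr"]) <= 1e-12).all()

    def test_class_count_mismatch(self, tiny_dataset):
        with pytest.raises(ValueError, match="classes"):
            train(tiny_dataset, ModelConfig(num_classes=17, image_size=32))

    def test_checkpoint_round_trip(self, tiny_dataset, tmp_path):
        cfg = ModelConfig(num_classes=5, image_size=32)
        model, _ = train(tiny_dataset, cfg, TrainConfig(epochs=1, seed=0))
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        probs_a = predict_probabilities(model, tiny_dataset.subset(np.arange(4)))
        probs_b = predict_probabilities(restored, tiny_dataset.subset(np.arange(4)))
        assert np.allclose(probs_a, probs_b)
        assert probs_a.shape == (4, 5)
        assert np.allclose(probs_a.sum(axis=1), 1.0)
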