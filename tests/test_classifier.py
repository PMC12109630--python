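"""GlandNet topology, augmentation, training and prediction contracts."""

import numpy as np
import pytest

from glandcell.classifier import (
    AugmentPolicy,
    GlandNet,
    ModelSpec,
    TrainConfig,
    augment,
    build_model,
    classify,
    predict_proba,
    train,
)


def _toy_data(n_per_class=30, size=32, seed=0):
    """Linearly separable patches: bright class vs dark class."""
    rng = np.random.default_rng(seed)
    bright = rng.normal(190, 10, size=(n_per_class, size, size)).clip(0, 255)
    dark = rng.normal(70, 10, size=(n_per_class, size, size)).clip(0, 255)
    x = np.concatenate([bright, dark]).astype(np.float32)
    y = np.array([1] * n_per_class + [0] * n_per_class)
    return x, y


def _tiny_spec(size=32):
    return ModelSpec(
        width_scale=1 / 16, input_size=size, allow_any_input_size=True, noise_sigma=0.1
    )


class TestTopology:
    def test_full_size_spec_enumerates_16_weight_and_24_layers(self):
        spec = ModelSpec()
        assert spec.n_conv_layers == 13
        assert spec.n_weight_layers == 16
        assert spec.n_layers == 24

    def test_built_model_layer_sequence(self):
        model = build_model(_tiny_spec())
        kinds = model.layer_kinds
        assert kinds.count("conv") == 13
        assert kinds.count("maxpool") == 5
        assert kinds.count("gap") == 1
        assert kinds.count("noise") == 2
        assert kinds.count("dense") == 3
        assert len(kinds) == 24
        assert model.n_weight_layers == 16
        # the head is GAP -> dense -> noise -> dense -> noise -> dense
        assert kinds[-6:] == ["gap", "dense", "noise", "dense", "noise", "dense"]
        # output layer has exactly two units
        assert model.net.layers[-1].d_out == 2

    def test_width_scale_shrinks_conv_parameters_quadratically(self):
        full = build_model(
            ModelSpec(width_scale=1, input_size=64, allow_any_input_size=True)
        )
        eighth = build_model(
            ModelSpec(width_scale=1 / 8, input_size=64, allow_any_input_size=True)
        )
        assert full.layer_kinds == eighth.layer_kinds
        ratio = full.conv_param_count() / eighth.conv_param_count()
        assert ratio == pytest.approx(64, rel=0.15)

    def test_unusual_input_size_needs_override(self):
        with pytest.raises(ValueError):
            ModelSpec(input_size=64).validate()
        ModelSpec(input_size=64, allow_any_input_size=True).validate()
        with pytest.raises(ValueError):
            ModelSpec(input_size=48, allow_any_input_size=True).validate()  # not /32

    def test_pretrained_init_requires_weight_source(self):
        with pytest.raises(ValueError, match="pretrained"):
            build_model(ModelSpec(pretrained_init=True, input_size=128))

    def test_eval_mode_is_deterministic(self):
        model = build_model(_tiny_spec(), seed=3)
        x = np.random.default_rng(0).uniform(0, 255, size=(2, 32, 32, 1)).astype(np.float32)
        p1 = model.predict_proba_array(x)
        p2 = model.predict_proba_array(x)
        np.testing.assert_array_equal(p1, p2)


class TestAugment:
    def test_identity_policy_is_exact_passthrough(self, rng):
        patch = rng.uniform(0, 255, size=(32, 32)).astype(np.float32)
        out = augment(patch, AugmentPolicy.identity(), rng)
        np.testing.assert_array_equal(out, patch)

    def test_hflip_is_an_involution(self, rng):
        policy = AugmentPolicy(hflip_prob=1.0, vflip_prob=0.0, rotation_degrees=0,
                               zoom_fraction=0, width_shift_fraction=0, height_shift_fraction=0)
        patch = rng.uniform(0, 255, size=(16, 16)).astype(np.float32)
        once = augment(patch, policy, np.random.default_rng(0))
        twice = augment(once, policy, np.random.default_rng(0))
        np.testing.assert_array_equal(twice, patch)
        assert not np.array_equal(once, patch)

    def test_fixed_seed_reproduces_output(self, rng):
        patch = rng.uniform(0, 255, size=(32, 32)).astype(np.float32)
        policy = AugmentPolicy()  # full stochastic policy
        a = augment(patch, policy, np.random.default_rng(99))
        b = augment(patch, policy, np.random.default_rng(99))
        np.testing.assert_array_equal(a, b)
        assert a.shape == patch.shape

    def test_invalid_policy_rejected(self):
        with pytest.raises(ValueError):
            AugmentPolicy(hflip_prob=1.5)
        with pytest.raises(ValueError):
            AugmentPolicy(zoom_fraction=1.0)


class TestTraining:
    def test_separable_toy_data_reaches_95_percent(self):
        x, y = _toy_data()
        model = build_model(_tiny_spec(), seed=0)
        cfg = TrainConfig(learning_rate=1e-3, batch_size=16, epochs=10, augment=None, seed=0)
        history = train(model, (x, y), cfg)
        assert len(history["loss"]) == 10
        assert history["accuracy"][-1] >= 0.95

    def test_history_reproducible_under_fixed_seeds(self):
        x, y = _toy_data(n_per_class=10)
        cfg = TrainConfig(learning_rate=1e-3, batch_size=8, epochs=3, augment=None, seed=7)
        h1 = train(build_model(_tiny_spec(), seed=7), (x, y), cfg)
        h2 = train(build_model(_tiny_spec(), seed=7), (x, y), cfg)
        assert h1 == h2

    def test_single_class_data_rejected(self):
        x, _ = _toy_data(n_per_class=8)
        model = build_model(_tiny_spec(), seed=0)
        with pytest.raises(ValueError, match="both classes"):
            train(model, (x, np.ones(len(x), dtype=int)), TrainConfig(epochs=1))

    def test_validation_history_and_best_val_selection(self):
        x, y = _toy_data(n_per_class=12)
        cfg = TrainConfig(
            learning_rate=1e-3, batch_size=8, epochs=4, augment=None,
            epoch_selection="best_val", seed=1,
        )
        model = build_model(_tiny_spec(), seed=1)
        history = train(model, (x, y), cfg, val_data=(x, y))
        assert len(history["val_accuracy"]) == 4

    def test_checkpoint_round_trip(self, tmp_path):
        x, y = _toy_data(n_per_class=8)
        model = build_model(_tiny_spec(), seed=2)
        train(model, (x, y), TrainConfig(learning_rate=1e-3, batch_size=8, epochs=2, augment=None, seed=2))
        path = model.save(tmp_path / "ckpt.npz")
        clone = GlandNet.load(path)
        np.testing.assert_array_equal(
            model.predict_proba_array(x), clone.predict_proba_array(x)
        )
        assert (tmp_path / "ckpt.npz.topology.json").exists()


class TestPrediction:
    def test_probabilities_aligned_and_stored(self, scene_container):
        model = build_model(
            ModelSpec(width_scale=1 / 16, input_size=64, allow_any_input_size=True), seed=0
        )
        probs = predict_proba(model, scene_container)
        assert len(probs) == len(scene_container.records)
        assert np.all((probs >= 0) & (probs <= 1))
        for rec, p in zip(scene_container.records, probs):
            assert rec.prediction == pytest.approx(p)

    def test_duplicated_patch_gets_identical_probability(self, scene_container):
        model = build_model(
            ModelSpec(width_scale=1 / 16, input_size=64, allow_any_input_size=True), seed=0
        )
        probs = predict_proba(model, scene_container)
        x = scene_container.records[0].pixels[..., None].astype(np.float32)
        pair = model.predict_proba_array(np.stack([x, x]))
        assert pair[0] == pair[1]

    def test_patch_size_mismatch_rejected(self, scene_container):
        model = build_model(
            ModelSpec(width_scale=1 / 16, input_size=32, allow_any_input_size=True), seed=0
        )
        with pytest.raises(ValueError, match="patch"):
            predict_proba(model, scene_container)


class TestClassify:
    @pytest.mark.parametrize(
        "p, tau, expected",
        [
            (0.51, 0.5, "gland"),
            (0.5, 0.5, "stroma"),  # strictly-greater rule
            (0.49, 0.5, "stroma"),
            (0.0, 0.5, "stroma"),
            (1.0, 0.5, "gland"),
        ],
    )
    def test_threshold_rule(self, p, tau, expected):
        assert classify(p, tau) == expected

    def test_decision_flips_exactly_once_over_threshold_sweep(self, rng):
        probs = rng.uniform(size=20)
        taus = np.linspace(0, 1, 101)
        for p in probs:
            decisions = [classify(float(p), float(t)) == "gland" for t in taus]
            flips = sum(a != b for a, b in zip(decisions, decisions[1:]))
            assert flips == 1 or (flips == 0 and not decisions[-1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify(1.2, 0.5)
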