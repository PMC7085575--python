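import numpy as np
import pytest

from dwigrade._nn import ConvNet, weighted_softmax_loss
from dwigrade.graders import (ADC_DESIGN, ADC_TRAINING, CHB_DESIGN,
                              CHB_TRAINING, SequencerDesign, TrainingConfig,
                              load_model, predict_proba, save_model, train_dr,
                              train_zone_x, weighted_cross_entropy)


class TestWeightedCrossEntropy:
    def test_perfect_prediction_near_zero(self):
        assert weighted_cross_entropy([1], [1 - 1e-9], (1, 1)) < 1e-6

    def test_uninformative_prediction_is_ln2(self):
        assert weighted_cross_entropy([1], [0.5], (1, 1)) == \
            pytest.approx(np.log(2.0), rel=1e-12)

    def test_positive_weight_scales_term_exactly(self):
        base = weighted_cross_entropy([1], [0.5], (1, 1))
        assert weighted_cross_entropy([1], [0.5], (1, 150)) == \
            pytest.approx(150.0 * base, rel=1e-12)
        # identical errors on opposite classes differ by exactly the ratio
        neg = weighted_cross_entropy([0], [0.5], (1, 150))
        pos = weighted_cross_entropy([1], [0.5], (1, 150))
        assert pos == pytest.approx(150.0 * neg, rel=1e-12)

    def test_matches_term_by_term_summation_oracle(self):
        rng = np.random.default_rng(23)
        y = (rng.random(50) < 0.3).astype(int)
        p = rng.uniform(0.01, 0.99, 50)
        total = 0.0
        for yi, pi in zip(y, p):
            w = 150.0 if yi == 1 else 1.0
            total += w * -(yi * np.log(pi) + (1 - yi) * np.log(1 - pi))
        assert weighted_cross_entropy(y, p, (1, 150)) == \
            pytest.approx(total / 50, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_cross_entropy([0, 1], [0.5], (1, 1))


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(0)
    X0 = rng.normal(0.0, 0.3, (30, 2))
    X1 = rng.normal(3.0, 0.3, (30, 2))
    return np.vstack([X0, X1]), np.array([0] * 30 + [1] * 30)


class TestZoneXGraders:
    def test_lr_separable_perfect_at_half(self, separable):
        X, y = separable
        model = train_zone_x(X, y, "lr")
        pred = predict_proba(model, X) >= 0.5
        assert np.array_equal(pred.astype(int), y)

    @pytest.mark.parametrize("kind", ["lr", "rf", "svm"])
    def test_deterministic_given_seed(self, separable, kind):
        X, y = separable
        p1 = predict_proba(train_zone_x(X, y, kind, seed=3), X)
        p2 = predict_proba(train_zone_x(X, y, kind, seed=3), X)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_zone_x(np.ones((5, 2)), [0] * 5, "lr")

    def test_unknown_kind_rejected(self, separable):
        X, y = separable
        with pytest.raises(ValueError):
            train_zone_x(X, y, "mlp")

    def test_lr_probabilities_match_logistic_closed_form(self, separable):
        X, y = separable
        model = train_zone_x(X, y, "lr")
        scaler = model.estimator.named_steps["scale"]
        clf = model.estimator.named_steps["clf"]
        Xs = (X - scaler.mean_) / scaler.scale_
        z = Xs @ clf.coef_.ravel() + clf.intercept_[0]
        assert np.allclose(predict_proba(model, X), 1 / (1 + np.exp(-z)),
                           atol=1e-10)

    def test_probabilities_bounded(self, separable):
        X, y = separable
        for kind in ("lr", "rf", "svm"):
            p = predict_proba(train_zone_x(X, y, kind), X)
            assert len(p) == len(X)
            assert np.all((p >= 0) & (p <= 1))


class TestConvNet:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        net = ConvNet([("conv", 3), ("maxpool",), ("conv", 4)], rng)
        x = rng.standard_normal((5, 8, 8, 1))
        y = np.array([0, 1, 0, 1, 1])
        cache = []
        loss, dlog = weighted_softmax_loss(net.forward(x, cache), y, (1.0, 150.0))
        grads = net.backward(dlog, cache)
        eps, idx_rng = 1e-3, np.random.default_rng(1)
        for p, g in zip(net.parameters(), grads):
            for _ in range(3):
                idx = tuple(idx_rng.integers(0, s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                l1, _ = weighted_softmax_loss(net.forward(x), y, (1.0, 150.0))
                p[idx] = orig - eps
                l2, _ = weighted_softmax_loss(net.forward(x), y, (1.0, 150.0))
                p[idx] = orig
                num = (l1 - l2) / (2 * eps)
                # float32 forward passes limit finite-difference accuracy
                assert abs(num - g[idx]) <= 1e-2 * max(1.0, abs(num))

    def test_softmax_loss_agrees_with_probability_form(self):
        rng = np.random.default_rng(4)
        logits = rng.standard_normal((20, 2))
        y = (rng.random(20) < 0.4).astype(int)
        loss, _ = weighted_softmax_loss(logits, y, (1.0, 150.0))
        p1 = np.exp(logits[:, 1]) / np.exp(logits).sum(axis=1)
        assert loss == pytest.approx(weighted_cross_entropy(y, p1, (1, 150)),
                                     rel=1e-6)

    def test_design_constraints_validated(self):
        with pytest.raises(ValueError):
            SequencerDesign(layer_spec=(("maxpool",),))
        with pytest.raises(ValueError):
            SequencerDesign(layer_spec=(("dense", 4),))
        with pytest.raises(ValueError):
            TrainingConfig(batch_size=0)

    def test_adc_design_smaller_than_chb_design(self):
        assert ADC_DESIGN.n_parameters() < CHB_DESIGN.n_parameters()

    def test_modality_hyperparameter_defaults(self):
        assert (ADC_TRAINING.batch_size, ADC_TRAINING.learning_rate,
                ADC_TRAINING.patience) == (219, 2e-4, 50)
        assert (CHB_TRAINING.batch_size, CHB_TRAINING.learning_rate,
                CHB_TRAINING.patience) == (163, 2e-3, 16)
        assert ADC_TRAINING.class_weights == (1.0, 150.0)


@pytest.fixture(scope="module")
def toy_patches():
    """Separable 32x32 patch set: positives carry a bright center blob."""
    rng = np.random.default_rng(7)
    n = 160
    y = (rng.random(n) < 0.3).astype(int)
    X = rng.normal(0.4, 0.05, (n, 32, 32))
    X[y == 1, 10:22, 10:22] += 0.4
    pids = [f"P{i % 8}" for i in range(n)]
    return X, y, pids


TOY_CONFIG = TrainingConfig(batch_size=32, learning_rate=1e-3, patience=5,
                            max_epochs=12, seed=1)
TOY_DESIGN = SequencerDesign(layer_spec=(("conv", 4), ("maxpool",), ("conv", 8)))


class TestTrainDR:
    def test_single_class_refused(self, toy_patches):
        X, _, pids = toy_patches
        with pytest.raises(ValueError):
            train_dr(X, np.zeros(len(X), int), TOY_DESIGN, TOY_CONFIG,
                     patient_ids=pids)

    def test_no_validation_split_refused(self, toy_patches):
        X, y, _ = toy_patches
        with pytest.raises(ValueError):
            train_dr(X, y, TOY_DESIGN, TOY_CONFIG,
                     patient_ids=["P0"] * len(X))

    def test_bad_patch_shape_refused(self):
        with pytest.raises(ValueError):
            train_dr(np.ones((10, 16, 16)), [0, 1] * 5, TOY_DESIGN, TOY_CONFIG)

    def test_training_reproducible_and_loss_decreases(self, toy_patches):
        X, y, pids = toy_patches
        m1 = train_dr(X, y, TOY_DESIGN, TOY_CONFIG, patient_ids=pids)
        m2 = train_dr(X, y, TOY_DESIGN, TOY_CONFIG, patient_ids=pids)
        assert m1.history == m2.history
        p1, p2 = predict_proba(m1, X), predict_proba(m2, X)
        assert np.allclose(p1, p2, atol=1e-6)
        train_losses = [h[1] for h in m1.history]
        assert train_losses[-1] < train_losses[0]    # learning happened

    def test_predict_contracts(self, toy_patches):
        X, y, pids = toy_patches
        model = train_dr(X, y, TOY_DESIGN, TOY_CONFIG, patient_ids=pids)
        p = predict_proba(model, X[:6])
        assert p.shape == (6,)
        assert np.all((p >= 0) & (p <= 1))
        dup = predict_proba(model, np.stack([X[0], X[0]]))
        assert dup[0] == dup[1]
        from dwigrade.graders import GraderModel
        with pytest.raises(RuntimeError):
            predict_proba(GraderModel(kind="dr"), X[:1])

    def test_checkpoint_roundtrip(self, toy_patches, tmp_path):
        X, y, pids = toy_patches
        model = train_dr(X, y, TOY_DESIGN, TOY_CONFIG, patient_ids=pids)
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        assert np.allclose(predict_proba(loaded, X[:10]),
                           predict_proba(model, X[:10]), atol=1e-7)
        assert loaded.training.batch_size == TOY_CONFIG.batch_size
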