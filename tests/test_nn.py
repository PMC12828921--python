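"""Network: initialisation law, forward contracts, loss oracle, gradient
check, clipping, early stopping, training smoke."""

import copy

import numpy as np
import pytest

from strabplan import LossWeights, ModelConfig, MultiTaskNet, init_model, multitask_loss
from strabplan.nn import EarlyStopper, clip_gradients, count_params, _sigmoid


def small_config(**kw):
    base = dict(
        input_width=5, trunk_widths=(7, 6), dropout=0.0, seed=3, n_outputs=4,
        mask_regression=False,
    )
    base.update(kw)
    return ModelConfig(**base)


class TestInit:
    def test_deterministic_per_seed(self):
        a = init_model(small_config())
        b = init_model(small_config())
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])
        c = init_model(small_config(seed=4))
        assert any((a[k] != c[k]).any() for k in a if k.startswith("W"))

    def test_xavier_bound(self):
        params = init_model(ModelConfig(input_width=3, trunk_widths=(3,), seed=0))
        assert np.abs(params["W0"]).max() <= np.sqrt(6 / 6)  # fan_in = fan_out = 3

    def test_xavier_variance(self):
        """Empirical variance of Uniform(-b, b), b = sqrt(6/(fan_in+fan_out)),
        is 2/(fan_in+fan_out) within 5% at 10^5 samples."""
        rng = np.random.default_rng(0)
        fan_in, fan_out = 250, 400
        from strabplan.nn import xavier_uniform

        w = xavier_uniform(rng, fan_in, fan_out)  # 10^5 weights
        expected = 2.0 / (fan_in + fan_out)
        assert w.var() == pytest.approx(expected, rel=0.05)
        assert w.size == 100_000

    def test_param_count_deterministic(self):
        cfg = ModelConfig(input_width=10)
        net = MultiTaskNet(cfg)
        # input->109 (+BN) ->35 (+BN) -> 8+8 heads with shared regression base
        expected = (
            10 * 109 + 109 + 2 * 109
            + 109 * 35 + 35 + 2 * 35
            + 35 * 8 + 8          # classification head
            + 35 + 1 + 35 * 8 + 8  # regression: shared base + per-slot deltas
        )
        assert net.n_params == expected == count_params(net.params)


class TestForward:
    def test_output_ranges(self):
        net = MultiTaskNet(small_config())
        X = np.random.default_rng(0).normal(size=(20, 5)) * 5
        probs, doses = net.forward(X)
        assert ((probs >= 0) & (probs <= 1)).all()
        assert ((doses >= 0) & (doses <= 10)).all()

    def test_zero_params_give_half_probs_zero_doses(self):
        net = MultiTaskNet(small_config())
        for k in net.params:
            net.params[k][...] = 0.0
        probs, doses = net.forward(np.random.default_rng(1).normal(size=(4, 5)))
        np.testing.assert_allclose(probs, 0.5)
        np.testing.assert_allclose(doses, 0.0)

    def test_inference_deterministic(self):
        net = MultiTaskNet(small_config(dropout=0.3))
        X = np.random.default_rng(2).normal(size=(6, 5))
        a = net.forward(X)
        b = net.forward(X)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_width_mismatch_raises(self):
        net = MultiTaskNet(small_config())
        with pytest.raises(ValueError, match="input_width"):
            net.forward(np.zeros((3, 7)))


class TestLoss:
    def test_single_label_closed_form(self):
        w = LossWeights(pos_weights=np.ones(1), lam=1.0)
        loss = multitask_loss(
            probs=np.array([[0.5]]), doses=np.array([[2.0]]),
            labels=np.array([[1]]), true_doses=np.array([[2.0]]), weights=w,
        )
        assert loss == pytest.approx(-np.log(0.5), abs=1e-9)

    def test_perfect_prediction_loss_vanishes(self):
        w = LossWeights(pos_weights=np.ones(3), lam=1.0)
        y = np.array([[1, 0, 1]], dtype=float)
        d = np.array([[5.0, 0.0, 3.0]])
        loss_small = multitask_loss(y, d, y, d, w, eps=1e-9)
        loss_tiny = multitask_loss(y, d, y, d, w, eps=1e-12)
        assert loss_tiny < loss_small < 1e-7

    def test_matches_independent_scalar_oracle(self):
        rng = np.random.default_rng(5)
        n, k = 7, 4
        probs = rng.uniform(0.05, 0.95, (n, k))
        doses = rng.uniform(0, 10, (n, k))
        labels = (rng.random((n, k)) < 0.5).astype(float)
        true_d = rng.uniform(0, 10, (n, k))
        w = LossWeights(pos_weights=rng.uniform(0.5, 3.0, k), lam=1.7)
        # hand-rolled scalar recomputation
        total = 0.0
        for i in range(n):
            for j in range(k):
                p = probs[i, j]
                total += -(
                    w.pos_weights[j] * labels[i, j] * np.log(p)
                    + (1 - labels[i, j]) * np.log(1 - p)
                )
        expected = total / (n * k) + 1.7 * np.mean((doses - true_d) ** 2)
        assert multitask_loss(probs, doses, labels, true_d, w) == pytest.approx(expected)

    def test_non_finite_prediction_raises(self):
        w = LossWeights(pos_weights=np.ones(1))
        with pytest.raises(FloatingPointError):
            multitask_loss(np.array([[np.nan]]), np.zeros((1, 1)),
                           np.ones((1, 1)), np.zeros((1, 1)), w)


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        """Central-difference check of every parameter group."""
        net = MultiTaskNet(small_config())
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 5))
        Y = (rng.random((12, 4)) < 0.4).astype(float)
        D = rng.normal(size=(12, 4))
        w = LossWeights(pos_weights=np.array([1.0, 2.0, 0.5, 1.5]), lam=1.3)
        snap = (copy.deepcopy(net.running_mean), copy.deepcopy(net.running_var))
        _, grads = net._loss_and_grads(X, Y, D, w, np.random.default_rng(1), None)
        eps = 1e-6
        for key, P in net.params.items():
            idx = tuple(rng.integers(0, s) for s in P.shape)
            old = P[idx]
            vals = []
            for sign in (+1, -1):
                P[idx] = old + sign * eps
                net.running_mean = copy.deepcopy(snap[0])
                net.running_var = copy.deepcopy(snap[1])
                loss, _ = net._loss_and_grads(
                    X, Y, D, w, np.random.default_rng(1), None
                )
                vals.append(loss)
            P[idx] = old
            numeric = (vals[0] - vals[1]) / (2 * eps)
            assert grads[key][idx] == pytest.approx(numeric, rel=1e-4, abs=1e-8), key


class TestClipping:
    def test_norm_10_clipped_to_1(self):
        g = {"a": np.array([6.0, 8.0])}  # norm 10
        pre = clip_gradients(g, 1.0)
        assert pre == pytest.approx(10.0)
        assert np.linalg.norm(g["a"]) == pytest.approx(1.0)

    def test_small_gradient_untouched(self):
        g = {"a": np.array([0.3, 0.4])}
        clip_gradients(g, 1.0)
        np.testing.assert_allclose(g["a"], [0.3, 0.4])


class TestEarlyStopping:
    def test_strictly_increasing_loss_stops_at_patience_plus_one(self):
        """Validation loss increasing from epoch 1: stop at epoch 21 with
        epoch 1 as best (patience 20)."""
        stopper = EarlyStopper(patience=20)
        losses = 1.0 + 0.01 * np.arange(100)
        stopped_at = None
        for epoch, loss in enumerate(losses, start=1):
            if stopper.update(epoch, float(loss)):
                stopped_at = epoch
                break
        assert stopped_at == 21
        assert stopper.best_epoch == 1

    def test_training_returns_best_epoch_parameters(self):
        """With restarts disabled, an immediately worsening validation loss
        leaves the network holding early parameters."""
        cfg = small_config(patience=3, max_epochs=50, lr_restarts=0,
                           learning_rate=0.5)  # huge lr => diverging val loss
        net = MultiTaskNet(cfg)
        rng = np.random.default_rng(0)
        Xt = rng.normal(size=(40, 5)); Yt = (rng.random((40, 4)) < 0.5).astype(float)
        Dt = rng.uniform(0, 10, (40, 4))
        Xv = rng.normal(size=(20, 5)); Yv = (rng.random((20, 4)) < 0.5).astype(float)
        Dv = rng.uniform(0, 10, (20, 4))
        log = net.train(Xt, Yt, Dt, Xv, Yv, Dv)
        assert log["best_epoch"] <= log["stopped_epoch"]
        assert log["val_loss"][log["best_epoch"] - 1] == pytest.approx(
            log["best_val_loss"]
        )

    def test_learnability_smoke(self):
        """On a separable toy task the training loss decreases."""
        cfg = small_config(max_epochs=100, patience=100, lr_restarts=0, seed=1)
        net = MultiTaskNet(cfg)
        rng = np.random.default_rng(3)
        X = rng.normal(size=(120, 5))
        Y = (X[:, :4] > 0).astype(float)
        D = np.abs(X[:, :4]) * Y
        log = net.train(X[:100], Y[:100], D[:100], X[100:], Y[100:], D[100:])
        assert log["train_loss"][-1] < log["train_loss"][0]
        assert min(log["val_loss"]) < log["val_loss"][0]

    def test_divergence_aborts(self):
        """Non-finite parameters make the loss non-finite: training aborts
        with a diagnostic instead of silently continuing."""
        cfg = small_config(max_epochs=10)
        net = MultiTaskNet(cfg)
        net.params["W0"][0, 0] = np.nan
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 5))
        Y = (rng.random((30, 4)) < 0.5).astype(float)
        D = rng.uniform(0, 10, (30, 4))
        from strabplan.nn import TrainingDiverged

        with pytest.raises(TrainingDiverged):
            net.train(X[:20], Y[:20], D[:20], X[20:], Y[20:], D[20:])
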