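import math
from dataclasses import replace

import numpy as np
import pytest

from biosorb.ann import (
    MLPNetwork,
    TrainConfig,
    _loss_and_grad,
    evaluate,
    forward,
    train,
    train_restarts,
)
from biosorb.dataset import CCDDataset, CCDRun
from biosorb.errors import ConfigurationError


def identity_net(W1, b1, W2, b2, activation="tanh"):
    """Network whose scaling is the identity on [-1, 1]."""
    return MLPNetwork(
        hidden_weights=W1, hidden_bias=b1, output_weights=W2, output_bias=b2,
        hidden_activation=activation,
        input_min=np.full(4, -1.0), input_max=np.full(4, 1.0),
        output_min=-1.0, output_max=1.0,
    )


def make_dataset(X, y, split="train"):
    runs = [
        CCDRun(dose=x[0], ph=x[1], temp=x[2], conc=x[3], removal_obs=yi, split=split)
        for x, yi in zip(X, y)
    ]
    return CCDDataset(runs=runs)


class TestForward:
    def test_zero_weights_returns_scaled_bias(self):
        H = 5
        net = MLPNetwork(
            np.zeros((H, 4)), np.zeros(H), np.zeros(H), output_bias=0.0,
            input_min=np.array([0.1, 2, 25, 0.1]),
            input_max=np.array([1.3, 10, 45, 1.3]),
            output_min=0.0, output_max=100.0,
        )
        # scaled output 0 maps to the midpoint of (0, 100)
        for x in ([0.7, 6, 35, 0.7], [1.3, 10, 45, 1.3], [0.1, 2, 25, 0.1]):
            assert forward(net, x) == pytest.approx(50.0)

    def test_single_node_hand_arithmetic(self):
        w = np.array([[0.2, -0.4, 0.1, 0.3]])
        theta, w_o, b = 0.15, 0.8, -0.05
        net = identity_net(w, np.array([theta]), np.array([w_o]), b)
        x = np.array([0.5, -0.25, 0.75, -1.0])
        expected = math.tanh(float((w @ x)[0]) + theta) * w_o + b
        assert net.forward_scaled(x[None, :])[0][0] == pytest.approx(expected)

    def test_logistic_activation_hand_arithmetic(self):
        w = np.array([[0.3, 0.3, -0.2, 0.0]])
        net = identity_net(w, np.array([0.1]), np.array([1.5]), 0.2,
                           activation="logistic")
        x = np.array([1.0, -1.0, 0.5, 0.0])
        s = float((w @ x)[0]) + 0.1
        expected = 1.5 / (1 + math.exp(-s)) + 0.2
        assert net.forward_scaled(x[None, :])[0][0] == pytest.approx(expected)

    def test_output_layer_linearity(self, rng):
        W1 = rng.normal(size=(3, 4))
        b1 = rng.normal(size=3)
        W2 = rng.normal(size=3)
        net1 = identity_net(W1, b1, W2, 0.3)
        net2 = identity_net(W1, b1, 2 * W2, 0.3)
        X = rng.uniform(-1, 1, size=(10, 4))
        o1 = net1.forward_scaled(X)[0] - 0.3
        o2 = net2.forward_scaled(X)[0] - 0.3
        np.testing.assert_allclose(o2, 2 * o1, rtol=1e-12)

    def test_json_roundtrip_preserves_predictions(self, table2, rng):
        cfg = TrainConfig(hidden_nodes=3, max_epochs=50, seed=5)
        net = train(table2, cfg).network
        back = MLPNetwork.from_dict(net.to_dict())
        X = table2.actual_matrix()
        np.testing.assert_allclose(back.predict(X), net.predict(X), rtol=0, atol=0)


class TestGradient:
    @pytest.mark.parametrize("activation", ["tanh", "logistic"])
    def test_backprop_matches_finite_differences(self, activation, rng):
        """Analytic gradient vs central differences on small random nets."""
        H = 3
        Xs = rng.uniform(-1, 1, size=(7, 4))
        ys = rng.uniform(-1, 1, size=7)
        params = (
            rng.normal(size=(H, 4)) * 0.5,
            rng.normal(size=H) * 0.5,
            rng.normal(size=H) * 0.5,
            float(rng.normal() * 0.5),
        )
        _, grads = _loss_and_grad(params, Xs, ys, activation)
        eps = 1e-6

        def loss_with(pl):
            return _loss_and_grad(pl, Xs, ys, activation)[0]

        flat_params = list(params)
        for k, g in enumerate(grads):
            g = np.atleast_1d(np.asarray(g, dtype=float))
            it = np.ndindex(g.shape)
            for ij in it:
                def perturbed(sign):
                    q = [np.array(p, dtype=float, copy=True) if np.ndim(p) else p
                         for p in flat_params]
                    if np.ndim(q[k]):
                        q[k][ij] += sign * eps
                    else:
                        q[k] += sign * eps
                    return tuple(q)
                num = (loss_with(perturbed(+1)) - loss_with(perturbed(-1))) / (2 * eps)
                assert num == pytest.approx(g[ij], abs=1e-6)


class TestTrain:
    def test_deterministic_under_seed(self, table2):
        cfg = TrainConfig(hidden_nodes=4, max_epochs=300, seed=11)
        r1, r2 = train(table2, cfg), train(table2, cfg)
        np.testing.assert_array_equal(
            r1.network.hidden_weights, r2.network.hidden_weights
        )
        assert r1.mse_train == r2.mse_train
        assert r1.epochs_run == r2.epochs_run
        assert r1.mse_history == r2.mse_history

    def test_easy_linear_target(self, rng):
        """A linear map of one input is learnable to tiny training MSE."""
        X = rng.uniform([0.1, 2, 25, 0.1], [1.3, 10, 45, 1.3], size=(30, 4))
        y = 50.0 + 30.0 * (X[:, 0] - 0.7) / 0.6
        ds = make_dataset(X, y)
        cfg = TrainConfig(hidden_nodes=2, max_epochs=4000, mse_goal=1e-5,
                          monitor="none", seed=3)
        res = train(ds, cfg)
        assert res.mse_train < 1e-4

    def test_train_split_fit_quality_on_ccd(self, table2):
        """Fully converged training interpolates the 24 training runs to
        R^2 >= 0.99 on that split, across restarts."""
        tr24 = table2.subset("train")
        obs = tr24.response()
        for seed in (0, 1, 2):
            res = train(table2, TrainConfig(monitor="none", seed=seed))
            pred = res.network.predict(tr24.actual_matrix())
            r2 = 1 - np.sum((obs - pred) ** 2) / np.sum((obs - obs.mean()) ** 2)
            assert r2 >= 0.99

    def test_loss_nonincreasing_when_no_uphill_allowed(self, table2):
        cfg = TrainConfig(hidden_nodes=4, max_epochs=500, max_perf_inc=1.0,
                          monitor="none", seed=2)
        res = train(table2, cfg)
        h = res.mse_history
        assert all(b <= a + 1e-15 for a, b in zip(h, h[1:]))

    def test_goal_stops_early(self, rng):
        X = rng.uniform([0.1, 2, 25, 0.1], [1.3, 10, 45, 1.3], size=(30, 4))
        y = 50.0 + 30.0 * (X[:, 0] - 0.7) / 0.6
        ds = make_dataset(X, y)
        res = train(ds, TrainConfig(hidden_nodes=2, mse_goal=1e-3,
                                    monitor="none", seed=1))
        assert res.epochs_run < 10000
        assert res.mse_train <= 1e-3

    def test_teacher_student_recovery(self, rng):
        """Trained on 200 noiseless samples of a known small network, the
        student reproduces the teacher on a held-out grid."""
        teacher = MLPNetwork(
            hidden_weights=np.array([[0.8, -0.5, 0.3, 0.2], [-0.4, 0.6, 0.1, -0.7]]),
            hidden_bias=np.array([0.1, -0.2]),
            output_weights=np.array([0.4, -0.3]),
            output_bias=0.0,
            input_min=np.array([0.1, 2.0, 25.0, 0.1]),
            input_max=np.array([1.3, 10.0, 45.0, 1.3]),
            output_min=40.0, output_max=100.0,
        )
        X = rng.uniform([0.1, 2, 25, 0.1], [1.3, 10, 45, 1.3], size=(200, 4))
        y = np.asarray(teacher.predict(X))
        ds = make_dataset(X, y)
        res = train(ds, TrainConfig(hidden_nodes=4, max_epochs=6000,
                                    monitor="none", seed=8))
        Xg = rng.uniform([0.1, 2, 25, 0.1], [1.3, 10, 45, 1.3], size=(300, 4))
        scaled_err = res.network.scale_output(np.asarray(res.network.predict(Xg))) \
            - res.network.scale_output(np.asarray(teacher.predict(Xg)))
        assert float(np.mean(scaled_err**2)) < 1e-3

    def test_restart_selection_prefers_lower_test_mse(self, table2):
        cfg = TrainConfig(hidden_nodes=4, max_epochs=400, seed=9)
        seeds = np.random.SeedSequence(9).generate_state(4) % (2**31)
        singles = [train(table2, replace(cfg, seed=int(s))) for s in seeds]
        best = train_restarts(table2, cfg, n_restarts=4)
        assert best.mse_test == min(r.mse_test for r in singles)

    def test_empty_training_split_rejected(self, table2):
        only_test = CCDDataset(
            table2.factors, [r for r in table2.runs if r.split == "test"]
        )
        with pytest.raises(ConfigurationError):
            train(only_test, TrainConfig())


class TestEvaluate:
    def test_perfect_predictor(self, table2):
        """A predictor reproducing every observation scores R^2 = 1, error 0."""
        obs_all = table2.response()

        class Memorizer(MLPNetwork):
            # replays the observed responses in dataset order; replicated
            # centre points make a value-keyed lookup impossible
            def predict(self, X):
                return obs_all[: len(np.atleast_2d(X))].copy()

        net = Memorizer(np.zeros((1, 4)), np.zeros(1), np.zeros(1), 0.0,
                        output_min=0.0, output_max=100.0)
        ev = evaluate(net, table2)
        assert ev.r2_all == pytest.approx(1.0)
        assert ev.avg_pred_error_train == pytest.approx(0.0)
        assert ev.avg_pred_error_test == pytest.approx(0.0)

    def test_constant_mean_predictor_scores_zero(self, table2):
        mean = table2.response().mean()

        class Constant(MLPNetwork):
            def predict(self, X):
                return np.full(len(np.atleast_2d(X)), mean)

        net = Constant(np.zeros((1, 4)), np.zeros(1), np.zeros(1), 0.0,
                       output_min=0.0, output_max=100.0)
        assert evaluate(net, table2).r2_all == pytest.approx(0.0)

    def test_study_ann_column_r2_by_oracle_accumulation(self, table2):
        """R^2 of the study's printed network predictions against the
        observations, accumulated independently."""
        obs = np.array([r.removal_obs for r in table2.runs])
        pred = np.array([r.removal_ann for r in table2.runs])
        ss_res = sum((o - p) ** 2 for o, p in zip(obs, pred))
        ss_tot = sum((o - obs.mean()) ** 2 for o in obs)
        r2 = 1 - ss_res / ss_tot
        assert r2 == pytest.approx(0.996249, abs=1e-6)
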