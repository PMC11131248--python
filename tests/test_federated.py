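import numpy as np
import pytest
from scipy.special import expit

from fedprog.federated import (
    FedConfig,
    LinearModelParams,
    aggregate,
    bce_loss,
    init_params,
    local_update,
    predict_proba,
    run_fedavg,
    train_centralized,
    train_local_only,
)


def _toy_data(seed=0, n=200, p=4, signal=1.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    w_true = np.zeros(p)
    w_true[0] = signal
    y = (rng.random(n) < expit(X @ w_true - 1.0)).astype(int)
    return X, y


class TestInitAndPredict:
    def test_init_is_deterministic_per_seed(self):
        a, b = init_params(3, seed=5), init_params(3, seed=5)
        assert np.array_equal(a.w, b.w) and a.b == b.b
        assert not np.array_equal(a.w, init_params(3, seed=6).w)

    def test_init_shape_and_range(self):
        p = init_params(7, seed=1)
        assert p.w.shape == (7,) and p.b == 0.0
        assert (np.abs(p.w) <= 0.01).all()

    def test_init_needs_positive_dimension(self):
        with pytest.raises(ValueError):
            init_params(0)

    def test_zero_params_predict_half(self):
        params = LinearModelParams(np.zeros(2), 0.0)
        assert predict_proba(params, np.array([[3.0, -1.0]]))[0] == 0.5

    def test_bias_log3_predicts_three_quarters(self):
        params = LinearModelParams(np.zeros(1), np.log(3.0))
        assert predict_proba(params, np.array([[0.0]]))[0] == pytest.approx(0.75)

    def test_dimension_mismatch_rejected(self):
        params = LinearModelParams(np.zeros(2), 0.0)
        with pytest.raises(ValueError, match="columns"):
            predict_proba(params, np.zeros((1, 3)))

    def test_extreme_logit_stays_positive_and_loss_finite(self):
        params = LinearModelParams(np.array([-50.0]), 0.0)
        X, y = np.array([[1.0]]), np.array([1])
        prob = predict_proba(params, X)[0]
        assert 0.0 < prob < 1e-20
        assert np.isfinite(bce_loss(params, X, y))


class TestLocalUpdate:
    def test_hand_computed_single_step(self):
        # one sample x=1, y=1 from w=0, b=0: residual sigma(0)-1 = -0.5,
        # so with eta=1 both w and b move to +0.5
        params = LinearModelParams(np.zeros(1), 0.0)
        out = local_update(
            params, np.array([[1.0]]), np.array([1]), B=1, E=1, eta=1.0, seed=0
        )
        assert out.w[0] == pytest.approx(0.5)
        assert out.b == pytest.approx(0.5)

    def test_zero_learning_rate_is_identity(self):
        X, y = _toy_data()
        params = init_params(X.shape[1], seed=2)
        out = local_update(params, X, y, B=16, E=3, eta=0.0, seed=1)
        assert np.array_equal(out.w, params.w) and out.b == params.b

    def test_two_epochs_decompose_into_two_single_epochs(self):
        X, y = _toy_data(seed=3)
        params = init_params(X.shape[1], seed=0)
        joint = local_update(params, X, y, B=32, E=2, eta=0.1, seed=7)
        step1 = local_update(params, X, y, B=32, E=1, eta=0.1, seed=7, epoch_offset=0)
        step2 = local_update(step1, X, y, B=32, E=1, eta=0.1, seed=7, epoch_offset=1)
        assert np.array_equal(joint.w, step2.w) and joint.b == step2.b

    def test_empty_data_rejected(self):
        params = init_params(2)
        with pytest.raises(ValueError, match="non-empty"):
            local_update(params, np.zeros((0, 2)), np.zeros(0), B=1, E=1, eta=0.1, seed=0)


class TestAggregate:
    def test_identical_params_are_a_fixed_point(self):
        p = LinearModelParams(np.array([1.0, -2.0]), 0.3)
        out = aggregate([p.copy(), p.copy(), p.copy()], [5, 1, 3])
        assert np.allclose(out.w, p.w) and out.b == pytest.approx(p.b)

    def test_weighted_mean(self):
        p1 = LinearModelParams(np.array([0.0]), 0.0)
        p2 = LinearModelParams(np.array([4.0]), 4.0)
        out = aggregate([p1, p2], [1, 3])
        assert out.w[0] == pytest.approx(3.0) and out.b == pytest.approx(3.0)

    def test_single_client_identity(self):
        p = LinearModelParams(np.array([2.0]), -1.0)
        out = aggregate([p], [10])
        assert np.array_equal(out.w, p.w) and out.b == p.b

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        params = [LinearModelParams(rng.normal(size=3), rng.normal()) for _ in range(4)]
        sizes = [3, 9, 1, 7]
        a = aggregate(params, sizes)
        order = [2, 0, 3, 1]
        b = aggregate([params[i] for i in order], [sizes[i] for i in order])
        assert np.allclose(a.w, b.w, atol=1e-15) and a.b == pytest.approx(b.b, abs=1e-15)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate([], [])


class TestFedAvgLoop:
    def test_single_client_full_batch_equals_plain_gradient_descent(self):
        """FedAvg with K=1 and B=n degenerates round-for-round to full-batch
        gradient descent (independent re-implementation as the oracle)."""
        X, y = _toy_data(seed=5, n=120)
        eta, rounds = 0.2, 50
        cfg = FedConfig(K=1, B=len(y), E=1, eta=eta, rounds=rounds, seed=9,
                        convergence_tol=None)
        _, trace = run_fedavg([(X, y)], cfg)

        w = init_params(X.shape[1], seed=9).w.copy()
        b = 0.0
        for t in range(rounds):
            resid = expit(X @ w + b) - y
            w = w - eta * X.T @ resid / len(y)
            b = b - eta * resid.mean()
            got = trace.params_history[t + 1]
            assert np.abs(got.w - w).max() < 1e-12
            assert abs(got.b - b) < 1e-12

    def test_zero_rounds_returns_initialization(self):
        X, y = _toy_data()
        cfg = FedConfig(K=1, B=32, rounds=0, seed=3)
        params, trace = run_fedavg([(X, y)], cfg)
        init = init_params(X.shape[1], seed=3)
        assert np.array_equal(params.w, init.w) and params.b == init.b
        assert trace.executed_rounds == 0

    def test_identical_clients_match_single_client_trajectory(self):
        X, y = _toy_data(seed=6)
        cfg = FedConfig(K=1, B=len(y), E=1, eta=0.1, rounds=20, seed=1,
                        convergence_tol=None)
        _, solo = run_fedavg([(X, y)], cfg)
        _, trio = run_fedavg([(X, y)] * 3, cfg)
        for a, b in zip(solo.params_history, trio.params_history):
            assert np.abs(a.w - b.w).max() < 1e-12

    def test_empty_client_rejected(self):
        X, y = _toy_data()
        with pytest.raises(ValueError, match="no data"):
            run_fedavg([(X, y), (np.zeros((0, X.shape[1])), np.zeros(0))], FedConfig())

    def test_convergence_tolerance_stops_early(self):
        X, y = _toy_data(seed=8, n=80)
        cfg = FedConfig(K=1, B=len(y), E=1, eta=0.5, rounds=5000, seed=0,
                        convergence_tol=1e-7)
        _, trace = run_fedavg([(X, y)], cfg)
        assert trace.executed_rounds < 5000
        assert trace.param_deltas[-1] < 1e-7

    def test_validation_trace_length(self):
        X, y = _toy_data(seed=2)
        cfg = FedConfig(K=2, B=32, rounds=4, seed=0, convergence_tol=None)
        half = len(y) // 2
        _, trace = run_fedavg(
            [(X[:half], y[:half]), (X[half:], y[half:])], cfg,
            validation=(X, y),
        )
        assert len(trace.validation_auc) == trace.executed_rounds + 1


class TestBaselines:
    def test_centralized_equals_single_client_fedavg(self):
        X, y = _toy_data(seed=7)
        cfg = FedConfig(K=1, B=32, rounds=10, seed=4, convergence_tol=None)
        a, _ = run_fedavg([(X, y)], cfg)
        b, _ = train_centralized(X, y, cfg)
        assert np.array_equal(a.w, b.w) and a.b == b.b

    def test_local_only_matches_centralized_on_same_shard(self):
        X, y = _toy_data(seed=9)
        cfg = FedConfig(K=1, B=16, rounds=8, seed=2, convergence_tol=None)
        local = train_local_only(X, y, cfg)
        cent, _ = train_centralized(X, y, cfg)
        assert np.array_equal(local.w, cent.w) and local.b == cent.b

    def test_fedavg_differs_from_local_when_shards_differ(self):
        Xa, ya = _toy_data(seed=10)
        Xb, yb = _toy_data(seed=11, signal=-1.5)
        cfg = FedConfig(K=2, B=32, rounds=10, seed=0, convergence_tol=None)
        fed, _ = run_fedavg([(Xa, ya), (Xb, yb)], cfg)
        solo = train_local_only(Xa, ya, cfg)
        assert not np.allclose(fed.w, solo.w)

    def test_full_batch_loss_non_increasing_at_small_eta(self):
        X, y = _toy_data(seed=12, n=300)
        cfg = FedConfig(K=1, B=len(y), E=1, eta=0.01, rounds=60, seed=1,
                        convergence_tol=None)
        _, trace = train_centralized(X, y, cfg)
        losses = [bce_loss(p, X, y) for p in trace.params_history]
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_deterministic_per_seed(self):
        X, y = _toy_data(seed=13)
        cfg = FedConfig(K=2, B=16, rounds=6, seed=5, convergence_tol=None)
        half = len(y) // 2
        clients = [(X[:half], y[:half]), (X[half:], y[half:])]
        a, _ = run_fedavg(clients, cfg)
        b, _ = run_fedavg(clients, cfg)
        assert np.array_equal(a.w, b.w) and a.b == b.b


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs", [{"K": 0}, {"B": 0}, {"E": 0}, {"eta": -0.1}, {"rounds": -1}]
    )
    def test_invalid_hyperparameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FedConfig(**kwargs)
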