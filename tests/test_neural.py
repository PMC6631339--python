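"""Networks, the four trainers, and their independent numerical oracles."""

import numpy as np
import pytest
from scipy.optimize import linprog

from rhythmnet.neural import (
    TrainerConfig,
    UnsupportedStructureError,
    gradient_vector,
    init_network,
    jacobian,
    lm_step,
    load_network,
    mse,
    predict_state,
    rprop_update,
    save_network,
    train,
    train_backprop,
    train_error_correction,
    train_lm,
    train_rprop,
)

# ---------------------------------------------------------------------------
# oracles


def numerical_gradient(net, X, T, h=1e-6):
    """Central-difference gradient of the batch MSE, independent of backprop."""
    theta = net.get_params()
    grad = np.empty_like(theta)
    probe = net.copy()
    for i in range(theta.size):
        for sign, slot in ((+1, 0), (-1, 1)):
            shifted = theta.copy()
            shifted[i] += sign * h
            probe.set_params(shifted)
            if slot == 0:
                up = mse(probe, X, T)
            else:
                down = mse(probe, X, T)
        grad[i] = (up - down) / (2 * h)
    return grad


def linearly_separable(X, T):
    """LP feasibility oracle: does a hyperplane with margin 1 exist?"""
    signs = np.where(np.asarray(T) > 0.5, 1.0, -1.0)
    A = -signs[:, None] * np.column_stack([X, np.ones(len(T))])
    b = -np.ones(len(T))
    res = linprog(
        c=np.zeros(A.shape[1]),
        A_ub=A,
        b_ub=b,
        bounds=[(None, None)] * A.shape[1],
        method="highs",
    )
    return res.status == 0


def xor_in_5d():
    """XOR on the first two inputs, remaining three inputs zero."""
    X = np.array(
        [[0, 0, 0, 0, 0], [0, 1, 0, 0, 0], [1, 0, 0, 0, 0], [1, 1, 0, 0, 0]],
        dtype=float,
    )
    T = np.array([0.0, 1.0, 1.0, 0.0])
    return X, T


def and_like_16():
    """All 16 sign patterns of two informative inputs, labelled by AND."""
    rng = np.random.default_rng(0)
    X = rng.uniform(-1, 1, size=(16, 5))
    X[:, 0] = np.repeat([1.0, -1.0], 8)
    X[:, 1] = np.tile(np.repeat([1.0, -1.0], 4), 2)
    T = ((X[:, 0] > 0) & (X[:, 1] > 0)).astype(float)
    return X, T


# ---------------------------------------------------------------------------


class TestNetwork:
    def test_seeded_init_deterministic(self):
        assert init_network((5, 6, 6, 1), seed=1) == init_network((5, 6, 6, 1), seed=1)
        assert init_network((5, 1), seed=1) != init_network((5, 1), seed=2)

    def test_multilayer_shapes(self):
        net = init_network((5, 6, 6, 1), seed=0)
        assert [w.shape for w in net.weights] == [(6, 5), (6, 6), (1, 6)]

    def test_single_layer_shape(self):
        net = init_network((5, 1), seed=0)
        assert [w.shape for w in net.weights] == [(1, 5)]

    def test_zero_network_outputs_half(self):
        net = init_network((5, 6, 6, 1), seed=0)
        net.set_params(np.zeros(net.n_params))
        assert net.forward(np.ones(5)) == 0.5

    def test_forward_matches_straight_line_oracle(self):
        net = init_network((5, 6, 6, 1), seed=3)
        x = np.random.default_rng(4).standard_normal(5)
        a = x
        for W, b in zip(net.weights, net.biases):
            a = 1.0 / (1.0 + np.exp(-(W @ a + b)))
        assert net.forward(x) == pytest.approx(float(a[0]), abs=1e-12)

    def test_output_saturates_with_weight_scaling(self):
        net = init_network((5, 1), seed=0)
        x = np.ones(5)
        z = (net.weights[0] @ x + net.biases[0]).item()
        outputs = []
        for scale in (1.0, 10.0, 100.0):
            scaled = net.copy()
            scaled.weights[0] *= scale
            scaled.biases[0] *= scale
            outputs.append(scaled.forward(x))
        if z > 0:
            assert outputs == sorted(outputs) and outputs[-1] > 0.999
        else:
            assert outputs == sorted(outputs, reverse=True) and outputs[-1] < 0.001

    def test_predict_state_threshold_and_tie(self):
        net = init_network((5, 1), seed=0)
        net.set_params(np.zeros(net.n_params))  # forward == 0.5 exactly
        assert predict_state(net, np.ones(5)) == 0
        net.set_params(np.array([1.0, 0, 0, 0, 0, 2.0]))
        assert predict_state(net, np.ones(5)) == 1
        net.set_params(np.array([1.0, 0, 0, 0, 0, -2.0]))
        assert predict_state(net, np.zeros(5)) == 0

    def test_serialization_roundtrip_bit_identical(self, tmp_path):
        net = init_network((5, 6, 6, 1), seed=42)
        path = tmp_path / "net.json"
        save_network(net, path)
        assert load_network(path) == net


class TestGradients:
    def test_backprop_matches_central_difference(self):
        rng = np.random.default_rng(12)
        net = init_network((5, 6, 6, 1), seed=12)
        X = rng.standard_normal((8, 5))
        T = rng.integers(0, 2, size=8).astype(float)
        analytic = gradient_vector(net, X, T)
        numeric = numerical_gradient(net, X, T)
        # components far below the dominant gradient scale are compared
        # at that scale: central differences cannot resolve them further
        denom = np.maximum(np.abs(numeric), 1e-3 * np.abs(numeric).max())
        assert np.max(np.abs(analytic - numeric) / denom) < 1e-5

    def test_jacobian_gradient_consistency(self):
        """J^T r must equal half the MSE gradient times n (LM's gradient)."""
        rng = np.random.default_rng(2)
        net = init_network((5, 6, 6, 1), seed=2)
        X = rng.standard_normal((6, 5))
        T = rng.integers(0, 2, size=6).astype(float)
        J = jacobian(net, X)
        r = net.forward_batch(X) - T
        assert np.allclose(2.0 * J.T @ r / len(T), gradient_vector(net, X, T))


class TestBackprop:
    def test_zero_learning_rate_leaves_network_unchanged(self):
        X, T = xor_in_5d()
        net = init_network((5, 6, 6, 1), seed=0)
        out = train_backprop(net, X, T, TrainerConfig(algorithm="backprop", learning_rate=0.0))
        assert out == net

    def test_loss_non_increasing_for_small_learning_rate(self):
        X, T = xor_in_5d()
        cfg = TrainerConfig(algorithm="backprop", learning_rate=0.05, epochs=1, mse_tol=0.0)
        net = init_network((5, 6, 6, 1), seed=1)
        losses = [mse(net, X, T)]
        for _ in range(200):
            net = train_backprop(net, X, T, cfg)
            losses.append(mse(net, X, T))
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_solves_xor_in_5d_on_some_seed(self):
        # plain gradient descent needs a long budget on XOR from small
        # random weights; 20k epochs at lr 0.5 solves it from cold starts
        X, T = xor_in_5d()
        cfg = TrainerConfig(
            algorithm="backprop", learning_rate=0.5, epochs=20000, mse_tol=0.0
        )
        final = [
            mse(train_backprop(init_network((5, 6, 6, 1), s), X, T, cfg), X, T)
            for s in range(5)
        ]
        assert min(final) < 0.05


class TestRprop:
    def test_sign_invariance_of_update_trajectory(self):
        rng = np.random.default_rng(8)
        grads = rng.standard_normal((20, 7))
        for scale in (1.0, 3.7, 250.0):
            prev = np.zeros(7)
            step = np.full(7, 0.1)
            theta = np.zeros(7)
            for g in grads:
                upd, prev, step = rprop_update(scale * g, prev, step)
                theta = theta + upd
            if scale == 1.0:
                reference = theta
            else:
                assert np.array_equal(theta, reference)

    def test_hand_simulated_quadratic_steps(self):
        """Quadratic loss (w-3)^2 from w=0: steps +0.1, +0.12, +0.144."""
        w = np.array([0.0])
        prev = np.zeros(1)
        step = np.array([0.1])
        moves = []
        for _ in range(3):
            grad = 2 * (w - 3.0)
            upd, prev, step = rprop_update(grad, prev, step)
            w = w + upd
            moves.append(float(upd[0]))
        assert moves == pytest.approx([0.1, 0.12, 0.144])

    def test_sign_flip_shrinks_step_and_skips_update(self):
        upd, prev, step = rprop_update(
            np.array([1.0]), np.array([-1.0]), np.array([0.1])
        )
        assert upd[0] == 0.0 and prev[0] == 0.0 and step[0] == pytest.approx(0.05)

    def test_step_clamped_to_bounds(self):
        _, _, step = rprop_update(
            np.array([1.0]), np.array([1.0]), np.array([60.0]), delta_max=50.0
        )
        assert step[0] == 50.0
        _, _, step = rprop_update(
            np.array([1.0]), np.array([-1.0]), np.array([1e-6]), delta_min=1e-6
        )
        assert step[0] == 1e-6

    def test_solves_xor_in_5d_on_most_seeds(self):
        X, T = xor_in_5d()
        cfg = TrainerConfig(algorithm="rprop", epochs=2000, mse_tol=0.0)
        final = [
            mse(train_rprop(init_network((5, 6, 6, 1), s), X, T, cfg), X, T)
            for s in range(5)
        ]
        assert sum(f < 0.05 for f in final) >= 3


class TestLevenbergMarquardt:
    def test_zero_residuals_zero_step(self):
        net = init_network((5, 6, 6, 1), seed=5)
        X = np.random.default_rng(5).standard_normal((4, 5))
        T = net.forward_batch(X)  # residuals exactly zero
        candidate, sse = lm_step(net, X, T, lam=0.01)
        assert np.allclose(candidate, net.get_params())
        assert sse == pytest.approx(0.0, abs=1e-20)

    def test_huge_damping_recovers_gradient_direction(self):
        rng = np.random.default_rng(6)
        net = init_network((5, 6, 6, 1), seed=6)
        X = rng.standard_normal((10, 5))
        T = rng.integers(0, 2, size=10).astype(float)
        lam = 1e8
        candidate, _ = lm_step(net, X, T, lam)
        step = candidate - net.get_params()
        J = jacobian(net, X)
        r = net.forward_batch(X) - T
        grad_dir = -(J.T @ r)
        cos = step @ grad_dir / (np.linalg.norm(step) * np.linalg.norm(grad_dir))
        assert np.arccos(np.clip(cos, -1, 1)) < 1e-3

    def test_undamped_step_on_linear_net_is_least_squares(self):
        """With identity activation and lam=0 one step lands on the normal
        equations solution."""
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 5))
        T = rng.standard_normal(30)
        net = init_network((5, 1), seed=7)
        net.activation = "identity"
        candidate, _ = lm_step(net, X, T, lam=0.0)
        design = np.column_stack([X, np.ones(len(T))])
        theta_ls, *_ = np.linalg.lstsq(design, T, rcond=None)
        assert np.allclose(candidate, theta_ls, atol=1e-8)

    def test_accepted_sse_strictly_decreasing(self):
        rng = np.random.default_rng(9)
        net = init_network((5, 6, 6, 1), seed=9)
        X = rng.standard_normal((20, 5))
        T = rng.integers(0, 2, size=20).astype(float)
        history: list = []
        train_lm(net, X, T, TrainerConfig(epochs=30, mse_tol=0.0), history=history)
        assert len(history) >= 2
        assert all(b < a for a, b in zip(history, history[1:]))

    def test_training_reduces_error(self):
        X, T = xor_in_5d()
        net = init_network((5, 6, 6, 1), seed=1)
        trained = train_lm(net, X, T, TrainerConfig(epochs=50, mse_tol=0.0))
        assert mse(trained, X, T) < mse(net, X, T)


class TestErrorCorrection:
    def test_rejects_multilayer_network(self):
        with pytest.raises(UnsupportedStructureError):
            train_error_correction(
                init_network((5, 6, 6, 1), 0), np.zeros((1, 5)), [0],
                TrainerConfig(algorithm="error_correction"),
            )

    def test_correct_sample_leaves_weights_unchanged(self):
        net = init_network((5, 1), seed=0)
        x = np.ones((1, 5))
        t = [float(net.forward(x[0]) > 0.5)]
        out = train_error_correction(
            net, x, t, TrainerConfig(algorithm="error_correction", epochs=3)
        )
        assert out == net

    def test_converges_on_separable_data(self):
        X, T = and_like_16()
        assert linearly_separable(X, T)  # oracle: a separator exists
        cfg = TrainerConfig(algorithm="error_correction", learning_rate=0.5, epochs=100)
        net = train_error_correction(init_network((5, 1), 1), X, T, cfg)
        preds = (net.forward_batch(X) > 0.5).astype(float)
        assert np.array_equal(preds, T)

    def test_stuck_below_75_percent_on_xor(self):
        X, T = xor_in_5d()
        assert not linearly_separable(X, T)  # oracle: no separator exists
        cfg = TrainerConfig(algorithm="error_correction", learning_rate=0.5, epochs=1)
        net = init_network((5, 1), 1)
        for _ in range(200):
            net = train_error_correction(net, X, T, cfg)
            acc = np.mean((net.forward_batch(X) > 0.5).astype(float) == T)
            assert acc <= 0.75


class TestDeterminism:
    @pytest.mark.parametrize(
        "algorithm", ["error_correction", "backprop", "rprop", "levenberg_marquardt"]
    )
    def test_trainers_deterministic(self, algorithm):
        rng = np.random.default_rng(20)
        X = rng.standard_normal((12, 5))
        T = rng.integers(0, 2, size=12).astype(float)
        cfg = TrainerConfig(algorithm=algorithm, epochs=10)
        sizes = cfg.network_sizes()
        a = train(init_network(sizes, 3), X, T, cfg)
        b = train(init_network(sizes, 3), X, T, cfg)
        assert a == b


class TestConfigValidation:
    def test_eta_ordering_enforced(self):
        with pytest.raises(ValueError):
            TrainerConfig(eta_plus=0.9)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            TrainerConfig(algorithm="adam")

    def test_structures_by_algorithm(self):
        assert TrainerConfig(algorithm="error_correction").network_sizes() == (5, 1)
        assert TrainerConfig(algorithm="levenberg_marquardt").network_sizes() == (5, 6, 6, 1)
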