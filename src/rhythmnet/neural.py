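"""Perceptron networks and the four training algorithms.

The classifier is a small feed-forward perceptron with logistic-sigmoid
units: a single-layer 5-1 structure for the classic error-correction
(perceptron) rule, and a 5-6-6-1 structure for the gradient-based
trainers.  The five inputs are the normalized band amplitudes (alpha,
beta0, beta1, beta2, delta); the single output in (0, 1) is thresholded at
0.5 into the binary brain-state prediction.

All four trainers are implemented here from first principles on a mean
squared error loss:

``error_correction``
    Per-sample perceptron rule ``w <- w + lr * (target - predicted) * x``
    on the thresholded output; single-layer networks only.
``backprop``
    Full-batch gradient descent with backpropagated MSE gradients.
``rprop``
    Rprop- (resilient backpropagation): per-weight adaptive step sizes
    grown by ``eta_plus`` while the gradient sign persists and shrunk by
    ``eta_minus`` on a sign flip (that step's update is skipped); only the
    sign of the gradient is used.
``levenberg_marquardt``
    Damped Gauss-Newton on the per-sample residuals: solve
    ``(J^T J + lambda I) delta = -J^T r`` with ``lambda`` multiplied up on
    a rejected (SSE-increasing) step and down on an accepted one, so the
    SSE of accepted steps is strictly decreasing.

Everything is deterministic given (seed, data, config).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

ALGORITHMS = ("error_correction", "backprop", "rprop", "levenberg_marquardt")

SINGLE_LAYER_SIZES = (5, 1)
MULTI_LAYER_SIZES = (5, 6, 6, 1)

WEIGHT_INIT_HALF_RANGE = 0.5


class UnsupportedStructureError(ValueError):
    """The trainer cannot handle this network structure."""


@dataclass
class TrainerConfig:
    """Hyperparameters for one training algorithm.

    The Rprop constants default to the canonical published values
    (eta+ 1.2, eta- 0.5, step0 0.1, clamped to [1e-6, 50]); the
    Levenberg-Marquardt damping starts at 1e-3 and moves by x10 / x0.1.
    A training call runs at most ``epochs`` passes, stopping early once
    the batch MSE drops below ``mse_tol``.
    """

    algorithm: str = "levenberg_marquardt"
    learning_rate: float = 0.5
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta0: float = 0.1
    delta_min: float = 1e-6
    delta_max: float = 50.0
    lambda0: float = 1e-3
    lambda_up: float = 10.0
    lambda_down: float = 0.1
    max_lambda_escalations: int = 5
    epochs: int = 50
    mse_tol: float = 0.01
    seed: int = 0
    layer_sizes: tuple | None = None

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )
        if not (self.eta_minus < 1.0 < self.eta_plus):
            raise ValueError("require eta_minus < 1 < eta_plus")
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def network_sizes(self) -> tuple:
        if self.layer_sizes is not None:
            return tuple(self.layer_sizes)
        if self.algorithm == "error_correction":
            return SINGLE_LAYER_SIZES
        return MULTI_LAYER_SIZES


def _activate(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "sigmoid":
        return expit(z)
    if activation == "identity":
        return z
    raise ValueError(f"unknown activation {activation!r}")


def _activate_deriv(a: np.ndarray, activation: str) -> np.ndarray:
    if activation == "sigmoid":
        return a * (1.0 - a)
    if activation == "identity":
        return np.ones_like(a)
    raise ValueError(f"unknown activation {activation!r}")


@dataclass
class Network:
    """Layered perceptron weights and biases.

    ``weights[l]`` has shape ``(layer_sizes[l+1], layer_sizes[l])``;
    ``biases[l]`` has shape ``(layer_sizes[l+1],)``.  The activation is
    the logistic sigmoid; an identity activation is supported for linear
    diagnostics.
    """

    layer_sizes: tuple
    weights: list
    biases: list
    activation: str = "sigmoid"

    def __post_init__(self):
        self.layer_sizes = tuple(int(s) for s in self.layer_sizes)
        expected = list(zip(self.layer_sizes[1:], self.layer_sizes[:-1]))
        shapes = [w.shape for w in self.weights]
        if shapes != expected:
            raise ValueError(f"weight shapes {shapes} do not match {expected}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return (
            self.layer_sizes == other.layer_sizes
            and self.activation == other.activation
            and all(np.array_equal(a, b) for a, b in zip(self.weights, other.weights))
            and all(np.array_equal(a, b) for a, b in zip(self.biases, other.biases))
        )

    def copy(self) -> "Network":
        return Network(
            self.layer_sizes,
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            self.activation,
        )

    @property
    def n_params(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    # -- forward passes -----------------------------------------------------

    def activations(self, X: np.ndarray) -> list:
        """Layer outputs for a batch, including the input layer."""
        A = [np.atleast_2d(np.asarray(X, dtype=float))]
        for W, b in zip(self.weights, self.biases):
            A.append(_activate(A[-1] @ W.T + b, self.activation))
        return A

    def forward_batch(self, X: np.ndarray) -> np.ndarray:
        return self.activations(X)[-1][:, 0]

    def forward(self, x) -> float:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.layer_sizes[0],):
            raise ValueError(
                f"input of shape {x.shape} does not match {self.layer_sizes[0]} inputs"
            )
        return float(self.forward_batch(x[None, :])[0])

    # -- flat parameter view (used by Rprop and LM) -------------------------

    def get_params(self) -> np.ndarray:
        parts = []
        for W, b in zip(self.weights, self.biases):
            parts.append(W.ravel())
            parts.append(b.ravel())
        return np.concatenate(parts)

    def set_params(self, theta: np.ndarray) -> None:
        i = 0
        for W, b in zip(self.weights, self.biases):
            W[...] = theta[i : i + W.size].reshape(W.shape)
            i += W.size
            b[...] = theta[i : i + b.size]
            i += b.size


def init_network(layer_sizes, seed: int) -> Network:
    """Seeded network with weights and biases uniform in [-0.5, 0.5]."""
    sizes = tuple(int(s) for s in layer_sizes)
    if len(sizes) < 2 or sizes[0] != 5 or sizes[-1] != 1:
        raise ValueError(f"layer sizes must run from 5 inputs to 1 output, got {sizes}")
    rng = np.random.default_rng(seed)
    r = WEIGHT_INIT_HALF_RANGE
    weights = [
        rng.uniform(-r, r, size=(n_out, n_in))
        for n_in, n_out in zip(sizes[:-1], sizes[1:])
    ]
    biases = [rng.uniform(-r, r, size=n_out) for n_out in sizes[1:]]
    return Network(sizes, weights, biases)


def forward(net: Network, x) -> float:
    return net.forward(x)


def predict_state(net: Network, x) -> int:
    """Binary state: 1 iff the output exceeds 0.5 (a tie maps to 0)."""
    return int(net.forward(x) > 0.5)


def predict_batch(net: Network, X) -> np.ndarray:
    return (net.forward_batch(X) > 0.5).astype(int)


# ---------------------------------------------------------------------------
# Loss and gradients


def _check_data(net: Network, X, T):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.asarray(T, dtype=float).ravel()
    if X.shape[1] != net.layer_sizes[0]:
        raise ValueError(
            f"{X.shape[1]} features do not match {net.layer_sizes[0]} inputs"
        )
    if X.shape[0] != T.size:
        raise ValueError("feature/target count mismatch")
    return X, T


def mse(net: Network, X, T) -> float:
    X, T = _check_data(net, X, T)
    return float(np.mean((net.forward_batch(X) - T) ** 2))


def gradients(net: Network, X, T):
    """Backpropagated gradients of the batch MSE w.r.t. weights and biases."""
    X, T = _check_data(net, X, T)
    n = X.shape[0]
    A = net.activations(X)
    delta = (2.0 / n) * (A[-1] - T[:, None]) * _activate_deriv(A[-1], net.activation)
    grads_w = [None] * len(net.weights)
    grads_b = [None] * len(net.biases)
    for l in range(len(net.weights) - 1, -1, -1):
        grads_w[l] = delta.T @ A[l]
        grads_b[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ net.weights[l]) * _activate_deriv(A[l], net.activation)
    return grads_w, grads_b


def gradient_vector(net: Network, X, T) -> np.ndarray:
    gw, gb = gradients(net, X, T)
    parts = []
    for W, b in zip(gw, gb):
        parts.append(W.ravel())
        parts.append(b.ravel())
    return np.concatenate(parts)


def jacobian(net: Network, X) -> np.ndarray:
    """Per-sample Jacobian of the network output w.r.t. all parameters.

    Row i is d y_i / d theta in the same flat ordering as ``get_params``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    A = net.activations(X)
    delta = _activate_deriv(A[-1], net.activation)  # (n, 1)
    blocks = [None] * len(net.weights)
    for l in range(len(net.weights) - 1, -1, -1):
        jw = np.einsum("no,ni->noi", delta, A[l]).reshape(n, -1)
        blocks[l] = (jw, delta.copy())
        if l > 0:
            delta = (delta @ net.weights[l]) * _activate_deriv(A[l], net.activation)
    cols = []
    for jw, jb in blocks:
        cols.append(jw)
        cols.append(jb)
    return np.concatenate(cols, axis=1)


# ---------------------------------------------------------------------------
# Trainers


def train_error_correction(net: Network, X, T, config: TrainerConfig) -> Network:
    """Classic perceptron rule on a single-layer network.

    Updates per sample, in data order; stops early after an epoch with no
    misclassification (the perceptron convergence criterion).
    """
    if len(net.layer_sizes) != 2:
        raise UnsupportedStructureError(
            "the error-correction rule trains single-layer (5-1) networks only"
        )
    X, T = _check_data(net, X, T)
    net = net.copy()
    W, b = net.weights[0], net.biases[0]
    lr = config.learning_rate
    for _ in range(config.epochs):
        changed = False
        for x, t in zip(X, T):
            predicted = float((W[0] @ x + b[0]) > 0)  # sigmoid(z) > 0.5 <=> z > 0
            err = t - predicted
            if err != 0:
                W[0] += lr * err * x
                b[0] += lr * err
                changed = True
        if not changed:
            break
    return net


def train_backprop(net: Network, X, T, config: TrainerConfig) -> Network:
    """Full-batch gradient descent on the MSE."""
    X, T = _check_data(net, X, T)
    net = net.copy()
    lr = config.learning_rate
    for _ in range(config.epochs):
        if mse(net, X, T) < config.mse_tol:
            break
        gw, gb = gradients(net, X, T)
        for W, b, gW, gB in zip(net.weights, net.biases, gw, gb):
            W -= lr * gW
            b -= lr * gB
    return net


def rprop_update(
    grad: np.ndarray,
    prev_grad: np.ndarray,
    step: np.ndarray,
    *,
    eta_plus: float = 1.2,
    eta_minus: float = 0.5,
    delta_min: float = 1e-6,
    delta_max: float = 50.0,
):
    """One Rprop- step for a flat parameter vector.

    Returns ``(update, new_prev_grad, new_step)``.  The update depends only
    on the *sign* of the gradient; on a sign flip the step size shrinks and
    the update for that parameter is skipped (its stored gradient is
    zeroed so the next step is treated as sign-neutral).
    """
    sign_product = grad * prev_grad
    step = np.where(
        sign_product > 0,
        np.minimum(step * eta_plus, delta_max),
        np.where(sign_product < 0, np.maximum(step * eta_minus, delta_min), step),
    )
    effective_grad = np.where(sign_product < 0, 0.0, grad)
    update = -np.sign(effective_grad) * step
    return update, effective_grad, step


def train_rprop(net: Network, X, T, config: TrainerConfig) -> Network:
    """Rprop- with full-batch gradients and per-weight adaptive steps."""
    X, T = _check_data(net, X, T)
    net = net.copy()
    theta = net.get_params()
    prev_grad = np.zeros_like(theta)
    step = np.full_like(theta, config.delta0)
    for _ in range(config.epochs):
        if mse(net, X, T) < config.mse_tol:
            break
        grad = gradient_vector(net, X, T)
        update, prev_grad, step = rprop_update(
            grad,
            prev_grad,
            step,
            eta_plus=config.eta_plus,
            eta_minus=config.eta_minus,
            delta_min=config.delta_min,
            delta_max=config.delta_max,
        )
        theta = theta + update
        net.set_params(theta)
    return net


def lm_step(net: Network, X, T, lam: float):
    """One Levenberg-Marquardt trial step at damping ``lam``.

    Solves ``(J^T J + lam I) delta = -J^T r`` for the residuals
    ``r = y - t`` and returns ``(candidate_params, candidate_sse)``, or
    ``(None, inf)`` if the damped normal matrix is singular.
    """
    X, T = _check_data(net, X, T)
    J = jacobian(net, X)
    r = net.forward_batch(X) - T
    H = J.T @ J + lam * np.eye(J.shape[1])
    g = J.T @ r
    try:
        delta = np.linalg.solve(H, -g)
    except np.linalg.LinAlgError:
        return None, float("inf")
    if not np.all(np.isfinite(delta)):
        return None, float("inf")
    candidate = net.get_params() + delta
    trial = net.copy()
    trial.set_params(candidate)
    r_new = trial.forward_batch(X) - T
    return candidate, float(r_new @ r_new)


def train_lm(
    net: Network, X, T, config: TrainerConfig, history: list | None = None
) -> Network:
    """Levenberg-Marquardt with multiplicative damping control.

    A step that increases the sum of squared errors is rejected and the
    damping multiplied by ``lambda_up`` (at most
    ``max_lambda_escalations`` retries per epoch, after which the epoch
    stalls and training stops); an accepted step multiplies the damping by
    ``lambda_down``, so accepted SSE values decrease strictly.  If a list
    is passed as ``history`` the SSE after each accepted step is appended
    to it (diagnostic hook).
    """
    X, T = _check_data(net, X, T)
    net = net.copy()
    lam = config.lambda0
    r = net.forward_batch(X) - T
    sse = float(r @ r)
    n = X.shape[0]
    for _ in range(config.epochs):
        if sse / n < config.mse_tol:
            break
        accepted = False
        for _attempt in range(config.max_lambda_escalations + 1):
            candidate, sse_new = lm_step(net, X, T, lam)
            if candidate is not None and sse_new < sse:
                net.set_params(candidate)
                sse = sse_new
                if history is not None:
                    history.append(sse)
                lam = max(lam * config.lambda_down, 1e-12)
                accepted = True
                break
            lam *= config.lambda_up
        if not accepted:
            break  # stalled: no damping level improved the SSE
    return net


_TRAINERS = {
    "error_correction": train_error_correction,
    "backprop": train_backprop,
    "rprop": train_rprop,
    "levenberg_marquardt": train_lm,
}


def train(net: Network, X, T, config: TrainerConfig) -> Network:
    """Dispatch to the configured training algorithm."""
    return _TRAINERS[config.algorithm](net, X, T, config)


# ---------------------------------------------------------------------------
# Serialization


def save_network(net: Network, path) -> None:
    payload = {
        "layer_sizes": list(net.layer_sizes),
        "activation": net.activation,
        "weights": [w.tolist() for w in net.weights],
        "biases": [b.tolist() for b in net.biases],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_network(path) -> Network:
    with open(path) as fh:
        payload = json.load(fh)
    return Network(
        tuple(payload["layer_sizes"]),
        [np.asarray(w, dtype=float) for w in payload["weights"]],
        [np.asarray(b, dtype=float) for b in payload["biases"]],
        payload["activation"],
    )
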