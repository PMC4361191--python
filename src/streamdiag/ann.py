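"""Small feed-forward neural network with batch Levenberg-Marquardt training.

The default architecture is the one used throughout the pipeline: 9 external
inputs -> 6 tan-sigmoid neurons -> 3 tan-sigmoid neurons -> 1 linear output
neuron. Each neuron computes ``f(sum_i w_i x_i + b)``; the linear output is
unbounded, and the network is trained to emit 1 (low stress) or 2 (high
stress), so the output's proximity to either value carries confidence
information.

Training minimises the mean squared error of the residuals ``e = yhat - y``
in batch mode with Levenberg-Marquardt: the Jacobian J of the network
outputs with respect to the flattened parameter vector is computed by
backpropagation, and each step solves ``(J'J + mu*I) delta = -J'e``. The
damping parameter mu shrinks (x0.1) after an accepted step and grows (x10)
when a step would increase the MSE; the step is retried until it improves or
mu exceeds a ceiling (1e10), at which point training stops unconverged.
Training stops successfully as soon as the MSE reaches the goal (default
0.2 — deliberately loose, to avoid overfitting tiny training sets).

A plain gradient-descent trainer with momentum and an adaptive learning
rate is available via ``train(..., method="gdm")`` as a secondary mode.

Inputs are integer codes in [-2, +3] and are fed without rescaling: they
already sit inside the weakly non-linear range (about -3 to +3) of the
tan-sigmoid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InferenceError, NumericalError

__all__ = [
    "Network",
    "TrainingState",
    "tansig",
    "forward",
    "forward_batch",
    "init_network",
    "train",
    "network_to_json",
    "network_from_json",
    "mse_gradient",
]

MU_INIT = 1e-3
MU_DEC = 0.1
MU_INC = 10.0
MU_MAX = 1e10


def tansig(z):
    """Tangent-sigmoid transfer function 2/(1 + e^(-2z)) - 1, in (-1, 1)."""
    z = np.asarray(z, dtype=float)
    with np.errstate(over="ignore"):
        out = 2.0 / (1.0 + np.exp(-2.0 * z)) - 1.0
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Network:
    """Weights and biases of a feed-forward net; transfer per layer."""

    weights: tuple[np.ndarray, ...]  # (n_1 x n_in), (n_2 x n_1), (1 x n_2)
    biases: tuple[np.ndarray, ...]
    transfer: tuple[str, ...] = ("tansig", "tansig", "linear")
    seed: int | None = None

    def __post_init__(self):
        if len(self.weights) != len(self.biases) or len(self.weights) != len(self.transfer):
            raise InferenceError("inconsistent layer counts")
        prev = self.n_inputs
        for w, b in zip(self.weights, self.biases):
            if w.ndim != 2 or b.ndim != 1 or w.shape[0] != b.shape[0] or w.shape[1] != prev:
                raise InferenceError(f"inconsistent layer shapes: {w.shape}, {b.shape}")
            if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
                raise NumericalError("non-finite network parameters")
            prev = w.shape[0]
        if self.transfer[-1] != "linear":
            raise InferenceError("output layer must use the linear transfer")

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[1]

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return tuple(w.shape[0] for w in self.weights)

    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))


@dataclass(frozen=True)
class TrainingState:
    epoch: int
    mse: float
    mu: float
    converged: bool
    failed: bool = field(default=False)


def init_network(
    seed: int, scale: float = 0.5, n_inputs: int = 9, hidden: tuple[int, ...] = (6, 3)
) -> Network:
    """Random network: weights and biases uniform on [-scale, +scale]."""
    rng = np.random.default_rng(seed)
    sizes = (n_inputs, *hidden, 1)
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.uniform(-scale, scale, (fan_out, fan_in)))
        biases.append(rng.uniform(-scale, scale, fan_out))
    transfer = ("tansig",) * len(hidden) + ("linear",)
    return Network(tuple(weights), tuple(biases), transfer, seed=seed)


def _activations(net: Network, X: np.ndarray) -> list[np.ndarray]:
    """Per-layer activations for a batch; X is (n, n_inputs)."""
    acts = [X]
    a = X
    for w, b, tf in zip(net.weights, net.biases, net.transfer):
        z = a @ w.T + b
        a = tansig(z) if tf == "tansig" else z
        acts.append(a)
    return acts


def forward_batch(net: Network, X) -> np.ndarray:
    """Network outputs for an (n, n_inputs) batch; returns shape (n,)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != net.n_inputs:
        raise InferenceError(
            f"expected (n, {net.n_inputs}) inputs, got shape {X.shape}"
        )
    if not np.all(np.isfinite(X)):
        raise InferenceError("non-finite network input")
    return _activations(net, X)[-1][:, 0]


def forward(net: Network, x) -> float:
    """Single-record forward pass; pure function of (net, x)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] != net.n_inputs:
        raise InferenceError(f"expected {net.n_inputs} inputs, got shape {x.shape}")
    return float(forward_batch(net, x[None, :])[0])


def _pack(net: Network) -> np.ndarray:
    return np.concatenate(
        [np.concatenate([w.ravel(), b]) for w, b in zip(net.weights, net.biases)]
    )


def _unpack(theta: np.ndarray, template: Network) -> Network:
    weights, biases = [], []
    i = 0
    for w, b in zip(template.weights, template.biases):
        weights.append(theta[i : i + w.size].reshape(w.shape))
        i += w.size
        biases.append(theta[i : i + b.size])
        i += b.size
    return Network(tuple(weights), tuple(biases), template.transfer, seed=template.seed)


def _jacobian(net: Network, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Outputs and Jacobian d yhat / d theta via backpropagation.

    Returns ``(yhat (n,), J (n, n_params))`` with columns ordered exactly as
    ``_pack``: W1, b1, W2, b2, ..., row-major.
    """
    acts = _activations(net, X)
    yhat = acts[-1][:, 0]
    n = X.shape[0]
    L = len(net.weights)
    # delta[l] = d yhat / d z_l, shape (n, size_l); output layer is linear.
    deltas: list[np.ndarray] = [None] * L
    deltas[L - 1] = np.ones((n, 1))
    for l in range(L - 2, -1, -1):
        back = deltas[l + 1] @ net.weights[l + 1]  # (n, size_l)
        if net.transfer[l] == "tansig":
            back = back * (1.0 - acts[l + 1] ** 2)
        deltas[l] = back
    blocks = []
    for l in range(L):
        # d yhat / d W_l[i, j] = delta_l[:, i] * a_{l-1}[:, j]
        blocks.append((deltas[l][:, :, None] * acts[l][:, None, :]).reshape(n, -1))
        blocks.append(deltas[l])
    return yhat, np.concatenate(blocks, axis=1)


def mse_gradient(net: Network, X, y) -> np.ndarray:
    """Gradient of the MSE with respect to the flattened parameter vector."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    yhat, J = _jacobian(net, X)
    e = yhat - y
    return 2.0 * (J.T @ e) / len(y)


def _check_training_inputs(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise InferenceError(f"incompatible training shapes {X.shape}, {y.shape}")
    if X.shape[0] < 2:
        raise InferenceError("need at least 2 training records")
    return X, y


def _mse(e: np.ndarray) -> float:
    m = float(np.mean(e * e))
    if not np.isfinite(m):
        raise NumericalError("non-finite residuals during training")
    return m


def train(
    net: Network,
    X,
    y,
    goal: float = 0.2,
    max_epochs: int = 1000,
    method: str = "lm",
    **kwargs,
) -> tuple[Network, TrainingState]:
    """Batch-train ``net`` on (X, y) until MSE <= goal or max_epochs.

    Never raises on non-convergence: inspect ``state.converged`` (goal
    reached) and ``state.failed`` (damping ceiling hit / learning-rate
    underflow). An epoch is one accepted parameter update.
    """
    if method == "lm":
        return _train_lm(net, X, y, goal, max_epochs, **kwargs)
    if method == "gdm":
        return _train_gdm(net, X, y, goal, max_epochs, **kwargs)
    raise InferenceError(f"unknown training method {method!r}")


def _train_lm(
    net: Network,
    X,
    y,
    goal: float,
    max_epochs: int,
    mu_init: float = MU_INIT,
    mu_max: float = MU_MAX,
) -> tuple[Network, TrainingState]:
    X, y = _check_training_inputs(X, y)
    theta = _pack(net)
    yhat, J = _jacobian(net, X)
    mse = _mse(yhat - y)
    mu = mu_init
    if mse <= goal:
        return net, TrainingState(epoch=0, mse=mse, mu=mu, converged=True)
    eye = np.eye(theta.size)
    for epoch in range(1, max_epochs + 1):
        e = yhat - y
        g = J.T @ e
        H = J.T @ J
        accepted = False
        while not accepted:
            try:
                delta = np.linalg.solve(H + mu * eye, -g)
                theta_new = theta + delta
                net_new = _unpack(theta_new, net)
                yhat_new = forward_batch(net_new, X)
                mse_new = _mse(yhat_new - y)
                ok = mse_new < mse
            except (np.linalg.LinAlgError, NumericalError):
                ok = False
            if ok:
                theta, net, mse = theta_new, net_new, mse_new
                mu = max(mu * MU_DEC, 1e-20)
                accepted = True
            else:
                mu *= MU_INC
                if mu > mu_max:
                    return net, TrainingState(
                        epoch=epoch - 1, mse=mse, mu=mu, converged=False, failed=True
                    )
        if mse <= goal:
            return net, TrainingState(epoch=epoch, mse=mse, mu=mu, converged=True)
        yhat, J = _jacobian(net, X)
    return net, TrainingState(epoch=max_epochs, mse=mse, mu=mu, converged=False)


def _train_gdm(
    net: Network,
    X,
    y,
    goal: float,
    max_epochs: int,
    lr: float = 0.01,
    momentum: float = 0.9,
    lr_inc: float = 1.05,
    lr_dec: float = 0.7,
    max_perf_inc: float = 1.04,
) -> tuple[Network, TrainingState]:
    """Gradient descent with momentum and adaptive learning rate."""
    X, y = _check_training_inputs(X, y)
    theta = _pack(net)
    mse = _mse(forward_batch(net, X) - y)
    if mse <= goal:
        return net, TrainingState(epoch=0, mse=mse, mu=lr, converged=True)
    velocity = np.zeros_like(theta)
    for epoch in range(1, max_epochs + 1):
        g = mse_gradient(_unpack(theta, net), X, y)
        velocity = momentum * velocity - lr * g
        theta_new = theta + velocity
        net_new = _unpack(theta_new, net)
        mse_new = _mse(forward_batch(net_new, X) - y)
        if mse_new > max_perf_inc * mse:
            lr *= lr_dec
            velocity[:] = 0.0
            if lr < 1e-12:
                return _unpack(theta, net), TrainingState(
                    epoch=epoch - 1, mse=mse, mu=lr, converged=False, failed=True
                )
            continue
        if mse_new < mse:
            lr *= lr_inc
        theta, mse = theta_new, mse_new
        if mse <= goal:
            return _unpack(theta, net), TrainingState(
                epoch=epoch, mse=mse, mu=lr, converged=True
            )
    return _unpack(theta, net), TrainingState(
        epoch=max_epochs, mse=mse, mu=lr, converged=False
    )


def network_to_json(net: Network) -> str:
    """Serialize to JSON with weights as 17-significant-digit decimal strings.

    17 significant digits round-trip IEEE doubles exactly, so
    ``network_from_json(network_to_json(net))`` is bit-identical.
    """
    doc = {
        "n_inputs": net.n_inputs,
        "layer_sizes": list(net.layer_sizes),
        "transfer": list(net.transfer),
        "seed": net.seed,
        "weights": [[format(v, ".17g") for v in w.ravel()] for w in net.weights],
        "biases": [[format(v, ".17g") for v in b] for b in net.biases],
    }
    return json.dumps(doc, sort_keys=True)


def network_from_json(text: str) -> Network:
    doc = json.loads(text)
    sizes = [doc["n_inputs"], *doc["layer_sizes"]]
    weights = tuple(
        np.array([float(v) for v in flat]).reshape(fan_out, fan_in)
        for flat, fan_in, fan_out in zip(doc["weights"], sizes[:-1], sizes[1:])
    )
    biases = tuple(np.array([float(v) for v in b]) for b in doc["biases"])
    return Network(weights, biases, tuple(doc["transfer"]), seed=doc.get("seed"))
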