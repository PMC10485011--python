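"""Semi-supervised graph convolutional network over a patient-similarity graph.

Layers propagate node features through the fixed normalized adjacency before
a learned linear map and ReLU: L[k+1] = relu(A_norm @ L[k] @ W[k]); the final
layer is a 2-class softmax head. Training minimizes masked binary
cross-entropy plus an L2 weight penalty, optimized with Adam. Gradients are
computed analytically in numpy (no autodiff dependency), which keeps runs
bit-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import SampleGraph

__all__ = [
    "GCNConfig",
    "GCNModel",
    "init_model",
    "gcn_forward",
    "gcn_loss",
    "loss_and_grads",
    "train_gcn",
    "extract_embeddings",
]

_EPS = 1e-12


@dataclass
class GCNConfig:
    """Architecture and optimization settings."""

    hidden_sizes: tuple[int, ...] = (200, 150, 100)
    epochs: int = 200
    learning_rate: float = 0.001
    l2_coeff: float = 5e-4
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if not self.hidden_sizes:
            raise ValueError("hidden_sizes must be nonempty")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.l2_coeff < 0:
            raise ValueError("l2_coeff must be nonnegative")
        if self.epochs < 0:
            raise ValueError("epochs must be nonnegative")


@dataclass
class GCNModel:
    """Weight matrices chaining input -> hidden... -> 2 output classes."""

    weights: list[np.ndarray]
    activations: list[np.ndarray] = field(default_factory=list, repr=False)

    @property
    def n_hidden(self) -> int:
        return len(self.weights) - 1


def init_model(n_features: int, config: GCNConfig) -> GCNModel:
    """Seeded Glorot-uniform initialization."""
    rng = np.random.default_rng(config.seed)
    sizes = (n_features, *config.hidden_sizes, 2)
    weights = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
    return GCNModel(weights=weights)


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    e = np.exp(Z)
    return e / e.sum(axis=1, keepdims=True)


def gcn_forward(
    graph: SampleGraph, model: GCNModel
) -> tuple[list[np.ndarray], np.ndarray]:
    """Run the forward pass; returns (per-layer activations, class probabilities).

    activations[0] is the input feature matrix, activations[k] the kth hidden
    layer; probabilities are the row-wise softmax of the output layer.
    """
    if graph.X is None:
        raise ValueError("graph has no node feature matrix")
    H = np.asarray(graph.X, dtype=float)
    if H.shape[1] != model.weights[0].shape[0]:
        raise ValueError(
            f"feature width {H.shape[1]} does not match W[0] rows "
            f"{model.weights[0].shape[0]}"
        )
    A = graph.A_norm
    acts = [H]
    for W in model.weights[:-1]:
        H = np.maximum(A @ H @ W, 0.0)
        acts.append(H)
    probs = _softmax(A @ H @ model.weights[-1])
    model.activations = acts
    return acts, probs


def gcn_loss(
    y_true: np.ndarray,
    y_prob: np.ndarray,
    model: GCNModel,
    l2_coeff: float = 0.0,
    mask: np.ndarray | None = None,
) -> float:
    """Masked mean binary cross-entropy plus (l2/2) * sum of squared weights.

    ``y_prob`` may be the full (n, 2) softmax output or the class-1 column;
    ``mask`` selects the labeled (training) nodes.
    """
    y_true = np.asarray(y_true)
    p1 = np.asarray(y_prob)
    if p1.ndim == 2:
        p1 = p1[:, 1]
    if mask is not None:
        mask = np.asarray(mask)
        if mask.dtype == bool:
            mask = np.flatnonzero(mask)
        if mask.size == 0:
            raise ValueError("empty training mask")
        y_true = y_true[mask]
        p1 = p1[mask]
    if y_true.size == 0:
        raise ValueError("no labeled nodes to evaluate the loss on")
    p1 = np.clip(p1, _EPS, 1.0 - _EPS)
    ce = -np.mean(y_true * np.log(p1) + (1 - y_true) * np.log(1 - p1))
    reg = 0.5 * l2_coeff * sum(float(np.sum(W * W)) for W in model.weights)
    return float(ce + reg)


def loss_and_grads(
    graph: SampleGraph,
    model: GCNModel,
    y: np.ndarray,
    mask: np.ndarray,
    l2_coeff: float,
) -> tuple[float, list[np.ndarray]]:
    """Loss plus analytic gradients w.r.t. every weight matrix.

    With a 2-class softmax head, the masked BCE gradient at the output
    logits is (P - Y_onehot) / n_labeled on masked rows and 0 elsewhere.
    ReLU is back-propagated through the cached pre-activation signs, and the
    symmetric A_norm is its own transpose.
    """
    mask = np.asarray(mask)
    if mask.dtype == bool:
        mask = np.flatnonzero(mask)
    if mask.size == 0:
        raise ValueError("empty training mask")
    acts, probs = gcn_forward(graph, model)
    loss = gcn_loss(y[mask], probs[mask], model, l2_coeff=l2_coeff)

    A = graph.A_norm
    n_lab = mask.size
    Y = np.zeros_like(probs)
    Y[np.arange(len(y)), np.asarray(y, dtype=int)] = 1.0
    dZ = np.zeros_like(probs)
    dZ[mask] = (probs[mask] - Y[mask]) / n_lab

    grads: list[np.ndarray] = [np.empty(0)] * len(model.weights)
    # output layer: logits = A @ acts[-1] @ W[-1]
    grads[-1] = (A @ acts[-1]).T @ dZ + l2_coeff * model.weights[-1]
    dH = A @ (dZ @ model.weights[-1].T)
    for k in range(len(model.weights) - 2, -1, -1):
        dPre = dH * (acts[k + 1] > 0)
        grads[k] = (A @ acts[k]).T @ dPre + l2_coeff * model.weights[k]
        if k > 0:
            dH = A @ (dPre @ model.weights[k].T)
    return loss, grads


def train_gcn(
    graph: SampleGraph,
    y: np.ndarray,
    train_mask: np.ndarray,
    config: GCNConfig,
) -> tuple[GCNModel, np.ndarray]:
    """Adam training on the masked loss; returns (model, per-epoch loss trace).

    Deterministic given the seed: fixed Glorot init and a fixed update
    order. Labels outside ``train_mask`` are never read.
    """
    model = init_model(graph.X.shape[1], config)
    if config.epochs == 0:
        return model, np.empty(0)

    y = np.asarray(y, dtype=int)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m = [np.zeros_like(W) for W in model.weights]
    v = [np.zeros_like(W) for W in model.weights]
    trace = np.empty(config.epochs)
    for epoch in range(config.epochs):
        loss, grads = loss_and_grads(graph, model, y, train_mask, config.l2_coeff)
        if not np.isfinite(loss):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        trace[epoch] = loss
        t = epoch + 1
        for k, g in enumerate(grads):
            m[k] = beta1 * m[k] + (1 - beta1) * g
            v[k] = beta2 * v[k] + (1 - beta2) * g * g
            m_hat = m[k] / (1 - beta1**t)
            v_hat = v[k] / (1 - beta2**t)
            model.weights[k] -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
    return model, trace


def extract_embeddings(graph: SampleGraph, model: GCNModel) -> np.ndarray:
    """Last hidden-layer activations for every node (labeled or not)."""
    acts, _ = gcn_forward(graph, model)
    return acts[-1]
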