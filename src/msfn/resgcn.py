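"""Residual graph-convolutional branch over the patient similarity network.

Message passing uses the renormalized adjacency
``D^{-1/2} (A + I) D^{-1/2}`` (self-loops plus symmetric degree
normalization). The first layer projects the concatenated omics features to
the hidden width; every later layer is a residual block
``H <- relu(A_hat H W + b) + H``, so a zero-weight block is exactly the
identity and depth does not strangle gradient flow. A fusion layer (dense
over the concatenation of all block outputs) produces the patient-similarity
feature representation F_PSN; a linear head on top yields the 2-class
logits. Training is transductive: every patient participates in propagation,
but the cross-entropy is masked to training patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import FeatureBlock, LabelVector
from .nn import Adam, cross_entropy_grad, dropout_mask, glorot_uniform, relu


@dataclass
class GraphInput:
    adjacency: np.ndarray
    node_features: np.ndarray
    patient_ids: np.ndarray
    train_mask: np.ndarray
    val_mask: np.ndarray | None = None
    test_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(A, A.T, atol=1e-8):
            raise ValueError("adjacency must be symmetric")
        if self.node_features.shape[0] != A.shape[0]:
            raise ValueError("node feature rows must match adjacency size")
        for other in (self.val_mask, self.test_mask):
            if other is not None and (self.train_mask & other).any():
                raise ValueError("masks must be disjoint")


@dataclass
class ResGCNConfig:
    n_layers: int = 2
    hidden_dim: int = 64
    fusion_dim: int = 64
    learning_rate: float = 0.01
    weight_decay: float = 5e-4
    epochs: int = 300
    dropout: float = 0.5
    patience: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("need at least one graph layer")


@dataclass
class TrainedResGCN:
    params: dict[str, np.ndarray]
    config: ResGCNConfig
    history: list[float] = field(default_factory=list)


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Self-loop renormalization ``D^{-1/2} (A + I) D^{-1/2}``.

    The output is symmetric with spectral radius at most 1.
    """
    A = np.asarray(A, dtype=float)
    if A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("adjacency must be symmetric")
    if (A < 0).any():
        raise ValueError("adjacency must be nonnegative")
    A_tilde = A + np.eye(len(A))
    d = A_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return A_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]


def init_params(config: ResGCNConfig, n_input: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(config.seed)
    h, fd = config.hidden_dim, config.fusion_dim
    params: dict[str, np.ndarray] = {
        "W1": glorot_uniform(rng, (n_input, h), n_input, h),
        "b1": np.zeros(h),
    }
    for layer in range(2, config.n_layers + 1):
        params[f"W{layer}"] = glorot_uniform(rng, (h, h), h, h)
        params[f"b{layer}"] = np.zeros(h)
    concat = config.n_layers * h
    params["Wf"] = glorot_uniform(rng, (concat, fd), concat, fd)
    params["bf"] = np.zeros(fd)
    params["Wo"] = glorot_uniform(rng, (fd, 2), fd, 2)
    params["bo"] = np.zeros(2)
    return params


def _forward(
    params: dict[str, np.ndarray],
    A_hat: np.ndarray,
    X: np.ndarray,
    n_layers: int,
    drop: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    cache: dict[str, np.ndarray] = {}
    pre = A_hat @ X @ params["W1"] + params["b1"]
    H = relu(pre)
    cache["pre1"], cache["H1"] = pre, H
    for layer in range(2, n_layers + 1):
        pre = A_hat @ H @ params[f"W{layer}"] + params[f"b{layer}"]
        H = relu(pre) + H
        cache[f"pre{layer}"], cache[f"H{layer}"] = pre, H
    concat = np.concatenate([cache[f"H{l}"] for l in range(1, n_layers + 1)], axis=1)
    cache["concat"] = concat
    fpre = concat @ params["Wf"] + params["bf"]
    fusion = relu(fpre)
    cache["fpre"], cache["fusion"] = fpre, fusion
    fused = fusion if drop is None else fusion * drop
    cache["fused"] = fused
    cache["logits"] = fused @ params["Wo"] + params["bo"]
    return cache


def resgcn_forward(
    graph: GraphInput, model: TrainedResGCN
) -> tuple[np.ndarray, np.ndarray]:
    """Inference pass: (n x 2 logits, n x fusion_dim fusion features)."""
    A_hat = normalize_adjacency(graph.adjacency)
    if graph.node_features.shape[1] != model.params["W1"].shape[0]:
        raise ValueError("feature dimension does not match the trained model")
    cache = _forward(model.params, A_hat, graph.node_features, model.config.n_layers)
    return cache["logits"], cache["fusion"]


def train_resgcn(
    graph: GraphInput, labels: LabelVector, config: ResGCNConfig
) -> TrainedResGCN:
    """Fit the branch by masked cross-entropy with Adam; seeded, full-batch."""
    if not graph.train_mask.any():
        raise ValueError("empty training mask")
    y = np.asarray(labels.label, dtype=int)
    if len(np.unique(y[graph.train_mask])) < 2:
        raise ValueError("training labels contain a single class")
    A_hat = normalize_adjacency(graph.adjacency)
    X = graph.node_features
    params = init_params(config, X.shape[1])
    opt = Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    weight = graph.train_mask.astype(float)
    n_layers = config.n_layers

    history: list[float] = []
    best_val, best_params, patience_left = np.inf, None, config.patience
    for _ in range(config.epochs):
        drop = dropout_mask(rng, (X.shape[0], config.fusion_dim), config.dropout)
        cache = _forward(params, A_hat, X, n_layers, drop)
        loss, dlogits = cross_entropy_grad(cache["logits"], y, weight)
        history.append(loss)

        grads: dict[str, np.ndarray] = {}
        grads["Wo"] = cache["fused"].T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dfusion = (dlogits @ params["Wo"].T) * drop
        dfpre = dfusion * (cache["fpre"] > 0)
        grads["Wf"] = cache["concat"].T @ dfpre
        grads["bf"] = dfpre.sum(axis=0)
        dconcat = dfpre @ params["Wf"].T
        h = config.hidden_dim
        d_direct = [
            dconcat[:, (l - 1) * h : l * h] for l in range(1, n_layers + 1)
        ]
        g = d_direct[-1]
        for layer in range(n_layers, 1, -1):
            dpre = g * (cache[f"pre{layer}"] > 0)
            H_prev = cache[f"H{layer - 1}"]
            grads[f"W{layer}"] = (A_hat @ H_prev).T @ dpre
            grads[f"b{layer}"] = dpre.sum(axis=0)
            g = A_hat @ (dpre @ params[f"W{layer}"].T) + g  # residual passthrough
            g = g + d_direct[layer - 2]
        dpre = g * (cache["pre1"] > 0)
        grads["W1"] = (A_hat @ X).T @ dpre
        grads["b1"] = dpre.sum(axis=0)

        for key in params:
            if key.startswith("W"):
                grads[key] = grads[key] + config.weight_decay * params[key]
        opt.step(grads)

        if graph.val_mask is not None and graph.val_mask.any():
            eval_cache = _forward(params, A_hat, X, n_layers)
            val_loss, _ = cross_entropy_grad(
                eval_cache["logits"], y, graph.val_mask.astype(float)
            )
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in params.items()}
                patience_left = config.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
    if best_params is not None:
        params = best_params
    return TrainedResGCN(params=params, config=config, history=history)


def extract_psn_features(model: TrainedResGCN, graph: GraphInput) -> FeatureBlock:
    """Fusion-layer activations for every node: the F_PSN block."""
    _, fusion = resgcn_forward(graph, model)
    return FeatureBlock(values=fusion, source="PSN", patient_ids=graph.patient_ids)
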