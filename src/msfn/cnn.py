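"""Per-view 1-D convolutional branch extracting view-specific features.

Architecture per view: input row -> single-channel 1-D convolution with
same-padding (glorot-initialized kernels) -> flatten -> fully connected
layer (150 units by default) -> 2-class output. Dropout on the dense layer
and an L2 penalty regularize training. The dense-layer activations are the
view's specificity feature block (F_Clin / F_Expr / F_CNV).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import FeatureBlock, LabelVector, OmicsBlock
from .nn import (
    Adam,
    conv1d_same,
    conv1d_same_backward,
    cross_entropy_grad,
    dropout_mask,
    glorot_uniform,
    relu,
)

_SOURCE_BY_VIEW = {"clinical": "Clin", "expression": "Expr", "cnv": "CNV"}


@dataclass
class CNNConfig:
    n_filters: int = 32
    kernel_size: int = 5
    fc_units: int = 150
    dropout: float = 0.5
    l2_penalty: float = 1e-4
    epochs: int = 100
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_units < 1:
            raise ValueError("fc_units must be >= 1")


@dataclass
class TrainedCNN:
    params: dict[str, np.ndarray]
    config: CNNConfig
    n_features: int
    history: list[float] = field(default_factory=list)
    #: dense-layer activations on the training block at the final parameters
    train_activations: np.ndarray | None = None


def _forward(params: dict[str, np.ndarray], X: np.ndarray, drop: np.ndarray | None = None):
    feat, patches = conv1d_same(X, params["K"], params["bk"])
    act = relu(feat)
    flat = act.reshape(len(X), -1)
    dpre = flat @ params["W1"] + params["b1"]
    dense = relu(dpre)
    dense_used = dense if drop is None else dense * drop
    logits = dense_used @ params["W2"] + params["b2"]
    return {
        "patches": patches, "feat": feat, "flat": flat, "dpre": dpre,
        "dense": dense, "dense_used": dense_used, "logits": logits,
    }


def train_cnn(block: OmicsBlock, labels: LabelVector, config: CNNConfig) -> TrainedCNN:
    """Fit one convolutional branch on a view; seeded and full-batch."""
    if not np.array_equal(block.patient_ids, labels.patient_ids):
        raise ValueError("block and labels must be aligned")
    if block.has_missing():
        raise ValueError("view contains missing values")
    y = labels.label
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    X = block.values
    n, f = X.shape
    ksize = min(config.kernel_size, f)  # narrow views shrink the kernel
    c = config.n_filters

    rng = np.random.default_rng(config.seed)
    params: dict[str, np.ndarray] = {
        "K": glorot_uniform(rng, (ksize, c), ksize, c),
        "bk": np.zeros(c),
        "W1": glorot_uniform(rng, (f * c, config.fc_units), f * c, config.fc_units),
        "b1": np.zeros(config.fc_units),
        "W2": glorot_uniform(rng, (config.fc_units, 2), config.fc_units, 2),
        "b2": np.zeros(2),
    }
    opt = Adam(params, lr=config.learning_rate)
    history: list[float] = []
    for _ in range(config.epochs):
        drop = dropout_mask(rng, (n, config.fc_units), config.dropout)
        cache = _forward(params, X, drop)
        loss, dlogits = cross_entropy_grad(cache["logits"], y)
        l2 = config.l2_penalty
        loss += l2 * sum(
            float((params[k] ** 2).sum()) for k in ("K", "W1", "W2")
        )
        history.append(loss)

        grads: dict[str, np.ndarray] = {}
        grads["W2"] = cache["dense_used"].T @ dlogits
        grads["b2"] = dlogits.sum(axis=0)
        ddense = (dlogits @ params["W2"].T) * drop
        ddpre = ddense * (cache["dpre"] > 0)
        grads["W1"] = cache["flat"].T @ ddpre
        grads["b1"] = ddpre.sum(axis=0)
        dflat = ddpre @ params["W1"].T
        dact = dflat.reshape(n, f, c) * (cache["feat"] > 0)
        _, grads["K"], grads["bk"] = conv1d_same_backward(
            dact, cache["patches"], params["K"], f
        )
        for key in ("K", "W1", "W2"):
            grads[key] = grads[key] + 2.0 * l2 * params[key]
        opt.step(grads)

    model = TrainedCNN(
        params=params,
        config=replace(config, kernel_size=ksize),
        n_features=f,
        history=history,
    )
    model.train_activations = _forward(params, X)["dense"]
    return model


def extract_cnn_features(model: TrainedCNN, block: OmicsBlock) -> FeatureBlock:
    """Dense-layer activations for each patient row (dropout disabled)."""
    if block.n_features != model.n_features:
        raise ValueError("feature count does not match the trained model")
    cache = _forward(model.params, block.values)
    source = _SOURCE_BY_VIEW.get(block.view_kind, "Expr")
    return FeatureBlock(
        values=cache["dense"], source=source, patient_ids=block.patient_ids
    )
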