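"""Graph-branch identities: renormalization closed forms, residual identity,
permutation equivariance, gradient correctness and training behaviour."""

import numpy as np
import pytest

from msfn.datatypes import LabelVector
from msfn.nn import cross_entropy_grad
from msfn.resgcn import (
    GraphInput,
    ResGCNConfig,
    TrainedResGCN,
    _forward,
    extract_psn_features,
    init_params,
    normalize_adjacency,
    resgcn_forward,
    train_resgcn,
)


class TestNormalizeAdjacency:
    def test_empty_graph_gives_identity(self):
        np.testing.assert_allclose(normalize_adjacency(np.zeros((3, 3))), np.eye(3))

    def test_two_node_closed_form(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(normalize_adjacency(A), np.full((2, 2), 0.5))

    def test_three_node_path_closed_form(self):
        # path 0-1-2: degrees of A+I are (2, 3, 2)
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        expected = np.array(
            [
                [1 / 2, 1 / np.sqrt(6), 0],
                [1 / np.sqrt(6), 1 / 3, 1 / np.sqrt(6)],
                [0, 1 / np.sqrt(6), 1 / 2],
            ]
        )
        np.testing.assert_allclose(normalize_adjacency(A), expected, atol=1e-12)

    def test_spectral_radius_at_most_one(self, rng):
        for _ in range(50):
            n = rng.integers(3, 12)
            A = np.abs(rng.random((n, n)))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 0.0)
            eig = np.linalg.eigvalsh(normalize_adjacency(A))
            assert np.abs(eig).max() <= 1 + 1e-10

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            normalize_adjacency(np.array([[0.0, 1.0], [0.0, 0.0]]))


def small_graph(rng, n=12, d=5):
    A = np.abs(rng.random((n, n)))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0.0)
    X = rng.standard_normal((n, d))
    mask = np.zeros(n, dtype=bool)
    mask[: n // 2] = True
    return GraphInput(A, X, np.array([f"P{i}" for i in range(n)], dtype=object), mask)


def test_zero_weight_residual_blocks_are_identity(rng):
    """With zeroed residual weights each block maps its input to itself."""
    graph = small_graph(rng)
    config = ResGCNConfig(n_layers=3, hidden_dim=8, fusion_dim=4, seed=0)
    params = init_params(config, 5)
    for layer in (2, 3):
        params[f"W{layer}"][:] = 0.0
        params[f"b{layer}"][:] = 0.0
    A_hat = normalize_adjacency(graph.adjacency)
    cache = _forward(params, A_hat, graph.node_features, 3)
    np.testing.assert_array_equal(cache["H2"], cache["H1"])
    np.testing.assert_array_equal(cache["H3"], cache["H1"])


def test_isolated_node_equals_plain_mlp(rng):
    """With no edges the renormalized adjacency is I: graph layers reduce to
    dense layers evaluated row-wise."""
    n, d = 1, 4
    X = rng.standard_normal((n, d))
    config = ResGCNConfig(n_layers=2, hidden_dim=6, fusion_dim=3, seed=1)
    params = init_params(config, d)
    graph = GraphInput(
        np.zeros((n, n)), X, np.array(["P0"], dtype=object), np.ones(n, dtype=bool)
    )
    model = TrainedResGCN(params=params, config=config)
    logits, fusion = resgcn_forward(graph, model)

    h1 = np.maximum(X @ params["W1"] + params["b1"], 0.0)
    h2 = np.maximum(h1 @ params["W2"] + params["b2"], 0.0) + h1
    fus = np.maximum(np.concatenate([h1, h2], axis=1) @ params["Wf"] + params["bf"], 0.0)
    np.testing.assert_allclose(fusion, fus, atol=1e-12)
    np.testing.assert_allclose(logits, fus @ params["Wo"] + params["bo"], atol=1e-12)


def test_permutation_equivariance(rng):
    graph = small_graph(rng)
    config = ResGCNConfig(n_layers=2, hidden_dim=8, fusion_dim=4, seed=3)
    model = TrainedResGCN(params=init_params(config, 5), config=config)
    logits, fusion = resgcn_forward(graph, model)
    perm = rng.permutation(len(graph.adjacency))
    graph_p = GraphInput(
        graph.adjacency[np.ix_(perm, perm)],
        graph.node_features[perm],
        graph.patient_ids[perm],
        graph.train_mask[perm],
    )
    logits_p, fusion_p = resgcn_forward(graph_p, model)
    np.testing.assert_allclose(logits_p, logits[perm], atol=1e-10)
    np.testing.assert_allclose(fusion_p, fusion[perm], atol=1e-10)


def test_gradients_match_finite_differences(rng):
    """One training step's gradient against central differences."""
    graph = small_graph(rng, n=8, d=3)
    y = rng.integers(0, 2, size=8)
    config = ResGCNConfig(
        n_layers=2, hidden_dim=4, fusion_dim=3, dropout=0.0, weight_decay=0.0, seed=0
    )
    params = init_params(config, 3)
    A_hat = normalize_adjacency(graph.adjacency)
    X = graph.node_features
    weight = graph.train_mask.astype(float)

    def loss_of(p):
        cache = _forward(p, A_hat, X, 2)
        loss, _ = cross_entropy_grad(cache["logits"], y, weight)
        return loss

    # analytic gradients (mirrors the training loop with dropout disabled)
    cache = _forward(params, A_hat, X, 2)
    _, dlogits = cross_entropy_grad(cache["logits"], y, weight)
    grads = {}
    grads["Wo"] = cache["fused"].T @ dlogits
    dfusion = dlogits @ params["Wo"].T
    dfpre = dfusion * (cache["fpre"] > 0)
    grads["Wf"] = cache["concat"].T @ dfpre
    dconcat = dfpre @ params["Wf"].T
    d1, d2 = dconcat[:, :4], dconcat[:, 4:]
    dpre2 = d2 * (cache["pre2"] > 0)
    grads["W2"] = (A_hat @ cache["H1"]).T @ dpre2
    g = A_hat @ (dpre2 @ params["W2"].T) + d2 + d1
    dpre1 = g * (cache["pre1"] > 0)
    grads["W1"] = (A_hat @ X).T @ dpre1

    eps = 1e-6
    for key in ("W1", "W2", "Wf", "Wo"):
        W = params[key]
        for idx in [(0, 0), (W.shape[0] - 1, W.shape[1] - 1)]:
            orig = W[idx]
            W[idx] = orig + eps
            up = loss_of(params)
            W[idx] = orig - eps
            down = loss_of(params)
            W[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert grads[key][idx] == pytest.approx(numeric, rel=1e-4, abs=1e-8)


class TestTraining:
    def _separable_graph(self, seed, n=60):
        rng = np.random.default_rng(seed)
        y = (np.arange(n) % 2).astype(int)
        X = rng.standard_normal((n, 6)) + 2.0 * y[:, None]
        same = y[:, None] == y[None, :]
        A = np.where(same, 0.8, 0.05) * rng.random((n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        mask = np.zeros(n, dtype=bool)
        mask[: int(0.7 * n)] = True
        ids = np.array([f"P{i}" for i in range(n)], dtype=object)
        return GraphInput(A, X, ids, mask), LabelVector(ids, y)

    def test_loss_decreases_early(self):
        for seed in range(5):
            graph, labels = self._separable_graph(seed)
            model = train_resgcn(
                graph, labels, ResGCNConfig(hidden_dim=8, fusion_dim=8, epochs=12, seed=seed)
            )
            assert model.history[9] < model.history[0]

    def test_two_layer_branch_fits_separable_cohort(self):
        graph, labels = self._separable_graph(0, n=80)
        model = train_resgcn(
            graph, labels,
            ResGCNConfig(n_layers=2, hidden_dim=16, fusion_dim=16, epochs=200, seed=0),
        )
        logits, _ = resgcn_forward(graph, model)
        preds = logits.argmax(axis=1)
        train_acc = (preds[graph.train_mask] == labels.label[graph.train_mask]).mean()
        assert train_acc > 0.9

    def test_same_seed_reproduces_weights(self):
        graph, labels = self._separable_graph(2)
        cfg = ResGCNConfig(hidden_dim=8, fusion_dim=8, epochs=20, seed=5)
        a = train_resgcn(graph, labels, cfg)
        b = train_resgcn(graph, labels, cfg)
        for key in a.params:
            np.testing.assert_array_equal(a.params[key], b.params[key])

    def test_single_class_training_labels_rejected(self):
        graph, labels = self._separable_graph(3)
        bad = LabelVector(labels.patient_ids, np.zeros(len(labels), dtype=int))
        with pytest.raises(ValueError):
            train_resgcn(graph, bad, ResGCNConfig(epochs=2))

    def test_feature_block_shape_and_duplicate_rows(self):
        graph, labels = self._separable_graph(4)
        cfg = ResGCNConfig(hidden_dim=8, fusion_dim=10, epochs=15, seed=1)
        model = train_resgcn(graph, labels, cfg)
        fb = extract_psn_features(model, graph)
        assert fb.values.shape == (len(labels), 10)
        assert fb.source == "PSN"
        # duplicate a node (same features, same neighbourhood) -> same row
        n = len(labels)
        A2 = np.zeros((n + 1, n + 1))
        A2[:n, :n] = graph.adjacency
        A2[n, :n] = graph.adjacency[0]
        A2[:n, n] = graph.adjacency[0]
        A2[n, 0] = A2[0, n] = 0.0
        A2[0, 0] = 0.0
        X2 = np.vstack([graph.node_features, graph.node_features[0]])
        ids2 = np.append(graph.patient_ids, "P_dup")
        g2 = GraphInput(A2, X2, ids2, np.zeros(n + 1, dtype=bool))
        fb2 = extract_psn_features(model, g2)
        np.testing.assert_allclose(fb2.values[n], fb2.values[0], atol=1e-10)
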