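"""GCN-LSTM: layer oracles, reshape contract, training behavior, serialization."""

import numpy as np
import pandas as pd
import pytest

from tinnigraph._autograd import Tensor
from tinnigraph.features import FeatureMatrix
from tinnigraph.graph import build_graph, normalize_adjacency
from tinnigraph.model import (GCNLSTM, ModelConfig, gcn_layer_forward,
                              load_model, lstm_forward, predict,
                              reshape_to_sequence, save_model, train)


def toy_graph(n_per_cluster=30, d=4, seed=0, sep=(0.2, 0.8), spread=0.03,
              epsilon=0.3):
    """Two epsilon-separated Gaussian clusters with distinct labels."""
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(sep[0], spread, (n_per_cluster, d)),
                   rng.normal(sep[1], spread, (n_per_cluster, d))])
    y = np.repeat([0, 1], n_per_cluster)
    fm = FeatureMatrix(X=X, y=y, feature_names=[f"f{i}" for i in range(d)],
                       provenance=pd.DataFrame())
    return build_graph(fm, epsilon=epsilon)


def dense_gcn_oracle(X, edges, W):
    """Explicit dense D^-1/2 (A + I) D^-1/2 X W with ReLU."""
    n = X.shape[0]
    A = np.zeros((n, n))
    for i, j in edges:
        A[i, j] = A[j, i] = 1.0
    A_hat = A + np.eye(n)
    d = A_hat.sum(axis=1)
    D_inv_sqrt = np.diag(1.0 / np.sqrt(d))
    out = D_inv_sqrt @ A_hat @ D_inv_sqrt @ X @ W
    return np.maximum(out, 0.0)


class TestGcnLayer:
    def test_isolated_nodes_give_relu_of_xw(self):
        g = toy_graph(1, d=2, epsilon=1e-9)  # two isolated nodes
        na = normalize_adjacency(g)
        x = Tensor(np.array([[-1.0, 2.0], [3.0, -4.0]]))
        out = gcn_layer_forward(x, na, Tensor(np.eye(2)))
        assert np.allclose(out.data, [[0.0, 2.0], [3.0, 0.0]])

    def test_zero_weights_annihilate(self, rng):
        g = toy_graph(5, epsilon=0.5)
        na = normalize_adjacency(g)
        out = gcn_layer_forward(Tensor(g.X), na, Tensor(np.zeros((4, 3))))
        assert np.all(out.data == 0)

    def test_matches_dense_oracle_on_random_graphs(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 20))
            d_in, d_out = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            X = rng.normal(size=(n, d_in))
            fm = FeatureMatrix(X=rng.random((n, 3)), y=np.zeros(n, dtype=int),
                               feature_names=["a", "b", "c"],
                               provenance=pd.DataFrame())
            g = build_graph(fm, epsilon=float(rng.uniform(0.2, 1.0)))
            na = normalize_adjacency(g)
            W = rng.normal(size=(d_in, d_out))
            out = gcn_layer_forward(Tensor(X), na, Tensor(W))
            assert np.allclose(out.data, dense_gcn_oracle(X, g.edges, W),
                               atol=1e-5)

    def test_shape_mismatch_rejected(self):
        g = toy_graph(3)
        na = normalize_adjacency(g)
        with pytest.raises(ValueError, match="mismatch"):
            gcn_layer_forward(Tensor(np.ones((6, 4))), na,
                              Tensor(np.ones((5, 2))))


class TestReshape:
    def test_round_trip(self, rng):
        x = Tensor(rng.normal(size=(5, 8)))
        steps = reshape_to_sequence(x, 4)
        assert len(steps) == 4 and steps[0].shape == (5, 2)
        assert np.array_equal(np.hstack([s.data for s in steps]), x.data)

    def test_single_step_identity(self, rng):
        x = Tensor(rng.normal(size=(3, 6)))
        steps = reshape_to_sequence(x, 1)
        assert np.array_equal(steps[0].data, x.data)

    def test_contiguous_chunks(self):
        x = Tensor(np.arange(1.0, 9.0).reshape(1, 8))
        steps = reshape_to_sequence(x, 2)
        assert np.array_equal(steps[0].data, [[1, 2, 3, 4]])
        assert np.array_equal(steps[1].data, [[5, 6, 7, 8]])

    def test_indivisible_width_rejected(self):
        with pytest.raises(ValueError):
            reshape_to_sequence(Tensor(np.ones((2, 7))), 4)
        with pytest.raises(ValueError):
            ModelConfig(gcn_dims=(64, 30), lstm_steps=4)


def manual_lstm_cell(x, h, c, wx, wh, b, H):
    """Independent scalar-level single-cell computation."""
    gates = x @ wx + h @ wh + b
    sig = lambda z: 1.0 / (1.0 + np.exp(-z))
    i = sig(gates[:, :H])
    f = sig(gates[:, H:2 * H])
    g = np.tanh(gates[:, 2 * H:3 * H])
    o = sig(gates[:, 3 * H:])
    c2 = f * c + i * g
    return o * np.tanh(c2), c2


class TestLstm:
    def test_zero_input_zero_bias_fixed_point(self):
        H = 3
        steps = [Tensor(np.zeros((4, 2))) for _ in range(5)]
        outs, h, c = lstm_forward(steps, Tensor(np.zeros((2, 4 * H))),
                                  Tensor(np.zeros((H, 4 * H))),
                                  Tensor(np.zeros(4 * H)), H)
        assert all(np.all(o.data == 0) for o in outs)
        assert np.all(h.data == 0) and np.all(c.data == 0)

    def test_single_step_matches_manual_cell(self, rng):
        H, n, din = 4, 3, 2
        x = rng.normal(size=(n, din))
        wx = rng.normal(size=(din, 4 * H))
        wh = rng.normal(size=(H, 4 * H))
        b = rng.normal(size=4 * H)
        outs, h, c = lstm_forward([Tensor(x)], Tensor(wx), Tensor(wh),
                                  Tensor(b), H)
        h_ref, c_ref = manual_lstm_cell(x, np.zeros((n, H)), np.zeros((n, H)),
                                        wx, wh, b, H)
        assert np.allclose(h.data, h_ref, atol=1e-12)
        assert np.allclose(c.data, c_ref, atol=1e-12)

    def test_hidden_state_bounded(self, rng):
        H = 4
        steps = [Tensor(rng.normal(size=(6, 3)) * 5) for _ in range(4)]
        outs, _, _ = lstm_forward(steps, Tensor(rng.normal(size=(3, 4 * H))),
                                  Tensor(rng.normal(size=(H, 4 * H))),
                                  Tensor(rng.normal(size=4 * H)), H)
        for o in outs:
            assert np.all(np.abs(o.data) < 1.0)


class TestForward:
    def test_logit_shape_and_determinism(self):
        g = toy_graph(10)
        na = normalize_adjacency(g)
        model = GCNLSTM(4, ModelConfig(seed=0))
        a, _ = model.forward(g.X, na)
        b, _ = model.forward(g.X, na)
        assert a.data.shape == (20, 2)
        assert np.array_equal(a.data, b.data)

    def test_permutation_equivariance(self, rng):
        g = toy_graph(8, seed=2)
        na = normalize_adjacency(g)
        model = GCNLSTM(4, ModelConfig(seed=0))
        logits, _ = model.forward(g.X, na)
        perm = rng.permutation(g.n_nodes)
        fm = FeatureMatrix(X=g.X[perm], y=g.y[perm],
                           feature_names=["a", "b", "c", "d"],
                           provenance=pd.DataFrame())
        g2 = build_graph(fm, epsilon=g.epsilon)
        logits2, _ = model.forward(g2.X, normalize_adjacency(g2))
        assert np.allclose(logits2.data, logits.data[perm], atol=1e-10)


class TestTraining:
    def test_separable_clusters_reach_full_train_accuracy(self):
        g = toy_graph()
        idx = np.arange(g.n_nodes)
        train_idx = idx[idx % 3 != 0]
        val_idx = idx[idx % 3 == 0]
        tm = train(g, train_idx, val_idx,
                   ModelConfig(max_epochs=200, patience=200, seed=1))
        assert max(tm.history["train_acc"]) == 1.0

    def test_training_deterministic(self):
        g = toy_graph()
        idx = np.arange(g.n_nodes)
        cfg = ModelConfig(max_epochs=30, patience=30, seed=3)
        a = train(g, idx[:40], idx[40:], cfg)
        b = train(g, idx[:40], idx[40:], cfg)
        for k in a.model.params:
            assert np.array_equal(a.model.params[k].data,
                                  b.model.params[k].data)
        assert a.history == b.history

    def test_loss_decreases_in_windowed_median(self):
        g = toy_graph()
        idx = np.arange(g.n_nodes)
        tm = train(g, idx[idx % 3 != 0], idx[idx % 3 == 0],
                   ModelConfig(max_epochs=150, patience=150, seed=1))
        loss = np.array(tm.history["train_loss"])
        early = np.median(loss[:50])
        late = np.median(loss[-50:])
        assert late < early

    def test_default_epoch_budget(self):
        assert ModelConfig().max_epochs == 1500

    def test_single_class_train_mask_rejected(self):
        g = toy_graph()
        with pytest.raises(ValueError, match="both classes"):
            train(g, np.arange(10), np.arange(10, 20), ModelConfig())

    def test_accuracy_increases_with_effect_size(self):
        """Held-out accuracy is monotone in cluster separation (3-point check)."""
        accs = []
        for sep_hi in (0.30, 0.45, 0.8):
            g = toy_graph(n_per_cluster=25, sep=(0.25, sep_hi), spread=0.08,
                          epsilon=0.25, seed=6)
            idx = np.arange(g.n_nodes)
            rng = np.random.default_rng(0)
            perm = rng.permutation(idx)
            tr, va, te = perm[:30], perm[30:40], perm[40:]
            tm = train(g, tr, va, ModelConfig(max_epochs=150, patience=150,
                                              seed=2))
            labels, _, _ = predict(tm, g, mask=te)
            accs.append((labels == g.y[te]).mean())
        assert accs[0] <= accs[1] + 0.1 and accs[1] <= accs[2] + 0.05
        assert accs[2] > accs[0]


class TestPredictAndSerialize:
    def test_probabilities_normalized_and_consistent(self):
        g = toy_graph()
        idx = np.arange(g.n_nodes)
        tm = train(g, idx[:40], idx[40:50],
                   ModelConfig(max_epochs=20, patience=20, seed=0))
        labels, probs, _ = predict(tm, g)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.array_equal(labels, probs.argmax(axis=1))

    def test_save_load_bit_identical_predictions(self, tmp_path):
        g = toy_graph()
        idx = np.arange(g.n_nodes)
        tm = train(g, idx[:40], idx[40:50],
                   ModelConfig(max_epochs=10, patience=10, seed=0))
        _, probs, _ = predict(tm, g)
        save_model(tm, tmp_path / "m")
        back = load_model(tmp_path / "m")
        _, probs2, _ = predict(back, g)
        assert np.array_equal(probs, probs2)
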