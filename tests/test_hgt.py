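"""Graph construction, attention math, layer oracle and training contracts."""

import numpy as np
import pytest

from branchgas._autograd import constant
from branchgas.hgt import (
    HGTConfig,
    HGTModel,
    attention_scores,
    build_bipartite_graph,
    compute_gas,
    kl_loss,
    reconstruct,
    train,
)


class TestBipartiteGraph:
    def test_edges_follow_definition(self):
        X = np.array([[0.0, 2.0], [3.0, 0.0]])  # cells x genes
        g = build_bipartite_graph(X, gene_ids=["g1", "g2"],
                                  cell_ids=["c1", "c2"])
        edges = set(zip(g.gene_idx.tolist(), g.cell_idx.tolist()))
        assert edges == {(1, 0), (0, 1)}
        assert g.n_edges == (X > 0).sum()

    def test_threshold_monotone(self, rng):
        X = rng.uniform(0, 1, (10, 8))
        counts = [build_bipartite_graph(X, edge_threshold=t).n_edges
                  for t in (0.0, 0.3, 0.6)]
        assert counts[0] >= counts[1] >= counts[2] > 0

    def test_zero_edges_rejected(self):
        with pytest.raises(ValueError):
            build_bipartite_graph(np.zeros((3, 3)))

    def test_neighborhoods(self):
        X = np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        g = build_bipartite_graph(X)
        assert g.neighborhoods() == {0: [0, 1], 1: [2]}


class TestAttentionScores:
    def test_single_neighbor_alpha_one(self, rng):
        K = rng.standard_normal((1, 4))
        _, alpha = attention_scores(K, rng.standard_normal(4), 4)
        assert alpha == pytest.approx([1.0])

    def test_equal_scores_split_evenly(self):
        K = np.ones((2, 4))
        _, alpha = attention_scores(K, np.ones(4), 4)
        assert np.allclose(alpha, 0.5)

    def test_hand_computed_softmax(self):
        # engineered raw scores e = (1, 0)
        d_h = 4
        Q = np.array([2.0, 0.0, 0.0, 0.0])
        K = np.array([[1.0, 0, 0, 0], [0.0, 0, 0, 0]])
        e, alpha = attention_scores(K, Q, d_h)
        assert np.allclose(e, [1.0, 0.0])
        assert np.allclose(alpha, [0.7311, 0.2689], atol=1e-4)

    def test_empty_neighborhood_rejected(self):
        with pytest.raises(ValueError):
            attention_scores(np.empty((0, 4)), np.ones(4), 4)


class TestReconstruct:
    def test_row_sums_one(self, rng):
        out = reconstruct(rng.standard_normal((6, 4)),
                          rng.standard_normal((5, 4)))
        assert out.shape == (5, 6)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-6)

    def test_hand_example(self):
        genes = np.array([[1.0, 0.0], [0.0, 1.0]])
        cells = np.array([[1.0, 0.0], [1.0, 1.0]])
        out = reconstruct(genes, cells)
        sp = np.logaddexp(0, np.array([[1.0, 0.0], [1.0, 1.0]]))
        expected = sp / sp.sum(axis=1, keepdims=True)
        assert np.allclose(out, expected)

    def test_dim_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            reconstruct(rng.standard_normal((3, 4)),
                        rng.standard_normal((3, 5)))


class TestKLLoss:
    def test_identity_zero(self):
        P = np.array([[0.25, 0.75], [0.5, 0.5]])
        assert kl_loss(P, P, pseudocount=0.0) == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed(self):
        X = np.array([[0.5, 0.5]])
        Xhat = np.array([[0.9, 0.1]])
        expected = 0.5 * np.log(0.5 / 0.9) + 0.5 * np.log(0.5 / 0.1)
        assert kl_loss(X, Xhat, pseudocount=0.0) == pytest.approx(
            expected, abs=1e-4)
        assert expected == pytest.approx(0.5108, abs=1e-4)

    def test_nonnegative_for_distributions(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(5), size=3)
            q = rng.dirichlet(np.ones(5), size=3)
            assert kl_loss(p, q, pseudocount=0.0) >= -1e-9


def _loop_layer_oracle(model, raw_gene, raw_cell):
    """Straight-line re-computation of the stacked layers with python loops."""
    p = {k: v.data.astype(np.float64) for k, v in model.params.items()}
    cfg = model.config
    H, dh = cfg.n_heads, cfg.d_h
    hg = raw_gene @ p["gene_in"] + p["gene_in_b"]
    hg = hg @ p["gene_hid"] + p["gene_hid_b"]
    hc = raw_cell @ p["cell_in"] + p["cell_in_b"]
    hc = hc @ p["cell_hid"] + p["cell_hid_b"]

    def ln(x, g, b, eps=1e-5):
        mu = x.mean(-1, keepdims=True)
        var = ((x - mu) ** 2).mean(-1, keepdims=True)
        return (x - mu) / np.sqrt(var + eps) * g + b

    nb_of_cell = {}
    nb_of_gene = {}
    for gi, ci in zip(model.graph.gene_idx, model.graph.cell_idx):
        nb_of_cell.setdefault(int(ci), []).append(int(gi))
        nb_of_gene.setdefault(int(gi), []).append(int(ci))

    for layer in range(cfg.n_layers):
        new_hc = hc.copy()
        for j, neighbors in nb_of_cell.items():
            K = hg[neighbors] @ p[f"WK_g2c_{layer}"]
            Q = hc[j] @ p[f"WQ_g2c_{layer}"]
            V = hg[neighbors] @ p[f"WV_g2c_{layer}"]
            heads = []
            for h in range(H):
                sl = slice(h * dh, (h + 1) * dh)
                e = K[:, sl] @ Q[sl] / np.sqrt(dh)
                a = np.exp(e - e.max())
                a /= a.sum()
                heads.append(a @ V[:, sl])
            msg = np.concatenate(heads)
            out = hc[j] + msg @ p[f"WO_g2c_{layer}"] + p[f"bO_g2c_{layer}"]
            new_hc[j] = ln(out, p[f"ln_g_cell_{layer}"], p[f"ln_b_cell_{layer}"])
        new_hg = hg.copy()
        for i, neighbors in nb_of_gene.items():
            K = hc[neighbors] @ p[f"WK_c2g_{layer}"]
            Q = hg[i] @ p[f"WQ_c2g_{layer}"]
            V = hc[neighbors] @ p[f"WV_c2g_{layer}"]
            heads = []
            for h in range(H):
                sl = slice(h * dh, (h + 1) * dh)
                e = K[:, sl] @ Q[sl] / np.sqrt(dh)
                a = np.exp(e - e.max())
                a /= a.sum()
                heads.append(a @ V[:, sl])
            msg = np.concatenate(heads)
            out = hg[i] + msg @ p[f"WO_c2g_{layer}"] + p[f"bO_c2g_{layer}"]
            new_hg[i] = ln(out, p[f"ln_g_gene_{layer}"], p[f"ln_b_gene_{layer}"])
        hg, hc = new_hg, new_hc
    return hg, hc


@pytest.fixture(scope="module")
def tiny_setup(rng=None):
    rng = np.random.default_rng(3)
    X = rng.uniform(0, 1, (3, 5))  # 3 cells x 5 genes
    X[0, 0] = 0.0
    graph = build_bipartite_graph(X)
    cfg = HGTConfig(embed_dim=16, hidden_dim=8, n_heads=2, n_layers=2,
                    epochs=1, seed=0)
    model = HGTModel(graph, cfg, raw_gene_dim=3, raw_cell_dim=5)
    return X, graph, cfg, model


class TestLayerForward:
    def test_vectorized_matches_loop_oracle(self, tiny_setup):
        """The batched forward agrees with an explicit per-node, per-head
        loop implementation of the same attention equations."""
        X, graph, cfg, model = tiny_setup
        raw_gene = X.T.astype(np.float32)
        raw_cell = X.astype(np.float32)
        hg, hc, attn = model.forward(raw_gene, raw_cell)
        og, oc = _loop_layer_oracle(model, raw_gene.astype(float),
                                    raw_cell.astype(float))
        assert np.allclose(hc.data, oc, atol=1e-5)
        assert np.allclose(hg.data, og, atol=1e-5)

    def test_attention_normalized_per_cell_per_head(self, tiny_setup):
        X, graph, cfg, model = tiny_setup
        _, _, attn = model.forward(X.T.astype(np.float32),
                                   X.astype(np.float32))
        for layer in attn:
            a = layer["g2c"].data
            for j in range(graph.n_cells):
                mask = graph.cell_idx == j
                if mask.any():
                    sums = a[mask].sum(axis=0)
                    assert np.allclose(sums, 1.0, atol=1e-6)

    def test_identical_values_give_convex_combination(self, tiny_setup):
        """If all value vectors are identical the aggregated message equals
        that vector for every head (convexity of attention weights)."""
        X, graph, cfg, model = tiny_setup
        hg = constant(np.ones((graph.n_genes, cfg.hidden_dim)))
        hc = constant(np.zeros((graph.n_cells, cfg.hidden_dim)))
        # with identical gene embeddings, every V_i is identical
        _, alpha = model._relation_forward(
            hg, hc, "g2c", 0, model._gather_gene, model._gather_cell,
            model._scatter_cell, "cell", np.empty(graph.n_cells))
        a = alpha.data
        for j in range(graph.n_cells):
            mask = graph.cell_idx == j
            assert np.allclose(a[mask].sum(axis=0), 1.0, atol=1e-6)


class TestTraining:
    def test_loss_descends_and_deterministic(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (30, 50)) * (rng.random((30, 50)) > 0.3)
        graph = build_bipartite_graph(X)
        cfg = HGTConfig(embed_dim=32, hidden_dim=16, n_heads=4, n_layers=2,
                        epochs=30, seed=0)
        _, attn1, log1 = train(graph, X, cfg)
        assert log1.losses[-1] < log1.losses[0]
        _, _, log2 = train(graph, X, cfg)
        assert abs(log1.losses[-1] - log2.losses[-1]) < 1e-6

    def test_invalid_epochs_rejected(self):
        with pytest.raises(ValueError):
            HGTConfig(epochs=0)

    def test_hidden_head_divisibility(self):
        with pytest.raises(ValueError):
            HGTConfig(hidden_dim=10, n_heads=4)


class TestComputeGAS:
    def _graph_line(self):
        # 2 genes fully connected to 2 cells
        return build_bipartite_graph(np.ones((2, 2)))

    def test_single_neighbor_degenerate(self):
        g = build_bipartite_graph(np.array([[1.0]]))
        attn = [{"g2c": np.ones((1, 1))}]
        gas = compute_gas(attn, g)
        assert np.allclose(gas.scores, [[1.0]])

    def test_uniform_attention_algebra(self):
        """k neighbors with uniform alpha = 1/k over H heads: raw H/k^2 per
        gene, 1/k after per-cell normalization."""
        g = self._graph_line()
        H = 4
        attn = [{"g2c": np.full((g.n_edges, H), 0.5)}]
        gas = compute_gas(attn, g)
        assert np.allclose(gas.scores, 0.5)

    def test_per_cell_sums_one(self, rng):
        X = rng.uniform(0, 1, (6, 9)) * (rng.random((6, 9)) > 0.4)
        g = build_bipartite_graph(X)
        attn = []
        for _ in range(2):
            a = rng.uniform(0.1, 1.0, (g.n_edges, 3))
            for j in range(g.n_cells):
                mask = g.cell_idx == j
                a[mask] /= a[mask].sum(axis=0)
            attn.append({"g2c": a})
        gas = compute_gas(attn, g)
        connected = np.unique(g.cell_idx)
        assert np.allclose(gas.scores[:, connected].sum(axis=0), 1.0,
                           atol=1e-6)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            compute_gas([], self._graph_line())
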