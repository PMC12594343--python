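"""Gene-cell bipartite graph transformer and Gene Attention Scores (GAS).

The Gene Integration Matrix is turned into a bipartite graph (edge whenever a
gene is expressed in a cell, binary weights). Gene and cell nodes are
projected into 256-dimensional embeddings by independent linear maps, then
refined by stacked multi-head attention layers with relation-specific query/
key/value projections: each cell aggregates messages from its gene neighbors
(and symmetrically each gene from its cells), with scaled dot-product
attention

    e_ij^h = (K_i . Q_j) / sqrt(d_h),   alpha_ij^h = softmax over i in N(j),

a concatenated-head linear output map, a residual connection and layer
normalization. Training is unsupervised: embeddings reconstruct the input
matrix through a softplus inner product normalized per cell, minimizing the
KL divergence between the per-cell input distribution and the
reconstruction. After training, attention weights from all heads and layers
are squared, summed, and normalized per cell into the GAS matrix, the
per-gene importance signal used for branch-gene selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator

from ._autograd import Adam, Tensor, constant, layer_norm, parameter, spmm

logger = logging.getLogger(__name__)


@dataclass
class BipartiteGraph:
    """Gene-cell graph: edges where the GIM exceeds `edge_threshold`."""

    gene_ids: list
    cell_ids: list
    gene_idx: np.ndarray  # per edge
    cell_idx: np.ndarray  # per edge
    edge_threshold: float = 0.0

    @property
    def n_genes(self):
        return len(self.gene_ids)

    @property
    def n_cells(self):
        return len(self.cell_ids)

    @property
    def n_edges(self):
        return len(self.gene_idx)

    def neighborhoods(self):
        """Per cell j, the sorted gene neighborhood N(j)."""
        nb = {j: [] for j in range(self.n_cells)}
        for g, c in zip(self.gene_idx, self.cell_idx):
            nb[int(c)].append(int(g))
        return {j: sorted(v) for j, v in nb.items()}

    def isolated_cells(self):
        mask = np.ones(self.n_cells, bool)
        mask[self.cell_idx] = False
        return np.flatnonzero(mask)

    def isolated_genes(self):
        mask = np.ones(self.n_genes, bool)
        mask[self.gene_idx] = False
        return np.flatnonzero(mask)


@dataclass
class HGTConfig:
    embed_dim: int = 256
    hidden_dim: int = 128
    n_heads: int = 16
    n_layers: int = 2
    epochs: int = 100
    lr: float = 0.01
    lr_patience: int = 10
    clip_norm: float = 0.0  # optional global gradient-norm clip; 0 disables
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dim % self.n_heads:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @property
    def d_h(self):
        return self.hidden_dim // self.n_heads


@dataclass
class TrainingLog:
    losses: list = field(default_factory=list)
    lrs: list = field(default_factory=list)
    seed: int = 0


@dataclass
class GASMatrix:
    """Genes x cells attention scores, normalized to sum to 1 per cell."""

    scores: np.ndarray
    gene_ids: list
    cell_ids: list


def build_bipartite_graph(X, gene_ids=None, cell_ids=None,
                          edge_threshold: float = 0.0) -> BipartiteGraph:
    """Edge (gene i, cell j) iff X[j, i] > edge_threshold (X is cells x genes)."""
    if edge_threshold < 0:
        raise ValueError("edge_threshold must be >= 0")
    X = np.asarray(getattr(X, "X", X), dtype=float)
    cell_idx, gene_idx = np.nonzero(X > edge_threshold)
    if len(gene_idx) == 0:
        raise ValueError("graph has zero edges")
    n_cells, n_genes = X.shape
    gene_ids = list(gene_ids) if gene_ids is not None else [
        f"g{i}" for i in range(n_genes)]
    cell_ids = list(cell_ids) if cell_ids is not None else [
        f"c{j}" for j in range(n_cells)]
    graph = BipartiteGraph(gene_ids=gene_ids, cell_ids=cell_ids,
                           gene_idx=gene_idx, cell_idx=cell_idx,
                           edge_threshold=edge_threshold)
    iso = len(graph.isolated_cells()) + len(graph.isolated_genes())
    if iso:
        logger.warning("%d isolated nodes retained in the graph", iso)
    return graph


def attention_scores(K, Q, d_h: int):
    """Scaled dot-product attention of one cell over its gene neighbors.

    K: (n_neighbors, d_h) key vectors; Q: (d_h,) query. Returns (raw e,
    softmax-normalized alpha).
    """
    K = np.asarray(K, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if K.shape[0] == 0:
        raise ValueError("empty neighborhood")
    e = K @ Q / np.sqrt(d_h)
    ex = np.exp(e - e.max())
    return e, ex / ex.sum()


def reconstruct(gene_embeddings, cell_embeddings):
    """Cells x genes reconstruction: softplus inner product, row-normalized."""
    G = np.asarray(gene_embeddings, dtype=float)
    C = np.asarray(cell_embeddings, dtype=float)
    if G.shape[1] != C.shape[1]:
        raise ValueError("embedding dimensions differ")
    S = C @ G.T
    sp = np.logaddexp(0.0, S)
    return sp / sp.sum(axis=1, keepdims=True)


def kl_loss(X, X_hat, pseudocount: float = 1e-8) -> float:
    """KL divergence between per-cell distributions of X and X_hat.

    X rows are normalized to distributions with `pseudocount`; zeros in X_hat
    where P > 0 are clamped at 1e-12 with a warning. 0*log0 = 0.
    """
    X = np.asarray(X, dtype=float) + pseudocount
    P = X / X.sum(axis=1, keepdims=True)
    Q = np.asarray(X_hat, dtype=float)
    if ((Q <= 0) & (P > 0)).any():
        logger.warning("clamping nonpositive reconstruction entries at 1e-12")
        Q = np.maximum(Q, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P / Q), 0.0)
    return float(terms.sum())


def _xavier(rng, fan_in, fan_out):
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.standard_normal((fan_in, fan_out)) * std


class HGTModel:
    """Parameters and forward pass of the bipartite graph transformer."""

    RELATIONS = ("g2c", "c2g")

    def __init__(self, graph: BipartiteGraph, config: HGTConfig,
                 raw_gene_dim: int, raw_cell_dim: int):
        self.graph = graph
        self.config = config
        rng = np.random.default_rng(config.seed)
        e, h = config.embed_dim, config.hidden_dim
        self.params = {}

        def P(name, shape_in, shape_out):
            self.params[name] = parameter(_xavier(rng, shape_in, shape_out))

        def B(name, dim):
            self.params[name] = parameter(np.zeros(dim))

        # independent linear projections of raw features into 256-dim
        # embeddings, then into the working width
        P("gene_in", raw_gene_dim, e); B("gene_in_b", e)
        P("cell_in", raw_cell_dim, e); B("cell_in_b", e)
        P("gene_hid", e, h); B("gene_hid_b", h)
        P("cell_hid", e, h); B("cell_hid_b", h)
        for layer in range(config.n_layers):
            for rel in self.RELATIONS:
                for w in ("WQ", "WK", "WV", "WO"):
                    P(f"{w}_{rel}_{layer}", h, h)
                B(f"bO_{rel}_{layer}", h)
            for nt in ("gene", "cell"):
                self.params[f"ln_g_{nt}_{layer}"] = parameter(np.ones(h))
                self.params[f"ln_b_{nt}_{layer}"] = parameter(np.zeros(h))
        # edge gather/scatter operators
        E = graph.n_edges
        ones = np.ones(E, dtype=np.float32)
        self._gather_gene = sparse.csr_matrix(
            (ones, (np.arange(E), graph.gene_idx)), shape=(E, graph.n_genes))
        self._gather_cell = sparse.csr_matrix(
            (ones, (np.arange(E), graph.cell_idx)), shape=(E, graph.n_cells))
        self._scatter_gene = self._gather_gene.T.tocsr()
        self._scatter_cell = self._gather_cell.T.tocsr()

    def parameter_list(self):
        return list(self.params.values())

    def _relation_forward(self, h_src, h_tgt, rel, layer, gather_src,
                          gather_tgt, scatter_tgt, tgt_type, tgt_segments):
        cfg = self.config
        p = self.params
        K = h_src @ p[f"WK_{rel}_{layer}"]
        Q = h_tgt @ p[f"WQ_{rel}_{layer}"]
        V = h_src @ p[f"WV_{rel}_{layer}"]
        Ke, Qe, Ve = spmm(gather_src, K), spmm(gather_tgt, Q), spmm(gather_src, V)
        E = Ke.shape[0]
        H, dh = cfg.n_heads, cfg.d_h
        prod = (Ke * Qe).reshape(E, H, dh)
        e_scores = prod.sum(axis=2) * (1.0 / np.sqrt(dh))  # (E, H)
        # segment softmax over the target's neighborhood; the max shift is a
        # constant (softmax is shift-invariant)
        seg_max = np.full((tgt_segments.shape[0], H), -np.inf, dtype=np.float32)
        np.maximum.at(seg_max, self._seg_idx(rel), e_scores.data)
        shifted = e_scores - constant(seg_max[self._seg_idx(rel)])
        ex = shifted.exp()
        denom = spmm(scatter_tgt, ex)  # (n_tgt, H)
        alpha = ex / spmm(gather_tgt, denom)  # (E, H)
        msg_e = (alpha.reshape(E, H, 1) * Ve.reshape(E, H, dh)).reshape(E, H * dh)
        msg = spmm(scatter_tgt, msg_e)  # (n_tgt, hidden)
        out = h_tgt + (msg @ p[f"WO_{rel}_{layer}"] + p[f"bO_{rel}_{layer}"])
        out = layer_norm(out, p[f"ln_g_{tgt_type}_{layer}"],
                         p[f"ln_b_{tgt_type}_{layer}"])
        return out, alpha

    def _seg_idx(self, rel):
        return (self.graph.cell_idx if rel == "g2c" else self.graph.gene_idx)

    def layer_forward(self, h_gene: Tensor, h_cell: Tensor, layer: int):
        """One layer: cells aggregate from genes and genes from cells, in
        parallel from the previous embeddings."""
        new_cell, alpha_g2c = self._relation_forward(
            h_gene, h_cell, "g2c", layer, self._gather_gene, self._gather_cell,
            self._scatter_cell, "cell",
            np.empty(self.graph.n_cells))
        new_gene, alpha_c2g = self._relation_forward(
            h_cell, h_gene, "c2g", layer, self._gather_cell, self._gather_gene,
            self._scatter_gene, "gene",
            np.empty(self.graph.n_genes))
        return new_gene, new_cell, {"g2c": alpha_g2c, "c2g": alpha_c2g}

    def forward(self, raw_gene, raw_cell):
        """Full forward pass; returns (h_gene, h_cell, attention per layer)."""
        p = self.params
        hg = constant(raw_gene) @ p["gene_in"] + p["gene_in_b"]
        hg = hg @ p["gene_hid"] + p["gene_hid_b"]
        hc = constant(raw_cell) @ p["cell_in"] + p["cell_in_b"]
        hc = hc @ p["cell_hid"] + p["cell_hid_b"]
        attn = []
        for layer in range(self.config.n_layers):
            hg, hc, a = self.layer_forward(hg, hc, layer)
            attn.append(a)
        return hg, hc, attn

    def loss(self, raw_gene, raw_cell, P_const, logP_sum):
        hg, hc, attn = self.forward(raw_gene, raw_cell)
        S = hc @ hg.transpose()
        # the floor keeps row sums positive when softplus underflows
        sp = S.softplus() + 1e-8
        xhat = sp / sp.sum(axis=1, keepdims=True)
        loss = (constant(P_const) * xhat.log()).sum() * (-1.0) + logP_sum
        return loss, attn


def train(graph: BipartiteGraph, X, config: HGTConfig = None):
    """Train the graph transformer on the GIM with the KL reconstruction loss.

    Full-graph Adam for `config.epochs` epochs; the learning rate is halved
    whenever the loss fails to improve for `lr_patience` epochs. Deterministic
    given `config.seed`. Returns (model, attention records from the final
    epoch, TrainingLog).
    """
    config = config or HGTConfig()
    X = np.asarray(getattr(X, "X", X), dtype=float)
    if X.shape != (graph.n_cells, graph.n_genes):
        raise ValueError("X shape does not match the graph")
    Xp = X + 1e-8
    P = (Xp / Xp.sum(axis=1, keepdims=True)).astype(np.float32)
    logP_sum = float((P * np.log(P)).sum())
    raw_gene = X.T.astype(np.float32)
    raw_cell = X.astype(np.float32)
    model = HGTModel(graph, config, raw_gene_dim=raw_gene.shape[1],
                     raw_cell_dim=raw_cell.shape[1])
    opt = Adam(model.parameter_list(), lr=config.lr)
    log = TrainingLog(seed=config.seed)
    best, stall = np.inf, 0
    attn_records = None
    for epoch in range(config.epochs):
        opt.zero_grad()
        loss_t, attn = model.loss(raw_gene, raw_cell, P, logP_sum)
        loss = float(loss_t.data)
        if not np.isfinite(loss) or loss > 1e6:
            raise RuntimeError(
                f"training diverged at epoch {epoch} (loss={loss}); "
                f"log so far: {log.losses}")
        loss_t.backward()
        if config.clip_norm:
            total = np.sqrt(sum(float((p.grad ** 2).sum())
                                for p in model.parameter_list()
                                if p.grad is not None))
            if total > config.clip_norm:
                scale = np.float32(config.clip_norm / total)
                for p in model.parameter_list():
                    if p.grad is not None:
                        p.grad = p.grad * scale
        opt.step()
        log.losses.append(loss)
        log.lrs.append(opt.lr)
        if loss < best - 1e-6:
            best, stall = loss, 0
        else:
            stall += 1
            if stall >= config.lr_patience:
                opt.lr *= 0.5
                stall = 0
        attn_records = [
            {rel: a[rel].data.astype(float).copy() for rel in a} for a in attn
        ]
    return model, attn_records, log


def compute_gas(attn_records, graph: BipartiteGraph) -> GASMatrix:
    """Combine the mutual attention into the GAS matrix.

    raw(i, j) = sum over layers, heads and both relation directions of the
    squared attention weight on edge (i, j); each cell's column is then
    normalized to sum to 1 over its connected genes. The gene-side direction
    (how gene i distributes attention over its cells) is what separates
    specifically expressed genes from broadly expressed ones: a gene
    attending to few cells concentrates its mass there, while a housekeeping
    gene spreads it thin. Cells with no edges get all-zero columns.
    """
    if not attn_records:
        raise ValueError("need attention records from at least one layer")
    raw_edge = np.zeros(graph.n_edges)
    for layer in attn_records:
        for rel in ("g2c", "c2g"):
            if rel in layer:
                raw_edge += (layer[rel] ** 2).sum(axis=1)
    scores = np.zeros((graph.n_genes, graph.n_cells))
    np.add.at(scores, (graph.gene_idx, graph.cell_idx), raw_edge)
    col = scores.sum(axis=0, keepdims=True)
    iso = np.flatnonzero(col[0] == 0)
    if iso.size:
        logger.warning("%d cells have no edges; their GAS columns are zero",
                       iso.size)
    scores = np.divide(scores, col, out=np.zeros_like(scores), where=col > 0)
    return GASMatrix(scores=scores, gene_ids=list(graph.gene_ids),
                     cell_ids=list(graph.cell_ids))


class GeneAttentionHGT(BaseEstimator):
    """Estimator: fit the graph transformer on a GIM, expose the GAS matrix.

    Attributes after fit: graph_, model_, log_ (loss trace), attention_,
    gas_ (GASMatrix), reconstruction_.
    """

    def __init__(self, embed_dim=256, hidden_dim=128, n_heads=16, n_layers=2,
                 epochs=100, lr=0.01, edge_threshold=0.0, seed=0):
        self.embed_dim = embed_dim
        self.hidden_dim = hidden_dim
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.epochs = epochs
        self.lr = lr
        self.edge_threshold = edge_threshold
        self.seed = seed

    def fit(self, X, gene_ids=None, cell_ids=None):
        mat = np.asarray(getattr(X, "X", X), dtype=float)
        gene_ids = gene_ids or getattr(X, "gene_ids", None)
        cell_ids = cell_ids or getattr(X, "cell_ids", None)
        config = HGTConfig(embed_dim=self.embed_dim, hidden_dim=self.hidden_dim,
                           n_heads=self.n_heads, n_layers=self.n_layers,
                           epochs=self.epochs, lr=self.lr, seed=self.seed)
        self.graph_ = build_bipartite_graph(
            mat, gene_ids=gene_ids, cell_ids=cell_ids,
            edge_threshold=self.edge_threshold)
        self.model_, self.attention_, self.log_ = train(self.graph_, mat, config)
        self.gas_ = compute_gas(self.attention_, self.graph_)
        return self

    def fit_transform(self, X, **kw) -> np.ndarray:
        """Fit and return the genes x cells GAS score matrix."""
        return self.fit(X, **kw).gas_.scores
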