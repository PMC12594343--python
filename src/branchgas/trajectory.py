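"""Bifurcating trajectory inference on the Gene Integration Matrix.

Cells are reduced with PCA and clustered with a Gaussian mixture; a Euclidean
minimum spanning tree over cluster centroids defines the lineage tree, and
every root-to-leaf path is a lineage. A cell's pseudotime on a lineage is the
arc-length of its orthogonal projection onto the piecewise-linear centroid
path, normalized to [0, 1]; lineage assignment weights are the cell's
posterior mass over the clusters of each lineage, renormalized.

This is a deliberately minimal stand-in for principal-curve lineage fitting:
it keeps the quantities downstream stages need (branch point, per-lineage
pseudotime, soft lineage assignment) in an exactly testable form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)


@dataclass
class CellClustering:
    labels: np.ndarray
    posteriors: np.ndarray  # cells x clusters, rows sum to 1
    centroids: np.ndarray  # clusters x d
    bic: float = np.nan


@dataclass
class LineageModel:
    mst_edges: list  # undirected (a, b) cluster pairs
    root: int
    lineages: list  # ordered cluster paths, each starting at root
    pseudotime: np.ndarray  # cells x lineages, in [0, 1]
    lineage_weights: np.ndarray  # cells x lineages, rows sum to 1
    cluster_labels: np.ndarray = field(default=None)

    @property
    def n_lineages(self):
        return len(self.lineages)

    def cell_pseudotime(self):
        """Pseudotime on each cell's max-weight lineage."""
        best = np.argmax(self.lineage_weights, axis=1)
        return self.pseudotime[np.arange(len(best)), best]


def pca_reduce(X, n_components: int = 20):
    """Centered PCA with a deterministic sign convention.

    Each component is flipped so its largest-magnitude loading is positive.
    Returns (scores, fitted PCA).
    """
    X = np.asarray(X, dtype=float)
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    comp = pca.components_
    flip = np.sign(comp[np.arange(comp.shape[0]), np.abs(comp).argmax(axis=1)])
    flip[flip == 0] = 1.0
    pca.components_ = comp * flip[:, None]
    scores = scores * flip[None, :]
    return scores, pca


def gmm_cluster(embedding, k: int, seed: int = 0, n_init: int = 10
                ) -> CellClustering:
    """Full-covariance Gaussian mixture clustering with restarts."""
    embedding = np.asarray(embedding, dtype=float)
    if k < 1 or embedding.shape[0] <= k:
        raise ValueError("need 1 <= k < n_cells")
    gmm = GaussianMixture(
        n_components=k, covariance_type="full", n_init=n_init,
        random_state=seed, reg_covar=1e-6,
    )
    labels = gmm.fit_predict(embedding)
    post = gmm.predict_proba(embedding)
    return CellClustering(labels=labels, posteriors=post,
                          centroids=gmm.means_, bic=float(gmm.bic(embedding)))


def choose_k_bic(embedding, k_range=range(2, 11), seed: int = 0) -> int:
    """Pick the mixture size minimizing BIC over `k_range`."""
    embedding = np.asarray(embedding, dtype=float)
    bics = {}
    for k in k_range:
        if k >= embedding.shape[0]:
            break
        gmm = GaussianMixture(n_components=k, covariance_type="full",
                              n_init=3, random_state=seed, reg_covar=1e-6)
        gmm.fit(embedding)
        bics[k] = gmm.bic(embedding)
    return min(bics, key=bics.get)


def _mst_adjacency(centroids):
    dists = cdist(centroids, centroids)
    mst = minimum_spanning_tree(dists).toarray()
    n = len(centroids)
    adj = {i: [] for i in range(n)}
    edges = []
    for a in range(n):
        for b in range(n):
            if mst[a, b] > 0:
                adj[a].append(b)
                adj[b].append(a)
                edges.append((min(a, b), max(a, b)))
    for v in adj:
        adj[v] = sorted(set(adj[v]))
    return sorted(set(edges)), adj


def _farthest(adj, start):
    """BFS returning the farthest node (hop count) from `start`."""
    seen, frontier, last = {start}, [start], start
    while frontier:
        nxt = []
        for v in frontier:
            for w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    nxt.append(w)
        if nxt:
            last = nxt[-1]
        frontier = nxt
    return last


def _paths_to_leaves(adj, root):
    paths, stack = [], [(root, [root])]
    while stack:
        node, path = stack.pop()
        children = [w for w in adj[node] if w not in path]
        if not children:
            if len(path) > 1 or len(adj) == 1:
                paths.append(path)
            continue
        for w in sorted(children, reverse=True):
            stack.append((w, path + [w]))
    return sorted(paths)


def _project_onto_path(points, path_pts):
    """Arc-length of each point's orthogonal projection onto a polyline.

    Ties (equidistant segments) go to the earlier segment.
    """
    seg_starts = path_pts[:-1]
    seg_vecs = np.diff(path_pts, axis=0)
    seg_lens = np.linalg.norm(seg_vecs, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_lens)])
    total = max(cum[-1], 1e-12)
    best_d = np.full(len(points), np.inf)
    best_arc = np.zeros(len(points))
    for s in range(len(seg_vecs)):
        v = seg_vecs[s]
        L2 = max(seg_lens[s] ** 2, 1e-24)
        tt = np.clip((points - seg_starts[s]) @ v / L2, 0.0, 1.0)
        proj = seg_starts[s] + tt[:, None] * v
        d = np.linalg.norm(points - proj, axis=1)
        better = d < best_d - 1e-12  # strict: earlier segment wins ties
        best_d[better] = d[better]
        best_arc[better] = cum[s] + tt[better] * seg_lens[s]
    return best_arc / total


def infer_lineages(clustering: CellClustering, embedding, root=None,
                   cell_totals=None) -> LineageModel:
    """Build the lineage tree and per-cell pseudotime from a clustering.

    root: cluster id, or None for automatic selection: among the leaf
    clusters of the MST, the one with the lowest mean `cell_totals` (per-cell
    GIM totals, the expected transcriptional floor of progenitors) is taken;
    without totals the lower cluster id wins.
    """
    embedding = np.asarray(embedding, dtype=float)
    k = clustering.centroids.shape[0]
    if k < 2:
        raise ValueError("need at least two clusters to build lineages")
    edges, adj = _mst_adjacency(clustering.centroids)
    if root is None:
        cands = sorted(v for v in adj if len(adj[v]) <= 1)
        if not cands:
            a = _farthest(adj, 0)
            cands = sorted({a, _farthest(adj, a)})
        if cell_totals is not None:
            totals = np.asarray(cell_totals, dtype=float)
            means = [totals[clustering.labels == c].mean() if
                     (clustering.labels == c).any() else np.inf for c in cands]
            root = cands[int(np.argmin(means))]
        else:
            root = cands[0]
    lineages = _paths_to_leaves(adj, root)
    if not lineages:
        lineages = [[root]]
    n_cells = embedding.shape[0]
    pseudotime = np.zeros((n_cells, len(lineages)))
    weights = np.zeros((n_cells, len(lineages)))
    for li, path in enumerate(lineages):
        path_pts = clustering.centroids[path]
        if len(path) == 1:
            pseudotime[:, li] = 0.0
        else:
            pseudotime[:, li] = _project_onto_path(embedding, path_pts)
        weights[:, li] = clustering.posteriors[:, path].sum(axis=1)
    row_sums = weights.sum(axis=1, keepdims=True)
    weights = np.divide(weights, row_sums, out=np.zeros_like(weights),
                        where=row_sums > 0)
    return LineageModel(mst_edges=edges, root=int(root), lineages=lineages,
                        pseudotime=pseudotime, lineage_weights=weights,
                        cluster_labels=clustering.labels)


class TrajectoryInference(BaseEstimator):
    """PCA + Gaussian-mixture + MST lineage inference over a GIM.

    Parameters
    ----------
    n_components : PCA dimensionality (default 20).
    k : mixture size; None triggers a BIC scan over 2..10.
    root : root cluster id or None for automatic selection.
    seed : RNG seed for the mixture restarts.

    Attributes (after fit)
    ----------------------
    embedding_, clustering_, lineage_model_, labels_
    """

    def __init__(self, n_components=20, k=None, root=None, seed=0, n_init=10,
                 k_range=tuple(range(3, 9))):
        self.n_components = n_components
        self.k = k
        self.root = root
        self.seed = seed
        self.n_init = n_init
        self.k_range = k_range

    def fit(self, X, cell_totals=None):
        X = np.asarray(X, dtype=float)
        n_comp = min(self.n_components, min(X.shape))
        self.embedding_, self.pca_ = pca_reduce(X, n_comp)
        if cell_totals is None:
            cell_totals = X.sum(axis=1)
        if self.k is not None:
            self.clustering_ = gmm_cluster(self.embedding_, self.k,
                                           seed=self.seed, n_init=self.n_init)
            self.lineage_model_ = infer_lineages(
                self.clustering_, self.embedding_, root=self.root,
                cell_totals=cell_totals)
        else:
            # scan k by BIC, preferring mixture sizes whose centroid MST
            # actually exposes a bifurcation (the object of study)
            candidates = []
            for k in self.k_range:
                if k >= self.embedding_.shape[0]:
                    break
                clust = gmm_cluster(self.embedding_, k, seed=self.seed,
                                    n_init=self.n_init)
                model = infer_lineages(clust, self.embedding_, root=self.root,
                                       cell_totals=cell_totals)
                candidates.append(
                    (model.n_lineages < 2, clust.bic, k, clust, model))
            candidates.sort(key=lambda c: c[:3])
            _, _, self.k_, self.clustering_, self.lineage_model_ = candidates[0]
        self.labels_ = self.clustering_.labels
        return self

    def fit_predict(self, X, cell_totals=None):
        return self.fit(X, cell_totals=cell_totals).labels_
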