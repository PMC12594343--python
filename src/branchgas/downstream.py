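"""Validation of selected genes: trajectory re-reconstruction, staged
differential expression, and tree-ensemble regulatory-network inference.

Re-reconstruction reruns the trajectory stage on the gene-restricted GIM and
correlates the resulting pseudotime with the full-gene ordering. Staged DE
compares adjacent trajectory clusters with Welch two-sample t-tests on
per-cell mean expression of the candidate gene set, with Benjamini-Hochberg
adjustment across the comparison family. The GRN step scores each
regulator->target edge by random-forest feature importance in a per-target
regression (the GENIE3 recipe: sqrt-subset of candidate regulators per
split, importance = total impurity reduction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from statsmodels.stats.multitest import multipletests

from .integration import GeneIntegrationMatrix
from .trajectory import TrajectoryInference

logger = logging.getLogger(__name__)


@dataclass
class GRNetwork:
    """Directed regulator->target edges with nonnegative importances."""

    edges: pd.DataFrame  # regulator, target, weight
    phase: str = ""

    def top_edges(self, k):
        return self.edges.nlargest(k, "weight")

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph(phase=self.phase)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.regulator, row.target, weight=float(row.weight))
        return g


def log2fc(x: float, y: float, pseudocount: float = 1e-9) -> float:
    """log2 fold change of mean expressions; pseudocount only when a mean is 0."""
    if x < 0 or y < 0:
        raise ValueError("means must be nonnegative")
    if x > 0 and y > 0:
        return float(np.log2(x / y))
    logger.warning("zero mean encountered; applying pseudocount %g", pseudocount)
    return float(np.log2((x + pseudocount) / (y + pseudocount)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _welch(a, b):
    """Welch t-test handling the degenerate zero-variance case explicitly."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def stage_de(X: GeneIntegrationMatrix, genes, cluster_labels, comparisons,
             min_cells: int = 3) -> pd.DataFrame:
    """Differential expression between adjacent trajectory stages.

    For each (experimental, control) cluster pair: per-cell mean of the gene
    set in each cluster, Welch t-test between the two per-cell mean vectors,
    log2 fold change of the group means, and BH adjustment across the family
    of comparisons. Pairs with a cluster of fewer than `min_cells` cells are
    skipped with a warning.
    """
    mat = np.asarray(getattr(X, "X", X), dtype=float)
    gene_ids = list(getattr(X, "gene_ids", range(mat.shape[1])))
    gidx = [gene_ids.index(g) for g in genes]
    labels = np.asarray(cluster_labels)
    rows = []
    for exp_c, ctl_c in comparisons:
        a = mat[np.ix_(labels == exp_c, gidx)].mean(axis=1)
        b = mat[np.ix_(labels == ctl_c, gidx)].mean(axis=1)
        if len(a) < min_cells or len(b) < min_cells:
            logger.warning("skipping %s vs %s: fewer than %d cells",
                           exp_c, ctl_c, min_cells)
            continue
        t, p = _welch(a, b)
        rows.append({
            "experimental": exp_c, "control": ctl_c,
            "x": float(a.mean()), "y": float(b.mean()),
            "log2fc": log2fc(float(a.mean()), float(b.mean())),
            "t": t, "p_value": p,
        })
    table = pd.DataFrame(rows)
    if not table.empty:
        table["fdr"] = bh_adjust(table["p_value"].to_numpy())
    return table


def reconstruct_with_selected(X: GeneIntegrationMatrix, genes,
                              full_model=None, n_components=20, k=None,
                              seed=0):
    """Rerun trajectory inference on the gene-restricted GIM and compare.

    Returns (restricted LineageModel, report dict with the Pearson
    correlation between restricted and full-gene pseudotime over all cells,
    and the lineage counts of both runs).
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 selected genes")
    missing = set(genes) - set(X.gene_ids)
    if missing:
        raise ValueError(f"genes absent from GIM: {sorted(missing)[:5]}")
    if full_model is None:
        full = TrajectoryInference(n_components=n_components, k=k, seed=seed)
        full.fit(X.X, cell_totals=X.X.sum(axis=1))
        full_model = full.lineage_model_
    sub = X.restrict_genes(genes)
    restricted = TrajectoryInference(
        n_components=min(n_components, len(genes)), k=k, seed=seed)
    restricted.fit(sub.X, cell_totals=X.X.sum(axis=1))
    pt_full = full_model.cell_pseudotime()
    pt_res = restricted.lineage_model_.cell_pseudotime()
    r = float(stats.pearsonr(pt_full, pt_res)[0])
    report = {
        "pearson_pseudotime": r,
        "n_lineages_full": full_model.n_lineages,
        "n_lineages_restricted": restricted.lineage_model_.n_lineages,
        "same_topology": full_model.n_lineages
        == restricted.lineage_model_.n_lineages,
    }
    return restricted.lineage_model_, report


def grn_importance(expr, regulators, targets, n_trees: int = 1000,
                   seed: int = 0, gene_ids=None, top_k=None) -> GRNetwork:
    """GENIE3-style network inference.

    For each target, a random forest regresses the target's standardized
    expression on all regulators (excluding the target itself) with
    sqrt-of-p candidate features per split; the importance of a regulator is
    its total impurity reduction. Constant targets yield zero importances.
    """
    if n_trees < 10:
        raise ValueError("n_trees must be >= 10")
    mat = np.asarray(getattr(expr, "X", expr), dtype=float)
    gene_ids = list(gene_ids) if gene_ids is not None else list(
        getattr(expr, "gene_ids", range(mat.shape[1])))
    pos = {g: i for i, g in enumerate(gene_ids)}
    for g in list(regulators) + list(targets):
        if g not in pos:
            raise ValueError(f"gene {g!r} absent from expression matrix")
    rows = []
    rng = np.random.default_rng(seed)
    for target in targets:
        feats = [r for r in regulators if r != target]
        if not feats:
            continue
        y = mat[:, pos[target]]
        if y.std() == 0:
            logger.warning("constant target %s: zero importances", target)
            for r in feats:
                rows.append({"regulator": r, "target": target, "weight": 0.0})
            continue
        y = (y - y.mean()) / y.std()
        Xf = mat[:, [pos[r] for r in feats]]
        forest = RandomForestRegressor(
            n_estimators=n_trees, max_features="sqrt",
            random_state=int(rng.integers(2**31)), n_jobs=1)
        forest.fit(Xf, y)
        for r, w in zip(feats, forest.feature_importances_):
            rows.append({"regulator": r, "target": target, "weight": float(w)})
    edges = pd.DataFrame(rows, columns=["regulator", "target", "weight"])
    if top_k is not None and not edges.empty:
        edges = edges.nlargest(top_k, "weight").reset_index(drop=True)
    return GRNetwork(edges=edges)


class GRNInference:
    """Estimator wrapper around `grn_importance`.

    Attributes after fit: network_ (GRNetwork).
    """

    def __init__(self, n_trees=1000, seed=0, top_k=None):
        self.n_trees = n_trees
        self.seed = seed
        self.top_k = top_k

    def get_params(self, deep=True):
        return {"n_trees": self.n_trees, "seed": self.seed, "top_k": self.top_k}

    def set_params(self, **kw):
        for k, v in kw.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, expr, regulators=None, targets=None, gene_ids=None):
        gene_ids = list(gene_ids) if gene_ids is not None else list(
            getattr(expr, "gene_ids",
                    range(np.asarray(getattr(expr, "X", expr)).shape[1])))
        regulators = list(regulators) if regulators is not None else gene_ids
        targets = list(targets) if targets is not None else gene_ids
        self.network_ = grn_importance(expr, regulators, targets,
                                       n_trees=self.n_trees, seed=self.seed,
                                       gene_ids=gene_ids, top_k=self.top_k)
        return self
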