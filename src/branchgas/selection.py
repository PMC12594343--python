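"""Rank genes by attention score within a phase and select branch genes.

Genes are ranked per cell by descending GAS (average ranks on ties); a gene
is selected when it passes the GAS criterion (mean score above a threshold,
or mean rank within the top N) and is expressed (GIM value > 0, the same
predicate that creates graph edges) in at least a `prevalence` fraction of
the phase's cells (>= 50% by default).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .hgt import GASMatrix

logger = logging.getLogger(__name__)


def rank_genes(gas: GASMatrix, cells) -> pd.DataFrame:
    """Per-gene mean GAS and mean per-cell rank over a cell set.

    `cells` may be cell ids or integer indices. Ranks are computed per cell,
    descending (rank 1 = highest GAS), with average ranks on ties.
    """
    cells = list(cells)
    if not cells:
        raise ValueError("empty cell set")
    if all(isinstance(c, (int, np.integer)) for c in cells):
        idx = [int(c) for c in cells]
        bad = [c for c in idx if c < 0 or c >= len(gas.cell_ids)]
    else:
        pos = {c: i for i, c in enumerate(gas.cell_ids)}
        bad = [c for c in cells if c not in pos]
        idx = [pos[c] for c in cells if c in pos]
    if bad:
        raise ValueError(f"unknown cells: {bad[:10]}")
    sub = gas.scores[:, idx]  # genes x cells
    ranks = np.column_stack([rankdata(-sub[:, j], method="average")
                             for j in range(sub.shape[1])])
    return pd.DataFrame({
        "gene": gas.gene_ids,
        "mean_gas": sub.mean(axis=1),
        "mean_rank": ranks.mean(axis=1),
    }).set_index("gene")


def select_branch_genes(table: pd.DataFrame, X, cells, gas_threshold=None,
                        top_n=None, prevalence: float = 0.5,
                        gene_ids=None) -> list:
    """Apply the GAS criterion and the expression-prevalence filter.

    Exactly one of `gas_threshold` (mean GAS must exceed it) or `top_n`
    (mean rank within the best N) must be given. `prevalence` is the minimum
    fraction of the cell set with GIM value > 0 (inclusive boundary: 0.50
    passes at 50%). Returns selected gene ids sorted by mean GAS descending.
    """
    if (gas_threshold is None) == (top_n is None):
        raise ValueError("give exactly one of gas_threshold or top_n")
    if not (0 < prevalence <= 1):
        raise ValueError("prevalence must be in (0, 1]")
    mat = np.asarray(getattr(X, "X", X), dtype=float)
    gene_ids = list(gene_ids) if gene_ids is not None else list(
        getattr(X, "gene_ids", table.index))
    cells = [int(c) for c in cells]
    frac = pd.Series(
        (mat[cells] > 0).mean(axis=0), index=gene_ids, name="expr_frac")
    tab = table.join(frac)
    if gas_threshold is not None:
        gas_ok = tab["mean_gas"] > gas_threshold
    else:
        order = tab["mean_rank"].rank(method="first")
        gas_ok = order <= top_n
    selected = tab[gas_ok & (tab["expr_frac"] >= prevalence)]
    if selected.empty:
        logger.warning("no gene passes the selection filters")
    return selected.sort_values("mean_gas", ascending=False).index.tolist()


class BranchGeneSelector(BaseEstimator):
    """Estimator wrapping rank_genes + select_branch_genes.

    Attributes after fit: table_ (per-gene score table with expression
    fraction and selection flag), selected_genes_.
    """

    def __init__(self, gas_threshold=None, top_n=None, prevalence=0.5):
        self.gas_threshold = gas_threshold
        self.top_n = top_n
        self.prevalence = prevalence

    def fit(self, gas: GASMatrix, X, cells):
        table = rank_genes(gas, cells)
        self.selected_genes_ = select_branch_genes(
            table, X, cells, gas_threshold=self.gas_threshold,
            top_n=self.top_n, prevalence=self.prevalence)
        mat = np.asarray(getattr(X, "X", X), dtype=float)
        gene_ids = list(getattr(X, "gene_ids", table.index))
        table = table.join(pd.Series((mat[[int(c) for c in cells]] > 0).mean(axis=0),
                                     index=gene_ids, name="expr_frac"))
        table["selected"] = table.index.isin(self.selected_genes_)
        self.table_ = table
        return self
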