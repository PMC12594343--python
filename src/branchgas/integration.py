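"""Fuse paired RNA and ATAC profiles into a Gene Integration Matrix (GIM).

The pipeline is: library-size log-normalization of RNA counts; TF-IDF
reweighting of the peak matrix; distance-decayed regulatory-potential (RP)
gene activity from peaks around each gene's TSS/body; optional CCA alignment
of the two modalities; and per-gene fusion into a single nonnegative
cells x genes matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

DEFAULT_DECAY_BP = 10_000
DEFAULT_WINDOW_BP = 50_000


@dataclass
class GeneActivityMatrix:
    """Cells x genes regulatory-potential scores derived from ATAC peaks."""

    values: np.ndarray
    gene_ids: list
    cell_ids: list = field(default_factory=list)


@dataclass
class GeneIntegrationMatrix:
    """The fused cells x genes signal consumed by every downstream stage."""

    X: np.ndarray
    cell_ids: list
    gene_ids: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if np.isnan(self.X).any() or (self.X < 0).any():
            raise ValueError("GIM must be nonnegative with no NaN")

    @property
    def shape(self):
        return self.X.shape

    def restrict_genes(self, genes):
        idx = [self.gene_ids.index(g) for g in genes]
        return GeneIntegrationMatrix(
            self.X[:, idx], list(self.cell_ids), [self.gene_ids[i] for i in idx],
            dict(self.provenance),
        )


def normalize_rna(counts, target_sum: float = 10_000.0):
    """Log-normalize RNA counts: log1p of counts scaled to `target_sum` per cell.

    All-zero cells are dropped with a warning. Returns (matrix, kept_cell_index).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0 or not counts.any():
        raise ValueError("all-zero count matrix")
    totals = counts.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        logger.warning("dropping %d all-zero cells", int((~keep).sum()))
    counts = counts[keep]
    scaled = counts / counts.sum(axis=1, keepdims=True) * target_sum
    return np.log1p(scaled), np.flatnonzero(keep)


def tfidf_normalize(peaks, scale: float = 10_000.0):
    """TF-IDF transform of a cells x peaks matrix.

    value(c, p) = log1p( count(c,p)/total(c) * n_cells/(1 + n_cells_with_peak(p))
    * scale ). Zero-total cells are dropped with a warning; returns
    (matrix, kept_cell_index).
    """
    peaks = np.asarray(peaks, dtype=float)
    if (peaks < 0).any():
        raise ValueError("peak matrix must be nonnegative")
    totals = peaks.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        logger.warning("dropping %d zero-total cells", int((~keep).sum()))
    peaks = peaks[keep]
    tf = peaks / peaks.sum(axis=1, keepdims=True)
    idf = peaks.shape[0] / (1.0 + (peaks > 0).sum(axis=0))
    return np.log1p(tf * idf * scale), np.flatnonzero(keep)


def compute_rp_scores(peaks, peak_coords: pd.DataFrame, genes: pd.DataFrame,
                      decay_bp: int = DEFAULT_DECAY_BP,
                      window_bp: int = DEFAULT_WINDOW_BP,
                      cell_ids=None) -> GeneActivityMatrix:
    """Regulatory-potential gene activity: distance-decayed sum of peak signal.

    RP(c, g) = sum over peaks p within `window_bp` of gene g's TSS of
    access(c, p) * 2^(-d(p, g)/decay_bp), where d is the distance from the
    peak center to the TSS, taken as 0 when the peak overlaps the promoter
    region or the gene body. Coordinates are BED-style 0-based half-open.
    """
    if decay_bp <= 0:
        raise ValueError("decay_bp must be positive")
    peaks = np.asarray(peaks, dtype=float)
    n_cells = peaks.shape[0]
    values = np.zeros((n_cells, len(genes)))
    chroms = set(genes["chrom"])
    skipped = int((~peak_coords["chrom"].isin(chroms)).sum())
    if skipped:
        logger.warning("ignoring %d peaks on chromosomes absent from annotation",
                       skipped)
    centers = (peak_coords["start"].to_numpy() + peak_coords["end"].to_numpy()) / 2.0
    for gi, gene in enumerate(genes.itertuples(index=False)):
        on_chrom = (peak_coords["chrom"] == gene.chrom).to_numpy()
        if not on_chrom.any():
            continue
        d = np.abs(centers - gene.tss)
        body_lo, body_hi = min(gene.start, gene.end), max(gene.start, gene.end)
        overlaps = (
            (peak_coords["end"].to_numpy() > body_lo)
            & (peak_coords["start"].to_numpy() < body_hi)
        )
        d = np.where(overlaps, 0.0, d)
        sel = on_chrom & (d <= window_bp)
        if not sel.any():
            continue
        w = np.power(2.0, -d[sel] / decay_bp)
        values[:, gi] = peaks[:, sel] @ w
    return GeneActivityMatrix(values=values, gene_ids=list(genes["gene_id"]),
                              cell_ids=list(cell_ids) if cell_ids is not None else [])


def _standardize_drop_constant(mat):
    mat = np.asarray(mat, dtype=float)
    std = mat.std(axis=0)
    keep = std > 1e-12
    if not keep.all():
        logger.warning("dropping %d constant columns before CCA",
                       int((~keep).sum()))
    mat = mat[:, keep]
    return (mat - mat.mean(axis=0)) / mat.std(axis=0), np.flatnonzero(keep)


def cca_align(rna, activity, k: int = 20):
    """Canonical correlation analysis between the two modalities.

    Column-standardizes both matrices (constant columns dropped), then
    computes the top-k canonical directions via QR factorizations and an SVD,
    so the canonical correlations come out in [0, 1] (clipped) and
    nonincreasing.

    Returns (shared_embedding cells x k, correlations, (x_loadings, y_loadings),
    (kept_x_cols, kept_y_cols)).
    """
    Xs, keep_x = _standardize_drop_constant(rna)
    Ys, keep_y = _standardize_drop_constant(activity)
    if Xs.shape[0] != Ys.shape[0]:
        raise ValueError("modalities must share the cell axis")
    if k > min(Xs.shape[1], Ys.shape[1]):
        raise ValueError("k exceeds the usable column count")
    qx, rx = np.linalg.qr(Xs)
    qy, ry = np.linalg.qr(Ys)
    u, s, vt = np.linalg.svd(qx.T @ qy, full_matrices=False)
    corrs = np.clip(s[:k], 0.0, 1.0)
    a = sla.lstsq(rx, u[:, :k])[0]
    b = sla.lstsq(ry, vt.T[:, :k])[0]
    embedding = 0.5 * (Xs @ a + Ys @ b)
    return embedding, corrs, (a, b), (keep_x, keep_y)


def _minmax_per_gene(mat):
    lo = mat.min(axis=0)
    rng = mat.max(axis=0) - lo
    rng = np.where(rng > 0, rng, 1.0)
    return (mat - lo) / rng


def build_gim(rna_norm, activity: GeneActivityMatrix, mode: str = "average",
              rna_gene_ids=None, cell_ids=None, n_neighbors: int = 10,
              cca_k: int = 20) -> GeneIntegrationMatrix:
    """Fuse normalized expression and gene activity into the GIM.

    mode="average": mean of the two per-gene min-max-scaled modalities.
    mode="cca_smoothed": the activity rows are first replaced by their
    nearest-neighbor averages in CCA space (Seurat-flavored smoothing), then
    fused the same way.
    """
    rna_norm = np.asarray(rna_norm, dtype=float)
    rna_genes = list(rna_gene_ids) if rna_gene_ids is not None else list(
        activity.gene_ids)
    shared = [g for g in rna_genes if g in set(activity.gene_ids)]
    if not shared:
        raise ValueError("empty gene intersection between modalities")
    ri = [rna_genes.index(g) for g in shared]
    ai = [activity.gene_ids.index(g) for g in shared]
    rna_s = _minmax_per_gene(rna_norm[:, ri])
    act = activity.values[:, ai]
    if mode == "cca_smoothed":
        k = min(cca_k, rna_s.shape[1] - 1, act.shape[1] - 1)
        k = max(k, 1)
        emb, _, _, _ = cca_align(rna_norm[:, ri], act, k=k)
        nn = NearestNeighbors(n_neighbors=min(n_neighbors, emb.shape[0]))
        nn.fit(emb)
        _, idx = nn.kneighbors(emb)
        act = act[idx].mean(axis=1)
    elif mode != "average":
        raise ValueError(f"unknown fusion mode: {mode!r}")
    act_s = _minmax_per_gene(act)
    X = 0.5 * (rna_s + act_s)
    cells = list(cell_ids) if cell_ids is not None else [
        f"cell{i}" for i in range(X.shape[0])
    ]
    return GeneIntegrationMatrix(
        X=X, cell_ids=cells, gene_ids=shared,
        provenance={"mode": mode, "rna": "lognorm10k-minmax",
                    "activity": "rp-minmax"},
    )


class MultiomeIntegrator(BaseEstimator):
    """Estimator that builds a Gene Integration Matrix from paired counts.

    Parameters
    ----------
    mode : "average" or "cca_smoothed" fusion of the scaled modalities.
    decay_bp, window_bp : regulatory-potential decay half-distance and window.
    target_sum : per-cell scaling total for RNA log-normalization.

    Attributes (after fit)
    ----------------------
    gim_ : GeneIntegrationMatrix
    activity_ : GeneActivityMatrix
    kept_cells_ : indices of cells retained in both modalities
    """

    def __init__(self, mode="average", decay_bp=DEFAULT_DECAY_BP,
                 window_bp=DEFAULT_WINDOW_BP, target_sum=10_000.0):
        self.mode = mode
        self.decay_bp = decay_bp
        self.window_bp = window_bp
        self.target_sum = target_sum

    def fit(self, rna_counts, peak_counts, peak_coords, annotation,
            cell_ids=None, gene_ids=None):
        rna_counts = np.asarray(rna_counts)
        peak_counts = np.asarray(peak_counts)
        if rna_counts.shape[0] != peak_counts.shape[0]:
            raise ValueError("paired modalities must share the cell axis")
        cell_ids = list(cell_ids) if cell_ids is not None else [
            f"cell{i}" for i in range(rna_counts.shape[0])
        ]
        gene_ids = list(gene_ids) if gene_ids is not None else list(
            annotation["gene_id"])
        rna_norm, keep_rna = normalize_rna(rna_counts, self.target_sum)
        tfidf, keep_atac = tfidf_normalize(peak_counts[keep_rna])
        kept = keep_rna[keep_atac]
        rna_norm = rna_norm[keep_atac]
        if len(kept) < len(cell_ids):
            logger.warning("dropped %d cells missing signal in a modality",
                           len(cell_ids) - len(kept))
        activity = compute_rp_scores(
            tfidf, peak_coords, annotation, self.decay_bp, self.window_bp,
            cell_ids=[cell_ids[i] for i in kept],
        )
        self.activity_ = activity
        self.kept_cells_ = kept
        self.gim_ = build_gim(
            rna_norm, activity, mode=self.mode, rna_gene_ids=gene_ids,
            cell_ids=[cell_ids[i] for i in kept],
        )
        return self

    def fit_transform(self, rna_counts, peak_counts, peak_coords, annotation,
                      **kw) -> GeneIntegrationMatrix:
        return self.fit(rna_counts, peak_counts, peak_coords, annotation,
                        **kw).gim_
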