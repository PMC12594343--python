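"""Synthetic paired multiome over a known bifurcating differentiation.

The generator lays cells along a Y-shaped trajectory in pseudotime t in [0, 1]:
a shared trunk (pre-branching, then branch-point cells) that splits into two
descendant lineages. Gene expression follows smooth mean programs:

* flat housekeeping genes,
* monotone "ramp" genes shared by both lineages (the broad transcriptional
  drift of differentiation, which carries most of the pseudotime signal),
* late lineage-marker genes that switch on well after the branch point in
  one descendant lineage only (the terminal identity programs that make the
  two lineages separable),
* planted branch-specific genes: near-silent before the branch point, rising
  sharply in branch-point cells, sustained in exactly one descendant lineage
  and decaying in the other.

Counts are negative-binomial around the mean programs with per-cell library
size factors. Each gene gets 1-3 linked ATAC peaks within +/-50 kb of its
TSS whose expected accessibility is proportional to the gene's program, so
chromatin tracks expression by construction.

Everything is reproducible bitwise from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import os

import numpy as np
import pandas as pd

from . import io as bio

# pseudotime layout of the Y shape
T_BRANCH_START = 0.4
T_BRANCH_END = 0.6

# phase occupancy: trunk-heavy so that branch-point cells sit at or above the
# global median pseudotime (the geometry the phase classifier expects)
PHASE_FRACTIONS = {"pre": 0.45, "branch": 0.25, "L1": 0.15, "L2": 0.15}

RAMP_GENE_FRACTION = 0.3
MARKER_GENE_FRACTION = 0.3
PEAK_WIDTH = 500
PEAK_MAX_DIST = 50_000


@dataclass
class BifurcationTruth:
    """Ground truth of a simulated bifurcation."""

    n_cells: int
    n_genes: int
    n_peaks: int
    phase_fractions: dict
    planted_branch_genes: list
    planted_lineage: dict  # gene id -> {"lineage1", "lineage2", "both"}
    true_pseudotime: np.ndarray  # per cell, in [0, 1]
    true_lineage: np.ndarray  # per cell, in {"pre", "branch", "L1", "L2"}
    seed: int


@dataclass
class SyntheticMultiome:
    """Paired RNA/ATAC counts with generation ground truth."""

    rna_counts: np.ndarray  # cells x genes, nonnegative int
    peak_counts: np.ndarray  # cells x peaks, nonnegative int
    peak_to_gene: pd.DataFrame  # peak_id, gene_id, distance (signed bp to TSS)
    gene_annotation: pd.DataFrame  # gene_id, chrom, strand, tss, start, end
    peak_bed: pd.DataFrame  # chrom, start, end, name
    truth: BifurcationTruth
    cell_ids: list = field(default_factory=list)
    gene_ids: list = field(default_factory=list)
    rna_mean: np.ndarray = None  # expected expression programs (cells x genes)
    peak_mean: np.ndarray = None  # expected accessibility (cells x peaks)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _nb_sample(rng, mean, dispersion):
    """Negative binomial with var = mean + dispersion * mean^2."""
    mean = np.maximum(mean, 1e-9)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _mean_programs(t, lineage, gene_kind, gene_lineage, base, amp, ramp_center,
                   ramp_up):
    """Expected expression (cells x genes) before library-size factors/noise."""
    n_cells, n_genes = len(t), len(gene_kind)
    mu = np.empty((n_cells, n_genes))
    on_l1 = lineage == "L1"
    on_l2 = lineage == "L2"
    for g in range(n_genes):
        kind = gene_kind[g]
        if kind == "flat":
            mu[:, g] = base[g]
        elif kind == "ramp":
            s = _sigmoid((t - ramp_center[g]) / 0.15)
            if not ramp_up[g]:
                s = 1.0 - s
            mu[:, g] = base[g] * (0.15 + 0.85 * s)
        elif kind == "marker":
            s = _sigmoid((t - 0.7) / 0.08)
            own = on_l1 if gene_lineage[g] == "lineage1" else on_l2
            mu[:, g] = base[g] * (0.1 + 0.9 * s * own)
        else:  # planted branch gene
            rise = _sigmoid((t - T_BRANCH_START) / 0.04)
            keep = np.ones(n_cells)
            decay = _sigmoid(-(t - (T_BRANCH_END + 0.1)) / 0.05)
            if gene_lineage[g] == "lineage1":
                keep[on_l2] = decay[on_l2]
            else:
                keep[on_l1] = decay[on_l1]
            mu[:, g] = base[g] + amp[g] * rise * keep
    return mu


def simulate_bifurcation(n_cells=300, n_genes=200, n_branch_genes=20,
                         noise=0.3, seed=0) -> SyntheticMultiome:
    """Simulate a paired multiome over a two-lineage bifurcation.

    Parameters
    ----------
    n_cells, n_genes : sizes of the count matrix (n_cells >= 60).
    n_branch_genes : number of planted branch-specific genes (< n_genes).
    noise : negative-binomial dispersion, var = mu + noise * mu^2.
    seed : RNG seed; output is bitwise reproducible.
    """
    if n_cells < 60 or n_genes <= 0 or n_branch_genes <= 0:
        raise ValueError("n_cells >= 60, n_genes > 0, n_branch_genes > 0 required")
    if n_branch_genes >= n_genes:
        raise ValueError("n_branch_genes must be smaller than n_genes")
    rng = np.random.default_rng(seed)

    # --- cells: phase occupancy and pseudotime -------------------------
    fr = PHASE_FRACTIONS
    n_pre = int(round(fr["pre"] * n_cells))
    n_br = int(round(fr["branch"] * n_cells))
    n_l1 = int(round(fr["L1"] * n_cells))
    n_l2 = n_cells - n_pre - n_br - n_l1
    lineage = np.array(
        ["pre"] * n_pre + ["branch"] * n_br + ["L1"] * n_l1 + ["L2"] * n_l2
    )
    t = np.concatenate([
        rng.uniform(0.0, T_BRANCH_START, n_pre),
        rng.uniform(T_BRANCH_START, T_BRANCH_END, n_br),
        rng.uniform(T_BRANCH_END, 1.0, n_l1),
        rng.uniform(T_BRANCH_END, 1.0, n_l2),
    ])
    order = rng.permutation(n_cells)
    lineage, t = lineage[order], t[order]

    # --- genes: kinds and program parameters ---------------------------
    gene_ids = [f"gene{i:04d}" for i in range(n_genes)]
    planted_idx = rng.choice(n_genes, size=n_branch_genes, replace=False)
    planted_idx.sort()
    gene_kind = np.array(["flat"] * n_genes, dtype=object)
    rest = np.setdiff1d(np.arange(n_genes), planted_idx)
    n_ramp = int(round(RAMP_GENE_FRACTION * len(rest)))
    n_marker = int(round(MARKER_GENE_FRACTION * len(rest)))
    dyn_idx = rng.choice(rest, size=n_ramp + n_marker, replace=False)
    ramp_idx, marker_idx = dyn_idx[:n_ramp], dyn_idx[n_ramp:]
    gene_kind[ramp_idx] = "ramp"
    gene_kind[marker_idx] = "marker"
    gene_kind[planted_idx] = "branch"

    gene_lineage = np.array(["both"] * n_genes, dtype=object)
    gene_lineage[planted_idx] = [
        "lineage1" if i % 2 == 0 else "lineage2" for i in range(n_branch_genes)
    ]
    gene_lineage[marker_idx] = [
        "lineage1" if i % 2 == 0 else "lineage2" for i in range(n_marker)
    ]

    base = np.exp(rng.normal(np.log(1.5), 0.8, n_genes))
    base[ramp_idx] = np.exp(rng.normal(np.log(4.0), 0.5, n_ramp))
    base[marker_idx] = np.exp(rng.normal(np.log(4.0), 0.5, n_marker))
    base[planted_idx] = 0.2
    amp = np.zeros(n_genes)
    amp[planted_idx] = rng.uniform(8.0, 15.0, n_branch_genes)
    ramp_center = rng.uniform(0.25, 0.75, n_genes)
    ramp_up = rng.random(n_genes) < 0.5

    mu = _mean_programs(t, lineage, gene_kind, gene_lineage, base, amp,
                        ramp_center, ramp_up)
    size_factor = np.exp(rng.normal(0.0, 0.3, n_cells))
    rna_counts = _nb_sample(rng, mu * size_factor[:, None], noise).astype(np.int64)

    # --- gene annotation and linked ATAC peaks -------------------------
    gene_start = 1_000_000 + 200_000 * np.arange(n_genes)
    strand = np.where(np.arange(n_genes) % 2 == 0, "+", "-")
    gene_end = gene_start + 20_000
    tss = np.where(strand == "+", gene_start, gene_end)
    gene_annotation = pd.DataFrame({
        "gene_id": gene_ids, "chrom": "chr1", "strand": strand,
        "tss": tss, "start": gene_start, "end": gene_end,
    })

    peak_rows, link_rows, peak_mu_cols = [], [], []
    pk = 0
    prog_max = mu.max(axis=0)
    for g in range(n_genes):
        for _ in range(rng.integers(1, 4)):
            dist = int(rng.integers(-PEAK_MAX_DIST, PEAK_MAX_DIST + 1))
            center = int(tss[g]) + dist
            name = f"peak{pk:05d}"
            peak_rows.append({
                "chrom": "chr1",
                "start": max(center - PEAK_WIDTH // 2, 0),
                "end": max(center - PEAK_WIDTH // 2, 0) + PEAK_WIDTH,
                "name": name,
            })
            link_rows.append({"peak_id": name, "gene_id": gene_ids[g],
                              "distance": dist})
            prog = mu[:, g] / max(prog_max[g], 1e-9)
            peak_mu_cols.append(0.2 + 1.5 * prog)
            pk += 1
    peak_bed = pd.DataFrame(peak_rows)
    peak_to_gene = pd.DataFrame(link_rows)
    peak_mu = np.column_stack(peak_mu_cols)
    peak_counts = _nb_sample(
        rng, peak_mu * size_factor[:, None], noise
    ).astype(np.int64)

    truth = BifurcationTruth(
        n_cells=n_cells, n_genes=n_genes, n_peaks=pk,
        phase_fractions=dict(fr),
        planted_branch_genes=[gene_ids[i] for i in planted_idx],
        planted_lineage={gene_ids[i]: gene_lineage[i] for i in range(n_genes)},
        true_pseudotime=t, true_lineage=lineage, seed=seed,
    )
    cell_ids = [f"cell{i:04d}" for i in range(n_cells)]
    return SyntheticMultiome(
        rna_counts=rna_counts, peak_counts=peak_counts,
        peak_to_gene=peak_to_gene, gene_annotation=gene_annotation,
        peak_bed=peak_bed, truth=truth, cell_ids=cell_ids, gene_ids=gene_ids,
        rna_mean=mu, peak_mean=peak_mu,
    )


def write_multiome(sim: SyntheticMultiome, directory) -> dict:
    """Write a simulation as MTX/TSV/BED files; returns the file map."""
    if not sim.truth.planted_branch_genes:
        raise ValueError("simulation has no planted branch genes")
    os.makedirs(directory, exist_ok=True)
    rna_dir = os.path.join(directory, "rna")
    atac_dir = os.path.join(directory, "atac")
    bio.write_counts_dir(sim.rna_counts, sim.cell_ids, sim.gene_ids, rna_dir)
    peak_names = sim.peak_bed["name"].tolist()
    bio.write_counts_dir(sim.peak_counts, sim.cell_ids, peak_names, atac_dir)
    bed_path = os.path.join(atac_dir, "peaks.bed")
    bio.write_bed(sim.peak_bed, bed_path)
    ann_path = os.path.join(directory, "genes.tsv")
    bio.write_annotation(sim.gene_annotation, ann_path)
    links_path = os.path.join(directory, "peak_to_gene.tsv")
    sim.peak_to_gene.to_csv(links_path, sep="\t", index=False)
    truth_cells = pd.DataFrame({
        "cell_id": sim.cell_ids,
        "true_pseudotime": sim.truth.true_pseudotime,
        "true_lineage": sim.truth.true_lineage,
    })
    truth_cells_path = os.path.join(directory, "truth_cells.tsv")
    truth_cells.to_csv(truth_cells_path, sep="\t", index=False)
    truth_genes = pd.DataFrame({
        "gene_id": sim.gene_ids,
        "planted": [g in set(sim.truth.planted_branch_genes) for g in sim.gene_ids],
        "lineage": [sim.truth.planted_lineage[g] for g in sim.gene_ids],
    })
    truth_genes_path = os.path.join(directory, "truth_genes.tsv")
    truth_genes.to_csv(truth_genes_path, sep="\t", index=False)
    return {
        "rna": rna_dir, "atac": atac_dir, "peaks_bed": bed_path,
        "annotation": ann_path, "peak_to_gene": links_path,
        "truth_cells": truth_cells_path, "truth_genes": truth_genes_path,
    }


def read_multiome(directory):
    """Read back what `write_multiome` wrote.

    Returns (rna, cell_ids, gene_ids, peaks, peak_names, peak_bed, annotation,
    truth_cells, truth_genes).
    """
    rna, cells, genes = bio.read_counts_dir(os.path.join(directory, "rna"))
    atac, cells2, peak_names = bio.read_counts_dir(os.path.join(directory, "atac"))
    if cells != cells2:
        raise ValueError("RNA and ATAC barcodes differ")
    peak_bed = bio.read_bed(os.path.join(directory, "atac", "peaks.bed"))
    ann = bio.read_annotation(os.path.join(directory, "genes.tsv"))
    truth_cells = pd.read_csv(os.path.join(directory, "truth_cells.tsv"), sep="\t")
    truth_genes = pd.read_csv(os.path.join(directory, "truth_genes.tsv"), sep="\t")
    return rna, cells, genes, atac, peak_names, peak_bed, ann, truth_cells, truth_genes
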