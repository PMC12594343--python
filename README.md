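# branchgas

Branch-specific regulatory gene discovery from paired single-cell
multiome data (scRNA-seq + scATAC-seq of the same cells).

When a differentiating cell population splits into two lineages, the genes
that drive the decision turn on sharply at the branch point and stay on in
exactly one descendant lineage. Classical differential expression finds
global markers but misses these context-dependent regulators. `branchgas`
finds them by combining three ingredients:

1. **Gene Integration Matrix (GIM).** RNA counts are log-normalized;
   chromatin accessibility is TF-IDF weighted and summarized per gene as a
   distance-decayed regulatory-potential score
   RP(c, g) = Σ_p access(c, p) · 2^(−d(p,g)/10 kb) over peaks within 50 kb
   of the TSS. The two modalities are fused per gene into one nonnegative
   cells × genes matrix X.
2. **Bifurcating trajectory.** PCA + Gaussian-mixture clustering, a minimum
   spanning tree over cluster centroids, per-lineage pseudotime in [0, 1],
   and classification of clusters into pre-branching / branching /
   post-branching phases using thresholds ρ = 2 (associated lineages) and
   θ = 0.3 (median-pseudotime spread).
3. **Gene Attention Scores (GAS).** X becomes a gene-cell bipartite graph
   (edge iff the gene is expressed in the cell). A 2-layer, 16-head
   heterogeneous graph transformer with relation-specific projections is
   trained unsupervised by minimizing the KL divergence
   ℒ = Σ_{ij} X̃_ij log(X̃_ij / X̂_ij) between per-cell expression
   distributions and their reconstruction from the learned embeddings
   (Adam, lr 0.01, 100 epochs). The attention weights α_ij^h from all
   heads, layers and both relation directions are squared, summed and
   normalized per cell into the GAS matrix — a per-cell measure of each
   gene's importance.

Genes ranked by GAS within the branching-phase cells, filtered to those
expressed in ≥ 50% of them, are the branch-specific candidates. They are
validated by rebuilding the trajectory from the selected genes alone
(Pearson correlation of pseudotimes), staged differential expression
(Welch t-tests between adjacent clusters, Benjamini–Hochberg FDR), and
per-phase gene-regulatory networks from tree-ensemble importances.

A synthetic-data module generates paired multiome counts over a known
Y-shaped bifurcation with planted branch genes, so the whole pipeline has
a ground-truth test surface without any downloads.

## Worked example

```python
import numpy as np
from branchgas import (
    simulate_bifurcation, MultiomeIntegrator, TrajectoryInference,
    PhaseClassifier, phase_cells, GeneAttentionHGT, rank_genes,
    select_branch_genes,
)

sim = simulate_bifurcation(n_cells=300, n_genes=200, n_branch_genes=20,
                           noise=0.3, seed=7)
gim = MultiomeIntegrator().fit_transform(
    sim.rna_counts, sim.peak_counts, sim.peak_bed, sim.gene_annotation,
    cell_ids=sim.cell_ids, gene_ids=sim.gene_ids)

traj = TrajectoryInference(n_components=20, seed=9)
traj.fit(gim.X, cell_totals=gim.X.sum(axis=1))
phases = PhaseClassifier().fit(traj.lineage_model_)
branch_cells = phase_cells(phases.labeling_, traj.clustering_, "branching")

hgt = GeneAttentionHGT(epochs=100, lr=0.01, seed=11).fit(gim)
table = rank_genes(hgt.gas_, [int(c) for c in branch_cells])
selected = select_branch_genes(table, gim, branch_cells,
                               top_n=40, prevalence=0.5)

planted = set(sim.truth.planted_branch_genes)
print(f"lineages: {traj.lineage_model_.n_lineages}, "
      f"phases: {sorted(set(phases.phase_.values()))}")
print(f"selected {len(selected)} genes, "
      f"{len(planted & set(selected))} of {len(planted)} planted recovered")
```

Output:

```
lineages: 2, phases: ['branching', 'post', 'pre']
selected 40 genes, 20 of 20 planted recovered
```

The trajectory recovers the planted Y shape (two lineages sharing the
trunk, with the pre/branching/post phases in order), and the attention
ranking places all 20 planted branch genes inside the top-40 selection:
the genes that rise at the branch point and commit to one lineage are
exactly the ones the attention model scores highest in branch-point cells.

The same stages are available from a shell:

```bash
branchgas simulate --cells 300 --genes 200 --branch-genes 20 --seed 7 --out sim/
branchgas integrate --rna sim/rna --atac sim/atac --annotation sim/genes.tsv --out gim/
branchgas trajectory --gim gim/ --pcs 20 --out traj/
branchgas phases --trajectory traj/ --out phases/
branchgas train --gim gim/ --epochs 100 --out gas/
branchgas run --config run.json   # the full pipeline with one config
```

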