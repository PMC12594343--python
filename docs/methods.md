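# Methods

`branchgas` identifies genes that drive a fate bifurcation from paired
single-cell RNA and chromatin-accessibility profiles of the same cells. The
pipeline has three parts: building a fused gene-by-cell signal (the Gene
Integration Matrix, GIM), inferring a bifurcating trajectory and its phases,
and learning per-cell gene importance with a heterogeneous graph
transformer whose attention yields the Gene Attention Score (GAS) matrix
used for selection. This note records the model, its assumptions, the
parameters that matter, and the choices made where the design was open.

## Gene Integration Matrix

RNA counts are library-size normalized (counts scaled to a common per-cell
total of 10,000, then log1p). The peak matrix is TF-IDF reweighted:
`log1p(tf * idf * 1e4)` with `tf = count/cell total` and
`idf = n_cells / (1 + n_cells with peak)`. Chromatin is summarized per gene
as a regulatory-potential (RP) score: the sum of peak signal within
`window_bp` (default 50 kb) of the gene's TSS, weighted `2^(-d/decay_bp)`
with `decay_bp` = 10 kb, where `d` is the peak-center-to-TSS distance and
`d = 0` for peaks overlapping the promoter or gene body. Coordinates are
BED-convention 0-based half-open; strand is used only to place the TSS.

The two modalities are fused per gene. The default (`mode="average"`) is
the mean of the two per-gene min-max-scaled matrices, which guarantees a
nonnegative GIM on a common [0, 1] scale. `mode="cca_smoothed"` first
replaces each cell's activity row by its 10-nearest-neighbor average in CCA
space before fusing, trading a little signal independence for noise
suppression. CCA itself is the classical formulation computed through
column standardization, QR factorization of both blocks and an SVD of
`Qx' Qy`, so canonical correlations are exact and lie in [0, 1]; constant
columns are dropped first. Simplifications relative to the heavier tools a
practitioner might use (variance-stabilizing RNA normalization, fragment
level ATAC models) are deliberate: they keep every step exactly
specifiable, at the cost of not reproducing those tools numerically.

## Trajectory and branching phases

The GIM is reduced to 20 principal components (deterministic sign fix:
each component's largest-magnitude loading is positive) and clustered with
a full-covariance Gaussian mixture (10 EM restarts, fixed seed). When the
mixture size is not given, it is chosen by BIC over k = 3..8 with one
structural preference: among candidate sizes, those whose cluster-centroid
minimum spanning tree exposes at least two root-to-leaf paths (i.e., an
actual bifurcation, the object of study) are preferred, then BIC decides.

Lineages are all root-to-leaf paths of the centroid MST. The root is the
user's choice, or automatically the leaf cluster with the lowest mean GIM
total (progenitors carry the lowest transcriptional load in this setting;
the MST-diameter endpoint is not used because when the two arms of the Y
are longer than the trunk, the diameter connects the two leaves and would
root the tree in a terminal state). A cell's pseudotime on a lineage is the
arc-length of its orthogonal projection onto the piecewise-linear centroid
path, normalized to [0, 1] per lineage; when a cell is equidistant from two
segments the earlier segment wins, which makes the map deterministic.
Lineage weights are the cell's posterior mass over the clusters of each
lineage, renormalized across lineages.

Clusters are assigned to pre-branching / branching / post-branching with
thresholds `rho` (minimum number of associated lineages, default 2) and
`theta` (maximum spread of per-lineage median pseudotimes, default 0.3 on
the [0, 1] scale). A cell lies on a lineage when its weight is at least
half its maximum weight, so trunk cells count for every lineage they
straddle; a lineage is associated with a cluster when at least
`assoc_frac` (0.2) of the cluster's cells lie on it. A cluster is *pre*
when it is associated with >= `rho` lineages, its per-lineage medians agree
within `theta`, and its overall median pseudotime is below the global
median; *post* when at least `dominant_frac` (0.8) of its cells lie
exclusively on one lineage and its median pseudotime is at or above the
global median; otherwise *branching*. Exclusive membership matters: trunk
cells straddle both lineages, so without it every trunk cluster would look
"dominant" on both. Comparing to the global median makes "early"/"late"
scale-free across datasets whose pseudotime spans differ, which is why the
defaults travel reasonably well.

## Graph transformer and Gene Attention Scores

The GIM becomes a bipartite graph: an edge joins gene i and cell j when
`X[j, i] > edge_threshold` (default 0), with binary weights. Gene nodes are
featurized by their expression profile across cells and cell nodes by their
profile across genes; independent linear maps project both into 256
dimensions and then to the 128-dimensional working width. Each of the 2
layers runs 16-head scaled dot-product attention per relation
(gene-to-cell and cell-to-gene), with relation-specific query/key/value
projections (per-head dimension 8), a concatenated-head output map, a
residual connection and layer normalization; both node sets update in
parallel from the previous layer's embeddings.

Training is unsupervised. The decoder reconstructs each cell's expression
distribution as the row-normalized softplus of the cell-gene embedding
inner products (a 1e-8 floor keeps rows normalizable when softplus
underflows), and the loss is the KL divergence between the per-cell input
distribution (GIM rows normalized with a 1e-8 pseudocount) and the
reconstruction. Row normalization is what makes a KL objective between two
nonnegative matrices well-posed and nonnegative. Optimization is full-graph
Adam, learning rate 0.01 halved after 10 epochs without improvement, 100
epochs, everything deterministic given the seed. Gradient clipping is
available but off by default: the large early steps are precisely what
shapes the expression-tracking attention, and clipping them measurably
erases the planted-gene signal on synthetic data. All arithmetic inside the network runs in float32 through a small
in-repo reverse-mode autodiff engine (dense matmul, broadcast arithmetic,
segment softmax via constant sparse gather/scatter operators, layer norm),
gradient-checked against central finite differences in the test suite.

The GAS matrix combines the mutual attention of the final epoch: for every
edge, the squared attention weights are summed over all heads, both
relation directions, and both layers, and each cell's scores are then
normalized to sum to one over its connected genes. The two directions
carry different information, and the distinction is load-bearing. The
cell-normalized direction (each cell's softmax over its gene neighborhood)
converges to a near-global gene weighting dominated by overall expression
structure — it cannot separate a branch-specific gene from a broadly
expressed one. The gene-side direction (each gene's attention over its
cells) concentrates a specifically expressed gene's mass on exactly the
cells that define its program, while a housekeeping gene spreads the same
mass over every cell; after per-cell normalization this is what ranks
branch genes above the background in branch-point cells. Combining both,
which is also the natural reading of "mutual" attention, is the default.

## Selection, validation, networks

Within a phase's cells, genes are ranked per cell by descending GAS
(average ranks on ties). A gene is selected when its mean rank is within
the top N (or its mean GAS above a threshold) and it is expressed — GIM
value > 0, the same predicate that creates graph edges — in at least 50% of
the phase's cells. Both filters are monotone, so tightening either can
only shrink the list.

Validation reruns the trajectory stage on the GIM restricted to the
selected genes and reports the Pearson correlation between restricted and
full-gene pseudotime plus a branch-topology comparison. Staged differential
expression compares adjacent trajectory clusters only: per-cell means of
the candidate gene set, Welch's t-test (the unequal-variance form, since
cluster variances differ), log2 fold change of group means with a
pseudocount only when a mean is zero, and Benjamini-Hochberg adjustment
across the supplied comparison family. Two degenerate cases are pinned
down: identical constant groups give t = 0, p = 1; constant groups with
different means give p = 0. Per-phase regulatory networks use the
tree-ensemble recipe: for each target gene a random forest (sqrt-of-p
candidate features per split) regresses the standardized target on all
other regulators, and the edge weight is the regulator's total
impurity-reduction importance; constant targets get zero importances and
self-edges are never emitted.

## Synthetic data

The generator emulates the study conditions end to end. Cells occupy a
Y-shaped pseudotime course: 45% trunk progenitors (t < 0.4), 25%
branch-point cells (0.4 <= t < 0.6), and 15% in each descendant lineage
(t >= 0.6); the trunk-heavy occupancy puts branch cells at or above the
global median pseudotime, which is the geometry the phase rules describe.
Genes follow smooth mean programs: 40% flat housekeeping; 30% monotone
ramps shared by both lineages (the broad transcriptional drift that
carries most of the pseudotime signal); 30% late lineage markers switching
on at t ~ 0.7 in one lineage only (the terminal identity programs that make
the lineages separable); and the planted branch genes — baseline 0.2,
rising sigmoidally at the branch point to an amplitude drawn U[8, 15],
sustained in exactly one lineage and decaying in the other. Counts are
negative binomial (`var = mu + noise * mu^2`, default dispersion 0.3) with
log-normal per-cell library factors (sigma 0.3). Each gene gets 1-3 ATAC
peaks within +/-50 kb of its TSS whose expected accessibility is an affine
function of the gene's program (so the expectation-level peak-gene
correlation is 1 by construction) at realistic scATAC sparsity (accessible
peak means ~1.7 counts); the noisy count-level correlation is necessarily
attenuated. The generator does not emulate doublets, batch effects,
ambient contamination, or multi-furcations, so green tests here say the
method recovers planted structure under clean bifurcation geometry — not
that it is robust to those artifacts on real data.

## Problem sizes and numerical notes

The reference study scale is 300 cells x 200 genes x ~400 peaks with 20
planted branch genes, three independent datasets (generator seeds), 100
training epochs; network inference fixtures use 200-500 observations and
100 trees, and the pipeline default of 100 trees per target keeps per-phase
networks of a few dozen genes quick. These sizes were chosen as the
smallest at which every stage's statistical behavior is visible and stable.
Degenerate inputs are handled explicitly: all-zero cells are dropped with a
warning, constant columns are removed before CCA, mixtures are ridge
regularized (1e-6), zero-variance groups short-circuit the t-test, and
cells without graph edges get all-zero GAS columns rather than NaNs.

## Known limitations

The fusion rule for the two modalities and the GAS normalization are
under-determined by the method description this package implements; both
are therefore isolated behind single functions (`build_gim`, `compute_gas`)
with the defaults documented above. Trajectories are restricted to a
single bifurcation (two lineages); multi-furcations are out of scope. The
attention model is trained full-graph and CPU-only, which is comfortable at
desk scale but would need minibatching beyond ~10^4 cells.
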