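# Methods

`ccinet` infers cell–cell interactions (CCIs) from single-cell RNA-seq counts
in three stages: unsupervised cell clustering, statistical labeling of
significant ligand–receptor (L–R) interactions between clusters, and a
supervised classifier that learns to reproduce those labels from expression
features. This note describes the models, their assumptions, the tunable
parameters, and the design decisions taken where more than one reasonable
construction existed.

## Preprocessing

Two tracks feed the pipeline.

**Clustering track.** Genes nonzero in strictly more than `gene_frac` (default
1%) of cells are kept, then cells nonzero in strictly more than `cell_frac`
(1%) of the retained genes. Each cell is scaled to a total of 10 000 counts
and transformed with the natural `log1p` (the Seurat convention). Genes are
ranked by standard deviation and the top `n_top` (2000) are retained. Strict
inequalities implement "more than 1%"; filtering applies genes first, then
cells, in one pass.

**Interaction track.** Differential expression is one-vs-rest per cluster with
the Wilcoxon rank-sum test (SciPy's `mannwhitneyu`, exact for small groups),
one-sided *greater* because the pipeline needs over-expressed signaling genes;
the flag threshold is a raw p ≤ 0.05 with an optional Benjamini–Hochberg
switch that is off by default. An L–R pair survives projection when some
cluster over-expresses every ligand subunit and some cluster over-expresses
every receptor subunit; when a protein–protein interaction edge list is
supplied, at least one (ligand-subunit, receptor-subunit) edge must also be
present. Cluster-level expression summaries use a truncated mean that drops
`floor(0.10 · n)` values from *each* tail, damping extreme values.

## Cluster model

A fully connected autoencoder (AE) with encoder widths input→256→128→32
(decoder mirrored; hidden ReLU, linear outputs) is pretrained full-batch on
the reconstruction objective `L_res = ||X − X̂||²_F / (2N)` with Adam at
lr 1e-3 for 80 epochs. The cell graph links each cell to its K = 10 nearest
Euclidean neighbors in the 50-component PCA space of the log-normalized
variable-gene matrix, symmetrized by union with deterministic index
tie-breaks, and is renormalized as `D̃^{-1/2}(A + I)D̃^{-1/2}`.

The GCN branch propagates through this normalized adjacency; at every depth
its output is fused with the matching encoder representation,
`Z̃ = (1 − ε)Z + εH` with ε = 0.5, and the final GCN layer produces an
assignment distribution Z by row softmax. Soft assignments use a Student's-t
kernel with v = 1 degree of freedom around trainable centers μ_j initialized
by k-means on the pretrained embedding (k-means re-seeds, up to 10 times, if
a cluster comes back empty). The self-training target
`p_ij ∝ q_ij² / f_j` (f_j the soft cluster frequencies) is refreshed every 5
epochs, and the joint objective

    L = α·KL(P‖Q) + β·KL(P‖Z) + L_res,    α = 1e-4, β = 1e-3

is descended full-batch with Adam at lr 1e-4 for 60 epochs. Hard labels are
the row argmax of Q. The joint phase is intentionally short: on data with
clear population structure the pretrained embedding plus k-means is already
close, and the joint phase sharpens assignments rather than restructuring
them; these widths and epoch counts are the package defaults chosen so a
full 1000-cell training runs in about a minute on one CPU core.

When the cluster number is not supplied it is estimated by Louvain community
detection (resolution 1.0, seeded) on the cell graph.

Setting ε = 1 and β = 0 removes the GCN's influence and reduces the method to
an AE with deep embedded clustering; this degenerate configuration is
supported and tested.

All logarithms are floored at 1e-12. Every source of randomness — weight
initialization, k-means, permutations — derives from a single user seed.

## Interaction probability and significance labeling

For source cluster i, target cluster j and pair k the interaction probability
is the product `P_ij^k = L_i · R_j` of the clusters' complex summaries, where
a complex with subunits s₁…s_m is summarized by the geometric mean of the
subunits' truncated-mean expressions — one silent subunit inactivates the
whole complex. Single-subunit complexes bypass the log/exp round-trip so that
ties in the permutation null remain exact.

Significance is a majority vote (≥ 2 of 3) over three in-package scorers:

1. **Regularized product** `√(l·r) / (μ + √(l·r))` on plain cluster means,
   with μ the mean of the processed expression matrix, thresholded at 0.5
   (SingleCellSignalR-style).
2. **Permutation test on plain mean products** (CellPhoneDB-style), p ≤ 0.01.
3. **Permutation test on truncated-mean products** (CellChat-style), p ≤ 0.01.

Permutation tests shuffle the cluster labels over all cells and use the
add-one estimator `p = (1 + #{perm ≥ obs}) / (1 + n_perm)` with
n_perm = 1000, so p ∈ [1/(n_perm+1), 1] and a zero observed statistic yields
p = 1. Inside `label_significant` both permutation scorers share the same
label permutations; this is faster and makes the two votes consistent, at the
price of correlating them — the single-pair `permutation_pvalue` entry point
draws independent permutations and is what the type-I-error calibration
uses.

## L–R pair graph and supervised interaction model

Pairs are ranked by their total interaction probability over all ordered
cluster combinations; the top 200 become graph nodes. Edges connect nodes
whose probability profiles have |Pearson r| ≥ τ = 0.95 (population
covariance; zero-variance profiles get correlation 0 with a warning). The
printed inequality in the source method's adjacency rule points the other way
(edge when r < τ), which would connect essentially all weakly related pairs
and contradicts the stated aim of capturing correlations; the package
defaults to |r| ≥ τ and preserves the literal rule behind `literal_lt=True`.

Each ordered cluster pair is one sample. Its features stack, per pair, the
per-cell complex-ligand expression over source-cluster cells and complex-
receptor expression over target-cluster cells, each (pairs × cells) block
reduced to d columns by exact truncated SVD (deterministic sign convention:
the largest-magnitude cell loading of each component is positive;
rank-deficient blocks are zero-padded). The SVD resolves the varying
cell-count problem — clusters of different sizes yield fixed-width features.
`d = 64` is the general default; the desk-scale experiments use d = 32, which
is past the elbow of the singular-value spectrum for a few hundred cells per
cluster and halves the cost.

The classifier combines a residual MLP over feature rows (width 128, three
identity-skip blocks) with a two-layer GCN over the pair graph, by row-wise
dot product, followed by a final fully connected layer over pairs and a
sigmoid. Training minimizes the focal loss with γ = 2 (probabilities clamped
to [1e-7, 1−1e-7]) under 5-fold cross-validation stratified by each sample's
positive-label density; per-fold feature standardization is fit on the
training folds only. Recall, precision, accuracy, F1 and AUC are reported per
fold; a single-class fold reports AUC as missing with a warning.

Two design choices matter for generalization across folds. First, the GCN's
node embeddings start *identical* across pairs, so at initialization the
model is one shared row-wise predictor and node embeddings only differentiate
where the labels warrant it. Second, a small per-step shrinkage
(`pair_shrink = 0.005`) pulls node-embedding deviations, the final layer's
off-diagonal weights, and its bias toward the shared predictor — pair-identity
channels must be continually re-earned by the labels. Without these, the
model memorizes which pairs were positive in training and systematically
inverts its ranking on pairs whose only positives are held out.

## Evaluation metrics

The adjusted Rand index is computed through the contingency-table identity;
its equality with the definitional pair-counting form is verified in the test
suite over exhaustive small partitions rather than assumed. The degenerate
case in which max(RI) equals E[RI] (e.g. both partitions trivial) returns 1
by convention, logged. ROC AUC is the Mann–Whitney normalization with ties
counted half. Metrics with zero denominators are reported as explicit missing
values, never as silent zeros.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, not
biological realism. Counts are gamma-Poisson (negative binomial) with
gene-level dispersion 0.3 — matching UMI overdispersion — and log-normal
baseline means (σ = 0.5) across genes. Each cluster over-expresses a disjoint
block of marker genes by `de_strength` (default 8), making planted labels
unambiguous. With `de_strength = 1` the generator produces an exchangeable
null.

Planted interactions are cluster-restricted: a planted pair's ligand genes
are expressed (NB, mean 2 before amplification) only in source-cluster cells
and its receptor genes only in target-cluster cells, then multiplied by the
planted effect. This reflects cell-type-specific signaling and is also what
makes planted triples identifiable: a global label-permutation test is
scale-free, so with a uniform baseline a ligand elevated in cluster i drives
p ≤ 0.01 for *every* target j′ — under the majority-vote rule those triples
would be called, and no threshold choice could separate them. When one pair
is planted at several combinations, the full bipartite product
sources(k) × targets(k) is expression-active and is therefore the ground
truth. Non-planted pairs are decoys with exactly one side expressed
(uniformly, mean 0.5), probing that one-sided expression is never called.

What passing these tests shows — and does not show. The synthetic data has no
batch effects, doublets, ambient RNA, or continuous trajectories; clusters
are well-separated by construction. Success on it validates the
implementation (formulas, calibration, optimization, determinism), not
performance on real tissue.

## Numerical and reproducibility choices

- All neural components run on an in-package reverse-mode autodiff engine
  (`ccinet.nnet`) in float64, gradient-checked against central finite
  differences; optimizers are plain Adam (decoupled weight decay available).
- KNN ties break by ascending cell index (stable sort); k-means uses 10
  restarts; SVD signs are fixed as described.
- Probabilities inside losses are clamped (1e-7), logs floored (1e-12),
  permutation p-values use the add-one estimator.
- Every command and every training routine is a pure function of
  (inputs, config, seed); byte-identical reruns are covered by tests.

## Problem sizes used in the shipped experiments

Clustering recovery uses 1000 cells × 2000 genes with 3–5 clusters;
significance labeling uses 450 cells × ~350 genes, 20 pairs, 1000
permutations; the interaction model uses 6 clusters × 200 pairs
(600 cells), 5-fold CV. These sizes exercise every code path at full
statistical settings while keeping a complete run on one CPU core within a
few minutes per stage.

## Known limitations

- The three significance scorers are in-package surrogates for the published
  tools they emulate; their exact parameterizations within the original
  labeling procedure are not public, and real tool outputs can be substituted
  through the same interface.
- The interaction model's pair graph and node set are built once on the full
  dataset before cross-validation (the transductive design of the original
  procedure); CV therefore measures generalization across cluster pairs, not
  across datasets.
- Atlas-scale inputs (≫10⁴ cells) would need mini-batching and approximate
  nearest neighbors, both out of scope.
- Ortholog mapping between species, doublet detection, batch correction and
  spatial data are out of scope.
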