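# ccinet

Cell–cell interaction (CCI) inference from single-cell RNA-seq data, for
computational biologists who want to go from a raw count matrix to a ranked,
statistically labeled set of ligand–receptor (L–R) interactions between cell
populations — with or without existing cell-type labels.

Signaling between cell types is mediated by a ligand expressed in a *source*
population binding a receptor — often a multi-subunit complex such as
TGFB1 → (TGFBR1+TGFBR2) — expressed in a *target* population. `ccinet`
implements a three-stage pipeline around that idea:

1. **Clustering.** A fully connected autoencoder is trained jointly with a
   graph convolutional network (GCN) over the K-nearest-neighbor cell graph.
   At every depth the two branches are fused, `Z̃ = (1−ε)Z + εH`, and cluster
   membership is a Student's-t soft assignment
   `q_ij ∝ (1 + ‖h_i − μ_j‖²/v)^{−(v+1)/2}` sharpened by the self-training
   target `p_ij ∝ q_ij²/f_j`. The joint loss is
   `α·KL(P‖Q) + β·KL(P‖Z) + L_res` with α = 1e-4, β = 1e-3. The cluster
   number, when unknown, comes from Louvain communities of the cell graph.
2. **Interaction scoring.** For clusters i, j and pair k the interaction
   probability is `P_ij^k = L_i·R_j`, where each complex is the geometric
   mean of its subunits' 10%-truncated cluster means (a silent subunit
   inactivates the complex). An interaction is *significant* when at least
   two of three scorers agree: a regularized product score ≥ 0.5, and two
   label-permutation tests (plain and truncated means) at p ≤ 0.01.
3. **Supervised CCI model.** The significant labels train a classifier that
   fuses a residual MLP over SVD-reduced per-cell expression features with a
   GCN over the graph of the top-200 pairs (edges: |Pearson r| ≥ 0.95
   between probability profiles), trained with focal loss under 5-fold
   cross-validation.

A deterministic synthetic-data module generates negative-binomial counts with
planted clusters and planted, cluster-restricted L–R signals, and is the test
substrate for the whole pipeline.

## Worked example

Simulate a dataset with three cell populations and three planted
interactions, cluster it without using the true labels, then score
interactions between the discovered clusters:

```bash
ccinet simulate --spec spec.json --n-pairs 6 --outdir demo
ccinet cluster --expression demo/matrix --labels demo/labels.csv --outdir demo
ccinet score --expression demo/matrix --lr-db demo/lridb.tsv --outdir demo
ccinet viz --outdir demo
```

with `spec.json`:

```json
{"n_cells": 300, "n_genes": 150, "n_clusters": 3, "de_strength": 8.0,
 "markers_per_cluster": 15, "seed": 17,
 "planted_ccis": [[0, 1, 0, 8.0], [1, 2, 1, 8.0], [2, 0, 2, 8.0]]}
```

The cluster step logs

```
ccinet INFO clustering 300 cells into 3 clusters
ccinet INFO ARI against reference labels: 1.0000
```

— Louvain found the three planted populations and the joint model reproduced
the planted labels exactly (adjusted Rand index 1.0 against the reference
labels we passed for evaluation). The score step then writes
`demo/interactions.csv`; its significant rows are exactly the planted
triples, e.g.

```
source_cluster,target_cluster,ligand,receptor,probability,lrscore,pval_mean,pval_trunc,votes,significant
0,1,LG0001A,RG0001A,30.44,0.6791,0.000999,0.000999,3,True
1,2,LG0002A,RG0002A,28.63,0.6737,0.000999,0.000999,3,True
2,0,LG0000A,RG0000A,29.21,0.6759,0.000999,0.000999,3,True
```

(The discovered cluster ids are a relabeling of the planted ones — pair
`LG0001A→RG0001A` was planted from the population the model called
cluster 0 to the one it called cluster 1.)

Each row is one (source cluster, target cluster, pair): `probability` is the
product of the truncated-mean complex summaries, `lrscore` the regularized
product score, the two p-values come from 1000 label permutations
(add-one estimator, so 0.000999 = 1/1001 is the smallest attainable value),
and `significant` is the 2-of-3 majority vote. `viz` aggregates the same
table into bubble/chord/heatmap/network tables ready for plotting.

The same workflow runs on real data: point `--expression` at a Matrix Market
directory (`matrix.mtx` + `genes.tsv` + `barcodes.tsv`) or a dense CSV/TSV,
and `--lr-db` at an interaction TSV with `ligand`, `receptor` (subunits
joined by `+`), `species`, `source`, `evidence` columns. `ccinet train` /
`ccinet predict` add the supervised model on top of a scored run.

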