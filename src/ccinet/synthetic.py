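"""Deterministic generators: planted-cluster counts and planted L-R signals.

The count generator emulates the statistical structure UMI count matrices
present to this pipeline: negative-binomial genes (gamma-Poisson mixture with
gene-level dispersion), log-normal baseline means across genes, and disjoint
marker-gene blocks over-expressed per cluster so planted labels are
unambiguous.  The interaction generator embeds toy ligand/receptor genes with
cluster-restricted expression — a planted interaction's ligand is expressed
only in its source cluster and the receptor only in its target cluster,
mirroring cell-type-specific signaling; non-planted pairs have at most one
side expressed, so the planted (source, target, pair) triples are the unique
true positives.

All generators are pure functions of their spec: a fixed seed reproduces
output bitwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .lridb import LigandReceptorPair, LRIDBTable
from .preprocessing import ClusterLabels, ExpressionMatrix


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-cluster count generator."""

    n_cells: int = 1000
    n_genes: int = 2000
    n_clusters: int = 3
    proportions: tuple = ()        # empty -> equal proportions
    baseline_mean: float = 1.0
    dispersion: float = 0.3
    de_strength: float = 8.0       # fold change of cluster marker genes
    markers_per_cluster: int = 50
    planted_ccis: tuple = ()       # (source, target, pair_index, effect) tuples
    seed: int = 0

    def __post_init__(self):
        props = self.proportions or tuple([1.0 / self.n_clusters] * self.n_clusters)
        object.__setattr__(self, "proportions", tuple(float(p) for p in props))
        object.__setattr__(self, "planted_ccis", tuple(tuple(c) for c in self.planted_ccis))
        if len(self.proportions) != self.n_clusters:
            raise ValueError("proportions length must equal n_clusters")
        if abs(sum(self.proportions) - 1.0) > 1e-8:
            raise ValueError("proportions must sum to 1")
        if self.de_strength < 1.0:
            raise ValueError("de_strength must be >= 1")
        for c in self.planted_ccis:
            if len(c) == 4 and c[3] <= 1.0:
                raise ValueError("planted effect multipliers must be > 1")
        if self.n_clusters * self.markers_per_cluster > self.n_genes:
            raise ValueError("more marker-block genes than genes available")

    @classmethod
    def from_json(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2 (Poisson at 0)."""
    if dispersion <= 0:
        return rng.poisson(mean).astype(np.float64)
    r = 1.0 / dispersion
    lam = rng.gamma(shape=r, scale=np.maximum(mean, 0.0) / r)
    return rng.poisson(lam).astype(np.float64)


def simulate_counts(spec: SyntheticSpec) -> tuple[ExpressionMatrix, ClusterLabels]:
    """Negative-binomial counts with disjoint per-cluster marker blocks."""
    rng = np.random.default_rng(spec.seed)
    counts_per_cluster = np.floor(np.asarray(spec.proportions) * spec.n_cells).astype(int)
    counts_per_cluster[0] += spec.n_cells - counts_per_cluster.sum()
    labels = np.repeat(np.arange(spec.n_clusters), counts_per_cluster)
    labels = rng.permutation(labels)

    base = spec.baseline_mean * rng.lognormal(mean=0.0, sigma=0.5, size=spec.n_genes)
    mean = np.tile(base[:, None], (1, spec.n_cells))
    for c in range(spec.n_clusters):
        block = slice(c * spec.markers_per_cluster, (c + 1) * spec.markers_per_cluster)
        mean[block, labels == c] *= spec.de_strength
    values = _nb_sample(rng, mean, spec.dispersion)
    X = ExpressionMatrix(
        values,
        np.array([f"G{i:05d}" for i in range(spec.n_genes)], dtype=object),
        np.array([f"CELL{i:05d}" for i in range(spec.n_cells)], dtype=object),
    )
    return X, ClusterLabels(labels, spec.n_clusters)


def make_toy_lridb(n_pairs: int, multi_subunit_frac: float = 0.0, seed: int = 0,
                   species: str = "human") -> LRIDBTable:
    """Toy interaction table with synthetic, pair-disjoint gene symbols.

    A ``multi_subunit_frac`` fraction of pairs get a 2-subunit ligand or
    receptor (or both sides).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_pairs):
        multi = rng.random() < multi_subunit_frac
        side = int(rng.integers(3)) if multi else -1  # 0: ligand, 1: receptor, 2: both
        lig = (f"LG{i:04d}A", f"LG{i:04d}B") if side in (0, 2) else (f"LG{i:04d}A",)
        rec = (f"RG{i:04d}A", f"RG{i:04d}B") if side in (1, 2) else (f"RG{i:04d}A",)
        pairs.append(LigandReceptorPair(lig, rec, species, sources=("synthetic",)))
    return LRIDBTable(pairs=pairs, species=species)


def write_synthetic_lridb_tsv(path, n_pairs: int, species: str = "human",
                              seed: int = 0, multi_subunit_frac: float = 0.3,
                              n_duplicates: int = 0) -> None:
    """Write a raw synthetic interaction TSV of ``n_pairs`` distinct records.

    ``n_duplicates`` extra rows re-list existing multi-subunit pairs with their
    subunits permuted (and a different source annotation), so a loader that
    canonicalizes and unions provenance must still report ``n_pairs``.
    Synthetic stand-in for a curated interaction table.
    """
    import pandas as pd

    table = make_toy_lridb(n_pairs, multi_subunit_frac, seed=seed, species=species)
    rng = np.random.default_rng(seed + 1)
    rows = [
        {
            "ligand": "+".join(p.ligand_subunits),
            "receptor": "+".join(p.receptor_subunits),
            "species": p.species,
            "source": ",".join(p.sources),
            "evidence": "",
        }
        for p in table.pairs
    ]
    multi = [p for p in table.pairs if len(p.ligand_subunits) > 1 or len(p.receptor_subunits) > 1]
    for j in range(n_duplicates):
        p = multi[int(rng.integers(len(multi)))] if multi else table.pairs[int(rng.integers(len(table.pairs)))]
        rows.append({
            "ligand": "+".join(reversed(p.ligand_subunits)),
            "receptor": "+".join(reversed(p.receptor_subunits)),
            "species": p.species,
            "source": f"relisting{j}",
            "evidence": f"PMID:{int(rng.integers(10**6, 10**7))}",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def plant_lr_signal(X: ExpressionMatrix, labels: ClusterLabels, lridb: LRIDBTable,
                    planted, effect: float) -> ExpressionMatrix:
    """Multiply ligand genes by ``effect`` in source-cluster cells and receptor
    genes in target-cluster cells; every other entry is untouched."""
    if effect <= 0:
        raise ValueError("effect must be positive")
    values = X.values.copy()
    gene_pos = {g: i for i, g in enumerate(X.gene_names)}
    for source, target, pair_index in ((p[0], p[1], p[2]) for p in planted):
        if not (0 <= source < labels.n_clusters and 0 <= target < labels.n_clusters):
            raise ValueError(f"unknown cluster in planted CCI ({source}, {target})")
        if not (0 <= pair_index < len(lridb.pairs)):
            raise ValueError(f"unknown pair index {pair_index}")
        pair = lridb.pairs[pair_index]
        try:
            lig_rows = [gene_pos[g] for g in pair.ligand_subunits]
            rec_rows = [gene_pos[g] for g in pair.receptor_subunits]
        except KeyError as e:
            raise ValueError(f"pair gene {e.args[0]!r} not in expression matrix") from e
        values[np.ix_(lig_rows, labels.labels == source)] *= effect
        values[np.ix_(rec_rows, labels.labels == target)] *= effect
    return ExpressionMatrix(values, X.gene_names, X.cell_barcodes)


def simulate_cci_dataset(
    spec: SyntheticSpec,
    n_pairs: int,
    multi_subunit_frac: float = 0.0,
    lr_base_mean: float = 2.0,
    decoy_mean: float = 0.5,
):
    """Counts + toy L-R table with planted, cluster-restricted interactions.

    Planted pairs (from ``spec.planted_ccis``) have their ligand genes
    expressed (negative-binomial, mean ``lr_base_mean``) only in source-cluster
    cells and receptor genes only in target-cluster cells, then amplified by
    the planted effect via :func:`plant_lr_signal`.  Non-planted pairs are
    decoys: one side expressed uniformly at ``decoy_mean`` across all cells,
    the other silent — expression on one side only must not be called an
    interaction.

    Returns ``(X, labels, lridb, truth)``.  Because expression is restricted
    per gene (a ligand is expressed in every cluster it was planted as a
    source for, a receptor in every target cluster), planting one pair at
    several combos activates the full bipartite product: ``truth`` is the set
    of (source, target, pair_index) triples in sources(k) x targets(k) for
    every planted pair k.
    """
    X0, labels = simulate_counts(spec)
    lridb = make_toy_lridb(n_pairs, multi_subunit_frac, seed=spec.seed + 1)
    rng = np.random.default_rng(spec.seed + 2)
    planted_idx = {c[2] for c in spec.planted_ccis}
    if any(i >= n_pairs for i in planted_idx):
        raise ValueError("planted pair index out of range")

    lr_genes: list[str] = []
    for p in lridb.pairs:
        lr_genes.extend(p.ligand_subunits)
        lr_genes.extend(p.receptor_subunits)
    extra = np.zeros((len(lr_genes), spec.n_cells))
    row = {g: i for i, g in enumerate(lr_genes)}

    for c in spec.planted_ccis:
        source, target, k = c[0], c[1], c[2]
        pair = lridb.pairs[k]
        src_cells = labels.labels == source
        tgt_cells = labels.labels == target
        for g in pair.ligand_subunits:
            extra[row[g], src_cells] = _nb_sample(
                rng, np.full(int(src_cells.sum()), lr_base_mean), spec.dispersion)
        for g in pair.receptor_subunits:
            extra[row[g], tgt_cells] = _nb_sample(
                rng, np.full(int(tgt_cells.sum()), lr_base_mean), spec.dispersion)
    for k, pair in enumerate(lridb.pairs):
        if k in planted_idx:
            continue
        # decoy: express one side everywhere, leave the other silent
        side = pair.ligand_subunits if rng.random() < 0.5 else pair.receptor_subunits
        for g in side:
            extra[row[g]] = _nb_sample(
                rng, np.full(spec.n_cells, decoy_mean), spec.dispersion)

    X = ExpressionMatrix(
        np.vstack([X0.values, extra]),
        np.concatenate([X0.gene_names, np.asarray(lr_genes, dtype=object)]),
        X0.cell_barcodes,
    )
    # amplify each (pair, cluster) side once, even when a pair is planted at
    # several combos sharing a source or target
    lig_mult: dict[tuple[int, int], float] = {}
    rec_mult: dict[tuple[int, int], float] = {}
    for c in spec.planted_ccis:
        if len(c) > 3:
            lig_mult[(c[2], c[0])] = max(lig_mult.get((c[2], c[0]), 1.0), c[3])
            rec_mult[(c[2], c[1])] = max(rec_mult.get((c[2], c[1]), 1.0), c[3])
    values = X.values.copy()
    gene_pos = {g: i for i, g in enumerate(X.gene_names)}
    for (k, s), eff in lig_mult.items():
        rows = [gene_pos[g] for g in lridb.pairs[k].ligand_subunits]
        values[np.ix_(rows, labels.labels == s)] *= eff
    for (k, t), eff in rec_mult.items():
        rows = [gene_pos[g] for g in lridb.pairs[k].receptor_subunits]
        values[np.ix_(rows, labels.labels == t)] *= eff
    X = ExpressionMatrix(values, X.gene_names, X.cell_barcodes)
    sources: dict[int, set[int]] = {}
    targets: dict[int, set[int]] = {}
    for c in spec.planted_ccis:
        sources.setdefault(c[2], set()).add(c[0])
        targets.setdefault(c[2], set()).add(c[1])
    truth = {(s, t, k) for k in sources for s in sources[k] for t in targets[k]}
    return X, labels, lridb, truth
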