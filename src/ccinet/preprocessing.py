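"""Expression-matrix container, I/O, quality control and summaries.

Two preprocessing tracks feed the pipeline, mirroring how clustering and
interaction scoring consume different views of the same counts:

* clustering track — QC filter, per-cell normalization to a fixed total with
  log1p, then the top variable genes ranked by standard deviation;
* interaction track — one-vs-rest Wilcoxon rank-sum differential expression
  per cluster, optional restriction of the ligand-receptor table by a
  protein-protein interaction edge list, and 10%-truncated cluster means to
  damp extreme values.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy import stats

from .lridb import LRIDBTable

logger = logging.getLogger(__name__)


class EmptyResultError(ValueError):
    """Raised when a filtering step leaves no genes or no cells."""


@dataclass
class ExpressionMatrix:
    """Genes x cells non-negative expression values with name indices."""

    values: np.ndarray
    gene_names: np.ndarray
    cell_barcodes: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.cell_barcodes = np.asarray(self.cell_barcodes, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x cells)")
        if self.values.shape != (len(self.gene_names), len(self.cell_barcodes)):
            raise ValueError("dimensions do not match gene/barcode name lists")
        if (self.values < 0).any():
            raise ValueError("expression values must be non-negative")
        for names, what in ((self.gene_names, "gene"), (self.cell_barcodes, "barcode")):
            if len(set(names)) != len(names):
                raise ValueError(f"{what} names are not unique")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_names)}
        return np.array([lookup[g] for g in genes], dtype=int)

    # ---- I/O -------------------------------------------------------------
    @classmethod
    def read_mtx(cls, directory) -> "ExpressionMatrix":
        """Read a Matrix Market triplet directory (matrix.mtx + genes.tsv + barcodes.tsv)."""
        d = Path(directory)
        m = scipy.io.mmread(d / "matrix.mtx")
        values = np.asarray(m.todense() if sp.issparse(m) else m, dtype=np.float64)
        genes = pd.read_csv(d / "genes.tsv", sep="\t", header=None).iloc[:, 0].astype(str).to_numpy()
        barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None).iloc[:, 0].astype(str).to_numpy()
        return cls(values, genes, barcodes)

    @classmethod
    def read_csv(cls, path, sep: str | None = None) -> "ExpressionMatrix":
        """Read a dense table: genes as rows, first column gene names, header barcodes."""
        path = Path(path)
        if sep is None:
            sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(df.to_numpy(dtype=np.float64), df.index.astype(str).to_numpy(),
                   df.columns.astype(str).to_numpy())

    def write_mtx(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(d / "matrix.mtx"), sp.coo_matrix(self.values))
        pd.Series(self.gene_names).to_csv(d / "genes.tsv", sep="\t", header=False, index=False)
        pd.Series(self.cell_barcodes).to_csv(d / "barcodes.tsv", sep="\t", header=False, index=False)

    def write_csv(self, path, sep: str = ",") -> None:
        pd.DataFrame(self.values, index=self.gene_names, columns=self.cell_barcodes).to_csv(
            path, sep=sep
        )


@dataclass
class ClusterLabels:
    """One integer cluster id per cell; ids are contiguous and non-empty."""

    labels: np.ndarray
    n_clusters: int = 0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.n_clusters == 0:
            self.n_clusters = int(len(np.unique(self.labels)))
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(self.n_clusters)):
            raise ValueError(
                "labels must cover 0..n_clusters-1 with every cluster non-empty; "
                "use ClusterLabels.from_values for arbitrary label values"
            )

    @classmethod
    def from_values(cls, values) -> tuple["ClusterLabels", np.ndarray]:
        """Map arbitrary label values to contiguous codes; returns (labels, value_per_code)."""
        codes, uniques = pd.factorize(np.asarray(values), sort=True)
        return cls(codes, len(uniques)), np.asarray(uniques)

    def __len__(self) -> int:
        return len(self.labels)


def read_labels(path, barcodes) -> ClusterLabels:
    """Read a (barcode, label) CSV and align it to ``barcodes``."""
    df = pd.read_csv(path, header=None if _headerless(path) else 0)
    df.columns = ["barcode", "label"][: df.shape[1]]
    mapping = dict(zip(df["barcode"].astype(str), df["label"]))
    try:
        values = [mapping[str(b)] for b in barcodes]
    except KeyError as e:
        raise ValueError(f"label file is missing barcode {e.args[0]!r}") from e
    labels, _ = ClusterLabels.from_values(values)
    return labels


def _headerless(path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return "barcode" not in first.lower()


@dataclass
class DEResult:
    """Per (cluster, gene) one-vs-rest rank-sum statistic, p-value and flag."""

    statistic: np.ndarray      # (n_clusters, n_genes)
    pvalue: np.ndarray         # (n_clusters, n_genes), NaN where undefined
    overexpressed: np.ndarray  # boolean, False where undefined
    genes: np.ndarray
    clusters: np.ndarray
    undefined_clusters: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def overexpressed_genes(self, cluster: int) -> set[str]:
        i = int(np.flatnonzero(self.clusters == cluster)[0])
        return set(self.genes[self.overexpressed[i]])


# ---- operations ----------------------------------------------------------

def qc_filter(X: ExpressionMatrix, gene_frac: float = 0.01,
              cell_frac: float = 0.01) -> ExpressionMatrix:
    """Keep genes nonzero in > ``gene_frac`` of cells, then cells nonzero in
    > ``cell_frac`` of the retained genes.  Strict inequalities; returns a new
    matrix."""
    for f in (gene_frac, cell_frac):
        if not (0 <= f < 1):
            raise ValueError("fractions must lie in [0, 1)")
    nz = X.values > 0
    gene_keep = nz.mean(axis=1) > gene_frac
    if not gene_keep.any():
        raise EmptyResultError("no genes survive the QC filter")
    cell_keep = nz[gene_keep].mean(axis=0) > cell_frac
    if not cell_keep.any():
        raise EmptyResultError("no cells survive the QC filter")
    return ExpressionMatrix(
        X.values[np.ix_(gene_keep, cell_keep)],
        X.gene_names[gene_keep],
        X.cell_barcodes[cell_keep],
    )


def normalize_log(X: ExpressionMatrix, scale: float = 10000.0) -> ExpressionMatrix:
    """Scale each cell to a fixed total count, then log1p (natural log)."""
    totals = X.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cell {X.cell_barcodes[zero[0]]!r} has zero total count")
    return ExpressionMatrix(
        np.log1p(X.values / totals * scale), X.gene_names, X.cell_barcodes
    )


def select_hvg(X: ExpressionMatrix, n_top: int = 2000) -> ExpressionMatrix:
    """Restrict to the ``n_top`` genes with largest standard deviation,
    preserving original gene order."""
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if n_top >= X.n_genes:
        if n_top > X.n_genes:
            warnings.warn(
                f"requested {n_top} variable genes but only {X.n_genes} available",
                stacklevel=2,
            )
        return ExpressionMatrix(X.values.copy(), X.gene_names, X.cell_barcodes)
    sd = X.values.std(axis=1)
    top = np.sort(np.argsort(-sd, kind="stable")[:n_top])
    return ExpressionMatrix(X.values[top], X.gene_names[top], X.cell_barcodes)


def wilcoxon_de(X: ExpressionMatrix, labels: ClusterLabels, alpha: float = 0.05,
                genes=None, alternative: str = "greater",
                bh_correct: bool = False) -> DEResult:
    """One-vs-rest Wilcoxon rank-sum test per (cluster, gene).

    The over-expressed flag marks genes whose one-sided (greater) p-value is
    at or below ``alpha``.  Clusters with fewer than 2 cells are reported as
    undefined (NaN p-values, flag False) rather than dropped.  ``bh_correct``
    applies Benjamini-Hochberg within each cluster before thresholding
    (off by default).
    """
    if labels.n_clusters < 2:
        raise ValueError("differential expression needs at least 2 clusters")
    if len(labels) != X.n_cells:
        raise ValueError("labels length does not match cell count")
    if genes is not None:
        genes = list(genes)
        unknown = set(genes) - set(X.gene_names)
        if unknown:
            raise ValueError(f"genes not in matrix: {sorted(unknown)[:5]}")
        idx = X.gene_index(genes)
    else:
        genes = list(X.gene_names)
        idx = np.arange(X.n_genes)
    V = X.values[idx]
    k, g = labels.n_clusters, len(idx)
    statistic = np.full((k, g), np.nan)
    pvalue = np.full((k, g), np.nan)
    undefined = []
    for c in range(k):
        mask = labels.labels == c
        if mask.sum() < 2 or (~mask).sum() < 2:
            undefined.append(c)
            continue
        res = stats.mannwhitneyu(V[:, mask], V[:, ~mask], axis=1,
                                 alternative=alternative, method="auto")
        statistic[c] = res.statistic
        pvalue[c] = res.pvalue
    padj = pvalue.copy()
    if bh_correct:
        for c in range(k):
            if c not in undefined and not np.isnan(pvalue[c]).all():
                padj[c] = stats.false_discovery_control(pvalue[c])
    with np.errstate(invalid="ignore"):
        flag = np.where(np.isnan(padj), False, padj <= alpha)
    return DEResult(statistic, pvalue, flag.astype(bool), np.asarray(genes, dtype=object),
                    np.arange(k), np.asarray(undefined, dtype=int))


def ppi_project(de: DEResult, ppi_edges, lridb: LRIDBTable) -> LRIDBTable:
    """Keep pairs over-expressed on both sides, optionally PPI-supported.

    A pair survives when some cluster over-expresses every ligand subunit and
    some cluster over-expresses every receptor subunit.  With a non-empty
    ``ppi_edges`` set (unordered gene pairs), at least one
    (ligand-subunit, receptor-subunit) edge must also be present; an empty set
    skips that condition with a logged notice.
    """
    edges = {frozenset(e) for e in ppi_edges}
    if not edges:
        logger.info("empty PPI edge list: skipping the PPI support condition")
    per_cluster = [de.overexpressed_genes(int(c)) for c in de.clusters]
    kept = []
    for p in lridb.pairs:
        lig_ok = any(set(p.ligand_subunits) <= s for s in per_cluster)
        rec_ok = any(set(p.receptor_subunits) <= s for s in per_cluster)
        if not (lig_ok and rec_ok):
            continue
        if edges and not any(
            frozenset((l, r)) in edges
            for l in p.ligand_subunits for r in p.receptor_subunits
        ):
            continue
        kept.append(p)
    return LRIDBTable(pairs=kept, species=lridb.species)


def truncated_mean(values, trunc: float = 0.10) -> float:
    """Mean after dropping floor(trunc*n) smallest and largest values per tail."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("truncated_mean of empty input")
    if not (0 <= trunc < 0.5):
        raise ValueError("trunc must lie in [0, 0.5)")
    k = math.floor(trunc * v.size)
    v = np.sort(v)
    return float(v[k: v.size - k].mean())


def read_ppi_edges(path) -> set[frozenset]:
    """Read a two-column TSV of gene symbols into a set of unordered edges."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    return {frozenset((a, b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])}
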