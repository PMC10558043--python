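"""Ligand-receptor interaction database: data model, parsing, deduplication.

An interaction record pairs a ligand with a receptor, each of which may be a
multi-subunit complex (e.g. the heteromeric TGF-beta receptor TGFBR1+TGFBR2).
Records carry species, provenance (origin databases) and optional literature
evidence.  Tables are read from a TSV layout in which complex subunits are
joined by ``+``.

Deduplication uses a canonical key of (sorted ligand subunits, sorted receptor
subunits, species), so two listings of the same complex in different subunit
order collide; provenance of merged duplicates is unioned.  Directionality is
preserved: a pair and its reverse are distinct records.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

SPECIES = ("human", "mouse")
REQUIRED_COLUMNS = ("ligand", "receptor", "species")


class LRIDBFormatError(ValueError):
    """Raised when an input table violates the expected TSV layout."""


class EmptyTableError(ValueError):
    """Raised when parsing/filtering leaves no interaction records."""


def _check_subunits(subunits: tuple[str, ...], side: str) -> None:
    if len(subunits) < 1:
        raise ValueError(f"{side} must have at least one subunit")
    if len(set(subunits)) != len(subunits):
        raise ValueError(f"duplicate symbols within {side} subunits: {subunits}")
    for s in subunits:
        if not s or "+" in s:
            raise ValueError(f"invalid gene symbol in {side}: {s!r}")


@dataclass(frozen=True)
class LigandReceptorPair:
    """One directed ligand->receptor interaction, possibly multi-subunit."""

    ligand_subunits: tuple[str, ...]
    receptor_subunits: tuple[str, ...]
    species: str
    sources: tuple[str, ...] = ()
    evidence: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "ligand_subunits", tuple(self.ligand_subunits))
        object.__setattr__(self, "receptor_subunits", tuple(self.receptor_subunits))
        object.__setattr__(self, "sources", tuple(self.sources))
        object.__setattr__(self, "evidence", tuple(self.evidence))
        _check_subunits(self.ligand_subunits, "ligand")
        _check_subunits(self.receptor_subunits, "receptor")
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}; expected one of {SPECIES}")

    @property
    def canonical_key(self) -> tuple[tuple[str, ...], tuple[str, ...], str]:
        return (
            tuple(sorted(self.ligand_subunits)),
            tuple(sorted(self.receptor_subunits)),
            self.species,
        )

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.ligand_subunits) | frozenset(self.receptor_subunits)

    @property
    def name(self) -> str:
        return f"{'+'.join(self.ligand_subunits)}->{'+'.join(self.receptor_subunits)}"


@dataclass
class LRIDBTable:
    """A deduplicated, single-species collection of interaction records."""

    pairs: list[LigandReceptorPair]
    species: str

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        keys = set()
        for p in self.pairs:
            if p.species != self.species:
                raise ValueError("all pairs must share the table's species")
            if p.canonical_key in keys:
                raise ValueError(f"duplicate canonical key: {p.canonical_key}")
            keys.add(p.canonical_key)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def gene_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for p in self.pairs:
            out |= p.genes
        return frozenset(out)


def _split(cell, sep: str) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return ()
    return tuple(part.strip() for part in str(cell).split(sep) if part.strip())


def deduplicate_pairs(pairs: list[LigandReceptorPair]) -> list[LigandReceptorPair]:
    """Collapse records sharing a canonical key, unioning provenance.

    First-seen order (and first-seen subunit ordering) is preserved.
    Idempotent by construction.
    """
    merged: dict[tuple, LigandReceptorPair] = {}
    for p in pairs:
        key = p.canonical_key
        if key not in merged:
            merged[key] = p
        else:
            kept = merged[key]
            sources = kept.sources + tuple(s for s in p.sources if s not in kept.sources)
            evidence = kept.evidence + tuple(e for e in p.evidence if e not in kept.evidence)
            merged[key] = LigandReceptorPair(
                kept.ligand_subunits, kept.receptor_subunits, kept.species,
                sources, evidence,
            )
    return list(merged.values())


def load_lridb(path, species: str, case_fold: bool = False) -> LRIDBTable:
    """Read an interaction TSV, restrict to ``species``, and deduplicate.

    The file must carry header columns ``ligand``, ``receptor`` and ``species``
    (complex subunits joined by ``+``); ``source`` and ``evidence`` columns are
    optional comma-separated lists.  ``case_fold=True`` upper-cases gene symbols
    on input, for mouse/human symbol-style mismatches.
    """
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise LRIDBFormatError(f"missing required column(s): {missing}")
    pairs: list[LigandReceptorPair] = []
    for row in df.itertuples(index=False):
        if getattr(row, "species") != species:
            continue
        lig = _split(getattr(row, "ligand"), "+")
        rec = _split(getattr(row, "receptor"), "+")
        if case_fold:
            lig = tuple(s.upper() for s in lig)
            rec = tuple(s.upper() for s in rec)
        pairs.append(
            LigandReceptorPair(
                lig, rec, species,
                sources=_split(getattr(row, "source", ""), ","),
                evidence=_split(getattr(row, "evidence", ""), ","),
            )
        )
    pairs = deduplicate_pairs(pairs)
    if not pairs:
        raise EmptyTableError(f"no {species} interactions found in {path}")
    logger.info("loaded %d %s ligand-receptor pairs from %s", len(pairs), species, path)
    return LRIDBTable(pairs=pairs, species=species)


def filter_pairs_to_genes(table: LRIDBTable, gene_universe) -> LRIDBTable:
    """Restrict to pairs whose every subunit is in ``gene_universe``."""
    universe = set(gene_universe)
    if not universe:
        raise ValueError("gene_universe must be non-empty")
    kept = [p for p in table.pairs if p.genes <= universe]
    if not kept:
        warnings.warn("no ligand-receptor pairs overlap the gene universe", stacklevel=2)
    return LRIDBTable(pairs=kept, species=table.species)


def write_lridb(table: LRIDBTable, path) -> None:
    """Write a table back to the TSV dialect ``load_lridb`` reads."""
    rows = [
        {
            "ligand": "+".join(p.ligand_subunits),
            "receptor": "+".join(p.receptor_subunits),
            "species": p.species,
            "source": ",".join(p.sources),
            "evidence": ",".join(p.evidence),
        }
        for p in table.pairs
    ]
    pd.DataFrame(rows, columns=["ligand", "receptor", "species", "source", "evidence"]).to_csv(
        path, sep="\t", index=False
    )
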