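"""Core in-memory containers shared across the pipeline.

Coordinate conventions
----------------------
All I/O-facing site tables use the VCF convention: ``pos`` is 1-based and
refers to the first reference base of the record.  Gene models use 0-based
half-open intervals internally; conversion happens exactly once, at the
GFF3/VCF boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

#: Site-level INFO annotations carried through the pipeline (GATK names).
INFO_FIELDS = ("MQ", "QD", "FS", "SOR", "MQRankSum", "ReadPosRankSum")

SITE_COLUMNS = ["snp_id", "scaffold", "pos", "ref", "alt", "is_biallelic_snp", *INFO_FIELDS]


@dataclass
class SnpDataset:
    """A set of variant sites plus the diploid genotype matrix over samples.

    Attributes
    ----------
    sites:
        One row per variant with columns :data:`SITE_COLUMNS`.  ``pos`` is
        1-based; INFO annotations are floats with ``NaN`` meaning absent.
    samples:
        Ordered sample identifiers (columns of the genotype arrays).
    dosage:
        ``(n_sites, n_samples)`` int8 ALT-allele dosage, ``-1`` = missing.
    gq, dp:
        Per-genotype quality and depth, same shape as ``dosage``.
    """

    sites: pd.DataFrame
    samples: list[str]
    dosage: np.ndarray
    gq: np.ndarray | None = None
    dp: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"({len(self.sites)} sites, {len(self.samples)} samples)"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in dataset: {missing}")
        return np.asarray([lookup[s] for s in sample_ids], dtype=int)

    def take_sites(self, row_indexer) -> "SnpDataset":
        """Subset sites by boolean mask or integer positions (order kept)."""
        mask = np.asarray(row_indexer)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SnpDataset(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            dosage=self.dosage[idx],
            gq=None if self.gq is None else self.gq[idx],
            dp=None if self.dp is None else self.dp[idx],
        )

    def copy(self) -> "SnpDataset":
        return SnpDataset(
            sites=self.sites.copy(),
            samples=list(self.samples),
            dosage=self.dosage.copy(),
            gq=None if self.gq is None else self.gq.copy(),
            dp=None if self.dp is None else self.dp.copy(),
        )


@dataclass
class Gene:
    """One gene model; intervals are 0-based half-open genomic tuples.

    ``exons``/``cds``/``utr5``/``utr3`` are sorted by genomic start
    irrespective of strand.  ``cds`` segments concatenated in transcription
    order (reverse order, reverse-complemented on the minus strand) give the
    coding sequence, whose length must be a multiple of 3 with frame 0 at
    the first base.
    """

    gene_id: str
    scaffold: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons (genomic order)."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def cds_genomic_positions(self) -> np.ndarray:
        """Genomic positions (0-based) of coding bases in transcription order."""
        pos = np.concatenate([np.arange(s, e) for s, e in self.cds]) if self.cds else np.empty(0, int)
        if self.strand == "-":
            pos = pos[::-1]
        return pos

    def cds_sequence(self, genome: dict[str, str]) -> str:
        seq = "".join(genome[self.scaffold][s:e] for s, e in self.cds)
        if self.strand == "-":
            seq = revcomp(seq)
        return seq


_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class GeneModelSet:
    """Collection of :class:`Gene` with per-scaffold interval lookup."""

    def __init__(self, genes: list[Gene]):
        self.genes: dict[str, Gene] = {g.gene_id: g for g in genes}
        if len(self.genes) != len(genes):
            raise ValueError("duplicate gene ids")
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            self._trees.setdefault(g.scaffold, IntervalTree()).addi(g.start, g.end, g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> Gene:
        return self.genes[gene_id]

    def genes_at(self, scaffold: str, pos0: int) -> list[Gene]:
        """Genes whose span contains the 0-based position, id-sorted."""
        tree = self._trees.get(scaffold)
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.at(pos0))
        return [self.genes[g] for g in hits]


@dataclass(frozen=True)
class ComparisonSpec:
    """Two named, disjoint groups of individuals defining an F_ST contrast."""

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self):
        if not self.group_a or not self.group_b:
            raise ValueError(f"comparison {self.name!r}: both groups must be non-empty")
        if set(self.group_a) & set(self.group_b):
            raise ValueError(f"comparison {self.name!r}: groups overlap")
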