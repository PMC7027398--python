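"""SNP effect classification over gene models and genome sequence.

Every SNP receives exactly one of seven classes: synonymous,
nonsynonymous, 5'UTR, 3'UTR, intron, splice site, or intergenic.  When a
position carries several annotations (overlapping genes or features) the
precedence is splice_site > CDS > 5'UTR > 3'UTR > intron > intergenic,
with ties between genes broken by lexicographically smallest gene id.
Splice sites are the first/last ``splice_width`` bases of each intron (the
canonical donor/acceptor dinucleotides by default).

Coding effects substitute the ALT allele into its codon (strand-aware) and
translate with the standard genetic code.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from enum import Enum

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .containers import Gene, GeneModelSet

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: codon -> amino acid, stops as '*'
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TO_AA[_stop] = "*"


class EffectClass(str, Enum):
    synonymous = "synonymous"
    nonsynonymous = "nonsynonymous"
    five_prime_utr = "five_prime_UTR"
    three_prime_utr = "three_prime_UTR"
    intron = "intron"
    splice_site = "splice_site"
    intergenic = "intergenic"


#: evaluation order within a gene (highest precedence first); CDS expands
#: to synonymous/nonsynonymous.
_PRECEDENCE = ("splice_site", "cds", "utr5", "utr3", "intron")
_RANK = {name: i for i, name in enumerate(_PRECEDENCE)}

ALL_CLASSES = [
    EffectClass.synonymous, EffectClass.nonsynonymous, EffectClass.five_prime_utr,
    EffectClass.three_prime_utr, EffectClass.intron, EffectClass.splice_site,
    EffectClass.intergenic,
]


def _in_any(pos0: int, intervals) -> bool:
    return any(s <= pos0 < e for s, e in intervals)


def _feature_of(gene: Gene, pos0: int, splice_width: int) -> str | None:
    """Highest-precedence feature of ``gene`` containing ``pos0``, or None."""
    introns = gene.introns()
    for s, e in introns:
        w = min(splice_width, e - s)
        if s <= pos0 < s + w or e - w <= pos0 < e:
            return "splice_site"
    if _in_any(pos0, gene.cds):
        return "cds"
    if _in_any(pos0, gene.utr5):
        return "utr5"
    if _in_any(pos0, gene.utr3):
        return "utr3"
    if gene.start <= pos0 < gene.end:
        # inside the span but in no annotated feature -> intronic by decree
        return "intron"
    return None


class _CodonIndex:
    """Lazy per-gene map from genomic position to CDS index + ref CDS."""

    def __init__(self, genome: dict[str, str]):
        self.genome = genome
        self._cache: dict[str, tuple[dict[int, int], str]] = {}

    def get(self, gene: Gene) -> tuple[dict[int, int], str]:
        if gene.gene_id not in self._cache:
            if gene.cds_length() % 3 != 0:
                raise ValueError(f"gene {gene.gene_id}: CDS length not divisible by 3")
            pos = gene.cds_genomic_positions()
            cds_seq = gene.cds_sequence(self.genome)
            self._cache[gene.gene_id] = ({int(p): i for i, p in enumerate(pos)}, cds_seq)
        return self._cache[gene.gene_id]


def _coding_effect(gene: Gene, pos0: int, ref: str, alt: str,
                   index: _CodonIndex) -> EffectClass:
    cds_map, cds_seq = index.get(gene)
    i = cds_map[pos0]
    if gene.strand == "-":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    if cds_seq[i] != ref:
        raise ValueError(
            f"REF mismatch at {gene.scaffold}:{pos0 + 1} in {gene.gene_id}: "
            f"CDS has {cds_seq[i]}, record says {ref}"
        )
    codon_start = 3 * (i // 3)
    codon = cds_seq[codon_start:codon_start + 3]
    mutated = codon[: i % 3] + alt + codon[i % 3 + 1:]
    same = CODON_TO_AA[codon] == CODON_TO_AA[mutated]
    return EffectClass.synonymous if same else EffectClass.nonsynonymous


def classify_variant(scaffold: str, pos: int, ref: str, alt: str,
                     models: GeneModelSet, genome: dict[str, str],
                     splice_width: int = 2,
                     _index: _CodonIndex | None = None) -> tuple[EffectClass, str | None]:
    """Classify one SNP (``pos`` 1-based); returns (class, gene id or None)."""
    pos0 = pos - 1
    if genome[scaffold][pos0] != ref:
        raise ValueError(f"REF mismatch at {scaffold}:{pos}: genome has "
                         f"{genome[scaffold][pos0]}, record says {ref}")
    index = _index or _CodonIndex(genome)
    best: tuple[int, str, Gene] | None = None
    for gene in models.genes_at(scaffold, pos0):  # id-sorted: stable tie-break
        feat = _feature_of(gene, pos0, splice_width)
        if feat is not None and (best is None or _RANK[feat] < best[0]):
            best = (_RANK[feat], feat, gene)
    if best is None:
        return EffectClass.intergenic, None
    _, feat, gene = best
    if feat == "cds":
        return _coding_effect(gene, pos0, ref, alt, index), gene.gene_id
    mapping = {"splice_site": EffectClass.splice_site, "utr5": EffectClass.five_prime_utr,
               "utr3": EffectClass.three_prime_utr, "intron": EffectClass.intron}
    return mapping[feat], gene.gene_id


def classify_variants(sites: pd.DataFrame, models: GeneModelSet,
                      genome: dict[str, str], splice_width: int = 2) -> pd.DataFrame:
    """Classify every row of a site table; adds ``effect`` and ``gene_id``."""
    index = _CodonIndex(genome)
    effects, gene_ids = [], []
    for row in sites.itertuples(index=False):
        eff, gid = classify_variant(row.scaffold, int(row.pos), row.ref, row.alt,
                                    models, genome, splice_width, _index=index)
        effects.append(eff.value)
        gene_ids.append(gid)
    out = sites.copy()
    out["effect"] = effects
    out["gene_id"] = gene_ids
    return out


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (the convention of printed percentage tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_annotation(classified) -> pd.DataFrame:
    """Per-class counts and percentages (2 decimals, half-up).

    ``classified`` may be a sequence/Series of class labels or a mapping
    ``class -> count``.  An empty input yields a zero-count summary with no
    percentages computed.
    """
    if isinstance(classified, dict):
        counts = {EffectClass(k).value: int(v) for k, v in classified.items()}
    else:
        vc = pd.Series(classified).value_counts()
        counts = {str(k): int(v) for k, v in vc.items()}
    total = sum(counts.values())
    rows = []
    for cls in ALL_CLASSES:
        c = counts.get(cls.value, 0)
        pct = round_half_up(100.0 * c / total) if total else np.nan
        rows.append((cls.value, c, pct))
    df = pd.DataFrame(rows, columns=["effect", "count", "percent"])
    df.attrs["total"] = total
    return df
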