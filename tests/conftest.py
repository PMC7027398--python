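import numpy as np
import pytest

from gardenscan import SimConfig, simulate
from gardenscan.containers import Gene, GeneModelSet


@pytest.fixture(scope="session")
def sim_small():
    """A modest cohort with planted selection, reused across read-only tests."""
    cfg = SimConfig(n_snps=800, n_genes=40, n_planted=8, n_indels=12,
                    n_scaffolds=6, scaffold_length=20_000, seed=11)
    return simulate(cfg)


@pytest.fixture(scope="session")
def filter_fixture():
    """Cohort rigged so that only the planted records can fail any filter:
    high MAF floor and no random missingness keep the background clean."""
    cfg = SimConfig(n_snps=600, n_genes=30, n_planted=0, n_indels=12,
                    n_scaffolds=6, scaffold_length=20_000, seed=5,
                    maf_floor=0.2, missing_rate=0.0, background_fst=0.02,
                    n_fail_near_indel=3, n_fail_hard=4, n_fail_missing=3, n_fail_maf=3)
    return simulate(cfg)


def _write(genome: list[str], start: int, seq: str) -> None:
    genome[start:start + len(seq)] = list(seq)


@pytest.fixture(scope="session")
def toy_gene_models():
    """Two handmade genes with fully known structure on one 300 bp scaffold.

    Plus-strand gene gp: CDS = ATG AAA CCC | GGG TTT TAA (two exons).
    Minus-strand gene gm: CDS = ATG GCA ATC TAA (two exons, genomic
    reverse-complement).
    """
    rng = np.random.default_rng(99)
    genome = rng.choice(list("ACGT"), size=300).tolist()

    gp = Gene(
        gene_id="gp", scaffold="chr1", strand="+", start=10, end=70,
        exons=[(10, 16), (20, 29), (49, 58), (60, 70)],
        cds=[(20, 29), (49, 58)], utr5=[(10, 16)], utr3=[(60, 70)],
    )
    _write(genome, 20, "ATGAAACCC")
    _write(genome, 49, "GGGTTTTAA")

    gm = Gene(
        gene_id="gm", scaffold="chr1", strand="-", start=100, end=136,
        exons=[(100, 106), (110, 116), (120, 126), (130, 136)],
        cds=[(110, 116), (120, 126)], utr5=[(130, 136)], utr3=[(100, 106)],
    )
    # revcomp("ATGGCAATCTAA") laid left-to-right on the genomic strand
    _write(genome, 110, "TTAGAT")
    _write(genome, 120, "TGCCAT")

    return GeneModelSet([gp, gm]), {"chr1": "".join(genome)}
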