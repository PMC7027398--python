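"""Readers and writers for VCF 4.2, GFF3, FASTA and the TSV side tables.

VCF records are read with :mod:`cyvcf2`; GFF3 via :mod:`gffutils`; FASTA via
Biopython.  Writing goes through small text emitters so that seeded
simulation output is byte-reproducible.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .containers import INFO_FIELDS, Gene, GeneModelSet, SnpDataset

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER_META = (
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS Mapping Quality">\n'
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant Confidence/Quality by Depth">\n'
    '##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled p-value using Fisher\'s exact test to detect strand bias">\n'
    '##INFO=<ID=SOR,Number=1,Type=Float,Description="Symmetric Odds Ratio of 2x2 contingency table to detect strand bias">\n'
    '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Z-score from Wilcoxon rank sum test of Alt vs. Ref read mapping qualities">\n'
    '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Z-score from Wilcoxon rank sum test of Alt vs. Ref read position bias">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n'
)

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(
    path: str | os.PathLike,
    dataset: SnpDataset,
    indels: pd.DataFrame | None = None,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write the dataset (and optional indel records) as an uncompressed VCF.

    ``indels`` needs columns ``snp_id, scaffold, pos, ref, alt``; indel
    genotypes are emitted as homozygous reference (they only exist to
    exercise proximity filtering).  Records are sorted by (scaffold, pos).
    """
    sites = dataset.sites
    rows = []
    for i in range(len(sites)):
        rows.append((sites.at[i, "scaffold"], int(sites.at[i, "pos"]), "snp", i))
    if indels is not None:
        for j in range(len(indels)):
            rows.append((indels.at[j, "scaffold"], int(indels.at[j, "pos"]), "indel", j))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gardenscan\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(_VCF_HEADER_META)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(dataset.samples) + "\n")
        for scaffold, pos, kind, i in rows:
            if kind == "snp":
                row = sites.iloc[i]
                info = ";".join(
                    f"{k}={row[k]:.2f}" for k in INFO_FIELDS if not pd.isna(row[k])
                ) or "."
                gts = []
                for j in range(dataset.n_samples):
                    gq = int(dataset.gq[i, j]) if dataset.gq is not None else 99
                    dp = int(dataset.dp[i, j]) if dataset.dp is not None else 30
                    gts.append(f"{_GT_STR[int(dataset.dosage[i, j])]}:{gq}:{dp}")
                fh.write(
                    f"{scaffold}\t{pos}\t{row['snp_id']}\t{row['ref']}\t{row['alt']}\t.\t.\t{info}\tGT:GQ:DP\t"
                    + "\t".join(gts) + "\n"
                )
            else:
                row = indels.iloc[i]
                info = ";".join(f"{k}={row[k]:.2f}" for k in INFO_FIELDS if k in row and not pd.isna(row[k])) or "."
                gts = "\t".join("0/0:99:30" for _ in dataset.samples)
                fh.write(
                    f"{scaffold}\t{pos}\t{row['snp_id']}\t{row['ref']}\t{row['alt']}\t.\t.\t{info}\tGT:GQ:DP\t{gts}\n"
                )


def read_vcf(path: str | os.PathLike) -> tuple[SnpDataset, pd.DataFrame]:
    """Read a multi-sample VCF into a :class:`SnpDataset` plus an indel table.

    Biallelic single-base records become dataset rows; everything else
    (indels, multi-allelic records) goes to the returned indel/other table
    so the proximity filter can see it.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    site_rows, dosages, gqs, dps, indel_rows = [], [], [], [], []
    for k, v in enumerate(vcf):
        alts = v.ALT
        is_snp = len(alts) == 1 and len(v.REF) == 1 and len(alts[0]) == 1
        rid = v.ID if v.ID not in (None, ".") else f"rec{k:06d}"
        if not is_snp:
            indel_rows.append({"snp_id": rid, "scaffold": v.CHROM, "pos": v.POS,
                               "ref": v.REF, "alt": ",".join(alts)})
            continue
        info = {f: v.INFO.get(f) for f in INFO_FIELDS}
        site_rows.append({"snp_id": rid, "scaffold": v.CHROM, "pos": v.POS,
                          "ref": v.REF, "alt": alts[0], "is_biallelic_snp": True,
                          **{f: (np.nan if info[f] is None else float(info[f])) for f in INFO_FIELDS}})
        gt = np.asarray(v.genotypes, dtype=int)[:, :2]
        dos = np.where((gt < 0).any(axis=1), -1, gt.clip(0).sum(axis=1))
        dosages.append(dos.astype(np.int8))
        gq = v.format("GQ")
        dp = v.format("DP")
        gqs.append(np.zeros(len(samples), np.int16) if gq is None else gq.reshape(-1).astype(np.int16))
        dps.append(np.zeros(len(samples), np.int16) if dp is None else dp.reshape(-1).astype(np.int16))
    sites = pd.DataFrame(site_rows)
    ds = SnpDataset(
        sites=sites,
        samples=samples,
        dosage=np.vstack(dosages) if dosages else np.empty((0, len(samples)), np.int8),
        gq=np.vstack(gqs) if gqs else None,
        dp=np.vstack(dps) if dps else None,
    )
    indels = pd.DataFrame(indel_rows, columns=["snp_id", "scaffold", "pos", "ref", "alt"])
    return ds, indels


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(path: str | os.PathLike, genome: dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3

def write_gff3(path: str | os.PathLike, models: GeneModelSet) -> None:
    """Emit gene/mRNA/exon/CDS/UTR features, 1-based closed coordinates."""

    def line(g: Gene, ftype: str, s: int, e: int, attrs: str, phase: str = ".") -> str:
        return f"{g.scaffold}\tgardenscan\t{ftype}\t{s + 1}\t{e}\t.\t{g.strand}\t{phase}\t{attrs}\n"

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(models, key=lambda g: (g.scaffold, g.start)):
            mrna_id = f"{g.gene_id}.mRNA"
            fh.write(line(g, "gene", g.start, g.end, f"ID={g.gene_id}"))
            fh.write(line(g, "mRNA", g.start, g.end, f"ID={mrna_id};Parent={g.gene_id}"))
            for s, e in g.exons:
                fh.write(line(g, "exon", s, e, f"Parent={mrna_id}"))
            segs = g.cds if g.strand == "+" else list(reversed(g.cds))
            consumed = 0
            phased = []
            for s, e in segs:  # transcription order for phase bookkeeping
                phased.append((s, e, (3 - consumed % 3) % 3))
                consumed += e - s
            for s, e, ph in sorted(phased):
                fh.write(line(g, "CDS", s, e, f"Parent={mrna_id}", str(ph)))
            for s, e in g.utr5:
                fh.write(line(g, "five_prime_UTR", s, e, f"Parent={mrna_id}"))
            for s, e in g.utr3:
                fh.write(line(g, "three_prime_UTR", s, e, f"Parent={mrna_id}"))


def read_gff3(path: str | os.PathLike) -> GeneModelSet:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for grec in db.features_of_type("gene"):
        gid = grec.id
        exons, cds, utr5, utr3 = [], [], [], []
        for child in db.children(grec, level=2):
            iv = (child.start - 1, child.end)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                cds.append(iv)
            elif child.featuretype == "five_prime_UTR":
                utr5.append(iv)
            elif child.featuretype == "three_prime_UTR":
                utr3.append(iv)
        genes.append(Gene(
            gene_id=gid, scaffold=grec.seqid, strand=grec.strand,
            start=grec.start - 1, end=grec.end,
            exons=sorted(exons), cds=sorted(cds),
            utr5=sorted(utr5), utr3=sorted(utr3),
        ))
    return GeneModelSet(genes)


# ---------------------------------------------------------------------------
# TSV side tables

def write_population_map(path: str | os.PathLike, popmap: pd.DataFrame) -> None:
    popmap[["individual", "population", "site"]].to_csv(path, sep="\t", index=False)


def read_population_map(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual", "population", "site"}
    if not required.issubset(df.columns):
        raise ValueError(f"population map needs columns {sorted(required)}")
    return df


def write_term_map(path: str | os.PathLike, terms: pd.DataFrame) -> None:
    terms[["gene_id", "term_id", "term_name"]].to_csv(path, sep="\t", index=False)


def read_term_map(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "term_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"term map needs columns {sorted(required)}")
    if "term_name" not in df.columns:
        df["term_name"] = df["term_id"]
    return df
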