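"""Synthetic common-garden cohort generator with full ground truth.

The generator emulates the data shape of a two-site conifer common-garden
study genotyped by RNA-seq: seven source populations grown at a low- and a
high-elevation site, where only a handful of trees from one population
survive at altitude.  It produces

* a small multi-scaffold genome with realistic gene models (UTRs, multi-exon
  CDS, introns, both strands),
* a multi-sample VCF of biallelic SNPs (plus indel records) with per-site
  QC annotations and per-genotype GQ/DP,
* a population map (individual, population, garden site),
* a gene-to-term map for enrichment testing, and
* a :class:`TruthTable` recording every planted signal.

Population allele frequencies follow the Balding–Nichols model: an
ancestral frequency ``p`` is drawn per SNP and each population's frequency
is Beta(p(1-F)/F, (1-p)(1-F)/F) with ``F = background_fst``, so one knob
controls the background differentiation.  Viability selection at the high
site is emulated by drawing the survivor group from the source population's
frequencies but, at a set of *planted* coding SNPs, shifting the selected
(ALT) allele frequency upward by ``planted_freq_shift``.

One global seed drives independent substreams (genome, gene placement,
frequencies, genotypes, QC, missingness, indels, terms) so that changing
one knob does not reshuffle unrelated draws, and a fixed seed reproduces
every output file byte for byte.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as gsio
from .containers import INFO_FIELDS, ComparisonSpec, Gene, GeneModelSet, SnpDataset, revcomp

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                   if a + b + c not in _STOPS]

#: Default population labels and sample sizes (lowland garden), survivor
#: group of 5 from population KM at the high-elevation garden: 54 trees.
DEFAULT_POP_LABELS = ("LJ", "YL", "BS", "GS", "YX", "ZD", "KM")
DEFAULT_POP_SIZES = (10, 10, 5, 4, 5, 5, 10)


@dataclass
class SimConfig:
    """All knobs of the generator; defaults mirror the study design."""

    pop_labels: tuple[str, ...] = DEFAULT_POP_LABELS
    pop_sizes: tuple[int, ...] = DEFAULT_POP_SIZES
    survivor_pop: str = "KM"
    n_survivors: int = 5

    n_scaffolds: int = 8
    scaffold_length: int = 25_000
    n_genes: int = 100
    n_snps: int = 5_000
    n_indels: int = 40

    background_fst: float = 0.05
    n_planted: int = 20
    planted_freq_shift: float = 0.6
    missing_rate: float = 0.05
    maf_floor: float = 0.05

    # planted filter failures (counts of background SNPs rigged to fail)
    n_fail_near_indel: int = 0
    n_fail_hard: int = 0
    n_fail_missing: int = 0
    n_fail_maf: int = 0

    # term-map shape
    n_terms: int = 30
    planted_term_coverage: float = 1.0
    planted_term_background: float = 0.05

    seed: int = 0

    def validate(self) -> None:
        if len(self.pop_labels) != len(self.pop_sizes):
            raise ValueError("pop_labels and pop_sizes lengths differ")
        if any(s <= 0 for s in self.pop_sizes) or min(
            self.n_scaffolds, self.scaffold_length, self.n_genes, self.n_snps, self.n_survivors
        ) <= 0:
            raise ValueError("all counts must be positive")
        if self.survivor_pop not in self.pop_labels:
            raise ValueError(f"survivor_pop {self.survivor_pop!r} not in pop_labels")
        if sum(self.pop_sizes) < self.n_survivors:
            raise ValueError("total population size smaller than survivor group")
        if not (0 <= self.background_fst < 1):
            raise ValueError("background_fst must be in [0, 1)")
        if not (0 < self.planted_freq_shift <= 1) and self.n_planted:
            raise ValueError("planted_freq_shift must be in (0, 1]")
        if self.n_planted > self.n_snps:
            raise ValueError("n_planted exceeds n_snps")
        if self.n_planted > self.n_genes:
            raise ValueError("n_planted exceeds n_genes (one planted SNP per gene)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0 < self.maf_floor < 0.5):
            raise ValueError("maf_floor must be in (0, 0.5)")
        n_fail = self.n_fail_near_indel + self.n_fail_hard + self.n_fail_missing + self.n_fail_maf
        if n_fail > self.n_snps - self.n_planted:
            raise ValueError("too many planted filter failures for n_snps")
        if self.n_fail_near_indel > self.n_indels:
            raise ValueError("n_fail_near_indel exceeds n_indels")

    @property
    def n_individuals(self) -> int:
        return sum(self.pop_sizes) + self.n_survivors


@dataclass
class TruthTable:
    """Ground truth of every planted signal, keyed by emitted SNP ids."""

    snps: pd.DataFrame  # snp_id, planted flag, gene_id, p_anc, p_lowland, p_survivor
    planted_snp_ids: list[str]
    planted_gene_ids: list[str]
    fail_near_indel_ids: list[str] = field(default_factory=list)
    fail_hard_ids: list[str] = field(default_factory=list)
    fail_missing_ids: list[str] = field(default_factory=list)
    fail_maf_ids: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "planted_snp_ids": self.planted_snp_ids,
            "planted_gene_ids": self.planted_gene_ids,
            "fail_near_indel_ids": self.fail_near_indel_ids,
            "fail_hard_ids": self.fail_hard_ids,
            "fail_missing_ids": self.fail_missing_ids,
            "fail_maf_ids": self.fail_maf_ids,
            "snps": self.snps.to_dict(orient="list"),
        }
        return json.dumps(payload, indent=1)


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    names = ("genome", "genes", "placement", "freqs", "genotypes", "qc",
             "missing", "indels", "terms")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# gene models + genome


def generate_gene_models(config: SimConfig) -> tuple[GeneModelSet, dict[str, str]]:
    """Place non-overlapping genes on random scaffolds and bake their CDS.

    Each gene gets a 5'UTR exon, 1-3 CDS exons (length divisible by 3,
    starting ATG, ending in a stop, no internal stops), introns between all
    exons, and a 3'UTR exon; strands alternate randomly.  Raises
    ``ValueError`` when the requested genes cannot be placed.
    """
    config.validate()
    rngs = _substreams(config.seed)
    rng_genome, rng_genes = rngs["genome"], rngs["genes"]

    scaffolds = [f"scaffold{r + 1:03d}" for r in range(config.n_scaffolds)]
    genome = {name: rng_genome.choice(_BASES, size=config.scaffold_length).tolist()
              for name in scaffolds}

    cursors = {name: 0 for name in scaffolds}
    genes: list[Gene] = []
    for gi in range(config.n_genes):
        strand = "+" if rng_genes.random() < 0.5 else "-"
        u5 = int(rng_genes.integers(60, 151))
        u3 = int(rng_genes.integers(60, 151))
        n_exons = int(rng_genes.integers(1, 4))
        n_codons = int(rng_genes.integers(30, 121))  # incl. start + stop
        cds_len = 3 * n_codons
        cuts = sorted(rng_genes.choice(np.arange(1, n_codons), size=n_exons - 1,
                                       replace=False).tolist()) if n_exons > 1 else []
        seg_codons = np.diff([0, *cuts, n_codons])
        exon_lens = [u5, *(3 * int(c) for c in seg_codons), u3]
        intron_lens = [int(rng_genes.integers(60, 201)) for _ in range(len(exon_lens) - 1)]
        gene_len = sum(exon_lens) + sum(intron_lens)
        gap = int(rng_genes.integers(200, 801))

        placed = None
        order = sorted(scaffolds, key=lambda s: cursors[s])
        for name in order:
            start = cursors[name] + gap
            if start + gene_len <= config.scaffold_length:
                placed = (name, start)
                break
        if placed is None:
            raise ValueError(
                f"cannot place gene {gi + 1}/{config.n_genes}: scaffolds exhausted "
                f"(increase scaffold_length or n_scaffolds)"
            )
        name, start = placed
        cursors[name] = start + gene_len

        # transcription-order parts -> genomic intervals
        parts = [("utr5", u5)] + [("cds", 3 * int(c)) for c in seg_codons] + [("utr3", u3)]
        order_parts = parts if strand == "+" else parts[::-1]
        pos = start
        exons, cds, utr5, utr3 = [], [], [], []
        for k, (kind, length) in enumerate(order_parts):
            iv = (pos, pos + length)
            exons.append(iv)
            {"cds": cds, "utr5": utr5, "utr3": utr3}[kind].append(iv)
            pos += length
            if k < len(order_parts) - 1:
                pos += intron_lens[k]
        gene = Gene(
            gene_id=f"gene{gi + 1:04d}", scaffold=name, strand=strand,
            start=start, end=pos, exons=sorted(exons), cds=sorted(cds),
            utr5=sorted(utr5), utr3=sorted(utr3),
        )

        # coding sequence: ATG + non-stop codons + stop, written to genome
        codons = ["ATG"] + [
            _NONSTOP_CODONS[int(i)]
            for i in rng_genes.integers(0, len(_NONSTOP_CODONS), size=n_codons - 2)
        ] + [_STOPS[int(rng_genes.integers(0, 3))]]
        mrna_cds = "".join(codons)
        genomic_cds = mrna_cds if strand == "+" else revcomp(mrna_cds)
        offset = 0
        for s, e in gene.cds:
            genome[name][s:e] = list(genomic_cds[offset:offset + (e - s)])
            offset += e - s
        genes.append(gene)

    return GeneModelSet(genes), {k: "".join(v) for k, v in genome.items()}


# ---------------------------------------------------------------------------
# cohort


def _population_map(config: SimConfig) -> pd.DataFrame:
    rows = []
    for pop, size in zip(config.pop_labels, config.pop_sizes):
        for i in range(size):
            rows.append((f"{pop}{i + 1:02d}_KM", pop, "KM"))
    for i in range(config.n_survivors):
        rows.append((f"{config.survivor_pop}{i + 1:02d}_LZ", config.survivor_pop, "LZ"))
    return pd.DataFrame(rows, columns=["individual", "population", "site"])


def generate_cohort(
    config: SimConfig, models: GeneModelSet, genome: dict[str, str]
) -> tuple[SnpDataset, pd.DataFrame, pd.DataFrame, TruthTable]:
    """Draw the genotype cohort; returns (dataset, indels, popmap, truth)."""
    config.validate()
    rngs = _substreams(config.seed)
    rng_place, rng_freq = rngs["placement"], rngs["freqs"]
    rng_geno, rng_qc = rngs["genotypes"], rngs["qc"]
    rng_missing, rng_indel = rngs["missing"], rngs["indels"]

    popmap = _population_map(config)
    n_ind = len(popmap)
    scaffolds = sorted(genome)

    # --- SNP positions: planted SNPs sit in distinct genes' CDS
    gene_ids = sorted(models.genes)
    planted_genes = [gene_ids[int(i)] for i in
                     rng_place.choice(len(gene_ids), size=config.n_planted, replace=False)]
    taken: set[tuple[str, int]] = set()
    planted_pos: list[tuple[str, int]] = []
    for gid in planted_genes:
        g = models[gid]
        cds_pos = g.cds_genomic_positions()
        # avoid start and stop codons so planted SNPs stay ordinary coding sites
        inner = cds_pos[3:-3] if len(cds_pos) > 6 else cds_pos
        while True:
            p0 = int(inner[int(rng_place.integers(0, len(inner)))])
            if (g.scaffold, p0) not in taken:
                break
        taken.add((g.scaffold, p0))
        planted_pos.append((g.scaffold, p0))

    n_background = config.n_snps - config.n_planted
    background_pos: list[tuple[str, int]] = []
    while len(background_pos) < n_background:
        sc = scaffolds[int(rng_place.integers(0, len(scaffolds)))]
        p0 = int(rng_place.integers(0, len(genome[sc])))
        if (sc, p0) in taken:
            continue
        taken.add((sc, p0))
        background_pos.append((sc, p0))

    all_pos = planted_pos + background_pos
    planted_mask = np.zeros(config.n_snps, bool)
    planted_mask[: config.n_planted] = True

    # --- planted filter failures: background SNPs, mutually disjoint,
    # near-indel candidates must be isolated so indels hit nothing else
    snp_pos_by_scaffold: dict[str, np.ndarray] = {}
    for sc in scaffolds:
        snp_pos_by_scaffold[sc] = np.asarray(sorted(p for s, p in all_pos if s == sc))
    bg_idx = np.arange(config.n_planted, config.n_snps)
    shuffled = bg_idx[rng_place.permutation(len(bg_idx))]

    def isolated(i: int) -> bool:
        sc, p0 = all_pos[i]
        arr = snp_pos_by_scaffold[sc]
        near = arr[(np.abs(arr - p0) <= 12) & (arr != p0)]
        return len(near) == 0 and p0 + 8 < len(genome[sc])

    fail_near: list[int] = []
    pool = iter(shuffled.tolist())
    used: set[int] = set()
    while len(fail_near) < config.n_fail_near_indel:
        i = next(pool)  # raises StopIteration -> config infeasible, acceptable
        if isolated(i):
            fail_near.append(i)
            used.add(i)
    rest = [i for i in shuffled.tolist() if i not in used]
    fail_hard = rest[: config.n_fail_hard]
    rest = rest[config.n_fail_hard:]
    fail_missing = rest[: config.n_fail_missing]
    rest = rest[config.n_fail_missing:]
    fail_maf = rest[: config.n_fail_maf]

    # --- allele frequencies (Balding–Nichols around ancestral p)
    lo, hi = config.maf_floor, 1 - config.maf_floor
    p_anc = rng_freq.uniform(lo, hi, size=config.n_snps)
    if config.n_planted:
        p_hi = max(lo + 0.01, 1 - config.planted_freq_shift - config.maf_floor)
        p_anc[planted_mask] = rng_freq.uniform(lo, p_hi, size=config.n_planted)
    F = config.background_fst
    n_pops = len(config.pop_labels)
    if F > 0:
        shape = (n_pops, config.n_snps)
        pop_freq = rng_freq.beta(p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F, size=shape)
    else:
        pop_freq = np.tile(p_anc, (n_pops, 1))

    surv_idx = config.pop_labels.index(config.survivor_pop)
    p_lowland = pop_freq[surv_idx].copy()
    p_survivor = p_lowland.copy()
    p_survivor[planted_mask] = np.clip(
        p_survivor[planted_mask] + config.planted_freq_shift, 0.0, 1.0
    )

    # --- genotypes (Hardy–Weinberg binomial draws per individual)
    dosage = np.empty((config.n_snps, n_ind), dtype=np.int8)
    col = 0
    for pi, size in enumerate(config.pop_sizes):
        dosage[:, col:col + size] = rng_geno.binomial(
            2, pop_freq[pi][:, None], size=(config.n_snps, size)
        )
        col += size
    dosage[:, col:] = rng_geno.binomial(
        2, p_survivor[:, None], size=(config.n_snps, config.n_survivors)
    )

    # --- QC annotations: all-pass by default, planted failures explicit
    info = {
        "MQ": rng_qc.uniform(50, 60, config.n_snps),
        "QD": rng_qc.uniform(15, 30, config.n_snps),
        "FS": rng_qc.uniform(0, 5, config.n_snps),
        "SOR": rng_qc.uniform(0.5, 2.0, config.n_snps),
        "MQRankSum": rng_qc.uniform(-2, 2, config.n_snps),
        "ReadPosRankSum": rng_qc.uniform(-2, 2, config.n_snps),
    }
    hard_breaks = {"MQ": 30.0, "QD": 1.0, "FS": 40.0, "SOR": 6.0,
                   "MQRankSum": -20.0, "ReadPosRankSum": -10.0}
    for k, i in enumerate(fail_hard):
        fld = INFO_FIELDS[k % len(INFO_FIELDS)]
        info[fld][i] = hard_breaks[fld]

    gq = rng_qc.integers(60, 100, size=(config.n_snps, n_ind)).astype(np.int16)
    dp = rng_qc.integers(20, 61, size=(config.n_snps, n_ind)).astype(np.int16)
    n_low = int(np.floor(0.2 * n_ind)) + 1  # enough to push missing rate over 20%
    for i in fail_missing:
        chosen = rng_qc.choice(n_ind, size=n_low, replace=False)
        gq[i, chosen] = 5

    # --- missingness
    if config.missing_rate > 0:
        miss = rng_missing.random((config.n_snps, n_ind)) < config.missing_rate
        dosage[miss] = -1

    # --- MAF failures: one heterozygote, everyone else hom-ref and called
    for i in fail_maf:
        dosage[i, :] = 0
        dosage[i, int(rng_qc.integers(0, n_ind))] = 1
        gq[i, :] = np.maximum(gq[i, :], 60)

    # --- REF/ALT from genome
    refs, alts = [], []
    for sc, p0 in all_pos:
        ref = genome[sc][p0]
        alt_choices = [b for b in "ACGT" if b != ref]
        alts.append(alt_choices[int(rng_freq.integers(0, 3))])
        refs.append(ref)

    sites = pd.DataFrame({
        "scaffold": [sc for sc, _ in all_pos],
        "pos": [p0 + 1 for _, p0 in all_pos],
        "ref": refs,
        "alt": alts,
        "is_biallelic_snp": True,
        **info,
    })

    # sort genome-wise, then assign stable ids
    order = np.lexsort((sites["pos"].to_numpy(), sites["scaffold"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    sites.insert(0, "snp_id", [f"snp{i + 1:06d}" for i in range(len(sites))])
    dosage, gq, dp = dosage[order], gq[order], dp[order]
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))  # generation index -> sorted row

    dataset = SnpDataset(sites=sites, samples=popmap["individual"].tolist(),
                         dosage=dosage, gq=gq, dp=dp)

    # --- indel records
    indel_rows = []
    for k, i in enumerate(fail_near):
        sc, p0 = all_pos[i]
        s = p0 + 2  # REF span within 4 bp of the SNP -> removed by proximity
        ref = genome[sc][s:s + 3]
        indel_rows.append((f"ind{k + 1:04d}", sc, s + 1, ref, ref[0]))
    k0 = len(indel_rows)
    attempts = 0
    while len(indel_rows) < config.n_indels and attempts < 100 * config.n_indels:
        attempts += 1
        sc = scaffolds[int(rng_indel.integers(0, len(scaffolds)))]
        s = int(rng_indel.integers(0, len(genome[sc]) - 6))
        span_len = int(rng_indel.integers(1, 4))
        arr = snp_pos_by_scaffold[sc]
        # keep honest background indels clear of every SNP
        if len(arr) and np.min(np.abs(arr - s)) <= span_len + 8:
            continue
        if int(rng_indel.integers(0, 2)):  # deletion: anchor base + deleted bases
            ref = genome[sc][s:s + span_len + 1]
            rec = (f"ind{len(indel_rows) + 1:04d}", sc, s + 1, ref, ref[0])
        else:  # insertion
            ref = genome[sc][s]
            ins = "".join(_BASES[int(b)] for b in rng_indel.integers(0, 4, size=span_len))
            rec = (f"ind{len(indel_rows) + 1:04d}", sc, s + 1, ref, ref + ins)
        indel_rows.append(rec)
    indels = pd.DataFrame(indel_rows, columns=["snp_id", "scaffold", "pos", "ref", "alt"])

    # --- truth table
    snp_ids = sites["snp_id"].to_numpy()
    gene_of = np.full(config.n_snps, "", dtype=object)
    for j, gid in enumerate(planted_genes):
        gene_of[inv[j]] = gid
    truth_df = pd.DataFrame({
        "snp_id": snp_ids,
        "planted": planted_mask[order],
        "gene_id": gene_of,
        "p_anc": p_anc[order],
        "p_lowland": p_lowland[order],
        "p_survivor": p_survivor[order],
    })
    truth = TruthTable(
        snps=truth_df,
        planted_snp_ids=[snp_ids[inv[i]] for i in range(config.n_planted)],
        planted_gene_ids=list(planted_genes),
        fail_near_indel_ids=[snp_ids[inv[i]] for i in fail_near],
        fail_hard_ids=[snp_ids[inv[i]] for i in fail_hard],
        fail_missing_ids=[snp_ids[inv[i]] for i in fail_missing],
        fail_maf_ids=[snp_ids[inv[i]] for i in fail_maf],
    )
    return dataset, indels, popmap, truth


# ---------------------------------------------------------------------------
# term map


def generate_term_map(config: SimConfig, models: GeneModelSet,
                      truth: TruthTable | None = None) -> pd.DataFrame:
    """Assign 1-4 random terms per gene, plus one planted enriched term.

    The designated term ``T_SEL`` covers ``planted_term_coverage`` of the
    planted genes and ``planted_term_background`` of the remaining genes;
    with no planted genes it is simply absent.
    """
    config.validate()
    rng = _substreams(config.seed)["terms"]
    gene_ids = sorted(models.genes)
    planted = set(truth.planted_gene_ids) if truth is not None else set()
    rows = []
    for gid in gene_ids:
        k = int(rng.integers(1, 5))
        terms = rng.choice(config.n_terms, size=min(k, config.n_terms), replace=False)
        for t in sorted(int(x) for x in terms):
            rows.append((gid, f"T{t + 1:04d}", f"term {t + 1}"))
        if gid in planted:
            if rng.random() < config.planted_term_coverage:
                rows.append((gid, "T_SEL", "selected pathway"))
        elif planted and rng.random() < config.planted_term_background:
            rows.append((gid, "T_SEL", "selected pathway"))
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"])


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SimResult:
    config: SimConfig
    models: GeneModelSet
    genome: dict[str, str]
    dataset: SnpDataset
    indels: pd.DataFrame
    popmap: pd.DataFrame
    truth: TruthTable
    term_map: pd.DataFrame

    def write(self, outdir: str | os.PathLike) -> dict[str, str]:
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "vcf": os.path.join(outdir, "cohort.vcf"),
            "gff3": os.path.join(outdir, "genes.gff3"),
            "fasta": os.path.join(outdir, "genome.fa"),
            "popmap": os.path.join(outdir, "popmap.tsv"),
            "terms": os.path.join(outdir, "terms.tsv"),
            "truth": os.path.join(outdir, "truth.json"),
        }
        contigs = {name: len(seq) for name, seq in sorted(self.genome.items())}
        gsio.write_vcf(paths["vcf"], self.dataset, self.indels, contigs=contigs)
        gsio.write_gff3(paths["gff3"], self.models)
        gsio.write_fasta(paths["fasta"], self.genome)
        gsio.write_population_map(paths["popmap"], self.popmap)
        gsio.write_term_map(paths["terms"], self.term_map)
        with open(paths["truth"], "w") as fh:
            fh.write(self.truth.to_json())
        return paths


def simulate(config: SimConfig) -> SimResult:
    """Run the full generator: gene models, cohort and term map."""
    models, genome = generate_gene_models(config)
    dataset, indels, popmap, truth = generate_cohort(config, models, genome)
    term_map = generate_term_map(config, models, truth)
    return SimResult(config, models, genome, dataset, indels, popmap, truth, term_map)


def default_comparisons(popmap: pd.DataFrame,
                        core_pops: tuple[str, ...] = ("KM", "YL"),
                        excluded_pops: tuple[str, ...] = ("BS",)) -> list[ComparisonSpec]:
    """The study's two contrasts: survivors vs the core lowland cluster, and
    survivors vs all lowland populations minus the genetically distinct one."""
    surv = tuple(popmap.loc[popmap["site"] == "LZ", "individual"])
    low = popmap[popmap["site"] != "LZ"]
    core = tuple(low.loc[low["population"].isin(core_pops), "individual"])
    allg = tuple(low.loc[~low["population"].isin(excluded_pops), "individual"])
    return [
        ComparisonSpec("survivors_vs_core", surv, core),
        ComparisonSpec("survivors_vs_all", surv, allg),
    ]
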