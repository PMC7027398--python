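"""Per-SNP F_ST, per-gene diversity statistics, LD thinning and PCA.

F_ST follows the Weir & Cockerham (1984) moment estimator for two groups
with the n_c correction for unequal, SNP-specific sample sizes (missing
genotypes excluded per site).  Nucleotide diversity is the classic
per-site average pairwise difference summed over coding SNPs and divided
by coding length.  dN/dS uses Nei & Gojobori (1986) pathway counting with
the Jukes–Cantor correction, computed over all pairs of pseudo-haplotype
coding sequences.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .containers import Gene, GeneModelSet, SnpDataset
from .effects import CODON_TO_AA

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST


def weir_cockerham_fst(
    dosage: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray
) -> pd.DataFrame:
    """Per-SNP Weir-Cockerham variance components for a two-group contrast.

    Parameters
    ----------
    dosage:
        ``(n_snps, n_samples)`` ALT dosage with ``-1`` for missing.
    idx_a, idx_b:
        Column indices of the two groups.

    Returns a DataFrame with columns ``a`` (among-group), ``b``
    (among-individuals-within-group), ``c`` (within-individual), ``theta``
    = a/(a+b+c) and ``defined``.  ``theta`` is reported as computed
    (negatives not truncated); it is undefined when either group has fewer
    than two informative individuals at the SNP or when a+b+c == 0.
    """
    r = 2
    stats = []
    for idx in (idx_a, idx_b):
        sub = dosage[:, idx]
        called = sub >= 0
        n_i = called.sum(axis=1).astype(float)               # individuals
        alt = np.where(called, sub, 0).sum(axis=1).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_i = np.where(n_i > 0, alt / (2 * n_i), np.nan)
            h_i = np.where(n_i > 0, (sub == 1).sum(axis=1) / np.maximum(n_i, 1), np.nan)
        stats.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = stats

    informative = (n1 >= 2) & (n2 >= 2)
    n_bar = (n1 + n2) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        denom = a + b + c
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1), np.nan)

    defined = informative & np.isfinite(denom) & (denom != 0)
    theta = np.where(defined, theta, np.nan)
    return pd.DataFrame({
        "a": np.where(informative, a, np.nan),
        "b": np.where(informative, b, np.nan),
        "c": np.where(informative, c, np.nan),
        "theta": theta,
        "defined": defined,
    })


def fst_table(ds: SnpDataset, group_a, group_b) -> pd.DataFrame:
    """F_ST per SNP for two groups of sample ids, with site coordinates."""
    res = weir_cockerham_fst(ds.dosage, ds.sample_indices(group_a), ds.sample_indices(group_b))
    return pd.concat([ds.sites[["snp_id", "scaffold", "pos"]].reset_index(drop=True), res], axis=1)


# ---------------------------------------------------------------------------
# nucleotide diversity


def site_pi(dosage_row: np.ndarray, sample_idx: np.ndarray) -> float:
    """Average pairwise difference among non-missing alleles at one SNP:
    ``2 * c_ref * c_alt / (n * (n-1))`` for ``n`` non-missing alleles."""
    sub = dosage_row[sample_idx]
    called = sub >= 0
    n = 2 * int(called.sum())
    if n < 2:
        return 0.0
    alt = int(sub[called].sum())
    ref = n - alt
    return 2.0 * ref * alt / (n * (n - 1))


def cds_snp_rows(sites: pd.DataFrame, gene: Gene) -> tuple[np.ndarray, np.ndarray]:
    """Row indices of SNPs inside the gene's CDS, with their CDS indices
    (transcription order)."""
    pos_map = {int(p): i for i, p in enumerate(gene.cds_genomic_positions())}
    rows, cds_idx = [], []
    on_scaffold = np.flatnonzero((sites["scaffold"] == gene.scaffold).to_numpy())
    pos = sites["pos"].to_numpy()
    for r in on_scaffold:
        i = pos_map.get(int(pos[r]) - 1)
        if i is not None:
            rows.append(r)
            cds_idx.append(i)
    return np.asarray(rows, dtype=int), np.asarray(cds_idx, dtype=int)


def gene_pi(ds: SnpDataset, gene: Gene, sample_idx: np.ndarray) -> float:
    """Per-site nucleotide diversity over the gene's coding region.

    Monomorphic coding sites contribute 0 to the numerator and the full
    coding length to the denominator.  NaN when the gene has no CDS.
    """
    length = gene.cds_length()
    if length == 0:
        return float("nan")
    rows, _ = cds_snp_rows(ds.sites, gene)
    total = sum(site_pi(ds.dosage[r], sample_idx) for r in rows)
    return total / length


# ---------------------------------------------------------------------------
# Nei-Gojobori dN/dS


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts of one codon.

    Each position contributes the fraction of its three possible changes
    that are synonymous; changes to stop codons count as nonsynonymous.
    """
    syn = 0.0
    aa = CODON_TO_AA[codon]
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1:]
            if CODON_TO_AA[mut] == aa and CODON_TO_AA[mut] != "*":
                syn += 1 / 3
    return 3.0 - syn, syn


@lru_cache(maxsize=None)
def codon_path_differences(c1: str, c2: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) differences between two codons, averaged
    over all mutational pathways; pathways through stop codons are skipped
    unless every pathway hits one."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        nd = sd = 0
        blocked = False
        for k, i in enumerate(order):
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if CODON_TO_AA[nxt] == "*" and k < len(order) - 1:
                blocked = True
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((nd, sd, blocked))
    valid = [(nd, sd) for nd, sd, blocked in paths if not blocked]
    if not valid:
        valid = [(nd, sd) for nd, sd, _ in paths]
    nd = sum(p[0] for p in valid) / len(valid)
    sd = sum(p[1] for p in valid) / len(valid)
    return nd, sd


def jukes_cantor(p: float) -> tuple[float, bool]:
    """JC-corrected distance; returns (d, corrected?).  When p >= 3/4 the
    correction is undefined and the raw proportion is returned flagged."""
    if p < 0.75:
        return -0.75 * math.log1p(-4.0 * p / 3.0), True
    return p, False


@dataclass
class DnDsResult:
    dn: float
    ds: float
    ratio: float  # NaN when dS == 0
    n_pairs: int
    jc_corrected: bool  # False if any pair needed the uncorrected fallback


def pairwise_dnds(
    ds: SnpDataset, gene: Gene, genome: dict[str, str], sample_idx: np.ndarray,
    phase: str = "alt_first", seed: int | None = None,
) -> DnDsResult:
    """Mean pairwise Nei-Gojobori dN and dS over a group's coding haplotypes.

    Unphased diploids are split into two pseudo-haplotypes per individual:
    with ``phase="alt_first"`` ALT alleles at heterozygous sites go to
    haplotype 1 (deterministic); ``phase="random"`` randomizes each het
    assignment using ``seed``.  Missing genotypes are treated as reference.
    The terminal stop codon is excluded from counting.
    """
    cds_seq = gene.cds_sequence(genome)
    L = len(cds_seq)
    rows, cds_idx = cds_snp_rows(ds.sites, gene)
    keep = cds_idx < L - 3  # drop terminal stop codon
    rows, cds_idx = rows[keep], cds_idx[keep]
    n_codons = L // 3 - 1

    n = len(sample_idx)
    n_hap = 2 * n
    n_pairs = n_hap * (n_hap - 1) // 2
    ref_codons = [cds_seq[3 * i: 3 * i + 3] for i in range(n_codons)]
    ref_counts = [codon_site_counts(c) for c in ref_codons]
    ref_N = sum(c[0] for c in ref_counts)
    ref_S = sum(c[1] for c in ref_counts)

    if len(rows) == 0:
        return DnDsResult(0.0, 0.0, float("nan"), n_pairs, True)

    sub = ds.dosage[np.ix_(rows, sample_idx)]
    called = sub >= 0
    dos = np.where(called, sub, 0)
    if phase == "alt_first":
        hap1 = (dos >= 1)
        hap2 = (dos == 2)
    elif phase == "random":
        rng = np.random.default_rng(seed)
        flip = rng.integers(0, 2, size=dos.shape).astype(bool)
        het = dos == 1
        hap1 = (dos == 2) | (het & ~flip)
        hap2 = (dos == 2) | (het & flip)
    else:
        raise ValueError(f"unknown phase rule {phase!r}")
    haps = np.concatenate([hap1.T, hap2.T], axis=0)  # (2n, m) ALT-carrier bits

    # coding-strand ALT base per variant site
    alts = ds.sites["alt"].to_numpy()
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    alt_c = [a if gene.strand == "+" else comp[a] for a in alts[rows]]

    uniq, inverse, counts = np.unique(haps, axis=0, return_inverse=True, return_counts=True)

    def mutated_codons(bits: np.ndarray) -> dict[int, str]:
        """codon index -> mutated codon string for one haplotype pattern."""
        out: dict[int, str] = {}
        for j in np.flatnonzero(bits):
            i = int(cds_idx[j])
            ci = i // 3
            codon = out.get(ci, ref_codons[ci])
            off = i % 3
            out[ci] = codon[:off] + alt_c[j] + codon[off + 1:]
        return out

    muts = [mutated_codons(u) for u in uniq]
    NS = []
    for mu in muts:
        dN_sites = sum(codon_site_counts(c)[0] - ref_counts[ci][0] for ci, c in mu.items())
        dS_sites = sum(codon_site_counts(c)[1] - ref_counts[ci][1] for ci, c in mu.items())
        NS.append((ref_N + dN_sites, ref_S + dS_sites))

    sum_dn = 0.0
    sum_ds = 0.0
    all_corrected = True
    for u in range(len(uniq)):
        for v in range(u, len(uniq)):
            w = counts[u] * (counts[u] - 1) // 2 if u == v else counts[u] * counts[v]
            if w == 0 or u == v:
                continue  # identical haplotypes: dN = dS = 0
            codons = set(muts[u]) | set(muts[v])
            nd = sd = 0.0
            for ci in codons:
                c1 = muts[u].get(ci, ref_codons[ci])
                c2 = muts[v].get(ci, ref_codons[ci])
                d_n, d_s = codon_path_differences(c1, c2)
                nd += d_n
                sd += d_s
            N = (NS[u][0] + NS[v][0]) / 2
            S = (NS[u][1] + NS[v][1]) / 2
            pn = nd / N if N > 0 else 0.0
            ps = sd / S if S > 0 else 0.0
            dn, ok_n = jukes_cantor(pn)
            dsyn, ok_s = jukes_cantor(ps)
            all_corrected &= ok_n and ok_s
            sum_dn += w * dn
            sum_ds += w * dsyn
    dn = sum_dn / n_pairs if n_pairs else 0.0
    dsyn = sum_ds / n_pairs if n_pairs else 0.0
    ratio = dn / dsyn if dsyn > 0 else float("nan")
    return DnDsResult(dn, dsyn, ratio, n_pairs, all_corrected)


def gene_diversity_table(
    ds: SnpDataset, models: GeneModelSet, genome: dict[str, str], sample_ids,
    phase: str = "alt_first",
) -> pd.DataFrame:
    """π, dN, dS and dN/dS for every gene, for one group of individuals."""
    idx = ds.sample_indices(sample_ids)
    rows = []
    for gene in sorted(models, key=lambda g: g.gene_id):
        pi = gene_pi(ds, gene, idx)
        res = pairwise_dnds(ds, gene, genome, idx, phase=phase)
        n_used = len(cds_snp_rows(ds.sites, gene)[0])
        rows.append((gene.gene_id, pi, res.dn, res.ds, res.ratio, n_used))
    return pd.DataFrame(rows, columns=["gene_id", "pi", "dn", "ds", "dnds", "n_snps_used"])


# ---------------------------------------------------------------------------
# LD thinning


def ld_thin(sites: pd.DataFrame, window_bp: int = 5000) -> np.ndarray:
    """Boolean keep-mask retaining the lowest-position SNP per non-empty
    ``window_bp`` window (windows anchored at position 1 per scaffold)."""
    order = np.lexsort((sites["pos"].to_numpy(), sites["scaffold"].to_numpy()))
    keep = np.zeros(len(sites), dtype=bool)
    seen: set[tuple[str, int]] = set()
    scaff = sites["scaffold"].to_numpy()
    pos = sites["pos"].to_numpy()
    for i in order:
        win = (scaff[i], int((pos[i] - 1) // window_bp))
        if win not in seen:
            seen.add(win)
            keep[i] = True
    return keep


# ---------------------------------------------------------------------------
# PCA


def pca(dosage: np.ndarray, n_components: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Genotype PCA with Patterson normalization.

    Missing dosages are mean-imputed per SNP; columns are centered by
    ``2 p_hat`` and scaled by ``sqrt(2 p_hat (1 - p_hat))``;
    zero-variance SNPs are dropped.  Returns (scores ``(n_samples, k)``,
    variance fractions summing to 1 over all components).
    """
    X = dosage.T.astype(float)  # samples x snps
    miss = X < 0
    with np.errstate(invalid="ignore"):
        col_mean = np.where(
            (~miss).sum(axis=0) > 0,
            np.where(miss, 0, X).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1),
            np.nan,
        )
    X = np.where(miss, col_mean, X)
    p_hat = col_mean / 2.0
    var_ok = np.isfinite(p_hat) & (p_hat > 0) & (p_hat < 1)
    if (~var_ok).any():
        log.info("pca: dropping %d zero-variance or all-missing SNP(s)", int((~var_ok).sum()))
    X = X[:, var_ok]
    p = p_hat[var_ok]
    Xc = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("pca needs at least 2 samples and 2 polymorphic SNPs")
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U * s
    varfrac = s**2 / np.sum(s**2)
    if n_components is not None:
        scores = scores[:, :n_components]
    return scores, varfrac
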