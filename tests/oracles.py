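"""Independent brute-force oracles and small dataset builders for the tests.

Everything here recomputes quantities by a route deliberately different
from the package implementation (scalar loops, exhaustive enumeration,
full-sequence translation) so agreement is evidence, not tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from gardenscan.containers import INFO_FIELDS, SnpDataset

# ---------------------------------------------------------------------------
# dataset builder


def make_dataset(dosage, scaffold="chr1", positions=None, ref="A", alt="T",
                 gq=None, dp=None, info=None, biallelic=None) -> SnpDataset:
    """Construct a SnpDataset from a dosage matrix (n_snps, n_samples)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_snps, n_samples = dosage.shape
    positions = list(positions) if positions is not None else list(range(1, n_snps + 1))
    refs = [ref] * n_snps if isinstance(ref, str) else list(ref)
    alts = [alt] * n_snps if isinstance(alt, str) else list(alt)
    scaffolds = [scaffold] * n_snps if isinstance(scaffold, str) else list(scaffold)
    sites = pd.DataFrame({
        "snp_id": [f"s{i + 1:04d}" for i in range(n_snps)],
        "scaffold": scaffolds, "pos": positions, "ref": refs, "alt": alts,
        "is_biallelic_snp": biallelic if biallelic is not None else True,
    })
    for f in INFO_FIELDS:
        sites[f] = (info or {}).get(f, np.nan)
    samples = [f"i{j + 1:03d}" for j in range(n_samples)]
    gq = np.full(dosage.shape, 99, np.int16) if gq is None else np.asarray(gq, np.int16)
    dp = np.full(dosage.shape, 30, np.int16) if dp is None else np.asarray(dp, np.int16)
    return SnpDataset(sites=sites, samples=samples, dosage=dosage, gq=gq, dp=dp)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta, scalar per-allele-sum form


def wc_components_oracle(geno_a, geno_b):
    """Variance components summed over both alleles; returns (A, B, C) or
    None when a group has < 2 called individuals.  Biallelic theta equals
    A/(A+B+C); each per-allele component is half of A/B/C."""
    groups = [[g for g in geno_a if g >= 0], [g for g in geno_b if g >= 0]]
    n = [len(g) for g in groups]
    if min(n) < 2:
        return None
    r = 2
    nbar = sum(n) / r
    nc = (sum(n) - sum(ni * ni for ni in n) / sum(n)) / (r - 1)
    A = B = C = 0.0
    for allele in (0, 1):
        p, h = [], []
        for g in groups:
            freq_alt = sum(g) / (2 * len(g))
            p.append(freq_alt if allele == 1 else 1 - freq_alt)
            h.append(sum(1 for x in g if x == 1) / len(g))
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / sum(n)
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / sum(n)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        A, B, C = A + a, B + b, C + c
    return A, B, C


def wc_theta_oracle(geno_a, geno_b):
    comps = wc_components_oracle(geno_a, geno_b)
    if comps is None:
        return None
    A, B, C = comps
    if A + B + C == 0:
        return None
    return A / (A + B + C)


# ---------------------------------------------------------------------------
# nucleotide diversity by allele-pair enumeration


def site_pi_oracle(dosages) -> float:
    """Average difference over every pair of non-missing alleles at a site."""
    alleles = []
    for d in dosages:
        if d >= 0:
            alleles += [1] * d + [0] * (2 - d)
    pairs = list(itertools.combinations(alleles, 2))
    if not pairs:
        return 0.0
    return sum(x != y for x, y in pairs) / len(pairs)


# ---------------------------------------------------------------------------
# Nei-Gojobori by recursive pathway enumeration over full sequences

_STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    from Bio.Seq import Seq
    return str(Seq(codon).translate())


def ng_sites_oracle(seq: str) -> tuple[float, float]:
    """(N, S) sites of one coding sequence by enumerating all 9 point
    mutations per codon (mutations creating stops count nonsynonymous)."""
    N = S = 0.0
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        for j in range(3):
            syn = 0
            for b in "ACGT":
                if b == codon[j]:
                    continue
                mut = codon[:j] + b + codon[j + 1:]
                if mut not in _STOPS and _aa(mut) == _aa(codon):
                    syn += 1
            S += syn / 3
            N += (3 - syn) / 3
    return N, S


def _codon_paths(c1: str, c2: str):
    """Yield (nd, sd, blocked) for every substitution ordering."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    for order in itertools.permutations(diff):
        cur, nd, sd, blocked = c1, 0, 0, False
        for k, i in enumerate(order):
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if nxt in _STOPS and k < len(order) - 1:
                blocked = True
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        yield nd, sd, blocked


def ng_differences_oracle(seq1: str, seq2: str) -> tuple[float, float]:
    """(Nd, Sd) between two aligned coding sequences, pathway-averaged with
    stop-passing pathways excluded when any clean pathway exists."""
    Nd = Sd = 0.0
    for i in range(0, len(seq1), 3):
        paths = list(_codon_paths(seq1[i:i + 3], seq2[i:i + 3]))
        if not paths:
            continue
        ok = [(n, s) for n, s, blocked in paths if not blocked] or \
             [(n, s) for n, s, _ in paths]
        Nd += sum(p[0] for p in ok) / len(ok)
        Sd += sum(p[1] for p in ok) / len(ok)
    return Nd, Sd


def ng_dnds_oracle(seq1: str, seq2: str) -> tuple[float, float]:
    """Jukes-Cantor corrected (dN, dS) for one sequence pair."""
    n1 = ng_sites_oracle(seq1)
    n2 = ng_sites_oracle(seq2)
    N, S = (n1[0] + n2[0]) / 2, (n1[1] + n2[1]) / 2
    Nd, Sd = ng_differences_oracle(seq1, seq2)
    pn, ps = Nd / N if N else 0.0, Sd / S if S else 0.0
    dn = -0.75 * math.log1p(-4 * pn / 3) if pn < 0.75 else pn
    dsyn = -0.75 * math.log1p(-4 * ps / 3) if ps < 0.75 else ps
    return dn, dsyn


# ---------------------------------------------------------------------------
# hypergeometric upper tail


def hypergeom_sf_comb(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] via the closed comb-sum formula."""
    denom = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(k, min(K, n) + 1)) / denom


def hypergeom_sf_enumerate(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] by exhaustive enumeration of all C(N, n) draws (tiny N)."""
    hits = 0
    total = 0
    population = list(range(N))
    marked = set(range(K))
    for draw in itertools.combinations(population, n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# BH step-up reference


def bh_reference(pvals):
    """Plain textbook step-up: q_(i) = min_{j>=i} (m * p_(j) / j), capped."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = min(running, 1.0)
    return q


# ---------------------------------------------------------------------------
# exact two-sided rank-sum p by label enumeration


def ranksum_p_enumeration(x, y) -> float:
    """Two-sided Mann-Whitney p by enumerating all group labelings."""
    combined = list(x) + list(y)
    nx = len(x)
    idx = range(len(combined))

    def u_stat(ix):
        xs = [combined[i] for i in ix]
        ys = [combined[i] for i in idx if i not in set(ix)]
        u = sum((xi > yi) + 0.5 * (xi == yi) for xi in xs for yi in ys)
        return u

    observed = u_stat(range(nx))
    mean_u = nx * (len(combined) - nx) / 2
    obs_dev = abs(observed - mean_u)
    total = extreme = 0
    for ix in itertools.combinations(idx, nx):
        total += 1
        if abs(u_stat(ix) - mean_u) >= obs_dev - 1e-12:
            extreme += 1
    return extreme / total
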