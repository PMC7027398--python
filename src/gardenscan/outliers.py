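"""Top-quantile F_ST outlier scan with a permutation recurrence filter.

The procedure: rank per-SNP F_ST, take the top ``q`` (default 1%) as
putative outliers, then repeat the scan on ``n_perm`` random re-partitions
of the individuals into pseudo-groups of the original sizes.  A putative
outlier is retained only when its recurrence rate across permutations is
strictly below ``rate_max`` (default 0.01) -- an empirical false-discovery
control: SNPs whose extreme differentiation reappears under label
permutation are judged reproducible by chance and dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ComparisonSpec, GeneModelSet, SnpDataset
from .popgen import weir_cockerham_fst

log = logging.getLogger(__name__)


@dataclass
class OutlierReport:
    comparison: str
    q: float
    n_perm: int
    putative: pd.DataFrame  # snp_id, theta, rank (1 = highest theta)
    recurrence: dict[str, int] = field(default_factory=dict)
    retained_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    @property
    def putative_ids(self) -> list[str]:
        return self.putative["snp_id"].tolist()


def putative_indices(theta: np.ndarray, defined: np.ndarray, q: float) -> np.ndarray:
    """Indices of SNPs in the top-q tail of defined theta values.

    The threshold is the empirical (1-q) quantile of defined thetas; all
    SNPs with theta >= threshold are putative, so ties may push the set
    beyond q*M.  With fewer than 1/q defined SNPs the quantile is
    meaningless and the top ceil(q*M) SNPs are returned with a warning.
    """
    if not (0 < q < 0.5):
        raise ValueError("q must be in (0, 0.5)")
    ok = np.flatnonzero(defined & np.isfinite(theta))
    if len(ok) == 0:
        return np.empty(0, dtype=int)
    vals = theta[ok]
    if len(ok) < 1.0 / q:
        log.warning("only %d defined F_ST values for q=%g; taking top ceil(q*M)", len(ok), q)
        k = max(1, math.ceil(q * len(ok)))
        top = ok[np.argsort(-vals, kind="stable")[:k]]
        return np.sort(top)
    thr = np.quantile(vals, 1.0 - q)
    return ok[vals >= thr]


def top_quantile_outliers(fst: pd.DataFrame, q: float = 0.01) -> pd.DataFrame:
    """Putative outlier table (snp_id, theta, rank) from an F_ST table."""
    theta = fst["theta"].to_numpy(float)
    defined = fst["defined"].to_numpy(bool)
    idx = putative_indices(theta, defined, q)
    sub = fst.iloc[idx][["snp_id", "theta"]].copy()
    sub["rank"] = sub["theta"].rank(ascending=False, method="min").astype(int)
    return sub.sort_values("rank", kind="stable").reset_index(drop=True)


def permutation_null(
    ds: SnpDataset,
    comparison: ComparisonSpec,
    putative_ids,
    q: float = 0.01,
    n_perm: int = 100,
    seed: int | None = None,
    pool: str = "union",
) -> dict[str, int]:
    """Recurrence counts of putative outliers across permuted comparisons.

    Each permutation draws pseudo-groups of the original sizes without
    replacement from the resampling pool: ``pool="all"`` uses every
    individual in the dataset (re-sampling from the whole sample set),
    ``pool="union"`` only the individuals of the two compared groups.
    """
    if seed is None:
        raise ValueError("a seed is required: permutation runs must be reproducible")
    if n_perm < 0:
        raise ValueError("n_perm must be >= 0")
    rng = np.random.default_rng(seed)
    n_a, n_b = len(comparison.group_a), len(comparison.group_b)
    if pool == "union":
        pool_idx = ds.sample_indices(list(comparison.group_a) + list(comparison.group_b))
    elif pool == "all":
        pool_idx = np.arange(ds.n_samples)
    else:
        raise ValueError(f"unknown pool {pool!r}")
    if n_a + n_b > len(pool_idx):
        raise ValueError("resampling pool smaller than the two groups combined")

    snp_ids = ds.sites["snp_id"].to_numpy()
    id_row = {s: i for i, s in enumerate(snp_ids)}
    put_rows = np.asarray([id_row[s] for s in putative_ids], dtype=int)
    recurrence = {s: 0 for s in putative_ids}
    for _ in range(n_perm):
        perm = rng.permutation(pool_idx)
        idx_a, idx_b = perm[:n_a], perm[n_a:n_a + n_b]
        res = weir_cockerham_fst(ds.dosage, idx_a, idx_b)
        sel = putative_indices(res["theta"].to_numpy(), res["defined"].to_numpy(), q)
        hit = np.intersect1d(sel, put_rows, assume_unique=False)
        for row in hit:
            recurrence[snp_ids[row]] += 1
    return recurrence


def genes_overlapping(snp_rows: pd.DataFrame, models: GeneModelSet) -> list[str]:
    """Distinct gene ids whose span contains any of the given SNPs."""
    hits: set[str] = set()
    for row in snp_rows.itertuples(index=False):
        for g in models.genes_at(row.scaffold, int(row.pos) - 1):
            hits.add(g.gene_id)
    return sorted(hits)


def retain_by_recurrence(
    putative: pd.DataFrame,
    recurrence: dict[str, int],
    n_perm: int,
    rate_max: float = 0.01,
    sites: pd.DataFrame | None = None,
    models: GeneModelSet | None = None,
) -> tuple[list[str], list[str]]:
    """Retained outliers (recurrence rate strictly < rate_max) + gene overlap."""
    missing = [s for s in putative["snp_id"] if s not in recurrence]
    if missing:
        raise ValueError(f"recurrence missing for putative SNPs: {missing[:5]}...")
    if n_perm > 0:
        retained = [s for s in putative["snp_id"] if recurrence[s] / n_perm < rate_max]
    else:
        retained = putative["snp_id"].tolist()
    genes: list[str] = []
    if sites is not None and models is not None and retained:
        genes = genes_overlapping(sites[sites["snp_id"].isin(retained)], models)
    return retained, genes


def scan_outliers(
    ds: SnpDataset,
    comparison: ComparisonSpec,
    q: float = 0.01,
    n_perm: int = 100,
    rate_max: float = 0.01,
    seed: int | None = None,
    pool: str = "union",
    models: GeneModelSet | None = None,
) -> OutlierReport:
    """Full scan for one comparison: F_ST -> top-q -> permutation filter."""
    idx_a = ds.sample_indices(comparison.group_a)
    idx_b = ds.sample_indices(comparison.group_b)
    res = weir_cockerham_fst(ds.dosage, idx_a, idx_b)
    fst = pd.concat([ds.sites[["snp_id"]].reset_index(drop=True), res], axis=1)
    putative = top_quantile_outliers(fst, q)
    if n_perm > 0:
        recurrence = permutation_null(ds, comparison, putative["snp_id"], q, n_perm,
                                      seed=seed, pool=pool)
    else:
        recurrence = {s: 0 for s in putative["snp_id"]}
    retained, genes = retain_by_recurrence(putative, recurrence, n_perm, rate_max,
                                           sites=ds.sites, models=models)
    return OutlierReport(
        comparison=comparison.name, q=q, n_perm=n_perm, putative=putative,
        recurrence=recurrence, retained_ids=retained, gene_ids=genes,
    )


def intersect_comparisons(
    report_1: OutlierReport, report_2: OutlierReport,
    sites: pd.DataFrame | None = None, models: GeneModelSet | None = None,
) -> tuple[list[str], list[str]]:
    """Overlap of two retained outlier sets; gene overlap recomputed on it."""
    overlap = sorted(set(report_1.retained_ids) & set(report_2.retained_ids))
    genes: list[str] = []
    if sites is not None and models is not None and overlap:
        genes = genes_overlapping(sites[sites["snp_id"].isin(overlap)], models)
    return overlap, genes
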