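"""Four-step SNP quality filter for multi-sample VCF data.

The pipeline order is fixed: (1) keep biallelic SNPs at least ``window_bp``
from any indel, (2) site-level hard filters on the GATK annotations, (3)
mask low-confidence genotypes and drop SNPs with too much missingness,
(4) drop low minor-allele-frequency SNPs.  Each removed SNP is attributed
to exactly the first step that rejects it, so report counts are conserved.

Thresholds default to: indel window 5 bp; MQ < 40, QD < 2, FS > 30,
SOR > 4, MQRankSum < -12.5, ReadPosRankSum < -8 (any violating annotation
removes the site, absent annotations pass); genotypes with GQ < 20 or
DP < 10 masked; missing rate strictly > 20% removes; MAF strictly < 5%
removes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import SnpDataset

log = logging.getLogger(__name__)

HARD_FILTER_RULES: dict[str, tuple[str, float]] = {
    # annotation -> (failing direction, threshold); "lt": fail if value < thr
    "MQ": ("lt", 40.0),
    "QD": ("lt", 2.0),
    "FS": ("gt", 30.0),
    "SOR": ("gt", 4.0),
    "MQRankSum": ("lt", -12.5),
    "ReadPosRankSum": ("lt", -8.0),
}


@dataclass
class FilterParams:
    indel_window: int = 5
    gq_min: int = 20
    dp_min: int = 10
    max_missing: float = 0.20
    maf_min: float = 0.05
    mask_rule: str = "or"  # "or": GQ or DP failure masks; "and": both must fail


@dataclass
class FilterReport:
    n_input: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    removed_ids: dict[str, list[str]] = field(default_factory=dict)
    n_genotypes_masked: int = 0
    n_retained: int = 0

    def record(self, step: str, ids: list[str]) -> None:
        self.removed[step] = self.removed.get(step, 0) + len(ids)
        self.removed_ids.setdefault(step, []).extend(ids)

    def as_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)]
        rows += [(f"removed_{k}", v) for k, v in self.removed.items()]
        rows += [("genotypes_masked", self.n_genotypes_masked),
                 ("retained", self.n_retained)]
        return pd.DataFrame(rows, columns=["step", "count"])

    def check_conserved(self) -> bool:
        return self.n_input == self.n_retained + sum(self.removed.values())


def _ensure_sorted(ds: SnpDataset) -> SnpDataset:
    key = list(zip(ds.sites["scaffold"], ds.sites["pos"]))
    if all(a <= b for a, b in zip(key, key[1:])):
        return ds
    log.warning("input sites unsorted; sorting by (scaffold, pos)")
    order = np.lexsort((ds.sites["pos"].to_numpy(), ds.sites["scaffold"].to_numpy()))
    return ds.take_sites(order)


def indel_distance(snp_pos: int, indel_pos: int, indel_ref: str) -> int:
    """Distance in bp from a SNP to the nearest base of an indel's REF span.

    Both positions are 1-based; the affected span covers the REF allele's
    bases ``[indel_pos, indel_pos + len(ref) - 1]``.  Distance 0 means the
    SNP lies inside the span.
    """
    span_start, span_end = indel_pos, indel_pos + len(indel_ref) - 1
    return max(span_start - snp_pos, snp_pos - span_end, 0)


def filter_biallelic_near_indel(
    ds: SnpDataset, indels: pd.DataFrame, window_bp: int = 5,
    report: FilterReport | None = None,
) -> SnpDataset:
    """Keep biallelic SNPs at least ``window_bp`` from every indel span."""
    ds = _ensure_sorted(ds)
    sites = ds.sites
    bad = set(sites.index[~sites["is_biallelic_snp"].astype(bool)])
    for _, ind in indels.iterrows():
        ref = str(ind["ref"])
        alt = str(ind["alt"])
        if not (set(ref) | set(alt.replace(",", ""))) <= set("ACGTacgt"):
            raise ValueError(f"malformed alleles in indel record {ind['snp_id']!r}: {ref}>{alt}")
        sel = sites.index[
            (sites["scaffold"] == ind["scaffold"])
            & (sites["pos"] >= int(ind["pos"]) - (window_bp - 1))
            & (sites["pos"] <= int(ind["pos"]) + len(ref) - 1 + (window_bp - 1))
        ]
        bad.update(sel)
    keep = np.ones(len(sites), bool)
    keep[sorted(bad)] = False
    if report is not None:
        report.record("near_indel", sites.loc[sorted(bad), "snp_id"].tolist())
    return ds.take_sites(keep)


def apply_site_hard_filters(ds: SnpDataset, report: FilterReport | None = None) -> SnpDataset:
    """Remove sites where any *present* annotation violates its threshold."""
    sites = ds.sites
    fail = np.zeros(len(sites), bool)
    for fld, (direction, thr) in HARD_FILTER_RULES.items():
        if fld not in sites.columns:
            continue
        vals = pd.to_numeric(sites[fld], errors="raise").to_numpy(float)
        with np.errstate(invalid="ignore"):
            this = (vals < thr) if direction == "lt" else (vals > thr)
        this &= ~np.isnan(vals)  # absent annotations never trigger removal
        fail |= this
    if report is not None:
        report.record("hard_filter", sites.loc[fail, "snp_id"].tolist())
    return ds.take_sites(~fail)


def mask_genotypes_and_filter_missing(
    ds: SnpDataset, gq_min: int = 20, dp_min: int = 10, max_missing: float = 0.20,
    mask_rule: str = "or", report: FilterReport | None = None,
) -> SnpDataset:
    """Mask low-confidence genotypes, then drop sites too full of holes.

    A called genotype is set missing when GQ < ``gq_min`` or DP < ``dp_min``
    (rule ``"or"``; ``"and"`` requires both).  A site is removed when its
    missing fraction is strictly greater than ``max_missing``.
    """
    if not (0 <= max_missing <= 1):
        raise ValueError("max_missing must be in [0, 1]")
    if ds.gq is None or ds.dp is None:
        raise ValueError("dataset lacks GQ/DP arrays required for masking")
    out = ds.copy()
    called = out.dosage >= 0
    low_gq = out.gq < gq_min
    low_dp = out.dp < dp_min
    low = (low_gq | low_dp) if mask_rule == "or" else (low_gq & low_dp)
    to_mask = called & low
    out.dosage[to_mask] = -1
    n_masked = int(to_mask.sum())
    miss_frac = (out.dosage == -1).mean(axis=1)
    keep = miss_frac <= max_missing
    if report is not None:
        report.n_genotypes_masked += n_masked
        report.record("missing_rate", out.sites.loc[~keep, "snp_id"].tolist())
    return out.take_sites(keep)


def minor_allele_frequency(dosage: np.ndarray) -> np.ndarray:
    """Per-site MAF over non-missing alleles; NaN when everything is missing."""
    called = dosage >= 0
    n_alleles = 2 * called.sum(axis=1)
    alt = np.where(called, dosage, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return np.minimum(p, 1 - p)


def filter_maf(ds: SnpDataset, maf_min: float = 0.05,
               report: FilterReport | None = None) -> SnpDataset:
    """Remove sites with minor allele frequency strictly below ``maf_min``."""
    maf = minor_allele_frequency(ds.dosage)
    all_missing = np.isnan(maf)
    if all_missing.any():
        log.warning("%d site(s) with all genotypes missing removed at MAF step "
                    "(missing-rate semantics)", int(all_missing.sum()))
    with np.errstate(invalid="ignore"):
        fail = (maf < maf_min) | all_missing
    if report is not None:
        report.record("maf", ds.sites.loc[fail, "snp_id"].tolist())
    return ds.take_sites(~fail)


def run_filter_pipeline(
    ds: SnpDataset, indels: pd.DataFrame, params: FilterParams | None = None
) -> tuple[SnpDataset, FilterReport]:
    """Run all four steps in order and return the surviving dataset + report."""
    params = params or FilterParams()
    report = FilterReport(n_input=ds.n_sites)
    ds = filter_biallelic_near_indel(ds, indels, params.indel_window, report)
    ds = apply_site_hard_filters(ds, report)
    ds = mask_genotypes_and_filter_missing(
        ds, params.gq_min, params.dp_min, params.max_missing, params.mask_rule, report
    )
    ds = filter_maf(ds, params.maf_min, report)
    report.n_retained = ds.n_sites
    for step in ("near_indel", "hard_filter", "missing_rate", "maf"):
        report.removed.setdefault(step, 0)
        report.removed_ids.setdefault(step, [])
        log.info("filter step %-12s removed %d", step, report.removed[step])
    return ds, report
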