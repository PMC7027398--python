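"""End-to-end orchestration: simulate/load -> filter -> annotate -> stats ->
outlier scan -> enrichment, with a manifest and summary report per run.

All stage thresholds default to the study's printed values: 5 bp indel
window, GQ 20 / DP 10, 20% missing, 5% MAF, top 1% F_ST, 100 permutations,
recurrence rate 0.01, BH q 0.05, 5 kb thinning.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import mannwhitneyu

from . import io as gsio
from .effects import classify_variants, summarize_annotation
from .enrich import enrichment_permutation, hypergeometric_enrichment
from .filters import FilterParams, run_filter_pipeline
from .outliers import OutlierReport, intersect_comparisons, scan_outliers
from .popgen import gene_diversity_table, ld_thin, pca
from .simulate import SimConfig, default_comparisons, simulate

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (simulation-driven or file-driven)."""

    sim: SimConfig | None = None
    inputs: dict[str, str] | None = None  # vcf, gff3, fasta, popmap, terms
    filter_params: FilterParams = field(default_factory=FilterParams)
    q: float = 0.01
    n_perm: int = 100
    rate_max: float = 0.01
    pool: str = "union"
    alpha: float = 0.05
    thin_window: int = 5000
    phase: str = "alt_first"
    seed: int = 0

    def validate(self) -> None:
        if (self.sim is None) == (self.inputs is None):
            raise ValueError("provide exactly one of sim config or input paths")
        if not (0 < self.q < 0.5) or self.n_perm < 0 or not (0 < self.rate_max <= 1):
            raise ValueError("outlier thresholds out of range")
        if not (0 < self.alpha < 1) or self.thin_window <= 0:
            raise ValueError("alpha/thin_window out of range")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in raw.get("sim", {}).items()}) if "sim" in raw else None
        return cls(
            sim=sim,
            inputs=raw.get("inputs"),
            filter_params=FilterParams(**raw.get("filter", {})),
            **{k: raw[k] for k in ("q", "n_perm", "rate_max", "pool", "alpha",
                                   "thin_window", "phase", "seed") if k in raw},
        )

    def digest(self) -> str:
        payload = {
            "sim": None if self.sim is None else dataclasses.asdict(self.sim),
            "inputs": self.inputs,
            "filter": dataclasses.asdict(self.filter_params),
            "q": self.q, "n_perm": self.n_perm, "rate_max": self.rate_max,
            "pool": self.pool, "alpha": self.alpha, "thin_window": self.thin_window,
            "phase": self.phase, "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True, default=list).encode()
        return hashlib.sha256(blob).hexdigest()


def compare_diversity(gene_stats: pd.DataFrame, outlier_genes) -> tuple[pd.DataFrame, dict]:
    """Mean π/dN/dS/dN-dS summaries for whole genome vs outlier genes, with
    two-sided Wilcoxon rank-sum p values for π and dN/dS.

    The exact null distribution is used when both strata have <= 25 genes,
    the continuity-corrected normal approximation otherwise.
    """
    outlier_genes = set(outlier_genes)
    is_out = gene_stats["gene_id"].isin(outlier_genes)
    strata = {"whole_genome": gene_stats, "outlier": gene_stats[is_out]}
    rows = []
    for name, sub in strata.items():
        rows.append((
            name, len(sub),
            *(float(np.nanmean(sub[c])) if len(sub) and sub[c].notna().any() else float("nan")
              for c in ("pi", "dn", "ds", "dnds")),
        ))
    summary = pd.DataFrame(rows, columns=["stratum", "n_genes", "pi", "dn", "ds", "dnds"])
    pvals = {}
    rest = gene_stats[~is_out]
    for col in ("pi", "dnds"):
        x = gene_stats.loc[is_out, col].dropna().to_numpy()
        y = rest[col].dropna().to_numpy()
        if len(x) >= 2 and len(y) >= 2:
            method = "exact" if max(len(x), len(y)) <= 25 else "asymptotic"
            pvals[col] = float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
        else:
            pvals[col] = float("nan")
    return summary, pvals


def _load_inputs(paths: dict[str, str]):
    ds, indels = gsio.read_vcf(paths["vcf"])
    models = gsio.read_gff3(paths["gff3"])
    genome = gsio.read_fasta(paths["fasta"])
    popmap = gsio.read_population_map(paths["popmap"])
    terms = gsio.read_term_map(paths["terms"]) if "terms" in paths else None
    return ds, indels, models, genome, popmap, terms


def run_pipeline(config: RunConfig, outdir: str | os.PathLike) -> dict:
    """Run every stage; writes TSV outputs + manifest and returns a summary."""
    config.validate()
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    t0 = time.time()
    stage_counts: dict[str, int] = {}

    # --- stage: data
    if config.sim is not None:
        sim = simulate(config.sim)
        sim.write(os.path.join(outdir, "sim"))
        ds, indels, models, genome = sim.dataset, sim.indels, sim.models, sim.genome
        popmap, terms = sim.popmap, sim.term_map
        truth = sim.truth
    else:
        ds, indels, models, genome, popmap, terms = _load_inputs(config.inputs)
        truth = None
    stage_counts["input_snps"] = ds.n_sites
    stage_counts["individuals"] = ds.n_samples

    # --- stage: filter
    ds_f, report = run_filter_pipeline(ds, indels, config.filter_params)
    if not report.check_conserved():
        raise RuntimeError("filter stage lost accounting of removed SNPs")
    report.n_retained = ds_f.n_sites
    report.as_frame().to_csv(os.path.join(outdir, "filter_report.tsv"), sep="\t", index=False)
    stage_counts["filtered_snps"] = ds_f.n_sites

    # --- stage: annotation
    annotated = classify_variants(ds_f.sites, models, genome)
    annotated.to_csv(os.path.join(outdir, "annotated_snps.tsv"), sep="\t", index=False)
    ann_summary = summarize_annotation(annotated["effect"])
    ann_summary.to_csv(os.path.join(outdir, "annotation_summary.tsv"), sep="\t", index=False)

    # --- stage: structure (thinning + PCA)
    keep = ld_thin(ds_f.sites, config.thin_window)
    stage_counts["thinned_snps"] = int(keep.sum())
    ds_f.sites.loc[keep, ["snp_id", "scaffold", "pos"]].to_csv(
        os.path.join(outdir, "thinned_snps.tsv"), sep="\t", index=False)
    scores, varfrac = pca(ds_f.dosage)
    pd.DataFrame({
        "individual": ds_f.samples,
        "PC1": scores[:, 0], "PC2": scores[:, 1],
    }).to_csv(os.path.join(outdir, "pca.tsv"), sep="\t", index=False)

    # --- stage: outlier scans
    comparisons = default_comparisons(popmap)
    reports: list[OutlierReport] = []
    seed_stream = np.random.SeedSequence(config.seed).spawn(len(comparisons) + 1)
    for comp, ss in zip(comparisons, seed_stream):
        rep = scan_outliers(
            ds_f, comp, q=config.q, n_perm=config.n_perm, rate_max=config.rate_max,
            seed=int(ss.generate_state(1)[0] % (2**31)), pool=config.pool, models=models,
        )
        reports.append(rep)
        out = rep.putative.copy()
        out["recurrence"] = [rep.recurrence[s] for s in out["snp_id"]]
        out["retained"] = out["snp_id"].isin(rep.retained_ids)
        out.to_csv(os.path.join(outdir, f"outliers_{comp.name}.tsv"), sep="\t", index=False)
        eff = annotated[annotated["snp_id"].isin(rep.retained_ids)]["effect"]
        summarize_annotation(eff).to_csv(
            os.path.join(outdir, f"outlier_annotation_{comp.name}.tsv"), sep="\t", index=False)
    overlap_snps, overlap_genes = intersect_comparisons(
        reports[0], reports[1], sites=ds_f.sites, models=models)

    # --- stage: diversity (survivor group)
    survivors = popmap.loc[popmap["site"] == "LZ", "individual"].tolist()
    gene_stats = gene_diversity_table(ds_f, models, genome, survivors, phase=config.phase)
    gene_stats.to_csv(os.path.join(outdir, "gene_diversity.tsv"), sep="\t", index=False)
    div_summary, div_pvals = compare_diversity(gene_stats, reports[0].gene_ids)
    div_summary.to_csv(os.path.join(outdir, "diversity_summary.tsv"), sep="\t", index=False)

    # --- stage: enrichment
    enrichment = None
    enrich_recurrence: dict[str, int] = {}
    if terms is not None:
        background = sorted(set(annotated.loc[annotated["gene_id"].notna(), "gene_id"]))
        outlier_genes = [g for g in reports[0].gene_ids if g in set(background)]
        if outlier_genes:
            enrichment = hypergeometric_enrichment(outlier_genes, terms, background,
                                                   alpha=config.alpha)
            enrichment.to_csv(os.path.join(outdir, "enrichment.tsv"), sep="\t", index=False)
            sig = enrichment.loc[enrichment["significant"], "term_id"].tolist()
            enrich_seed = int(seed_stream[-1].generate_state(1)[0] % (2**31))
            enrich_recurrence = enrichment_permutation(
                terms, background, len(outlier_genes), sig,
                n_perm=config.n_perm, seed=enrich_seed, alpha=config.alpha)

    def _finite(x):
        return float(x) if x is not None and np.isfinite(x) else None

    summary = {
        "counts": stage_counts,
        "filter": {k: int(v) for k, v in report.removed.items()},
        "pca_varfrac": [float(v) for v in varfrac[:2]],
        "outliers": {
            rep.comparison: {
                "putative": len(rep.putative), "retained": len(rep.retained_ids),
                "genes": len(rep.gene_ids),
            } for rep in reports
        },
        "overlap": {"snps": len(overlap_snps), "genes": len(overlap_genes)},
        "diversity_p": {k: _finite(v) for k, v in div_pvals.items()},
        "diversity_means": {
            k: {c: _finite(v) for c, v in row.items()}
            for k, row in div_summary.set_index("stratum")[["pi", "dnds"]]
            .to_dict("index").items()
        },
        "enrichment_significant": [] if enrichment is None
        else enrichment.loc[enrichment["significant"], "term_id"].tolist(),
        "enrichment_recurrence": enrich_recurrence,
    }
    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "stage_counts": stage_counts,
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    result = dict(summary)
    result["_objects"] = {
        "dataset": ds_f, "annotated": annotated, "reports": reports,
        "gene_stats": gene_stats, "models": models, "truth": truth,
        "overlap_snps": overlap_snps, "overlap_genes": overlap_genes,
        "enrichment": enrichment,
    }
    return result
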