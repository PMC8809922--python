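"""End-to-end orchestration of the integration pipeline.

Stages: SNP-probe filtering -> differential methylation -> window/chromosome
landscape -> differential expression -> DMP/DEG intersection -> cis eQTM
regression with latent-factor correction -> variance decomposition summary.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .config import PipelineConfig
from .eqtm import CisEqtmAnalysis, find_cis_pairs
from .expression import intersect_dmp_deg, test_deg
from .io import (
    FeatureMatrix,
    ProbeAnnotation,
    SampleInfo,
    write_bed,
    write_table,
)
from .methylation import (
    chromosome_table,
    filter_probes,
    region_distribution,
    test_dmp,
    top_k_sites,
    window_summary,
)


@dataclass
class PipelineResult:
    """All stage outputs of one pipeline run."""

    dmps: pd.DataFrame
    windows: pd.DataFrame
    chrom_table: pd.DataFrame
    region_dist: dict[str, float]
    top_sites: list[str]
    degs: pd.DataFrame
    dmp_deg_overlap: pd.DataFrame
    cis_pairs: pd.DataFrame
    eqtm_fits: pd.DataFrame
    variance: pd.DataFrame
    eqtm_summary: dict
    cohort_variance: dict
    counts: dict = field(default_factory=dict)


def run_pipeline(
    m: FeatureMatrix,
    expr: FeatureMatrix,
    annotation: Sequence[ProbeAnnotation],
    samples: Sequence[SampleInfo],
    gene_tss: Mapping[str, tuple[str, int]],
    chrom_lengths_mb: Mapping[str, float],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every stage on gene-level expression and probe-level M-values."""
    cfg = config or PipelineConfig()
    kept = filter_probes(annotation)
    kept &= set(m.feature_ids)
    dmps = test_dmp(
        m, samples, kept,
        fdr_threshold=cfg.fdr_threshold,
        delta_m_threshold=cfg.delta_m_threshold,
        equal_var=cfg.equal_var,
    )
    windows = window_summary(
        dmps, annotation, chrom_lengths_mb,
        window_size=cfg.window_size_bp, domain_ratio=cfg.domain_ratio,
    )
    chrom_tab = chromosome_table(dmps, annotation, chrom_lengths_mb)
    region = region_distribution(dmps, annotation)
    top = top_k_sites(dmps, k=500)

    degs = test_deg(
        expr, samples,
        p_threshold=cfg.deg_p_threshold,
        strong_lfc=cfg.strong_lfc,
        weak_lfc=cfg.weak_lfc,
        equal_var=cfg.equal_var,
        use_fdr=cfg.deg_use_fdr,
    )
    overlap = intersect_dmp_deg(dmps, annotation, degs, tier=cfg.deg_tier)

    pairs = find_cis_pairs(
        dmps, annotation, gene_tss,
        window_bp=cfg.cis_window_bp, hypo_only=cfg.hypo_only,
    )
    eqtm = CisEqtmAnalysis(n_factors=cfg.n_factors, alpha=cfg.eqtm_alpha)
    eqtm.fit(m, expr, pairs, samples)

    n_called = int((dmps["call"] != "not_significant").sum())
    counts = {
        "n_probes_tested": int(len(dmps)),
        "n_dmp": n_called,
        "n_hypo": int((dmps["call"] == "hypo").sum()),
        "n_hyper": int((dmps["call"] == "hyper").sum()),
        "n_genes_tested": int(len(degs)),
        "n_deg_strong": int((degs["tier"] == "strong").sum()),
        "n_deg_weak_or_strong": int(degs["tier"].isin(["strong", "weak"]).sum()),
        "n_overlap_genes": int(len(overlap)),
        "n_cis_pairs": int(len(pairs)),
    }
    return PipelineResult(
        dmps=dmps,
        windows=windows,
        chrom_table=chrom_tab,
        region_dist=region,
        top_sites=top,
        degs=degs,
        dmp_deg_overlap=overlap,
        cis_pairs=pairs,
        eqtm_fits=eqtm.fits_,
        variance=eqtm.decomposition_,
        eqtm_summary=eqtm.summary_,
        cohort_variance=eqtm.cohort_variance_,
        counts=counts,
    )


def write_results(result: PipelineResult, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(result.dmps, out / "dmp_results.tsv")
    write_table(result.windows, out / "windows.tsv")
    write_bed(result.windows, out / "windows.bed", name_col="domain_call")
    write_table(result.chrom_table, out / "chromosome_table.tsv")
    write_table(
        pd.DataFrame(
            [result.region_dist] if result.region_dist else [],
            columns=["promoter_region", "other"],
        ),
        out / "region_distribution.tsv",
    )
    (out / "top_sites.txt").write_text("\n".join(result.top_sites) + "\n")
    write_table(result.degs, out / "deg_results.tsv")
    write_table(result.dmp_deg_overlap, out / "dmp_deg_overlap.tsv")
    write_table(result.cis_pairs, out / "cis_pairs.tsv")
    write_table(result.eqtm_fits, out / "eqtm_fits.tsv")
    write_table(result.variance, out / "variance_decomposition.tsv")
    summary = {
        **result.counts,
        **{f"eqtm_{k}": v for k, v in result.eqtm_summary.items()},
        **{f"variance_{k}": v for k, v in result.cohort_variance.items()},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))


def read_gene_tss(path: str | Path) -> dict[str, tuple[str, int]]:
    """Read gene TSS TSV (gene, chrom, tss; 1-based) to a 0-based map."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    required = {"gene", "chrom", "tss"}
    if not required <= set(frame.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    out = {}
    for row in frame.itertuples(index=False):
        tss = int(row.tss)
        if tss < 1:
            raise ValueError(f"{path}: TSS must be >= 1 (1-based), got {tss}")
        out[str(row.gene)] = (str(row.chrom), tss - 1)
    return out


def write_gene_tss(gene_tss: Mapping[str, tuple[str, int]], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "gene": list(gene_tss),
            "chrom": [c for c, _ in gene_tss.values()],
            "tss": [p + 1 for _, p in gene_tss.values()],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_chrom_lengths(path: str | Path) -> dict[str, float]:
    """Read a chromosome-length TSV (chrom, length_mb)."""
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not {"chrom", "length_mb"} <= set(frame.columns):
        raise ValueError(f"{path}: expected columns chrom, length_mb")
    return {str(r.chrom): float(r.length_mb) for r in frame.itertuples(index=False)}
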