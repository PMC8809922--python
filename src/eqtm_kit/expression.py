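"""Probe-to-gene aggregation, differential expression, and the DMP/DEG overlap.

Genes are tested on log2 expression with a two-group t-test and tiered by
raw p and fold change: strong = p < 0.05 and |log2FC| > 2, weak = p < 0.05
and |log2FC| > 1 (both strict). No multiplicity correction is applied by
default; BH is available by switch.
"""
from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import (
    FeatureMatrix,
    ProbeAnnotation,
    SampleInfo,
    split_groups,
)
from .methylation import bh_adjust

logger = logging.getLogger(__name__)

DEG_COLUMNS = [
    "gene", "mean_case", "mean_control", "log2_fc", "t_stat", "p_value", "tier",
]


def aggregate_probes_to_genes(
    expr: FeatureMatrix,
    probe_gene_map: Mapping[str, str | Sequence[str]],
) -> FeatureMatrix:
    """Collapse expression probes to genes by unweighted per-sample mean.

    Probes without a gene mapping are dropped (and counted); a probe mapped
    to several genes contributes to each of them.
    """
    if expr.value_kind != "log2_expression":
        raise ValueError("matrix value_kind must be 'log2_expression'")
    if not probe_gene_map:
        raise ValueError("probe -> gene mapping is empty")
    gene_rows: dict[str, list[int]] = {}
    n_unmapped = 0
    n_multi = 0
    for i, pid in enumerate(expr.feature_ids):
        genes = probe_gene_map.get(pid)
        if genes is None:
            n_unmapped += 1
            continue
        if isinstance(genes, str):
            genes = [genes]
        if len(genes) > 1:
            n_multi += 1
        for g in genes:
            gene_rows.setdefault(g, []).append(i)
    if n_unmapped:
        logger.info("%d probe(s) without gene mapping dropped", n_unmapped)
    if n_multi:
        logger.info("%d probe(s) mapped to multiple genes (counted in each)", n_multi)
    if not gene_rows:
        raise ValueError("no probe mapped to any gene")
    genes = sorted(gene_rows)
    values = np.vstack([expr.values[gene_rows[g]].mean(axis=0) for g in genes])
    return FeatureMatrix(genes, list(expr.sample_ids), values, "log2_expression")


class DifferentialExpression(BaseEstimator):
    """Per-gene case/control differential testing on log2 expression.

    Parameters
    ----------
    p_threshold : float
        Raw-p cutoff (default 0.05); applied to BH-adjusted p instead when
        `use_fdr` is True.
    strong_lfc, weak_lfc : float
        Strict |log2FC| cutoffs for the two significance tiers (2 and 1).
    equal_var : bool
        False (default) = Welch's t-test.

    Attributes
    ----------
    results_ : pandas.DataFrame
        gene, group means, log2_fc, t_stat, p_value (plus fdr when
        `use_fdr`), tier in {strong, weak, not_significant}.
    """

    def __init__(
        self,
        p_threshold: float = 0.05,
        strong_lfc: float = 2.0,
        weak_lfc: float = 1.0,
        equal_var: bool = False,
        use_fdr: bool = False,
    ):
        self.p_threshold = p_threshold
        self.strong_lfc = strong_lfc
        self.weak_lfc = weak_lfc
        self.equal_var = equal_var
        self.use_fdr = use_fdr

    def fit(
        self, gene_expr: FeatureMatrix, samples: Sequence[SampleInfo]
    ) -> "DifferentialExpression":
        if gene_expr.value_kind != "log2_expression":
            raise ValueError("matrix value_kind must be 'log2_expression'")
        case, ctrl = split_groups(gene_expr, samples)
        if case.shape[1] < 2 or ctrl.shape[1] < 2:
            raise ValueError("each group needs at least 2 samples")
        mean_case = case.mean(axis=1)
        mean_ctrl = ctrl.mean(axis=1)
        lfc = mean_case - mean_ctrl
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=self.equal_var)
        degenerate = ~np.isfinite(t_stat)
        if degenerate.any():
            t_stat = np.where(degenerate, 0.0, t_stat)
            p = np.where(degenerate, 1.0, p)
        frame = pd.DataFrame(
            {
                "gene": gene_expr.feature_ids,
                "mean_case": mean_case,
                "mean_control": mean_ctrl,
                "log2_fc": lfc,
                "t_stat": t_stat,
                "p_value": p,
            }
        )
        p_for_tier = p
        if self.use_fdr:
            frame["fdr"] = bh_adjust(p)
            p_for_tier = frame["fdr"].to_numpy()
        tier = np.full(len(lfc), "not_significant", dtype=object)
        sig = p_for_tier < self.p_threshold
        tier[sig & (np.abs(lfc) > self.weak_lfc)] = "weak"
        tier[sig & (np.abs(lfc) > self.strong_lfc)] = "strong"
        frame["tier"] = tier
        self.results_ = frame
        return self


def test_deg(
    gene_expr: FeatureMatrix,
    samples: Sequence[SampleInfo],
    p_threshold: float = 0.05,
    strong_lfc: float = 2.0,
    weak_lfc: float = 1.0,
    equal_var: bool = False,
    use_fdr: bool = False,
) -> pd.DataFrame:
    """Functional wrapper over :class:`DifferentialExpression`."""
    est = DifferentialExpression(p_threshold, strong_lfc, weak_lfc, equal_var, use_fdr)
    return est.fit(gene_expr, samples).results_


test_deg.__test__ = False  # not a test despite the name


def intersect_dmp_deg(
    dmps: pd.DataFrame,
    annotation: Sequence[ProbeAnnotation],
    degs: pd.DataFrame,
    tier: str = "strong",
) -> pd.DataFrame:
    """Differentially expressed genes carrying at least one significant DMP.

    `tier` = "strong" keeps only strong DEGs; "weak" keeps both tiers
    (strong genes also satisfy the weak criterion). Each returned gene
    lists its supporting probes and the sign pattern of (delta_m, log2_fc).
    """
    if tier not in ("strong", "weak"):
        raise ValueError("tier must be 'strong' or 'weak'")
    tiers = {"strong"} if tier == "strong" else {"strong", "weak"}
    called = dmps[dmps["call"] != "not_significant"]
    gene_of = {a.probe_id: a.gene for a in annotation if a.gene is not None}
    probes_by_gene: dict[str, list[str]] = {}
    for _, row in called.iterrows():
        g = gene_of.get(row["probe_id"])
        if g is not None:
            probes_by_gene.setdefault(g, []).append(row["probe_id"])
    delta = dict(zip(dmps["probe_id"], dmps["delta_m"]))
    rows = []
    for _, row in degs[degs["tier"].isin(tiers)].iterrows():
        g = row["gene"]
        support = probes_by_gene.get(g)
        if not support:
            continue
        signs = ";".join(
            f"{'-' if delta[p] < 0 else '+'}/{'-' if row['log2_fc'] < 0 else '+'}"
            for p in support
        )
        rows.append(
            {
                "gene": g,
                "log2_fc": row["log2_fc"],
                "tier": row["tier"],
                "n_support_probes": len(support),
                "support_probes": ";".join(support),
                "sign_pattern": signs,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "log2_fc", "tier", "n_support_probes",
            "support_probes", "sign_pattern",
        ],
    )
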