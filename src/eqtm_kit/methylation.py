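"""Differential methylation on M-values and the genomic methylation landscape.

Per-probe two-group testing (Welch by default) with a single
Benjamini-Hochberg pass, hypo/hyper calling at FDR < 0.05 and |dM| > 0.3,
10 Mb window domain calling under the strict 1.5 count-ratio rule, and the
per-chromosome density table with its density -> count reconstruction.
"""
from __future__ import annotations

import logging
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import (
    FeatureMatrix,
    ProbeAnnotation,
    PROMOTER_REGION_CLASSES,
    SampleInfo,
    annotation_to_frame,
    split_groups,
)

logger = logging.getLogger(__name__)

DMP_COLUMNS = [
    "probe_id", "mean_case", "mean_control", "delta_m",
    "t_stat", "p_value", "fdr", "call",
]

#: sentinel used wherever a ratio has a zero denominator
UNDEFINED = float("nan")


def compute_m_value(
    meth_intensity: float, unmeth_intensity: float, offset: float = 0.0
) -> float:
    """M-value: log2 of methylated over unmethylated signal intensity.

    A small positive `offset` stabilises probes with near-zero signal in
    either channel (common array practice); the default is 0.
    """
    meth = np.asarray(meth_intensity, dtype=float)
    unmeth = np.asarray(unmeth_intensity, dtype=float)
    if offset < 0:
        raise ValueError("offset must be non-negative")
    if np.any(meth < 0) or np.any(unmeth < 0):
        raise ValueError("intensities must be non-negative")
    num = meth + offset
    den = unmeth + offset
    if np.any(num == 0) and np.any(den == 0) and np.any((num == 0) & (den == 0)):
        raise ValueError("both intensities zero with zero offset")
    if np.any(den == 0) or np.any(num == 0):
        raise ValueError("zero intensity with zero offset; use a positive offset")
    out = np.log2(num / den)
    return float(out) if out.ndim == 0 else out


def filter_probes(annotation: Sequence[ProbeAnnotation]) -> set[str]:
    """Drop probes overlapping a SNP; everything else (sex chromosomes
    included) stays in the analysis."""
    if not annotation:
        raise ValueError("annotation is empty")
    kept = {a.probe_id for a in annotation if not a.snp_overlap}
    logger.info(
        "probe filter: kept %d, excluded %d SNP-overlapping",
        len(kept), len(annotation) - len(kept),
    )
    return kept


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class DifferentialMethylation(BaseEstimator):
    """Per-probe case/control differential testing on M-values.

    Parameters
    ----------
    fdr_threshold : float
        BH-adjusted p cutoff for a significant call (default 0.05).
    delta_m_threshold : float
        Minimum |mean case - mean control| in M-value units, applied as a
        strict inequality (default 0.3).
    equal_var : bool
        False (default) uses Welch's unequal-variance t-test; True uses the
        pooled-variance Student t-test.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per tested probe: probe_id, group means, delta_m, t_stat,
        p_value, fdr and the call in {hypo, hyper, not_significant}.
    n_tested_ : int
    """

    def __init__(
        self,
        fdr_threshold: float = 0.05,
        delta_m_threshold: float = 0.3,
        equal_var: bool = False,
    ):
        self.fdr_threshold = fdr_threshold
        self.delta_m_threshold = delta_m_threshold
        self.equal_var = equal_var

    def fit(
        self,
        m: FeatureMatrix,
        samples: Sequence[SampleInfo],
        kept: Iterable[str] | None = None,
    ) -> "DifferentialMethylation":
        if m.value_kind != "m_value":
            raise ValueError("matrix value_kind must be 'm_value'")
        if kept is not None:
            kept = set(kept)
            unknown = kept - set(m.feature_ids)
            if unknown:
                raise ValueError(
                    f"kept probes absent from matrix: {sorted(unknown)[:5]}"
                )
            m = m.subset_features(kept)
        case, ctrl = split_groups(m, samples)
        if case.shape[1] < 2 or ctrl.shape[1] < 2:
            raise ValueError("each group needs at least 2 samples")

        mean_case = case.mean(axis=1)
        mean_ctrl = ctrl.mean(axis=1)
        delta = mean_case - mean_ctrl
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat, p = stats.ttest_ind(
                case, ctrl, axis=1, equal_var=self.equal_var
            )
        # probes constant within both groups: no evidence either way
        degenerate = ~np.isfinite(t_stat)
        if degenerate.any():
            logger.info("%d constant probe(s): p recorded as 1", int(degenerate.sum()))
            t_stat = np.where(degenerate, 0.0, t_stat)
            p = np.where(degenerate, 1.0, p)
        fdr = bh_adjust(p)
        call = np.full(len(delta), "not_significant", dtype=object)
        sig = fdr < self.fdr_threshold
        call[sig & (delta < -self.delta_m_threshold)] = "hypo"
        call[sig & (delta > self.delta_m_threshold)] = "hyper"
        self.results_ = pd.DataFrame(
            {
                "probe_id": m.feature_ids,
                "mean_case": mean_case,
                "mean_control": mean_ctrl,
                "delta_m": delta,
                "t_stat": t_stat,
                "p_value": p,
                "fdr": fdr,
                "call": call,
            }
        )
        self.n_tested_ = len(m.feature_ids)
        return self


def test_dmp(
    m: FeatureMatrix,
    samples: Sequence[SampleInfo],
    kept: Iterable[str] | None = None,
    fdr_threshold: float = 0.05,
    delta_m_threshold: float = 0.3,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Functional wrapper over :class:`DifferentialMethylation`."""
    est = DifferentialMethylation(fdr_threshold, delta_m_threshold, equal_var)
    return est.fit(m, samples, kept).results_


test_dmp.__test__ = False  # not a test despite the name


def _positions(
    dmps: pd.DataFrame, annotation: Sequence[ProbeAnnotation]
) -> pd.DataFrame:
    ann = annotation_to_frame(annotation)
    called = dmps[dmps["call"] != "not_significant"]
    merged = called.merge(ann, on="probe_id", how="left", validate="1:1")
    if merged["chrom"].isna().any():
        missing = merged.loc[merged["chrom"].isna(), "probe_id"].tolist()
        raise ValueError(f"called probes without annotation: {missing[:5]}")
    return merged


def _domain_call(n_hypo: int, n_hyper: int, ratio: float = 1.5) -> str:
    if n_hypo == 0 and n_hyper == 0:
        return "none"
    if n_hyper == 0:
        return "hypo_domain"
    if n_hypo == 0:
        return "hyper_domain"
    if n_hypo / n_hyper > ratio:
        return "hypo_domain"
    if n_hyper / n_hypo > ratio:
        return "hyper_domain"
    return "none"


def window_summary(
    dmps: pd.DataFrame,
    annotation: Sequence[ProbeAnnotation],
    chrom_lengths_mb: Mapping[str, float],
    window_size: int = 10_000_000,
    domain_ratio: float = 1.5,
) -> pd.DataFrame:
    """Tile each chromosome from 0 in fixed windows and call methylation
    domains from the hypo:hyper count ratio (strictly > `domain_ratio`).

    Windows are 0-based half-open; the terminal window is truncated at the
    chromosome end. Zero-count windows are emitted with domain_call none.
    """
    merged = _positions(dmps, annotation)
    lengths_bp = {c: int(round(l * 1e6)) for c, l in chrom_lengths_mb.items()}
    for _, row in merged.iterrows():
        if row["chrom"] not in lengths_bp:
            raise ValueError(f"no declared length for chromosome {row['chrom']!r}")
        if row["pos"] >= lengths_bp[row["chrom"]]:
            raise ValueError(
                f"probe {row['probe_id']} at {row['chrom']}:{row['pos']} lies "
                f"beyond the declared chromosome length {lengths_bp[row['chrom']]}"
            )
    rows = []
    for chrom, length in lengths_bp.items():
        sub = merged[merged["chrom"] == chrom]
        n_windows = max(1, math.ceil(length / window_size))
        for w in range(n_windows):
            start = w * window_size
            end = min(start + window_size, length)
            in_win = sub[(sub["pos"] >= start) & (sub["pos"] < end)]
            n_hypo = int((in_win["call"] == "hypo").sum())
            n_hyper = int((in_win["call"] == "hyper").sum())
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_hypo": n_hypo,
                    "n_hyper": n_hyper,
                    "domain_call": _domain_call(n_hypo, n_hyper, domain_ratio),
                }
            )
    return pd.DataFrame(rows)


def chromosome_table(
    dmps: pd.DataFrame,
    annotation: Sequence[ProbeAnnotation],
    chrom_lengths_mb: Mapping[str, float],
) -> pd.DataFrame:
    """Per-chromosome hypo/hyper counts, per-Mb densities and the
    hypo:hyper ratio (NaN sentinel when no hyper site exists)."""
    merged = _positions(dmps, annotation)
    missing = set(merged["chrom"]) - set(chrom_lengths_mb)
    if missing:
        raise ValueError(f"no declared length for chromosome(s) {sorted(missing)}")
    rows = []
    for chrom, length_mb in chrom_lengths_mb.items():
        sub = merged[merged["chrom"] == chrom]
        n_hypo = int((sub["call"] == "hypo").sum())
        n_hyper = int((sub["call"] == "hyper").sum())
        rows.append(
            {
                "chrom": chrom,
                "length_mb": float(length_mb),
                "n_hyper": n_hyper,
                "n_hypo": n_hypo,
                "hyper_per_mb": n_hyper / length_mb,
                "hypo_per_mb": n_hypo / length_mb,
                "total_per_mb": (n_hyper + n_hypo) / length_mb,
                "hypo_hyper_ratio": n_hypo / n_hyper if n_hyper > 0 else UNDEFINED,
            }
        )
    return pd.DataFrame(rows)


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def reconstruct_counts_from_densities(
    length_mb: float, hyper_per_mb: float, hypo_per_mb: float
) -> tuple[int, int, float]:
    """Recover integer site counts, and their ratio, from printed per-Mb
    densities (rounding half away from zero)."""
    if length_mb <= 0:
        raise ValueError("length_mb must be positive")
    if hyper_per_mb < 0 or hypo_per_mb < 0:
        raise ValueError("densities must be non-negative")
    n_hyper = _round_half_away(hyper_per_mb * length_mb)
    n_hypo = _round_half_away(hypo_per_mb * length_mb)
    ratio = n_hypo / n_hyper if n_hyper > 0 else UNDEFINED
    return n_hyper, n_hypo, ratio


def region_distribution(
    dmps: pd.DataFrame, annotation: Sequence[ProbeAnnotation]
) -> dict[str, float]:
    """Fraction of called probes in the promoter region (promoter, 5'UTR,
    first exon) versus all other locations."""
    merged = _positions(dmps, annotation)
    if merged.empty:
        warnings.warn("no called probes; region distribution is empty")
        return {}
    in_prom = merged["region_class"].isin(PROMOTER_REGION_CLASSES)
    frac = float(in_prom.mean())
    return {"promoter_region": frac, "other": 1.0 - frac}


def top_k_sites(dmps: pd.DataFrame, k: int = 500) -> list[str]:
    """The k most significant probes (ascending FDR, then descending |dM|,
    then probe id), e.g. as clustering input."""
    if k < 1:
        raise ValueError("k must be >= 1")
    sig = dmps[dmps["call"] != "not_significant"].copy()
    sig["abs_dm"] = sig["delta_m"].abs()
    sig = sig.sort_values(
        ["fdr", "abs_dm", "probe_id"], ascending=[True, False, True], kind="mergesort"
    )
    return sig["probe_id"].head(k).tolist()
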