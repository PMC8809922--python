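"""Cis methylation-expression association with latent-factor correction.

A CpG probe and a gene form a cis pair when the probe lies in the promoter
region (promoter / 5'UTR / first exon) within 1 Mb of the gene's TSS. For
each pair, gene expression is regressed on methylation plus known
covariates (age, sex, batch) and k latent expression factors ("peers",
default k = 5) estimated from the covariate-residualized expression matrix.
A sequential variance decomposition adds the blocks in the fixed order
age -> sex(+batch) -> factors -> methylation and reports both the R^2
increment of each block and the partial R^2 of methylation after all
corrections.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import (
    FeatureMatrix,
    ProbeAnnotation,
    PROMOTER_REGION_CLASSES,
    SampleInfo,
)

EQTM_COLUMNS = [
    "probe_id", "gene", "distance_bp", "beta", "se", "p_value",
    "partial_r2_meth", "n_samples", "degenerate",
]

VARIANCE_BLOCKS = ("age", "sex", "peers", "methylation")


def find_cis_pairs(
    dmps: pd.DataFrame,
    annotation: Sequence[ProbeAnnotation],
    gene_tss: Mapping[str, tuple[str, int]],
    window_bp: int = 1_000_000,
    hypo_only: bool = True,
) -> pd.DataFrame:
    """Enumerate promoter-region probe / gene pairs within the cis window.

    The window is closed (distance <= window_bp) and anchored at the gene
    TSS, on either side. With `hypo_only` (the default) only probes called
    hypo enter pairing; otherwise any significant call qualifies.
    """
    call_of = dict(zip(dmps["probe_id"], dmps["call"]))
    wanted = {"hypo"} if hypo_only else {"hypo", "hyper"}
    rows = []
    for a in annotation:
        if a.region_class not in PROMOTER_REGION_CLASSES:
            continue
        if call_of.get(a.probe_id) not in wanted:
            continue
        for gene, (chrom, tss) in gene_tss.items():
            if chrom != a.chrom:
                continue
            dist = abs(a.pos - tss)
            if dist <= window_bp:
                rows.append(
                    {"probe_id": a.probe_id, "gene": gene, "distance_bp": int(dist)}
                )
    return pd.DataFrame(rows, columns=["probe_id", "gene", "distance_bp"])


def _covariate_design(
    samples: Sequence[SampleInfo], sample_order: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (age column, sex column, batch dummy block) aligned to
    `sample_order`; batch dummies drop the first level."""
    by_id = {s.sample_id: s for s in samples}
    missing = [sid for sid in sample_order if sid not in by_id]
    if missing:
        raise KeyError(f"samples without sheet entry: {missing}")
    ordered = [by_id[sid] for sid in sample_order]
    age = np.array([s.age for s in ordered])[:, None]
    sex = np.array([1.0 if s.sex == "female" else 0.0 for s in ordered])[:, None]
    batches = sorted({s.batch for s in ordered})
    dummies = np.column_stack(
        [
            np.array([1.0 if s.batch == b else 0.0 for s in ordered])
            for b in batches[1:]
        ]
    ) if len(batches) > 1 else np.zeros((len(ordered), 0))
    return age, sex, dummies


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ beta
    return float(resid @ resid)


class LatentFactorModel(BaseEstimator):
    """Latent expression factors ("peers") from covariate-residualized SVD.

    Expression is residualized per gene against intercept + age + sex +
    batch; the factors are the first `n_factors` sample-space singular
    directions of the residual matrix, standardized to zero mean and unit
    variance with the sign fixed so each factor's largest-magnitude
    loading is positive.

    Attributes
    ----------
    factors_ : ndarray of shape (n_samples, n_factors)
    singular_values_ : ndarray
    """

    def __init__(self, n_factors: int = 5):
        self.n_factors = n_factors

    def fit(
        self, expr: FeatureMatrix, samples: Sequence[SampleInfo]
    ) -> "LatentFactorModel":
        n_samples = len(expr.sample_ids)
        age, sex, batch = _covariate_design(samples, expr.sample_ids)
        X = np.hstack([np.ones((n_samples, 1)), age, sex, batch])
        n_cov = X.shape[1]
        if self.n_factors < 0:
            raise ValueError("n_factors must be >= 0")
        if self.n_factors >= n_samples - n_cov:
            raise ValueError(
                f"n_factors={self.n_factors} too large for {n_samples} samples "
                f"and {n_cov} covariate columns"
            )
        Y = expr.values.T  # samples x genes
        resid = Y - X @ np.linalg.lstsq(X, Y, rcond=None)[0]
        U, S, _ = np.linalg.svd(resid, full_matrices=False)
        k = self.n_factors
        factors = U[:, :k]
        self.singular_values_ = S[:k]
        if k:
            # residuals are centered, so U columns have (near-)zero mean;
            # standardize and orient each factor deterministically
            factors = factors - factors.mean(axis=0)
            sd = factors.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            factors = factors / sd
            flip = np.sign(factors[np.abs(factors).argmax(axis=0), np.arange(k)])
            flip[flip == 0] = 1.0
            factors = factors * flip
        self.factors_ = factors
        return self

    def transform(
        self, expr: FeatureMatrix, samples: Sequence[SampleInfo]
    ) -> np.ndarray:
        return self.fit(expr, samples).factors_


def estimate_latent_factors(
    expr: FeatureMatrix, samples: Sequence[SampleInfo], k: int = 5
) -> np.ndarray:
    """Functional wrapper over :class:`LatentFactorModel`."""
    return LatentFactorModel(n_factors=k).fit(expr, samples).factors_


@dataclass
class EqtmFit:
    """Per-pair regression result: methylation effect on expression."""

    probe_id: str
    gene: str
    distance_bp: int
    beta: float
    se: float
    p_value: float
    partial_r2_meth: float
    n_samples: int
    degenerate: bool = False


def fit_eqtm(
    probe_id: str,
    gene: str,
    m: FeatureMatrix,
    expr: FeatureMatrix,
    samples: Sequence[SampleInfo],
    factors: np.ndarray,
    distance_bp: int = 0,
) -> EqtmFit:
    """OLS of one gene's expression on one probe's methylation plus
    intercept, age, sex, batch and the latent factors.

    partial_r2_meth compares the full model against the same model without
    the methylation column: (RSS_reduced - RSS_full) / RSS_reduced.
    """
    if list(m.sample_ids) != list(expr.sample_ids):
        expr = expr.reorder_samples(m.sample_ids)
    y = expr.row(gene)
    meth = m.row(probe_id)
    n = len(y)
    age, sex, batch = _covariate_design(samples, m.sample_ids)
    base = np.hstack([np.ones((n, 1)), age, sex, batch, np.asarray(factors)])
    if np.ptp(meth) == 0.0:
        return EqtmFit(
            probe_id, gene, distance_bp,
            float("nan"), float("nan"), float("nan"), float("nan"), n,
            degenerate=True,
        )
    X = np.hstack([meth[:, None], base])
    if n <= X.shape[1]:
        raise ValueError(
            f"{n} samples cannot support {X.shape[1]} regression parameters"
        )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss_full = float(resid @ resid)
    dof = n - X.shape[1]
    sigma2 = rss_full / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[0, 0]))
    beta = float(coef[0])
    t = beta / se if se > 0 else 0.0
    p = float(2.0 * stats.t.sf(abs(t), dof))
    rss_red = _rss(y, base)
    partial = (rss_red - rss_full) / rss_red if rss_red > 0 else 0.0
    return EqtmFit(
        probe_id, gene, distance_bp, beta, se, p,
        float(np.clip(partial, 0.0, 1.0)), n,
    )


@dataclass
class VarianceDecomposition:
    """Sequential variance-explained decomposition for one gene."""

    gene: str
    probe_id: str
    frac_age: float
    frac_sex: float
    frac_peers: float
    frac_meth: float
    cumulative: tuple[float, float, float, float]
    meth_after_correction: float


def variance_decomposition(
    gene: str,
    expr: FeatureMatrix,
    m: FeatureMatrix,
    best_probe: str,
    samples: Sequence[SampleInfo],
    factors: np.ndarray,
) -> VarianceDecomposition:
    """Nested-OLS R^2 decomposition adding age, sex(+batch), peers, then
    methylation; block fractions are R^2 increments, and
    meth_after_correction is the partial R^2 of methylation given all
    preceding blocks.
    """
    if list(m.sample_ids) != list(expr.sample_ids):
        expr = expr.reorder_samples(m.sample_ids)
    y = expr.row(gene)
    meth = m.row(best_probe)
    n = len(y)
    age, sex, batch = _covariate_design(samples, m.sample_ids)
    blocks = [age, np.hstack([sex, batch]), np.asarray(factors), meth[:, None]]
    n_params = 1 + sum(b.shape[1] for b in blocks)
    if n < n_params:
        raise ValueError(f"{n} samples cannot support {n_params} parameters")
    tss = float(np.sum((y - y.mean()) ** 2))
    X = np.ones((n, 1))
    rss_seq = []
    for block in blocks:
        X = np.hstack([X, block])
        rss_seq.append(_rss(y, X))
    r2 = [1.0 - rss / tss if tss > 0 else 0.0 for rss in rss_seq]
    cumulative = tuple(float(max(0.0, v)) for v in r2)
    fracs = [cumulative[0]] + [
        max(0.0, cumulative[i] - cumulative[i - 1]) for i in range(1, 4)
    ]
    rss_before_meth = rss_seq[2]
    meth_partial = (
        (rss_before_meth - rss_seq[3]) / rss_before_meth
        if rss_before_meth > 0
        else 0.0
    )
    return VarianceDecomposition(
        gene=gene,
        probe_id=best_probe,
        frac_age=fracs[0],
        frac_sex=fracs[1],
        frac_peers=fracs[2],
        frac_meth=fracs[3],
        cumulative=cumulative,
        meth_after_correction=float(max(0.0, meth_partial)),
    )


def summarize_eqtm(fits: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Cohort summary: significant pairs split by effect sign, distinct
    probes/genes per sign, and the |beta| range among significant pairs."""
    usable = fits[~fits["degenerate"].astype(bool)]
    sig = usable[usable["p_value"] < alpha]
    neg = sig[sig["beta"] < 0]
    pos = sig[sig["beta"] > 0]
    abs_beta = sig["beta"].abs()
    return {
        "n_pairs_tested": int(len(usable)),
        "n_significant": int(len(sig)),
        "n_negative": int(len(neg)),
        "n_positive": int(len(pos)),
        "n_probes_negative": int(neg["probe_id"].nunique()),
        "n_genes_negative": int(neg["gene"].nunique()),
        "n_probes_positive": int(pos["probe_id"].nunique()),
        "n_genes_positive": int(pos["gene"].nunique()),
        "min_abs_beta": float(abs_beta.min()) if len(sig) else float("nan"),
        "max_abs_beta": float(abs_beta.max()) if len(sig) else float("nan"),
        "mean_abs_beta": float(abs_beta.mean()) if len(sig) else float("nan"),
    }


class CisEqtmAnalysis(BaseEstimator):
    """End-to-end cis eQTM stage: latent factors, per-pair OLS fits,
    per-gene variance decomposition and the cohort summary.

    Parameters
    ----------
    n_factors : int
        Number of latent expression factors (default 5).
    alpha : float
        Significance level on the per-pair methylation p-value.

    Attributes
    ----------
    factors_ : ndarray (n_samples, n_factors)
    fits_ : DataFrame, one row per cis pair.
    decomposition_ : DataFrame, one row per gene (best probe by smallest
        p, tie-broken by distance then probe id).
    summary_ : dict
    cohort_variance_ : dict
        Per-gene means of each block fraction and of the corrected
        methylation partial R^2, as percentages.
    """

    def __init__(self, n_factors: int = 5, alpha: float = 0.05):
        self.n_factors = n_factors
        self.alpha = alpha

    def fit(
        self,
        m: FeatureMatrix,
        expr: FeatureMatrix,
        pairs: pd.DataFrame,
        samples: Sequence[SampleInfo],
    ) -> "CisEqtmAnalysis":
        expr = expr.reorder_samples(m.sample_ids)
        self.factors_ = estimate_latent_factors(expr, samples, self.n_factors)
        records = []
        for row in pairs.itertuples(index=False):
            fit = fit_eqtm(
                row.probe_id, row.gene, m, expr, samples, self.factors_,
                distance_bp=int(row.distance_bp),
            )
            records.append(fit.__dict__)
        self.fits_ = pd.DataFrame(records, columns=EQTM_COLUMNS)
        decomp_rows = []
        usable = self.fits_[~self.fits_["degenerate"].astype(bool)]
        if len(usable):
            best = (
                usable.sort_values(
                    ["p_value", "distance_bp", "probe_id"], kind="mergesort"
                )
                .groupby("gene", sort=True)
                .head(1)
            )
            for row in best.itertuples(index=False):
                vd = variance_decomposition(
                    row.gene, expr, m, row.probe_id, samples, self.factors_
                )
                decomp_rows.append(
                    {
                        "gene": vd.gene,
                        "probe_id": vd.probe_id,
                        "frac_age": vd.frac_age,
                        "frac_sex": vd.frac_sex,
                        "frac_peers": vd.frac_peers,
                        "frac_meth": vd.frac_meth,
                        "cum_age": vd.cumulative[0],
                        "cum_sex": vd.cumulative[1],
                        "cum_peers": vd.cumulative[2],
                        "cum_meth": vd.cumulative[3],
                        "meth_after_correction": vd.meth_after_correction,
                    }
                )
        self.decomposition_ = pd.DataFrame(
            decomp_rows,
            columns=[
                "gene", "probe_id", "frac_age", "frac_sex", "frac_peers",
                "frac_meth", "cum_age", "cum_sex", "cum_peers", "cum_meth",
                "meth_after_correction",
            ],
        )
        self.summary_ = summarize_eqtm(self.fits_, self.alpha)
        d = self.decomposition_
        self.cohort_variance_ = {
            "age_percent": float(d["cum_age"].mean() * 100) if len(d) else float("nan"),
            "sex_percent": float(d["cum_sex"].mean() * 100) if len(d) else float("nan"),
            "peers_percent": float(d["cum_peers"].mean() * 100) if len(d) else float("nan"),
            "methylation_percent": float(d["cum_meth"].mean() * 100) if len(d) else float("nan"),
            "meth_after_correction_percent": (
                float(d["meth_after_correction"].mean() * 100) if len(d) else float("nan")
            ),
        }
        return self
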