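"""Seeded case/control methylation + expression simulator with a truth ledger.

The generator emulates the statistical structure a 450K-style case/control
integration study assumes: per-probe M-values with planted group effects at
a configurable hypo:hyper imbalance, log2 expression with planted cis
methylation effects, age/sex covariate effects, latent confounders shared
between the two data layers, and a binary-call validation cohort. Every
planted effect is recorded in a :class:`SyntheticTruth` ledger so that
downstream stages can be tested for recovery, not just for running.

The generative model is linear-Gaussian::

    M[p, i] = mu_p + dM_p * 1[case_i] + sum_k gamma[p, k] h[k, i] + eps,
    E[g, i] = alpha_g + beta_g * M[c(g), i] + a_g * age_i
              + s_g * 1[female_i] + sum_k lambda[g, k] h[k, i] + eps',

with h_k ~ Normal(0, 1) latent confounders common to both layers and
eps ~ Normal(0, noise_sd). Each cis gene g is wired to a dedicated promoter
probe c(g) placed within the cis window of its TSS.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    FeatureMatrix,
    ProbeAnnotation,
    SampleInfo,
)

#: Autosome lengths in Mb for the default pseudo-genome (hg19 scale).
DEFAULT_CHROM_LENGTHS_MB: dict[str, float] = {
    "chr1": 249.25, "chr2": 243.20, "chr3": 198.02, "chr4": 191.15,
    "chr5": 180.92, "chr6": 171.12, "chr7": 159.14, "chr8": 146.36,
    "chr9": 141.21, "chr10": 135.53, "chr11": 135.01, "chr12": 133.85,
    "chr13": 115.17, "chr14": 107.35, "chr15": 102.53, "chr16": 90.35,
    "chr17": 81.20, "chr18": 78.08, "chr19": 59.13, "chr20": 63.03,
    "chr21": 48.13, "chr22": 51.30,
}

# Region-class sampling weights, chosen so that the promoter region
# (promoter + 5'UTR + first exon) holds ~48% of probes, the composition
# scale typical of 450K designs.
_REGION_CLASS_PROBS = {
    "promoter": 0.25,
    "utr5": 0.12,
    "first_exon": 0.11,
    "body": 0.28,
    "utr3": 0.06,
    "downstream": 0.06,
    "intergenic": 0.12,
}


@dataclass
class SimConfig:
    """Parameters of one simulated case/control dataset.

    The cohort defaults mirror the study scale the pipeline targets:
    12 cases vs 12 controls, a ~95:5 hypo:hyper imbalance among planted
    differential probes, five latent confounders, and a planted cis effect
    of 2.0 expression units per M-value unit. Matrix sizes default to a
    desk scale (5,000 probes x 800 genes) that preserves the structure of
    the full array without its bulk.
    """

    n_case: int = 12
    n_control: int = 12
    n_probes: int = 5000
    n_genes: int = 800
    frac_dmp: float = 0.10
    hypo_fraction: float = 0.95
    dmp_effect: float = 0.8
    frac_snp: float = 0.25
    n_latent: int = 5
    latent_sd: float = 0.3
    noise_sd_m: float = 0.2
    noise_sd_e: float = 0.5
    frac_cis: float = 0.10
    cis_beta: float = 2.0
    age_beta: float = 0.01
    sex_beta: float = 0.3
    seed: int = 0
    chrom_lengths_mb: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS_MB)
    )

    def __post_init__(self) -> None:
        for name in ("frac_dmp", "hypo_fraction", "frac_snp", "frac_cis"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("latent_sd", "noise_sd_m", "noise_sd_e"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("n_case", "n_control", "n_probes", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_latent < 0:
            raise ValueError("n_latent must be >= 0")


@dataclass
class SyntheticTruth:
    """Ledger of planted effects for recovery testing.

    variance_fractions holds, per gene, the sequential R^2 increments of
    the noiseless generative blocks in the analysis order (age, sex,
    latent, methylation) plus the residual noise share; increments are
    non-negative by construction and sum to <= 1.
    """

    dmp_probes: dict[str, float]
    cis_pairs: dict[tuple[str, str], float]
    latent_loadings: np.ndarray          # genes x k expression loadings
    probe_latent_loadings: np.ndarray    # probes x k methylation loadings
    latent_factors: np.ndarray           # k x samples realized confounders
    covariate_effects: dict[str, tuple[float, float]]  # gene -> (age, sex)
    variance_fractions: pd.DataFrame     # gene x (age, sex, latent, methylation, noise)
    gene_tss: dict[str, tuple[str, int]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dmp_probes": self.dmp_probes,
            "cis_pairs": {f"{p}|{g}": b for (p, g), b in self.cis_pairs.items()},
            "latent_loadings": self.latent_loadings.tolist(),
            "probe_latent_loadings": self.probe_latent_loadings.tolist(),
            "latent_factors": self.latent_factors.tolist(),
            "covariate_effects": {g: list(v) for g, v in self.covariate_effects.items()},
            "variance_fractions": self.variance_fractions.reset_index().to_dict("list"),
            "gene_tss": {g: [c, int(p)] for g, (c, p) in self.gene_tss.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        data = json.loads(Path(path).read_text())
        vf = pd.DataFrame(data["variance_fractions"]).set_index("gene")
        return cls(
            dmp_probes=data["dmp_probes"],
            cis_pairs={
                tuple(k.split("|", 1)): v for k, v in data["cis_pairs"].items()
            },
            latent_loadings=np.asarray(data["latent_loadings"]),
            probe_latent_loadings=np.asarray(data["probe_latent_loadings"]),
            latent_factors=np.asarray(data["latent_factors"]),
            covariate_effects={
                g: tuple(v) for g, v in data["covariate_effects"].items()
            },
            variance_fractions=vf,
            gene_tss={g: (c, int(p)) for g, (c, p) in data["gene_tss"].items()},
        )


def _sequential_fractions(y: np.ndarray, blocks: list[np.ndarray]) -> list[float]:
    """R^2 increments of nested OLS fits adding each block in order."""
    n = y.shape[0]
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        return [0.0] * len(blocks)
    X = np.ones((n, 1))
    rss_prev = tss
    out = []
    for block in blocks:
        X = np.hstack([X, block])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(resid @ resid)
        out.append(max(0.0, (rss_prev - rss) / tss))
        rss_prev = rss
    return out


def generate_dataset(
    config: SimConfig,
) -> tuple[FeatureMatrix, FeatureMatrix, list[ProbeAnnotation], list[SampleInfo], SyntheticTruth]:
    """Generate one seeded case/control methylation + expression dataset.

    Returns (m_values, expression, probe annotation, sample sheet, truth).
    The same config (including seed) always yields bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_case + config.n_control
    chroms = list(config.chrom_lengths_mb)
    lengths_bp = np.array(
        [int(round(config.chrom_lengths_mb[c] * 1e6)) for c in chroms]
    )
    chrom_probs = lengths_bp / lengths_bp.sum()

    # --- samples ------------------------------------------------------
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    groups = ["case"] * config.n_case + ["control"] * config.n_control
    ages = rng.uniform(20.0, 60.0, size=n_samples)
    sexes = np.where(rng.random(n_samples) < 0.5, "female", "male")
    batches = [f"b{(i % 2) + 1}" for i in range(n_samples)]
    samples = [
        SampleInfo(sample_ids[i], groups[i], float(ages[i]), str(sexes[i]), batches[i])
        for i in range(n_samples)
    ]
    is_case = np.array([g == "case" for g in groups], dtype=float)
    is_female = np.array([s == "female" for s in sexes], dtype=float)

    # --- probe scaffold ----------------------------------------------
    probe_ids = [f"cg{i:08d}" for i in range(config.n_probes)]
    probe_chrom_idx = rng.choice(len(chroms), size=config.n_probes, p=chrom_probs)
    probe_pos = np.array(
        [rng.integers(0, lengths_bp[c]) for c in probe_chrom_idx], dtype=np.int64
    )
    region_labels = list(_REGION_CLASS_PROBS)
    region_p = np.array([_REGION_CLASS_PROBS[r] for r in region_labels])
    probe_region = rng.choice(region_labels, size=config.n_probes, p=region_p)
    snp_flags = rng.random(config.n_probes) < config.frac_snp

    # --- gene scaffold ------------------------------------------------
    gene_ids = [f"g{i + 1:05d}" for i in range(config.n_genes)]
    gene_chrom_idx = rng.choice(len(chroms), size=config.n_genes, p=chrom_probs)
    gene_tss_pos = np.array(
        [rng.integers(0, lengths_bp[c]) for c in gene_chrom_idx], dtype=np.int64
    )
    gene_tss = {
        gene_ids[i]: (chroms[gene_chrom_idx[i]], int(gene_tss_pos[i]))
        for i in range(config.n_genes)
    }

    # --- planted methylation effects ---------------------------------
    n_dmp = int(round(config.frac_dmp * config.n_probes))
    delta_m = np.zeros(config.n_probes)
    if config.frac_dmp > 0 and n_dmp < 1:
        warnings.warn("frac_dmp * n_probes < 1: no differential effects planted")
    non_snp = np.flatnonzero(~snp_flags)
    dmp_idx = rng.choice(non_snp, size=min(n_dmp, non_snp.size), replace=False)
    hypo_mask = rng.random(dmp_idx.size) < config.hypo_fraction
    delta_m[dmp_idx[hypo_mask]] = -config.dmp_effect
    delta_m[dmp_idx[~hypo_mask]] = config.dmp_effect

    # --- wire cis genes to planted hypo promoter probes ---------------
    n_cis = int(round(config.frac_cis * config.n_genes))
    cis_gene_idx = rng.choice(config.n_genes, size=n_cis, replace=False)
    hypo_pool = list(dmp_idx[hypo_mask])
    rng.shuffle(hypo_pool)
    spare_pool = [i for i in non_snp if delta_m[i] == 0.0]
    rng.shuffle(spare_pool)
    cis_probe_of_gene: dict[int, int] = {}
    for gi in cis_gene_idx:
        if hypo_pool:
            pi = hypo_pool.pop()
        elif spare_pool:
            pi = spare_pool.pop()
            delta_m[pi] = -config.dmp_effect  # keep cis probes discoverable
        else:  # pragma: no cover - degenerate tiny configs
            break
        cis_probe_of_gene[int(gi)] = int(pi)
        chrom_i = gene_chrom_idx[gi]
        tss = int(gene_tss_pos[gi])
        offset = int(rng.integers(-200_000, 200_001))
        pos = int(np.clip(tss + offset, 0, lengths_bp[chrom_i] - 1))
        probe_chrom_idx[pi] = chrom_i
        probe_pos[pi] = pos
        probe_region[pi] = "promoter"

    # --- latent confounders and matrices ------------------------------
    k = config.n_latent
    h = rng.standard_normal((k, n_samples)) if k else np.zeros((0, n_samples))
    gamma = (
        rng.normal(0.0, config.latent_sd, size=(config.n_probes, k))
        if k
        else np.zeros((config.n_probes, 0))
    )
    lam = (
        rng.normal(0.0, config.latent_sd, size=(config.n_genes, k))
        if k
        else np.zeros((config.n_genes, 0))
    )
    mu = rng.normal(0.0, 2.0, size=config.n_probes)
    m_noise = rng.normal(0.0, config.noise_sd_m, size=(config.n_probes, n_samples))
    m_values = (
        mu[:, None]
        + np.outer(delta_m, is_case)
        + gamma @ h
        + m_noise
    )

    alpha = rng.normal(7.0, 2.0, size=config.n_genes)
    age_betas = rng.normal(0.0, config.age_beta, size=config.n_genes)
    sex_betas = rng.normal(0.0, config.sex_beta, size=config.n_genes)
    e_noise = rng.normal(0.0, config.noise_sd_e, size=(config.n_genes, n_samples))
    expression = (
        alpha[:, None]
        + np.outer(age_betas, ages)
        + np.outer(sex_betas, is_female)
        + lam @ h
        + e_noise
    )
    for gi, pi in cis_probe_of_gene.items():
        expression[gi] += config.cis_beta * m_values[pi]

    # --- annotation --------------------------------------------------
    annotation = []
    for i in range(config.n_probes):
        gene = None
        tssd = None
        if i in cis_probe_of_gene.values():
            gi = next(g for g, p in cis_probe_of_gene.items() if p == i)
            gene = gene_ids[gi]
            tssd = int(probe_pos[i] - gene_tss_pos[gi])
        annotation.append(
            ProbeAnnotation(
                probe_id=probe_ids[i],
                chrom=chroms[probe_chrom_idx[i]],
                pos=int(probe_pos[i]),
                region_class=str(probe_region[i]),
                snp_overlap=bool(snp_flags[i]),
                gene=gene,
                tss_distance=tssd,
            )
        )

    # --- truth ledger -------------------------------------------------
    dmp_truth = {
        probe_ids[i]: float(delta_m[i]) for i in np.flatnonzero(delta_m != 0.0)
    }
    cis_truth = {
        (probe_ids[pi], gene_ids[gi]): float(config.cis_beta)
        for gi, pi in cis_probe_of_gene.items()
    }
    rows = []
    # the sex block carries the batch indicator, mirroring how the
    # decomposition folds batch into the sex reporting block
    is_b2 = np.array([b == "b2" for b in batches], dtype=float)
    for gi in range(config.n_genes):
        y = expression[gi]
        blocks = [
            ages[:, None],
            np.column_stack([is_female, is_b2]),
            h.T if k else np.zeros((n_samples, 0)),
        ]
        if gi in cis_probe_of_gene:
            blocks.append(m_values[cis_probe_of_gene[gi]][:, None])
        else:
            blocks.append(np.zeros((n_samples, 0)))
        fr = _sequential_fractions(y, blocks)
        rows.append(
            {
                "gene": gene_ids[gi],
                "age": fr[0],
                "sex": fr[1],
                "latent": fr[2],
                "methylation": fr[3],
                "noise": max(0.0, 1.0 - sum(fr)),
            }
        )
    variance_fractions = pd.DataFrame(rows).set_index("gene")

    truth = SyntheticTruth(
        dmp_probes=dmp_truth,
        cis_pairs=cis_truth,
        latent_loadings=lam,
        probe_latent_loadings=gamma,
        latent_factors=h,
        covariate_effects={
            gene_ids[i]: (float(age_betas[i]), float(sex_betas[i]))
            for i in range(config.n_genes)
        },
        variance_fractions=variance_fractions,
        gene_tss=gene_tss,
    )
    m_matrix = FeatureMatrix(probe_ids, sample_ids, m_values, "m_value")
    e_matrix = FeatureMatrix(gene_ids, sample_ids, expression, "log2_expression")
    return m_matrix, e_matrix, annotation, samples, truth


def generate_msp_cohort(
    n_case: int,
    n_control: int,
    p_case: float,
    p_control: float,
    seed: int,
) -> pd.DataFrame:
    """Simulate binary methylation calls for an MSP-PCR validation cohort.

    Each sample's call is an independent Bernoulli draw with the group's
    methylation probability. Returns columns sample_id, group, methylated.
    """
    for name, p in (("p_case", p_case), ("p_control", p_control)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    if n_case < 1 or n_control < 1:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    calls_case = rng.random(n_case) < p_case
    calls_ctrl = rng.random(n_control) < p_control
    return pd.DataFrame(
        {
            "sample_id": [f"V{i + 1:03d}" for i in range(n_case + n_control)],
            "group": ["case"] * n_case + ["control"] * n_control,
            "methylated": np.concatenate([calls_case, calls_ctrl]),
        }
    )


def msp_contingency(calls: pd.DataFrame) -> tuple[int, int, int, int]:
    """Collapse per-sample binary calls to the 2x2 table
    (methylated-case, methylated-control, unmethylated-case, unmethylated-control)."""
    case = calls[calls["group"] == "case"]["methylated"].astype(bool)
    ctrl = calls[calls["group"] == "control"]["methylated"].astype(bool)
    return (
        int(case.sum()),
        int(ctrl.sum()),
        int((~case).sum()),
        int((~ctrl).sum()),
    )
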