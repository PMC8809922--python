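"""Pipeline configuration: every analysis threshold in one YAML-serializable record."""
from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Thresholds and switches for every pipeline stage.

    Defaults are the study's published cutoffs: FDR < 0.05 with |dM| > 0.3
    for differential methylation, raw p < 0.05 with |log2FC| > 2 (strong) or
    > 1 (weak) for expression, 10 Mb windows with a strict 1.5 count ratio
    for domain calls, a 1 Mb promoter-anchored cis window, five latent
    expression factors, and 10-500 gene-set sizes for over-representation.
    """

    # differential methylation
    fdr_threshold: float = 0.05
    delta_m_threshold: float = 0.3
    equal_var: bool = False          # False = Welch t-test
    m_value_offset: float = 0.0
    # window / domain landscape
    window_size_bp: int = 10_000_000
    domain_ratio: float = 1.5
    # differential expression
    deg_p_threshold: float = 0.05
    strong_lfc: float = 2.0
    weak_lfc: float = 1.0
    deg_use_fdr: bool = False
    deg_tier: str = "strong"         # tier feeding the DMP/DEG intersection
    # cis eQTM
    cis_window_bp: int = 1_000_000
    hypo_only: bool = True
    n_factors: int = 5
    eqtm_alpha: float = 0.05
    eqtm_use_fdr: bool = False
    batch_as_own_block: bool = False  # default folds batch into the sex block
    # over-representation
    ora_min_size: int = 10
    ora_max_size: int = 500
    ora_fdr_threshold: float = 0.05

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
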