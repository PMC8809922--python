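"""Validation-cohort statistics and gene-set over-representation.

Covers the wet-lab follow-up arithmetic: the two-sided Fisher's exact test
on a methylated/unmethylated x case/control table (MSP-PCR calls), simple
percentage reporting, the unpaired Welch t-test on expression, and a
generic hypergeometric over-representation test against user-supplied gene
sets with the 10-500 set-size filter and BH correction.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Collection, Sequence

import pandas as pd
from scipy import stats

from .io import GeneSet
from .methylation import bh_adjust

ENRICHMENT_COLUMNS = [
    "set_id", "overlap", "set_size", "study_size", "universe_size",
    "p_value", "fdr",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows methylated/unmethylated and columns case/control."""

    a: int  # methylated, case
    b: int  # methylated, control
    c: int  # unmethylated, case
    d: int  # unmethylated, control

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p by the probability-mass rule: the sum of
    hypergeometric probabilities of all tables with the observed margins
    whose point probability does not exceed the observed table's."""
    if min(table.a + table.b, table.c + table.d, table.a + table.c, table.b + table.d) == 0:
        warnings.warn("a zero margin makes the table uninformative; p = 1")
        return 1.0
    _, p = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    )
    return float(p)


def proportion(count: int, total: int, decimals: int = 1) -> float:
    """Percentage 100*count/total, rounded half away from zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    x = 100.0 * count / total
    scale = 10 ** decimals
    return math.floor(x * scale + 0.5) / scale


def unpaired_t(
    values_case: Sequence[float], values_control: Sequence[float]
) -> tuple[float, float]:
    """Welch two-sided t-test comparing the two groups' values."""
    if len(values_case) < 2 or len(values_control) < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(values_case, values_control, equal_var=False)
    if not math.isfinite(t):  # both groups constant and equal
        return 0.0, 1.0
    return float(t), float(p)


def ora_hypergeometric(
    study_genes: Collection[str],
    sets: Sequence[GeneSet],
    universe: Collection[str],
    min_size: int = 10,
    max_size: int = 500,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of `study_genes` in
    each gene set, BH-corrected across the sets that survive the size
    filter (applied after intersecting each set with the universe)."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    study = set(study_genes)
    stray = study - universe
    if stray:
        raise ValueError(
            f"study genes outside the universe: {sorted(stray)[:5]}"
        )
    n_universe = len(universe)
    n_study = len(study)
    rows = []
    for gs in sets:
        members = gs.genes & universe
        if not min_size <= len(members) <= max_size:
            continue
        overlap = len(study & members)
        # P(X >= overlap), X ~ Hypergeom(N=universe, K=set, n=study)
        p = float(stats.hypergeom.sf(overlap - 1, n_universe, len(members), n_study))
        rows.append(
            {
                "set_id": gs.set_id,
                "overlap": overlap,
                "set_size": len(members),
                "study_size": n_study,
                "universe_size": n_universe,
                "p_value": min(1.0, p),
            }
        )
    frame = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    frame["fdr"] = bh_adjust(frame["p_value"]) if len(frame) else []
    return frame
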