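"""Tabular I/O and shared domain types.

All genomic positions are 0-based internally; annotation files carry 1-based
positions (array-manifest convention) and are converted once at read time.
BED exports are 0-based half-open.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALUE_KINDS = ("m_value", "log2_expression")
REGION_CLASSES = (
    "promoter",
    "utr5",
    "first_exon",
    "body",
    "utr3",
    "downstream",
    "intergenic",
)
#: region classes counted as "promoter region" (near the TSS)
PROMOTER_REGION_CLASSES = frozenset({"promoter", "utr5", "first_exon"})

GROUPS = ("case", "control")
SEXES = ("female", "male")

_TRUE_STRINGS = {"true", "t", "1", "yes", "y"}
_FALSE_STRINGS = {"false", "f", "0", "no", "n"}


@dataclass
class FeatureMatrix:
    """Features x samples numeric matrix (M-values or log2 expression).

    Rows are features (probes or genes), columns are samples. Identifiers
    must be unique and the values finite: rows with missing cells are
    resolved at load time (dropped), never carried through the pipeline.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    value_kind: str

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(
                f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}"
            )
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {name} id: {dup!r}")
        if self.values.size == 0:
            raise ValueError("empty matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite values")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, value_kind: str) -> "FeatureMatrix":
        return cls(
            feature_ids=list(frame.index.astype(str)),
            sample_ids=list(frame.columns.astype(str)),
            values=frame.to_numpy(dtype=float),
            value_kind=value_kind,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.feature_ids, name="feature_id"),
            columns=self.sample_ids,
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, feature_id: str) -> np.ndarray:
        try:
            i = self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"feature {feature_id!r} not in matrix") from None
        return self.values[i]

    def subset_features(self, keep: Iterable[str]) -> "FeatureMatrix":
        keep = set(keep)
        idx = [i for i, f in enumerate(self.feature_ids) if f in keep]
        return FeatureMatrix(
            [self.feature_ids[i] for i in idx],
            list(self.sample_ids),
            self.values[idx],
            self.value_kind,
        )

    def reorder_samples(self, order: Sequence[str]) -> "FeatureMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in order if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        idx = [pos[s] for s in order]
        return FeatureMatrix(
            list(self.feature_ids), list(order), self.values[:, idx], self.value_kind
        )


@dataclass(frozen=True)
class ProbeAnnotation:
    """Genomic annotation of one methylation probe (0-based position)."""

    probe_id: str
    chrom: str
    pos: int
    region_class: str
    snp_overlap: bool
    gene: str | None = None
    tss_distance: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"probe {self.probe_id}: negative position {self.pos}")
        if self.region_class not in REGION_CLASSES:
            raise ValueError(
                f"probe {self.probe_id}: unknown region_class "
                f"{self.region_class!r}; valid labels: {', '.join(REGION_CLASSES)}"
            )


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    group: str
    age: float
    sex: str
    batch: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"sample {self.sample_id}: unknown group {self.group!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sample {self.sample_id}: unknown sex {self.sex!r}")
        if not self.age > 0:
            raise ValueError(f"sample {self.sample_id}: non-positive age {self.age}")


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.set_id}: empty")


def _first_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_feature_matrix(path: str | Path, value_kind: str) -> FeatureMatrix:
    """Read a features x samples TSV (header = sample ids, first column = ids).

    Rows containing any non-numeric or missing cell are dropped, with the
    count logged. Duplicate identifiers and empty matrices are hard errors.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.empty:
        raise ValueError(f"{path}: empty matrix")
    dup = _first_duplicate(list(frame.index.astype(str)))
    if dup is not None:
        raise ValueError(f"{path}: duplicate feature id {dup!r}")
    dup = _first_duplicate(list(frame.columns.astype(str)))
    if dup is not None:
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        logger.info("%s: %d row(s) dropped (non-numeric or missing cells)", path, int(bad.sum()))
        numeric = numeric.loc[~bad]
    if numeric.empty:
        raise ValueError(f"{path}: no rows left after dropping incomplete rows")
    return FeatureMatrix.from_frame(numeric, value_kind)


def _parse_bool(text: str, path: str | Path, line: int) -> bool:
    low = str(text).strip().lower()
    if low in _TRUE_STRINGS:
        return True
    if low in _FALSE_STRINGS:
        return False
    raise ValueError(f"{path}, line {line}: malformed boolean {text!r}")


def read_probe_annotation(path: str | Path) -> list[ProbeAnnotation]:
    """Read probe annotation TSV; 1-based input positions become 0-based."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probe_id", "chrom", "pos", "region_class", "snp_overlap"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: list[ProbeAnnotation] = []
    seen: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        rec = row._asdict()
        pid = str(rec["probe_id"])
        if pid in seen:
            raise ValueError(f"{path}, line {i}: duplicate probe id {pid!r}")
        seen.add(pid)
        try:
            pos1 = int(rec["pos"])
        except (TypeError, ValueError):
            raise ValueError(f"{path}, line {i}: non-integer position {rec['pos']!r}") from None
        if pos1 < 1:
            raise ValueError(f"{path}, line {i}: position must be >= 1 (1-based), got {pos1}")
        gene = rec.get("gene")
        gene = None if gene is None or pd.isna(gene) or gene == "" else str(gene)
        tssd = rec.get("tss_distance")
        tssd = None if tssd is None or pd.isna(tssd) or tssd == "" else int(float(tssd))
        try:
            out.append(
                ProbeAnnotation(
                    probe_id=pid,
                    chrom=str(rec["chrom"]),
                    pos=pos1 - 1,
                    region_class=str(rec["region_class"]).strip().lower(),
                    snp_overlap=_parse_bool(rec["snp_overlap"], path, i),
                    gene=gene,
                    tss_distance=tssd,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from None
    return out


def read_sample_sheet(path: str | Path) -> list[SampleInfo]:
    """Read the sample sheet TSV (sample_id, group, age, sex, batch)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "age", "sex", "batch"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: list[SampleInfo] = []
    seen: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        rec = row._asdict()
        sid = str(rec["sample_id"])
        if sid in seen:
            raise ValueError(f"{path}, line {i}: duplicate sample id {sid!r}")
        seen.add(sid)
        try:
            out.append(
                SampleInfo(
                    sample_id=sid,
                    group=str(rec["group"]).strip().lower(),
                    age=float(rec["age"]),
                    sex=str(rec["sex"]).strip().lower(),
                    batch=str(rec["batch"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from None
    return out


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets in GMT format (set id, description, gene symbols)."""
    sets: list[GeneSet] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}, line {i}: expected >= 3 tab-separated fields")
        genes = [g for g in parts[2:] if g]
        sets.append(GeneSet(set_id=parts[0], description=parts[1], genes=frozenset(genes)))
    return sets


def samples_to_frame(samples: Sequence[SampleInfo]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "group": [s.group for s in samples],
            "age": [s.age for s in samples],
            "sex": [s.sex for s in samples],
            "batch": [s.batch for s in samples],
        }
    )


def annotation_to_frame(annotation: Sequence[ProbeAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": [a.probe_id for a in annotation],
            "chrom": [a.chrom for a in annotation],
            "pos": [a.pos for a in annotation],
            "region_class": [a.region_class for a in annotation],
            "snp_overlap": [a.snp_overlap for a in annotation],
            "gene": [a.gene for a in annotation],
            "tss_distance": [a.tss_distance for a in annotation],
        }
    )


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with 6-significant-digit floats.

    Column and row order follow the input frame, so repeated runs produce
    byte-identical files suitable for diffing.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(records)
    records.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    frame = matrix.to_frame()
    frame.to_csv(path, sep="\t", float_format="%.6g")


def write_annotation(annotation: Sequence[ProbeAnnotation], path: str | Path) -> None:
    """Write annotation back to the 1-based TSV convention."""
    frame = annotation_to_frame(annotation)
    frame["pos"] = frame["pos"] + 1
    frame.to_csv(path, sep="\t", index=False)


def write_sample_sheet(samples: Sequence[SampleInfo], path: str | Path) -> None:
    samples_to_frame(samples).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_bed(intervals: pd.DataFrame, path: str | Path, name_col: str | None = None) -> None:
    """Write a BED file (0-based half-open) from columns chrom/start/end."""
    cols = ["chrom", "start", "end"]
    frame = intervals[cols].copy()
    if name_col is not None:
        frame["name"] = intervals[name_col]
    frame.to_csv(path, sep="\t", index=False, header=False)


def split_groups(
    matrix: FeatureMatrix, samples: Sequence[SampleInfo]
) -> tuple[np.ndarray, np.ndarray]:
    """Split matrix columns into (case, control) sub-matrices, sample-aligned."""
    by_id = {s.sample_id: s for s in samples}
    missing = [sid for sid in matrix.sample_ids if sid not in by_id]
    if missing:
        raise KeyError(f"samples without sheet entry: {missing}")
    case_idx = [j for j, sid in enumerate(matrix.sample_ids) if by_id[sid].group == "case"]
    ctrl_idx = [j for j, sid in enumerate(matrix.sample_ids) if by_id[sid].group == "control"]
    return matrix.values[:, case_idx], matrix.values[:, ctrl_idx]
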