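"""Reading, alignment and preprocessing of per-omics matrices.

All matrices are tab-delimited text with one header row and one id column.
Internally every omics layer is held samples x features; missing entries are
NaN until :func:`impute_zero` replaces them with 0.

The preprocessing pipeline applied per omics layer is fixed:

    log_transform (RNA/miRNA only) -> impute_zero -> variance_filter -> zscore

Variance filtering uses the population variance (denominator ``n``) and keeps
features whose variance is strictly greater than the threshold. Z-scoring
likewise standardises with the population standard deviation; constant
columns map to all-zeros rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

OMICS_ORDER = ("RNA", "Mut", "CNA", "miRNA")

#: Region tokens as they appear in annotation files, mapped to internal names.
REGION_TOKENS = {
    "CDS": "CDS",
    "PromCore": "PromCore",
    "5UTR": "UTR5",
    "3UTR": "UTR3",
    "Enhancer": "Enhancer",
    "ncRNA": "ncRNA",
    "SS": "SS",
    "NONE": "NONE",
}
REGION_NAMES = tuple(REGION_TOKENS.values())


class Orientation(str, Enum):
    samples_rows = "samples_rows"
    features_rows = "features_rows"


@dataclass
class OmicsMatrix:
    """One omics layer: ``values`` is samples x features, NaN marks missing."""

    omics_name: str
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.omics_name not in OMICS_ORDER:
            raise ValueError(f"unknown omics name {self.omics_name!r}; expected one of {OMICS_ORDER}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"{self.omics_name}: values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError(f"{self.omics_name}: duplicate sample ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError(f"{self.omics_name}: duplicate feature ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


@dataclass(frozen=True)
class FeatureAnnotation:
    feature_id: str
    omics_name: str
    region: str = "NONE"
    gene_symbol: str | None = None

    def __post_init__(self) -> None:
        if self.region not in REGION_NAMES:
            raise ValueError(f"unknown region {self.region!r}")
        if self.region != "NONE" and self.omics_name not in ("Mut", "CNA"):
            raise ValueError(
                f"feature {self.feature_id}: region {self.region} only valid for Mut/CNA features"
            )


@dataclass
class ClinicalTable:
    sample_ids: list[str]
    survival_time: np.ndarray  # days
    event: np.ndarray  # 1 = death observed, 0 = censored

    def __post_init__(self) -> None:
        self.survival_time = np.asarray(self.survival_time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in clinical table")
        if self.survival_time.shape != (len(self.sample_ids),) or self.event.shape != (len(self.sample_ids),):
            raise ValueError("clinical columns must align with sample ids")
        if np.any(self.survival_time < 0):
            raise ValueError("survival_time must be non-negative")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event must be 0 (censored) or 1 (death)")

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return ClinicalTable(list(sample_ids), self.survival_time[idx], self.event[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "survival_time": self.survival_time, "event": self.event}
        )


@dataclass
class MultiOmicsDataset:
    """Aligned omics layers (fixed order RNA, Mut, CNA, miRNA) plus clinical data."""

    omics: list[OmicsMatrix]
    clinical: ClinicalTable
    annotations: list[FeatureAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.omics:
            raise ValueError("at least one omics matrix required")
        ref = self.omics[0].sample_ids
        for m in self.omics[1:]:
            if m.sample_ids != ref:
                raise ValueError("all omics matrices must share identical sample order")
        if self.clinical.sample_ids != ref:
            raise ValueError("clinical table must be aligned to the omics sample order")
        order = {name: i for i, name in enumerate(OMICS_ORDER)}
        names = [m.omics_name for m in self.omics]
        if names != sorted(names, key=order.__getitem__):
            raise ValueError(f"omics must be ordered {OMICS_ORDER}, got {names}")

    @property
    def sample_ids(self) -> list[str]:
        return self.omics[0].sample_ids

    @property
    def n_samples(self) -> int:
        return self.omics[0].n_samples

    @property
    def combined_dim(self) -> int:
        return sum(m.n_features for m in self.omics)

    def get_omics(self, name: str) -> OmicsMatrix:
        for m in self.omics:
            if m.omics_name == name:
                return m
        raise KeyError(name)

    def annotation_map(self) -> dict[str, FeatureAnnotation]:
        return {a.feature_id: a for a in self.annotations}


# ---------------------------------------------------------------------------
# readers / writers


def read_omics_tsv(
    path, omics_name: str, orientation: Orientation | str = Orientation.samples_rows
) -> OmicsMatrix:
    """Read a tab-delimited omics matrix; empty cells become NaN (missing)."""
    orientation = Orientation(orientation)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate id {dup!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        values[:, j] = converted.to_numpy(dtype=float)
    rows, cols = list(df.index.astype(str)), list(df.columns.astype(str))
    if orientation is Orientation.features_rows:
        values = values.T
        rows, cols = cols, rows
    return OmicsMatrix(omics_name, rows, cols, values)


def write_omics_tsv(m: OmicsMatrix, path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_clinical_tsv(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = {"sample_id", "survival_time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing clinical columns {sorted(missing)}")
    return ClinicalTable(
        list(df["sample_id"]), df["survival_time"].to_numpy(float), df["event"].to_numpy(int)
    )


def write_clinical_tsv(c: ClinicalTable, path) -> None:
    c.to_frame().to_csv(path, sep="\t", index=False)


def read_annotations_tsv(path) -> list[FeatureAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for rec in df.itertuples(index=False):
        region = getattr(rec, "region", "") or "NONE"
        if region not in REGION_TOKENS:
            raise ValueError(f"{path}: unknown region token {region!r}")
        out.append(
            FeatureAnnotation(
                feature_id=rec.feature_id,
                omics_name=rec.omics,
                region=REGION_TOKENS[region],
                gene_symbol=getattr(rec, "gene", "") or None,
            )
        )
    return out


def write_annotations_tsv(annotations: Sequence[FeatureAnnotation], path) -> None:
    inv = {v: k for k, v in REGION_TOKENS.items()}
    pd.DataFrame(
        {
            "feature_id": [a.feature_id for a in annotations],
            "gene": [a.gene_symbol or "" for a in annotations],
            "omics": [a.omics_name for a in annotations],
            "region": [inv[a.region] for a in annotations],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# alignment and preprocessing


def align_samples(
    matrices: Sequence[OmicsMatrix],
    clinical: ClinicalTable,
    annotations: Sequence[FeatureAnnotation] = (),
) -> MultiOmicsDataset:
    """Intersect samples across omics layers and the clinical table (sorted order)."""
    if not matrices:
        raise ValueError("need at least one omics matrix")
    common = set(matrices[0].sample_ids)
    for m in matrices[1:]:
        common &= set(m.sample_ids)
    common &= set(clinical.sample_ids)
    if not common:
        raise ValueError("no samples shared by all omics layers and the clinical table")
    samples = sorted(common)
    order = {name: i for i, name in enumerate(OMICS_ORDER)}
    aligned = []
    for m in sorted(matrices, key=lambda m: order[m.omics_name]):
        pos = {s: i for i, s in enumerate(m.sample_ids)}
        idx = [pos[s] for s in samples]
        aligned.append(OmicsMatrix(m.omics_name, samples, list(m.feature_ids), m.values[idx]))
    return MultiOmicsDataset(aligned, clinical.subset(samples), list(annotations))


def log_transform(m: OmicsMatrix) -> OmicsMatrix:
    """log2(x + 1) for expression layers (RNA / miRNA only)."""
    if m.omics_name not in ("RNA", "miRNA"):
        raise ValueError(f"log transform applies to RNA/miRNA, not {m.omics_name}")
    if m.values.size and np.nanmin(m.values) < 0:
        raise ValueError(f"{m.omics_name}: negative value encountered before log transform")
    return replace(m, values=np.log2(m.values + 1.0))


def impute_zero(m: OmicsMatrix) -> OmicsMatrix:
    return replace(m, values=np.nan_to_num(m.values, nan=0.0))


def variance_filter(m: OmicsMatrix, threshold: float = 0.2) -> OmicsMatrix:
    """Keep features with population variance strictly above ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    var = m.values.var(axis=0)  # ddof=0: population variance
    keep = var > threshold
    if not keep.any():
        raise ValueError(
            f"{m.omics_name}: variance filter at {threshold} removed every feature; lower the threshold"
        )
    feats = [f for f, k in zip(m.feature_ids, keep) if k]
    return OmicsMatrix(m.omics_name, list(m.sample_ids), feats, m.values[:, keep])


def zscore(m: OmicsMatrix) -> OmicsMatrix:
    """Standardise each feature to mean 0, population sd 1; constant columns -> 0."""
    mean = m.values.mean(axis=0)
    sd = m.values.std(axis=0)  # population sd
    safe = np.where(sd > 0, sd, 1.0)
    vals = (m.values - mean) / safe
    vals[:, sd == 0] = 0.0
    return replace(m, values=vals)


def preprocess_matrix(m: OmicsMatrix, variance_threshold: float = 0.2) -> OmicsMatrix:
    """Fixed pipeline: log (expression layers) -> zero fill -> variance filter -> z-score."""
    if m.omics_name in ("RNA", "miRNA"):
        m = log_transform(m)
    m = impute_zero(m)
    m = variance_filter(m, variance_threshold)
    return zscore(m)


def preprocess_dataset(ds: MultiOmicsDataset, variance_threshold: float = 0.2) -> MultiOmicsDataset:
    return MultiOmicsDataset(
        [preprocess_matrix(m, variance_threshold) for m in ds.omics],
        ds.clinical,
        ds.annotations,
    )


def build_combined(ds: MultiOmicsDataset) -> tuple[np.ndarray, dict[str, slice]]:
    """Early-integration concatenation (RNA, Mut, CNA, miRNA) with a block map.

    Returns the n_samples x D matrix and a map from omics name to its column
    slice, so importance mass can be attributed back to each layer.
    """
    blocks: dict[str, slice] = {}
    start = 0
    parts = []
    for m in ds.omics:
        blocks[m.omics_name] = slice(start, start + m.n_features)
        start += m.n_features
        parts.append(m.values)
    return np.hstack(parts), blocks


def combined_feature_ids(ds: MultiOmicsDataset) -> list[str]:
    out: list[str] = []
    for m in ds.omics:
        out.extend(m.feature_ids)
    return out


def omics_of_column(blocks: dict[str, slice], col: int) -> str:
    for name, sl in blocks.items():
        if sl.start <= col < sl.stop:
            return name
    raise IndexError(f"column {col} outside combined matrix")
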