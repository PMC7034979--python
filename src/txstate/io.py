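"""Tabular input/output for abundance matrices and sample metadata.

All tables are plain TSV: tab separated, UTF-8, ``.`` decimal separator, no
quoting. The abundance matrix is genes x samples with the gene-id column
labeled ``gene``; metadata carries one row per sample with columns
``sample_id``, ``driver_id``, ``cell_type_id``, ``replicate`` and
``sample_class`` (``cell_catalog`` or ``dissected``). Floats are written with
17 significant digits so a write/read round trip reproduces values exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

SAMPLE_CLASSES = ("cell_catalog", "dissected")
METADATA_COLUMNS = ("sample_id", "driver_id", "cell_type_id", "replicate", "sample_class")

_FLOAT_FORMAT = "%.17g"


@dataclass
class AbundanceMatrix:
    """Genes x samples matrix of relative transcript abundance (TPM).

    ``data`` is a float DataFrame indexed by gene id with sample ids as
    columns. Values must be finite and non-negative; gene and sample ids must
    be unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        values = df.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                raise ValueError("abundance values must be numeric")
            bad = ~np.isfinite(values)
            if bad.any():
                g, s = np.argwhere(bad)[0]
                raise ValueError(
                    f"non-finite abundance at gene {df.index[g]!r}, sample {df.columns[s]!r}"
                )
            neg = values < 0
            if neg.any():
                g, s = np.argwhere(neg)[0]
                raise ValueError(
                    f"negative abundance at gene {df.index[g]!r}, sample {df.columns[s]!r}"
                )
        self.data = df.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class SampleMetadata:
    """Per-sample annotations: driver, cell type, replicate and sample class."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"metadata is missing columns: {missing}")
        df = df.loc[:, list(METADATA_COLUMNS)].copy()
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in metadata: {dupes[:5]}")
        bad_class = ~df["sample_class"].isin(SAMPLE_CLASSES)
        if bad_class.any():
            raise ValueError(
                f"unknown sample_class values: {df.loc[bad_class, 'sample_class'].unique().tolist()}"
            )
        df["replicate"] = df["replicate"].astype(int)
        if (df["replicate"] < 1).any():
            raise ValueError("replicate indices must be >= 1")
        # drivers must map to a single cell type
        per_driver = df.groupby("driver_id")["cell_type_id"].nunique()
        conflicted = per_driver[per_driver > 1].index.tolist()
        if conflicted:
            raise ValueError(f"drivers mapped to multiple cell types: {conflicted}")
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def reordered(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        idx = self.table.set_index("sample_id")
        out = idx.loc[list(sample_ids)].reset_index()
        return SampleMetadata(out)

    def catalog_samples(self) -> list[str]:
        t = self.table
        return t.loc[t["sample_class"] == "cell_catalog", "sample_id"].tolist()

    def dissected_samples(self) -> list[str]:
        t = self.table
        return t.loc[t["sample_class"] == "dissected", "sample_id"].tolist()

    def driver_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["driver_id"]

    def cell_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["cell_type_id"]


@dataclass
class FilterReport:
    """Counts from a gene pre-filter pass."""

    n_input: int
    n_retained: int
    n_noncoding: int
    n_excluded: int
    n_below_min: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"retained {self.n_retained}/{self.n_input} genes "
            f"({self.n_noncoding} non-coding, {self.n_excluded} excluded, "
            f"{self.n_below_min} below the abundance cutoff)"
        )


def read_abundance(path: str | Path) -> AbundanceMatrix:
    """Read a genes x samples TSV with a leading ``gene`` column."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str}, float_precision="round_trip")
    first = df.columns[0]
    df = df.set_index(first)
    df.index.name = "gene"
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                gene = df.index[np.flatnonzero(bad)[0]]
                raise ValueError(
                    f"non-numeric abundance at gene {gene!r}, sample {col!r}"
                )
            df[col] = coerced
    return AbundanceMatrix(df)


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "driver_id": str, "cell_type_id": str})
    return SampleMetadata(df)


def read_inputs(abundance_path: str | Path, metadata_path: str | Path) -> tuple[AbundanceMatrix, SampleMetadata]:
    """Read and cross-validate the abundance matrix and sample metadata.

    The returned metadata rows are reordered to match the matrix columns.
    """
    matrix = read_abundance(abundance_path)
    metadata = read_metadata(metadata_path)
    matrix_samples = set(matrix.samples)
    meta_samples = set(metadata.sample_ids)
    missing_meta = sorted(matrix_samples - meta_samples)
    if missing_meta:
        raise ValueError(f"samples missing from metadata: {missing_meta}")
    missing_matrix = sorted(meta_samples - matrix_samples)
    if missing_matrix:
        raise ValueError(f"metadata samples absent from abundance matrix: {missing_matrix}")
    return matrix, metadata.reordered(matrix.samples)


def filter_genes(
    matrix: AbundanceMatrix,
    coding_genes: Iterable[str],
    min_tpm: float = 10.0,
    exclude: Iterable[str] = (),
    renormalize: bool = False,
) -> tuple[AbundanceMatrix, FilterReport]:
    """Keep protein-coding genes detected at ``min_tpm`` TPM in >= 1 sample.

    ``coding_genes`` is an explicit id list (annotation versions differ, so it
    is always a user input). ``exclude`` drops ids regardless (rRNA, spike-ins,
    constructs). ``renormalize`` rescales the remaining columns to one million
    total transcripts; it is off by default because in the source protocol the
    renormalization happened upstream of this filter.
    """
    if min_tpm < 0:
        raise ValueError("min_tpm must be >= 0")
    coding = set(coding_genes)
    excluded = set(exclude)
    df = matrix.data
    is_coding = df.index.isin(coding)
    is_excluded = df.index.isin(excluded)
    max_ab = df.to_numpy().max(axis=1) if df.shape[1] else np.zeros(len(df))
    high_enough = max_ab >= min_tpm
    keep = is_coding & ~is_excluded & high_enough
    report = FilterReport(
        n_input=len(df),
        n_retained=int(keep.sum()),
        n_noncoding=int((~is_coding).sum()),
        n_excluded=int((is_coding & is_excluded).sum()),
        n_below_min=int((is_coding & ~is_excluded & ~high_enough).sum()),
    )
    out = df.loc[keep].copy()
    if report.n_retained == 0:
        warnings.warn("gene filter removed every gene; returning an empty matrix")
    if renormalize and out.shape[0]:
        sums = out.sum(axis=0)
        zero = sums == 0
        if zero.any():
            warnings.warn(
                f"columns with zero total abundance left unscaled: {list(sums.index[zero])}"
            )
        scale = np.where(zero, 1.0, 1e6 / sums.to_numpy())
        out = out * scale
    return AbundanceMatrix(out), report


def write_abundance(matrix: AbundanceMatrix, path: str | Path) -> None:
    _write_frame(matrix.data, path, index_label="gene")


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.table.to_csv(path, sep="\t", index=False)


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "gene") -> None:
    """Write a generic genes x units table (probabilities, states, coefficients)."""
    _write_frame(df, path, index_label=index_label)


def read_matrix(path: str | Path, numeric: bool = True) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=0,
        dtype={0: str},
        na_values=["NA"],
        keep_default_na=numeric,
        float_precision="round_trip",
    )
    df = df.set_index(df.columns[0])
    return df


def _write_frame(df: pd.DataFrame, path: str | Path, index_label: str) -> None:
    df.to_csv(
        path,
        sep="\t",
        index=True,
        index_label=index_label,
        float_format=_FLOAT_FORMAT,
        na_rep="NA",
    )
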