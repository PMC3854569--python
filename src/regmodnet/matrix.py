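"""Expression matrices: loading, RPKM-style normalization, log transform.

The pipeline works on a genes × conditions matrix that moves through three
scales: raw read counts, reads per kilobase of gene model per million mapped
reads (RPKM-style), and natural-log expression.  The ``scale_tag`` attribute
tracks which scale a matrix is on so downstream stages can refuse input on
the wrong scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SCALE_COUNTS = "counts"
SCALE_NORMALIZED = "normalized"
SCALE_LOG = "log"
_SCALES = (SCALE_COUNTS, SCALE_NORMALIZED, SCALE_LOG)


@dataclass
class GeneMeta:
    """Per-gene metadata: gene-model length and transcription-factor status."""

    gene_id: str
    length_bp: int
    is_tf: bool = False
    tf_family: str = ""

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"gene {self.gene_id!r}: length_bp must be > 0")
        if self.tf_family and not self.is_tf:
            raise ValueError(f"gene {self.gene_id!r}: tf_family set on non-TF")


@dataclass
class ExpressionMatrix:
    """Genes × conditions expression values with a scale tag.

    Parameters
    ----------
    data
        DataFrame with gene ids on the index and condition ids on the
        columns.  Ordering is preserved everywhere.
    scale_tag
        One of ``counts``, ``normalized`` or ``log``.  Counts and
        normalized values must be non-negative; log values may be any real.
    """

    data: pd.DataFrame
    scale_tag: str = SCALE_COUNTS

    def __post_init__(self) -> None:
        if self.scale_tag not in _SCALES:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate condition ids: {dups}")
        vals = self.data.to_numpy()
        if vals.size and not np.issubdtype(vals.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if self.scale_tag in (SCALE_COUNTS, SCALE_NORMALIZED) and vals.size:
            if np.nanmin(vals) < 0:
                raise ValueError(f"{self.scale_tag} values must be >= 0")

    # -- accessors ---------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.data.shape[1]

    def row(self, gene_id: str) -> np.ndarray:
        return self.data.loc[gene_id].to_numpy(dtype=float)

    def subset(
        self,
        genes: Sequence[str] | None = None,
        conditions: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        df = self.data
        if genes is not None:
            missing = [g for g in genes if g not in df.index]
            if missing:
                raise KeyError(f"genes absent from matrix: {missing[:5]}")
            df = df.loc[list(genes)]
        if conditions is not None:
            missing = [c for c in conditions if c not in df.columns]
            if missing:
                raise KeyError(f"conditions absent from matrix: {missing[:5]}")
            df = df[list(conditions)]
        return ExpressionMatrix(df.copy(), self.scale_tag)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id")


def load_counts(path: str | Path) -> ExpressionMatrix:
    """Read a tab-delimited raw count table (gene ids × condition header).

    Non-numeric cells and duplicated identifiers are hard errors; an empty
    data section yields a valid 0-gene matrix.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{path}: non-numeric count at gene {row!r}, condition {col!r}"
            )
        out[col] = converted
    if out.size:
        out = out.astype(float)
    return ExpressionMatrix(out, SCALE_COUNTS)


def load_gene_meta(path: str | Path) -> dict[str, GeneMeta]:
    """Read a gene metadata TSV: gene_id, length_bp[, is_tf[, tf_family]]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta: dict[str, GeneMeta] = {}
    cols = list(df.columns)
    for _, rec in df.iterrows():
        gid = str(rec[cols[0]])
        length = int(rec[cols[1]])
        is_tf = False
        fam = ""
        if len(cols) > 2 and not pd.isna(rec[cols[2]]):
            is_tf = str(rec[cols[2]]).strip().lower() in ("1", "true", "yes")
        if len(cols) > 3 and not pd.isna(rec[cols[3]]):
            fam = str(rec[cols[3]]).strip()
        if gid in meta:
            raise ValueError(f"duplicate gene id in metadata: {gid!r}")
        meta[gid] = GeneMeta(gid, length, is_tf, fam)
    return meta


def rpkm_normalize(
    counts: ExpressionMatrix,
    meta: Mapping[str, GeneMeta],
    library_sizes: Mapping[str, float] | None = None,
) -> ExpressionMatrix:
    """Normalize raw counts to reads per KB of gene per million mapped reads.

    value = count / (length_bp / 1000) / (library_size / 1e6).  When
    ``library_sizes`` is omitted the per-condition column totals of the raw
    count matrix are used.
    """
    if counts.scale_tag != SCALE_COUNTS:
        raise ValueError("rpkm_normalize expects a counts-scale matrix")
    missing = [g for g in counts.gene_ids if g not in meta]
    if missing:
        raise ValueError(f"missing gene lengths for: {missing[:10]}")
    if library_sizes is None:
        library_sizes = counts.data.sum(axis=0).to_dict()
    missing_lib = [
        c
        for c in counts.condition_ids
        if c not in library_sizes or library_sizes[c] <= 0
    ]
    if missing_lib:
        raise ValueError(f"missing/invalid library sizes for: {missing_lib[:10]}")
    lengths_kb = np.array(
        [meta[g].length_bp / 1000.0 for g in counts.gene_ids], dtype=float
    )
    lib_mb = np.array(
        [library_sizes[c] / 1e6 for c in counts.condition_ids], dtype=float
    )
    vals = counts.values / lengths_kb[:, None] / lib_mb[None, :]
    df = pd.DataFrame(vals, index=counts.gene_ids, columns=counts.condition_ids)
    return ExpressionMatrix(df, SCALE_NORMALIZED)


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Natural-log transform: ln(value + pseudocount)."""
    if m.scale_tag != SCALE_NORMALIZED:
        raise ValueError("log_transform expects a normalized-scale matrix")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    vals = m.values
    if vals.size and np.nanmin(vals) < 0:
        raise ValueError("negative expression value before log transform")
    shifted = vals + pseudocount
    if shifted.size and np.nanmin(shifted) <= 0:
        raise ValueError("log of non-positive value (zero value, zero pseudocount)")
    df = pd.DataFrame(
        np.log(shifted), index=m.gene_ids, columns=m.condition_ids
    )
    return ExpressionMatrix(df, SCALE_LOG)
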