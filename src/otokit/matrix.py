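"""Core data containers and file I/O.

The central object is :class:`ExpressionMatrix`, a genes-by-cells grid of
relative transcript abundances with a units tag tracking where the matrix
sits in the processing chain:

``TPM``
    raw relative abundance (transcripts per million, as estimated upstream);
``nTPM``
    TPM after cross-sample median-of-ratios normalization;
``log2nTPM``
    normalized abundance after limit-of-detection thresholding and log2
    transform, where 0 means "below LOD".

Files are plain text: tab-separated tables (genes in rows, first column the
gene id, header row of cell ids) or MatrixMarket coordinate files with
``genes.tsv`` / ``cells.tsv`` sidecars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

UNITS = ("TPM", "nTPM", "log2nTPM")


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


class UnitsError(ValidationError):
    """Raised when an operation receives a matrix in the wrong units."""


@dataclass
class ExpressionMatrix:
    """Gene x cell abundance grid with named axes and a units tag.

    ``values`` is a :class:`pandas.DataFrame` with gene ids on the index and
    cell ids on the columns. Entries are non-negative; for ``log2nTPM``
    matrices a 0 means the measurement fell below the limit of detection.
    """

    values: pd.DataFrame
    units: str = "TPM"

    def __post_init__(self) -> None:
        if self.units not in UNITS:
            raise UnitsError(f"unknown units {self.units!r}; expected one of {UNITS}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate cell ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if arr.size and np.nanmin(arr) < 0:
            raise ValidationError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def cell_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset(self, genes=None, cells=None) -> "ExpressionMatrix":
        df = self.values
        if genes is not None:
            missing = set(map(str, genes)) - set(df.index)
            if missing:
                raise KeyError(f"genes not in matrix: {sorted(missing)[:5]}")
            df = df.loc[list(map(str, genes))]
        if cells is not None:
            missing = set(map(str, cells)) - set(df.columns)
            if missing:
                raise KeyError(f"cells not in matrix: {sorted(missing)[:5]}")
            df = df[list(map(str, cells))]
        return ExpressionMatrix(df.copy(), self.units)


def require_units(matrix: ExpressionMatrix, *allowed: str) -> None:
    if matrix.units not in allowed:
        raise UnitsError(
            f"operation requires units in {allowed}, got {matrix.units!r}"
        )


# ---------------------------------------------------------------------------
# matrix I/O
# ---------------------------------------------------------------------------

def read_expression_matrix(path, format: str = "tsv", units: str = "TPM") -> ExpressionMatrix:
    """Read a genes-by-cells matrix from a TSV table or MatrixMarket triplet.

    For ``format="mtx"`` the row and column names are read from ``genes.tsv``
    and ``cells.tsv`` next to the matrix file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except (pd.errors.ParserError, ValueError) as exc:
            raise ValidationError(f"malformed TSV {path}: {exc}") from exc
        bad = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
        if len(df) and len(bad):
            for col in bad:
                coerced = pd.to_numeric(df[col], errors="coerce")
                failed = coerced.isna() & df[col].notna()
                if failed.any():
                    line = df.index.get_loc(failed.idxmax()) + 2  # header is line 1
                    raise ValidationError(
                        f"malformed TSV {path}: non-numeric value in column "
                        f"{col!r} at line {line}"
                    )
                df[col] = coerced
        return ExpressionMatrix(df, units)
    if format == "mtx":
        genes_path = path.parent / "genes.tsv"
        cells_path = path.parent / "cells.tsv"
        for side in (genes_path, cells_path):
            if not side.exists():
                raise FileNotFoundError(f"missing sidecar {side}")
        mat = scipy.io.mmread(path)
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str)
        cells = pd.read_csv(cells_path, sep="\t", header=None)[0].astype(str)
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        if dense.shape != (len(genes), len(cells)):
            raise ValidationError(
                f"matrix shape {dense.shape} does not match sidecars "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
        return ExpressionMatrix(pd.DataFrame(dense, index=genes, columns=cells), units)
    raise ValueError(f"unknown format {format!r}")


def write_expression_matrix(matrix: ExpressionMatrix, path, format: str = "tsv") -> None:
    """Write a matrix readable back by :func:`read_expression_matrix`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        out = matrix.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.17g")
        return
    if format == "mtx":
        sparse = scipy.sparse.coo_matrix(matrix.to_numpy())
        scipy.io.mmwrite(str(path), sparse)
        pd.Series(matrix.gene_ids).to_csv(path.parent / "genes.tsv", sep="\t", header=False, index=False)
        pd.Series(matrix.cell_ids).to_csv(path.parent / "cells.tsv", sep="\t", header=False, index=False)
        return
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# cell annotation
# ---------------------------------------------------------------------------

REQUIRED_ANNOTATION_COLUMNS = ("cell_id", "organ", "batch")


def validate_cell_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Check the per-cell metadata table and index it by cell id."""
    if "cell_id" in ann.columns:
        ann = ann.set_index("cell_id")
    ann.index = ann.index.astype(str)
    for col in ("organ", "batch"):
        if col not in ann.columns:
            raise ValidationError(f"annotation missing required column {col!r}")
    if ann.index.has_duplicates:
        dups = ann.index[ann.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate cell ids in annotation: {dups[:5]}")
    if ann["batch"].isna().any() or (ann["batch"].astype(str) == "").any():
        raise ValidationError("batch must be non-empty for every cell")
    return ann


def read_cell_annotation(path) -> pd.DataFrame:
    """Read a per-cell annotation TSV (required columns: cell_id, organ, batch)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ann = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "batch": str})
    missing = [c for c in REQUIRED_ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValidationError(f"annotation missing required columns: {missing}")
    return validate_cell_annotation(ann)


def write_cell_annotation(ann: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = ann.copy()
    out.index.name = "cell_id"
    out.to_csv(path, sep="\t")


def join_annotation(matrix: ExpressionMatrix, ann: pd.DataFrame) -> pd.DataFrame:
    """Align an annotation table to a matrix's cells, in matrix cell order."""
    missing = [c for c in matrix.cell_ids if c not in ann.index]
    if missing:
        raise ValidationError(f"annotation missing cells: {missing[:10]}")
    return ann.loc[matrix.cell_ids]
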