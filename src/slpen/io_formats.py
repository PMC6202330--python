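"""Tabular I/O for dependency-screen analysis.

The pipeline's substrate is a gene x cell-line table of real-valued
depletion Z scores (zGARP-, RSA- or DEMETER-like), read and written as
TSV — the dialect used by the published screen supplementary tables.
Comma dialects are rejected, not guessed. Missing cells may be encoded
as ``NA``, ``NaN`` or the empty string (the union of conventions across
the public screen exports).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING_TOKENS = ["NA", "NaN", ""]

#: canonical column order of a result table; readers and writers both use it
RESULT_COLUMNS = [
    "gene",
    "n_def",
    "n_not",
    "median_def",
    "median_not",
    "diff",
    "p",
    "q",
    "slp",
    "slc",
    "pass_p",
    "pass_median_def",
    "pass_median_not",
    "hit",
]

SCORE_KINDS = {"zgarp", "rsa", "demeter", "generic_z"}


class TableFormatError(ValueError):
    """Raised when an input table violates the expected layout."""


@dataclass
class GeneScoreMatrix:
    """Gene x cell-line matrix of depletion Z scores.

    Genes are rows, cell lines are columns. Missing entries are NaN;
    every non-missing entry must be finite.
    """

    scores: pd.DataFrame
    score_kind: str = "generic_z"

    def __post_init__(self) -> None:
        if self.score_kind not in SCORE_KINDS:
            raise ValueError(
                f"unknown score_kind {self.score_kind!r}; expected one of {sorted(SCORE_KINDS)}"
            )
        if self.scores.index.duplicated().any():
            dups = self.scores.index[self.scores.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate gene identifiers: {dups}")
        if self.scores.columns.duplicated().any():
            dups = self.scores.columns[self.scores.columns.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate cell-line identifiers: {dups}")
        values = self.scores.to_numpy(dtype=float, copy=False)
        bad = np.isinf(values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise TableFormatError(
                f"non-finite score at gene {self.scores.index[i]!r}, "
                f"line {self.scores.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def line_ids(self) -> list[str]:
        return list(self.scores.columns)

    def row(self, gene_id: str) -> pd.Series:
        """Scores for one gene across all lines (NaN where missing)."""
        if gene_id not in self.scores.index:
            raise KeyError(f"gene {gene_id!r} not in matrix")
        return self.scores.loc[gene_id]

    def subset_lines(self, line_ids: Sequence[str]) -> "GeneScoreMatrix":
        missing = [l for l in line_ids if l not in self.scores.columns]
        if missing:
            raise KeyError(f"lines not in matrix: {missing}")
        return GeneScoreMatrix(self.scores[list(line_ids)], self.score_kind)


@dataclass
class AnnotationTable:
    """Per-sample attribute table (status labels, histology, omics values)."""

    data: pd.DataFrame  # indexed by unique sample id

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate sample identifiers: {dups}")

    @property
    def line_ids(self) -> list[str]:
        return list(self.data.index)

    def column(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"attribute {name!r} not in annotation table")
        return self.data[name]


def read_gene_score_table(
    path: str | Path,
    score_kind: str = "generic_z",
    transpose: bool = False,
) -> GeneScoreMatrix:
    """Read a TSV of gene x cell-line scores.

    The header row holds cell-line identifiers; the first column holds
    gene identifiers. ``transpose=True`` reads a lines x genes layout
    instead (no auto-detection is attempted).
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=MISSING_TOKENS,
            keep_default_na=False,
            dtype=str,
        )
    except pd.errors.EmptyDataError as exc:
        raise TableFormatError(f"{path}: empty file") from exc
    if df.columns.size == 0:
        raise TableFormatError(f"{path}: no cell-line columns in header")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise TableFormatError(f"{path}: duplicate gene rows: {dups}")
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise TableFormatError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}: {df.loc[row, col]!r}"
            )
        numeric[col] = converted
    if transpose:
        numeric = numeric.T
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    numeric.index.name = None
    numeric.columns.name = None
    return GeneScoreMatrix(numeric, score_kind)


def write_gene_score_table(matrix: GeneScoreMatrix, path: str | Path) -> None:
    matrix.scores.to_csv(path, sep="\t", na_rep="NA", index_label="gene")


def read_annotation_table(path: str | Path) -> AnnotationTable:
    """Read a TSV of per-sample attributes; first column is the sample id.

    String attributes are preserved verbatim; columns that parse as
    numeric become numeric with NaN for missing tokens.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=MISSING_TOKENS,
            keep_default_na=False,
        )
    except pd.errors.EmptyDataError as exc:
        raise TableFormatError(f"{path}: empty file") from exc
    df.index = df.index.astype(str)
    return AnnotationTable(df)


def write_annotation_table(table: AnnotationTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")


def _validate_result_table(results: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise TableFormatError(f"result table missing columns: {missing}")
    if results["gene"].duplicated().any():
        dups = results.loc[results["gene"].duplicated(), "gene"].tolist()
        raise TableFormatError(f"duplicate genes in result table: {dups}")
    p = results["p"].dropna()
    if ((p <= 0) | (p > 1)).any():
        raise TableFormatError("p-values outside (0, 1]")
    for col in ("slp", "slc"):
        v = results[col].dropna()
        if ((v < 0) | (v > 100)).any():
            raise TableFormatError(f"{col} outside [0, 100]")
    return results[RESULT_COLUMNS]


def write_result_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write per-gene pipeline outputs as TSV in the canonical column order.

    Floats are serialised to 6 significant digits; booleans as
    ``True``/``False``; undefined SLC and untested p as ``NA``.
    """
    out = _validate_result_table(results)
    out.to_csv(path, sep="\t", na_rep="NA", index=False, float_format="%.6g")


def read_result_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", na_values=MISSING_TOKENS, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise TableFormatError(f"{path}: empty file") from exc
    for col in ("pass_p", "pass_median_def", "pass_median_not", "hit"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False})
    return _validate_result_table(df)
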