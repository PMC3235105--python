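"""Plain-text readers and writers for the pipeline's tabular formats.

All formats are TSV. The expression matrix is genes-as-rows with a header
row of array ids and an index column labelled ``gene``; floats are written
with Python's shortest round-trip representation so a write/read cycle is
lossless on the decimal text.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .core import DataError, validate_sheet


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_expression(path: str | Path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col="gene")
    if matrix.index.duplicated().any():
        raise DataError(f"duplicate gene ids in {path}")
    if matrix.columns.duplicated().any():
        raise DataError(f"duplicate array ids in {path}")
    return matrix


def write_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"array_id": str, "tissue": str, "stage": str})
    return validate_sheet(sheet)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index_label="gene")


def read_truth(path: str | Path) -> pd.DataFrame:
    # pattern bitstrings like "00000" must stay strings, never integers or NaN
    truth = pd.read_csv(
        path, sep="\t", index_col="gene", dtype={"pattern": str, "identity": str},
        keep_default_na=False, na_values=[],
    )
    truth["class_id"] = truth["class_id"].astype(int)
    truth["effect_log2fc"] = truth["effect_log2fc"].astype(float)
    return truth


def write_probe_map(probe_map: pd.Series, path: str | Path) -> None:
    """Probe→gene map as a two-column TSV (probe_id, gene)."""
    probe_map.rename("gene").to_csv(path, sep="\t", index_label="probe_id")


def read_probe_map(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", index_col="probe_id")
    if frame.index.duplicated().any():
        raise DataError(f"probe ids map to more than one gene in {path}")
    return frame["gene"]


def read_gene_list(path: str | Path) -> set[str]:
    """One-gene-per-line text file (e.g. a phenotype gene list)."""
    with open(path) as handle:
        return {line.strip() for line in handle if line.strip()}
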