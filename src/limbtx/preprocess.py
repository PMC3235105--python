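"""Normalization, probe summarization and blemish repair.

This is the computable core of the RMA protocol on log2-scale intensities:
quantile normalization (every array is forced onto the common distribution
of row-wise means of the sorted columns) followed by Tukey median-polish
summarization of each gene's probe-by-array submatrix. The convolution
background-correction step of full RMA is deliberately omitted — inputs
here are already log2-scale intensities.

Blemish repair replaces flagged cells of one array with the median of the
same gene across the array's replicate group, the generic form of
correcting a localized artifact on a single chip.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import DataError, group_arrays, validate_sheet


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean of the sorted columns.

    After normalization each column's sorted values equal the reference
    vector (row-wise means of the sorted input columns) and the original
    within-column rank order is preserved. Tied values within a column
    receive the mean of the reference values at the ranks they occupy.
    """
    if matrix.shape[1] < 2:
        raise DataError("quantile normalization needs >= 2 arrays")
    values = matrix.to_numpy(float)
    if not np.isfinite(values).all():
        raise DataError("expression matrix contains non-finite values")
    n = values.shape[0]
    reference = np.sort(values, axis=0).mean(axis=1)
    ref_cumsum = np.concatenate(([0.0], np.cumsum(reference)))
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        # boundaries of runs of tied values in the sorted column
        starts = np.flatnonzero(np.r_[True, sorted_col[1:] != sorted_col[:-1]])
        ends = np.r_[starts[1:], n]
        seg_mean = (ref_cumsum[ends] - ref_cumsum[starts]) / (ends - starts)
        assigned = np.repeat(seg_mean, ends - starts)
        out[order, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def median_polish(submatrix: np.ndarray, max_iter: int = 10, tol: float = 1e-6
                  ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish of one probes-by-arrays submatrix.

    Alternates subtracting row medians and column medians from the
    residuals until both are below ``tol`` or ``max_iter`` sweeps; the
    medians of the accumulated row/column effects are folded into the
    overall effect. Returns (overall, row_effects, col_effects, residuals).
    """
    residuals = np.asarray(submatrix, float).copy()
    if residuals.ndim != 2 or residuals.size == 0:
        raise DataError("median polish needs a non-empty 2-D submatrix")
    overall = 0.0
    row_eff = np.zeros(residuals.shape[0])
    col_eff = np.zeros(residuals.shape[1])
    for _ in range(max_iter):
        row_med = np.median(residuals, axis=1)
        row_eff += row_med
        residuals -= row_med[:, None]
        delta = np.median(col_eff)
        overall += delta
        col_eff -= delta
        col_med = np.median(residuals, axis=0)
        col_eff += col_med
        residuals -= col_med[None, :]
        delta = np.median(row_eff)
        overall += delta
        row_eff -= delta
        if np.abs(row_med).max() < tol and np.abs(col_med).max() < tol:
            break
    return overall, row_eff, col_eff, residuals


def median_polish_summarize(
    probe_matrix: pd.DataFrame,
    probe_map: pd.Series,
    max_iter: int = 10,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Summarize probe-level log2 intensities to one value per gene and array.

    Each gene's probes-by-arrays submatrix is median-polished and the gene's
    expression on an array is the overall effect plus that array's column
    effect (probe affinities are absorbed by the row effects).
    """
    missing = set(probe_matrix.index) - set(probe_map.index)
    if missing:
        raise DataError(f"{len(missing)} probes have no gene mapping, "
                        f"e.g. {sorted(missing)[:5]}")
    gene_order: list[str] = []
    seen = set()
    for probe in probe_matrix.index:
        gene = probe_map[probe]
        if gene not in seen:
            seen.add(gene)
            gene_order.append(gene)
    mapped = probe_map.loc[probe_matrix.index]
    probes_of = {gene: idx.tolist() for gene, idx in mapped.groupby(mapped).groups.items()}
    rows = []
    for gene in gene_order:
        probes = probes_of.get(gene, [])
        if len(probes) == 0:
            raise DataError(f"gene {gene!r} has zero probes")
        overall, _, col_eff, _ = median_polish(
            probe_matrix.loc[probes].to_numpy(float), max_iter=max_iter, tol=tol
        )
        rows.append(overall + col_eff)
    return pd.DataFrame(
        np.vstack(rows), index=pd.Index(gene_order, name="gene"),
        columns=probe_matrix.columns,
    )


def repair_blemish(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    flagged_array: str,
    flagged_genes,
) -> pd.DataFrame:
    """Replace flagged cells of one array by the replicate-group median.

    The reference is the median of the same gene across the other arrays of
    the flagged array's (tissue, stage) group. All other cells are untouched,
    and re-running the repair is a no-op.
    """
    validate_sheet(sheet)
    if flagged_array not in matrix.columns:
        raise DataError(f"array {flagged_array!r} not in the expression matrix")
    row = sheet.loc[sheet["array_id"] == flagged_array]
    if row.empty:
        raise DataError(f"array {flagged_array!r} not in the sample sheet")
    tissue, stage = row["tissue"].iloc[0], row["stage"].iloc[0]
    replicates = [a for a in group_arrays(sheet, tissue, stage) if a != flagged_array]
    replicates = [a for a in replicates if a in matrix.columns]
    if not replicates:
        raise DataError(f"array {flagged_array!r} has no replicate to repair against")
    flagged_genes = [g for g in flagged_genes]
    unknown = set(flagged_genes) - set(matrix.index)
    if unknown:
        raise DataError(f"flagged genes not in matrix: {sorted(unknown)[:5]}")
    repaired = matrix.copy()
    if flagged_genes:
        reference = matrix.loc[flagged_genes, replicates].median(axis=1)
        repaired.loc[flagged_genes, flagged_array] = reference
    return repaired
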