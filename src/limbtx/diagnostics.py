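"""Self-diagnostic analyses: per-gene z-normalization, Wilcoxon rank-sum
false-negative analysis against a phenotype gene list, and low-expression
flagging.

Comparing limb samples to whole-embryo controls misses genes expressed at
very low limb levels (they never clear the fold-change threshold even when
biologically essential). These diagnostics quantify that blind spot: the
rank-sum comparison asks whether known phenotype genes that were *not*
called up sit lower in the limb expression distribution, and the
low-expression screen flags genes whose mean limb expression stays below a
floor at every stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (STAGES, WHOLE_EMBRYO, DataError, limb_arrays,
                   validate_sheet)

logger = logging.getLogger(__name__)

EXACT_WILCOXON_MAX_N = 12


def z_normalize(matrix: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Center and scale each gene so its across-array mean is 0 and sd is 1.

    Population sd (ddof=0) by default, so a two-array gene maps to (-1, +1);
    set ddof=1 for the sample-sd convention. Constant genes cannot be scaled
    and are dropped with a logged list.
    """
    if matrix.shape[1] < 2:
        raise DataError("z-normalization needs >= 2 arrays")
    values = matrix.to_numpy(float)
    sd = values.std(axis=1, ddof=ddof)
    constant = sd == 0
    if constant.all():
        raise DataError("every gene is constant across arrays; nothing to normalize")
    if constant.any():
        dropped = matrix.index[constant].tolist()
        logger.warning("z-normalize: dropped %d constant genes (first few: %s)",
                       len(dropped), dropped[:5])
    keep = ~constant
    z = (values[keep] - values[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns)


def group_mean_profiles(z: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Mean z-score per gene for every (tissue, stage) replicate group.

    Columns are a MultiIndex (tissue, stage); used to inspect whether an
    apparently oscillating limb profile is driven by the limb samples or by
    dips in the whole-embryo control.
    """
    validate_sheet(sheet)
    groups = sheet.groupby(["tissue", "stage"])["array_id"].agg(list)
    data = {}
    for (tissue, stage), arrays in groups.items():
        arrays = [a for a in arrays if a in z.columns]
        if not arrays:
            raise DataError(f"group ({tissue}, {stage}) has no arrays in the matrix")
        data[(tissue, stage)] = z[arrays].mean(axis=1)
    out = pd.DataFrame(data)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["tissue", "stage"])
    return out


def _exact_wilcoxon_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum p by enumerating the null distribution of W.

    Midranks handle ties; the distribution of the x rank-sum over all
    C(n, n_x) equally likely rank assignments is built by dynamic
    programming over doubled (integer) midranks. Two-sided p doubles the
    smaller tail, capped at 1.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    doubled = np.rint(2 * ranks).astype(int)  # midranks are multiples of 1/2
    n, nx = len(pooled), len(x)
    w_obs = int(doubled[:nx].sum())
    # dp[(count, sum)] = number of subsets of given size and doubled-rank sum
    dp: dict[tuple[int, int], int] = {(0, 0): 1}
    for r in doubled:
        updates = {}
        for (c, s), ways in dp.items():
            if c < nx:
                key = (c + 1, s + r)
                updates[key] = updates.get(key, 0) + ways
        for key, ways in updates.items():
            dp[key] = dp.get(key, 0) + ways
    dist = {s: ways for (c, s), ways in dp.items() if c == nx}
    total = sum(dist.values())
    lower = sum(w for s, w in dist.items() if s <= w_obs) / total
    upper = sum(w for s, w in dist.items() if s >= w_obs) / total
    return float(ranks[:nx].sum()), min(1.0, 2.0 * min(lower, upper))


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p).

    W is the midrank sum of ``x``. Exact enumeration (tie-aware) when
    n_x + n_y <= 12, otherwise the normal approximation with tie-corrected
    variance and continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise DataError("both samples must be non-empty")
    if x.size + y.size <= EXACT_WILCOXON_MAX_N:
        return _exact_wilcoxon_p(x, y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = float(ranks[: x.size].sum())
    if np.ptp(np.concatenate([x, y])) == 0:
        return w, 1.0  # all values tied: no evidence either way
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return w, float(res.pvalue)


@dataclass
class FalseNegativeReport:
    """Counts and rank-sum comparisons for a phenotype gene list."""

    n_phenotype: int
    n_on_array: int
    n_up: int
    up_fraction: float
    #: (W, p) comparing limb expression of not-up vs up phenotype genes
    limb_notup_vs_up: tuple[float, float]
    #: same comparison on whole-embryo expression
    we_notup_vs_up: tuple[float, float]
    #: (W, p) comparing limb expression of not-up phenotype genes vs all genes
    limb_notup_vs_all: tuple[float, float]
    we_notup_vs_all: tuple[float, float]
    #: per-group quantiles of mean limb / whole-embryo expression, for plotting
    summaries: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("n_phenotype", self.n_phenotype), ("n_on_array", self.n_on_array),
            ("n_up", self.n_up), ("up_fraction", self.up_fraction),
            ("limb_notup_vs_up_W", self.limb_notup_vs_up[0]),
            ("limb_notup_vs_up_p", self.limb_notup_vs_up[1]),
            ("we_notup_vs_up_W", self.we_notup_vs_up[0]),
            ("we_notup_vs_up_p", self.we_notup_vs_up[1]),
            ("limb_notup_vs_all_W", self.limb_notup_vs_all[0]),
            ("limb_notup_vs_all_p", self.limb_notup_vs_all[1]),
            ("we_notup_vs_all_W", self.we_notup_vs_all[0]),
            ("we_notup_vs_all_p", self.we_notup_vs_all[1]),
        ]
        return pd.DataFrame(rows, columns=["metric", "value"])


def false_negative_report(
    de: pd.DataFrame, matrix: pd.DataFrame, sheet: pd.DataFrame, phenotype_genes
) -> FalseNegativeReport:
    """How many known phenotype genes the limb-vs-control screen recovers,
    and whether the missed ones simply sit low in the limb.

    "Up" means called up in at least one limb-vs-whole-embryo contrast.
    Expression per gene is the mean over all limb arrays (resp. all
    whole-embryo arrays).
    """
    validate_sheet(sheet)
    phenotype_genes = set(phenotype_genes)
    on_array = phenotype_genes & set(matrix.index)
    if not on_array:
        raise DataError("phenotype gene list shares no genes with the array")
    limb_vs_we = de[de["contrast"].str.contains("_vs_WE@")]
    up_genes = set(limb_vs_we.loc[limb_vs_we["call"] == "up", "gene"])
    up_phen = sorted(on_array & up_genes)
    notup_phen = sorted(on_array - up_genes)
    limb_cols = limb_arrays(sheet)
    we_cols = sheet.loc[sheet["tissue"] == WHOLE_EMBRYO, "array_id"].tolist()
    limb_expr = matrix[limb_cols].mean(axis=1)
    we_expr = matrix[we_cols].mean(axis=1)

    def compare(expr: pd.Series, group_a, group_b) -> tuple[float, float]:
        if not len(group_a) or not len(group_b):
            return (math.nan, math.nan)
        return wilcoxon_rank_sum(expr.loc[list(group_a)], expr.loc[list(group_b)])

    quantiles = (0.05, 0.25, 0.5, 0.75, 0.95)
    summaries = pd.DataFrame({
        ("limb", "all"): limb_expr.quantile(quantiles),
        ("limb", "phenotype_up"): limb_expr.loc[up_phen].quantile(quantiles),
        ("limb", "phenotype_not_up"): limb_expr.loc[notup_phen].quantile(quantiles),
        ("whole_embryo", "all"): we_expr.quantile(quantiles),
        ("whole_embryo", "phenotype_up"): we_expr.loc[up_phen].quantile(quantiles),
        ("whole_embryo", "phenotype_not_up"): we_expr.loc[notup_phen].quantile(quantiles),
    })
    summaries.columns = pd.MultiIndex.from_tuples(summaries.columns,
                                                  names=["compartment", "group"])
    return FalseNegativeReport(
        n_phenotype=len(phenotype_genes),
        n_on_array=len(on_array),
        n_up=len(up_phen),
        up_fraction=len(up_phen) / len(on_array),
        limb_notup_vs_up=compare(limb_expr, notup_phen, up_phen),
        we_notup_vs_up=compare(we_expr, notup_phen, up_phen),
        limb_notup_vs_all=compare(limb_expr, notup_phen, matrix.index),
        we_notup_vs_all=compare(we_expr, notup_phen, matrix.index),
        summaries=summaries,
    )


def low_expression_flags(
    matrix: pd.DataFrame, sheet: pd.DataFrame, threshold: float = 5.0
) -> set[str]:
    """Genes whose mean limb log2 expression is below ``threshold`` at
    every stage (candidates invisible to the fold-change screen)."""
    validate_sheet(sheet)
    stage_means = {}
    for stage in STAGES:
        arrays = limb_arrays(sheet, stages=[stage])
        if not arrays:
            raise DataError(f"no limb arrays at stage {stage}")
        stage_means[stage] = matrix[arrays].mean(axis=1)
    below = pd.DataFrame(stage_means) < threshold
    return set(matrix.index[below.all(axis=1)])
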