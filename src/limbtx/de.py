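"""Empirical-Bayes moderated-t differential expression for two-group contrasts.

Each contrast compares two replicate groups (limb vs time-matched whole
embryo, or forelimb vs hindlimb) on the log2 scale. Per gene g the
two-group linear model gives the mean difference (log2 fold change), the
pooled residual variance s_g^2 on d_g = n_A + n_B - 2 degrees of freedom,
and the contrast variance factor v_g = 1/n_A + 1/n_B.

The gene variances are shrunk toward a common prior. Under the hierarchical
model s_g^2 | sigma_g^2 ~ sigma_g^2 chi2_{d_g}/d_g with
sigma_g^2 ~ s_0^2 d_0 / chi2_{d_0}, the posterior variance is

    s_post^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g)

and t_mod = log2fc / sqrt(s_post^2 v_g) follows a Student t with
d_0 + d_g degrees of freedom. The hyperparameters (d_0, s_0^2) are
estimated by matching moments of e_g = log s_g^2:

    var(e_g)  = trigamma(d_g/2) + trigamma(d_0/2)
    mean(e_g) = log s_0^2 + [digamma(d_g/2) - log(d_g/2)]
                          - [digamma(d_0/2) - log(d_0/2)]

with d_0 = +inf (pure pooling) when the excess dispersion is non-positive.

A gene is called up when fc >= 2 and BH-adjusted p < 0.001, down when
fc <= 0.5 at the same p threshold, else unchanged; BH runs per contrast.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .core import (FORELIMB, HINDLIMB, STAGES, WHOLE_EMBRYO, DataError,
                   group_arrays, validate_sheet)

logger = logging.getLogger(__name__)

DE_COLUMNS = [
    "gene", "contrast", "mean_A", "mean_B", "log2fc", "fc",
    "t_mod", "df", "p", "adj_p", "call", "degenerate",
]


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison: group A vs group B at given (tissue, stage)s."""

    name: str
    tissue_a: str
    stage_a: str
    tissue_b: str
    stage_b: str

    def groups(self, sheet: pd.DataFrame) -> tuple[list[str], list[str]]:
        a = group_arrays(sheet, self.tissue_a, self.stage_a)
        b = group_arrays(sheet, self.tissue_b, self.stage_b)
        if set(a) & set(b):
            raise DataError(f"contrast {self.name}: groups overlap")
        return a, b


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes hyperparameters: prior df d0 and prior variance s0^2.

    d0 may be +inf (all genes share variance s0^2). s0_sq is positive except
    in the fully degenerate zero-noise design, where 0 is allowed.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0 or math.isnan(self.d0):
            raise DataError(f"d0 must be >= 0, got {self.d0}")
        if self.s0_sq < 0 or math.isnan(self.s0_sq):
            raise DataError(f"s0_sq must be >= 0, got {self.s0_sq}")


def fit_gene_stats(
    matrix: pd.DataFrame, sheet: pd.DataFrame, contrast: Contrast
) -> pd.DataFrame:
    """Two-group statistics per gene for one contrast.

    Returns a frame indexed by gene with columns mean_A, mean_B, log2fc,
    s2 (pooled residual variance), df (n_A + n_B - 2) and v (1/n_A + 1/n_B).
    """
    validate_sheet(sheet)
    arrays_a, arrays_b = contrast.groups(sheet)
    for label, arrays in (("A", arrays_a), ("B", arrays_b)):
        if len(arrays) < 2:
            raise DataError(
                f"contrast {contrast.name}: group {label} has {len(arrays)} arrays; "
                f"variance estimation needs >= 2"
            )
        missing = set(arrays) - set(matrix.columns)
        if missing:
            raise DataError(f"arrays {sorted(missing)} absent from expression matrix")
    a = matrix[arrays_a].to_numpy(float)
    b = matrix[arrays_b].to_numpy(float)
    n_a, n_b = a.shape[1], b.shape[1]
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    df = n_a + n_b - 2
    return pd.DataFrame(
        {
            "mean_A": mean_a,
            "mean_B": mean_b,
            "log2fc": mean_a - mean_b,
            "s2": ss / df,
            "df": float(df),
            "v": 1.0 / n_a + 1.0 / n_b,
        },
        index=matrix.index.rename("gene"),
    )


def _trigamma(x: np.ndarray | float) -> np.ndarray | float:
    return special.polygamma(1, x)


def inv_trigamma(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is strictly decreasing)."""
    if y <= 0:
        raise DataError(f"trigamma inverse needs y > 0, got {y}")
    lo, hi = 1e-8, 1e8
    if y >= _trigamma(lo):
        return lo
    if y <= _trigamma(hi):
        return hi
    return float(optimize.brentq(lambda x: _trigamma(x) - y, lo, hi, xtol=1e-12, rtol=1e-12))


def estimate_moderation(s2: Sequence[float], df: float) -> ModerationParams:
    """Method-of-moments fit of (d0, s0^2) from gene variances on df residual df.

    Zero variances carry no information about the log-variance moments and
    are excluded; an all-zero input is a degenerate (noise-free) simulation
    and raises.
    """
    s2 = np.asarray(s2, float)
    if df < 1:
        raise DataError(f"residual df must be >= 1, got {df}")
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise DataError("all gene variances are zero; cannot estimate moderation "
                        "(degenerate, noise-free input)")
    if positive.size < 10:
        raise DataError(f"need >= 10 genes with positive variance, got {positive.size}")
    if positive.size < s2.size:
        logger.warning("moderation: excluded %d zero-variance genes", s2.size - positive.size)
    e = np.log(positive)
    if e.var(ddof=1) == 0:
        # exactly equal variances: no chi2 dispersion at all, so the common
        # value is the prior itself
        return ModerationParams(d0=math.inf, s0_sq=float(positive[0]))
    excess = e.var(ddof=1) - float(_trigamma(df / 2.0))
    bias = float(special.digamma(df / 2.0) - math.log(df / 2.0))
    if excess <= 0:
        # no dispersion beyond sampling noise: infinite prior df, common variance
        return ModerationParams(d0=math.inf, s0_sq=float(np.exp(e.mean() - bias)))
    half_d0 = inv_trigamma(excess)
    log_s0 = e.mean() - bias + float(special.digamma(half_d0) - math.log(half_d0))
    return ModerationParams(d0=2.0 * half_d0, s0_sq=float(np.exp(log_s0)))


def moderated_t(
    log2fc: np.ndarray,
    s2: np.ndarray,
    df: float,
    v: np.ndarray | float,
    params: ModerationParams,
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Moderated t, total df, two-sided p, and a degeneracy flag per gene.

    The posterior variance is (d0 s0^2 + df s2)/(d0 + df), reducing to the
    ordinary pooled t at d0=0 and to a common variance s0^2 as d0 → inf.
    Genes with zero posterior variance get p=1 at log2fc=0 and are flagged
    (p=0, infinite t) otherwise.
    """
    log2fc = np.asarray(log2fc, float)
    s2 = np.asarray(s2, float)
    v = np.broadcast_to(np.asarray(v, float), log2fc.shape)
    if math.isinf(params.d0):
        s_post = np.full_like(s2, params.s0_sq)
        df_total = math.inf
    else:
        s_post = (params.d0 * params.s0_sq + df * s2) / (params.d0 + df)
        df_total = params.d0 + df
    degenerate = s_post * v == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / np.sqrt(s_post * v)
    p = np.empty_like(t)
    ok = ~degenerate
    if math.isinf(df_total):
        p[ok] = 2.0 * stats.norm.sf(np.abs(t[ok]))
    else:
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df_total)
    # zero posterior variance: exact zero fc is a definite non-change,
    # nonzero fc is infinitely significant (noise-free planted signal)
    zero_fc = degenerate & (log2fc == 0)
    t[zero_fc], p[zero_fc] = 0.0, 1.0
    inf_fc = degenerate & (log2fc != 0)
    t[inf_fc] = np.sign(log2fc[inf_fc]) * np.inf
    p[inf_fc] = 0.0
    return t, df_total, p, degenerate & (log2fc != 0)


def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values, in the input order."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_status(
    fc: np.ndarray, adj_p: np.ndarray, fc_threshold: float = 2.0, p_threshold: float = 0.001
) -> np.ndarray:
    """up / down / unchanged per the fold-change + adjusted-p rule."""
    if fc_threshold <= 1:
        raise DataError(f"fc_threshold must exceed 1, got {fc_threshold}")
    if not 0 < p_threshold <= 1:
        raise DataError(f"p_threshold must be in (0, 1], got {p_threshold}")
    fc = np.asarray(fc, float)
    adj_p = np.asarray(adj_p, float)
    if np.any(fc <= 0):
        raise DataError("fold changes must be positive")
    sig = adj_p < p_threshold
    call = np.where(sig & (fc >= fc_threshold), "up",
                    np.where(sig & (fc <= 1.0 / fc_threshold), "down", "unchanged"))
    return call


def standard_contrasts(sheet: pd.DataFrame) -> list[Contrast]:
    """Limb-vs-control contrasts at every covered stage plus FL-vs-HL at
    stages where both limbs were sampled."""
    contrasts = []
    for stage in STAGES:
        for tissue, label in ((FORELIMB, "FL"), (HINDLIMB, "HL")):
            if group_arrays(sheet, tissue, stage) and group_arrays(sheet, WHOLE_EMBRYO, stage):
                contrasts.append(Contrast(f"{label}_vs_WE@{stage}",
                                          tissue, stage, WHOLE_EMBRYO, stage))
    for stage in STAGES:
        if group_arrays(sheet, FORELIMB, stage) and group_arrays(sheet, HINDLIMB, stage):
            contrasts.append(Contrast(f"FL_vs_HL@{stage}", FORELIMB, stage, HINDLIMB, stage))
    return contrasts


def run_contrasts(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    contrasts: Iterable[Contrast],
    *,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.001,
    params: ModerationParams | None = None,
) -> pd.DataFrame:
    """Fit all contrasts, estimate moderation once per replicate structure,
    and return the tidy DE table.

    Moderation hyperparameters are estimated on the pooled gene variances of
    all contrasts sharing the same residual df (one prior per replicate
    structure) unless ``params`` overrides them. BH adjustment runs per
    contrast. Contrasts whose groups are missing or unreplicated are skipped
    with a warning.
    """
    fitted: list[tuple[Contrast, pd.DataFrame]] = []
    for contrast in contrasts:
        try:
            fitted.append((contrast, fit_gene_stats(matrix, sheet, contrast)))
        except DataError as err:
            logger.warning("skipping contrast %s: %s", contrast.name, err)
    if not fitted:
        raise DataError("no contrast could be fitted")

    by_df: dict[float, ModerationParams] = {}
    if params is None:
        for df in {stats_frame["df"].iloc[0] for _, stats_frame in fitted}:
            pooled = np.concatenate([
                f["s2"].to_numpy() for _, f in fitted if f["df"].iloc[0] == df
            ])
            if np.all(pooled == 0):
                logger.warning("all variances zero at df=%g (noise-free input); "
                               "using degenerate prior", df)
                by_df[df] = ModerationParams(d0=math.inf, s0_sq=0.0)
            else:
                by_df[df] = estimate_moderation(pooled, df)

    tables = []
    for contrast, f in fitted:
        df = float(f["df"].iloc[0])
        prm = params if params is not None else by_df[df]
        t, df_total, p, flagged = moderated_t(
            f["log2fc"].to_numpy(), f["s2"].to_numpy(), df, f["v"].to_numpy(), prm
        )
        adj_p = benjamini_hochberg(p)
        fc = np.exp2(f["log2fc"].to_numpy())
        tables.append(pd.DataFrame({
            "gene": f.index,
            "contrast": contrast.name,
            "mean_A": f["mean_A"].to_numpy(),
            "mean_B": f["mean_B"].to_numpy(),
            "log2fc": f["log2fc"].to_numpy(),
            "fc": fc,
            "t_mod": t,
            "df": df_total,
            "p": p,
            "adj_p": adj_p,
            "call": call_status(fc, adj_p, fc_threshold, p_threshold),
            "degenerate": flagged,
        }))
    return pd.concat(tables, ignore_index=True)


def run_all_contrasts(matrix: pd.DataFrame, sheet: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """DE table for the full standard design (limb-vs-WE and FL-vs-HL)."""
    return run_contrasts(matrix, sheet, standard_contrasts(sheet), **kwargs)


def write_de(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index=False)


def read_de(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
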