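"""Synthetic limb time-course expression data with planted ground truth.

The generator emulates the statistical shape of the study design the
analysis assumes: five stages (E9.5–E13.5), up to five limb replicates and
two whole-embryo controls per stage, no hindlimb sampling at E9.5, log2
expression spanning roughly 2.4–14.6 with a median near 6.1, plus three
kinds of planted signal with a recorded ground truth —

* temporal profiles: a fraction of genes is up-regulated (limb vs whole
  embryo) at a pattern of stages drawn from the 31 profile classes, with
  default weights proportional to the observed cluster sizes of this kind
  of time course and a small mass on never-observed patterns;
* limb identity: genes up-regulated in only one limb type at every stage it
  was sampled, never in the other;
* annotation: flat gene-set categories, some over-sampled from a profile
  class to a target fold enrichment, writable as GMT.

A single seed fans out into independent substreams per purpose (truth,
baselines, noise, probes, annotation), so e.g. changing the annotation
controls does not perturb the expression noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import pandas as pd

from .core import (FORELIMB, HINDLIMB, STAGES, WHOLE_EMBRYO, ConfigError,
                   DataError, stage_index)
from .enrichment import AnnotationSet, write_gmt
from .io import write_expression, write_sheet, write_truth
from .profiles import ALL_PATTERNS, class_id, pattern_to_string

#: Default sampling weights for the planted profile patterns. The twenty
#: observed patterns are weighted by the cluster sizes reported for this
#: kind of forelimb time course (early 44/68/68/67 of a 247 total; peak
#: 491/401/151; late 475/73/77; stage-specific 184/190/405/159/183;
#: oscillating 51/20/22/29/29 of a 151 total); the eleven remaining
#: patterns carry a small uniform mass.
OBSERVED_PATTERN_WEIGHTS: dict[str, float] = {
    # early: contiguous run from E9.5
    "11111": 44, "11110": 68, "11100": 68, "11000": 67,
    # peak: internal contiguous run
    "01100": 491, "01110": 401, "00110": 151,
    # late: contiguous run ending at E13.5
    "01111": 475, "00111": 73, "00011": 77,
    # stage-specific
    "10000": 184, "01000": 190, "00100": 405, "00010": 159, "00001": 183,
    # oscillating
    "01010": 51, "01001": 20, "10100": 22, "01011": 29, "11101": 29,
}
UNOBSERVED_PATTERN_WEIGHT = 4.0


def default_pattern_weights() -> dict[str, float]:
    weights = {pattern_to_string(p): UNOBSERVED_PATTERN_WEIGHT for p in ALL_PATTERNS}
    weights.update(OBSERVED_PATTERN_WEIGHTS)
    return weights


@dataclass(frozen=True)
class SimConfig:
    """Study-design and signal parameters of the generator.

    Defaults mirror the emulated design: 19040 genes, 5 forelimb and 5
    hindlimb replicates per stage (hindlimb from E10.5), 2 whole-embryo
    controls per stage, log2 baselines spanning 2.4–14.6 with median 6.1,
    planted log2 fold change of 2 and replicate noise sd of 0.25 log2 units.
    """

    n_genes: int = 19040
    stages: tuple[str, ...] = STAGES
    limb_reps: int = 5
    we_reps: int = 2
    hl_start_stage: str = "E10.5"
    drop_arrays: tuple[str, ...] = ()
    baseline_range: tuple[float, float] = (2.4, 14.6)
    baseline_median: float = 6.1
    baseline_log2_sigma: float = 0.7
    noise_sd: float = 0.25
    effect_log2fc: float = 2.0
    frac_profiled: float = 0.15
    pattern_weights: dict[str, float] | None = None
    n_fl_identity: int = 40
    n_hl_identity: int = 40
    n_categories: int = 40
    category_size_range: tuple[int, int] = (10, 200)
    n_planted_categories: int = 4
    planted_enrichment_fold: float = 8.0
    n_probes: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.baseline_range
        if not lo < self.baseline_median < hi:
            raise ConfigError(
                f"baseline median {self.baseline_median} must lie strictly inside "
                f"the range [{lo}, {hi}]"
            )
        if self.limb_reps < 2 or self.we_reps < 2:
            raise ConfigError("limb_reps and we_reps must be >= 2 "
                              "(variance estimation requires replication)")
        if tuple(self.stages) != tuple(sorted(self.stages, key=stage_index)):
            raise ConfigError(f"stages must be in canonical order {STAGES}")
        if self.hl_start_stage not in self.stages:
            raise ConfigError(f"hl_start_stage {self.hl_start_stage!r} not in stages")
        if self.hl_start_stage == self.stages[0]:
            raise ConfigError("hindlimb sampling must start after the first stage")
        if not 0 < self.frac_profiled <= 1:
            raise ConfigError(f"frac_profiled must be in (0, 1], got {self.frac_profiled}")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if self.noise_sd < 0 or self.effect_log2fc < 0:
            raise ConfigError("noise_sd and effect_log2fc must be non-negative")
        if self.category_size_range[0] < 1 or \
                self.category_size_range[0] > self.category_size_range[1]:
            raise ConfigError(f"bad category_size_range {self.category_size_range}")
        if self.planted_enrichment_fold < 1:
            raise ConfigError("planted_enrichment_fold must be >= 1")

    def with_(self, **changes) -> "SimConfig":
        return replace(self, **changes)

    def rng(self, purpose: str) -> np.random.Generator:
        """Independent substream for one purpose, derived from the seed."""
        offsets = {"truth": 1, "baseline": 2, "noise": 3, "probes": 4, "annotation": 5}
        if purpose not in offsets:
            raise ConfigError(f"unknown RNG purpose {purpose!r}")
        return np.random.default_rng(np.random.SeedSequence([self.seed, offsets[purpose]]))


def gene_ids(config: SimConfig) -> list[str]:
    width = max(5, len(str(config.n_genes)))
    return [f"g{i:0{width}d}" for i in range(1, config.n_genes + 1)]


def build_design(config: SimConfig) -> pd.DataFrame:
    """Sample sheet of the emulated design.

    Forelimb and whole-embryo arrays at every stage; hindlimb arrays from
    ``hl_start_stage`` onward. Array ids named ``{FL|HL|WE}_{stage}_r{k}``.
    An explicit ``drop_arrays`` list removes named arrays (the study used
    52 of the full 55-array grid without stating which were missing).
    """
    hl_from = stage_index(config.hl_start_stage, config.stages)
    rows = []
    for stage in config.stages:
        for rep in range(1, config.limb_reps + 1):
            rows.append((f"FL_{stage}_r{rep}", FORELIMB, stage, rep))
        if stage_index(stage, config.stages) >= hl_from:
            for rep in range(1, config.limb_reps + 1):
                rows.append((f"HL_{stage}_r{rep}", HINDLIMB, stage, rep))
        for rep in range(1, config.we_reps + 1):
            rows.append((f"WE_{stage}_r{rep}", WHOLE_EMBRYO, stage, rep))
    sheet = pd.DataFrame(rows, columns=["array_id", "tissue", "stage", "replicate"])
    unknown = set(config.drop_arrays) - set(sheet["array_id"])
    if unknown:
        raise ConfigError(f"drop_arrays names unknown arrays: {sorted(unknown)}")
    return sheet[~sheet["array_id"].isin(config.drop_arrays)].reset_index(drop=True)


def simulate_truth(config: SimConfig) -> pd.DataFrame:
    """Ground-truth table: planted pattern, class id, identity label, effect.

    A Bernoulli(frac_profiled) draw selects profiled genes; each receives a
    pattern sampled by weight. Identity genes are drawn from the remaining
    unprofiled genes: forelimb-identity genes are up in the forelimb at
    every stage and never in the hindlimb (and vice versa). Deterministic
    under a fixed seed.
    """
    rng = config.rng("truth")
    genes = gene_ids(config)
    n = config.n_genes
    weights = config.pattern_weights or default_pattern_weights()
    unknown = set(weights) - {pattern_to_string(p) for p in ALL_PATTERNS}
    if unknown:
        raise ConfigError(f"pattern_weights names unknown patterns {sorted(unknown)[:3]}")
    names = sorted(weights)
    probs = np.array([weights[k] for k in names], float)
    if probs.sum() <= 0:
        raise ConfigError("pattern weights must have positive total mass")
    probs /= probs.sum()

    profiled = rng.random(n) < config.frac_profiled
    patterns = np.full(n, "00000", dtype=object)
    patterns[profiled] = rng.choice(names, size=int(profiled.sum()), p=probs)

    identity = np.full(n, "none", dtype=object)
    free = np.flatnonzero(~profiled)
    need = config.n_fl_identity + config.n_hl_identity
    if need > free.size:
        raise ConfigError(f"cannot plant {need} identity genes among "
                          f"{free.size} unprofiled genes")
    if need:
        chosen = rng.choice(free, size=need, replace=False)
        identity[chosen[:config.n_fl_identity]] = "FL"
        identity[chosen[config.n_fl_identity:]] = "HL"

    class_ids = [0 if p == "00000" else class_id(tuple(c == "1" for c in p))
                 for p in patterns]
    effects = np.where((patterns != "00000") | (identity != "none"),
                       config.effect_log2fc, 0.0)
    return pd.DataFrame(
        {
            "pattern": patterns,
            "class_id": class_ids,
            "identity": identity,
            "effect_log2fc": effects,
        },
        index=pd.Index(genes, name="gene"),
    )


def _baselines(config: SimConfig, signal: np.ndarray) -> np.ndarray:
    """Log-normal-on-log2-scale baselines, clipped to the configured range.

    The distribution is anchored so its median equals ``baseline_median``
    (clipping leaves the median untouched because far less than half of the
    mass is clipped on either side). Genes carrying a planted effect draw
    from the same distribution conditioned below a headroom cap
    ``hi - effect - 6 * noise_sd`` so that their up-shifted values never
    reach the intensity ceiling and planted fold changes survive intact.
    """
    from scipy import stats as _stats

    rng = config.rng("baseline")
    lo, hi = config.baseline_range
    mu = math.log(config.baseline_median - lo)
    sigma = config.baseline_log2_sigma
    spread = rng.lognormal(mean=mu, sigma=sigma, size=config.n_genes)
    baseline = np.clip(lo + spread, lo, hi)
    if signal.any() and config.effect_log2fc > 0:
        cap = hi - config.effect_log2fc - 6.0 * config.noise_sd
        if cap <= lo:
            raise ConfigError(
                f"effect_log2fc {config.effect_log2fc} leaves no dynamic range "
                f"inside [{lo}, {hi}] at noise_sd {config.noise_sd}"
            )
        dist = _stats.lognorm(s=sigma, scale=math.exp(mu))
        p_cap = dist.cdf(cap - lo)
        # inverse-CDF draw conditioned on spread <= cap - lo
        u = rng.random(int(signal.sum())) * p_cap
        baseline[signal] = lo + dist.ppf(u)
    return baseline


def _effect_matrix(truth: pd.DataFrame, design: pd.DataFrame,
                   config: SimConfig) -> np.ndarray:
    """Planted log2 offsets per gene x array (0 where no signal)."""
    n, m = len(truth), len(design)
    effect = np.zeros((n, m))
    pattern_bits = np.array([[c == "1" for c in p] for p in truth["pattern"]])
    eff = truth["effect_log2fc"].to_numpy()
    fl_identity = (truth["identity"] == "FL").to_numpy()
    hl_identity = (truth["identity"] == "HL").to_numpy()
    for j, row in enumerate(design.itertuples(index=False)):
        if row.tissue == WHOLE_EMBRYO:
            continue
        s = stage_index(row.stage, config.stages)
        col = pattern_bits[:, s] * eff
        if row.tissue == FORELIMB:
            col = col + fl_identity * eff
        elif row.tissue == HINDLIMB:
            col = col + hl_identity * eff
        effect[:, j] = col
    return effect


def _signal_mask(truth: pd.DataFrame) -> np.ndarray:
    return ((truth["pattern"] != "00000") | (truth["identity"] != "none")).to_numpy()


def simulate_expression(truth: pd.DataFrame, design: pd.DataFrame,
                        config: SimConfig) -> pd.DataFrame:
    """Gene-level log2 expression matrix: baseline + planted effects + noise.

    The final values are clipped to ``baseline_range`` — an intensity
    floor/ceiling, so the simulated population spans exactly the configured
    range at scale. Signal genes are given baseline headroom below the
    ceiling (see :func:`_baselines`), so the clip never touches a planted
    effect.
    """
    if len(truth) != config.n_genes:
        raise DataError(f"truth table has {len(truth)} genes, config says {config.n_genes}")
    baseline = _baselines(config, _signal_mask(truth))
    effect = _effect_matrix(truth, design, config)
    noise = config.rng("noise").normal(0.0, config.noise_sd,
                                       size=(config.n_genes, len(design))) \
        if config.noise_sd > 0 else 0.0
    values = np.clip(baseline[:, None] + effect + noise, *config.baseline_range)
    return pd.DataFrame(values, index=truth.index.copy(),
                        columns=design["array_id"].tolist())


def simulate_probe_expression(
    truth: pd.DataFrame, design: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.Series]:
    """Optional probe-level output for exercising summarization.

    Each gene gets ``n_probes`` probes with fixed additive affinities
    (median-centered per gene, so median polish recovers the gene values);
    probe value = gene value + affinity + noise. Returns (probe matrix,
    probe→gene map).
    """
    if config.n_probes < 1:
        raise ConfigError("n_probes must be >= 1")
    baseline = _baselines(config, _signal_mask(truth))
    effect = _effect_matrix(truth, design, config)
    gene_values = baseline[:, None] + effect
    prng = config.rng("probes")
    affinities = prng.normal(0.0, 1.0, size=(config.n_genes, config.n_probes))
    affinities -= np.median(affinities, axis=1, keepdims=True)
    probe_ids, gene_of = [], []
    blocks = []
    nrng = config.rng("noise")
    for i, gene in enumerate(truth.index):
        block = gene_values[i][None, :] + affinities[i][:, None]
        if config.noise_sd > 0:
            block = block + nrng.normal(0.0, config.noise_sd, size=block.shape)
        blocks.append(block)
        for p in range(1, config.n_probes + 1):
            probe_ids.append(f"{gene}_p{p:02d}")
            gene_of.append(gene)
    probe_matrix = pd.DataFrame(np.vstack(blocks),
                                index=pd.Index(probe_ids, name="probe_id"),
                                columns=design["array_id"].tolist())
    probe_map = pd.Series(gene_of, index=probe_matrix.index, name="gene")
    return probe_matrix, probe_map


def simulate_annotation(truth: pd.DataFrame, config: SimConfig) -> AnnotationSet:
    """Flat annotation categories over the simulated gene universe.

    The first ``n_planted_categories`` categories are over-sampled from the
    largest planted profile classes so that the expected overlap matches
    ``planted_enrichment_fold``; the rest (and everything, at fold 1) are
    uniform random draws. Category sizes are uniform over
    ``category_size_range``.
    """
    rng = config.rng("annotation")
    universe = list(truth.index)
    n = len(universe)
    lo, hi = config.category_size_range
    if hi > n:
        raise ConfigError(f"category size bound {hi} exceeds universe size {n}")
    cluster_sizes = truth.loc[truth["class_id"] > 0, "class_id"].value_counts()
    planted_targets = cluster_sizes.index[:config.n_planted_categories].tolist()
    categories: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    gene_arr = np.array(universe, dtype=object)
    for c in range(1, config.n_categories + 1):
        name = f"SIM:{c:04d}"
        size = int(rng.integers(lo, hi + 1))
        planted_idx = c - 1
        if (planted_idx < len(planted_targets)
                and config.planted_enrichment_fold > 1):
            cid = planted_targets[planted_idx]
            members = truth.index[truth["class_id"] == cid].to_numpy(dtype=object)
            m = members.size
            # expected overlap under the target fold: k = fold * K * m / N
            k = int(round(config.planted_enrichment_fold * size * m / n))
            k = min(k, m, size)
            inside = rng.choice(members, size=k, replace=False)
            outside_pool = np.array(sorted(set(universe) - set(members)), dtype=object)
            outside = rng.choice(outside_pool, size=size - k, replace=False)
            chosen = np.concatenate([inside, outside])
            descriptions[name] = f"planted fold {config.planted_enrichment_fold} in class {cid}"
        else:
            chosen = rng.choice(gene_arr, size=size, replace=False)
            descriptions[name] = "random category"
        categories[name] = frozenset(chosen.tolist())
    return AnnotationSet(categories, frozenset(universe), descriptions)


def write_fixture(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    annotation: AnnotationSet,
    truth: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the four fixture files (TSV matrix/sheet/truth, GMT annotation)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "samples": out / "samples.tsv",
        "annotation": out / "annotation.gmt",
        "truth": out / "truth.tsv",
    }
    write_expression(matrix, paths["expression"])
    write_sheet(sheet, paths["samples"])
    write_gmt(annotation, paths["annotation"])
    write_truth(truth, paths["truth"])
    return paths


def simulate_all(config: SimConfig) -> dict:
    """Design + truth + expression + annotation in one call."""
    design = build_design(config)
    truth = simulate_truth(config)
    matrix = simulate_expression(truth, design, config)
    annotation = simulate_annotation(truth, config)
    return {"design": design, "truth": truth, "matrix": matrix,
            "annotation": annotation, "config": config}
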