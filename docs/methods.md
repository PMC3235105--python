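# Methods

This note documents the models, parameter choices and numerical conventions
behind `limbtx`, and what the synthetic-data generator does and does not
emulate.

## Study design and data model

The pipeline analyses a five-stage embryonic time course (E9.5, E10.5,
E11.5, E12.5, E13.5) with three tissues: forelimb, hindlimb and a
whole-embryo control. Hindlimb development lags the forelimb by roughly
half a day, so the design has no hindlimb samples at E9.5; the full
replicate grid is 5 forelimb + 5 hindlimb + 2 whole-embryo arrays per stage
(55 arrays; the emulated study analysed 52, without recording which three
of the grid were missing, so any drop list is explicit configuration
rather than a default). All expression values are log2-scale intensities;
every downstream quantity (fold change, variance, z-score) lives on that
scale.

## Preprocessing

Quantile normalization maps each array onto the common distribution given
by the row-wise means of the sorted columns. Ties within a column receive
the mean of the reference values at the ranks they span — the common
dialect; with tie-free (continuous) data the operation is exactly
idempotent, which the suite verifies. Probe-to-gene summarization uses
Tukey median polish per gene (row/column median sweeps on the
probe-by-array submatrix; defaults `max_iter=10`, `tol=1e-6`, matching the
usual RMA settings); a gene's expression on an array is the overall effect
plus the array's column effect. The convolution background-correction step
of full RMA is deliberately omitted: the pipeline's entry point is a
log2-scale expression matrix, not raw optical intensities. Blemish repair
replaces flagged cells of one array with the replicate-group median of the
same gene; which cells are blemished is caller input, since artifact
detection on chip images is out of scope.

## Empirical-Bayes differential expression

Each contrast is a strict two-group comparison (no covariates, no array
weights). Per gene: log2FC is the group mean difference, s² the pooled
variance on d_g = n_A + n_B − 2 df, and v = 1/n_A + 1/n_B. The
hierarchical model places a scaled inverse-chi-square prior on the true
variances, σ² ~ s₀²·d₀/χ²_{d₀}; the posterior variance
(d₀s₀² + d_g s²)/(d₀ + d_g) yields a t-statistic with d₀ + d_g df.
Hyperparameters are estimated by matching the mean and variance of
e = log s² (trigamma equation inverted by Brent root-finding; d₀ = ∞ with a
common variance when the observed dispersion of e does not exceed the
χ²_{d_g} sampling dispersion). Agreement with the reference Bioconductor
implementation is tested two ways: the posterior t and p match limma
exactly given limma's own hyperparameters, and the hyperparameter
estimates agree loosely (limma applies a small-sample moment correction
this implementation omits; at 400 genes the estimates differ by a few
percent).

Choices the data model leaves open, resolved as follows:

* **BH family** is per contrast, because the analysis reports
  per-comparison counts. BH itself is delegated to
  `statsmodels.stats.multitest` and cross-checked against a brute-force
  step-up oracle.
* **Moderation pooling**: one (d₀, s₀²) per replicate structure — all
  limb-vs-control contrasts (d_g = 5) share one prior estimated from their
  pooled gene variances; forelimb-vs-hindlimb contrasts (d_g = 8) get
  their own.
* **Calling rule**: up ⟺ FC ≥ 2 and adjusted p < 0.001; down ⟺ FC ≤ 0.5 at
  the same p threshold. The looser 5% FDR level is exposed as
  configuration but is not the default filter.
* **Degenerate genes**: zero posterior variance with zero log2FC is a
  definite non-change (p = 1); with nonzero log2FC (possible only in
  noise-free data) it is infinitely significant (p = 0) and flagged.
  A fully noise-free design, where every gene variance is zero and the
  moment equations are undefined, falls back to the degenerate prior
  (d₀ = ∞, s₀² = 0) with a warning — this keeps the zero-noise
  plant/recover closure exact, which the suite tests.
* **Exactly equal variances** across genes (another noise-free construct)
  yield d₀ = ∞ with s₀² equal to the common value rather than the
  chi-square-debiased geometric mean.

## Profile classes

Calls against the control are binarized per stage (up vs down/unchanged)
into an ordered 5-tuple. The 31 non-empty tuples are the profile classes;
the class id is the bitstring value with E9.5 as the most significant bit
(a fixed bijection — no claim is made that it matches any external cluster
numbering). Categories: stage-specific = exactly one up stage; early =
contiguous run from E9.5 of ≥2 stages; late = contiguous run ending at
E13.5 not starting at E9.5 (even the two-stage run — runs that persist to
the last observed stage are "late" regardless of length); peak = contiguous
internal run; oscillating = non-contiguous. The census 5/4/3/3/16 is
machine-checked by exhaustive enumeration. Ranking of top up-regulated
genes sorts by fold change descending with ties broken by adjusted p then
gene id, so output order is deterministic.

## Limb identity

Forelimb-specific at stage s: up in FL-vs-control at s, and not up in
HL-vs-control at s or s+1 (the delay veto). Hindlimb-specific mirrors this
with the preceding stage. Boundary stages use whichever vetoes exist: E9.5
forelimb calls rest on the E10.5 hindlimb veto alone (there is no E9.5
hindlimb sample), and E13.5 on the same-stage veto alone. A known
consequence, reproduced faithfully: at E9.5 the rule admits genes whose
hindlimb status at that stage is unknowable (e.g. genes up only at E9.5),
so E9.5 forelimb-identity sets are systematically the most permissive.
"Not up" always means the call is down *or* unchanged.

## Enrichment

One-sided hypergeometric upper tail P(X ≥ k) (scipy's stable
implementation) with fold enrichment (k/m)/(K/N). Only clusters with more
than 40 members are examined; BH runs per cluster across its categories
with non-zero overlap; reported rows clear fold ≥ 2 and adjusted p ≤ 0.05.
The universe N is the annotated genes present on the array; for the
reference fold computations N = 19040, derived by scanning integers in
[18000, 21000] for simultaneous two-decimal agreement with the documented
anchor folds (36.83, 124.44, 35.56, 12.06) — the acceptance script repeats
this derivation at run time. Annotation arrives as flat, pre-propagated
GMT sets; no ontology-graph propagation is performed.

## Diagnostics

Z-normalization uses the population (n) standard deviation, so a two-array
gene maps to (−1, +1); the sample-sd convention is available via `ddof=1`.
The Wilcoxon rank-sum test uses midranks for ties; for n_x + n_y ≤ 12 the
two-sided p is exact (null distribution of the rank sum built by dynamic
programming over doubled midranks, smaller tail doubled and capped at 1),
otherwise the normal approximation with tie-corrected variance and
continuity correction. The low-expression screen flags genes whose *mean*
limb expression (fore- and hindlimb replicates pooled per stage) stays
below 5 log2 units at every stage — per-stage means, not per-array values,
matching the averaging used elsewhere in the analysis.

## Synthetic-data generator

The generator's defaults are the emulated study conditions: 19040 genes,
the 55-array grid above, baseline log2 expression spanning 2.4–14.6 with
median 6.1, planted log2 fold change 2.0, replicate noise sd 0.25 (log2),
15% of genes profiled. Specifics:

* **Baselines** are log-normal on the log2 scale — lo + Lognormal(log(6.1 −
  lo), σ = 0.7), clipped to [2.4, 14.6]. σ = 0.7 makes the empirical
  minimum, median and maximum of a 19040-gene draw land within ±0.3 of
  2.4 / 6.1 / 14.6, which the suite checks. Final values are clipped to
  the same interval (an intensity floor/ceiling); genes carrying planted
  signal draw baselines conditioned below hi − effect − 6·noise_sd so the
  ceiling never truncates a planted fold change. This conditioning means
  signal genes are slightly under-represented at the very top of the
  expression range — a deliberate trade of tail realism for exact
  plant/recover semantics.
* **Patterns** are sampled with weights proportional to the cluster sizes
  observed in this kind of forelimb time course for the twenty observed
  patterns, with a small uniform mass (weight 4) on the eleven patterns
  never observed. Where only category totals are recorded (the 3-way split
  of the 203 non-all-stages early genes; the 58 genes of the two "off"
  oscillating clusters), the split is near-even — those subtotals are not
  documented anywhere.
* **Identity genes** are drawn from the unprofiled pool: forelimb-identity
  genes are up in the forelimb at every stage and never in the hindlimb
  (and vice versa), the cleanest signal satisfying the delay rule.
* **Annotation**: categories of uniform size in [10, 200]; planted
  categories over-sample the largest profile classes so the expected
  overlap matches `planted_enrichment_fold` (default 8); fold 1 reduces to
  a uniform draw.
* **Randomness**: one seed fans out through named substreams (truth,
  baseline, noise, probes, annotation), so changing, say, the annotation
  controls cannot perturb the expression noise; fixtures are byte-identical
  under a fixed seed.

What the generator does *not* emulate — and hence what passing tests do
not show about real arrays: probe-sequence effects and optical background,
litter/batch structure (replicates are exchangeable), correlated noise
between genes, mean–variance trends (noise sd is constant), and partial or
graded effects (planted effects are a single log2 shift). Recovery results
on this generator are best-case for the statistical machinery, not
estimates of sensitivity on real data.

## Problem sizes used in the checks

Planted-signal recovery runs at 5000 genes under otherwise-default
conditions (effect 2.0, noise 0.25, 5/2 replicates, fixed seed) — large
enough for stable rates while keeping the default test run fast.
Hyperparameter recovery uses 5000 simulated variances from d₀ = 4,
s₀² = 0.05. Oracle-equivalence checks use 500–1000 random instances per
primitive at small n where enumeration is exact.

## Known limitations

* Background correction and probe-level QC are out of scope; inputs are
  assumed artifact-free apart from explicitly flagged blemishes.
* The moment estimator of (d₀, s₀²) omits limma's small-sample bias
  adjustment; at genome scale the difference is negligible, at a few
  hundred genes it is a few percent.
* Per-contrast BH is a convention, not a theorem; a global family across
  all 13 contrasts would be more conservative and is not implemented.
* The enrichment universe is a single integer for the whole analysis;
  per-cluster annotation-restricted universes (which real GO tools
  sometimes use) are not supported.
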