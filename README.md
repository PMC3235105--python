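# limbtx

Time-course transcriptome analysis of murine limb development, rebuilt as a
tested, reusable Python pipeline.

The package is for developmental biologists and bioinformaticians analysing
bulk expression time courses in which a tissue of interest (here the
embryonic fore- and hindlimb at stages E9.5–E13.5) is compared against a
whole-embryo control at each stage. It implements, end to end:

1. **Preprocessing** — quantile normalization and Tukey median-polish probe
   summarization (the computable core of RMA on log2 intensities), plus
   replicate-median blemish repair;
2. **Differential expression** — per-stage two-group contrasts with an
   empirical-Bayes moderated t-statistic. Per gene *g*, the pooled variance
   s²_g on d_g df is shrunk toward a prior (d₀, s₀²) estimated by matching
   moments of log s²_g:

       s²_post = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),
       t_g = log2FC_g / sqrt(s²_post · (1/n_A + 1/n_B)),  df = d₀ + d_g

   with per-contrast Benjamini–Hochberg adjustment and the calling rule
   FC ≥ 2 and adjusted p < 0.001 (up), FC ≤ 0.5 (down);
3. **Profile clustering** — per-stage calls binarized to an ordered 5-bit
   up-pattern; the 31 non-empty patterns partition into stage-specific (5),
   early (4), late (3), peak (3) and oscillating (16) classes;
4. **Limb identity** — forelimb-specific genes are up in FL-vs-control and
   not up in HL-vs-control at the same *and the following* stage (hindlimb
   development lags ~half a day); hindlimb-specific genes symmetrically with
   the preceding stage; plus a direct FL-vs-HL moderated-t contrast;
5. **Enrichment** — hypergeometric upper-tail over-representation of GMT
   gene sets per profile class, fold enrichment (k/m)/(K/N), BH per
   cluster, reported at fold ≥ 2 and adjusted p ≤ 0.05 for clusters of
   more than 40 genes;
6. **Diagnostics** — per-gene z-normalization and group mean profiles for
   oscillation inspection, Wilcoxon rank-sum false-negative analysis
   against a phenotype gene list, and low-expression flagging (< 5 log2
   units at every stage).

A synthetic-data generator (`limbtx.simulate`) emulates the study design —
52–55 arrays, up to 5 limb and 2 whole-embryo replicates per stage, no
hindlimb at E9.5, log2 values spanning 2.4–14.6 with median 6.1 — with
planted temporal profiles, limb-identity genes and enriched annotation
categories, so every stage is testable without downloading anything.

## Worked example

Run the whole pipeline on a 5000-gene synthetic fixture:

```sh
limbtx all --n-genes 5000 --seed 2011 --out-dir run/
```

or equivalently from Python:

```python
from limbtx import (SimConfig, simulate_all, run_all_contrasts,
                    assign_profiles, identity_table, enrich_assignments)

bundle = simulate_all(SimConfig(n_genes=5000, seed=2011))
de = run_all_contrasts(bundle["matrix"], bundle["design"])
de[de["call"] == "up"].groupby("contrast").size()
```

which prints (among the 13 contrasts):

```
FL_vs_WE@E9.5     165
FL_vs_WE@E10.5    506
FL_vs_WE@E11.5    567
FL_vs_WE@E12.5    419
FL_vs_WE@E13.5    255
```

— the per-stage counts of genes called up in the forelimb against the
stage-matched whole-embryo control (E10.5–E11.5 carry the most planted
signal, mirroring the design of the emulated study). Continuing,

```python
assignments = assign_profiles(de)            # 805 genes in 31 classes
assignments["category"].value_counts()       # peak 260, stage-specific 255, ...
rows = enrich_assignments(assignments, bundle["annotation"])
```

recovers the planted annotation categories at their planted strength, e.g.

```
cluster  category   k    m    K     N      fold         adj_p
      4  SIM:0004  21   80  164  5000  8.00        1.2e-12
     14  SIM:0003  28   91  189  5000  8.14        1.7e-17
```

fold ≈ 8 is exactly the generator's `planted_enrichment_fold`. Each gene's
row in `assignments` gives its 5-bit up-pattern, class id and temporal
category, e.g. `g00029  11111  31  early` (up at every stage).

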