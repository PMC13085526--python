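# splitroot

Transcriptomic analysis of split-root nitrogen-foraging experiments, as a
tested, reusable Python library.

In a split-root experiment the root system of a single plant is divided
between two compartments with different nitrate supply, so that local
responses (to the nitrogen a root half actually sees) can be separated from
systemic responses (to whole-plant nitrogen status, relayed through the
shoot). The design compares shoots under three conditions — homogeneous
nitrate (C.NO3), heterogeneous split supply (Split), homogeneous depletion
(C.Cl) — and roots under four (C.NO3, Sp.NO3, Sp.Cl, C.Cl, where Sp.NO3 and
Sp.Cl are the nitrate-fed and nitrate-starved halves of the same split
plant), over a 0/2/4/8 h time course with replicates.

`splitroot` implements the analysis stack this design calls for:

* **Preprocessing** — full-quantile normalization (every sample is mapped
  onto the common per-rank mean distribution), low-expression filtering
  (max log2 expression >= 5), dynamic-range filtering (max/min >= 2) and
  log2 transformation.
* **Shoot pattern coding** — per time point, a one-way ANOVA over the three
  shoot conditions with Benjamini–Hochberg FDR <= 10%, then post-hoc Tukey
  HSD coding of each DEG into a three-digit code T₁T₂T₃
  (T₁: C.NO3 vs C.Cl, T₂: Split vs C.Cl, T₃: Split vs C.NO3; digits
  +1/−1/0 for significantly greater/smaller/not significant at α = 0.05).
  Codes with at least two significant digits define regulation groups and
  pattern classes (`split_induced`, `split_repressed`, `n_tracking_class`,
  `depletion_induced`).
* **Root pattern coding** — the two root halves of one plant are
  statistically interdependent (a permutation diagnostic for this is
  included), so roots are analyzed by six pairwise contrasts with the
  rank-product statistic: per replicate, genes are ranked by log fold
  change; RP = the geometric mean rank across replicates; significance is
  the permutation-estimated percentage of false prediction (PFP <= 10%).
  The six digits form an RP code R₁…R₆; genes with R₁ ≠ 0 (C.NO3 vs
  Sp.NO3) respond to systemic N-demand signals, genes with R₆ ≠ 0
  (Sp.Cl vs C.Cl) to systemic N-supply signals.
* **Inter-organ correlation networks** — every shoot gene × root gene pair
  is correlated over the matched time × replicate series of the same
  plants (split shoots pair with both Sp.NO3 and Sp.Cl roots), BH-adjusted
  over the full pair grid at FDR <= 0.001 (≈ |r| > 0.9 at 12 samples),
  then filtered to pairs whose members are DEGs in their organs and of
  which at least one is a reported shoot–root mobile transcript; the
  result is a condition- and sign-annotated network with 4-set Venn
  decomposition, SIF and GraphML export.
* **Cross-species set comparison** — best-hit reduction of scored homolog
  tables into a reference namespace, pairwise and three-way overlaps with
  hypergeometric upper-tail significance
  (p = P(X ≥ |A∩B|), X ~ Hypergeom(universe, |A|, |B|)), and flat
  hypergeometric term enrichment with BH control.
* **Synthetic data** — a seeded generator that emulates the full design
  with planted regulation classes, planted correlated shoot–root pairs,
  plant-pool random effects shared by the two root halves, mobile-transcript
  lists and multi-species gene sets with configured overlaps, so that every
  stage can be scored against known truth without any downloads.

## Worked example

```python
from splitroot import (SimulationConfig, generate_splitroot_experiment,
                       full_quantile_normalize, filter_low_expression,
                       shoot_deg_pipeline)

shoot, root, truth = generate_splitroot_experiment(
    SimulationConfig(n_genes=600, seed=2))
m = filter_low_expression(full_quantile_normalize(shoot))
records = shoot_deg_pipeline(m, fdr_cutoff=0.10, alpha=0.05)
```

Running `python examples/02_shoot_patterns.py` (which does the above and
summarizes per time point) prints:

```
   0 h:    0 DEGs; classes: {}
   2 h:  139 DEGs; classes: {'depletion_induced': 37, 'split_repressed': 33, 'n_tracking_class': 33, 'split_induced': 32, 'ambiguous': 4}
   4 h:  141 DEGs; classes: {'depletion_induced': 39, 'split_induced': 33, 'n_tracking_class': 32, 'split_repressed': 31, 'ambiguous': 6}
   8 h:  159 DEGs; classes: {'depletion_induced': 57, 'split_induced': 31, 'split_repressed': 31, 'n_tracking_class': 30, 'ambiguous': 10}
planted split_induced genes recovered at 8 h: 100.0%
```

No genes are differential at 0 h (pre-treatment), differential expression
builds up as the planted condition effects ramp in, and the planted
regulation classes are recovered with their planted Tukey patterns — e.g. a
split-induced gene codes (0, 1, 1): indistinguishable between the two
homogeneous controls, higher in split plants than either.

The other scripts in `examples/` walk through root RP coding
(`03_root_rank_products.py`), the three-step inter-organ pair analysis and
network assembly (`04_interorgan_network.py`), cross-species overlap testing
(`05_cross_species_overlap.py`) and the fully seeded pipeline with its
reproducibility manifest (`06_full_pipeline.py`). A thin CLI mirrors the
stages (`splitroot simulate | preprocess | shoot-deg | root-deg | correlate |
network | compare-sets | enrich | run-all`).

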