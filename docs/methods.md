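# Methods

This note documents the statistical procedures `splitroot` implements, the
model behind its synthetic data generator, the defaults and the numerical
choices, and what the package's tests do and do not establish about real
data.

## Experimental design being modeled

A split-root experiment divides one plant's root system between a
nitrate-supplied and a nitrate-depleted compartment. Shoots are observed
under three conditions (C.NO3 homogeneous nitrate, Split heterogeneous,
C.Cl homogeneous depletion by chloride substitution) and roots under four
(C.NO3, Sp.NO3, Sp.Cl, C.Cl), where Sp.NO3 and Sp.Cl are the two halves of
the same plant and share one Split shoot. Samples are taken at 0, 2, 4 and
8 h after treatment onset with three replicates. Two structural facts drive
the analysis design: (i) the Sp.NO3/Sp.Cl transcriptomes are
*interdependent* because they come from the same plants, which argues
against a joint four-condition model for roots; (ii) shoots and roots of
the same plants can be paired sample-by-sample, which makes inter-organ
correlation over the time course meaningful.

## Preprocessing

*Full-quantile normalization.* Every column is replaced by the per-rank
mean of the column order statistics: after normalization all samples share
one value multiset and the overall matrix mean is preserved. Ties receive
the average of their tied ranks' target values — deterministic, and
idempotent to < 1e-9 on tie-free data. Shoots and roots are normalized
separately.

*Filters.* A gene is kept for differential analysis when its maximum
expression reaches 2⁵ (equivalently log2 ≥ 5 — the same number serves both
organs, since both phrasings describe the same threshold on the log2
scale). Before correlation analysis a dynamic-range filter additionally
requires max/min ≥ 2 on the linear scale (a zero minimum with positive
maximum counts as passing; a log-scale matrix uses max − min ≥ log2(ratio)),
because a flat gene correlates spuriously well with anything. Whether the
range is assessed on linear or log values is a free choice; both are
supported and linear is the default. Log transformation is log2(x + 1); the
+1 offset handles exact zeros, which occur in counts and in synthetic data.

## Shoot analysis: ANOVA + Tukey codes

Each time point is analyzed independently. Per gene, a one-way ANOVA over
the three conditions (3 replicates each, F on (2, N−3) df) with
Benjamini–Hochberg adjustment across genes; DEG ⇔ FDR ≤ 0.10. Degenerate
genes with zero within-group variance get p = 1 when the group means
coincide and p = 0 otherwise (judged with a relative tolerance so float
noise cannot flip the rule).

DEGs are coded by Tukey HSD at α = 0.05 using the studentized-range
critical value with the pooled ANOVA MSE; the balanced design reduces the
Tukey–Kramer form to the classic equal-n HSD. The three comparisons
C.NO3 vs C.Cl, Split vs C.Cl, Split vs C.NO3 give digits T₁T₂T₃ in
{−1, 0, +1} (sign of the first condition's excess when significant). The
27 possible codes are enumerated lexicographically as the canonical
regulation-group table; codes with fewer than two significant digits have
no clearly defined pattern and carry no group. Pattern classes:

| class | rule | reading |
|---|---|---|
| split_induced | T₂ = +1 ∧ T₃ = +1 | up in split plants vs both controls |
| split_repressed | T₂ = −1 ∧ T₃ = −1 | down in split plants vs both controls |
| n_tracking_class | T₁ = +1 ∧ T₂ ≥ 0 ∧ T₃ ≤ 0 (not split-specific) | follows N supply, C.NO3 > Split > C.Cl |
| depletion_induced | T₁ = −1 ∧ T₂ ≤ 0 ∧ T₃ ≥ 0 (not split-specific) | up under homogeneous depletion |

No gene-wise variance moderation is applied (no empirical Bayes), and time
points are not modeled jointly.

## Root analysis: pairwise rank products

Six contrasts are tested per time point: (1) C.NO3 vs Sp.NO3,
(2) C.NO3 vs Sp.Cl, (3) C.NO3 vs C.Cl, (4) Sp.NO3 vs Sp.Cl,
(5) Sp.NO3 vs C.Cl, (6) Sp.Cl vs C.Cl. Replicates are paired by index
across conditions (the rank-product method operates on per-comparison
fold-change lists, and index pairing also cancels the shared plant-pool
effect in contrast 4). For contrast (A, B), replicate i gives per-gene
dᵢ = bᵢ − aᵢ on the log2 scale; genes are ranked by decreasing dᵢ (average
ranks on ties), RP_up = (∏ᵢ rankᵢ)^(1/k), and RP_down analogously on −dᵢ.

Significance is the permutation-based percentage of false prediction: null
rank products are generated by shuffling each replicate's rank vector
independently (default 1,000 permutations; when (G!)^k ≤ 10⁶ all joint
permutations are enumerated instead, which the tests exploit as an exact
oracle), and for the gene at sorted position j,
PFP = E[#null RP ≤ observed]/j, reported untruncated. A contrast digit is
+1 when the up tail passes PFP ≤ 0.10 (meaning the first condition is the
*lower* one), −1 for the down tail, 0 otherwise; if both tails pass the
smaller PFP wins and exact ties give 0. The six digits form the RP code;
all-zero codes are non-DEG, and regulation groups index the distinct
observed codes. Genes with R₁ ≠ 0 form the systemic N-demand set (same
local nitrate, different whole-plant status), genes with R₆ ≠ 0 the
systemic N-supply set.

*Interdependency diagnostic.* The choice of test for half-to-half
dependence is this package's own (labeled as such in its output): per gene,
residuals after removing per-condition per-time means are correlated
between the paired Sp.NO3/Sp.Cl samples; the statistic is the mean
correlation over genes, and its p-value comes from re-pairing the Sp.Cl
replicates within time points at random. Identical halves give statistic 1;
independent halves give a null-uniform p.

## Inter-organ correlation networks

Per root condition, the matched series pairs each root sample with the
shoot sample of the same plants (Split shoots serve both Sp.NO3 and Sp.Cl).
Pearson r and two-sided t-based p are computed for every shoot × root gene
pair over the 12 matched samples (4 times × 3 replicates, t = 0 included;
a collapse-replicates mode correlating the 4 time means exists, default
off, since the exact sample vector is a free choice). BH adjustment runs
over the full pair grid per condition — one p-value list per analysis, not
per shoot gene — and pairs with FDR ≤ 0.001 are retained, which at N = 12
corresponds approximately to |r| > 0.9. Pair filtering then requires the
shoot member to be a shoot DEG and the root member a root DEG (any time
point), and finally at least one member to appear in a supplied
mobile-transcript list; the two filters commute. Pair identity for
condition comparison is the unordered condition-free (shoot gene,
root gene) key; the 4-set Venn is reported for all 15 regions, optionally
split by correlation sign. The network places genes as (gene, organ) nodes
and one edge per pair carrying its condition set and per-condition signs;
exports are SIF and GraphML. No causal direction, no partial correlations,
no layout.

## Cross-species comparison and enrichment

Scored homolog tables (produced upstream by sequence search) are reduced to
best hits — maximal score per source gene, ties broken to the
lexicographically smallest target for determinism — and species gene sets
are mapped into the reference namespace before comparison. Overlap
significance is the hypergeometric upper tail P(X ≥ |A∩B|) with the stated
universe; a seeded Monte-Carlo z-score (random draws of |B| from the
universe, default 10,000 when enabled) is available for parity with
permutation-based platforms. The universe is the caller's choice (the
pipeline uses the reference namespace covered by the homolog table); since
published overlap tests rarely state their universe, absolute p-values for
real data depend on that choice and are not reproduction targets. Term
enrichment is flat hypergeometric with BH control across terms; ontology
DAG propagation is out of scope (supply pre-propagated annotations if
needed).

## Synthetic data model

Expression is log-normal around a deterministic log2 mean:

    log2 E[x] = baseline + effect_log2fc · ramp(t) · offset(class, condition)
                + pool effect (split root halves)

with baselines log-uniform over [2⁵, 2¹⁵] (so nearly all genes pass the
expression filter), ramp(t) = min(t/4 h, 1) — no effect at 0 h, half at
2 h, full from 4 h — mirroring the sparse-early/rich-late differential
expression of split-root time courses, and multiplicative log-normal noise
with CV `cv_noise` (default 0.1, ≈ 0.14 log2 units). Class offsets (in
units of `effect_log2fc`, default 2): split_induced/repressed ±1 in Split
shoots and both split root halves; n_tracking +1/−1 tracking nitrate
(C.NO3/Sp.NO3 up, Sp.Cl/C.Cl down in roots); depletion_induced +1 under
Cl conditions. Default class proportions are 5% per regulation class with
20% "noise" genes (condition-free fluctuation at 3× CV) and the rest flat —
matching the rough DEG fraction of real split-root shoot data at 4–8 h
(~20–25% of expressed genes). The two root halves of a plant share a
per-gene plant-pool effect (`pool_effect_sd`, default 0.15 log2 units,
comparable to the measurement noise), which is what makes the
interdependency diagnostic detectable, as in real data.

Planted inter-organ pairs overwrite a constant-class root gene's profile
under one condition with a signed affine transform of its shoot partner's
realized log2 profile plus calibrated noise, so the expected Pearson r over
the matched series equals `pair_r_target` (default 0.95; target 1 with the
noise term vanishing reproduces r = ±1 exactly). Shoot partners come from
regulation-class genes so pairs survive the DEG filter. The truth object
records planted classes, codes, pairs, the mobile set, and the noise-free
expected profiles, from which pair-level ground truth (profile correlation,
essentially bimodal at 0 and ±1 by design) is computed for scoring.

Multi-species sets are built blockwise in the reference namespace to hit
configured pairwise and three-way intersection sizes exactly (three-way
empty by default, as in the cross-species systemic-N comparison this
emulates), then translated to native species ids with top-scoring true
homolog hits plus lower-scoring decoys to exercise best-hit reduction.

What the generator does *not* model: read-level data, alignment, library
size and count dispersion (no negative-binomial layer), gene–gene
regulatory structure beyond the shared class ramps, and realistic effect
size distributions — per-gene effects are uniform within a class, chosen
for testability. Passing recovery tests therefore demonstrates correctness
of the statistical machinery under a known truthful model, not performance
on real RNA-seq data.

## Recovery behavior worth knowing

At correlation FDR 0.001 over a 2000 × 2000 pair grid, the BH threshold is
adaptive: with a background of co-regulated class genes (shared ramps →
genuinely correlated pairs), planted pairs at r ≈ 0.95 are recovered at
~86% with an empirical false-discovery proportion ≈ 0.001 (scored against
the noise-free profile truth). On a background of only independent genes
the step-up threshold tightens to p ≈ 5×10⁻⁸ and pairs at r ≈ 0.95
(p ≈ 2×10⁻⁶ at N = 12) are mostly missed — stringent grid-wide FDR control
at 0.001 is only compatible with high recall when substantial genuine
correlation structure is present, which real transcriptomes (and the
default synthetic design) have. Applying the dynamic-range pre-filter
before the recovery experiment removes planted root partners whose shoot
partner is flat under the designated condition, reducing recall to ~46%;
the acceptance experiment therefore correlates the full candidate space.

## Numerical and reproducibility choices

* Tukey significance uses the cached critical value
  `studentized_range.isf(α, k, df)`; decisions are identical to
  per-comparison p-values but orders of magnitude faster genome-wide.
* Zero-variance degeneracies: ANOVA p ∈ {0, 1} and Tukey digits from mean
  ties are decided with relative tolerances (1e-18 on sums of squares,
  1e-9 on means).
* Rank-product PFP compares observed to null statistics with a 1e-12
  relative slack so identical rank multisets count as ties despite
  float-order effects.
* All randomness flows from explicit integer seeds; the pipeline derives
  one stream per stage from the top-level seed and the stage name, so
  toggling stages never shifts other stages' randomness. Numeric output is
  written with 9 significant digits and the manifest hashes every output;
  identical configuration and seed reproduce identical hashes.
* Problem sizes in tests and the acceptance script (2000-gene experiments,
  10 or fewer seeds, 1,000–10,000 permutations) were chosen to exercise the
  same regime as the study design while keeping a full run to a few
  minutes on one CPU.

## Known limitations

* The exact group numbering of published split-root regulation tables is
  not reproducible from class semantics alone; this package's canonical
  27-code table is its own stable convention, and the biologically named
  classes carry the semantics.
* PFP estimates below ~1/n_perm are resolution-limited unless the
  exhaustive path engages.
* The interdependency diagnostic is a package-defined stand-in for an
  unspecified dependence test; treat its p-value as a design check, not a
  published statistic.
* Headline counts from real split-root studies (DEG counts, pair counts,
  network sizes) depend on deposited raw sequencing data and upstream
  alignment, which are outside this package's scope; its claims are
  property-based, on synthetic data with known truth.
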