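# Methods

## Model

The package scores the genetic burden a drug faces in a population by
aggregating variant-level tolerance predictions multiplicatively up a
three-level hierarchy.

Let an individual carry, in gene *g*, the nonsynonymous variants with
clamped SIFT scores `V_1 … V_k` (`V = max(sift, ε)`). The gene score is the
geometric mean `G_g = (∏ V_i)^(1/k)`, with `G_g = 1` when `k = 0`. For a
drug with PK/PD gene set *Γ* the drug score is `D = (∏_{g∈Γ} G_g)^(1/|Γ|)`.
The population score of a drug is `AUC = mean_i D_i`, `1 − AUC` is its
distance from a genetically ideal drug, and `V_t = |{i : D_i < t}| / n` is
the vulnerable fraction at risk threshold *t* (strict inequality; `V_t` as
a function of *t* is the empirical CDF of D).

Modelling assumptions baked into this hierarchy:

- **Boolean carriage.** An individual either carries ≥1 copy of an
  alternate allele or does not; zygosity and phase carry no weight. The
  gene score is defined over carried variants with no dose term, so a
  heterozygote and a homozygote contribute identically.
- **Missing genotypes are non-carriage.** Absence of evidence of a
  deleterious allele must not lower a score; missing calls are counted and
  logged but treated as reference.
- **Equal gene weighting.** All PK/PD genes of a drug are weighted equally;
  no pharmacokinetic parameters (Km/Vmax) enter. Two drugs with identical
  gene sets receive identical scores.
- **Multiplicative damage.** Geometric (not arithmetic) means encode that
  several mildly damaged genes and one severely damaged gene can be
  comparably worrying, and that a single very low V pulls D down through
  both levels.
- **Per-individual aggregation.** G is computed over the variants *that
  individual* carries, not over all variants segregating in the cohort —
  this is what makes D personal and gives each drug a population
  distribution rather than a single number.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `epsilon` | 0.001 | lower clamp on V. SIFT emits exact zeros; an unclamped zero annihilates every geometric mean above it and makes D independent of all other genes. 0.001 keeps a zero-scored variant maximally deleterious in effect (a single hit drags a 5-gene drug to `0.001^(1/5) ≈ 0.25`) while preserving the multiplicative model. Recorded in every output header. |
| `min_genes` | 5 | minimum distinct PK/PD genes for a drug to enter the analysis; drugs below it are excluded and counted. The sensitivity sweep re-runs everything at thresholds 1–10. |
| thresholds | 0.3, 0.7 | risk thresholds for `V_t` in the population summary. |
| `n_bins` | 10 | equal-width AUC bins, right-closed: bin *k* covers ((k−1)/n, k/n]; AUC = 0 joins bin 1 and AUC = 1 joins bin n. |
| bin scores | 1…k | Cochran–Armitage scores. The statistic is invariant under affine transformations, so equally spaced integers and bin midpoints are the same test. |

## Statistics

The Cochran–Armitage trend statistic for events `x_i` of `n_i` per bin with
scores `s_i` (N = Σn_i, p̄ = Σx_i/N) is

    z = Σ s_i (x_i − n_i p̄) / sqrt( p̄(1−p̄)[Σ s_i² n_i − (Σ s_i n_i)²/N] )

reported signed (negative = the proportion falls as the score rises) with
the two-sided asymptotic normal p-value and no continuity correction. On
two bins `z²` reduces exactly to the pooled two-proportion chi-square. The
implementation is validated in the tests against an exhaustive permutation
oracle on tiny tables and, during development, against R's
`prop.trend.test`. Degenerate tables — no events, all events, or fewer
than two non-empty bins — are flagged and reported as statistic 0, p = 1
rather than raised, so a batch over many rows cannot die on one empty row.

Group comparisons use one-way fixed-effects ANOVA (scipy) followed by
Tukey HSD (statsmodels), on the pooled observation list. Category
membership may overlap: a withdrawn drug on the Beers list contributes an
observation to both groups, and the "other" category is defined as
carrying no flag at all. No correction is applied across trend rows.

## The synthetic cohort generator

The generator emulates the statistical structure of a sequenced reference
cohort joined to a drug–gene knowledge base: per-gene variant counts are
Poisson (mean 10); allele frequencies are Beta(0.1, 3) (median ≈ 1%,
right-skewed as site-frequency spectra are); carriage is Hardy–Weinberg,
`P(carry) = 1 − (1−f)²`, independent across variants and individuals;
SIFT-like scores come from a two-component Beta mixture (30% deleterious
mass near 0, Beta(0.5, 8); 70% tolerated mass near 1, Beta(5, 1)),
mimicking the bimodal landscape of real tolerance predictions; drug gene
sets are drawn without replacement with |Γ| = 5 + Poisson(7.4)
(mean ≈ 12.4 genes per drug); and withdrawal labels follow
`P(withdrawn) = logistic(1.25 − 5·AUC)`.

Default sizes mirror a fully sequenced reference cohort joined to a curated
drug–gene knowledge base: 2504 individuals, 2807 genes, 1041 drugs with ≥5
genes each. The distributional defaults were
calibrated once so the simulated per-drug AUC lands near 0.6 with an SD
around 0.13 — the range real drug categories occupy — and so the default
link yields ≈15% withdrawn drugs, matching real registries.

What the generator deliberately omits: linkage disequilibrium, population
substructure and ethnicity, realistic gene lengths, correlated gene sets
between related drugs, and any non-genetic driver of withdrawal. Passing
end-to-end tests therefore demonstrates that the pipeline recovers an
AUC-linked withdrawal signal *when the generative model puts one there*;
it says nothing about how strong that signal is in real registries, where
withdrawal decisions also reflect usage, era, and regulatory policy.

## Problem sizes in tests and the acceptance script

The end-to-end trend experiments use a cohort of 250 individuals × 600
genes × 1000 drugs, scored once; the 200 per-seed replicates re-draw only
the withdrawal labels, which is exactly the randomness the generative
model places downstream of the AUC. 1000 drugs keeps per-bin counts large
enough for the asymptotic trend test while the whole experiment stays in
the seconds range. Oracle-equivalence checks run on cohorts of ≤10
individuals × ≤4 drugs, where a nested-loop reference implementation is
exact and fast.

## Numerical choices

- Geometric means are computed in log space; products of hundreds of
  sub-unity scores underflow in linear space.
- Equality of the vectorised scorer with the nested-loop oracle is asserted
  at 1e-12 relative error; log/exp round-trips cost a few ulps.
- The asymptotic trend p is compared to the exact permutation p within
  0.06 absolute on n ≈ 12 tables — the size of the normal-approximation
  error at that n, not a statement about large-table accuracy.
- Variant identity is exact string/integer equality on
  (chrom, pos, ref, alt) after splitting multi-allelic records one alt at
  a time; no indel normalisation or liftover is attempted.
- Duplicate (gene, variant) annotations count once per gene; a variant
  annotated to two genes contributes to both, keeping genes independent.
- Drugs whose genes carry no annotated variant in the cohort score D = 1
  for everyone (AUC = 1) with a warning — the "genetically ideal" limit is
  meaningful, so such drugs are kept, not dropped.
- Bins with zero drugs keep their position with an undefined (NaN)
  frequency so bin labels stay aligned across tables.

## Known limitations

- Consequence filtering is a controlled-vocabulary string match
  (`nonsynonymous`); upstream annotation tools must be mapped to it.
- Gene symbols are matched case-sensitively after whitespace trimming with
  no alias resolution; mismatched symbol vocabularies silently shrink the
  annotated gene set (the per-drug unannotated warning is the guard).
- The single pluggable score column assumes SIFT's orientation
  (lower = worse); differently oriented predictors must be transformed
  before ingestion.
- The asymptotic trend p-value is unreliable when event counts are very
  small; an exact test is provided only as a test-suite oracle.
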