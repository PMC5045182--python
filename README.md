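# pharmscore

Personal-genome drug safety scoring: aggregate per-variant deleteriousness
predictions into per-gene, per-drug, and population-level scores, and test
whether drugs with genetically more damaged pharmacokinetic/pharmacodynamic
(PK/PD) gene sets are withdrawn from the market or flagged with precautions
more often.

## Who this is for

Pharmacogenomics and drug-safety researchers who have (a) a multi-sample
VCF of a cohort, (b) SIFT-style tolerance annotations for nonsynonymous
coding variants, and (c) a drug → PK/PD gene map, and who want a
population-level, *ab initio* genomic safety measure per drug — before or
after market approval.

## The scores

For an individual and a drug with PK/PD gene set *Γ*:

- **V** — variant score: the SIFT score of a nonsynonymous variant
  (range 0–1, lower = more deleterious), floored at ε = 0.001 so an exact
  zero cannot collapse the products above it.
- **G** — gene score: the geometric mean of the V scores of the variants
  the individual *carries* in the gene; `G = 1` if none are carried.
- **D** — drug score: `D = (∏_{g∈Γ} G_g)^(1/|Γ|)`, all genes equally
  weighted. `D = 1` means the individual's copies of every relevant gene
  are free of damaging variants.
- **P (AUC)** — population score of a drug: the mean of D over all
  individuals, equal to the area under the ascending sorted D-score curve.
  `1 − AUC` is the drug's distance from a "genetically ideal" drug.
- **V_t** — vulnerable fraction: the share of the population with
  `D < t` for a risk threshold *t* (0.3 and 0.7 by default).

Validation statistics: drugs are placed into 10 equal-width AUC bins and a
Cochran–Armitage test for trend asks whether withdrawal/precaution rates
fall as AUC rises; one-way ANOVA with Tukey HSD compares AUC between
withdrawn, Beers-criteria, FDA-pharmacogenomics and unflagged drugs; a
sensitivity sweep repeats the comparison at PK/PD-gene inclusion
thresholds 1–10.

## Worked example

```python
import pharmscore as ps

# the packaged reference count table: withdrawals/precautions per AUC bin
table = ps.reference_trend_counts()
trend = ps.trend_table(table)
print(trend.loc[["withdrawn_un", "withdrawn_ema", "withdrawn_drugbank"],
                ["statistic", "p_value"]].round(4))
```

prints

```
                    statistic  p_value
label
withdrawn_un          -3.2673   0.0011
withdrawn_ema         -2.7094   0.0067
withdrawn_drugbank    -1.9337   0.0531
```

Each row is one source of withdrawal records (United Nations consolidated
lists, the European Medicines Agency, DrugBank annotations). The negative
statistics say that in every case the withdrawal rate *falls* as the
population deleteriousness score rises; the UN trend is significant at
p ≈ 0.001, the EMA trend at p ≈ 0.007, and the DrugBank-only trend is
borderline (p ≈ 0.053).

The same pipeline runs end-to-end on synthetic cohorts:

```python
cfg = ps.SimulationConfig(n_individuals=250, n_genes=600, n_drugs=1000, seed=1)
geno, annotations, drug_map = ps.simulate_cohort(cfg)
scores = ps.score_cohort(geno, annotations, drug_map)
summary = ps.summarize_population(scores)            # AUC, 1-AUC, V_0.3, V_0.7
status = ps.simulate_status(summary.frame["auc"], intercept=1.25, slope=-5.0, seed=2)
groups = ps.categorize_auc(summary.frame, status)
comparison = ps.anova_tukey({k: v for k, v in groups.items() if len(v) >= 2})
print(f"ANOVA F = {comparison.f_statistic:.1f}, p = {comparison.p_value:.2g}")
```

prints (seed 1/2):

```
ANOVA F = 53.1, p = 6.4e-13
```

— withdrawn drugs have markedly lower simulated AUC than the rest, the
effect injected by the negative logistic link.

A command-line interface mirrors the library:
`pharmscore score | summarize | trend | anova | sweep | simulate`
(see `pharmscore --help`); every output TSV embeds the tool version,
configuration hash, ε, gene threshold and seed as comment headers.

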