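# mathsurv

Intra-tumoral heterogeneity (ITH) — the coexistence of genetically distinct
subclones within one tumor — is a candidate prognostic marker: more
heterogeneous tumors have more raw material for progression and therapy
resistance. `mathsurv` implements the complete analysis that turns a somatic
mutation callset into that prognosis story, for cancer genomicists and
biostatisticians working with MAF-format variant calls, clinical follow-up
tables and RNA-seq expression matrices.

At its core is the **MATH score** (mutant-allele tumor heterogeneity). For a
tumor's variant allele fractions (VAF = alt reads / total reads at each
somatic variant),

```
MATH = 100 · (1.4826 · MAD) / median(VAF)
```

where MAD is the median absolute deviation, scaled by 1.4826 so it estimates
the standard deviation for normal data. A clonal, diploid tumor concentrates
its VAFs near one value (MATH ≈ noise floor); subclonal structure spreads
them out and raises the score.

Around the statistic, the package provides the full downstream pipeline:

- **maf_io** — MAF/GMT readers and writers, per-sample VAF profiles with a
  configurable classification filter and VAF ceiling;
- **heterogeneity** — per-sample MATH with QC flags, cohort summaries;
- **cohort** — rank-based tertile stratification (low / intermediate / high)
  and a "Table 1"-style baseline table with log-rank / ANOVA p-values;
- **survival** — Kaplan–Meier, k-group log-rank, and Cox proportional-hazards
  regression implemented directly on the partial likelihood (Efron or
  Breslow ties), with hazard ratios, Wald 95% CIs and p-values;
- **enrichment** — two-phenotype GSEA: signal-to-noise ranking, weighted-KS
  enrichment scores, phenotype-permutation NES / nominal p / FDR q, and the
  p < 0.05, |NES| ≥ 1, q < 0.25 significance rule;
- **immune** — ssGSEA-style single-sample scores for 28 immune cell-type
  signatures, Mann–Whitney group comparison, per-cell-type Cox models;
- **mutsummary** — classification counts, variant-load distribution, top
  mutated genes, and pairwise co-occurrence / mutual exclusivity by Fisher's
  exact test;
- **synthetic_data** — a generative cohort simulator (subclone CCFs, binomial
  read counts at ~150× depth, Weibull survival under proportional hazards,
  expression with planted immune shifts) with a ground-truth sidecar, so the
  whole pipeline is testable without any external download;
- **pipeline / cli** — `run_all` orchestration plus a thin `mathsurv`
  command-line wrapper (`simulate`, `math`, `stratify`, `survival`, `gsea`,
  `immune`, `mutsummary`, `run-all`, `fixtures`).

## Worked example

`examples/02_tertiles_and_survival.py` scores a simulated 385-sample cohort,
stratifies it and fits the survival models:

```
tertile sizes: {'low': 128, 'intermediate': 128, 'high': 129}
per-group median MATH: {'low': 14.9, 'intermediate': 24.5, 'high': 45.1}
  low           24-month survival: 0.49
  intermediate  24-month survival: 0.40
  high          24-month survival: 0.34
log-rank: chi2 = 12.48, df = 2, p = 0.0020
Cox per-tertile-step HR = 1.350 (1.136-1.606), p = 0.0007
(generator planted HR 1.433 per step)
```

The tertile split puts the remainder sample in the high group (385 →
128/128/129). Survival worsens monotonically with the MATH tertile, the
log-rank test rejects equality of the three curves, and the Cox model
recovers a hazard ratio per tertile step compatible with the planted truth
of 1.433 — i.e. each step up in heterogeneity multiplies the death hazard
by roughly 1.4. The other scripts in `examples/` walk through MATH scoring,
GSEA, immune-cell scoring and mutation summaries the same way.

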