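# Methods

## The MATH statistic

For one tumor, let `v_1 … v_n` be the variant allele fractions of its
retained somatic variants. The package computes

```
MATH = 100 · 1.4826 · median(|v_i − median(v)|) / median(v)
```

with the mean-of-central-pair convention for even-length medians. The
1.4826 factor makes the MAD a consistent estimator of the standard
deviation under normality, so MATH is a robust coefficient of variation in
percent. It is scale-invariant (tumor purity rescales all VAFs together)
and permutation-invariant, and it is zero exactly when all retained VAFs
are equal. Degenerate inputs are flagged, never silently dropped: fewer
than `min_variants` VAFs → `too_few_variants`; an all-zero vector →
`zero_median`.

Retention applies a classification include-list (default: every
classification, since mutant-allele dispersion is agnostic to coding
consequence; silent variants can be excluded by configuration) and a VAF
ceiling `vaf_max = 0.75`, which trims alleles inflated by copy-number gain
or LOH — the only outlier control applied. No subclone clustering,
cancer-cell-fraction reconstruction or purity/ploidy correction is
attempted; MATH is deliberately a one-number dispersion summary of raw
allele fractions.

`min_variants` defaults to 5 because a MAD over fewer points is unstable;
with ~63 variants per sample at default settings the flag is almost never
raised.

## Stratification and the baseline table

QC-passing samples are sorted ascending by MATH (ties broken by sample ID
for cross-platform determinism) and cut at ranks ⌊n/3⌋ and ⌊2n/3⌋. The
remainder when 3 ∤ n goes to the *high* group, so n = 385 splits
128/128/129 and n = 171 splits 57/57/57. The adjuvant-chemotherapy subset
re-derives its own tertiles from its own score distribution rather than
inheriting the full-cohort cut points.

The baseline table reports `count(percent)` per characteristic level with
percentages rounded half-up to one decimal; the univariate p per
categorical characteristic is a log-rank test across its non-NA levels
(NA rows are tabulated but excluded from the test), and continuous
covariates (MATH itself) are compared across the three groups by one-way
ANOVA.

## Survival models

*Kaplan–Meier* is the product-limit estimator over distinct event times;
censored records only shrink the risk set. *Log-rank* accumulates
observed-minus-expected death counts per group with the hypergeometric
covariance at each event time and forms the chi-square from the first
k−1 groups with a pseudo-inverse (df = k−1). *Cox regression* maximizes
the partial likelihood by Newton–Raphson with step-halving, covariates
centered for conditioning; convergence when the score's max component
falls below 1e-8, at most 50 iterations. Ties are handled by the Efron
correction by default (Breslow available — some standard packages default
to it). Standard errors come from the inverse observed information; 95%
CIs are exp(β ± 1.96·SE). A fit whose coefficients run beyond |β| > 15 is
flagged `monotone_likelihood` (perfect separation); failure to converge is
flagged, never silent.

The MATH group enters the multivariate model as one ordinal covariate
(low/intermediate/high → 0/1/2), giving a single per-step hazard ratio;
clinical covariates are likewise coded ordinally (stage I–IV → 1–4, grade
G1–G3 → 1–3 with Gx treated as missing, binary codings for sex, age group
and radiation, histology Diffuse/Intestinal/SignetRing → 1–3). Records
with a missing value in any model covariate are dropped listwise. With the
realistic NA rates of the generator (radiation ~48% NA, histology ~35%
NA) the seven-covariate model retains roughly a third of the cohort —
small cohorts should use a reduced covariate list.

## GSEA

Genes are ranked by signal-to-noise (μ_A−μ_B)/(σ_A+σ_B) with each class SD
floored at 0.2·|μ| (0.2 when μ = 0); ties break lexicographically. The
enrichment score is the extremum of the weighted-KS running sum (hits step
up by |metric|^p normalized over hits, default p = 1; misses step down by
1/(N−N_hit)). The null is phenotype-label permutation (default 1000,
seeded, capped with a warning at the number of distinct assignments):
NES = ES / mean |same-sign null ES|, nominal p uses the (b+1)/(B+1)
convention so it is never exactly zero, and FDR q is the classic ratio of
the pooled-null and observed NES tail fractions, clipped at 1. A set is
"significant" when nominal p < 0.05 AND |NES| ≥ 1 AND q < 0.25; the
|NES| reading resolves the ambiguity of a one-sided "NES ≥ 1" rule for
negative scores, with the direction reported separately.

Because the ranking is relative, enrichment is always *against the rest of
the genome*: if most genes shift together, the unshifted minority appears
depleted. The expression input is expected as log-scale normalized values
(e.g. log2(x+1) counts); no further normalization is applied.

## Immune-cell scoring

Per sample, genes are ranked descending and each of 28 cell-type sets is
scored by Σ_i [P_in^w(i) − P_out(i)], where P_in^w is the in-set rank ECDF
weighted by rank^α (α = 0.25 — mild emphasis of extreme ranks; α = 0 gives
the unweighted KS-area statistic) and P_out the out-of-set position ECDF.
The statistic is a rank functional, hence invariant under any strictly
monotone per-sample transform — normalization choices upstream cannot
change it. The scoring engine is deliberately this ssGSEA-style rank
statistic rather than a kernel-CDF GSVA: the downstream group tests are
rank-based (Mann–Whitney), so the engine choice does not affect the
inference, and α is configurable.

Group differences use the Mann–Whitney z with tie-corrected variance
(positive z = higher in the low/intermediate group). The continuity
correction is off by default — at cohort sample sizes it is immaterial —
but exhaustive enumeration shows that *with* the correction the normal
p agrees with the exact p within 0.02 throughout the rejection tail
(exact p ≤ 0.2) for all 3 ≤ n₁ ≤ n₂ ≤ 7; near the distribution center no
normal approximation can track the discrete exact p. Raw p-values are
reported by default (Benjamini–Hochberg available by flag). Per-cell-type
Cox models standardize the score so hazard ratios are per SD.

The packaged 28-set GMT carries the standard immune cell-type *names* but
**synthetic gene membership** (disjoint 30-gene blocks of the simulator's
universe, stated in the file's description column): the curated signatures
are not redistributable here, and any real GMT can be supplied in its
place. Consequently cell-type-level results on real data require a real
signature file.

## Mutation summaries

Classification counts, per-sample variant load with cohort median, and
genes ranked by number of mutated samples (each sample counted once per
gene, alphabetical tie-break). The gene × sample matrix marks non-silent
variants by default (configurable). All pairs among the `top_k = 25` most
mutated genes are tested by Fisher's exact test — two-sided by the
probability-mass rule (sum of hypergeometric probabilities ≤ the observed
table's), the same convention as the classical test — with calls
`co_occurring` (p < α, OR > 1) or `exclusive` (p < α, OR < 1). The
displayed odds ratio is the sample OR with a 0.5 Haldane correction when
a cell is zero.

## The synthetic cohort generator

The generator's defaults describe a resected gastric-adenocarcinoma cohort
profiled by whole-exome sequencing:

| parameter | default | rationale |
|---|---|---|
| n_samples | 385 | full-cohort size; chemo subset ~171 via `chemo_fraction` |
| variants per sample | NB(mean 63, size 12) | median load ≈ 61–64 |
| depth | Poisson(150) | ~150× mean coverage; zero-depth draws redrawn |
| purity | U(0.5, 0.9) | typical resected-tumor purity |
| subclones | 1–3, CCF ~ U(max(0.2, 1−5θ), 1) | θ is the single dispersion dial; 0.2 floor ≈ detection limit |
| θ (subclone dispersion) | 0.13 | cohort MATH median ≈ 23–26, range ≈ 7–75 |
| p_clonal | 0.5 | half of variants truncal |
| survival | Weibull(shape 1.2, scale 40 mo), log-HR log(1.433)/step | observed prognostic effect size |
| censoring | 0.5 target | uniform censoring, upper bound calibrated by bisection |
| expression | 2000 genes, Gaussian log-scale | 20 of 28 immune sets shifted +1 SD in low/intermediate |

True VAF is purity·CCF/2 — diploid heterozygous throughout, because
copy-number change would confound the dispersion ground truth. Mean MATH
rises monotonically in θ by construction. Clinical covariate levels follow
the frequency profile of a reference cohort (65.5% male, 68.8% ≥60y,
stage II+III ≈ 74%, with realistic NA rates for radiation and histology).
Censoring is independent of covariates so Cox recovery assumptions hold
exactly. All randomness flows from one seed through spawned sub-streams
(MAF / survival / expression independently reproducible), and every
generated cohort writes a ground-truth JSON sidecar.

What the generator does **not** emulate: MSI-hypermutator tails in the
load distribution, mutational signatures, CNA/LOH, germline contamination,
gene–gene mutational dependence (driver labels are drawn independently per
sample), and biologically correlated expression structure. Passing tests
therefore demonstrate that the estimators recover the planted truth under
a clean generative model — calibration of type-I error, power for 1-SD
set shifts at n = 171, HR recovery at n = 400 — not that real-cohort
effect sizes will match.

One consequence of rank-based scoring worth noting: when 20 of 28 sets are
shifted in one group, the 8 unshifted sets become *relatively* depleted
there, so the per-cell-type comparison typically flags all 28 with
opposite directions — the direction column, not just the count, carries
the signal.

## Test problem sizes

The stochastic suites use: 1000 random vectors against the brute-force
MATH oracle; 100 survival replicates at n = 400 (HR recovery) and 200 at
n = 150 (log-rank null); 50 GSEA runs at 600 genes × 40 samples with 500
permutations (null) and 50 at 900 genes × 171 samples (power); 50
immune-suite runs at 900 genes × 171 samples; exhaustive Fisher
enumeration for all 2×2 tables with n ≤ 20; and two full default pipeline
runs compared byte-for-byte.
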