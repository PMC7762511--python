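"""Somatic-mutation summaries and co-occurrence.

Counts variant classifications, per-sample variant load, and the most
recurrently mutated genes of a simulated cohort, then tests gene pairs
for co-occurrence / mutual exclusivity with Fisher's exact test.
"""

from mathsurv import (
    SyntheticConfig,
    cooccurrence_scan,
    gene_sample_matrix,
    simulate_maf,
    summarize_maf,
)

maf, _ = simulate_maf(SyntheticConfig(seed=5, n_samples=171))
summary = summarize_maf(maf, top_k=10)

print("variant classifications:")
print(summary.classification_counts.head(4).to_string())
print(f"\nmedian variant load: {summary.median_load:.0f} per sample")
print("\nmost recurrently mutated genes (samples carrying the gene):")
print(summary.top_genes.head(6).to_string(index=False))

matrix = gene_sample_matrix(maf)  # non-silent variants only
pairs = cooccurrence_scan(matrix, top_k=10, alpha=0.05)
called = pairs[pairs["call"] != "ns"]
print(f"\n{len(called)} of {len(pairs)} gene pairs called at p < 0.05:")
print(called[["gene_a", "gene_b", "odds_ratio", "p", "call"]].head(5).to_string(index=False))
print("(driver labels are drawn independently per sample, so most pairs are null)")
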