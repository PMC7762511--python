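"""Cohort-level somatic-mutation summaries.

Classification counts, per-sample variant load, top recurrently mutated
genes, and pairwise co-occurrence / mutual exclusivity of gene-level
mutation status by Fisher's exact test (two-sided, probability-mass
method — the sum of hypergeometric probabilities no larger than the
observed table's).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .maf_io import MafTable

__all__ = [
    "MafSummary",
    "summarize_maf",
    "gene_sample_matrix",
    "fisher_exact_2x2",
    "cooccurrence_scan",
    "NONSILENT_CLASSIFICATIONS",
]

#: default qualifying classifications for the gene x sample matrix
NONSILENT_CLASSIFICATIONS = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
    }
)


@dataclass
class MafSummary:
    classification_counts: pd.Series  # classification -> variant count
    sample_load: pd.Series  # sample -> variant count
    median_load: float
    top_genes: pd.DataFrame  # gene, n_samples (mutated-sample count)


def summarize_maf(maf: MafTable, top_k: int = 25) -> MafSummary:
    """Classification counts, per-sample load with median, top mutated genes.

    Gene ranking counts each *sample* once per gene (a gene hit twice in
    one sample contributes one), descending by sample count with
    alphabetical tie-break.
    """
    if len(maf) == 0:
        raise ValueError("summarize_maf requires a non-empty MafTable")
    f = maf.frame
    cls_counts = f["variant_classification"].value_counts()
    load = f.groupby("sample_id", sort=False).size()
    per_gene = (
        f[["gene", "sample_id"]]
        .drop_duplicates()
        .groupby("gene", sort=False)
        .size()
        .reset_index(name="n_samples")
        .sort_values(["n_samples", "gene"], ascending=[False, True], kind="stable")
        .head(top_k)
        .reset_index(drop=True)
    )
    return MafSummary(cls_counts, load, float(load.median()), per_gene)


def gene_sample_matrix(
    maf: MafTable, qualifying: Sequence[str] | None = None
) -> pd.DataFrame:
    """Binary gene x sample matrix: 1 = sample carries >=1 qualifying variant.

    ``qualifying`` defaults to the non-silent classifications.
    """
    quals = set(qualifying) if qualifying is not None else NONSILENT_CLASSIFICATIONS
    f = maf.frame[maf.frame["variant_classification"].isin(quals)]
    mat = pd.crosstab(f["gene"], f["sample_id"])
    # keep every sample of the cohort, even if it has no qualifying variant
    mat = mat.reindex(columns=maf.samples, fill_value=0)
    return (mat > 0).astype(np.int8)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns ``(odds_ratio, p_two_sided)``.  The p-value sums the
    hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's.  The odds
    ratio is the sample OR ad/bc, with a 0.5 Haldane correction applied
    to every cell when any cell is zero (for display only).
    """
    cells = (a, b, c, d)
    if any(int(v) != v or v < 0 for v in cells):
        raise ValueError("table entries must be non-negative integers")
    a, b, c, d = (int(v) for v in cells)
    if a + b + c + d == 0:
        raise ValueError("empty table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        orat = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        orat = a * d / (b * c)
    return float(orat), float(p)


def cooccurrence_scan(
    matrix: pd.DataFrame, top_k: int = 25, alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise Fisher tests among the ``top_k`` most mutated genes.

    Calls a pair ``co_occurring`` when p < alpha and OR > 1, ``exclusive``
    when p < alpha and OR < 1, else ``ns``.  The 2x2 counts per pair are
    (both, A-only, B-only, neither) over all samples.
    """
    if top_k < 2:
        raise ValueError("top_k must be at least 2")
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    freq = pd.DataFrame(
        {"gene": matrix.index.astype(str), "n": matrix.sum(axis=1).to_numpy()}
    )
    genes = (
        freq.sort_values(["n", "gene"], ascending=[False, True], kind="stable")
        .head(top_k)["gene"]
        .tolist()
    )
    m = matrix.loc[genes].to_numpy(dtype=bool)
    rows = []
    for i, j in combinations(range(len(genes)), 2):
        gi, gj = m[i], m[j]
        both = int((gi & gj).sum())
        a_only = int((gi & ~gj).sum())
        b_only = int((~gi & gj).sum())
        neither = int((~gi & ~gj).sum())
        orat, p = fisher_exact_2x2(both, a_only, b_only, neither)
        if p < alpha and orat > 1:
            call = "co_occurring"
        elif p < alpha and orat < 1:
            call = "exclusive"
        else:
            call = "ns"
        rows.append(
            {"gene_a": genes[i], "gene_b": genes[j], "both": both,
             "a_only": a_only, "b_only": b_only, "neither": neither,
             "odds_ratio": orat, "p": p, "call": call}
        )
    return pd.DataFrame(rows)
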