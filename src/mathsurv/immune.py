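"""Single-sample immune-cell enrichment and group comparison.

Each of 28 immune-cell-type gene sets is scored per sample with a
rank-based single-sample enrichment statistic (ssGSEA-style): genes are
ranked by expression within the sample and the score accumulates the gap
between the weighted in-set rank ECDF and the out-of-set position ECDF.
Because the statistic depends on within-sample ranks only, it is
invariant under any strictly monotone transform of a sample's
expression values.

Groups (high vs low/intermediate heterogeneity) are compared per cell
type with the Mann-Whitney rank-sum z statistic, and each cell type's
score can be related to overall survival with a Cox model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .maf_io import GeneSetCollection
from .survival import CoxFit, cox_fit

__all__ = [
    "ssgsea_score",
    "ssgsea_matrix",
    "mannwhitney_z",
    "immune_diff_table",
    "per_celltype_cox",
]


def ssgsea_score(expression_column: pd.Series, gene_set, alpha: float = 0.25) -> float:
    """Single-sample enrichment score of one gene set in one sample.

    Genes are ranked descending by expression (rank N = top).  With
    in-set indicator h and rank weights r^alpha, the score is

        sum_i [ P_in(i) - P_out(i) ]

    over list positions i, where P_in is the weighted ECDF of in-set
    genes and P_out the ECDF of out-of-set positions.  alpha = 0 reduces
    to an unweighted KS-style area statistic; the default 0.25 mildly
    emphasizes extreme ranks.
    """
    scores = ssgsea_matrix(
        expression_column.to_frame(name="s"), GeneSetCollection({"set": list(gene_set)}), alpha
    )
    return float(scores.iloc[0, 0])


def ssgsea_matrix(
    expression: pd.DataFrame, sets: GeneSetCollection, alpha: float = 0.25
) -> pd.DataFrame:
    """ssGSEA-style scores for every set x sample.

    ``expression``: genes x samples.  Every set must intersect the gene
    index and must not cover it entirely.  Ties in expression are broken
    by gene-index order (stable), so scores are deterministic.
    """
    n_genes, n_samples = expression.shape
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    gene_names = expression.index.astype(str).to_numpy()
    X = expression.to_numpy(dtype=float)

    hits = np.empty((len(sets), n_genes), dtype=bool)
    for i, (name, genes) in enumerate(sets.items()):
        mask = np.isin(gene_names, genes)
        if not mask.any():
            raise ValueError(f"gene set {name!r} shares no genes with the matrix")
        if mask.all():
            raise ValueError(f"gene set {name!r} covers every gene")
        hits[i] = mask

    # descending order per sample; stable -> ties broken by gene order
    order = np.argsort(-X, axis=0, kind="stable")  # genes x samples
    # rank value of the gene at descending position i is N - i
    rank_at_pos = (n_genes - np.arange(n_genes)).astype(float)
    w = rank_at_pos**alpha

    out = np.empty((len(sets), n_samples))
    for j in range(n_samples):
        h_ord = hits[:, order[:, j]]  # sets x positions
        hit_w = h_ord * w
        p_in = np.cumsum(hit_w, axis=1) / hit_w.sum(axis=1, keepdims=True)
        n_out = (~h_ord).sum(axis=1, keepdims=True)
        p_out = np.cumsum(~h_ord, axis=1) / n_out
        out[:, j] = (p_in - p_out).sum(axis=1)
    return pd.DataFrame(out, index=list(sets), columns=expression.columns)


def mannwhitney_z(x, y, continuity: bool = False) -> tuple[float, float]:
    """Mann-Whitney rank-sum test, normal approximation with tie correction.

    Returns ``(z, p)`` two-sided, with U computed for ``x``: positive z
    means ``x`` tends to exceed ``y``.  When every value is tied across
    both samples the test is degenerate and returns ``(0, 1)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mean = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations tied
        return 0.0, 1.0
    diff = u - mean
    if continuity:
        diff = np.sign(diff) * max(abs(diff) - 0.5, 0.0)
    z = diff / np.sqrt(var)
    p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return float(z), p


def immune_diff_table(
    scores: pd.DataFrame,
    group_labels: pd.Series,
    reference: str = "low_intermediate",
    alpha_level: float = 0.05,
    continuity: bool = False,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-cell-type comparison of enrichment scores between two groups.

    ``scores``: cell types x samples; ``group_labels``: sample ->
    {"low_intermediate", "high"}.  z is computed with the reference
    (low/intermediate) group as x, so positive z means higher scores in
    low/intermediate.  Direction labels follow the sign of the median
    score difference.  ``adjust="bh"`` applies Benjamini-Hochberg to the
    p column (off by default; raw p is what is tabulated).
    """
    labels = group_labels.reindex(scores.columns)
    mask_ref = (labels == reference).to_numpy()
    mask_other = labels.notna().to_numpy() & ~mask_ref
    if mask_ref.sum() < 2 or mask_other.sum() < 2:
        raise ValueError("both groups need at least 2 samples")
    rows = []
    for cell_type, vals in scores.iterrows():
        v = vals.to_numpy(dtype=float)
        z, p = mannwhitney_z(v[mask_ref], v[mask_other], continuity=continuity)
        med_diff = np.median(v[mask_ref]) - np.median(v[mask_other])
        if med_diff > 0:
            direction = "higher_in_low_intermediate"
        elif med_diff < 0:
            direction = "higher_in_high"
        else:
            direction = "higher_in_low_intermediate" if z >= 0 else "higher_in_high"
        rows.append({"cell_type": cell_type, "z": z, "p": p, "direction": direction})
    out = pd.DataFrame(rows)
    if adjust == "bh":
        out["p_adj"] = _benjamini_hochberg(out["p"].to_numpy())
        out["significant"] = out["p_adj"] < alpha_level
    else:
        out["significant"] = out["p"] < alpha_level
    out.attrs["n_significant"] = int(out["significant"].sum())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.minimum(adj, 1.0)


@dataclass
class CellTypeCoxRow:
    cell_type: str
    fit: CoxFit | None
    flag: str  # "" or the reason the fit was skipped


def per_celltype_cox(
    scores: pd.DataFrame,
    times,
    events,
    covariates: pd.DataFrame | None = None,
    standardize: bool = True,
) -> pd.DataFrame:
    """Cox model of overall survival on each cell type's score.

    Scores are standardized (mean 0, SD 1) by default so hazard ratios
    are per-SD.  Optional ``covariates`` (aligned to the score columns)
    are added to every model.  Constant score rows are flagged and not
    fitted.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    rows = []
    for cell_type, vals in scores.iterrows():
        v = vals.to_numpy(dtype=float)
        if np.ptp(v) == 0:
            rows.append(
                {"cell_type": cell_type, "hr": np.nan, "ci_low": np.nan,
                 "ci_high": np.nan, "p": np.nan, "flag": "constant_score"}
            )
            continue
        if standardize:
            v = (v - v.mean()) / v.std(ddof=1)
        design = pd.DataFrame({"score": v})
        if covariates is not None:
            design = pd.concat([design, covariates.reset_index(drop=True)], axis=1)
        fit = cox_fit(t, e, design)
        row = fit.table.iloc[0]
        rows.append(
            {"cell_type": cell_type, "hr": row["hr"], "ci_low": row["ci_low"],
             "ci_high": row["ci_high"], "p": row["p"],
             "flag": ";".join(fit.flags)}
        )
    return pd.DataFrame(rows)
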