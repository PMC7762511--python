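"""Two-phenotype gene-set enrichment analysis (GSEA).

Genes are ranked by a signal-to-noise metric between two phenotype
classes; each gene set's enrichment score (ES) is the extremum of a
weighted Kolmogorov-Smirnov running sum down that ranking; significance
comes from a phenotype-label permutation null: the normalized enrichment
score (NES) divides ES by the mean magnitude of same-sign null scores,
the nominal p is the fraction of same-sign null scores at least as
extreme (with the (b+1)/(B+1) convention, so never exactly zero), and the
FDR q compares the pooled null NES distribution with the observed NES
distribution.  A set is called significant under the rule
``nominal p < 0.05 and |NES| >= 1 and q < 0.25``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .maf_io import GeneSetCollection

__all__ = ["rank_genes", "enrichment_score", "gsea_significance", "GseaSettings"]


@dataclass(frozen=True)
class GseaSettings:
    """Significance thresholds and permutation settings."""

    n_perm: int = 1000
    weight_p: float = 1.0
    p_threshold: float = 0.05
    nes_threshold: float = 1.0
    q_threshold: float = 0.25


def _snr_metric(X: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Signal-to-noise (mu_A - mu_B)/(s_A + s_B) with the GSEA SD floor.

    Each class SD is floored at 0.2 * |class mean| (0.2 absolute when the
    mean is zero), which keeps low-variance genes from dominating.
    """
    a = X[:, mask_a]
    b = X[:, ~mask_a]
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    sd_a, sd_b = a.std(axis=1, ddof=1), b.std(axis=1, ddof=1)
    sd_a = np.maximum(sd_a, np.where(mu_a != 0, 0.2 * np.abs(mu_a), 0.2))
    sd_b = np.maximum(sd_b, np.where(mu_b != 0, 0.2 * np.abs(mu_b), 0.2))
    return (mu_a - mu_b) / (sd_a + sd_b)


def rank_genes(expression: pd.DataFrame, phenotype, positive_class=None) -> pd.DataFrame:
    """Rank genes by signal-to-noise between two phenotype classes.

    Parameters
    ----------
    expression
        genes x samples DataFrame (index = gene symbols).
    phenotype
        per-sample labels with exactly two distinct values; class A (the
        metric's positive direction) is ``positive_class`` or, when None,
        the first label in sorted order.

    Returns a DataFrame (gene, metric) in descending metric order, ties
    broken by gene symbol.
    """
    labels = np.asarray(phenotype)
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) != 2:
        raise ValueError(f"phenotype must have exactly 2 classes, got {classes}")
    pos = classes[0] if positive_class is None else positive_class
    mask_a = labels == pos
    if mask_a.sum() < 2 or (~mask_a).sum() < 2:
        raise ValueError("each phenotype class needs at least 2 samples")
    metric = _snr_metric(expression.to_numpy(dtype=float), mask_a)
    out = pd.DataFrame({"gene": expression.index.astype(str), "metric": metric})
    return out.sort_values(["metric", "gene"], ascending=[False, True], kind="stable").reset_index(drop=True)


def enrichment_score(
    ranked: pd.DataFrame, gene_set, weight_p: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score of one set against a ranked list.

    Hits step the running sum up by |metric|^p (normalized over hits);
    misses step it down by 1/(N - N_hit).  ES is the running-sum value of
    maximal absolute deviation from zero.
    """
    genes = ranked["gene"].to_numpy()
    metric = ranked["metric"].to_numpy(dtype=float)
    hit = np.isin(genes, list(gene_set))
    if not hit.any():
        raise ValueError("gene set does not intersect the ranked list")
    run = _running_sum(metric, hit, weight_p)
    es = float(run[np.argmax(np.abs(run))])
    return es, run


def _running_sum(metric: np.ndarray, hit: np.ndarray, weight_p: float) -> np.ndarray:
    n = metric.size
    n_hit = int(hit.sum())
    if n_hit == n:
        raise ValueError("gene set covers the entire ranked list")
    w = np.abs(metric) ** weight_p
    hit_w = np.where(hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all-zero metrics with p>0: fall back to equal hit weights
        hit_w = hit.astype(float)
        denom = float(n_hit)
    steps = hit_w / denom - (~hit) / (n - n_hit)
    return np.cumsum(steps)


def _es_all_sets(order: np.ndarray, metric: np.ndarray, hits: np.ndarray, weight_p: float) -> np.ndarray:
    """ES of every set (rows of boolean matrix ``hits``) for one ranking."""
    m = np.abs(metric[order]) ** weight_p
    h = hits[:, order]
    n = metric.size
    n_hit = h.sum(axis=1)
    hit_w = h * m
    denom = hit_w.sum(axis=1)
    fallback = denom == 0
    if fallback.any():
        hit_w[fallback] = h[fallback].astype(float)
        denom[fallback] = n_hit[fallback]
    steps = hit_w / denom[:, None] - (~h) / (n - n_hit)[:, None]
    run = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(run), axis=1)
    return run[np.arange(run.shape[0]), idx]


def gsea_significance(
    expression: pd.DataFrame,
    phenotype,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int | None = None,
    settings: GseaSettings | None = None,
    positive_class=None,
) -> pd.DataFrame:
    """GSEA with a phenotype-permutation null for a collection of sets.

    Returns one row per set: es, nes, nominal_p, fdr_q, direction
    (``up_in_A`` for positive ES, where A is the positive class) and a
    ``significant`` flag per the p/NES/q rule in :class:`GseaSettings`.
    Sets not intersecting the expression index are dropped with a warning.
    """
    settings = settings or GseaSettings(n_perm=n_perm)
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if seed is None:
        raise ValueError("a seed is required for the permutation null")
    labels = np.asarray(phenotype)
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) != 2:
        raise ValueError(f"phenotype must have exactly 2 classes, got {classes}")
    pos = classes[0] if positive_class is None else positive_class
    mask_a = labels == pos
    n_samples = labels.size
    n_a = int(mask_a.sum())
    max_distinct = comb(n_samples, n_a)
    if n_perm > max_distinct:
        warnings.warn(
            f"requested {n_perm} permutations but only {max_distinct} distinct "
            f"label assignments exist; capping",
            stacklevel=2,
        )
        n_perm = max_distinct

    # genes pre-sorted lexicographically: stable argsort then breaks metric
    # ties by gene symbol
    expr = expression.sort_index(kind="stable")
    gene_names = expr.index.astype(str).to_numpy()
    X = expr.to_numpy(dtype=float)

    set_names, hits_rows = [], []
    for name, genes in sets.items():
        mask = np.isin(gene_names, genes)
        if not mask.any():
            warnings.warn(f"gene set {name!r} has no genes in the expression matrix", stacklevel=2)
            continue
        if mask.all():
            raise ValueError(f"gene set {name!r} covers every gene")
        set_names.append(name)
        hits_rows.append(mask)
    if not set_names:
        raise ValueError("no gene set overlaps the expression matrix")
    hits = np.stack(hits_rows)

    metric_obs = _snr_metric(X, mask_a)
    order_obs = np.argsort(-metric_obs, kind="stable")
    es_obs = _es_all_sets(order_obs, metric_obs, hits, settings.weight_p)

    rng = np.random.default_rng(seed)
    es_null = np.empty((len(set_names), n_perm))
    idx = np.arange(n_samples)
    for b in range(n_perm):
        perm = rng.permutation(idx)
        mask_p = np.zeros(n_samples, dtype=bool)
        mask_p[perm[:n_a]] = True
        metric_p = _snr_metric(X, mask_p)
        order_p = np.argsort(-metric_p, kind="stable")
        es_null[:, b] = _es_all_sets(order_p, metric_p, hits, settings.weight_p)

    nes_obs = np.empty(len(set_names))
    nominal_p = np.empty(len(set_names))
    nes_null = np.empty_like(es_null)
    for i, es in enumerate(es_obs):
        null = es_null[i]
        pos_mean = null[null > 0].mean() if (null > 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        # normalize each null ES by its own sign's mean magnitude
        nes_null[i] = np.where(
            null >= 0,
            null / pos_mean if np.isfinite(pos_mean) else np.nan,
            null / neg_mean if np.isfinite(neg_mean) else np.nan,
        )
        same = null >= 0 if es >= 0 else null < 0
        b_extreme = int((np.abs(null[same]) >= abs(es)).sum())
        nominal_p[i] = (b_extreme + 1) / (int(same.sum()) + 1)
        mean_mag = pos_mean if es >= 0 else neg_mean
        nes_obs[i] = es / mean_mag if np.isfinite(mean_mag) else np.nan

    # FDR q: pooled-null vs observed tail ratio, per sign
    flat_null = nes_null[np.isfinite(nes_null)]
    fdr_q = np.empty(len(set_names))
    for i, nes in enumerate(nes_obs):
        if not np.isfinite(nes):
            fdr_q[i] = 1.0
            continue
        if nes >= 0:
            null_pool = flat_null[flat_null >= 0]
            obs_pool = nes_obs[np.isfinite(nes_obs) & (nes_obs >= 0)]
            num = (null_pool >= nes).mean() if null_pool.size else 1.0
            den = (obs_pool >= nes).mean()
        else:
            null_pool = flat_null[flat_null < 0]
            obs_pool = nes_obs[np.isfinite(nes_obs) & (nes_obs < 0)]
            num = (null_pool <= nes).mean() if null_pool.size else 1.0
            den = (obs_pool <= nes).mean()
        fdr_q[i] = min(1.0, num / den) if den > 0 else 1.0

    out = pd.DataFrame(
        {
            "set": set_names,
            "es": es_obs,
            "nes": nes_obs,
            "nominal_p": nominal_p,
            "fdr_q": fdr_q,
            "direction": np.where(es_obs >= 0, "up_in_A", "up_in_B"),
        }
    )
    out["significant"] = (
        (out["nominal_p"] < settings.p_threshold)
        & (out["nes"].abs() >= settings.nes_threshold)
        & (out["fdr_q"] < settings.q_threshold)
    )
    out.attrs["positive_class"] = pos
    out.attrs["n_perm"] = n_perm
    return out
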