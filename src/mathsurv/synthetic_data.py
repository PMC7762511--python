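"""Synthetic tumor cohorts with known ground truth.

Generates the three inputs the pipeline consumes — a somatic-mutation MAF,
a clinical/survival table, and a gene-expression matrix — from an explicit
generative model, and records the ground truth alongside so every pipeline
stage can be validated without external data.

The model, per sample:

* **Mutations.**  A purity is drawn uniformly from ``purity_range``; the
  tumor has a truncal clone (cancer-cell fraction 1) plus a random number
  of subclones with CCFs drawn uniformly from ``[max(0.2, 1 - 5*theta), 1]``
  — ``theta`` is the single dial for subclonal dispersion, and mean MATH
  rises monotonically with it (the 0.2 floor reflects the detection limit
  of variant calling at this depth).  Variant count is negative binomial
  (mean 63 by default, matching a whole-exome gastric cohort); each
  variant joins the truncal clone with probability ``p_clonal`` else a
  random subclone.  True VAF is ``purity * CCF / 2``
  (diploid heterozygous; no copy-number simulation so the truth stays
  clean), sequencing depth is Poisson (mean 150) with zero-depth draws
  redrawn, and alt reads are binomial.
* **Survival.**  Overall survival is Weibull with the log hazard shifted
  by ``group_log_hr`` per heterogeneity-group step (low=0, intermediate=1,
  high=2); censoring is an independent uniform time whose upper bound is
  calibrated by bisection to the target censoring fraction.  Clinical
  covariates are drawn with the level frequencies of a typical resected
  gastric-cancer cohort.
* **Expression.**  Log-scale Gaussian per gene; genes belonging to the
  configured shifted sets gain ``expression_shift`` (in units of the
  gene's SD) in the low/intermediate group, emulating higher immune
  infiltration in less heterogeneous tumors.

All randomness flows from one seed via ``numpy`` SeedSequence spawning,
so the MAF, survival and expression streams are independently
reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .maf_io import GeneSetCollection, MafTable, load_immune_sets

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "simulate_maf",
    "simulate_survival",
    "simulate_expression",
    "DEFAULT_SHIFTED_SETS",
    "DEFAULT_GENE_FREQUENCIES",
]

#: the 20 immune cell types shifted by default (more abundant in the
#: low/intermediate heterogeneity group)
DEFAULT_SHIFTED_SETS = (
    "Activated CD4 T cell",
    "Activated CD8 T cell",
    "Central memory CD4 T cell",
    "Central memory CD8 T cell",
    "Effector memory CD4 T cell",
    "Effector memory CD8 T cell",
    "Type 1 T helper cell",
    "Activated dendritic cell",
    "Natural killer cell",
    "Regulatory T cell",
    "Type 2 T helper cell",
    "Gamma delta T cell",
    "Activated B cell",
    "Immature B cell",
    "T follicular helper cell",
    "Mast cell",
    "MDSC",
    "Macrophage",
    "Eosinophil",
    "Monocyte",
)

#: frequently mutated gastric-cancer genes with per-sample mutation
#: probabilities used to label simulated variants (user-replaceable)
DEFAULT_GENE_FREQUENCIES = {
    "TTN": 0.50,
    "TP53": 0.45,
    "MUC16": 0.30,
    "LRP1B": 0.25,
    "FAT4": 0.22,
    "CSMD1": 0.20,
    "SYNE1": 0.20,
    "OBSCN": 0.18,
    "FLG": 0.16,
    "PIK3CA": 0.15,
}

VARIANT_CLASS_PROBS = {
    "Missense_Mutation": 0.60,
    "Silent": 0.15,
    "Nonsense_Mutation": 0.08,
    "Frame_Shift_Del": 0.05,
    "Frame_Shift_Ins": 0.04,
    "Splice_Site": 0.04,
    "In_Frame_Del": 0.02,
    "Nonstop_Mutation": 0.02,
}


@dataclass
class SyntheticConfig:
    """All generator dials with cohort-realistic defaults.

    Defaults describe a resected gastric-adenocarcinoma cohort profiled by
    whole-exome sequencing at ~150x with a median of ~63 somatic variants
    per sample, three heterogeneity tertiles with a hazard ratio of ~1.43
    per tertile step, and 20 of 28 immune cell types more infiltrated in
    the low/intermediate group.
    """

    seed: int
    n_samples: int = 385
    # mutations
    variants_mean: float = 63.0
    variants_dispersion: float = 12.0  # negative-binomial size parameter
    depth_mean: float = 150.0
    purity_range: tuple[float, float] = (0.5, 0.9)
    subclone_count_range: tuple[int, int] = (1, 3)
    subclone_dispersion: float = 0.13  # theta
    p_clonal: float = 0.5
    gene_frequencies: dict = field(default_factory=lambda: dict(DEFAULT_GENE_FREQUENCIES))
    n_background_genes: int = 400
    # survival (times in months)
    weibull_shape: float = 1.2
    weibull_scale: float = 40.0
    group_log_hr: float = float(np.log(1.433))
    censoring_target: float = 0.5
    chemo_fraction: float = 171.0 / 385.0
    # expression
    n_genes: int = 2000
    expression_shift: float = 1.0  # delta, in per-gene SD units
    shifted_sets: tuple[str, ...] = DEFAULT_SHIFTED_SETS

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0 <= self.purity_range[0] <= self.purity_range[1] <= 1):
            raise ValueError("purity_range must be within [0, 1]")
        if self.subclone_dispersion < 0:
            raise ValueError("subclone_dispersion must be >= 0")
        if not 0 <= self.censoring_target < 1:
            raise ValueError("censoring_target must be in [0, 1)")

    def streams(self) -> dict[str, np.random.Generator]:
        """Independent child generators for each component."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        names = ("maf", "survival", "expression")
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    theta: float
    purity: dict[str, float] = field(default_factory=dict)
    ccfs: dict[str, list[float]] = field(default_factory=dict)
    n_zero_depth_redraws: int = 0
    survival_log_hr: float | None = None
    censoring_achieved: float | None = None
    shifted_sets: list[str] = field(default_factory=list)
    expression_shift: float | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(1, n + 1)]


def simulate_maf(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[MafTable, GroundTruth]:
    """Simulate a cohort MAF and its ground truth (see module docstring)."""
    rng = rng or config.streams()["maf"]
    truth = GroundTruth(theta=config.subclone_dispersion)

    gene_names = list(config.gene_frequencies) + [
        f"GENE{i:04d}" for i in range(1, config.n_background_genes + 1)
    ]
    top_p = np.array(list(config.gene_frequencies.values()))
    classes = list(VARIANT_CLASS_PROBS)
    class_p = np.array(list(VARIANT_CLASS_PROBS.values()))
    class_p = class_p / class_p.sum()

    r = config.variants_dispersion
    nb_p = r / (r + config.variants_mean)

    rows: list[dict] = []
    for sid in _sample_ids(config.n_samples):
        purity = rng.uniform(*config.purity_range)
        k = int(rng.integers(config.subclone_count_range[0], config.subclone_count_range[1] + 1))
        if config.subclone_dispersion > 0:
            ccf_lo = max(0.2, 1.0 - 5.0 * config.subclone_dispersion)
            sub_ccfs = rng.uniform(ccf_lo, 1.0, size=k)
        else:
            sub_ccfs = np.ones(k)
        ccfs = np.concatenate([[1.0], sub_ccfs])
        truth.purity[sid] = float(purity)
        truth.ccfs[sid] = [float(c) for c in ccfs]

        n_var = int(rng.negative_binomial(r, nb_p))
        n_var = max(n_var, 1)
        clone_idx = np.where(
            rng.random(n_var) < config.p_clonal,
            0,
            rng.integers(1, len(ccfs), size=n_var),
        )
        true_vaf = purity * ccfs[clone_idx] / 2.0
        depth = rng.poisson(config.depth_mean, size=n_var)
        zero = depth == 0
        while zero.any():
            truth.n_zero_depth_redraws += int(zero.sum())
            depth[zero] = rng.poisson(config.depth_mean, size=int(zero.sum()))
            zero = depth == 0
        alt = rng.binomial(depth, true_vaf)
        ref = depth - alt

        # the ten driver-like genes appear at their configured per-sample
        # frequency; remaining variants get background labels
        mutated_top = np.flatnonzero(rng.random(top_p.size) < top_p)
        labels = [gene_names[g] for g in mutated_top[:n_var]]
        n_rest = n_var - len(labels)
        if n_rest > 0:
            labels += [
                gene_names[int(g)]
                for g in rng.integers(top_p.size, len(gene_names), size=n_rest)
            ]
        cls = rng.choice(classes, size=n_var, p=class_p)
        chrom = rng.integers(1, 23, size=n_var)
        pos = rng.integers(1, 100_000_000, size=n_var)
        for i in range(n_var):
            rows.append(
                {
                    "sample_id": sid,
                    "gene": labels[i],
                    "chromosome": str(chrom[i]),
                    "start_position": int(pos[i]),
                    "variant_classification": cls[i],
                    "t_ref_count": float(ref[i]),
                    "t_alt_count": float(alt[i]),
                    "vaf": float(alt[i] / depth[i]),
                }
            )
    frame = pd.DataFrame(rows, columns=MafTable.COLUMNS)
    return MafTable(frame), truth


def _calibrate_censoring(event_times: np.ndarray, target: float) -> float:
    """Upper bound of Uniform(0, c) censoring hitting the target fraction.

    P(censored | T) = min(T / c, 1); solved by bisection on c (the
    expected fraction is monotone decreasing in c).
    """
    if target <= 0:
        return np.inf

    def frac(c: float) -> float:
        return float(np.minimum(event_times / c, 1.0).mean())

    lo, hi = 1e-9, float(event_times.max()) * 1000
    if frac(hi) > target:  # even huge horizons censor more than asked
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


#: level frequencies of the clinical covariates (typical resected
#: gastric-cancer cohort; counts/385 of a reference distribution)
CLINICAL_LEVELS = {
    "sex": (("Male", 252), ("Female", 133)),
    "age_group": ((">=60", 265), ("<60", 120)),
    "stage": (("I", 49), ("II", 122), ("III", 162), ("IV", 36), ("NA", 16)),
    "grade": (("Gx", 9), ("G1", 10), ("G2", 144), ("G3", 222)),
    "radiation": (("Yes", 44), ("No", 156), ("NA", 185)),
    "histology": (("Diffuse", 53), ("Intestinal", 184), ("SignetRing", 12), ("NA", 136)),
}


def simulate_survival(
    config: SyntheticConfig,
    math_groups: pd.Series,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate survival + clinical covariates for labelled samples.

    ``math_groups``: sample_id -> group code {0, 1, 2} (or the labels
    low/intermediate/high).  Event times are Weibull under proportional
    hazards with ``config.group_log_hr`` per group step.
    """
    rng = rng or config.streams()["survival"]
    codes = math_groups.map({"low": 0, "intermediate": 1, "high": 2}).fillna(math_groups)
    g = codes.to_numpy(dtype=float)
    n = g.size
    if n == 0:
        raise ValueError("math_groups is empty")

    shape, scale, beta = config.weibull_shape, config.weibull_scale, config.group_log_hr
    u = rng.uniform(size=n)
    t_event = scale * (-np.log(u) / np.exp(beta * g)) ** (1.0 / shape)

    c_max = _calibrate_censoring(t_event, config.censoring_target)
    if np.isinf(c_max):
        os_time, os_event = t_event, np.ones(n, dtype=int)
        achieved = 0.0
    else:
        c = rng.uniform(0, c_max, size=n)
        os_event = (t_event <= c).astype(int)
        os_time = np.minimum(t_event, c)
        achieved = float(1 - os_event.mean())
    if abs(achieved - config.censoring_target) > 0.1:
        warnings.warn(
            f"achieved censoring fraction {achieved:.2f} differs from target "
            f"{config.censoring_target:.2f}",
            stacklevel=2,
        )

    clinical = pd.DataFrame({"sample_id": math_groups.index})
    for col, levels in CLINICAL_LEVELS.items():
        names = [lv for lv, _ in levels]
        weights = np.array([w for _, w in levels], dtype=float)
        clinical[col] = rng.choice(names, size=n, p=weights / weights.sum())
    age = np.where(
        clinical["age_group"] == ">=60",
        rng.integers(60, 91, size=n),
        rng.integers(30, 60, size=n),
    )
    clinical["age"] = age
    clinical["adjuvant_chemo"] = (rng.random(n) < config.chemo_fraction).astype(int)
    clinical["os_time"] = np.round(os_time, 3)
    clinical["os_event"] = os_event

    truth = GroundTruth(
        theta=config.subclone_dispersion,
        survival_log_hr=float(beta),
        censoring_achieved=achieved,
    )
    return clinical, truth


def simulate_expression(
    config: SyntheticConfig,
    math_groups: pd.Series,
    sets: GeneSetCollection | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a genes x samples log-expression matrix with planted shifts.

    Genes of every configured shifted set gain ``expression_shift`` SDs in
    the low/intermediate group (codes 0/1).  Overlapping shifted sets add
    their shifts (warned).
    """
    rng = rng or config.streams()["expression"]
    sets = sets or load_immune_sets()
    missing = [s for s in config.shifted_sets if s not in set(sets)]
    if missing:
        raise ValueError(f"shifted sets not in the collection: {missing}")

    codes = math_groups.map({"low": 0, "intermediate": 1, "high": 2}).fillna(math_groups)
    low_int = (codes.to_numpy(dtype=float) < 2).astype(float)
    samples = list(math_groups.index)
    n = len(samples)

    gene_names = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    mu = rng.normal(8.0, 2.0, size=config.n_genes)
    sd = rng.uniform(0.5, 1.5, size=config.n_genes)
    X = mu[:, None] + sd[:, None] * rng.standard_normal((config.n_genes, n))

    name_to_idx = {g: i for i, g in enumerate(gene_names)}
    shift_count = np.zeros(config.n_genes)
    for s in config.shifted_sets:
        for gene in sets[s]:
            if gene in name_to_idx:
                shift_count[name_to_idx[gene]] += 1
    if (shift_count > 1).any():
        warnings.warn("overlapping shifted sets: shifts add", stacklevel=2)
    X += (config.expression_shift * shift_count * sd)[:, None] * low_int[None, :]

    expr = pd.DataFrame(X, index=gene_names, columns=samples)
    truth = GroundTruth(
        theta=config.subclone_dispersion,
        shifted_sets=list(config.shifted_sets),
        expression_shift=float(config.expression_shift),
    )
    return expr, truth
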