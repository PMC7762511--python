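"""The MATH intra-tumoral-heterogeneity statistic.

MATH (mutant-allele tumor heterogeneity) summarizes how dispersed a
tumor's variant allele fractions are:

    MATH = 100 * MAD(VAF) / median(VAF)

where MAD is the median absolute deviation scaled by 1.4826 so that, for
normally distributed values, it estimates the standard deviation.  A
homogeneous (single-clone, diploid) tumor concentrates its VAFs near one
value and scores near 0; subclonal structure spreads the VAFs and raises
the score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["MAD_SCALE", "MathResult", "mad_scaled", "math_score", "cohort_math", "cohort_summary"]

#: normal-consistency factor: MAD * 1.4826 estimates sigma for Gaussian data
MAD_SCALE = 1.4826

QC_OK = "ok"
QC_TOO_FEW = "too_few_variants"
QC_ZERO_MEDIAN = "zero_median"


@dataclass(frozen=True)
class MathResult:
    """Per-sample MATH computation with its QC disposition."""

    sample_id: str
    n_variants: int
    median_vaf: float  # NaN when no variants
    mad_scaled: float  # NaN when no variants
    math: float  # NaN unless qc_flag == "ok"
    qc_flag: str


def mad_scaled(values: Sequence[float] | np.ndarray) -> float:
    """Scaled median absolute deviation: 1.4826 * median(|x - median(x)|).

    The median of an even-length vector is the mean of the two central
    order statistics.  Raises ``ValueError`` on an empty vector.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("mad_scaled requires a non-empty vector")
    med = np.median(x)
    return MAD_SCALE * float(np.median(np.abs(x - med)))


def math_score(
    vafs: Sequence[float] | np.ndarray,
    min_variants: int = 5,
    sample_id: str = "",
) -> MathResult:
    """MATH score of one sample's VAF vector.

    Degenerate inputs never raise: fewer than ``min_variants`` VAFs flag
    the result ``too_few_variants``; a zero median (all VAFs zero) flags
    ``zero_median``.  In both cases ``math`` is NaN.
    """
    x = np.asarray(vafs, dtype=float)
    n = x.size
    if n < min_variants:
        med = float(np.median(x)) if n else float("nan")
        mad = mad_scaled(x) if n else float("nan")
        return MathResult(sample_id, n, med, mad, float("nan"), QC_TOO_FEW)
    med = float(np.median(x))
    mad = mad_scaled(x)
    if med == 0:
        return MathResult(sample_id, n, med, mad, float("nan"), QC_ZERO_MEDIAN)
    return MathResult(sample_id, n, med, mad, 100.0 * mad / med, QC_OK)


def cohort_math(
    profiles: Mapping[str, Sequence[float] | np.ndarray],
    min_variants: int = 5,
) -> pd.DataFrame:
    """MATH for every sample of a cohort.

    Returns one row per sample (input order) with columns ``sample_id,
    n_variants, median_vaf, mad_scaled, math, qc_flag``.
    """
    if not profiles:
        raise ValueError("cohort_math requires a non-empty profile mapping")
    rows = [vars(math_score(v, min_variants, sample_id=s)) for s, v in profiles.items()]
    return pd.DataFrame(rows)


def cohort_summary(math_table: pd.DataFrame) -> dict:
    """Cohort median and range of MATH over QC-passing samples.

    All-flagged cohorts report NaN summaries and ``n_ok = 0``.
    """
    ok = math_table.loc[math_table["qc_flag"] == QC_OK, "math"]
    if ok.empty:
        return {"n_ok": 0, "median": float("nan"), "min": float("nan"), "max": float("nan")}
    return {
        "n_ok": int(len(ok)),
        "median": float(ok.median()),
        "min": float(ok.min()),
        "max": float(ok.max()),
    }
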