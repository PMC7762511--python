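"""Cohort assembly: clinical join, MATH tertiles, baseline table.

The cohort table is the join key of the whole pipeline: per-sample MATH
scores merged with clinical covariates, plus a ``math_group`` label (low /
intermediate / high) from a rank-based tertile split.  The baseline table
mirrors the familiar "Table 1" of a clinical study: counts and percentages
per characteristic level with a univariate survival p-value per
characteristic.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .heterogeneity import QC_OK
from .survival import logrank_test

__all__ = [
    "GROUP_LABELS",
    "read_clinical",
    "assign_tertiles",
    "format_count_pct",
    "baseline_table",
]

GROUP_LABELS = ("low", "intermediate", "high")

#: canonical clinical columns; os_time units (days/months) are declared by
#: the caller's config and never converted here.
CLINICAL_COLUMNS = [
    "sample_id",
    "os_time",
    "os_event",
    "age",
    "age_group",
    "sex",
    "stage",
    "grade",
    "radiation",
    "histology",
    "adjuvant_chemo",
]


def read_clinical(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a clinical TSV, renaming columns via ``column_map`` (file->canonical).

    Requires sample_id, os_time and os_event; other canonical columns are
    optional and filled with "NA" when absent.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if column_map:
        df = df.rename(columns=column_map)
    for col in ("sample_id", "os_time", "os_event"):
        if col not in df.columns:
            raise ValueError(f"clinical table missing required column {col!r}")
    df["os_time"] = pd.to_numeric(df["os_time"])
    df["os_event"] = pd.to_numeric(df["os_event"]).astype(int)
    if (df["os_time"] < 0).any():
        raise ValueError("negative os_time in clinical table")
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            df[col] = "NA"
    return df[CLINICAL_COLUMNS + [c for c in df.columns if c not in CLINICAL_COLUMNS]]


def assign_tertiles(math_table: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Tertile group labels from MATH scores.

    QC-passing samples are sorted ascending by MATH (ties broken by
    sample_id, stable) and cut at ranks ``floor(n/3)`` and ``floor(2n/3)``;
    the remainder when n is not divisible by 3 therefore lands in the
    *high* group (385 -> 128/128/129).  Samples failing QC get no label.

    Returns
    -------
    (groups, medians)
        ``groups``: sample_id -> label for QC-ok samples;
        ``medians``: per-group median MATH.
    """
    ok = math_table.loc[math_table["qc_flag"] == QC_OK, ["sample_id", "math"]]
    n = len(ok)
    if n < 3:
        raise ValueError(f"tertile assignment requires >=3 usable samples, got {n}")
    ok = ok.sort_values(["math", "sample_id"], kind="stable")
    k1, k2 = n // 3, (2 * n) // 3
    labels = np.empty(n, dtype=object)
    labels[:k1] = GROUP_LABELS[0]
    labels[k1:k2] = GROUP_LABELS[1]
    labels[k2:] = GROUP_LABELS[2]
    groups = pd.Series(labels, index=ok["sample_id"].values, name="math_group")
    medians = pd.Series(
        {lab: float(np.median(ok["math"].values[labels == lab])) for lab in GROUP_LABELS},
        name="median_math",
    )
    return groups, medians


def build_cohort(math_table: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Join MATH results with clinical covariates and label tertiles.

    Rows have a ``math_group`` exactly when their MATH QC flag is ok.
    """
    groups, _ = assign_tertiles(math_table)
    cohort = clinical.merge(math_table, on="sample_id", how="inner")
    cohort["math_group"] = cohort["sample_id"].map(groups)
    return cohort


def format_count_pct(count: int, total: int) -> str:
    """``"252(65.5%)"``-style cell: percent to one decimal, round half up."""
    pct = Decimal(count * 100) / Decimal(total)
    pct = pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return f"{count}({pct}%)"


def _anova_p(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F and p across >=2 groups."""
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def baseline_table(
    cohort: pd.DataFrame,
    characteristics: Sequence[str] = ("sex", "age_group", "stage", "grade", "radiation", "histology", "math_group"),
    continuous: Sequence[str] = (),
) -> pd.DataFrame:
    """Baseline-characteristics table with univariate OS p-values.

    For each categorical characteristic: one row per level with
    ``count(pct%)`` of the whole cohort and, on the first row, the log-rank
    p across its non-NA levels (NA rows are excluded from the test but
    counted in the table).  Each name in ``continuous`` instead gets a
    single row with a one-way ANOVA F-test p across MATH groups.
    """
    if cohort.empty:
        raise ValueError("baseline_table requires a non-empty cohort")
    total = len(cohort)
    rows = []
    for char in characteristics:
        if char not in cohort.columns:
            raise ValueError(f"characteristic {char!r} absent from cohort table")
        col = cohort[char].astype(object).where(cohort[char].notna(), "NA").astype(str)
        levels = sorted(col.unique(), key=lambda v: (v == "NA", v))
        usable = cohort[(col != "NA")]
        test_levels = col[col != "NA"]
        p = np.nan
        if test_levels.nunique() >= 2:
            p = logrank_test(
                usable["os_time"].to_numpy(),
                usable["os_event"].to_numpy(),
                test_levels.to_numpy(),
            ).p_value
        for i, lev in enumerate(levels):
            cnt = int((col == lev).sum())
            rows.append(
                {
                    "characteristic": char,
                    "level": lev,
                    "count": cnt,
                    "formatted": format_count_pct(cnt, total),
                    "p_value": p if i == 0 else np.nan,
                    "test": "logrank" if i == 0 else "",
                }
            )
    for char in continuous:
        if char not in cohort.columns:
            raise ValueError(f"characteristic {char!r} absent from cohort table")
        sub = cohort.dropna(subset=[char, "math_group"])
        parts = [
            sub.loc[sub["math_group"] == lab, char].to_numpy(dtype=float)
            for lab in GROUP_LABELS
            if (sub["math_group"] == lab).sum() >= 2
        ]
        _, p = _anova_p(parts) if len(parts) >= 2 else (np.nan, np.nan)
        rows.append(
            {
                "characteristic": char,
                "level": "(continuous)",
                "count": int(sub[char].notna().sum()),
                "formatted": f"{sub[char].mean():.1f}",
                "p_value": p,
                "test": "anova",
            }
        )
    return pd.DataFrame(rows)
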