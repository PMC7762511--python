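"""Reading and writing somatic-mutation (MAF) and gene-set (GMT) files.

MAF files are the tab-delimited somatic-variant exchange format used by
TCGA: one variant per row, ``#``-prefixed comment lines, a header row, and
1-based inclusive coordinates.  The loader derives a per-variant variant
allele fraction (VAF = alt reads / (alt + ref reads)) from the tumor read
counts, which is the quantity every downstream heterogeneity statistic
operates on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "MafTable",
    "GeneSetCollection",
    "DEFAULT_DIALECT",
    "read_maf",
    "write_maf",
    "vaf_profiles",
    "read_gmt",
    "write_gmt",
    "load_immune_sets",
]

#: canonical column name -> name expected in the file; values may be
#: overridden by the ``dialect`` argument of :func:`read_maf`.
DEFAULT_DIALECT: dict[str, str] = {
    "gene": "Hugo_Symbol",
    "chromosome": "Chromosome",
    "start_position": "Start_Position",
    "variant_classification": "Variant_Classification",
    "sample_id": "Tumor_Sample_Barcode",
    "t_ref_count": "t_ref_count",
    "t_alt_count": "t_alt_count",
}

#: columns whose absence is a hard error (the rest degrade gracefully).
REQUIRED_CANONICAL = ("gene", "sample_id", "variant_classification")


@dataclass(frozen=True)
class VariantRecord:
    """One somatic variant with tumor read counts and derived VAF.

    ``vaf`` is ``None`` when read counts are missing or unparseable;
    otherwise it equals ``t_alt_count / (t_alt_count + t_ref_count)``.
    Coordinates are 1-based inclusive, as in MAF, and never converted.
    """

    sample_id: str
    gene: str
    chromosome: str
    start_position: int
    variant_classification: str
    t_ref_count: int | None
    t_alt_count: int | None
    vaf: float | None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("VariantRecord requires a non-empty sample_id")
        if not self.gene:
            raise ValueError("VariantRecord requires a non-empty gene")
        if self.vaf is not None:
            depth = (self.t_alt_count or 0) + (self.t_ref_count or 0)
            if depth <= 0:
                raise ValueError("vaf present but read depth is zero")
            if abs(self.vaf - self.t_alt_count / depth) > 1e-12:
                raise ValueError("vaf inconsistent with read counts")


class MafTable:
    """Ordered collection of :class:`VariantRecord` backed by a DataFrame.

    Iteration order is the input row order of the source file (or the
    construction order for in-memory tables).
    """

    #: canonical column order of the backing frame
    COLUMNS = [
        "sample_id",
        "gene",
        "chromosome",
        "start_position",
        "variant_classification",
        "t_ref_count",
        "t_alt_count",
        "vaf",
    ]

    def __init__(
        self,
        frame: pd.DataFrame,
        source: str | Path | None = None,
        dialect: Mapping[str, str] | None = None,
        n_flagged: int = 0,
    ) -> None:
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"MafTable frame missing columns: {missing}")
        self.frame = frame[self.COLUMNS].reset_index(drop=True)
        self.source = str(source) if source is not None else None
        self.dialect = dict(dialect or DEFAULT_DIALECT)
        #: rows whose read counts were absent/unparseable (vaf set missing)
        self.n_flagged = int(n_flagged)

    @classmethod
    def from_records(cls, records: Iterable[VariantRecord]) -> "MafTable":
        rows = [vars(r) for r in records]
        frame = pd.DataFrame(rows, columns=cls.COLUMNS)
        return cls(frame)

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[VariantRecord]:
        for row in self.frame.itertuples(index=False):
            yield VariantRecord(
                sample_id=row.sample_id,
                gene=row.gene,
                chromosome=str(row.chromosome),
                start_position=int(row.start_position),
                variant_classification=row.variant_classification,
                t_ref_count=None if pd.isna(row.t_ref_count) else int(row.t_ref_count),
                t_alt_count=None if pd.isna(row.t_alt_count) else int(row.t_alt_count),
                vaf=None if pd.isna(row.vaf) else float(row.vaf),
            )

    @property
    def samples(self) -> list[str]:
        """Sample barcodes in order of first appearance."""
        return list(dict.fromkeys(self.frame["sample_id"]))


def _parse_count(value) -> float:
    """Return a non-negative count or NaN if unparseable/missing."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return np.nan
    try:
        n = int(float(value))
    except (TypeError, ValueError):
        return np.nan
    return float(n) if n >= 0 else np.nan


def read_maf(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> MafTable:
    """Read a tab-delimited MAF file into a :class:`MafTable`.

    Parameters
    ----------
    path
        MAF file; ``#`` comment lines are skipped, a header row is required.
    dialect
        Optional overrides of :data:`DEFAULT_DIALECT`, canonical name ->
        file column name (count-column names vary between MAF producers).

    Raises
    ------
    ValueError
        If a required column (Hugo_Symbol, Tumor_Sample_Barcode,
        Variant_Classification under the active dialect) is absent.

    Notes
    -----
    Rows with missing or unparseable read counts are kept with ``vaf``
    missing and counted in ``MafTable.n_flagged`` — they never crash the
    load.
    """
    colmap = dict(DEFAULT_DIALECT)
    colmap.update(dialect or {})
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for canonical in REQUIRED_CANONICAL:
        if colmap[canonical] not in raw.columns:
            raise ValueError(
                f"MAF file {path} is missing required column {colmap[canonical]!r}"
            )

    n = len(raw)
    frame = pd.DataFrame(index=range(n))
    frame["sample_id"] = raw[colmap["sample_id"]].values
    frame["gene"] = raw[colmap["gene"]].values
    frame["chromosome"] = (
        raw[colmap["chromosome"]].values if colmap["chromosome"] in raw.columns else ""
    )
    if colmap["start_position"] in raw.columns:
        frame["start_position"] = (
            pd.to_numeric(raw[colmap["start_position"]], errors="coerce")
            .fillna(0)
            .astype(int)
            .values
        )
    else:
        frame["start_position"] = 0
    frame["variant_classification"] = raw[colmap["variant_classification"]].values

    for cnt in ("t_ref_count", "t_alt_count"):
        if colmap[cnt] in raw.columns:
            frame[cnt] = np.array([_parse_count(v) for v in raw[colmap[cnt]]])
        else:
            frame[cnt] = np.nan
    depth = frame["t_ref_count"] + frame["t_alt_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = frame["t_alt_count"] / depth
    vaf[~(depth > 0)] = np.nan
    frame["vaf"] = vaf
    n_flagged = int(frame["vaf"].isna().sum())

    bad = (frame["sample_id"] == "") | (frame["gene"] == "")
    if bad.any():
        raise ValueError(
            f"MAF file {path}: {int(bad.sum())} rows with empty sample or gene"
        )
    return MafTable(frame, source=path, dialect=colmap, n_flagged=n_flagged)


def write_maf(maf: MafTable, path: str | Path) -> None:
    """Write a MafTable back to tab-delimited MAF (canonical TCGA headers)."""
    out = pd.DataFrame()
    colmap = DEFAULT_DIALECT
    for canonical in (
        "gene",
        "chromosome",
        "start_position",
        "variant_classification",
        "sample_id",
        "t_ref_count",
        "t_alt_count",
    ):
        col = maf.frame[canonical]
        if canonical in ("t_ref_count", "t_alt_count"):
            col = col.map(lambda v: "" if pd.isna(v) else str(int(v)))
        out[colmap[canonical]] = col
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def vaf_profiles(
    maf: MafTable,
    include: Sequence[str] | None = None,
    vaf_max: float = 0.75,
) -> dict[str, np.ndarray]:
    """Per-sample vectors of retained variant allele fractions.

    A variant is retained when its classification is in ``include`` (all
    classifications when ``include`` is None), its VAF is present, and
    VAF <= ``vaf_max``.  The VAF ceiling damps copy-number / LOH-inflated
    alleles, which would otherwise inflate the dispersion statistic.

    Every sample present in ``maf`` appears in the result, with an empty
    vector if it retains no variants.
    """
    if len(maf) == 0:
        raise ValueError("vaf_profiles requires a non-empty MafTable")
    if include is not None and len(include) == 0:
        raise ValueError("classification include-list must not be empty")
    f = maf.frame
    keep = f["vaf"].notna() & (f["vaf"] <= vaf_max)
    if include is not None:
        keep &= f["variant_classification"].isin(set(include))
    profiles: dict[str, np.ndarray] = {s: np.array([]) for s in maf.samples}
    for sample, grp in f.loc[keep].groupby("sample_id", sort=False):
        profiles[sample] = grp["vaf"].to_numpy(dtype=float)
    return profiles


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, non-empty sets."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: self.sets[n] for n in names},
            {n: self.descriptions.get(n, "") for n in names},
        )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a set are deduplicated (first occurrence kept);
    duplicate set names or a line without genes are errors.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(g.strip() for g in parts[2:]):
                raise ValueError(f"{path}, line {lineno}: gene set with no genes")
            name, desc = parts[0], parts[1]
            if name in sets:
                raise ValueError(f"{path}, line {lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g.strip() for g in parts[2:] if g.strip()))
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def load_immune_sets() -> GeneSetCollection:
    """The packaged 28 immune-cell-type gene sets (synthetic membership).

    Cell-type names are the standard 28-population immune signature
    (activated/memory T-cell subsets, B cells, NK subsets, dendritic cells,
    myeloid populations); the gene membership is synthetic, drawn from the
    simulator's gene universe, because the curated signatures are not
    redistributable here.  Replace with a real GMT for real data.
    """
    from importlib import resources

    with resources.as_file(
        resources.files("mathsurv.data") / "immune_cell_sets_synthetic.gmt"
    ) as p:
        return read_gmt(p)
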