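"""End-to-end orchestration of the heterogeneity-prognosis analysis.

``run_all`` executes the full flow — MATH scores, tertile stratification,
baseline table, Kaplan-Meier / log-rank / Cox survival analysis, GSEA,
immune-cell scoring and somatic-mutation summaries — on either real input
files or a fully synthetic cohort, writing every table as TSV plus a
manifest JSON keyed by a hash of the configuration.

Two cohort passes are made: the full cohort, and the adjuvant-chemotherapy
subset, which re-derives its own tertiles (its score distribution differs
from the full cohort's, so its cut points do too).  Expression-based
stages (GSEA, immune) run on the chemotherapy subset and are skipped with
a logged notice when no expression data is available.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import maf_io, heterogeneity, cohort as cohort_mod, survival as surv
from . import enrichment, immune, mutsummary, synthetic_data

__all__ = ["RunConfig", "StageError", "run_all"]

log = logging.getLogger("mathsurv")

#: ordinal codings used for the multivariate Cox model; levels missing
#: from a mapping become NA and are dropped listwise
ORDINAL_CODES = {
    "age_group": {"<60": 0, ">=60": 1},
    "sex": {"Female": 0, "Male": 1},
    "math_group": {"low": 0, "intermediate": 1, "high": 2},
    "stage": {"I": 1, "II": 2, "III": 3, "IV": 4},
    "grade": {"G1": 1, "G2": 2, "G3": 3},
    "radiation": {"No": 0, "Yes": 1},
    "histology": {"Diffuse": 1, "Intestinal": 2, "SignetRing": 3},
}

DEFAULT_COX_COVARIATES = (
    "age_group",
    "sex",
    "math_group",
    "stage",
    "grade",
    "radiation",
    "histology",
)


@dataclass
class RunConfig:
    """Everything a run needs; exactly one of synthetic / input paths."""

    outdir: str
    seed: int
    synthetic: synthetic_data.SyntheticConfig | None = None
    maf_path: str | None = None
    clinical_path: str | None = None
    expression_path: str | None = None
    immune_gmt_path: str | None = None  # defaults to the packaged 28-set GMT
    gsea_gmt_path: str | None = None  # defaults to the immune GMT
    include_classifications: tuple[str, ...] | None = None
    vaf_max: float = 0.75
    min_variants: int = 5
    cox_covariates: tuple[str, ...] = DEFAULT_COX_COVARIATES
    tie_method: str = "efron"
    n_perm: int = 1000
    ssgsea_alpha: float = 0.25
    top_k_genes: int = 25

    def __post_init__(self) -> None:
        has_paths = self.maf_path is not None
        if (self.synthetic is None) == (not has_paths):
            raise ValueError("exactly one of synthetic config or input paths required")
        if self.seed is None:
            raise ValueError("seed is required")

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("outdir")  # the hash identifies the analysis, not its location
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs remain on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
    manifest["outputs"][str(path.name) if path.parent.name == "" else f"{path.parent.name}/{path.name}"] = len(df)


def _ordinal_design(cohort: pd.DataFrame, covariates) -> pd.DataFrame:
    design = pd.DataFrame(index=cohort.index)
    for cov in covariates:
        if cov in ORDINAL_CODES:
            design[cov] = cohort[cov].map(ORDINAL_CODES[cov])
        else:
            design[cov] = pd.to_numeric(cohort[cov], errors="coerce")
    return design


def _survival_pass(cohort: pd.DataFrame, config: RunConfig, outdir: Path, manifest: dict, tag: str) -> dict:
    """KM per MATH group, 3-group and high-vs-rest log-rank, multivariate Cox."""
    results: dict = {}
    labeled = cohort.dropna(subset=["math_group"])
    times = labeled["os_time"].to_numpy(dtype=float)
    events = labeled["os_event"].to_numpy(dtype=int)
    groups = labeled["math_group"].to_numpy()

    for lab in cohort_mod.GROUP_LABELS:
        m = groups == lab
        km = surv.km_estimate(times[m], events[m])
        _write(km.to_frame(), outdir / f"km_{lab}.tsv", manifest)
    lr3 = surv.logrank_test(times, events, groups)
    high_vs_rest = np.where(groups == "high", "high", "low_intermediate")
    lr2 = surv.logrank_test(times, events, high_vs_rest)
    results["logrank_3group"] = lr3
    results["logrank_high_vs_rest"] = lr2
    _write(
        pd.DataFrame(
            [
                {"test": "three_group", "chi_square": lr3.chi_square, "df": lr3.df, "p": lr3.p_value},
                {"test": "high_vs_low_intermediate", "chi_square": lr2.chi_square, "df": lr2.df, "p": lr2.p_value},
            ]
        ),
        outdir / "logrank.tsv",
        manifest,
    )

    design = _ordinal_design(labeled, config.cox_covariates)
    keep = design.notna().all(axis=1)
    design = design.loc[keep]
    # drop covariates that are constant after listwise deletion
    usable = [c for c in design.columns if design[c].nunique() > 1]
    dropped = sorted(set(design.columns) - set(usable))
    if dropped:
        log.warning("%s: constant covariates dropped from Cox model: %s", tag, dropped)
    fit = surv.cox_fit(
        labeled.loc[keep, "os_time"].to_numpy(dtype=float),
        labeled.loc[keep, "os_event"].to_numpy(dtype=int),
        design[usable],
        tie_method=config.tie_method,
    )
    results["cox"] = fit
    table = fit.table.copy()
    table.insert(0, "n", int(keep.sum()))
    _write(table, outdir / "cox.tsv", manifest)
    return results


def run_all(config: RunConfig) -> dict:
    """Run the whole analysis; returns a dict of in-memory results.

    Outputs are written under ``config.outdir`` as TSV tables plus
    ``manifest.json``.  Any stage failure raises :class:`StageError`
    naming the stage; outputs of completed stages remain on disk.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "seed": config.seed, "outputs": {}}
    results: dict = {}

    stage = "inputs"
    try:
        if config.synthetic is not None:
            streams = config.synthetic.streams()
            maf, truth_maf = synthetic_data.simulate_maf(config.synthetic, streams["maf"])
            profiles = maf_io.vaf_profiles(maf, config.include_classifications, config.vaf_max)
            math_table = heterogeneity.cohort_math(profiles, config.min_variants)
            groups, _ = cohort_mod.assign_tertiles(math_table)
            clinical, truth_surv = synthetic_data.simulate_survival(
                config.synthetic, groups, streams["survival"]
            )
            immune_sets = (
                maf_io.read_gmt(config.immune_gmt_path)
                if config.immune_gmt_path
                else maf_io.load_immune_sets()
            )
            expression, truth_expr = synthetic_data.simulate_expression(
                config.synthetic, groups, immune_sets, streams["expression"]
            )
            inputs_dir = out / "inputs"
            inputs_dir.mkdir(exist_ok=True)
            maf_io.write_maf(maf, inputs_dir / "cohort.maf")
            clinical.to_csv(inputs_dir / "clinical.tsv", sep="\t", index=False, float_format="%.6g", lineterminator="\n")
            expression.round(4).to_csv(inputs_dir / "expression.tsv", sep="\t", float_format="%.6g", lineterminator="\n")
            truth = synthetic_data.GroundTruth(
                theta=truth_maf.theta,
                purity=truth_maf.purity,
                ccfs=truth_maf.ccfs,
                n_zero_depth_redraws=truth_maf.n_zero_depth_redraws,
                survival_log_hr=truth_surv.survival_log_hr,
                censoring_achieved=truth_surv.censoring_achieved,
                shifted_sets=truth_expr.shifted_sets,
                expression_shift=truth_expr.expression_shift,
            )
            truth.to_json(inputs_dir / "ground_truth.json")
            manifest["outputs"]["inputs/ground_truth.json"] = 1
        else:
            maf = maf_io.read_maf(config.maf_path)
            clinical = cohort_mod.read_clinical(config.clinical_path)
            expression = None
            if config.expression_path:
                expression = pd.read_csv(config.expression_path, sep="\t", index_col=0)
            immune_sets = (
                maf_io.read_gmt(config.immune_gmt_path)
                if config.immune_gmt_path
                else maf_io.load_immune_sets()
            )
            profiles = maf_io.vaf_profiles(maf, config.include_classifications, config.vaf_max)
            math_table = heterogeneity.cohort_math(profiles, config.min_variants)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    gsea_sets = (
        maf_io.read_gmt(config.gsea_gmt_path) if config.gsea_gmt_path else immune_sets
    )

    def run_stage(name, fn):
        nonlocal results
        log.info("stage %s: starting", name)
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError(name, exc) from exc
        log.info("stage %s: done", name)

    # ---- full cohort -------------------------------------------------
    full_dir = out / "full"
    full_dir.mkdir(exist_ok=True)

    def stage_math():
        _write(math_table, full_dir / "math.tsv", manifest)
        results["math_summary"] = heterogeneity.cohort_summary(math_table)
        summ = pd.DataFrame([results["math_summary"]])
        _write(summ, full_dir / "math_summary.tsv", manifest)

    run_stage("math", stage_math)

    def stage_cohort():
        full = cohort_mod.build_cohort(math_table, clinical)
        results["cohort"] = full
        _write(full, full_dir / "cohort.tsv", manifest)
        baseline = cohort_mod.baseline_table(full, continuous=("math",))
        results["baseline"] = baseline
        _write(baseline, full_dir / "baseline.tsv", manifest)
        (full_dir / "baseline.md").write_text(baseline.to_markdown(index=False) + "\n")

    run_stage("cohort", stage_cohort)

    def stage_survival():
        results["survival_full"] = _survival_pass(results["cohort"], config, full_dir, manifest, "full")

    run_stage("survival_full", stage_survival)

    # ---- adjuvant-chemotherapy subset -------------------------------
    chemo_dir = out / "chemo"
    chemo_dir.mkdir(exist_ok=True)
    full = results["cohort"]
    chemo_ids = full.loc[
        pd.to_numeric(full["adjuvant_chemo"], errors="coerce") == 1, "sample_id"
    ]
    chemo_math = math_table[math_table["sample_id"].isin(set(chemo_ids))].reset_index(drop=True)
    results["chemo_n"] = len(chemo_math)

    def stage_chemo():
        sub_clin = clinical[clinical["sample_id"].isin(set(chemo_ids))]
        chemo = cohort_mod.build_cohort(chemo_math, sub_clin)  # re-derived tertiles
        results["cohort_chemo"] = chemo
        _write(chemo, chemo_dir / "cohort.tsv", manifest)
        baseline = cohort_mod.baseline_table(chemo, continuous=("math",))
        _write(baseline, chemo_dir / "baseline.tsv", manifest)
        results["survival_chemo"] = _survival_pass(chemo, config, chemo_dir, manifest, "chemo")

    run_stage("chemo", stage_chemo)

    # ---- expression stages (chemo subset) ---------------------------
    if expression is None:
        log.info("no expression data: skipping GSEA and immune stages")
        results["gsea"] = None
        results["immune_diff"] = None
    else:
        chemo = results["cohort_chemo"]
        labeled = chemo.dropna(subset=["math_group"])
        pheno = pd.Series(
            np.where(labeled["math_group"] == "high", "high", "low_intermediate"),
            index=labeled["sample_id"].values,
        )
        expr_sub = expression[[s for s in pheno.index if s in expression.columns]]
        pheno = pheno.loc[expr_sub.columns]

        def stage_gsea():
            res = enrichment.gsea_significance(
                expr_sub,
                pheno.to_numpy(),
                gsea_sets,
                n_perm=config.n_perm,
                seed=config.seed,
                positive_class="low_intermediate",
            )
            results["gsea"] = res
            _write(res, chemo_dir / "gsea.tsv", manifest)

        run_stage("gsea", stage_gsea)

        def stage_immune():
            scores = immune.ssgsea_matrix(expr_sub, immune_sets, alpha=config.ssgsea_alpha)
            results["immune_scores"] = scores
            scores.round(4).to_csv(
                chemo_dir / "immune_scores.tsv", sep="\t", float_format="%.6g", lineterminator="\n"
            )
            manifest["outputs"]["chemo/immune_scores.tsv"] = len(scores)
            diff = immune.immune_diff_table(scores, pheno)
            results["immune_diff"] = diff
            _write(diff, chemo_dir / "immune_diff.tsv", manifest)
            sub = labeled.set_index("sample_id").loc[scores.columns]
            ct_cox = immune.per_celltype_cox(
                scores, sub["os_time"].to_numpy(dtype=float), sub["os_event"].to_numpy(dtype=int)
            )
            results["immune_cox"] = ct_cox
            _write(ct_cox, chemo_dir / "immune_cox.tsv", manifest)

        run_stage("immune", stage_immune)

    # ---- mutation summaries (chemo subset) --------------------------
    def stage_mutsummary():
        sub_frame = maf.frame[maf.frame["sample_id"].isin(set(chemo_ids))].reset_index(drop=True)
        sub_maf = maf_io.MafTable(sub_frame)
        summary = mutsummary.summarize_maf(sub_maf, top_k=config.top_k_genes)
        results["mutsummary"] = summary
        _write(
            summary.classification_counts.rename_axis("classification").reset_index(name="count"),
            chemo_dir / "classification_counts.tsv",
            manifest,
        )
        _write(
            summary.sample_load.rename_axis("sample_id").reset_index(name="n_variants"),
            chemo_dir / "sample_load.tsv",
            manifest,
        )
        _write(summary.top_genes, chemo_dir / "top_genes.tsv", manifest)
        matrix = mutsummary.gene_sample_matrix(sub_maf)
        pairs = mutsummary.cooccurrence_scan(matrix, top_k=config.top_k_genes)
        results["cooccurrence"] = pairs
        _write(pairs, chemo_dir / "cooccurrence.tsv", manifest)

    run_stage("mutsummary", stage_mutsummary)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["manifest"] = manifest
    return results
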