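import numpy as np
import pandas as pd
import pytest

from mathsurv import (
    SyntheticConfig,
    cohort_math,
    load_immune_sets,
    simulate_expression,
    simulate_maf,
    simulate_survival,
    vaf_profiles,
)
from mathsurv.synthetic_data import GroundTruth


def groups_for(n):
    ids = [f"S{i:04d}" for i in range(1, n + 1)]
    return pd.Series((np.arange(n) * 3 // n), index=ids)


class TestSimulateMaf:
    def test_same_seed_identical_output(self):
        a, _ = simulate_maf(SyntheticConfig(seed=42, n_samples=15))
        b, _ = simulate_maf(SyntheticConfig(seed=42, n_samples=15))
        assert a.frame.equals(b.frame)

    def test_different_seed_differs(self):
        a, _ = simulate_maf(SyntheticConfig(seed=42, n_samples=15))
        b, _ = simulate_maf(SyntheticConfig(seed=43, n_samples=15))
        assert not a.frame.equals(b.frame)

    def test_median_variant_load_near_target(self):
        maf, _ = simulate_maf(SyntheticConfig(seed=3, n_samples=171))
        load = maf.frame.groupby("sample_id").size()
        assert 55 <= load.median() <= 71

    def test_binomial_noise_only_math_is_small(self):
        """theta=0, purity 1: every true VAF is 0.5 and MATH reflects
        read-count noise only, E[MATH] ~ 100*sigma/0.5 ~ 8.2 at 150x."""
        cfg = SyntheticConfig(
            seed=5, n_samples=200, subclone_dispersion=0.0, purity_range=(1.0, 1.0)
        )
        maf, truth = simulate_maf(cfg)
        assert all(all(c == 1.0 for c in ccfs) for ccfs in truth.ccfs.values())
        table = cohort_math(vaf_profiles(maf, vaf_max=1.0))
        assert table["math"].mean() == pytest.approx(8.2, abs=1.0)
        assert (table["math"] < 10).mean() >= 0.85

    def test_ground_truth_sidecar_roundtrip(self, tmp_path):
        _, truth = simulate_maf(SyntheticConfig(seed=8, n_samples=5))
        p = tmp_path / "truth.json"
        truth.to_json(p)
        again = GroundTruth.from_json(p)
        assert again.purity == truth.purity
        assert again.ccfs == truth.ccfs

    def test_mean_math_monotone_in_theta_grid(self):
        means = []
        for theta in (0.0, 0.05, 0.1, 0.2):
            cfg = SyntheticConfig(seed=17, n_samples=120, subclone_dispersion=theta)
            maf, _ = simulate_maf(cfg)
            means.append(cohort_math(vaf_profiles(maf))["math"].mean())
        assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(seed=1, purity_range=(0.5, 1.5))
        with pytest.raises(ValueError):
            SyntheticConfig(seed=1, subclone_dispersion=-0.1)


class TestSimulateSurvival:
    def test_censoring_calibration(self):
        cfg = SyntheticConfig(seed=2, n_samples=400, censoring_target=0.3)
        clinical, truth = simulate_survival(cfg, groups_for(400))
        assert truth.censoring_achieved == pytest.approx(0.3, abs=0.05)
        assert clinical["os_event"].mean() == pytest.approx(0.7, abs=0.05)

    def test_zero_censoring_target(self):
        cfg = SyntheticConfig(seed=2, n_samples=50, censoring_target=0.0)
        clinical, _ = simulate_survival(cfg, groups_for(50))
        assert (clinical["os_event"] == 1).all()

    def test_higher_group_shorter_survival(self):
        cfg = SyntheticConfig(
            seed=4, n_samples=600, group_log_hr=np.log(2.0), censoring_target=0.0
        )
        clinical, _ = simulate_survival(cfg, groups_for(600))
        g = groups_for(600).to_numpy()
        med = [np.median(clinical["os_time"][g == k]) for k in (0, 1, 2)]
        assert med[0] > med[1] > med[2]

    def test_covariate_levels_and_determinism(self):
        cfg = SyntheticConfig(seed=11, n_samples=100)
        a, _ = simulate_survival(cfg, groups_for(100))
        b, _ = simulate_survival(cfg, groups_for(100))
        assert a.equals(b)
        assert set(a["sex"]) <= {"Male", "Female"}
        assert set(a["stage"]) <= {"I", "II", "III", "IV", "NA"}


class TestSimulateExpression:
    def test_same_seed_identical(self):
        cfg = SyntheticConfig(seed=9, n_samples=30)
        sets = load_immune_sets()
        a, _ = simulate_expression(cfg, groups_for(30), sets)
        b, _ = simulate_expression(cfg, groups_for(30), sets)
        assert a.equals(b)

    def test_shift_planted_in_low_intermediate(self):
        cfg = SyntheticConfig(seed=9, n_samples=200, expression_shift=2.0)
        sets = load_immune_sets()
        expr, truth = simulate_expression(cfg, groups_for(200), sets)
        g = groups_for(200).to_numpy()
        shifted_genes = [g_ for s in truth.shifted_sets for g_ in sets[s]]
        unshifted = [s for s in sets if s not in set(truth.shifted_sets)]
        null_genes = [g_ for s in unshifted for g_ in sets[s]]
        delta_shift = (
            expr.loc[shifted_genes, g < 2].mean(axis=1)
            - expr.loc[shifted_genes, g == 2].mean(axis=1)
        ).mean()
        delta_null = (
            expr.loc[null_genes, g < 2].mean(axis=1)
            - expr.loc[null_genes, g == 2].mean(axis=1)
        ).mean()
        assert delta_shift > 1.0
        assert abs(delta_null) < 0.2

    def test_unknown_shifted_set_rejected(self):
        cfg = SyntheticConfig(seed=9, n_samples=30, shifted_sets=("No such set",))
        with pytest.raises(ValueError, match="No such set"):
            simulate_expression(cfg, groups_for(30), load_immune_sets())

    def test_delta_zero_p_values_approximately_uniform(self):
        from scipy import stats

        from mathsurv import immune_diff_table, ssgsea_matrix

        cfg = SyntheticConfig(seed=13, n_samples=80, expression_shift=0.0, n_genes=900)
        sets = load_immune_sets()
        expr, _ = simulate_expression(cfg, groups_for(80), sets)
        groups = groups_for(80).map(lambda c: "high" if c == 2 else "low_intermediate")
        scores = ssgsea_matrix(expr, sets)
        table = immune_diff_table(scores, groups)
        ks = stats.kstest(table["p"], "uniform")
        assert ks.pvalue > 0.01
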