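from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mathsurv import (
    GeneSetCollection,
    immune_diff_table,
    mannwhitney_z,
    per_celltype_cox,
    ssgsea_matrix,
    ssgsea_score,
)


class TestSsgseaScore:
    @staticmethod
    def col4():
        return pd.Series([4.0, 3.0, 2.0, 1.0], index=["g1", "g2", "g3", "g4"])

    def test_top_gene_alpha0(self):
        assert ssgsea_score(self.col4(), {"g1"}, alpha=0) == pytest.approx(2.0)

    def test_bottom_gene_alpha0(self):
        assert ssgsea_score(self.col4(), {"g4"}, alpha=0) == pytest.approx(-2.0)

    def test_monotone_transform_invariance(self, rng):
        genes = [f"g{i:03d}" for i in range(40)]
        col = pd.Series(rng.uniform(1, 100, 40), index=genes)
        s = set(rng.choice(genes, 9, replace=False))
        base = ssgsea_score(col, s)
        assert ssgsea_score(np.log(col), s) == pytest.approx(base, abs=1e-12)
        assert ssgsea_score(col**3, s) == pytest.approx(base, abs=1e-12)
        assert ssgsea_score(10 * col + 7, s) == pytest.approx(base, abs=1e-12)

    def test_complement_equivariance_alpha0(self, rng):
        genes = [f"g{i:03d}" for i in range(30)]
        col = pd.Series(rng.standard_normal(30), index=genes)
        s = set(rng.choice(genes, 11, replace=False))
        comp = set(genes) - s
        assert ssgsea_score(col, s, alpha=0) == pytest.approx(
            -ssgsea_score(col, comp, alpha=0), abs=1e-9
        )

    def test_covering_set_rejected(self):
        with pytest.raises(ValueError):
            ssgsea_score(self.col4(), {"g1", "g2", "g3", "g4"})

    def test_matrix_shape_and_agreement_with_scalar(self, rng):
        genes = [f"g{i:03d}" for i in range(25)]
        expr = pd.DataFrame(
            rng.standard_normal((25, 4)), index=genes, columns=list("wxyz")
        )
        sets = GeneSetCollection(
            {"s1": genes[:5], "s2": genes[5:12]}
        )
        mat = ssgsea_matrix(expr, sets, alpha=0.25)
        assert mat.shape == (2, 4)
        assert mat.loc["s1", "w"] == pytest.approx(
            ssgsea_score(expr["w"], genes[:5], alpha=0.25)
        )


class TestMannWhitney:
    def test_hand_example(self):
        z, p = mannwhitney_z([1, 2, 3], [4, 5, 6])
        assert z == pytest.approx(-1.964, abs=0.001)

    def test_identical_samples(self):
        z, p = mannwhitney_z([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert (z, p) == (0.0, 1.0)

    def test_scale_invariance(self, rng):
        x, y = rng.standard_normal(12), rng.standard_normal(15)
        z1, _ = mannwhitney_z(x, y)
        z2, _ = mannwhitney_z(10 * x, 10 * y)
        assert z1 == pytest.approx(z2, abs=1e-12)

    def test_agrees_with_scipy_with_ties(self, rng):
        x = rng.integers(0, 6, 20).astype(float)
        y = rng.integers(0, 6, 25).astype(float)
        z, p = mannwhitney_z(x, y)
        ref = stats.mannwhitneyu(x, y, method="asymptotic", use_continuity=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_enumeration_small_samples(self):
        """Continuity-corrected p within 0.02 of exact enumeration, for every
        tail configuration (exact p <= 0.2) with 3 <= n1 <= n2 <= 7, no ties.

        The check is exhaustive over U values; near the distribution center
        the discrete exact p and any normal approximation necessarily
        diverge, so the bound is asserted where the test is actually used —
        in the rejection tail.
        """
        for n1 in range(3, 8):
            for n2 in range(n1, 8):
                ranks = np.arange(1, n1 + n2 + 1)
                us_all = np.array(
                    [
                        ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
                        for idx in combinations(range(n1 + n2), n1)
                    ]
                )
                mean_u = n1 * n2 / 2
                for u_obs in range(int(n1 * n2) + 1):
                    p_exact = (
                        np.abs(us_all - mean_u) >= abs(u_obs - mean_u) - 1e-9
                    ).mean()
                    if p_exact > 0.2:
                        continue
                    # realize this U with tie-free samples: x takes the rank
                    # positions of one observed assignment
                    idx = next(
                        i
                        for i in combinations(range(n1 + n2), n1)
                        if ranks[list(i)].sum() - n1 * (n1 + 1) / 2 == u_obs
                    )
                    x = np.array([ranks[list(idx)]]).ravel().astype(float)
                    y = np.array(
                        [r for r in ranks if r not in set(x)], dtype=float
                    )
                    _, p_norm = mannwhitney_z(x, y, continuity=True)
                    assert p_norm == pytest.approx(p_exact, abs=0.02)


class TestImmuneDiff:
    @staticmethod
    def scored_cohort(rng, n=40, n_types=6, shift_types=2, delta=1.5):
        samples = [f"S{i:03d}" for i in range(n)]
        groups = pd.Series(
            ["high" if i < n // 3 else "low_intermediate" for i in range(n)],
            index=samples,
        )
        scores = pd.DataFrame(
            rng.standard_normal((n_types, n)),
            index=[f"ct{j}" for j in range(n_types)],
            columns=samples,
        )
        scores.iloc[:shift_types, (groups == "low_intermediate").to_numpy()] += delta
        return scores, groups

    def test_one_row_per_cell_type(self, rng):
        scores, groups = self.scored_cohort(rng)
        table = immune_diff_table(scores, groups)
        assert len(table) == len(scores)

    def test_direction_matches_median_difference(self, rng):
        scores, groups = self.scored_cohort(rng)
        table = immune_diff_table(scores, groups).set_index("cell_type")
        for ct in scores.index:
            med_li = scores.loc[ct, groups == "low_intermediate"].median()
            med_hi = scores.loc[ct, groups == "high"].median()
            expected = (
                "higher_in_low_intermediate" if med_li > med_hi else "higher_in_high"
            )
            assert table.loc[ct, "direction"] == expected

    def test_shifted_types_significant_with_positive_z(self, rng):
        scores, groups = self.scored_cohort(rng)
        table = immune_diff_table(scores, groups).set_index("cell_type")
        assert table.loc["ct0", "p"] < 0.05 and table.loc["ct0", "z"] > 0
        assert table.loc["ct1", "p"] < 0.05
        assert table.attrs["n_significant"] >= 2

    def test_bh_adjustment_flag(self, rng):
        scores, groups = self.scored_cohort(rng)
        table = immune_diff_table(scores, groups, adjust="bh")
        assert "p_adj" in table.columns
        assert (table["p_adj"] >= table["p"] - 1e-12).all()


class TestPerCelltypeCox:
    def test_null_scores_cover_one(self, rng):
        n = 150
        t = rng.exponential(20, n)
        e = rng.integers(0, 2, n)
        scores = pd.DataFrame(
            rng.standard_normal((10, n)),
            index=[f"ct{j}" for j in range(10)],
            columns=[f"S{i}" for i in range(n)],
        )
        table = per_celltype_cox(scores, t, e)
        covered = ((table["ci_low"] <= 1) & (1 <= table["ci_high"])).mean()
        assert covered >= 0.8  # ~95% nominal; 10 draws, allow 2 misses

    def test_planted_hazard_recovered(self, rng):
        n = 400
        x = rng.standard_normal(n)
        beta = 0.5
        t = rng.exponential(np.exp(-beta * x) * 20, n)
        scores = pd.DataFrame([x], index=["ct0"], columns=[f"S{i}" for i in range(n)])
        table = per_celltype_cox(scores, t, np.ones(n, dtype=int), standardize=False)
        assert table.loc[0, "hr"] == pytest.approx(np.exp(beta), rel=0.1)

    def test_constant_score_flagged_not_fitted(self, rng):
        n = 30
        scores = pd.DataFrame(
            [np.ones(n), rng.standard_normal(n)],
            index=["flat", "ok"],
            columns=[f"S{i}" for i in range(n)],
        )
        table = per_celltype_cox(scores, rng.exponential(5, n), np.ones(n, dtype=int))
        assert table.set_index("cell_type").loc["flat", "flag"] == "constant_score"
        assert np.isnan(table.set_index("cell_type").loc["flat", "hr"])
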