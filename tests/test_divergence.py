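"""Variance components, P_ST machinery and the Mantel test."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_trait_table
from oracles import mantel_exhaustive_oracle, reml_matrix_oracle

from thermocline import (
    PstGridResult,
    VarianceComponents,
    compute_pst,
    critical_ch2_ratio,
    default_ratio_grid,
    fit_one_way_reml,
    mantel_test,
    pairwise_pst_matrix,
    pst_bootstrap_ci,
)
from thermocline.divergence import BEYOND_GRID, NONE_BELOW_GRID, _pst


def table(pops, values):
    return pd.DataFrame(
        {"population": pops, "trait": "T", "value_c": values}
    )


class TestREML:
    def test_balanced_closed_form_degenerate_within(self):
        vc = fit_one_way_reml(table(list("aabb"), [0.0, 0.0, 1.0, 1.0]))
        assert vc.sigma_w2 == pytest.approx(0.0, abs=1e-12)
        assert vc.sigma_b2 == pytest.approx(0.5, abs=1e-12)

    def test_all_equal_gives_zero_components(self):
        vc = fit_one_way_reml(table(list("aabb"), [3.0, 3.0, 3.0, 3.0]))
        assert (vc.sigma_b2, vc.sigma_w2) == (0.0, 0.0)

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            fit_one_way_reml(table(list("aaaa"), [1.0, 2.0, 3.0, 4.0]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_unbalanced_matches_matrix_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sizes = [3, 7, 12, 5, 9]
        codes = np.repeat(np.arange(len(sizes)), sizes)
        y = rng.normal(0, 1, len(codes)) + np.repeat(
            rng.normal(0, 0.8, len(sizes)), sizes
        )
        vc = fit_one_way_reml(
            pd.DataFrame({"population": codes.astype(str), "trait": "T", "value_c": y})
        )
        sb_o, sw_o = reml_matrix_oracle(y, codes)
        assert vc.sigma_w2 == pytest.approx(sw_o, rel=1e-6)
        assert vc.sigma_b2 == pytest.approx(sb_o, rel=1e-6, abs=1e-9)

    def test_balanced_interior_equals_anova_moments(self):
        df = make_trait_table(seed=8, n_pops=10, n_per_pop=20)
        vc = fit_one_way_reml(df)
        wide = df.assign(code=df["population"].astype("category").cat.codes)
        gm = wide.groupby("code")["value_c"]
        n = 20
        msw = (gm.var(ddof=1) * (n - 1)).sum() / (len(gm) * (n - 1))
        msb = n * gm.mean().var(ddof=1)
        assert vc.sigma_w2 == pytest.approx(msw, rel=1e-6)
        assert vc.sigma_b2 == pytest.approx((msb - msw) / n, rel=1e-6)


class TestComputePst:
    def test_limits_and_arithmetic(self):
        assert compute_pst(VarianceComponents(0.0, 1.0, 2, 10), 3.0) == 0.0
        assert compute_pst(VarianceComponents(2.0, 0.0, 2, 10), 0.5) == 1.0
        assert compute_pst(VarianceComponents(2.0, 1.0, 2, 10), 1.0) == 0.5

    def test_double_zero_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            compute_pst(VarianceComponents(0.0, 0.0, 2, 10), 1.0)

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValueError):
            compute_pst(VarianceComponents(1.0, 1.0, 2, 10), 0.0)

    def test_strictly_increasing_in_ratio(self):
        vc = VarianceComponents(0.7, 1.3, 5, 50)
        grid = default_ratio_grid()
        vals = [compute_pst(vc, r) for r in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("shift,scale", [(5.0, 1.0), (0.0, 3.0), (-2.0, 0.5)])
    def test_invariant_to_affine_trait_transform(self, shift, scale):
        df = make_trait_table(seed=4, n_pops=8, n_per_pop=15)
        p0 = compute_pst(fit_one_way_reml(df), 1.0)
        df2 = df.assign(value_c=df["value_c"] * scale + shift)
        p1 = compute_pst(fit_one_way_reml(df2), 1.0)
        # agreement is limited by the bounded search's xatol on log-lambda
        assert p1 == pytest.approx(p0, rel=1e-6)


class TestPstBootstrap:
    def test_noiseless_data_collapses_to_one(self):
        df = table(list("aaabbbccc"), [0.0] * 3 + [1.0] * 3 + [2.0] * 3)
        res = pst_bootstrap_ci(df, ratios=[0.5, 1.0], n_boot=500, seed=2)
        assert np.all(res.ci_low == 1.0)
        assert np.all(res.ci_high == 1.0)
        assert np.all(res.pst_point == 1.0)

    def test_seed_determinism(self):
        df = make_trait_table(seed=6, n_pops=8, n_per_pop=10)
        a = pst_bootstrap_ci(df, ratios=[1.0], n_boot=500, seed=5)
        b = pst_bootstrap_ci(df, ratios=[1.0], n_boot=500, seed=5)
        np.testing.assert_array_equal(a.ci_low, b.ci_low)
        np.testing.assert_array_equal(a.ci_high, b.ci_high)

    def test_small_population_rejected(self):
        df = table(["a", "b", "b"], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match=">= 2 individuals"):
            pst_bootstrap_ci(df, n_boot=500, seed=0)

    def test_ci_widens_with_population_unit(self):
        df = make_trait_table(seed=12, n_pops=10, n_per_pop=20)
        ind = pst_bootstrap_ci(df, ratios=[1.0], n_boot=500, seed=3, unit="individuals")
        pop = pst_bootstrap_ci(df, ratios=[1.0], n_boot=500, seed=3, unit="populations")
        assert (pop.ci_high[0] - pop.ci_low[0]) > (ind.ci_high[0] - ind.ci_low[0])


def constructed_grid(sb=1.0, sw=1.0, n_reps=400) -> PstGridResult:
    """Replicates with identical components: ci_low(r) = r*sb/(r*sb+2*sw)."""
    grid = default_ratio_grid()
    point = VarianceComponents(sb, sw, 5, 100)
    reps_b = np.full(n_reps, sb)
    reps_w = np.full(n_reps, sw)
    pst_point = np.array([compute_pst(point, r) for r in grid])
    lo = np.array([np.percentile(_pst(reps_b, reps_w, r), 2.5) for r in grid])
    hi = np.array([np.percentile(_pst(reps_b, reps_w, r), 97.5) for r in grid])
    return PstGridResult(
        ratios=grid, pst_point=pst_point, ci_low=lo, ci_high=hi,
        n_boot=n_reps, seed=0, components=point,
        boot_sigma_b2=reps_b, boot_sigma_w2=reps_w,
    )


class TestCriticalRatio:
    def test_closed_form_inversion(self):
        # with sb = sw, ci_low(r) = r/(r+2); r/(r+2) = 0.2 at r = 0.5
        grid = constructed_grid()
        crit = critical_ch2_ratio(grid, fst_upper=0.2)
        assert crit == pytest.approx(0.5, abs=1e-4)

    def test_fst_upper_one_is_beyond_grid(self):
        assert critical_ch2_ratio(constructed_grid(), 1.0) == BEYOND_GRID

    def test_fst_upper_zero_is_none_below_grid(self):
        assert critical_ch2_ratio(constructed_grid(), 0.0) == NONE_BELOW_GRID


class TestPairwisePst:
    def test_identical_populations_give_zero(self):
        df = table(list("aaabbb"), [1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        mat = pairwise_pst_matrix(df, ratio=1.0)
        assert mat.loc["a", "b"] == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_constant_populations_give_one(self):
        df = table(list("aaabbb"), [0.0, 0.0, 0.0, 5.0, 5.0, 5.0])
        mat = pairwise_pst_matrix(df, ratio=1.0)
        assert mat.loc["a", "b"] == 1.0

    def test_three_pop_entries_match_per_pair_oracle(self):
        df = make_trait_table(seed=15, n_pops=3, n_per_pop=12)
        mat = pairwise_pst_matrix(df, ratio=1.0)
        pops = sorted(df["population"].unique())
        for i in range(3):
            for j in range(i + 1, 3):
                sub = df[df["population"].isin([pops[i], pops[j]])]
                codes = (sub["population"] == pops[j]).astype(int).to_numpy()
                sb, sw = reml_matrix_oracle(sub["value_c"].to_numpy(), codes)
                expected = sb / (sb + 2 * sw)
                assert mat.loc[pops[i], pops[j]] == pytest.approx(expected, rel=1e-5, abs=1e-9)


class TestMantel:
    def make(self, seed=0, n=5):
        rng = np.random.default_rng(seed)
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        return a

    def test_self_correlation(self):
        # n large enough that no sampled permutation reproduces r = 1
        a = self.make(n=12)
        res = mantel_test(a, a, n_permutations=199, seed=1)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == pytest.approx(1 / 200)

    def test_anticorrelation(self):
        a = self.make()
        b = 10 - a
        np.fill_diagonal(b, 0)
        assert mantel_test(a, b, n_permutations=99, seed=1).r == pytest.approx(-1.0)

    def test_exhaustive_enumeration_matches_oracle(self):
        rng = np.random.default_rng(7)
        a = self.make(seed=3, n=4)
        b = a + rng.normal(0, 0.3, (4, 4))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        res = mantel_test(a, b, exact=True)
        r_o, p_o = mantel_exhaustive_oracle(a, b)
        assert res.r == pytest.approx(r_o, abs=1e-12)
        assert res.p_value == pytest.approx(p_o, abs=1e-12)
        assert res.n_permutations == 24

    def test_invariant_to_joint_relabeling(self):
        a = self.make(seed=2)
        b = self.make(seed=5)
        res = mantel_test(a, b, n_permutations=299, seed=4)
        perm = np.random.default_rng(1).permutation(5)
        res2 = mantel_test(
            a[np.ix_(perm, perm)], b[np.ix_(perm, perm)], n_permutations=299, seed=4
        )
        assert res2.r == pytest.approx(res.r, abs=1e-12)

    def test_rejects_missing_and_constant(self):
        a = self.make()
        bad = a.copy()
        bad[0, 1] = bad[1, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            mantel_test(a, bad)
        with pytest.raises(ValueError, match="constant"):
            mantel_test(a, np.zeros_like(a))
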