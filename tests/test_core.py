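"""Projection, pseudo-F, df scaling, analytic and permutation inference."""

import numpy as np
import pytest
from scipy import stats

from mdmr import (
    DataMatrix,
    DesignMatrix,
    analytic_pvalue,
    build_projection,
    compute_distance_matrix,
    gower_center,
    mdmr,
    permutation_test,
    pseudo_f,
    scaled_f,
)

from conftest import random_euclidean_gower


class TestProjection:
    def test_two_group_block_structure(self):
        design = DesignMatrix(np.array([0.0, 0.0, 1.0, 1.0]))
        h = build_projection(design).h
        block = np.full((2, 2), 0.5)
        expected = np.block([[block, np.zeros((2, 2))],
                             [np.zeros((2, 2)), block]])
        np.testing.assert_allclose(h, expected, atol=1e-12)

    def test_duplicated_regressor_dropped(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 1.0])
        single = build_projection(DesignMatrix(x, ["a"]))
        dup = build_projection(DesignMatrix(np.column_stack([x, x]), ["a", "b"]))
        np.testing.assert_allclose(dup.h, single.h, atol=1e-10)
        assert dup.dropped_columns in (["a"], ["b"])

    def test_projector_identities_and_reproduction(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.standard_normal((12, 3))
            proj = build_projection(DesignMatrix(x))
            h = proj.h
            np.testing.assert_allclose(h, h.T, atol=1e-10)
            np.testing.assert_allclose(h @ h, h, atol=1e-10)
            np.testing.assert_allclose(h @ x, x, atol=1e-8)
            assert proj.rank == 4

    def test_all_regressors_dependent_is_error(self):
        # single column collinear with the intercept is rejected upstream;
        # here two columns that jointly reduce to the constant direction
        x = np.column_stack([[0.0, 1, 0, 1, 0], [1.0, 0, 1, 0, 1]])
        proj = build_projection(DesignMatrix(x))
        assert len(proj.dropped_columns) == 1  # x2 = 1 - x1
        with pytest.raises(ValueError, match="constant"):
            DesignMatrix(np.ones((5, 1)))


class TestPseudoF:
    def test_anova_sums_of_squares(self, anova_case):
        _, _, g, design = anova_case
        f_raw, tr_model, tr_res = pseudo_f(g, build_projection(design))
        assert tr_model == pytest.approx(6.25)
        assert tr_res == pytest.approx(2.5)
        assert f_raw == pytest.approx(2.5)

    def test_shortcut_equals_literal_triple_product(self):
        rng = np.random.default_rng(4)
        _, g = random_euclidean_gower(rng, 10)
        proj = build_projection(DesignMatrix(rng.standard_normal((10, 2))))
        f_raw, tr_model, tr_res = pseudo_f(g, proj)
        h = proj.h
        assert tr_model == pytest.approx(np.trace(h @ g.g @ h), abs=1e-8)
        ih = np.eye(10) - h
        assert tr_res == pytest.approx(np.trace(ih @ g.g @ ih), abs=1e-8)

    def test_trace_partition(self):
        rng = np.random.default_rng(5)
        for n in (6, 11, 20):
            _, g = random_euclidean_gower(rng, n)
            proj = build_projection(DesignMatrix(rng.standard_normal(n)))
            _, tr_model, tr_res = pseudo_f(g, proj)
            assert tr_model + tr_res == pytest.approx(np.trace(g.g), abs=1e-8)

    def test_invariant_under_distance_scaling(self):
        rng = np.random.default_rng(6)
        data, g = random_euclidean_gower(rng, 9)
        scaled = DataMatrix(3.0 * data.values, data.sample_ids, data.variable_ids)
        g3 = gower_center(compute_distance_matrix(scaled))
        design = DesignMatrix(rng.standard_normal(9))
        proj = build_projection(design)
        assert pseudo_f(g, proj)[0] == pytest.approx(pseudo_f(g3, proj)[0], rel=1e-10)


class TestScaledF:
    @pytest.mark.parametrize("p,n,m,expected", [
        (1, 10, 1, (1, 8)),       # classical ANOVA df
        (10, 100, 1, (10, 998)),  # P and P*N - 2
        (1, 4, 1, (1, 2)),
    ])
    def test_df_rule(self, p, n, m, expected):
        _, df1, df2 = scaled_f(1.0, n, p, m)
        assert (df1, df2) == expected

    def test_worked_example_scaling(self):
        f_scaled, df1, df2 = scaled_f(2.5, 4, 1, 1)
        assert f_scaled == pytest.approx(5.0)

    def test_multi_regressor_extrapolated_df(self):
        _, df1, df2 = scaled_f(1.0, 30, 100, 4)
        assert (df1, df2) == (400, 100 * 30 - 5)

    def test_degenerate_df_is_error(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            scaled_f(1.0, 2, 1, 1)


class TestAnalyticPvalue:
    def test_closed_form_via_t_distribution(self):
        # F(1, 2) at 5.0 equals two-sided t(2) at sqrt(5)
        assert analytic_pvalue(5.0, 1, 2) == pytest.approx(0.1548, abs=5e-5)

    def test_limits(self):
        assert analytic_pvalue(0.0, 3, 7) == 1.0
        assert analytic_pvalue(1e12, 3, 7) < 1e-10


class TestPermutationTest:
    def test_exhaustive_enumeration_worked_example(self, anova_case):
        _, _, g, design = anova_case
        p, f_obs, null_f = permutation_test(g, design, n_perm=500, seed=0)
        assert f_obs == pytest.approx(2.5)
        assert p == pytest.approx(2.0 / 6.0)
        np.testing.assert_allclose(sorted(null_f),
                                   sorted([2.5, 2.5,               # {12|35}
                                           9 / 26, 9 / 26,          # {13|25}: 2.25/6.5
                                           1 / 34, 1 / 34]),        # {15|23}: 0.25/8.5
                                   rtol=1e-10)

    def test_observed_minimum_gives_p_one(self):
        data = DataMatrix(np.array([[1.0], [5.0], [2.0], [3.0]]),
                          list("abcd"), ["y"])
        g = gower_center(compute_distance_matrix(data))
        design = DesignMatrix(np.array([0.0, 0.0, 1.0, 1.0]))
        p, _, _ = permutation_test(g, design, n_perm=500, seed=0)
        assert p == 1.0

    def test_same_seed_reproduces(self):
        rng = np.random.default_rng(9)
        _, g = random_euclidean_gower(rng, 20)
        design = DesignMatrix(rng.standard_normal(20))
        res1 = permutation_test(g, design, n_perm=99, seed=42)
        res2 = permutation_test(g, design, n_perm=99, seed=42)
        assert res1[0] == res2[0]
        np.testing.assert_array_equal(res1[2], res2[2])

    def test_sampled_converges_to_exhaustive(self):
        # N=6 continuous regressor: 720 arrangements; sampled p with large
        # n_perm must agree with the exhaustive p within 3 binomial SEs
        rng = np.random.default_rng(10)
        _, g = random_euclidean_gower(rng, 6)
        design = DesignMatrix(rng.standard_normal(6))
        p_exact, _, _ = permutation_test(g, design, n_perm=720, seed=0)
        n_perm = 600  # below 720, forces sampling
        p_sampled, _, _ = permutation_test(g, design, n_perm=n_perm, seed=1)
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_sampled - p_exact) <= 3 * se + 1.0 / n_perm

    def test_general_m_branch_matches_single_column_branch(self):
        # a duplicated column exercises the M>1 code path with the same
        # projector as the single-column fast path
        rng = np.random.default_rng(11)
        _, g = random_euclidean_gower(rng, 5)
        x = rng.standard_normal(5)
        p1, f1, _ = permutation_test(g, DesignMatrix(x), n_perm=120, seed=0)
        p2, f2, _ = permutation_test(
            g, DesignMatrix(np.column_stack([x, x])), n_perm=120, seed=0)
        assert f2 == pytest.approx(f1, rel=1e-8)
        assert p2 == pytest.approx(p1, abs=1e-12)  # both exhaustive over 120 = 5!


class TestMDMRFacade:
    def test_composition_of_worked_example(self, anova_case):
        _, _, g, design = anova_case
        res = mdmr(g, design, n_perm=500, seed=0, p_variables=1)
        assert res.f_raw == pytest.approx(2.5)
        assert res.f_scaled == pytest.approx(5.0)
        assert (res.df1, res.df2) == (1, 2)
        assert res.p_analytic == pytest.approx(0.1548, abs=5e-5)
        assert res.p_permutation == pytest.approx(1.0 / 3.0)
        assert res.variance_fraction == pytest.approx(6.25 / 8.75)
        assert res.tr_model + res.tr_residual == pytest.approx(np.trace(g.g))

    def test_variance_fraction_bounded_for_euclidean(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            _, g = random_euclidean_gower(rng, 15)
            res = mdmr(g, DesignMatrix(rng.standard_normal(15)),
                       n_perm=49, seed=1, p_variables=3)
            assert 0.0 <= res.variance_fraction <= 1.0
            assert res.f_raw >= 0.0

    def test_per_regressor_marginals(self):
        rng = np.random.default_rng(13)
        _, g = random_euclidean_gower(rng, 12)
        design = DesignMatrix(rng.standard_normal((12, 2)), ["u", "w"])
        res = mdmr(g, design, n_perm=49, seed=2, p_variables=3,
                   per_regressor=True)
        assert len(res.per_regressor) == 2
        solo = mdmr(g, DesignMatrix(design.x[:, [0]], ["u"]),
                    n_perm=49, seed=res.seed + 1, p_variables=3)
        assert res.per_regressor[0].f_raw == pytest.approx(solo.f_raw)

    def test_invariance_under_affine_regressor_and_relabeling(self):
        rng = np.random.default_rng(14)
        data, g = random_euclidean_gower(rng, 10)
        x = rng.standard_normal(10)
        base = mdmr(g, DesignMatrix(x), n_perm=99, seed=5, p_variables=3)
        affine = mdmr(g, DesignMatrix(2.5 * x - 7.0), n_perm=99, seed=5,
                      p_variables=3)
        assert affine.f_raw == pytest.approx(base.f_raw, rel=1e-8)
        assert affine.p_permutation == base.p_permutation

        perm = rng.permutation(10)
        dperm = compute_distance_matrix(
            DataMatrix(data.values[perm],
                       [data.sample_ids[i] for i in perm], data.variable_ids))
        relab = mdmr(gower_center(dperm), DesignMatrix(x[perm]),
                     n_perm=99, seed=5, p_variables=3)
        assert relab.f_raw == pytest.approx(base.f_raw, rel=1e-8)


class TestAnovaEquivalence:
    def test_matches_classical_one_way_anova(self):
        """P=1 Euclidean MDMR with a 0/1 regressor is one-way ANOVA."""
        rng = np.random.default_rng(20)
        for _ in range(20):
            n = int(rng.integers(6, 16))
            n1 = int(rng.integers(2, n - 2))
            y = rng.standard_normal(n)
            x = np.zeros(n)
            x[n1:] = 1.0
            data = DataMatrix(y[:, None], [f"s{i}" for i in range(n)], ["y"])
            g = gower_center(compute_distance_matrix(data))
            f_raw, _, _ = pseudo_f(g, build_projection(DesignMatrix(x)))
            f_scaled, df1, df2 = scaled_f(f_raw, n, 1, 1)
            f_ref, p_ref = stats.f_oneway(y[:n1], y[n1:])
            assert f_scaled == pytest.approx(f_ref, abs=1e-8 * max(1, f_ref))
            assert analytic_pvalue(f_scaled, df1, df2) == pytest.approx(p_ref, abs=1e-8)
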