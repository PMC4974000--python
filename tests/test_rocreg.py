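"""Placement values, indicator expansion, probit ROC-GLM fit and AUC."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu, norm

from rocglm._probit import QuasiSeparationWarning, fit_probit
from rocglm.rocreg import (
    Direction,
    FprGrid,
    MarkerSpec,
    RocCoefficients,
    auc,
    auc_numeric,
    auc_table,
    bootstrap,
    expand_indicators,
    fit,
    orient_marker,
    placement_values,
    roc_at,
    study_profile,
)

HIGHER = MarkerSpec("m", Direction.HIGHER_IS_DISEASED)


def brute_placement(case, controls, inclusive=True):
    """Direct-count oracle for one placement value."""
    if inclusive:
        return sum(c >= case for c in controls) / len(controls)
    return sum(c > case for c in controls) / len(controls)


class TestOrientation:
    def test_lower_is_diseased_negates(self):
        out = orient_marker([80.0, 70.0], MarkerSpec("rnfl_avg"))
        assert out.tolist() == [-80.0, -70.0]

    def test_higher_is_diseased_identity(self):
        assert orient_marker([1.0, 2.0], HIGHER).tolist() == [1.0, 2.0]

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=20))
    def test_double_negation_is_involution(self, values):
        spec = MarkerSpec("m", Direction.LOWER_IS_DISEASED)
        twice = orient_marker(orient_marker(values, spec), spec)
        assert np.allclose(twice, values)


class TestPlacementValues:
    def test_direct_count(self):
        pv = placement_values([2.5], [1, 2, 3, 4])
        assert pv.values.tolist() == [0.5]

    def test_case_above_all_controls(self):
        pv = placement_values([10.0], [1, 2, 3, 4])
        assert pv.values.tolist() == [0.0]

    def test_inclusive_tie_counts_the_tied_control(self):
        assert placement_values([2.0], [1, 2, 3, 4]).values.tolist() == [
            brute_placement(2.0, [1, 2, 3, 4])
        ]
        assert placement_values([2.0], [1, 2, 3, 4]).values.tolist() == [0.75]

    def test_strict_tie_rule(self):
        pv = placement_values([2.0], [1, 2, 3, 4], tie_rule="strict")
        assert pv.values.tolist() == [brute_placement(2.0, [1, 2, 3, 4], inclusive=False)]

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError):
            placement_values([1.0], [])

    @settings(deadline=None, max_examples=50)
    @given(
        cases=st.lists(st.integers(-5, 5), min_size=1, max_size=15),
        controls=st.lists(st.integers(-5, 5), min_size=1, max_size=15),
    )
    def test_matches_brute_force_with_ties(self, cases, controls):
        pv = placement_values(cases, controls)
        expected = [brute_placement(c, controls) for c in cases]
        assert np.allclose(pv.values, expected)

    def test_monotone_nonincreasing_in_case_value(self):
        rng = np.random.default_rng(0)
        controls = rng.normal(size=50)
        cases = np.sort(rng.normal(size=30))
        pv = placement_values(cases, controls)
        assert np.all(np.diff(pv.values) <= 0)


class TestIndicatorExpansion:
    def test_pv_zero_all_indicators_one(self):
        table = expand_indicators(placement_values([10.0], [1.0]), FprGrid.uniform(5))
        assert table["u"].tolist() == [1.0] * 5

    def test_pv_one_all_indicators_zero(self):
        table = expand_indicators(placement_values([-10.0], [1.0]), FprGrid.uniform(5))
        assert table["u"].tolist() == [0.0] * 5

    def test_half_pv_splits_grid(self):
        pv = placement_values([2.5], [1, 2, 3, 4])
        table = expand_indicators(pv, FprGrid((0.25, 0.75)))
        assert table["u"].tolist() == [0.0, 1.0]

    def test_indicators_nondecreasing_within_case(self):
        rng = np.random.default_rng(1)
        pv = placement_values(rng.normal(size=20), rng.normal(size=30))
        table = expand_indicators(pv, FprGrid.uniform(10))
        for _, grp in table.groupby("case_index"):
            assert np.all(np.diff(grp["u"]) >= 0)

    def test_covariates_repeated_per_case(self):
        pv = placement_values([0.0, 1.0], [0.5])
        cov = pd.DataFrame({"age": [50.0, 60.0]})
        table = expand_indicators(pv, FprGrid.uniform(3), cov)
        assert len(table) == 6
        assert table["age"].tolist() == [50.0] * 3 + [60.0] * 3

    def test_covariate_row_mismatch_rejected(self):
        pv = placement_values([0.0], [0.5])
        with pytest.raises(ValueError):
            expand_indicators(pv, FprGrid.uniform(3), pd.DataFrame({"age": [1.0, 2.0]}))


class TestFprGrid:
    @pytest.mark.parametrize("values", [(0.0, 0.5), (0.5, 1.0), (0.5,), (0.6, 0.4)])
    def test_invalid_grids_rejected(self, values):
        with pytest.raises(ValueError):
            FprGrid(values)

    def test_uniform_midpoint_layout(self):
        g = FprGrid.uniform(100).as_array()
        assert len(g) == 100
        assert g[0] == pytest.approx(0.005) and g[-1] == pytest.approx(0.995)


class TestProbitSolver:
    def test_agrees_with_statsmodels_glm(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(500), rng.normal(size=500), rng.normal(size=500)])
        y = (rng.random(500) < norm.cdf(X @ [0.3, 1.0, -0.5])).astype(float)
        ours = fit_probit(X, y)
        glm = sm.GLM(y, X, family=sm.families.Binomial(sm.families.links.Probit())).fit()
        assert np.allclose(ours.params, glm.params, atol=1e-6)
        assert np.allclose(ours.cov, glm.cov_params(), rtol=1e-4, atol=1e-8)

    def test_degenerate_response_warns(self):
        X = np.column_stack([np.ones(20), np.linspace(-1, 1, 20)])
        with pytest.warns(QuasiSeparationWarning):
            res = fit_probit(X, np.ones(20))
        assert res.separation


class TestFit:
    def test_recovers_covariate_free_binormal_truth(self):
        # truth alpha1 = (mu1-mu0)/sigma1 = 1, alpha2 = sigma0/sigma1 = 1;
        # tolerance = 3 x Monte-Carlo SD of the estimator at n=2000/1000
        # (0.042 and 0.032, estimated by repeated simulation)
        rng = np.random.default_rng(2024)
        f = fit(rng.normal(1, 1, 2000), rng.normal(0, 1, 1000), None, HIGHER)
        assert f.converged
        assert f.alpha1 == pytest.approx(1.0, abs=0.13)
        assert f.alpha2 == pytest.approx(1.0, abs=0.10)

    def test_marker_direction_equivalence(self):
        # negating a lower-is-diseased marker must give the identical fit
        rng = np.random.default_rng(5)
        cases, controls = rng.normal(70, 8, 150), rng.normal(90, 8, 80)
        lo = fit(cases, controls, None, MarkerSpec("t", Direction.LOWER_IS_DISEASED))
        hi = fit(-cases, -controls, None, HIGHER)
        assert lo.alpha1 == pytest.approx(hi.alpha1, abs=1e-9)
        assert lo.alpha2 == pytest.approx(hi.alpha2, abs=1e-9)

    def test_constant_marker_warns_degenerate(self):
        with pytest.warns(QuasiSeparationWarning):
            f = fit(np.full(30, 5.0), np.full(20, 5.0), None, HIGHER)
        assert f.separation

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fit(np.array([]), np.array([1.0]), None, HIGHER)


class TestRocCurveAndAuc:
    def test_chance_line_identity(self):
        coeffs = RocCoefficients(0.0, 1.0)
        q = np.linspace(0.01, 0.99, 50)
        assert np.allclose(roc_at(coeffs, None, q), q, atol=1e-12)
        assert auc(coeffs) == 0.5

    def test_published_rnfl_sensitivity_at_half(self, reference_sets):
        # linear shift at the baseline profile with VFI 100 is 1.2606
        coeffs = reference_sets["rnfl_avg"]
        sens = roc_at(coeffs, study_profile(100.0), 0.5)
        assert coeffs.linear_shift(study_profile(100.0)) == pytest.approx(1.2606, abs=5e-4)
        assert sens == pytest.approx(0.896, abs=1e-3)

    def test_strictly_increasing_in_q(self, reference_sets):
        coeffs = reference_sets["gcipl_min"]
        q = np.linspace(0.001, 0.999, 200)
        sens = roc_at(coeffs, study_profile(85.0), q)
        assert np.all(np.diff(sens) > 0)
        assert roc_at(coeffs, study_profile(85.0), 0.2) < roc_at(
            coeffs, study_profile(85.0), 0.8
        )

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.1, 1.5])
    def test_fpr_domain_enforced(self, q):
        with pytest.raises(ValueError):
            roc_at(RocCoefficients(0.0, 1.0), None, q)

    def test_missing_profile_covariate_rejected(self, reference_sets):
        with pytest.raises(ValueError, match="missing covariate"):
            auc(reference_sets["rnfl_avg"], {"vfi": 90.0})

    def test_auc_requires_positive_slope(self):
        with pytest.raises(ValueError):
            auc(RocCoefficients(1.0, -0.5))

    def test_closed_form_agrees_with_quadrature(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            coeffs = RocCoefficients(
                rng.normal(0, 2), rng.uniform(0.3, 3.0), {"x": rng.normal(0, 0.5)}
            )
            profile = {"x": rng.normal(0, 2)}
            assert auc(coeffs, profile) == pytest.approx(
                auc_numeric(coeffs, profile), abs=1e-6
            )

    def test_quadrature_refines_monotonically(self):
        coeffs = RocCoefficients(1.3, 0.8)
        exact = auc(coeffs)
        errs = [abs(auc_numeric(coeffs, None, n) - exact) for n in (64, 128, 256)]
        assert errs[0] >= errs[1] >= errs[2] or errs[2] < 1e-14

    def test_negative_beta_makes_auc_decreasing_in_covariate(self, reference_sets):
        coeffs = reference_sets["rnfl_avg"]  # beta_vfi < 0
        aucs = [auc(coeffs, study_profile(v)) for v in (70, 80, 90, 100)]
        assert np.all(np.diff(aucs) < 0)

    def test_auc_table_matches_scalar_auc(self, reference_sets):
        coeffs = reference_sets["gcipl_avg"]
        profiles = [study_profile(v) for v in (100.0, 70.0)]
        table = auc_table(coeffs, profiles)
        assert len(table) == 2
        assert table["auc"][0] == pytest.approx(auc(coeffs, profiles[0]))
        assert auc_table(coeffs, []).empty


class TestModelVsEmpirical:
    def test_model_auc_matches_mann_whitney(self):
        """Covariate-free fit agrees with the rank-based empirical AUROC."""
        rng = np.random.default_rng(11)
        cases = rng.normal(1.2, 1.4, 1000)
        controls = rng.normal(0.0, 1.0, 500)
        f = fit(cases, controls, None, HIGHER)
        u = mannwhitneyu(cases, controls, alternative="two-sided").statistic
        empirical = u / (len(cases) * len(controls))
        assert auc(f.coefficients) == pytest.approx(empirical, abs=0.02)


class TestBootstrap:
    @staticmethod
    def _data(seed=9, n1=150, n0=80):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.0, 1.0, n1)
        cases = rng.normal(0.8 + 0.4 * x, 1.0)
        controls = rng.normal(0.0, 1.0, n0)
        return cases, controls, pd.DataFrame({"x": x})

    def test_deterministic_for_fixed_seed(self):
        cases, controls, cov = self._data()
        grid = FprGrid.uniform(20)
        a = bootstrap(cases, controls, cov, HIGHER, grid, B=200, seed=4)
        b = bootstrap(cases, controls, cov, HIGHER, grid, B=200, seed=4)
        assert a.as_frame().equals(b.as_frame())
        assert np.array_equal(a.draws, b.draws)

    def test_percentile_interval_brackets_estimate(self):
        cases, controls, cov = self._data()
        res = bootstrap(cases, controls, cov, HIGHER, FprGrid.uniform(20), B=200, seed=4)
        for s in res.summaries:
            assert s.ci_low <= s.estimate <= s.ci_high
            assert 0.0 <= s.p_value <= 1.0

    def test_doubling_B_shifts_ci_within_noise(self):
        cases, controls, cov = self._data()
        grid = FprGrid.uniform(20)
        small = bootstrap(cases, controls, cov, HIGHER, grid, B=200, seed=4)
        big = bootstrap(cases, controls, cov, HIGHER, grid, B=400, seed=4)
        # percentile endpoints from B=200 vs B=400 should differ by much
        # less than the coefficient's own bootstrap SD
        for i, (s2, s4) in enumerate(zip(small.summaries, big.summaries)):
            se = np.std(big.draws[:, i], ddof=1)
            assert abs(s2.ci_low - s4.ci_low) < se
            assert abs(s2.ci_high - s4.ci_high) < se

    def test_minimum_replicates_enforced(self):
        cases, controls, cov = self._data()
        with pytest.raises(ValueError):
            bootstrap(cases, controls, cov, HIGHER, B=50, seed=1)
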