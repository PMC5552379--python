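import warnings

import numpy as np
import pytest
from scipy import stats

import isobolo as ib
from isobolo.regression import PAPER_COMPAT, STRICT, critical_t
from conftest import random_table


def normal_equations_oracle(x, y):
    """Independent route: direct solve of the 2x2 normal equations."""
    n = len(x)
    lhs = np.array([[n, x.sum()], [x.sum(), (x * x).sum()]])
    rhs = np.array([y.sum(), (x * y).sum()])
    a, b = np.linalg.solve(lhs, rhs)
    return a, b


class TestFitLogDose:
    def test_noiseless_line_recovered_exactly(self):
        doses = np.array([0.1, 1.0, 10.0, 100.0])
        y = 10.0 + 5.0 * np.log10(doses)
        fit = ib.fit_log_dose(ib.DoseEffectTable.from_arrays("x", doses, y))
        assert fit.slope == pytest.approx(5.0, abs=1e-12)
        assert fit.intercept == pytest.approx(10.0, abs=1e-12)
        assert fit.s2 == pytest.approx(0.0, abs=1e-20)
        assert fit.slope_variance == pytest.approx(0.0, abs=1e-20)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(25):
            table = random_table(rng)
            fit = ib.fit_log_dose(table)
            a, b = normal_equations_oracle(table.log_doses, table.responses)
            assert fit.slope == pytest.approx(b, rel=1e-10)
            assert fit.intercept == pytest.approx(a, rel=1e-10)

    def test_matches_scipy_linregress(self, sb_ipl):
        fit = ib.fit_log_dose(sb_ipl)
        ref = stats.linregress(sb_ipl.log_doses, sb_ipl.responses)
        assert fit.slope == pytest.approx(ref.slope, rel=1e-12)
        assert fit.intercept == pytest.approx(ref.intercept, rel=1e-12)
        assert np.sqrt(fit.slope_variance) == pytest.approx(ref.stderr, rel=1e-10)

    def test_derived_sums_match_raw_sums(self, pha_ipl):
        fit = ib.fit_log_dose(pha_ipl)
        x, y = pha_ipl.log_doses, pha_ipl.responses
        assert fit.sum_x == pytest.approx(x.sum(), rel=1e-12)
        assert fit.sum_y == pytest.approx(y.sum(), rel=1e-12)
        assert fit.sum_x2 == pytest.approx((x * x).sum(), rel=1e-12)
        assert fit.sum_xy == pytest.approx((x * y).sum(), rel=1e-9)

    def test_scale_equivariance(self, rng):
        table = random_table(rng, n_levels=4, n_per_level=3)
        fit = ib.fit_log_dose(table)
        scaled = ib.DoseEffectTable.from_arrays("x", table.doses * 10.0, table.responses)
        fit10 = ib.fit_log_dose(scaled)
        assert fit10.slope == pytest.approx(fit.slope, rel=1e-9)
        assert fit10.s2 == pytest.approx(fit.s2, rel=1e-9)
        assert fit10.slope_variance == pytest.approx(fit.slope_variance, rel=1e-9)
        ed, ed10 = ib.effective_dose(fit), ib.effective_dose(fit10)
        assert ed10.log_ed == pytest.approx(ed.log_ed + 1.0, abs=1e-9)
        assert ed10.variance == pytest.approx(ed.variance, rel=1e-9)

    def test_parameter_recovery_coverage(self):
        # b_true within 2*sqrt(V(b)) in >=93% of replicates (nominal 95%)
        spec = ib.table1_like_spec()
        hits = 0
        n_rep = 1000
        for seed in range(n_rep):
            t = ib.simulate_single(ib.SimSpec(
                spec.intercept, spec.slope, spec.sigma,
                spec.dose_levels, spec.n_per_dose, seed=seed))
            fit = ib.fit_log_dose(t)
            hits += abs(fit.slope - spec.slope) <= 2.0 * np.sqrt(fit.slope_variance)
        assert hits / n_rep >= 0.93


class TestSlopeTest:
    def test_paper_compat_uses_large_sample_value(self, sb_ipl):
        st = ib.slope_test(ib.fit_log_dose(sb_ipl), mode=PAPER_COMPAT)
        assert st.t_table == 1.96

    def test_strict_uses_student_quantile(self, sb_ipl):
        st = ib.slope_test(ib.fit_log_dose(sb_ipl), mode=STRICT)
        assert st.t_table == pytest.approx(stats.t.ppf(0.975, 58), rel=1e-12)

    def test_perfect_fit_warns_and_is_significant(self):
        doses = np.array([0.1, 1.0, 10.0, 100.0])
        fit = ib.fit_log_dose(
            ib.DoseEffectTable.from_arrays("x", doses, 10 + 5 * np.log10(doses))
        )
        with pytest.warns(UserWarning, match="perfect fit"):
            st = ib.slope_test(fit)
        assert st.t_slope == np.inf
        assert st.significant

    def test_flat_noisy_data_not_significant(self, rng):
        doses = np.repeat([0.1, 1.0, 10.0], 4)
        y = rng.normal(0, 30, size=12)
        y = y - np.polyval(np.polyfit(np.log10(doses), y, 1), np.log10(doses))  # force b = 0
        st = ib.slope_test(ib.fit_log_dose(ib.DoseEffectTable.from_arrays("x", doses, y)))
        assert st.t_slope == pytest.approx(0.0, abs=1e-9)
        assert not st.significant


class TestEffectiveDose:
    def test_intercept_at_target_gives_unit_dose(self):
        doses = np.array([0.1, 0.5, 2.0, 10.0])
        rngl = np.random.default_rng(7)
        y = 20.0 + 8.0 * np.log10(doses) + rngl.normal(0, 5, 4)
        fit = ib.fit_log_dose(ib.DoseEffectTable.from_arrays("x", doses, y))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ed = ib.effective_dose(fit, gamma=fit.intercept)
        assert ed.log_ed == pytest.approx(0.0, abs=1e-12)
        assert ed.ed == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_gamma_for_positive_slope(self, sb_ipl):
        fit = ib.fit_log_dose(sb_ipl)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eds = [ib.effective_dose(fit, g).ed for g in (5, 10, 20, 40, 60)]
        assert np.all(np.diff(eds) > 0)

    def test_extrapolation_warns(self, sb_ipl):
        fit = ib.fit_log_dose(sb_ipl)
        with pytest.warns(UserWarning, match="extrapolation"):
            ib.effective_dose(fit, gamma=99.0)

    def test_zero_slope_rejected(self, rng):
        doses = np.repeat([0.1, 1.0, 10.0], 4)
        y = rng.normal(0, 30, size=12)
        y = y - np.polyval(np.polyfit(np.log10(doses), y, 1), np.log10(doses))
        fit = ib.fit_log_dose(ib.DoseEffectTable.from_arrays("x", doses, y))
        fit = ib.RegressionFit(**{**fit.__dict__, "slope": 0.0})
        with pytest.raises(ib.UndefinedDoseError):
            ib.effective_dose(fit)

    def test_delta_method_variance_formula(self, pha_it):
        fit = ib.fit_log_dose(pha_it)
        ed = ib.effective_dose(fit)
        expected = fit.s2 / fit.slope**2 * (1 / fit.n + (ed.log_ed - fit.x_mean) ** 2 / fit.sxx)
        assert ed.variance == pytest.approx(expected, rel=1e-12)


class TestCriticalT:
    def test_paper_compat_ignores_df(self):
        assert critical_t(0.05, 5, PAPER_COMPAT) == 1.96
        assert critical_t(0.05, 500, PAPER_COMPAT) == 1.96

    def test_strict_requires_positive_df(self):
        with pytest.raises(ib.InsufficientDataError):
            critical_t(0.05, 0, STRICT)


class TestSummaryBlock:
    def test_contains_headline_numbers(self, sb_ipl):
        fit = ib.fit_log_dose(sb_ipl)
        st = ib.slope_test(fit)
        ed = ib.effective_dose(fit)
        block = ib.summary_block(fit, st, ed, label="drug A")
        assert "drug A" in block
        assert f"{fit.slope:.4f}" in block
        assert f"{st.t_slope:.4f}" in block
        assert f"DE{ed.gamma:g}" in block
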