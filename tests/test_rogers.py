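import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import frcompare as fc
from frcompare.rogers import NoInformationError, neg_loglik

from conftest import binomial_group, group_frame


def bisection_kills(n0, a, h, T=1.0):
    """Independent 1-D root-bracketing oracle for the Rogers fixed point."""
    if n0 == 0 or a == 0 or T == 0:
        return 0.0
    f = lambda ne: ne - n0 * (1 - np.exp(a * (ne * h - T)))
    with np.errstate(over="ignore"):
        return brentq(f, 0.0, n0, xtol=1e-13, rtol=1e-15)


class TestExpectedKills:
    @pytest.mark.parametrize(
        "n0,a,h,T",
        [(0, 1.5, 0.03, 1.0), (32, 1.5, 0.03, 0.0), (32, 0.0, 0.03, 1.0)],
    )
    def test_degenerate_inputs_give_zero(self, n0, a, h, T):
        assert fc.rogers_expected_kills(n0, (a, h), T) == 0.0

    def test_zero_handling_time_reduces_to_exponential_depletion(self):
        ne = fc.rogers_expected_kills(40, (1.2, 0.0), 0.5)
        assert ne == pytest.approx(40 * (1 - np.exp(-1.2 * 0.5)), rel=1e-12)

    def test_matches_bisection_oracle_at_study_scale(self):
        # frozen from the bracketing oracle at (N0=64, a=1.584, h=0.032, T=1)
        ne = fc.rogers_expected_kills(64, fc.FRParams(1.584, 0.032), 1.0)
        assert ne == pytest.approx(22.638060877353684, abs=1e-9)

    @settings(max_examples=100, deadline=None)
    @given(
        n0=st.integers(1, 200),
        a=st.floats(0.01, 10.0),
        h=st.floats(0.0, 0.5),
        T=st.floats(0.05, 3.0),
    )
    def test_lambertw_agrees_with_bracketing(self, n0, a, h, T):
        ne = fc.rogers_expected_kills(n0, (a, h), T)
        ref = bisection_kills(n0, a, h, T)
        assert ne == pytest.approx(ref, rel=1e-9, abs=1e-9)

    @settings(max_examples=60, deadline=None)
    @given(
        n0=st.integers(1, 100),
        a=st.floats(0.05, 5.0),
        h=st.floats(0.005, 0.4),
        T=st.floats(0.1, 2.0),
    )
    def test_monotonicity_and_bounds(self, n0, a, h, T):
        ne = fc.rogers_expected_kills(n0, (a, h), T)
        assert 0.0 <= ne <= min(n0, T / h + 1)
        assert fc.rogers_expected_kills(n0, (a * 1.1, h), T) >= ne - 1e-9
        assert fc.rogers_expected_kills(n0, (a, h * 1.1), T) <= ne + 1e-9
        assert fc.rogers_expected_kills(n0 + 1, (a, h), T) >= ne - 1e-9
        assert fc.rogers_expected_kills(n0, (a, h), T * 1.1) >= ne - 1e-9

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            fc.rogers_expected_kills(10, (-1.0, 0.03))
        with pytest.raises(ValueError):
            fc.rogers_expected_kills(-5, (1.0, 0.03))


class TestNegLoglik:
    def test_additive_over_identical_trials(self):
        one = group_frame(np.array([16.0]), np.array([8.0]))
        two = pd.concat([one, one], ignore_index=True)
        params = fc.FRParams(1.0, 0.05)
        assert neg_loglik(params, two) == pytest.approx(
            2 * neg_loglik(params, one), rel=1e-12
        )

    def test_finite_under_total_depletion(self):
        # tiny attack rate but every prey killed: clamping keeps NLL finite
        df = group_frame(np.array([8.0, 16.0]), np.array([8.0, 16.0]))
        val = neg_loglik(fc.FRParams(1e-6, 0.01), df)
        assert np.isfinite(val)

    def test_rejects_control_rows(self):
        df = group_frame(np.array([8.0]), np.array([2.0]))
        df["is_control"] = True
        df["sex"] = None
        with pytest.raises(ValueError, match="control"):
            neg_loglik(fc.FRParams(1.0, 0.05), df)

    def test_single_trial_minimized_near_data(self):
        # with one trial at the rounded Rogers expectation, the generating
        # parameters beat every perturbed pair on a coarse grid
        n0 = np.array([32.0])
        params = fc.FRParams(1.5, 0.03)
        ne = np.array([round(fc.rogers_expected_kills(32, params))])
        df = group_frame(n0, ne)
        base = neg_loglik(params, df)
        for fa in (0.5, 0.75, 1.5, 2.0):
            for fh in (0.25, 0.5, 2.0, 4.0):
                other = fc.FRParams(1.5 * fa, 0.03 * fh)
                assert neg_loglik(other, df) >= base - 1e-6


class TestFitRogers:
    def test_parameter_recovery_within_wald_band(self):
        n0, ne = binomial_group(1.5, 0.03, reps=25, seed=11)  # 200 trials
        fit = fc.fit_rogers(group_frame(n0, ne))
        assert fit.converged
        assert abs(fit.params.attack_rate - 1.5) < 3 * fit.se[0]
        assert abs(fit.params.handling_time - 0.03) < 3 * fit.se[1]

    def test_optimum_beats_surrounding_log_grid(self):
        n0, ne = binomial_group(1.0, 0.08, reps=5, seed=3)
        df = group_frame(n0, ne)
        fit = fc.fit_rogers(df)
        best = -fit.loglik
        a_hat, h_hat = fit.params.attack_rate, fit.params.handling_time
        grid = np.linspace(-0.5, 0.5, 50)
        nlls = [
            neg_loglik((a_hat * np.exp(da), h_hat * np.exp(dh)), df)
            for da in grid
            for dh in grid
        ]
        assert best <= min(nlls) + 1e-6

    def test_fit_is_deterministic(self):
        n0, ne = binomial_group(0.8, 0.2, reps=5, seed=9)
        df = group_frame(n0, ne)
        f1, f2 = fc.fit_rogers(df), fc.fit_rogers(df)
        assert f1 == f2

    def test_all_zero_kills_not_identifiable(self):
        df = group_frame(np.array([4.0, 8.0, 16.0]), np.zeros(3))
        with pytest.raises(NoInformationError):
            fc.fit_rogers(df)

    def test_single_density_flagged_ill_posed(self):
        est = fc.RogersRandomPredator()
        with pytest.warns(UserWarning, match="single prey density"):
            est.fit(np.full(10, 16.0), np.full(10, 5.0))
        assert est.ill_posed_

    def test_estimator_predict_matches_closed_form(self):
        n0, ne = binomial_group(1.2, 0.05, reps=10, seed=4)
        est = fc.RogersRandomPredator().fit(n0, ne)
        pred = est.predict([8, 32])
        expect = fc.rogers_expected_kills(
            np.array([8.0, 32.0]), (est.attack_rate_, est.handling_time_)
        )
        np.testing.assert_allclose(pred, expect)

    def test_sklearn_param_interface(self):
        est = fc.RogersRandomPredator(tol=1e-6)
        assert est.get_params()["tol"] == 1e-6
        est.set_params(tol=1e-9)
        assert est.tol == 1e-9


class TestImpactMetrics:
    def test_exact_arithmetic(self):
        m = fc.impact_metrics(fc.FRParams(2.0, 0.5))
        assert m.max_feeding_rate == 2.0 and m.frr == 4.0

    def test_undefined_for_zero_handling(self):
        with pytest.raises(ZeroDivisionError):
            fc.impact_metrics(fc.FRParams(2.0, 0.0))

    def test_recomputable_from_fit(self):
        n0, ne = binomial_group(1.5, 0.03, reps=5, seed=2)
        fit = fc.fit_rogers(group_frame(n0, ne))
        m = fc.impact_metrics(fit)
        assert m.max_feeding_rate == 1.0 / fit.params.handling_time
        assert m.frr == fit.params.attack_rate / fit.params.handling_time
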