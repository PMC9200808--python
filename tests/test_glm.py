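import copy

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import frcompare as fc
from frcompare.glm import AliasedTermError, FactorialConsumptionGLM



def factorial_frame(p_fn, reps=5, densities=(1, 2, 4, 6, 8, 16, 32, 64),
                    seed=0, integer=True):
    """Crossed sex x temperature x salinity x density table with kills from
    probability function p_fn(sex, temp, sal, density)."""
    rng = np.random.default_rng(seed)
    rows = []
    for sex in ("M", "F"):
        for temp in (16.0, 22.0):
            for sal in (15.0, 10.0):
                for d in densities:
                    for _ in range(reps):
                        p = p_fn(sex, temp, sal, d)
                        nk = rng.binomial(d, p) if integer else p * d
                        rows.append(
                            {"sex": sex, "temperature": temp, "salinity": sal,
                             "n_initial": d, "n_killed": nk, "duration": 1.0,
                             "is_control": False}
                        )
    return pd.DataFrame(rows)


def logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


@pytest.fixture(scope="module")
def null_frame():
    # density effect only; no factor effects at all
    return factorial_frame(lambda s, t, sa, d: logistic(0.5 - 0.04 * d), seed=17)


class TestFitQuasibinomial:
    def test_no_factor_effects_means_near_zero_coefficients(self, null_frame):
        model = fc.fit_quasibinomial(null_frame)
        di = model.design_info_
        names = di.column_names
        se = np.sqrt(np.diag(model.result_.cov_params()) * model.dispersion_)
        z = model.params_ / se
        factor_cols = [i for i, n in enumerate(names)
                       if "Sum" in n and "density" not in n]
        assert np.all(np.abs(z[factor_cols]) < 4)

    def test_duplicating_rows_leaves_coefficients_unchanged(self, null_frame):
        doubled = pd.concat([null_frame, null_frame], ignore_index=True)
        m1 = fc.fit_quasibinomial(null_frame)
        m2 = fc.fit_quasibinomial(doubled)
        np.testing.assert_allclose(m1.params_, m2.params_, rtol=1e-8)

    def test_coefficients_identical_to_plain_binomial_fit(self, null_frame):
        # the quasibinomial layer scales inference only
        model = fc.fit_quasibinomial(null_frame)
        res = sm.GLM(model._endog, model._exog,
                     family=sm.families.Binomial()).fit()
        np.testing.assert_array_equal(model.params_, np.asarray(res.params))

    def test_dispersion_near_one_for_binomial_data(self):
        phis = [
            fc.fit_quasibinomial(
                factorial_frame(lambda s, t, sa, d: logistic(0.5 - 0.04 * d),
                                seed=100 + k)
            ).dispersion_
            for k in range(30)
        ]
        assert np.mean(phis) == pytest.approx(1.0, abs=0.05)

    def test_rejects_empty_input(self):
        with pytest.raises(ValueError):
            fc.fit_quasibinomial(pd.DataFrame(
                {"n_initial": [4], "n_killed": [1], "is_control": [True],
                 "sex": [None], "temperature": [16.0], "salinity": [15.0],
                 "duration": [1.0]}
            ))


class TestAnovaType3:
    def test_detects_injected_sex_effect(self):
        df = factorial_frame(
            lambda s, t, sa, d: logistic((1.0 if s == "M" else -0.2) - 0.04 * d),
            seed=23,
        )
        tab = fc.fit_quasibinomial(df).anova_type3()
        assert tab["Sex"]["p"] < 0.001
        assert tab["Density"]["p"] < 0.001
        assert tab["Salinity"]["p"] > 0.05

    def test_single_df_terms_in_two_level_factorial(self, null_frame):
        tab = fc.fit_quasibinomial(null_frame).anova_type3().table
        assert len(tab) == 15  # all mains, interactions up to 4-way
        assert (tab["df"] == 1).all()
        assert tab["p"].between(0, 1).all()

    def test_constant_factor_is_aliased(self, null_frame):
        df = null_frame.assign(salinity=15.0)
        with pytest.raises(AliasedTermError, match="alias"):
            fc.fit_quasibinomial(df)

    def test_type3_close_to_sequential_in_balanced_orthogonal_design(self):
        """In a balanced design whose contrasts are mutually orthogonal —
        sum-coded factors only, equal prey counts, so the IRLS weights are
        homogeneous — Type III tests coincide with sequential (Type I) tests.
        The classical equivalence is exact for linear models; the GLM deviance
        is quadratic only asymptotically, so agreement is asserted up to that
        nonlinearity. (With an uncentered covariate interacting with factors,
        e.g. density, the orthogonality premise itself fails and only the
        highest-order term would agree.)"""
        flat = factorial_frame(lambda s, t, sa, d: 0.45, densities=(16,),
                               reps=30, seed=17)
        model = FactorialConsumptionGLM(
            formula="C(sex, Sum) * C(temperature, Sum) * C(salinity, Sum)"
        ).fit(flat)
        t3 = model.anova_type3().table.set_index("raw_term")
        # sequential: add terms in formula order, record deviance drops
        terms = [t.name() for t in model.design_info_.terms if t.factors]
        dev_prev = sm.GLM(model._endog,
                          np.ones((len(model._endog), 1)),
                          family=sm.families.Binomial()).fit().deviance
        for i, term in enumerate(terms):
            cols = [0] + [
                j for t in terms[: i + 1]
                for j in range(*model.design_info_.term_name_slices[t].indices(
                    model._exog.shape[1]))
            ]
            res = sm.GLM(model._endog, model._exog[:, cols],
                         family=sm.families.Binomial()).fit()
            f_seq = (dev_prev - res.deviance) / model.dispersion_
            dev_prev = res.deviance
            assert f_seq == pytest.approx(t3.loc[term, "F"], rel=0.05, abs=0.05)


class TestBackwardSelect:
    def test_fully_significant_model_unchanged(self):
        df = factorial_frame(
            lambda s, t, sa, d: logistic(
                (0.8 if s == "M" else -0.8) * (1 + 0.02 * d) - 0.04 * d
            ),
            reps=10,
            seed=5,
        )
        model = FactorialConsumptionGLM(
            formula="C(sex, Sum) * density"
        ).fit(df)
        reduced, removed = model.backward_select()
        assert removed.empty
        assert len(reduced.anova_type3().table) == 3

    def test_pure_density_process_collapses_to_density(self, null_frame):
        model = fc.fit_quasibinomial(null_frame)
        reduced, removed = model.backward_select()
        kept = set(reduced.anova_type3().table["term"])
        assert "Density" in kept
        assert len(removed) >= 10

    def test_marginality_respected(self):
        # a strong three-way interaction protects its constituent terms
        df = factorial_frame(
            lambda s, t, sa, d: logistic(
                0.5
                - 0.03 * d
                - (0.04 * d if (s == "M" and t == 22.0) else 0.0)
            ),
            reps=10,
            seed=7,
        )
        reduced, _ = fc.fit_quasibinomial(df).backward_select()
        kept = set(reduced.anova_type3().table["term"])
        if "Sex x Temperature x Density" in kept:
            assert {"Sex", "Temperature", "Density", "Sex x Temperature",
                    "Sex x Density", "Temperature x Density"} <= kept


class TestDensitySlopeContrast:
    def test_zero_when_slopes_equal_by_construction(self):
        # expected counts generated exactly from a model with no
        # temperature-dependent slope: the MLE sits on that submodel
        df = factorial_frame(
            lambda s, t, sa, d: logistic(
                (0.5 if s == "M" else -0.5) - 0.03 * d
            ),
            integer=False,
            seed=0,
        )
        model = fc.fit_quasibinomial(df)
        est, se, stat, p = model.density_slope_contrast("M")
        assert est == pytest.approx(0.0, abs=1e-8)

    def test_detects_male_only_interaction(self, experiment_frame):
        # the bundled scenario lengthens male handling with warming, which
        # shows up as a steeper male proportion decline at 22 degrees
        model = fc.fit_quasibinomial(experiment_frame)
        est_m, _, _, p_m = model.density_slope_contrast("M", temps=(16.0, 22.0))
        _, _, _, p_f = model.density_slope_contrast("F", temps=(16.0, 22.0))
        assert est_m < 0 and p_m < 0.05
        assert p_f > 0.05

    def test_se_scales_with_sqrt_dispersion(self, null_frame):
        model = fc.fit_quasibinomial(null_frame)
        _, se1, _, _ = model.density_slope_contrast("M")
        inflated = copy.copy(model)
        inflated.dispersion_ = model.dispersion_ * 4.0
        _, se2, _, _ = inflated.density_slope_contrast("M")
        assert se2 == pytest.approx(2.0 * se1, rel=1e-10)

    def test_unknown_level_rejected(self, null_frame):
        model = fc.fit_quasibinomial(null_frame)
        with pytest.raises(ValueError, match="sex"):
            model.density_slope_contrast("X")
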