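"""Factorial consumption-rate analysis: quasibinomial GLM with Type III tests.

The proportion of prey killed per trial is modelled on the logit scale as a
function of the crossed treatment factors (sex, temperature, salinity — each
sum-to-zero coded) and prey density (continuous), with all interactions up to
the four-way term. The mean model is the ordinary binomial-logit GLM fit by
IRLS; overdispersion, ubiquitous in feeding-proportion data, is absorbed by a
quasibinomial dispersion parameter phi = Pearson chi^2 / df_resid, which leaves
the coefficients identical to the binomial fit and scales all inference.

Term significance uses Type III analysis of deviance: each term's columns are
removed from the full design matrix (all other terms retained, including
higher-order interactions) and F = (Delta deviance / Delta df) / phi is
referred to F(Delta df, df_resid). Sum-to-zero factor coding is what makes
these marginal tests meaningful in the presence of interactions — with
treatment coding the same procedure would test parameters at baseline levels.

Backward model selection removes, one per step, the least significant term
among the currently removable ones (those not contained in a retained
higher-order interaction), until every removable term is significant at
``alpha``. Post-hoc comparison of density slopes between temperatures within a
sex is a Wald contrast on the fitted coefficients with quasi-scaled covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
from scipy import stats
import statsmodels.api as sm

from .design import as_frame

__all__ = [
    "AliasedTermError",
    "FactorialConsumptionGLM",
    "DevianceTable",
    "fit_quasibinomial",
    "anova_type3",
    "backward_select",
    "density_slope_contrast",
]

FACTORS = ("sex", "temperature", "salinity")
FULL_FORMULA = (
    "C(sex, Sum) * C(temperature, Sum) * C(salinity, Sum) * density"
)


class AliasedTermError(ValueError):
    """Raised when a model term is aliased (e.g. a constant factor)."""


@dataclass(frozen=True)
class DevianceTable:
    """Per-term Type III F-tests."""

    table: pd.DataFrame  # columns: term, F, df, p

    def __getitem__(self, term: str) -> pd.Series:
        row = self.table[self.table["term"] == term]
        if row.empty:
            raise KeyError(term)
        return row.iloc[0]


def _pretty_term(term: str) -> str:
    # "C(sex, Sum):density" -> "Sex x Density"
    parts = []
    for f in term.split(":"):
        f = f.strip()
        if f.startswith("C(") and "," in f:
            f = f[2:].split(",")[0].strip()
        parts.append(f.capitalize())
    return " x ".join(parts)


def _term_factors(term) -> frozenset:
    return frozenset(f.name() for f in term.factors)


class FactorialConsumptionGLM:
    """Quasibinomial factorial GLM on proportion of prey killed.

    Parameters
    ----------
    formula : str
        Right-hand-side patsy formula; default the full four-way factorial with
        sum-to-zero factor contrasts and continuous density.
    """

    def __init__(self, formula: str = FULL_FORMULA):
        self.formula = formula

    # -- fitting -----------------------------------------------------------

    def fit(self, trials):
        """Fit to the non-control rows of a trial table."""
        df = as_frame(trials)
        df = df[~df["is_control"].astype(bool)].reset_index(drop=True)
        if len(df) == 0:
            raise ValueError("no predator trials")
        data = df.copy()
        data["density"] = data["n_initial"].astype(float)
        for f in FACTORS:
            if f in data.columns:
                data[f] = data[f].astype(str)
        self._data = data
        exog = patsy.dmatrix(self.formula, data, return_type="dataframe")
        self.design_info_ = exog.design_info
        self._check_aliasing(exog)
        endog = np.column_stack(
            [data["n_killed"].to_numpy(float),
             (data["n_initial"] - data["n_killed"]).to_numpy(float)]
        )
        self._endog = endog
        self._exog = np.asarray(exog)
        res = sm.GLM(endog, self._exog, family=sm.families.Binomial()).fit()
        self.result_ = res
        self.params_ = res.params
        self.deviance_ = float(res.deviance)
        self.df_resid_ = float(res.df_resid)
        self.dispersion_ = float(res.pearson_chi2 / res.df_resid)
        return self

    def _check_aliasing(self, exog: pd.DataFrame) -> None:
        di = exog.design_info
        X = np.asarray(exog)
        # a factor with a single level yields a zero column under Sum coding;
        # general rank deficiency is also reported as aliasing
        for term, sl in di.term_name_slices.items():
            if term == "Intercept":
                continue
            sub = X[:, sl]
            if sub.shape[1] == 0 or np.allclose(sub, 0) or np.allclose(sub.var(axis=0), 0):
                raise AliasedTermError(f"term '{term}' is aliased (constant columns)")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise AliasedTermError("design matrix is rank deficient: aliased terms present")

    def _require_fit(self):
        if not hasattr(self, "result_"):
            raise RuntimeError("model is not fitted")

    # -- Type III ----------------------------------------------------------

    def anova_type3(self) -> DevianceTable:
        """Type III analysis of deviance with quasibinomial F-tests."""
        self._require_fit()
        di = self.design_info_
        rows = []
        phi = self.dispersion_
        for term, sl in di.term_name_slices.items():
            if term == "Intercept":
                continue
            keep = np.ones(self._exog.shape[1], dtype=bool)
            keep[sl] = False
            res0 = sm.GLM(self._endog, self._exog[:, keep],
                          family=sm.families.Binomial()).fit()
            ddf = int((~keep).sum())
            ddev = float(res0.deviance - self.deviance_)
            F = (ddev / ddf) / phi
            p = float(stats.f.sf(F, ddf, self.df_resid_))
            rows.append({"term": _pretty_term(term), "raw_term": term,
                         "F": F, "df": ddf, "p": p})
        return DevianceTable(pd.DataFrame(rows))

    # -- backward selection ------------------------------------------------

    def _removable_terms(self) -> list[str]:
        di = self.design_info_
        terms = {t.name(): _term_factors(t) for t in di.terms if t.factors}
        removable = []
        for name, facs in terms.items():
            contained = any(
                facs < other and name != oname
                for oname, other in terms.items()
            )
            if not contained:
                removable.append(name)
        return removable

    def backward_select(self, alpha: float = 0.05):
        """Backward stepwise elimination by Type III p-value.

        Returns ``(reduced_model, history)`` where ``history`` is a DataFrame of
        the removed terms in order with the p-value at removal.
        """
        self._require_fit()
        current = self
        removed = []
        while True:
            tab = current.anova_type3().table.set_index("raw_term")
            removable = current._removable_terms()
            cand = tab.loc[[t for t in removable if t in tab.index]]
            cand = cand[cand["p"] >= alpha]
            if cand.empty:
                break
            worst = cand["p"].idxmax()
            removed.append({"term": _pretty_term(worst),
                            "p_at_removal": float(cand.loc[worst, "p"])})
            new_terms = [t.name() for t in current.design_info_.terms
                         if t.factors and t.name() != worst]
            if not new_terms:
                formula = "1"
            else:
                formula = " + ".join(new_terms)
            current = FactorialConsumptionGLM(formula=formula).fit(self._trials_frame())
        return current, pd.DataFrame(removed, columns=["term", "p_at_removal"])

    def _trials_frame(self) -> pd.DataFrame:
        return self._data

    # -- contrasts ---------------------------------------------------------

    def density_slope_contrast(self, sex: str, temps: tuple = None):
        """Difference in density slope between two temperatures within a sex.

        The slope of the linear predictor in density for a given cell is the
        difference of design rows at density d+1 and d, averaged over salinity
        levels. Returns ``(estimate, se, stat, p)`` with the covariance scaled
        by the quasibinomial dispersion and p from Student t on residual df.
        """
        self._require_fit()
        if "density" not in {f.name() for t in self.design_info_.terms
                             for f in t.factors}:
            raise ValueError("model has no density term")
        data = self._data
        temps_all = sorted(data["temperature"].unique())
        if temps is None:
            if len(temps_all) != 2:
                raise ValueError("specify temps: temperature has != 2 levels")
            temps = (temps_all[0], temps_all[1])
        t1, t2 = (str(t) for t in temps)
        sals = sorted(data["salinity"].unique())
        sex = str(sex)
        if sex not in set(data["sex"]):
            raise ValueError(f"unknown sex level {sex!r}")

        def slope_row(temp: str) -> np.ndarray:
            rows_lo = pd.DataFrame(
                {"sex": sex, "temperature": temp, "salinity": sals,
                 "density": 0.0}
            )
            rows_hi = rows_lo.assign(density=1.0)
            (x_lo,) = patsy.build_design_matrices([self.design_info_], rows_lo)
            (x_hi,) = patsy.build_design_matrices([self.design_info_], rows_hi)
            return np.asarray(x_hi).mean(axis=0) - np.asarray(x_lo).mean(axis=0)

        L = slope_row(t2) - slope_row(t1)
        est = float(L @ self.params_)
        cov = np.asarray(self.result_.cov_params()) * self.dispersion_
        se = float(np.sqrt(L @ cov @ L))
        stat = est / se
        p = float(2 * stats.t.sf(abs(stat), self.df_resid_))
        return est, se, stat, p


# -- module-level wrappers -------------------------------------------------


def fit_quasibinomial(trials, formula: str = FULL_FORMULA) -> FactorialConsumptionGLM:
    """Fit the quasibinomial factorial GLM to a trial table."""
    return FactorialConsumptionGLM(formula=formula).fit(trials)


def anova_type3(model: FactorialConsumptionGLM) -> DevianceTable:
    return model.anova_type3()


def backward_select(model: FactorialConsumptionGLM, alpha: float = 0.05):
    return model.backward_select(alpha=alpha)


def density_slope_contrast(model: FactorialConsumptionGLM, sex: str,
                           temps: tuple = None):
    return model.density_slope_contrast(sex, temps)
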