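"""Functional-response type determination and the LOWESS diagnostic.

Whether a response is Type II (saturating) or Type III (sigmoidal) is decided
before any mechanistic model is fit, from the shape of proportion killed
versus initial prey density. Two binomial logistic regressions are fit by IRLS,
sequentially, as the comparative-FR toolchains do:

    logit(Ne/N0) ~ N0            (first-order term: coef1, z1, p1)
    logit(Ne/N0) ~ N0 + N0^2     (second-order term: coef2, z2, p2)

A significant negative first-order term indicates Type II; a significant
positive first-order term followed by a significant negative second-order term
indicates Type III; anything else is indeterminate. Testing the first-order
term in the density-only model (rather than alongside the quadratic term)
keeps full power under strong prey depletion, where the proportion killed is
flat near 1 over the low densities and the quadratic term would otherwise
absorb most of the decline.

The LOWESS curve (locally weighted linear regression with tricube weights over
the nearest span-fraction of points, default span 0.9, no robustifying
iterations) is the standard visual companion: a proportion that falls
monotonically from the lowest densities corroborates Type II.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .design import as_frame

__all__ = [
    "TypeTestResult",
    "type_test",
    "lowess_proportions",
    "FunctionalResponseTypeTest",
]


@dataclass(frozen=True)
class TypeTestResult:
    """Sequential logistic-regression summary and the II/III/indeterminate call."""

    coef1: float
    coef2: float
    z1: float
    z2: float
    p1: float
    p2: float
    call: str  # "TypeII" | "TypeIII" | "indeterminate"
    alpha: float = 0.05
    separation: bool = False


class FunctionalResponseTypeTest(BaseEstimator):
    """Response-type classifier: sequential logistic regressions on density.

    Attributes after ``fit``: ``coef1_``, ``coef2_``, ``z1_``, ``z2_``,
    ``p1_``, ``p2_``, ``call_``, ``separation_``.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y):
        """Fit to initial densities ``X`` and kill counts ``y``."""
        n0 = np.asarray(X, dtype=float).reshape(-1)
        ne = np.asarray(y, dtype=float).reshape(-1)
        if len(np.unique(n0)) < 3:
            raise ValueError("type test needs >= 3 distinct prey densities")
        if np.any(ne > n0) or np.any(ne < 0):
            raise ValueError("kill counts must satisfy 0 <= n_killed <= n_initial")
        endog = np.column_stack([ne, n0 - ne])
        exog1 = sm.add_constant(n0)
        exog2 = sm.add_constant(np.column_stack([n0, n0 ** 2]))
        self.separation_ = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", PerfectSeparationWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                res1 = sm.GLM(endog, exog1, family=sm.families.Binomial()).fit()
                res2 = sm.GLM(endog, exog2, family=sm.families.Binomial()).fit()
            # diverging coefficients show up as enormous Wald SEs
            for res in (res1, res2):
                if not np.all(np.isfinite(res.bse)) or np.any(res.bse > 1e4):
                    self.separation_ = True
        except (ValueError, np.linalg.LinAlgError):
            self.separation_ = True
        if self.separation_:
            self.intercept_ = np.nan
            self.coef1_ = self.coef2_ = self.z1_ = self.z2_ = np.nan
            self.p1_ = self.p2_ = np.nan
            self.call_ = "indeterminate"
            return self
        self.intercept_ = float(res1.params[0])
        self._quad_params = np.asarray(res2.params, dtype=float)
        self.coef1_, self.z1_ = float(res1.params[1]), float(res1.tvalues[1])
        self.p1_ = float(res1.pvalues[1])
        self.coef2_, self.z2_ = float(res2.params[2]), float(res2.tvalues[2])
        self.p2_ = float(res2.pvalues[2])
        a = self.alpha
        if self.p1_ < a and self.coef1_ < 0:
            self.call_ = "TypeII"
        elif self.p1_ < a and self.coef1_ > 0 and self.p2_ < a and self.coef2_ < 0:
            self.call_ = "TypeIII"
        else:
            self.call_ = "indeterminate"
        return self

    def predict(self, X):
        """Kill proportion at densities ``X`` from the quadratic fit."""
        if not hasattr(self, "coef1_"):
            raise RuntimeError("estimator is not fitted")
        n0 = np.asarray(X, dtype=float).reshape(-1)
        b = self._quad_params
        eta = b[0] + b[1] * n0 + b[2] * n0 ** 2
        return 1.0 / (1.0 + np.exp(-eta))

    @property
    def result_(self) -> TypeTestResult:
        return TypeTestResult(
            coef1=self.coef1_, coef2=self.coef2_, z1=self.z1_, z2=self.z2_,
            p1=self.p1_, p2=self.p2_, call=self.call_, alpha=self.alpha,
            separation=self.separation_,
        )


def type_test(trials, alpha: float = 0.05) -> TypeTestResult:
    """Classify the functional-response type of a group of trials."""
    df = as_frame(trials)
    df = df[~df["is_control"].astype(bool)]
    est = FunctionalResponseTypeTest(alpha=alpha)
    est.fit(df["n_initial"].to_numpy(), df["n_killed"].to_numpy())
    return est.result_


def lowess_proportions(trials, span: float = 0.9, iters: int = 0):
    """LOWESS smooth of proportion killed against density.

    Returns ``(densities, fitted)`` evaluated at the sorted observed densities,
    with fitted proportions clipped to [0, 1] for reporting. ``span`` is the
    fraction of points used in each local regression (default 9/10); ``iters``
    robustifying iterations (default 0).
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    df = as_frame(trials)
    df = df[~df["is_control"].astype(bool)]
    n0 = df["n_initial"].to_numpy(dtype=float)
    if len(np.unique(n0)) < 2:
        raise ValueError("LOWESS needs >= 2 distinct prey densities")
    prop = df["n_killed"].to_numpy(dtype=float) / n0
    sm_out = _sm_lowess(prop, n0, frac=span, it=iters, return_sorted=True)
    grid, fitted = sm_out[:, 0], np.clip(sm_out[:, 1], 0.0, 1.0)
    # collapse duplicate x (lowess returns one row per point)
    uniq, idx = np.unique(grid, return_index=True)
    return uniq, fitted[idx]
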