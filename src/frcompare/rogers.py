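"""Rogers' random predator model: Type II functional response with prey depletion.

In a feeding trial without prey replacement the number killed, ``Ne``, feeds
back on itself — every prey consumed lowers the density for the rest of the
trial — so the Type II (saturating) response must be written implicitly:

    Ne = N0 * (1 - exp(a * (Ne * h - T)))

with attack rate ``a`` (per-period clearance), handling time ``h`` (periods per
prey) and trial duration ``T`` (periods). The unique root on [0, N0] has a
closed form through the principal branch of the Lambert W function,

    Ne = N0 - W(a h N0 exp(-a (T - h N0))) / (a h),

which this module uses for prediction and for the binomial likelihood of the
observed kill counts. Fitting is maximum likelihood on (log a, log h) —
positivity is enforced by the parameterization — via a derivative-free simplex
search polished by quasi-Newton, with standard errors from the inverse
numerical Hessian at the optimum.

Derived impact metrics follow the comparative functional-response literature:
the maximum feeding rate ``1/h`` (prey per period, the saturation ceiling) and
the functional response ratio ``FRR = a/h``, a composite index in which higher
values indicate greater predicted ecological impact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import lambertw, gammaln
from sklearn.base import BaseEstimator
from statsmodels.tools.numdiff import approx_hess

from .design import as_frame

__all__ = [
    "FRParams",
    "FRFit",
    "ImpactMetrics",
    "NoInformationError",
    "rogers_expected_kills",
    "neg_loglik",
    "fit_rogers",
    "impact_metrics",
    "RogersRandomPredator",
]

_EPS = 1e-9  # probability clamp; keeps the NLL finite under total depletion


class NoInformationError(ValueError):
    """Raised when the data cannot identify the attack rate (no kills at all)."""


@dataclass(frozen=True)
class FRParams:
    """Functional-response parameters: attack rate ``a`` and handling time ``h``."""

    attack_rate: float
    handling_time: float

    def __post_init__(self) -> None:
        if self.attack_rate < 0 or self.handling_time < 0:
            raise ValueError(
                f"attack_rate and handling_time must be >= 0, got "
                f"({self.attack_rate}, {self.handling_time})"
            )

    @property
    def max_feeding_rate(self) -> float:
        """Saturation feeding rate 1/h (prey per period)."""
        if self.handling_time == 0:
            raise ZeroDivisionError("max feeding rate undefined for h = 0")
        return 1.0 / self.handling_time

    @property
    def frr(self) -> float:
        """Functional response ratio a/h."""
        if self.handling_time == 0:
            raise ZeroDivisionError("FRR undefined for h = 0")
        return self.attack_rate / self.handling_time


@dataclass(frozen=True)
class ImpactMetrics:
    max_feeding_rate: float
    frr: float


@dataclass(frozen=True)
class FRFit:
    """A fitted Rogers model.

    ``se_log`` holds standard errors of (log a, log h); ``se`` the delta-method
    errors on the natural scale. ``p_attack``/``p_handling`` are two-sided Wald
    p-values for the natural-scale parameters against zero. ``ill_posed`` flags
    fits from a single prey density (curve shape not identifiable).
    """

    params: FRParams
    se_log: tuple[float, float]
    se: tuple[float, float]
    loglik: float
    converged: bool
    n_trials: int
    p_attack: float
    p_handling: float
    ill_posed: bool = False


def _coerce_params(params) -> tuple[float, float]:
    if isinstance(params, FRParams):
        return params.attack_rate, params.handling_time
    a, h = params
    if a < 0 or h < 0:
        raise ValueError(f"attack rate and handling time must be >= 0, got ({a}, {h})")
    return float(a), float(h)


def rogers_expected_kills(n_initial, params, duration=1.0):
    """Expected kills ``Ne`` from the Rogers equation (Lambert W closed form).

    Vectorized over ``n_initial`` and ``duration``. Limits: ``h = 0`` reduces to
    exponential depletion ``N0 (1 - exp(-a T))``; ``a = 0``, ``T = 0`` or
    ``N0 = 0`` give 0.
    """
    a, h = _coerce_params(params)
    n0 = np.asarray(n_initial, dtype=float)
    T = np.asarray(duration, dtype=float)
    if np.any(n0 < 0):
        raise ValueError("n_initial must be >= 0")
    if np.any(T < 0):
        raise ValueError("duration must be >= 0")
    if a == 0:
        return np.zeros(np.broadcast(n0, T).shape) if (n0.ndim or T.ndim) else 0.0
    n0b, Tb = np.broadcast_arrays(n0, T)
    ne = _ne_raw(n0b.astype(float), a, h, Tb.astype(float))
    return float(ne) if np.ndim(n0) == 0 and np.ndim(T) == 0 else ne


def _lambertw_exp(logz):
    """W(exp(logz)) on the principal branch, stable for large logz.

    For moderate arguments this is scipy's lambertw; past the overflow range it
    solves w + log w = logz by Newton from the two-term asymptotic expansion.
    """
    shape = np.shape(logz)
    logz = np.atleast_1d(np.asarray(logz, dtype=float))
    out = np.empty_like(logz)
    small = logz < 600.0
    if np.any(small):
        out[small] = lambertw(np.exp(logz[small])).real
    if np.any(~small):
        x = logz[~small]
        w = x - np.log(x)
        for _ in range(4):
            w -= (w + np.log(w) - x) / (1.0 + 1.0 / w)
        out[~small] = w
    return out.reshape(shape)


def _ne_raw(n0, a: float, h: float, T):
    # closed-form Rogers solution, no validation (hot path)
    if a == 0:
        return np.zeros_like(n0)
    if h == 0:
        return np.clip(n0 * (1.0 - np.exp(-a * T)), 0.0, n0)
    with np.errstate(divide="ignore"):
        logz = np.log(a * h * n0) - a * (T - h * n0)
    w = _lambertw_exp(logz)
    return np.clip(n0 - w / (a * h), 0.0, n0)


def _nll_arrays(log_a: float, log_h: float, n0, ne, T, binom_const) -> float:
    a, h = np.exp(log_a), np.exp(log_h)
    p = _ne_raw(n0, a, h, T) / n0
    p = np.clip(p, _EPS, 1.0 - _EPS)
    ll = binom_const + ne * np.log(p) + (n0 - ne) * np.log1p(-p)
    return -float(np.sum(ll))


def _nll_grad(log_a: float, log_h: float, n0, ne, T) -> np.ndarray:
    """Analytic gradient of the NLL in (log a, log h).

    From implicit differentiation of Ne = N0 (1 - exp(a (Ne h - T))):
        dNe/da = (N0 - Ne)(T - Ne h) / (1 + a h (N0 - Ne))
        dNe/dh = -a (N0 - Ne) Ne / (1 + a h (N0 - Ne))
    Contributions where the kill probability sits on the clamp are zero.
    """
    a, h = np.exp(log_a), np.exp(log_h)
    ne_det = _ne_raw(n0, a, h, T)
    p = ne_det / n0
    interior = (p > _EPS) & (p < 1.0 - _EPS)
    p = np.clip(p, _EPS, 1.0 - _EPS)
    dll_dp = np.where(interior, ne / p - (n0 - ne) / (1.0 - p), 0.0)
    denom = 1.0 + a * h * (n0 - ne_det)
    dne_da = (n0 - ne_det) * (T - ne_det * h) / denom
    dne_dh = -a * (n0 - ne_det) * ne_det / denom
    g_loga = -np.sum(dll_dp * dne_da / n0) * a
    g_logh = -np.sum(dll_dp * dne_dh / n0) * h
    return np.array([g_loga, g_logh])


def neg_loglik(params, trials) -> float:
    """Negative binomial log-likelihood of kill counts under the Rogers model.

    Each trial contributes Binomial(n_killed | n_initial, Ne/N0) with ``Ne`` the
    deterministic Rogers solution; the kill probability is clamped to
    [1e-9, 1 - 1e-9] so total depletion keeps the likelihood finite.
    """
    a, h = _coerce_params(params)
    df = as_frame(trials)
    if df["is_control"].any():
        raise ValueError("control rows present; likelihood is for predator trials only")
    if len(df) == 0:
        raise ValueError("no trials")
    n0 = df["n_initial"].to_numpy(dtype=float)
    ne = df["n_killed"].to_numpy(dtype=float)
    T = df["duration"].to_numpy(dtype=float)
    const = gammaln(n0 + 1) - gammaln(ne + 1) - gammaln(n0 - ne + 1)
    with np.errstate(over="ignore"):
        return _nll_arrays(np.log(a) if a > 0 else -np.inf,
                           np.log(h) if h > 0 else -np.inf,
                           n0, ne, T, const)


def _hanes_init(n0, ne, T) -> tuple[float, float]:
    # disc-equation linearization: T/Ne = 1/(a N0) + h
    mask = ne > 0
    if mask.sum() >= 2 and len(np.unique(n0[mask])) >= 2:
        y = T[mask] / ne[mask]
        x = 1.0 / n0[mask]
        slope, intercept = np.polyfit(x, y, 1)
        if slope > 0 and intercept > 0:
            return 1.0 / slope, intercept
    return 1.0, 1.0 / float(np.max(n0))


def _newton_polish(theta0, nll, grad, tol=1e-9, max_iter=40):
    """Damped Newton on (log a, log h) with finite-difference Hessian of the
    analytic gradient. Returns (theta, fun, converged). Cheap warm-start
    optimizer for bootstrap refits; falls back to the standard route on
    failure."""
    theta = np.asarray(theta0, dtype=float).copy()
    f = nll(theta)
    eps = 1e-6
    for _ in range(max_iter):
        g = grad(theta)
        if np.linalg.norm(g) < 1e-8:
            return theta, f, True
        h = np.empty((2, 2))
        for j in range(2):
            step = np.zeros(2)
            step[j] = eps
            h[:, j] = (grad(theta + step) - g) / eps
        h = 0.5 * (h + h.T)
        try:
            delta = np.linalg.solve(h, -g)
        except np.linalg.LinAlgError:
            return theta, f, False
        if not np.all(np.isfinite(delta)) or (delta @ g) > 0:
            delta = -g  # non-descent Newton step: steepest descent
        t = 1.0
        for _ in range(25):
            f_new = nll(theta + t * delta)
            if f_new <= f - 1e-4 * t * abs(delta @ g):
                break
            t *= 0.5
        else:
            return theta, f, abs(np.linalg.norm(g)) < 1e-6
        if f - f_new < tol and np.linalg.norm(t * delta) < 1e-8:
            return theta + t * delta, f_new, True
        theta = theta + t * delta
        f = f_new
    return theta, f, np.linalg.norm(grad(theta)) < 1e-6


class RogersRandomPredator(BaseEstimator):
    """Maximum-likelihood Rogers random predator fit, as an sklearn estimator.

    Parameters
    ----------
    init : FRParams or (a, h) pair, optional
        Starting values; by default a disc-equation linearization (regression of
        T/Ne on 1/N0) with fallback (1, 1/max density).
    tol : float
        Convergence tolerance on the negative log-likelihood.
    compute_se : bool
        Whether to compute standard errors from the numerical Hessian (skipped
        in bootstrap refits for speed).

    Attributes (after ``fit``)
    --------------------------
    attack_rate_, handling_time_ : float
        ML estimates.
    se_log_, se_ : ndarray
        Standard errors of (log a, log h) and delta-method (a, h) errors.
    loglik_ : float
    converged_ : bool
    ill_posed_ : bool
        True when only one distinct density is present.
    """

    def __init__(self, init=None, tol: float = 1e-8, compute_se: bool = True,
                 fast: bool = False):
        self.init = init
        self.tol = tol
        self.compute_se = compute_se
        self.fast = fast

    def fit(self, X, y, duration=1.0):
        """Fit to initial densities ``X`` and kill counts ``y``.

        ``duration`` may be a scalar or per-trial array (period units).
        """
        n0 = np.asarray(X, dtype=float).reshape(-1)
        ne = np.asarray(y, dtype=float).reshape(-1)
        if n0.shape != ne.shape:
            raise ValueError("X and y must have the same length")
        if len(n0) == 0:
            raise ValueError("no trials")
        if np.any(ne > n0) or np.any(ne < 0):
            raise ValueError("kill counts must satisfy 0 <= n_killed <= n_initial")
        T = np.broadcast_to(np.asarray(duration, dtype=float), n0.shape)
        if ne.sum() == 0:
            raise NoInformationError(
                "all kill counts are zero: attack rate not identifiable"
            )
        self.ill_posed_ = len(np.unique(n0)) < 2
        if self.ill_posed_:
            warnings.warn(
                "single prey density: functional-response shape is not identifiable",
                UserWarning,
                stacklevel=2,
            )

        if self.init is not None:
            a0, h0 = _coerce_params(self.init)
            if a0 <= 0 or h0 <= 0:
                raise ValueError("init must have a > 0 and h > 0")
        else:
            a0, h0 = _hanes_init(n0, ne, T)
        theta0 = np.array([np.log(a0), np.log(h0)])

        const = gammaln(n0 + 1) - gammaln(ne + 1) - gammaln(n0 - ne + 1)

        def nll(theta):
            return _nll_arrays(theta[0], theta[1], n0, ne, T, const)

        def grad(theta):
            return _nll_grad(theta[0], theta[1], n0, ne, T)

        # coarse derivative-free simplex for robustness, gradient polish for
        # precision (analytic gradient via implicit differentiation); the
        # ``fast`` path — for warm-started bootstrap refits — tries a damped
        # Newton step first and falls back to the full route if it stalls
        with np.errstate(over="ignore", invalid="ignore"):
            theta = fun = None
            ok = False
            if self.fast:
                t_n, f_n, conv = _newton_polish(theta0, nll, grad, tol=self.tol)
                if conv and f_n <= nll(theta0) + 1e-9:
                    theta, fun, ok = t_n, f_n, True
            if theta is None:
                simplex = optimize.minimize(
                    nll, theta0, method="Nelder-Mead",
                    options={"xatol": 1e-4, "fatol": self.tol, "maxiter": 200},
                )
                polish = optimize.minimize(
                    nll, simplex.x, jac=grad, method="BFGS",
                    options={"gtol": 1e-8, "maxiter": 100},
                )
                best = polish if polish.fun <= simplex.fun else simplex
                theta, fun = best.x, float(best.fun)
                # line-search "precision loss" endpoints are routinely at the
                # optimum; judge by gradient norm as well as status flags
                g_ok = np.linalg.norm(np.atleast_1d(polish.jac)) < 1e-4
                ok = bool(simplex.success or polish.success or g_ok)
        self.attack_rate_ = float(np.exp(theta[0]))
        self.handling_time_ = float(np.exp(theta[1]))
        self.loglik_ = -float(fun)
        self.n_trials_ = len(n0)

        self.se_log_ = np.full(2, np.nan)
        self.se_ = np.full(2, np.nan)
        if self.compute_se:
            with np.errstate(all="ignore"):
                try:
                    hess = approx_hess(theta, nll)
                    cov = np.linalg.inv(hess)
                    d = np.diag(cov)
                    if np.all(d > 0):
                        self.se_log_ = np.sqrt(d)
                        self.se_ = self.se_log_ * np.array(
                            [self.attack_rate_, self.handling_time_]
                        )
                except np.linalg.LinAlgError:
                    pass
            self.converged_ = ok and bool(np.all(np.isfinite(self.se_log_)))
        else:
            self.converged_ = ok
        return self

    def predict(self, X, duration=1.0):
        """Expected kills at initial densities ``X``."""
        if not hasattr(self, "attack_rate_"):
            raise RuntimeError("estimator is not fitted")
        return rogers_expected_kills(
            np.asarray(X, dtype=float).reshape(-1),
            (self.attack_rate_, self.handling_time_),
            duration,
        )

    @property
    def params_(self) -> FRParams:
        return FRParams(self.attack_rate_, self.handling_time_)


def fit_rogers(trials, init=None, compute_se: bool = True) -> FRFit:
    """Fit the Rogers model to a trial table (non-control rows) and return FRFit."""
    df = as_frame(trials)
    df = df[~df["is_control"].astype(bool)]
    if len(df) == 0:
        raise ValueError("no predator trials")
    est = RogersRandomPredator(init=init, compute_se=compute_se)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        est.fit(
            df["n_initial"].to_numpy(),
            df["n_killed"].to_numpy(),
            duration=df["duration"].to_numpy(dtype=float),
        )
    z_a = est.attack_rate_ / est.se_[0] if np.isfinite(est.se_[0]) else np.nan
    z_h = est.handling_time_ / est.se_[1] if np.isfinite(est.se_[1]) else np.nan
    return FRFit(
        params=est.params_,
        se_log=(float(est.se_log_[0]), float(est.se_log_[1])),
        se=(float(est.se_[0]), float(est.se_[1])),
        loglik=est.loglik_,
        converged=est.converged_,
        n_trials=est.n_trials_,
        p_attack=float(2 * stats.norm.sf(abs(z_a))) if np.isfinite(z_a) else np.nan,
        p_handling=float(2 * stats.norm.sf(abs(z_h))) if np.isfinite(z_h) else np.nan,
        ill_posed=est.ill_posed_,
    )


def impact_metrics(fit: FRFit | FRParams) -> ImpactMetrics:
    """Maximum feeding rate 1/h and FRR a/h from unrounded fitted parameters."""
    params = fit.params if isinstance(fit, FRFit) else fit
    if params.handling_time == 0:
        raise ZeroDivisionError("impact metrics undefined for h = 0")
    return ImpactMetrics(
        max_feeding_rate=1.0 / params.handling_time,
        frr=params.attack_rate / params.handling_time,
    )
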