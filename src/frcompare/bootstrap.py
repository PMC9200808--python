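"""Nonparametric bootstrap of the Rogers fit.

Trial rows are resampled with replacement (same n, unstratified), the Rogers
model is refit to each resample, and the replicate (a, h) draws yield 2.5/97.5
percentile intervals for the parameters and a pointwise 95% envelope of the
fitted curve over a density grid. Curve envelopes are the standard visual
device for comparing treatment groups: divergent envelopes across densities
indicate a credible difference in functional response.

Replicates whose refit fails are dropped and counted in ``n_failed`` rather
than redrawn, so the seed-to-output map is deterministic. Refits warm-start
from the point estimate and skip standard-error computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .design import as_frame
from .rogers import FRFit, RogersRandomPredator, fit_rogers, rogers_expected_kills

__all__ = ["BootstrapResult", "bootstrap_fit", "envelope_overlap", "RogersBootstrap"]


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap draws, percentile CIs, and the curve envelope."""

    n_boot: int
    draws: np.ndarray  # (n_usable, 2): columns attack rate, handling time
    param_ci: dict  # {"attack_rate": (lo, hi), "handling_time": (lo, hi)}
    density_grid: np.ndarray
    curve: np.ndarray  # point-estimate expected kills on the grid
    envelope_lo: np.ndarray
    envelope_hi: np.ndarray
    n_failed: int
    point: FRFit

    @property
    def n_usable(self) -> int:
        return len(self.draws)


class RogersBootstrap(BaseEstimator):
    """Bootstrap meta-estimator around :class:`RogersRandomPredator`.

    Parameters: ``n_boot`` resamples (default 2000), ``random_state`` seed,
    ``density_grid`` (default integers 1..max observed density). After ``fit``,
    ``result_`` holds the :class:`BootstrapResult`.
    """

    def __init__(self, n_boot: int = 2000, random_state=None, density_grid=None):
        self.n_boot = n_boot
        self.random_state = random_state
        self.density_grid = density_grid

    def fit(self, X, y, duration=1.0):
        n0 = np.asarray(X, dtype=float).reshape(-1)
        ne = np.asarray(y, dtype=float).reshape(-1)
        T = np.broadcast_to(np.asarray(duration, dtype=float), n0.shape)
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")

        point_est = RogersRandomPredator()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            point_est.fit(n0, ne, duration=T)
        init = (point_est.attack_rate_, point_est.handling_time_)

        grid = (np.arange(1, int(np.max(n0)) + 1, dtype=float)
                if self.density_grid is None
                else np.asarray(self.density_grid, dtype=float))
        rng = np.random.default_rng(self.random_state)
        n = len(n0)
        draws = np.empty((self.n_boot, 2))
        curves = np.empty((self.n_boot, len(grid)))
        ok = np.zeros(self.n_boot, dtype=bool)
        for b in range(self.n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                est = RogersRandomPredator(init=init, compute_se=False, fast=True)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    est.fit(n0[idx], ne[idx], duration=T[idx])
            except Exception:  # no kills in resample, optimizer failure, ...
                continue
            if not (np.isfinite(est.attack_rate_) and np.isfinite(est.handling_time_)):
                continue
            draws[b] = (est.attack_rate_, est.handling_time_)
            curves[b] = rogers_expected_kills(grid, (est.attack_rate_,
                                                     est.handling_time_),
                                              float(np.median(T)))
            ok[b] = True

        n_failed = int(self.n_boot - ok.sum())
        if ok.sum() == 0:
            raise RuntimeError("all bootstrap replicates failed to fit")
        if n_failed > 0.2 * self.n_boot:
            warnings.warn(
                f"{n_failed}/{self.n_boot} bootstrap replicates failed to fit",
                UserWarning, stacklevel=2,
            )
        draws, curves = draws[ok], curves[ok]
        lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
        env_lo, env_hi = np.percentile(curves, [2.5, 97.5], axis=0)
        point_fit = fit_rogers(
            _frame(n0, ne, T), init=init
        )
        self.result_ = BootstrapResult(
            n_boot=self.n_boot,
            draws=draws,
            param_ci={"attack_rate": (float(lo[0]), float(hi[0])),
                      "handling_time": (float(lo[1]), float(hi[1]))},
            density_grid=grid,
            curve=rogers_expected_kills(grid, init, float(np.median(T))),
            envelope_lo=env_lo,
            envelope_hi=env_hi,
            n_failed=n_failed,
            point=point_fit,
        )
        return self


def _frame(n0, ne, T):
    import pandas as pd

    return pd.DataFrame(
        {"sex": "X", "temperature": 0.0, "salinity": 0.0,
         "n_initial": n0.astype(int), "n_killed": ne.astype(int),
         "duration": T, "is_control": False}
    )


def bootstrap_fit(trials, n_boot: int = 2000, seed=None,
                  density_grid=None) -> BootstrapResult:
    """Bootstrap the Rogers fit of a trial table (non-control rows)."""
    df = as_frame(trials)
    df = df[~df["is_control"].astype(bool)]
    if len(df) == 0:
        raise ValueError("no predator trials")
    est = RogersBootstrap(n_boot=n_boot, random_state=seed,
                          density_grid=density_grid)
    est.fit(df["n_initial"].to_numpy(), df["n_killed"].to_numpy(),
            duration=df["duration"].to_numpy(dtype=float))
    return est.result_


def envelope_overlap(res_a: BootstrapResult, res_b: BootstrapResult):
    """Pointwise overlap of two 95% curve envelopes on a shared density grid.

    Returns ``(overlap, disjoint_fraction)``: a boolean array that is True where
    the two intervals intersect, and the fraction of grid points where they are
    disjoint (the divergence summary used to compare groups).
    """
    if (len(res_a.density_grid) != len(res_b.density_grid)
            or not np.allclose(res_a.density_grid, res_b.density_grid)):
        raise ValueError("bootstrap results have different density grids")
    overlap = (res_a.envelope_lo <= res_b.envelope_hi) & (
        res_b.envelope_lo <= res_a.envelope_hi
    )
    return overlap, float(1.0 - overlap.mean())
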