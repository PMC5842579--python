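"""Steady-state model and fitting of an auto-repressor under graded knockdown.

An auto-repressor expressed from its own promoter represses itself through
a Hill function.  Graded CRISPR knockdown multiplies the effective
initiation rate by the passage probability r, so the normalized
steady-state expression g solves the fixed point

    g = r * beta / (1 + (g / K)**n),

with K the binding constant (in units of normalized expression), n the Hill
coefficient, and beta the maximal normalized expression.  Because the right
side is strictly decreasing in g the positive root is unique.

Fitting minimizes weighted squared residuals of log-expression over (K, n)
or over K alone with n fixed, from a deterministic multi-start grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize, minimize_scalar

from .errors import FitFailureError
from .model import _check

__all__ = [
    "FeedbackParams",
    "FeedbackDataset",
    "FeedbackFit",
    "steady_state",
    "fit_feedback",
    "compare_hill",
]


@dataclass(frozen=True)
class FeedbackParams:
    """Hill-feedback parameters: binding constant K, coefficient n, max beta."""

    K: float
    n: float
    beta: float = 1.0
    dapg_label: str = ""

    def __post_init__(self) -> None:
        _check(self.K > 0.0, f"K must be > 0, got {self.K}")
        _check(self.n > 0.0, f"n must be > 0, got {self.n}")
        _check(self.beta > 0.0, f"beta must be > 0, got {self.beta}")


@dataclass(frozen=True)
class FeedbackDataset:
    """Observed normalized expression vs passage probability for one condition.

    ``points`` is a list of (r, g_obs, g_sd) triples; replicates appear as
    repeated r values.
    """

    points: tuple[tuple[float, float, float], ...]
    condition: str = ""

    def __post_init__(self) -> None:
        _check(len(self.points) >= 3, "need >= 3 points for a 2-parameter fit")
        for r, g, gsd in self.points:
            _check(0.0 < r <= 1.0, f"r must be in (0, 1], got {r}")
            _check(g > 0.0, f"g_obs must be > 0, got {g}")
            _check(gsd >= 0.0, "g_sd must be >= 0")


@dataclass(frozen=True)
class FeedbackFit:
    """Result of a feedback fit: parameters, RSS and per-point residuals."""

    params: FeedbackParams
    rss: float
    residuals: tuple[float, ...] = field(default=())
    n_fixed: bool = False


def steady_state(r: float, params: FeedbackParams, tol: float = 1e-10) -> float:
    """Unique positive steady state of the auto-repressor at knockdown level r.

    Solves g = r*beta/(1 + (g/K)^n) by bracketed root-finding on
    (0, r*beta]; the residual at the returned root is below ``tol``.
    """
    _check(0.0 < r <= 1.0, f"r must be in (0, 1], got {r}")
    top = r * params.beta

    def f(g: float) -> float:
        return g - top / (1.0 + (g / params.K) ** params.n)

    # f(0) = -top < 0 and f(top) >= 0, so the root is bracketed.
    return float(brentq(f, 0.0, top, xtol=tol, rtol=8.881784197001252e-16))


def _objective(data: FeedbackDataset, K: float, n: float, beta: float) -> float:
    rss = 0.0
    for r, g_obs, g_sd in data.points:
        g_hat = steady_state(r, FeedbackParams(K=K, n=n, beta=beta))
        w = 1.0 / max(g_sd / g_obs, 1e-3) ** 2 if g_sd > 0 else 1.0
        rss += w * (math.log(g_obs) - math.log(g_hat)) ** 2
    return rss


def fit_feedback(data: FeedbackDataset, n_fixed: float | None = None,
                 beta: float = 1.0) -> FeedbackFit:
    """Weighted least-squares fit of (K, n) on log-expression residuals.

    With ``n_fixed`` the optimization runs over K only.  Deterministic:
    multi-start from a log-spaced K grid (and an n grid when n is free),
    refined with Nelder-Mead.
    """
    lk_lo, lk_hi = math.log(1e-4), math.log(1e4)
    lk_grid = np.linspace(lk_lo, lk_hi, 81)
    best: tuple[float, float, float] | None = None  # (rss, K, n)

    if n_fixed is not None:
        _check(n_fixed > 0.0, "n_fixed must be > 0")
        vals = [_objective(data, math.exp(lk), n_fixed, beta) for lk in lk_grid]
        i = int(np.argmin(vals))
        lo = lk_grid[max(i - 1, 0)]
        hi = lk_grid[min(i + 1, len(lk_grid) - 1)]
        res = minimize_scalar(
            lambda lk: _objective(data, math.exp(lk), n_fixed, beta),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10})
        if res.success:
            best = (float(res.fun), math.exp(float(res.x)), float(n_fixed))
    else:
        n_grid = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0)
        coarse = sorted(
            ((_objective(data, math.exp(lk), n0, beta), lk, n0)
             for lk in lk_grid[::4] for n0 in n_grid))
        for _, lk0, n0 in coarse[:5]:
            res = minimize(
                lambda v: _objective(data, math.exp(v[0]), math.exp(v[1]), beta),
                x0=np.array([lk0, math.log(n0)]),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
            if res.success and (best is None or res.fun < best[0]):
                best = (float(res.fun), math.exp(float(res.x[0])),
                        math.exp(float(res.x[1])))
    if best is None:
        raise FitFailureError(
            f"feedback fit failed from all starting points "
            f"(condition {data.condition!r})")
    rss, K, n = best
    params = FeedbackParams(K=K, n=n, beta=beta, dapg_label=data.condition)
    resid = tuple(math.log(g) - math.log(steady_state(r, params))
                  for r, g, _ in data.points)
    return FeedbackFit(params=params, rss=rss, residuals=resid,
                       n_fixed=n_fixed is not None)


def compare_hill(data: FeedbackDataset,
                 candidates: tuple[float, ...] = (1.0, 2.0),
                 beta: float = 1.0) -> list[FeedbackFit]:
    """Fit each candidate Hill coefficient and rank by residual sum.

    Ties (within 1e-12) break toward the smaller n.  A single candidate is
    returned unchanged with its fit.
    """
    _check(len(candidates) >= 1, "need at least one candidate")
    fits = [fit_feedback(data, n_fixed=float(n), beta=beta) for n in candidates]
    fits.sort(key=lambda f: (round(f.rss, 12), f.params.n))
    return fits
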