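"""Analytic core of the kick-out model of dCas9-mediated repression.

A catalytically dead Cas9 bound inside an open reading frame acts as a
roadblock for elongating RNA polymerase.  On each collision the polymerase
passes with probability ``r = 1 - P(stop)`` set by guide-RNA/target
complementarity, and a successful passage ejects the roadblock with
frequency ``delta``.  The steady-state relative expression of the target,

    gamma* = (r + lambda*r + alpha) / (1 + lambda*r + alpha),

depends only on two dimensionless groups: ``lambda = delta*gamma0 /
(kon*[dCas9])`` (collision-driven ejection over rebinding) and ``alpha =
koff / (kon*[dCas9])`` (spontaneous unbinding over rebinding).

This module provides the forward equations, the inverse inference of the
normalized kick-out rate ``lambda*r`` from a measured relative expression,
cross-promoter prediction via promoter-strength scaling, bounds on the
spontaneous unbinding rate and on the roadblock-complex lifetime, the
Cooper-Helmstetter gene copy number, and Monte-Carlo uncertainty
propagation for all of the above.

Units: all rates are per minute; expression levels are dimensionless
fractions of the unrepressed level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy.optimize import brentq

from .errors import (
    IllPosedPropagationError,
    InconsistentInputsError,
    KickoutError,
    NoCrossingError,
    UndefinedOccupancyError,
    ValidationError,
)

__all__ = [
    "GuideSpec",
    "KineticParams",
    "DimensionlessPoint",
    "PromoterPair",
    "CopyNumberParams",
    "UncertainValue",
    "gamma_star",
    "relative_expression",
    "occupancy",
    "kout_rate",
    "infer_lambda_r",
    "predict_promoter",
    "alpha_crossing",
    "koff_upper_bound",
    "lifetime_bound",
    "gene_copy_number",
    "propagate_uncertainty",
]


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GuideSpec:
    """A guide RNA characterized by its RNAP passage probability.

    ``r = 1 - P(stop)`` is the probability that RNA polymerase transcribes
    through the roadblock upon collision; ``complementarity_bp`` counts
    matching PAM-proximal bases.
    """

    spacer_id: str
    complementarity_bp: int
    r: float
    r_sd: float = 0.0

    def __post_init__(self) -> None:
        _check(0 <= self.complementarity_bp <= 20,
               f"complementarity_bp must be in [0, 20], got {self.complementarity_bp}")
        _check(0.0 <= self.r <= 1.0, f"passage probability r must be in [0, 1], got {self.r}")
        _check(self.r_sd >= 0.0, f"r_sd must be >= 0, got {self.r_sd}")


@dataclass(frozen=True)
class KineticParams:
    """Kinetic rates of the roadblock cycle (all per minute).

    ``rebinding_rate`` is the product kon*[dCas9]; ``delta`` is the
    probability that a successful RNAP passage ejects the roadblock.
    """

    gamma0: float
    rebinding_rate: float
    koff: float = 0.0
    delta: float = 1.0

    def __post_init__(self) -> None:
        _check(self.gamma0 >= 0.0, "gamma0 must be >= 0")
        _check(self.rebinding_rate >= 0.0, "rebinding_rate must be >= 0")
        _check(self.koff >= 0.0, "koff must be >= 0")
        _check(0.0 <= self.delta <= 1.0, f"delta must be in [0, 1], got {self.delta}")


@dataclass(frozen=True)
class DimensionlessPoint:
    """Reduced model state (lambda, alpha, r)."""

    lambda_: float
    alpha: float
    r: float

    def __post_init__(self) -> None:
        _check(self.lambda_ >= 0.0, "lambda_ must be >= 0")
        _check(self.alpha >= 0.0, "alpha must be >= 0")
        _check(0.0 <= self.r <= 1.0, f"r must be in [0, 1], got {self.r}")

    @property
    def lambda_r(self) -> float:
        """The normalized kick-out rate lambda*r, the primary inferred group."""
        return self.lambda_ * self.r


@dataclass(frozen=True)
class PromoterPair:
    """A reference promoter with measured repression plus a stronger/weaker target.

    ``strength_fold`` is the target/reference ratio of unrepressed initiation
    rates; ``gamma_star_ref`` the measured relative expression of the
    repressed reference.
    """

    ref_name: str
    target_name: str
    strength_fold: float
    gamma_star_ref: float
    strength_fold_sd: float = 0.0
    gamma_star_ref_sd: float = 0.0

    def __post_init__(self) -> None:
        _check(self.strength_fold > 0.0, "strength_fold must be > 0")
        _check(0.0 < self.gamma_star_ref <= 1.0,
               f"gamma_star_ref must be in (0, 1], got {self.gamma_star_ref}")
        _check(self.strength_fold_sd >= 0.0, "strength_fold_sd must be >= 0")
        _check(self.gamma_star_ref_sd >= 0.0, "gamma_star_ref_sd must be >= 0")


@dataclass(frozen=True)
class CopyNumberParams:
    """Cooper-Helmstetter cell-cycle parameters (minutes) and locus position.

    ``phi`` is the relative origin-to-terminus distance of the locus
    (0 = origin, 1 = terminus).
    """

    tC: float
    tD: float
    td: float
    phi: float

    def __post_init__(self) -> None:
        _check(self.tC >= 0.0, "tC must be >= 0")
        _check(self.tD >= 0.0, "tD must be >= 0")
        _check(self.td > 0.0, "td must be > 0")
        _check(0.0 <= self.phi <= 1.0, f"phi must be in [0, 1], got {self.phi}")


@dataclass(frozen=True)
class UncertainValue:
    """A mean with a Gaussian standard deviation, for MC propagation."""

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        _check(self.sd >= 0.0, f"sd must be >= 0, got {self.sd}")


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def gamma_star(lambda_r: float, alpha: float, r: float) -> float:
    """Relative expression (r + lambda*r + alpha)/(1 + lambda*r + alpha).

    Functional core taking the normalized kick-out rate ``lambda_r``
    directly; always lies in [r, 1].
    """
    _check(lambda_r >= 0.0, "lambda_r must be >= 0")
    _check(alpha >= 0.0, "alpha must be >= 0")
    _check(0.0 <= r <= 1.0, "r must be in [0, 1]")
    return (r + lambda_r + alpha) / (1.0 + lambda_r + alpha)


def relative_expression(point: DimensionlessPoint) -> float:
    """Relative expression gamma* of a repressed gene at a reduced state."""
    return gamma_star(point.lambda_r, point.alpha, point.r)


def occupancy(params: KineticParams, kout: float) -> float:
    """Steady-state probability that the roadblock occupies its target.

    P(bound) = rebinding / (rebinding + kout).  Raises
    :class:`UndefinedOccupancyError` when both rates vanish.
    """
    _check(kout >= 0.0, "kout must be >= 0")
    if params.rebinding_rate == 0.0 and kout == 0.0:
        raise UndefinedOccupancyError("occupancy undefined: rebinding and leaving rates both zero")
    return params.rebinding_rate / (params.rebinding_rate + kout)


def kout_rate(params: KineticParams, guide: GuideSpec) -> float:
    """Combined leaving rate delta*r*gamma0 + koff (per minute)."""
    return params.delta * guide.r * params.gamma0 + params.koff


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def _r_of(guide: "GuideSpec | float") -> float:
    return guide.r if isinstance(guide, GuideSpec) else float(guide)


def infer_lambda_r(gamma_star_obs: float, guide: "GuideSpec | float",
                   alpha: float = 0.0) -> float:
    """Invert the expression equation for the normalized kick-out rate.

    lambda*r = ((1 + alpha)*gamma*_obs - r - alpha) / (1 - gamma*_obs).
    Exact inverse of :func:`gamma_star` in its first argument.
    """
    r = _r_of(guide)
    _check(0.0 <= r <= 1.0, "r must be in [0, 1]")
    _check(alpha >= 0.0, "alpha must be >= 0")
    if gamma_star_obs >= 1.0:
        raise InconsistentInputsError(
            f"gamma_star_obs must be < 1 (got {gamma_star_obs}): lambda_r diverges")
    lam_r = ((1.0 + alpha) * gamma_star_obs - r - alpha) / (1.0 - gamma_star_obs)
    if -1e-9 < lam_r < 0.0:  # round-off at the exact saturated floor
        return 0.0
    if lam_r < 0.0:
        raise InconsistentInputsError(
            f"observed expression {gamma_star_obs} lies below the saturated floor "
            f"gamma*(lambda_r=0) = {(r + alpha) / (1 + alpha):.4g}")
    return lam_r


def predict_promoter(pair: PromoterPair, guide: "GuideSpec | float",
                     alpha: float = 0.0) -> float:
    """Predict the relative expression of the target promoter.

    Infers lambda*r from the reference measurement, scales lambda by the
    promoter-strength fold (r is promoter-independent), and evaluates the
    forward equation.  Monotonically increasing in ``strength_fold`` and
    decreasing in ``alpha``.
    """
    r = _r_of(guide)
    lam_r_ref = infer_lambda_r(pair.gamma_star_ref, r, alpha)
    return gamma_star(pair.strength_fold * lam_r_ref, alpha, r)


def alpha_crossing(pair: PromoterPair, guide: "GuideSpec | float",
                   gamma_star_bound: float, alpha_max: float = 10.0,
                   tol: float = 1e-8) -> float:
    """Find the alpha at which the cross-promoter prediction drops to a bound.

    The prediction is strictly decreasing in alpha, so bracketed
    root-finding on [0, alpha_max] finds the unique crossing.  The search is
    capped at the feasibility limit alpha_feas = (gamma*_ref - r)/(1 -
    gamma*_ref), above which the reference inference has no non-negative
    solution; as alpha approaches it the prediction tends to gamma*_ref
    itself.  Raises :class:`NoCrossingError` if the bound is never reached.
    """
    r = _r_of(guide)

    def f(a: float) -> float:
        return predict_promoter(pair, r, a) - gamma_star_bound

    f0 = f(0.0)
    if f0 < 0.0:
        raise NoCrossingError("prediction at alpha=0 is already below the bound")
    if abs(f0) <= tol:
        return 0.0
    alpha_feas = infer_lambda_r(pair.gamma_star_ref, r, 0.0)
    hi = min(alpha_max, alpha_feas * (1.0 - 1e-12))
    if f(hi) > 0.0:
        raise NoCrossingError(
            f"prediction stays above the bound on [0, {hi:.4g}] "
            "(bound is at or below the reference expression)")
    return float(brentq(f, 0.0, hi, xtol=tol))


# ---------------------------------------------------------------------------
# bounds and copy number
# ---------------------------------------------------------------------------


def koff_upper_bound(alpha_max: float, lambda_: float, gamma0: float = 1.0,
                     delta: float = 1.0) -> float:
    """Upper bound on the spontaneous unbinding rate (per minute).

    From koff <= alpha_max * kon*[dCas9] and lambda = delta*gamma0/(kon*[dCas9]):
    koff <= alpha_max * delta * gamma0 / lambda.  Pass ``gamma0=1`` to get
    the dimensionless coefficient multiplying gamma0.
    """
    _check(alpha_max >= 0.0, "alpha_max must be >= 0")
    if lambda_ <= 0.0:
        raise ValidationError("lambda_ must be > 0 to bound koff")
    return alpha_max * delta * gamma0 / lambda_


def lifetime_bound(copy_number: float, koff_bound: float) -> float:
    """Minimum lifetime (minutes) of a single roadblock-DNA complex, n/koff."""
    _check(copy_number > 0.0, "copy_number must be > 0")
    _check(koff_bound >= 0.0, "koff_bound must be >= 0")
    if koff_bound == 0.0:
        return math.inf
    return copy_number / koff_bound


def gene_copy_number(params: CopyNumberParams) -> float:
    """Average gene copies per cell, 2**((tC*(1-phi) + tD)/td).

    Cooper-Helmstetter form for exponentially growing bacteria with
    overlapping replication rounds.
    """
    return 2.0 ** ((params.tC * (1.0 - params.phi) + params.tD) / params.td)


# ---------------------------------------------------------------------------
# Monte-Carlo uncertainty propagation
# ---------------------------------------------------------------------------


def propagate_uncertainty(inputs: Mapping[str, UncertainValue],
                          function: Callable[..., float],
                          n_draws: int = 100_000,
                          seed: int = 0) -> UncertainValue:
    """Propagate independent Gaussian input uncertainties through a model op.

    Draws each input independently, evaluates ``function(**draws)``, and
    returns the sample mean and sd of the output.  Draws that violate the
    operation's preconditions (any :class:`ValidationError` subclass) are
    rejected and resampled; if more than half of all attempts are rejected
    the propagation is declared ill-posed.
    """
    _check(n_draws >= 1000, "n_draws must be >= 1000")
    names = list(inputs)
    for nm in names:
        _check(inputs[nm].sd >= 0.0, f"sd of input {nm!r} must be >= 0")
    rng = np.random.default_rng(seed)

    out = np.empty(n_draws)
    accepted = 0
    attempted = 0
    max_attempts = 4 * n_draws
    while accepted < n_draws:
        batch = min(n_draws - accepted, n_draws)
        draws = {nm: rng.normal(inputs[nm].mean, inputs[nm].sd, size=batch)
                 for nm in names}
        for i in range(batch):
            attempted += 1
            try:
                val = function(**{nm: float(draws[nm][i]) for nm in names})
            except KickoutError:
                val = None
            if val is not None and math.isfinite(val):
                out[accepted] = val
                accepted += 1
        if attempted >= max_attempts and accepted < n_draws:
            raise IllPosedPropagationError(
                f"rejected {attempted - accepted}/{attempted} draws; "
                "inputs are incompatible with the operation's domain")
        if attempted > 2 * accepted and attempted > n_draws:
            raise IllPosedPropagationError(
                f"more than 50% of draws rejected ({attempted - accepted}/{attempted})")
    return UncertainValue(mean=float(np.mean(out)), sd=float(np.std(out, ddof=1)))
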