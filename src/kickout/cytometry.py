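"""Single-cell fluorescence statistics: trimming, blank correction, noise,
normalization, log-scale significance tests and growth-curve fitting.

Input samples are flat per-cell value vectors (CSV exports; FCS parsing is
out of scope).  All statistics operate on replicate-level means where the
analysis is comparative, never on pooled cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NoGrowthError, NormalizationError, ValidationError
from .model import _check

__all__ = [
    "PopulationSample",
    "NoiseSummary",
    "TTestResult",
    "trim_outliers",
    "noise_cv",
    "relative_expression_table",
    "log_t_test",
    "doubling_time",
]


@dataclass(frozen=True)
class PopulationSample:
    """Per-cell fluorescence values for one sample/channel/replicate."""

    sample_id: str
    replicate: int
    channel: Literal["GFP", "RFP"]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        _check(vals.ndim == 1 and vals.size >= 2,
               "values must be a 1-D array with >= 2 entries")
        _check(bool(np.all(np.isfinite(vals))), "values must be finite")
        _check(self.channel in ("GFP", "RFP"), f"unknown channel {self.channel!r}")

    def mean(self) -> float:
        return float(np.mean(self.values))

    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))


@dataclass(frozen=True)
class NoiseSummary:
    """Blank-corrected noise decomposition of one sample."""

    mu: float
    sigma: float
    sigma_sample: float
    sigma_blank: float
    noise: float

    def __post_init__(self) -> None:
        _check(self.noise >= 0.0, "noise must be >= 0")
        _check(self.sigma_sample >= 0.0, "sigma_sample must be >= 0")


@dataclass(frozen=True)
class TTestResult:
    p_value: float
    threshold: float
    significant: bool


def trim_outliers(sample: PopulationSample) -> tuple[PopulationSample, int]:
    """Drop values more than three standard deviations from the sample mean.

    Single pass: the mean and sd are computed once on the full sample; the
    trimmed sample and the number of removed points are returned.
    """
    _check(sample.values.size >= 3, "need >= 3 values to trim")
    mu = sample.mean()
    sd = sample.sd()
    keep = np.abs(sample.values - mu) <= 3.0 * sd
    removed = int(np.sum(~keep))
    trimmed = PopulationSample(sample.sample_id, sample.replicate,
                               sample.channel, sample.values[keep])
    return trimmed, removed


def noise_cv(sample: PopulationSample, blank: PopulationSample,
             blank_subtraction: Literal["quadrature", "linear"] = "quadrature",
             ) -> NoiseSummary:
    """Blank-corrected expression noise sigma/mu of one sample.

    mu is the sample mean minus the blank (autofluorescence) mean.  By
    default the blank sd is removed in quadrature, sigma =
    sqrt(sd_sample^2 - sd_blank^2), since independent noise sources add in
    variance; ``blank_subtraction="linear"`` reproduces a plain sd
    difference instead.
    """
    s_samp = sample.sd()
    s_blank = blank.sd()
    if s_blank > s_samp:
        raise ValidationError(
            f"blank sd {s_blank:.4g} exceeds sample sd {s_samp:.4g}: "
            "corrected variance would be negative")
    mu = sample.mean() - blank.mean()
    if mu <= 0.0:
        raise NormalizationError(
            f"blank-corrected mean is not positive ({mu:.4g})")
    if blank_subtraction == "quadrature":
        sigma = math.sqrt(s_samp ** 2 - s_blank ** 2)
    elif blank_subtraction == "linear":
        sigma = s_samp - s_blank
    else:
        raise ValidationError(f"unknown blank_subtraction {blank_subtraction!r}")
    return NoiseSummary(mu=mu, sigma=sigma, sigma_sample=s_samp,
                        sigma_blank=s_blank, noise=sigma / mu)


def relative_expression_table(samples: Sequence[PopulationSample],
                              control_id: str, blank_id: str) -> pd.DataFrame:
    """Blank-corrected means normalized to the non-targeting control.

    relative_mean = (mean - blank mean) / (control mean - blank mean); the
    control row is exactly 1.  Invariant to any common multiplicative gain.
    """
    by_id = {s.sample_id: s for s in samples}
    if control_id not in by_id:
        raise NormalizationError(f"control sample {control_id!r} not found")
    if blank_id not in by_id:
        raise NormalizationError(f"blank sample {blank_id!r} not found")
    blank_mean = by_id[blank_id].mean()
    control_corr = by_id[control_id].mean() - blank_mean
    if control_corr <= 0.0:
        raise NormalizationError(
            "control mean is at or below the autofluorescence blank")
    rows = []
    for s in samples:
        corr = s.mean() - blank_mean
        rows.append({
            "sample_id": s.sample_id,
            "replicate": s.replicate,
            "channel": s.channel,
            "mean": s.mean(),
            "relative_mean": corr / control_corr,
            "n_cells": int(s.values.size),
        })
    return pd.DataFrame(rows)


def log_t_test(group_a: Sequence[float], group_b: Sequence[float],
               n_comparisons: int = 1) -> TTestResult:
    """Two-sided t-test on natural logs of replicate means, Bonferroni-corrected.

    The corrected per-comparison threshold is 0.05/n_comparisons; the
    significance flag is p < threshold.  Groups are replicate-level means
    (never pooled cells) and must be strictly positive.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    _check(a.size >= 2 and b.size >= 2, "need >= 2 replicates per group")
    _check(bool(np.all(a > 0)) and bool(np.all(b > 0)),
           "replicate means must be > 0 for a log-scale test")
    _check(n_comparisons >= 1, "n_comparisons must be >= 1")
    la, lb = np.log(a), np.log(b)
    if np.ptp(la) == 0.0 and np.ptp(lb) == 0.0 and la[0] == lb[0]:
        p = 1.0  # identical constant groups: no evidence of a difference
    else:
        p = float(stats.ttest_ind(la, lb).pvalue)
    threshold = 0.05 / n_comparisons
    return TTestResult(p_value=p, threshold=threshold, significant=p < threshold)


def doubling_time(times: Sequence[float], od: Sequence[float],
                  window: slice | None = None) -> float:
    """Doubling time (minutes) from an exponential fit to growth-curve data.

    Linear regression of ln(OD) versus time over the user-selected window
    (default: all points); returns ln2/slope.  A non-positive slope raises
    :class:`NoGrowthError`.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    _check(t.size == y.size, "times and od must have equal length")
    if window is not None:
        t, y = t[window], y[window]
    _check(t.size >= 3, "need >= 3 points in the fitting window")
    _check(bool(np.all(y > 0)), "od values must be > 0")
    slope = float(stats.linregress(t, np.log(y)).slope)
    if slope <= 0.0:
        raise NoGrowthError(f"fitted growth rate is not positive ({slope:.3g}/min)")
    return math.log(2.0) / slope
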