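"""Seeded generators emulating single-cell measurement data.

Fluorescence is modeled as level x lognormal(extrinsic) x
lognormal(intrinsic) + Gaussian autofluorescence (truncated at zero):
positive, right-skewed, with CV-parameterized noise.  Two-color samples
share a configurable fraction of the extrinsic log-variance between
channels.  All generators draw from fixed sub-streams of the master seed
(counter-based), so adding samples never perturbs earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .cytometry import PopulationSample
from .feedback import FeedbackDataset, FeedbackParams, steady_state
from .model import _check
from .shape import CellContour
from .simulate import (
    SimulationConfig,
    active_dcas9_fraction,
    atc_induction,
    simulate_population,
)

__all__ = [
    "GeneratorConfig",
    "gen_population",
    "gen_blank",
    "gen_two_color",
    "gen_titration",
    "gen_feedback_dataset",
    "gen_capsule_contour",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the fluorescence-population generators."""

    true_relative_levels: tuple[float, ...] = (1.0,)
    extrinsic_cv: float = 0.25
    intrinsic_cv: float = 0.15
    autofluorescence_mean: float = 0.0
    autofluorescence_sd: float = 0.0
    two_color_shared_fraction: float = 1.0
    n_cells: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        _check(all(lv >= 0.0 for lv in self.true_relative_levels),
               "levels must be >= 0")
        _check(self.extrinsic_cv >= 0.0, "extrinsic_cv must be >= 0")
        _check(self.intrinsic_cv >= 0.0, "intrinsic_cv must be >= 0")
        _check(self.autofluorescence_sd >= 0.0, "autofluorescence_sd must be >= 0")
        _check(0.0 <= self.two_color_shared_fraction <= 1.0,
               "two_color_shared_fraction must be in [0, 1]")
        _check(self.n_cells >= 1, "n_cells must be >= 1")


def _ln_factor(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0.0:
        return np.ones(n)
    s2 = math.log(1.0 + cv * cv)
    return rng.lognormal(-s2 / 2.0, math.sqrt(s2), size=n)


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def gen_population(config: GeneratorConfig,
                   channel: str = "GFP") -> list[PopulationSample]:
    """One sample per entry of ``true_relative_levels``.

    value = level * LN(extrinsic) * LN(intrinsic) + N(af_mean, af_sd),
    truncated at 0.  Sample ids are ``level_<index>``.
    """
    samples = []
    for idx, level in enumerate(config.true_relative_levels):
        rng = _stream(config.seed, 10, idx)
        vals = (level
                * _ln_factor(rng, config.extrinsic_cv, config.n_cells)
                * _ln_factor(rng, config.intrinsic_cv, config.n_cells)
                + rng.normal(config.autofluorescence_mean,
                             config.autofluorescence_sd, config.n_cells))
        samples.append(PopulationSample(f"level_{idx}", 1, channel,
                                        np.clip(vals, 0.0, None)))
    return samples


def gen_blank(config: GeneratorConfig, channel: str = "GFP") -> PopulationSample:
    """A no-reporter (autofluorescence-only) sample matching the config."""
    rng = _stream(config.seed, 11)
    vals = rng.normal(config.autofluorescence_mean, config.autofluorescence_sd,
                      config.n_cells)
    return PopulationSample("blank", 1, channel, np.clip(vals, 0.0, None))


def gen_two_color(config: GeneratorConfig, level_gfp: float,
                  level_rfp: float) -> tuple[PopulationSample, PopulationSample]:
    """Paired GFP/RFP samples sharing a fraction of extrinsic log-variance.

    The extrinsic log-variance splits into a shared component (fraction
    ``two_color_shared_fraction``) applied to both channels and independent
    remainders; intrinsic factors are always channel-specific.
    """
    n = config.n_cells
    s2_ext = math.log(1.0 + config.extrinsic_cv ** 2)
    f = config.two_color_shared_fraction
    rng = _stream(config.seed, 20)
    shared = rng.normal(0.0, 1.0, n) * math.sqrt(f * s2_ext)
    own_g = rng.normal(0.0, 1.0, n) * math.sqrt((1.0 - f) * s2_ext)
    own_r = rng.normal(0.0, 1.0, n) * math.sqrt((1.0 - f) * s2_ext)
    ext_g = np.exp(shared + own_g - s2_ext / 2.0)
    ext_r = np.exp(shared + own_r - s2_ext / 2.0)
    int_g = _ln_factor(rng, config.intrinsic_cv, n)
    int_r = _ln_factor(rng, config.intrinsic_cv, n)
    af = lambda: rng.normal(config.autofluorescence_mean,
                            config.autofluorescence_sd, n)
    gfp = np.clip(level_gfp * ext_g * int_g + af(), 0.0, None)
    rfp = np.clip(level_rfp * ext_r * int_r + af(), 0.0, None)
    return (PopulationSample("pair", 1, "GFP", gfp),
            PopulationSample("pair", 1, "RFP", rfp))


def gen_titration(atc_series: Sequence[float], sim_config: SimulationConfig,
                  n_decoys: int = 0, vmax: float = 1.0, km: float = 10.0,
                  hill: float = 2.0, basal: float = 0.0) -> list[dict]:
    """Simulated dose-response scan over inducer concentrations.

    For each aTc value the mean active-complex level is the Hill dose
    response diluted by the decoy fraction; a population is simulated at
    that level.  Returns one dict per point with the aTc value, the
    active-complex multiplier and the population summary.

    Note the multiplier rescales the configured ``rebinding_rate``, which
    should be set to the value reached at full induction with no decoys.
    """
    out = []
    frac = active_dcas9_fraction(n_decoys)
    for i, atc in enumerate(atc_series):
        level = atc_induction(atc, vmax=vmax, km=km, hill=hill, basal=basal) * frac
        cfg = replace(sim_config,
                      kinetics=replace(sim_config.kinetics,
                                       rebinding_rate=sim_config.kinetics.rebinding_rate * level),
                      tuning_mode="concentration",
                      seed=sim_config.seed + i)
        if level == 0.0:
            cfg = replace(cfg, kinetics=replace(sim_config.kinetics, rebinding_rate=0.0))
        summary, _ = simulate_population(cfg)
        out.append({"atc": float(atc), "active_level": float(level),
                    "n_decoys": n_decoys, "summary": summary})
    return out


def gen_feedback_dataset(params: FeedbackParams, r_values: Sequence[float],
                         noise_cv: float = 0.05, n_replicates: int = 3,
                         seed: int = 0, condition: str = "") -> FeedbackDataset:
    """Synthetic auto-repressor measurements around the model steady state.

    g_obs = steady_state(r) * LN(noise_cv) per replicate; g_sd records the
    generative CV times the true value.
    """
    _check(noise_cv >= 0.0, "noise_cv must be >= 0")
    _check(n_replicates >= 1, "n_replicates must be >= 1")
    rng = _stream(seed, 30)
    pts = []
    for r in r_values:
        g_true = steady_state(float(r), params)
        noise = _ln_factor(rng, noise_cv, n_replicates)
        for rep in range(n_replicates):
            pts.append((float(r), float(g_true * noise[rep]),
                        float(noise_cv * g_true)))
    return FeedbackDataset(points=tuple(pts), condition=condition)


def gen_capsule_contour(radius: float, length: float, orientation: float = 0.0,
                        center: tuple[float, float] = (0.0, 0.0),
                        vertex_noise_sd: float = 0.0, n_vertices: int = 100,
                        seed: int = 0, cell_id: str = "capsule") -> CellContour:
    """Closed polygon sampling a spherocylinder (capsule) outline.

    Two semicircular caps of the given radius joined by straight sides, with
    total tip-to-tip ``length``, rotated by ``orientation`` degrees,
    translated to ``center``, with optional Gaussian vertex jitter.
    Vertices are equally spaced in arc length.
    """
    _check(radius > 0.0, "radius must be > 0")
    _check(length >= 2.0 * radius, "length must be >= 2*radius")
    _check(n_vertices >= 20, "need >= 20 vertices")
    half = (length - 2.0 * radius) / 2.0  # cylinder half-length
    side = 2.0 * half
    cap = math.pi * radius
    perimeter = 2.0 * side + 2.0 * cap
    arc = (np.arange(n_vertices) + 0.5) / n_vertices * perimeter
    pts = np.empty((n_vertices, 2))
    for i, a in enumerate(arc):
        if a < side:  # top side, left to right
            pts[i] = (-half + a, radius)
        elif a < side + cap:  # right cap
            th = math.pi / 2.0 - (a - side) / radius
            pts[i] = (half + radius * math.cos(th), radius * math.sin(th))
        elif a < 2.0 * side + cap:  # bottom side, right to left
            pts[i] = (half - (a - side - cap), -radius)
        else:  # left cap
            th = -math.pi / 2.0 - (a - 2.0 * side - cap) / radius
            pts[i] = (-half + radius * math.cos(th), radius * math.sin(th))
    if vertex_noise_sd > 0.0:
        rng = _stream(seed, 40)
        pts = pts + rng.normal(0.0, vertex_noise_sd, pts.shape)
    th = math.radians(orientation)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    pts = pts @ rot.T + np.asarray(center, dtype=float)
    return CellContour(cell_id=cell_id, vertices=pts, closed=True)
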