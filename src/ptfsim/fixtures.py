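"""Parametric stand-ins for the experimental input distributions.

The colony model consumes two empirical distributions: initial OCT4 levels
and cell-cycle durations.  When only summary statistics are available —
cycle durations with mean 10.3 h, SD 4 h on the range 0.25-30 h, and an
initial OCT4 level with median about 1290 a.f.u. — this module builds
positive-support, right-skewed parametric samplers matched to those
anchors:

* cell cycles: a Gamma distribution truncated to the observed range, with
  shape and scale solved numerically so the *post-truncation* mean and SD
  hit the targets;
* initial OCT4: a lognormal with the stated median and coefficient of
  variation (CV; the CV is not anchored by any published summary and
  defaults to 0.25 — swap in real data via :func:`load_empirical` where
  available).

These are synthetic stand-ins for kernel-density fits to real data, not
reconstructions of the experimental curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .colony import KDESampler, ParametricSampler, Sampler, kde_sampler

__all__ = [
    "FixtureConfig",
    "make_cycle_sampler",
    "make_initial_oct4_sampler",
    "load_empirical",
]


@dataclass(frozen=True)
class FixtureConfig:
    """Summary anchors for the parametric input samplers.

    cycle_mean, cycle_sd : hours
        Post-truncation mean and SD of cell-cycle durations.
    cycle_range : (hours, hours)
        Hard support of cycle durations.
    oct4_init_median : a.f.u.
        Median initial OCT4 level.
    oct4_init_cv : dimensionless
        Coefficient of variation of initial OCT4 (unanchored; default 0.25).
    """

    cycle_mean: float = 10.3
    cycle_sd: float = 4.0
    cycle_range: tuple[float, float] = (0.25, 30.0)
    oct4_init_median: float = 1290.0
    oct4_init_cv: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.cycle_range
        if not (0 < low < high):
            raise ValueError("cycle_range must satisfy 0 < low < high")
        if not (low <= self.cycle_mean <= high):
            raise ValueError("cycle_mean must lie inside cycle_range")
        if self.cycle_sd < 0:
            raise ValueError("cycle_sd must be >= 0")
        if self.oct4_init_median <= 0:
            raise ValueError("oct4_init_median must be positive")
        if self.oct4_init_cv < 0:
            raise ValueError("oct4_init_cv must be >= 0")

    def to_dict(self) -> dict:
        return {
            "cycle_mean": self.cycle_mean,
            "cycle_sd": self.cycle_sd,
            "cycle_range": list(self.cycle_range),
            "oct4_init_median": self.oct4_init_median,
            "oct4_init_cv": self.oct4_init_cv,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FixtureConfig":
        d = dict(d)
        if "cycle_range" in d:
            d["cycle_range"] = tuple(d["cycle_range"])
        return cls(**d)


def _truncated_gamma_moments(
    shape: float, scale: float, low: float, high: float
) -> tuple[float, float]:
    """Mean and SD of a Gamma(shape, scale) truncated to [low, high].

    Uses the identity E[X^k | low < X < high] =
    scale^k * Gamma(shape+k)/Gamma(shape) * (P(shape+k, high/scale) -
    P(shape+k, low/scale)) / (P(shape, high/scale) - P(shape, low/scale)),
    with P the regularised lower incomplete gamma function.
    """
    a, b = low / scale, high / scale
    z = special.gammainc(shape, b) - special.gammainc(shape, a)
    if z <= 0:
        return math.nan, math.nan

    def raw_moment(k: int) -> float:
        ratio = math.exp(special.gammaln(shape + k) - special.gammaln(shape))
        mass = special.gammainc(shape + k, b) - special.gammainc(shape + k, a)
        return scale**k * ratio * mass / z

    m1 = raw_moment(1)
    m2 = raw_moment(2)
    var = max(m2 - m1 * m1, 0.0)
    return m1, math.sqrt(var)


def make_cycle_sampler(cfg: FixtureConfig) -> Sampler:
    """Truncated-Gamma sampler for cell-cycle durations.

    Shape and scale are solved at construction so the post-truncation mean
    and SD match ``(cfg.cycle_mean, cfg.cycle_sd)``; the support is exactly
    ``cfg.cycle_range``.  A (near-)zero cycle_sd degenerates to a
    point-mass at the mean.  Raises if the moment targets are infeasible on
    the given support.
    """
    low, high = cfg.cycle_range
    if cfg.cycle_sd < 1e-9:
        frozen = stats.uniform(loc=cfg.cycle_mean - 5e-10, scale=1e-9)
        return ParametricSampler(frozen, cfg.cycle_range, cfg.seed)

    def residuals(log_params: np.ndarray) -> np.ndarray:
        shape, scale = np.exp(log_params)
        m, s = _truncated_gamma_moments(shape, scale, low, high)
        if not (math.isfinite(m) and math.isfinite(s)):
            return np.array([1e6, 1e6])
        return np.array([m - cfg.cycle_mean, s - cfg.cycle_sd])

    # Untruncated-moment initial guess.
    shape0 = (cfg.cycle_mean / cfg.cycle_sd) ** 2
    scale0 = cfg.cycle_sd**2 / cfg.cycle_mean
    sol = optimize.least_squares(
        residuals, np.log([shape0, scale0]), xtol=1e-14, ftol=1e-14
    )
    shape, scale = np.exp(sol.x)
    m, s = _truncated_gamma_moments(shape, scale, low, high)
    if abs(m - cfg.cycle_mean) > 0.02 * cfg.cycle_mean or abs(
        s - cfg.cycle_sd
    ) > 0.02 * cfg.cycle_sd:
        raise ValueError(
            "cycle-duration moment targets are infeasible on the support "
            f"{cfg.cycle_range}: achieved mean {m:.3f} h, SD {s:.3f} h"
        )
    return ParametricSampler(stats.gamma(shape, scale=scale), cfg.cycle_range, cfg.seed)


def make_initial_oct4_sampler(cfg: FixtureConfig) -> Sampler:
    """Lognormal sampler for initial OCT4 levels.

    Parameterised by median and CV: sigma^2 = ln(1 + CV^2) and the scale is
    the median itself (the lognormal median is exp(mu)).  Support (0, inf);
    a zero CV degenerates to a point-mass at the median.
    """
    if cfg.oct4_init_cv < 1e-12:
        frozen = stats.uniform(loc=cfg.oct4_init_median - 5e-10, scale=1e-9)
        return ParametricSampler(frozen, (0.0, np.inf), cfg.seed + 1)
    sigma = math.sqrt(math.log1p(cfg.oct4_init_cv**2))
    frozen = stats.lognorm(s=sigma, scale=cfg.oct4_init_median)
    return ParametricSampler(frozen, (0.0, np.inf), cfg.seed + 1)


def load_empirical(
    path, support: tuple[float, float], seed: int = 0
) -> KDESampler:
    """Build a KDE sampler from a plain-text column of values.

    The file holds one positive real per line (blank lines ignored);
    unparseable lines are reported with their line numbers.
    """
    values = []
    bad: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                bad.append(lineno)
    if bad:
        shown = ", ".join(map(str, bad[:10]))
        raise ValueError(f"unparseable lines in {path}: {shown}")
    if not values:
        raise ValueError(f"{path} contains no values")
    return kde_sampler(values, support, seed)
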