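"""Summary statistics and feature diagnostics for colony trajectories.

Reproduces the quantitative checks used to characterise OCT4 dynamics:

* the pooled one-frame increment SD (the sigma that calibrates the noise
  scale of the fBm walk and additive SLE);
* the carrying-capacity estimate as the in-window median expression;
* time-binned OCT4 histograms per fate with per-bin cell counts and sample
  skewness (the positive-skew and mode-shift diagnostics);
* two-sample Kolmogorov-Smirnov comparisons at the 95% level;
* per-frame central tracks (mean / median / KDE-mode) per fate;
* the ensemble of per-cell Hurst-exponent estimates.

Everything operates on :class:`~ptfsim.colony.ColonyTrajectory`, whether
simulated or read back from CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .colony import ColonyTrajectory
from .dynamics import FRAMES_PER_HOUR
from .fbm import MIN_SERIES_FRAMES, estimate_hurst

__all__ = [
    "SummaryBundle",
    "increment_sd",
    "estimate_K",
    "binned_distributions",
    "ks_two_sample",
    "central_tracks",
    "hurst_ensemble",
    "summarise",
]


def increment_sd(traj: ColonyTrajectory, t_max: float | None = None) -> float:
    """SD of within-cell one-frame OCT4 increments, pooled over all cells.

    Mother-to-daughter joins never contribute: increments are taken inside
    each cell's own series, and a daughter's first value equals its
    mother's last by construction, so including joins would only pad the
    sample with zeros and bias sigma downwards.
    """
    diffs = []
    for c in traj.cells:
        s = c.series
        if s is None or len(s) < 2:
            continue
        if t_max is not None:
            n_keep = int(np.floor(t_max * FRAMES_PER_HOUR + 1e-9)) - c.birth_frame
            if n_keep < 1:
                continue
            s = s[: n_keep + 1]
            if len(s) < 2:
                continue
        diffs.append(np.diff(s))
    if not diffs:
        raise ValueError("no series with at least two frames in the window")
    pooled = np.concatenate(diffs)
    if pooled.size < 2:
        raise ValueError("need at least two increments to estimate sigma")
    return float(np.std(pooled, ddof=1))


def _window_values(
    traj: ColonyTrajectory, window: tuple[float, float], fate: str | None
) -> np.ndarray:
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window must satisfy t0 < t1")
    chunks = []
    for c in traj.cells:
        if c.series is None or (fate is not None and c.fate != fate):
            continue
        t = c.times()
        mask = (t >= t0) & (t <= t1)
        if np.any(mask):
            chunks.append(c.series[mask])
    if not chunks:
        return np.empty(0)
    return np.concatenate(chunks)


def estimate_K(
    traj: ColonyTrajectory,
    window: tuple[float, float],
    fate: str | None = None,
) -> float:
    """Carrying-capacity estimate: the median OCT4 value in the window.

    With even counts this is the midpoint convention (numpy median).
    """
    values = _window_values(traj, window, fate)
    if values.size == 0:
        raise ValueError(f"no OCT4 values in window {window}")
    return float(np.median(values))


def _kde_mode(values: np.ndarray, n_grid: int = 512) -> float:
    """Argmax of a Gaussian KDE (Silverman bandwidth) over the values."""
    if values.size == 1 or np.ptp(values) == 0:
        return float(values[0])
    kde = stats.gaussian_kde(values, bw_method="silverman")
    lo, hi = float(values.min()), float(values.max())
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, n_grid)
    return float(grid[np.argmax(kde(grid))])


def binned_distributions(
    traj: ColonyTrajectory,
    bin_edges: Sequence[float] | None = None,
    n_histogram_bins: int = 30,
) -> pd.DataFrame:
    """Per-fate, per-time-bin OCT4 histograms with counts and skewness.

    ``bin_edges`` are hours (default: the [0, 43] h analysis window split
    into four equal bins).  The returned tidy frame has one row per
    histogram bar with columns ``fate, bin_start_h, bin_end_h,
    oct4_bin_mid, density, N, skewness, mode``; densities within one
    (fate, time-bin) group sum to 1, N counts the distinct cells
    contributing to that time bin.
    """
    if bin_edges is None:
        bin_edges = np.linspace(0.0, 43.0, 5)
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be a strictly increasing 1-D sequence")

    rows = []
    fates = sorted({c.fate for c in traj.cells})
    for fate in fates:
        for t0, t1 in zip(edges[:-1], edges[1:]):
            values, n_cells = [], 0
            for c in traj.cells:
                if c.fate != fate or c.series is None:
                    continue
                t = c.times()
                mask = (t >= t0) & (t < t1)
                if np.any(mask):
                    values.append(c.series[mask])
                    n_cells += 1
            if not values:
                continue
            pooled = np.concatenate(values)
            hist, oct4_edges = np.histogram(pooled, bins=n_histogram_bins)
            density = hist / hist.sum()
            mids = 0.5 * (oct4_edges[:-1] + oct4_edges[1:])
            skew = float(stats.skew(pooled)) if pooled.size > 2 else np.nan
            mode = _kde_mode(pooled)
            for mid, dens in zip(mids, density):
                rows.append(
                    {
                        "fate": fate,
                        "bin_start_h": float(t0),
                        "bin_end_h": float(t1),
                        "oct4_bin_mid": float(mid),
                        "density": float(dens),
                        "N": int(n_cells),
                        "skewness": skew,
                        "mode": mode,
                    }
                )
    return pd.DataFrame(rows)


def ks_two_sample(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float, bool]:
    """Two-sample Kolmogorov-Smirnov test at the 95% level.

    Returns ``(statistic, p_value, reject)`` with reject true iff
    p < 0.05; the statistic is sup |F_a - F_b| over the pooled support.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < 0.05)


def central_tracks(
    traj: ColonyTrajectory, statistic: str = "mean"
) -> pd.DataFrame:
    """Per-fate, per-frame central OCT4 track.

    ``statistic`` is one of mean / median / mode (mode = argmax of a
    Gaussian KDE with Silverman bandwidth over that frame's values).
    Frames where a fate has no live cells are simply absent from its
    track — missing, not zero.  Columns: ``fate, t_hours, value, n_cells``.
    """
    if statistic not in ("mean", "median", "mode"):
        raise ValueError("statistic must be 'mean', 'median' or 'mode'")
    per_frame: dict[tuple[str, int], list[float]] = {}
    for c in traj.cells:
        if c.series is None:
            continue
        for k, v in enumerate(c.series):
            per_frame.setdefault((c.fate, c.birth_frame + k), []).append(float(v))
    rows = []
    for (fate, frame), values in sorted(per_frame.items()):
        arr = np.asarray(values)
        if statistic == "mean":
            value = float(arr.mean())
        elif statistic == "median":
            value = float(np.median(arr))
        else:
            value = _kde_mode(arr)
        rows.append(
            {
                "fate": fate,
                "t_hours": frame / FRAMES_PER_HOUR,
                "value": value,
                "n_cells": int(arr.size),
            }
        )
    if not rows:
        raise ValueError("trajectory contains no simulated series")
    return pd.DataFrame(rows)


def hurst_ensemble(
    traj: ColonyTrajectory, method: str = "DFA"
) -> tuple[float, float, int]:
    """Ensemble mean and SD of per-cell Hurst estimates.

    Applies :func:`~ptfsim.fbm.estimate_hurst` to every cell with more
    than 50 frames; returns ``(mean, sd, n_ineligible)`` where the last
    entry counts the cells skipped by the inclusion rule (or for being
    constant).
    """
    estimates = []
    ineligible = 0
    for c in traj.cells:
        if c.series is None or len(c.series) <= MIN_SERIES_FRAMES:
            ineligible += 1
            continue
        try:
            estimates.append(estimate_hurst(c.series, method=method).value)
        except ValueError:
            ineligible += 1
    if not estimates:
        raise ValueError(
            "no cell has the >50 frames required for Hurst estimation"
        )
    arr = np.asarray(estimates)
    return float(arr.mean()), float(arr.std(ddof=0)), ineligible


@dataclass
class SummaryBundle:
    """Bundle of trajectory summaries, serialisable to JSON and tidy CSV."""

    hurst_mean_sd: tuple[float, float] | None
    sigma_hat: float
    K_hat: float
    histograms: pd.DataFrame
    tracks: pd.DataFrame
    fate_fractions: dict[str, float]
    n_cells: int = 0

    def to_json(self, path=None) -> str:
        payload = {
            "hurst_mean": None if self.hurst_mean_sd is None else self.hurst_mean_sd[0],
            "hurst_sd": None if self.hurst_mean_sd is None else self.hurst_mean_sd[1],
            "sigma_hat_afu": self.sigma_hat,
            "K_hat_afu": self.K_hat,
            "fate_fractions": self.fate_fractions,
            "n_cells": self.n_cells,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def summarise(
    traj: ColonyTrajectory,
    bin_edges: Sequence[float] | None = None,
    K_window: tuple[float, float] | None = None,
    hurst_method: str = "DFA",
) -> SummaryBundle:
    """Compute the full summary bundle for a trajectory."""
    t_end = traj.max_frame() / FRAMES_PER_HOUR
    if K_window is None:
        K_window = (0.0, min(25.0, t_end) if t_end > 0 else t_end or 1.0)
    try:
        h_mean, h_sd, _ = hurst_ensemble(traj, method=hurst_method)
        hurst_mean_sd = (h_mean, h_sd)
    except ValueError:
        hurst_mean_sd = None
    leaves = traj.leaves()
    counts = {fate: 0 for fate in ("pluripotent", "differentiated")}
    for c in leaves:
        if c.fate in counts:
            counts[c.fate] += 1
    total = sum(counts.values())
    fractions = {
        fate: (n / total if total else float("nan")) for fate, n in counts.items()
    }
    return SummaryBundle(
        hurst_mean_sd=hurst_mean_sd,
        sigma_hat=increment_sd(traj),
        K_hat=estimate_K(traj, K_window),
        histograms=binned_distributions(traj, bin_edges=bin_edges),
        tracks=central_tracks(traj, "mean"),
        fate_fractions=fractions,
        n_cells=len(traj.cells),
    )
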