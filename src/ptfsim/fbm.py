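"""Exact fractional Gaussian noise and Hurst-exponent estimation.

Fractional Brownian motion (fBm) generalises Brownian motion to correlated
increments controlled by the Hurst exponent H in (0, 1): H < 0.5 gives
anti-persistent increments (an increase is more likely followed by a
decrease), H = 0.5 recovers ordinary Brownian motion, H > 0.5 gives
persistent, long-memory increments.  OCT4 traces in growing hPSC colonies
are anti-persistent with H around 0.38, so all stochastic drivers in this
package are fGn streams.

Generation uses circulant embedding (Davies-Harte), which is exact in law
for every H in (0, 1): the fGn autocovariance sequence is embedded into a
circulant matrix whose eigenvalues are obtained by FFT, and a complex
Gaussian vector coloured by the eigenvalue square roots yields a sample
whose covariance is exactly the target.

Estimation offers rescaled-range (R/S) analysis and detrended fluctuation
analysis (DFA, the default: less biased on short anti-persistent series).
Both estimators take the *level* series (an OCT4 trace or fBm path) and
difference it once internally to obtain the stationary increments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "NoisePack",
    "HurstEstimate",
    "fgn_autocovariance",
    "generate_fgn",
    "fbm_path",
    "estimate_hurst",
    "MIN_SERIES_FRAMES",
]

#: Per-cell inclusion rule: Hurst estimates are only attempted on series
#: with more than this many frames.
MIN_SERIES_FRAMES = 50


@dataclass(frozen=True)
class NoisePack:
    """A pre-generated stream of unit-variance fractional Gaussian noise.

    Packs are cheap to regenerate: the triple ``(hurst, length, seed)``
    reproduces the identical sequence bit-for-bit, so packs are never
    serialised.
    """

    increments: np.ndarray
    hurst: float
    seed: int
    length: int = field(init=False)

    def __post_init__(self) -> None:
        inc = np.asarray(self.increments, dtype=float)
        if inc.ndim != 1 or inc.size < 1:
            raise ValueError("increments must be a non-empty 1-D array")
        object.__setattr__(self, "increments", inc)
        object.__setattr__(self, "length", int(inc.size))
        _check_hurst(self.hurst)


@dataclass(frozen=True)
class HurstEstimate:
    """A single Hurst-exponent estimate and how it was obtained."""

    value: float
    method: Literal["RS", "DFA"]
    series_length: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("Hurst estimate is not finite")
        if self.series_length <= MIN_SERIES_FRAMES:
            raise ValueError(
                f"series of {self.series_length} frames is below the "
                f">{MIN_SERIES_FRAMES}-frame inclusion rule"
            )


def _check_hurst(hurst: float) -> None:
    if not (0.0 < hurst < 1.0):
        raise ValueError(f"Hurst exponent must lie in (0, 1), got {hurst}")


def fgn_autocovariance(lag: int | np.ndarray, hurst: float) -> float | np.ndarray:
    """Autocovariance gamma(k) of unit-variance fGn at integer lag k.

    gamma(k) = 0.5 * (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}).

    This closed form is the reference against which the generator is
    validated; gamma(0) = 1 and, for H = 0.5, gamma(k) = 0 for k >= 1.
    """
    _check_hurst(hurst)
    k = np.asarray(lag, dtype=float)
    if np.any(k < 0):
        raise ValueError("lag must be non-negative")
    two_h = 2.0 * hurst
    gamma = 0.5 * (
        np.abs(k + 1.0) ** two_h - 2.0 * np.abs(k) ** two_h + np.abs(k - 1.0) ** two_h
    )
    if np.isscalar(lag) or np.ndim(lag) == 0:
        return float(gamma)
    return gamma


def generate_fgn(length: int, hurst: float, seed: int) -> NoisePack:
    """Generate exact unit-variance fGn by circulant embedding.

    The covariance of the returned sample equals :func:`fgn_autocovariance`
    exactly (in law), for every H in (0, 1).  The same ``(length, hurst,
    seed)`` triple always returns the identical sequence.

    Raises
    ------
    ValueError
        If length < 1 or H outside (0, 1); RuntimeError if the circulant
        eigenvalues come out negative beyond round-off (cannot happen for
        valid fGn autocovariances, so it is raised, never clipped silently).
    """
    _check_hurst(hurst)
    length = int(length)
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.Generator(np.random.PCG64(seed))
    if length == 1:
        return NoisePack(rng.standard_normal(1), hurst, seed)

    n = length
    m = 2 * n
    # First row of the circulant embedding of the n x n Toeplitz covariance.
    gamma = fgn_autocovariance(np.arange(n), hurst)
    row = np.concatenate([gamma, [0.0], gamma[-1:0:-1]])
    eigenvalues = np.fft.rfft(row).real
    tol = 1e-9 * float(np.max(np.abs(eigenvalues)))
    if np.min(eigenvalues) < -tol:
        raise RuntimeError(
            "circulant embedding produced negative eigenvalues "
            f"(min {np.min(eigenvalues):.3e}); refusing to clip"
        )
    eigenvalues = np.clip(eigenvalues, 0.0, None)  # round-off only, by tol check

    # Colour a complex Gaussian vector; rfft layout has m//2 + 1 bins with
    # real-valued DC and Nyquist components.
    n_bins = eigenvalues.size
    real = rng.standard_normal(n_bins)
    imag = rng.standard_normal(n_bins)
    imag[0] = 0.0
    imag[-1] = 0.0
    real[0] *= np.sqrt(2.0)
    real[-1] *= np.sqrt(2.0)
    spectrum = (real + 1j * imag) * np.sqrt(eigenvalues / (2.0 * m))
    sample = np.fft.irfft(spectrum, n=m) * m
    return NoisePack(sample[:n].copy(), hurst, seed)


def fbm_path(pack: NoisePack, start: float, scale: float) -> np.ndarray:
    """Integrate an fGn pack into an fBm path.

    path[0] = start and path[t] = start + scale * sum of the first t
    increments, so the path has ``pack.length + 1`` points and one-step
    differences with standard deviation ``scale``.
    """
    if scale < 0:
        raise ValueError("scale must be non-negative")
    path = np.empty(pack.length + 1)
    path[0] = start
    np.cumsum(pack.increments, out=path[1:])
    path[1:] *= scale
    path[1:] += start
    return path


def _dfa_fluctuation(profile: np.ndarray, window: int) -> float:
    """RMS of linearly detrended profile over non-overlapping windows,
    taken forward and backward so trailing points are not discarded."""
    n = profile.size
    k = n // window
    x = np.arange(window, dtype=float)
    x -= x.mean()
    denom = float(np.sum(x * x))
    out = 0.0
    count = 0
    for segs in (
        profile[: k * window].reshape(k, window),
        profile[n - k * window:].reshape(k, window),
    ):
        means = segs.mean(axis=1, keepdims=True)
        slopes = (segs @ x)[:, None] / denom
        resid = segs - means - slopes * x
        out += float(np.sum(resid * resid))
        count += segs.size
    return np.sqrt(out / count)


def _window_sizes(n: int, smallest: int, largest: int, n_scales: int = 16) -> np.ndarray:
    sizes = np.unique(
        np.floor(np.geomspace(smallest, largest, n_scales)).astype(int)
    )
    return sizes[sizes >= smallest]


def _estimate_dfa(increments: np.ndarray) -> float:
    profile = np.cumsum(increments - increments.mean())
    n = profile.size
    windows = _window_sizes(n, smallest=6, largest=max(8, n // 4))
    if windows.size < 4:
        raise ValueError("series too short for DFA window range")
    fluct = np.array([_dfa_fluctuation(profile, int(w)) for w in windows])
    if np.any(fluct <= 0):
        raise ValueError("degenerate (constant) series: DFA fluctuation is zero")
    slope = np.polyfit(np.log(windows), np.log(fluct), 1)[0]
    return float(slope)


def _estimate_rs(increments: np.ndarray) -> float:
    n = increments.size
    windows = _window_sizes(n, smallest=8, largest=n)
    if windows.size < 4:
        raise ValueError("series too short for R/S window range")
    log_w, log_rs = [], []
    for w in windows:
        k = n // int(w)
        segs = increments[: k * int(w)].reshape(k, int(w))
        dev = np.cumsum(segs - segs.mean(axis=1, keepdims=True), axis=1)
        rng_ = dev.max(axis=1) - dev.min(axis=1)
        sd = segs.std(axis=1, ddof=0)
        ok = sd > 0
        if not np.any(ok):
            continue
        rs = np.mean(rng_[ok] / sd[ok])
        if rs > 0:
            log_w.append(np.log(w))
            log_rs.append(np.log(rs))
    if len(log_w) < 4:
        raise ValueError("degenerate series: R/S statistic undefined")
    return float(np.polyfit(log_w, log_rs, 1)[0])


def estimate_hurst(
    series: Sequence[float] | np.ndarray, method: Literal["RS", "DFA"] = "DFA"
) -> HurstEstimate:
    """Estimate the Hurst exponent of a measured level series.

    The input is the time series of levels (an OCT4 trace or an fBm path);
    it is differenced once internally and the estimator is applied to the
    increments, so an fBm path with Hurst exponent H yields an estimate
    near H.  Series of 50 frames or fewer are rejected, matching the
    per-cell inclusion rule used for experimental traces.

    DFA (default) computes the RMS of the linearly detrended increment
    profile over log-spaced window sizes and reads H off the log-log
    slope; R/S uses the classical rescaled-range statistic.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if x.size <= MIN_SERIES_FRAMES:
        raise ValueError(
            f"series has {x.size} frames; estimation requires more than "
            f"{MIN_SERIES_FRAMES} frames (per-cell inclusion rule)"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    increments = np.diff(x)
    if np.allclose(increments, 0.0):
        raise ValueError("constant series: Hurst exponent undefined")
    if method == "DFA":
        value = _estimate_dfa(increments)
    elif method == "RS":
        value = _estimate_rs(increments)
    else:
        raise ValueError(f"unknown method {method!r}; use 'RS' or 'DFA'")
    value = float(np.clip(value, 1e-6, 1.0 - 1e-6))
    return HurstEstimate(value=value, method=method, series_length=x.size)
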