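"""Per-cell OCT4 dynamics: fBm walks and the stochastic logistic family.

Every model advances an OCT4 level O(t) on a 5-minute frame grid, driven by
fractional Gaussian noise (fGn) with Hurst exponent H (0.38 by default, the
anti-persistent regime measured in hPSC colonies).  Rates are expressed per
frame, i.e. per 5 minutes.

Models
------
FBM_WALK
    O(t) = O(0) + sigma_A * B_H(t): a pure fractional Brownian walk,
    optionally confined by absorbing or reflecting boundaries.
SLE_ADDITIVE
    dO/dt = r O (1 - O/K) + sigma_A xi, integrated in O-space with an
    absorbing floor at 0 (below 0 the drift is negative and O runs away to
    -infinity, so the walk is stopped there).
SLE_MULTIPLICATIVE, SLE_COMBINED, SLE_TIME_K, SLE_ALLEE
    Integrated in log-space, X = ln O:

        X' = X + r(t) (1 - e^X / K(t)) g(t)
               + sigma_A(t) e^{-X} xi1 + sigma_M(t) xi2,

    where g(t) = 1 except for the Allee model, which uses
    g(t) = (e^X - A) / K(t) once the Allee term is switched on.  The
    sigma_M term is multiplicative in O (state-proportional fluctuations);
    the sigma_A e^{-X} term is the additive noise of the O-space equation
    carried through the substitution.  r, K, sigma_A and sigma_M may all be
    piecewise-constant in time (noise switches, carrying-capacity drops,
    differentiation schedules).

The Allee term creates an unstable threshold A between extinction (O -> 0)
and the carrying capacity: cells whose expression fluctuates below A after
the switch-on time collapse to zero (differentiation); the rest stay
regulated at K.  :func:`classify_fates_allee` turns that into per-cell fate
labels, back-propagated through the lineage as pro-fates.
"""

from __future__ import annotations

import enum
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np

from .fbm import NoisePack

if TYPE_CHECKING:  # pragma: no cover
    from .colony import ColonyTrajectory

__all__ = [
    "Model",
    "Schedule",
    "make_schedule",
    "BoundarySpec",
    "ModelSpec",
    "simulate_fbm_walk",
    "integrate_sle",
    "preset",
    "PRESET_NAMES",
    "classify_fates_allee",
    "FRAMES_PER_HOUR",
    "OCT4_CAP",
]

#: 5-minute frames per hour.
FRAMES_PER_HOUR = 12

#: Overflow guard for the log-space integrators, in a.f.u.
OCT4_CAP = 1.0e6


class Model(str, enum.Enum):
    """Which dynamics equation generates a cell's OCT4 series."""

    FBM_WALK = "FBM_WALK"
    SLE_ADDITIVE = "SLE_ADDITIVE"
    SLE_MULTIPLICATIVE = "SLE_MULTIPLICATIVE"
    SLE_COMBINED = "SLE_COMBINED"
    SLE_TIME_K = "SLE_TIME_K"
    SLE_ALLEE = "SLE_ALLEE"


@dataclass(frozen=True)
class Schedule:
    """Right-continuous piecewise-constant function of time (hours).

    ``schedule(t)`` is the value of the latest breakpoint at or before t.
    The first breakpoint must sit at t = 0 so the schedule covers the whole
    simulation window.
    """

    times: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values) or not self.times:
            raise ValueError("schedule needs equally many times and values, >= 1")
        if self.times[0] != 0.0:
            raise ValueError("schedules must start at t = 0")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("schedule breakpoint times must be strictly increasing")

    def __call__(self, t_hours: float) -> float:
        if t_hours < 0:
            raise ValueError("schedules are defined for t >= 0")
        return self.values[bisect_right(self.times, t_hours) - 1]

    @property
    def is_constant(self) -> bool:
        return len(set(self.values)) == 1

    def breakpoints(self) -> list[list[float]]:
        return [[t, v] for t, v in zip(self.times, self.values)]


def make_schedule(breakpoints: float | Sequence[tuple[float, float]]) -> Schedule:
    """Build a piecewise-constant schedule from (time_hours, value) pairs.

    A bare number is shorthand for a constant schedule.
    """
    if isinstance(breakpoints, (int, float)):
        return Schedule((0.0,), (float(breakpoints),))
    pairs = [(float(t), float(v)) for t, v in breakpoints]
    return Schedule(tuple(t for t, _ in pairs), tuple(v for _, v in pairs))


@dataclass(frozen=True)
class BoundarySpec:
    """Confinement for the pure fBm walk.

    The lower bound 0 reflects the positivity of fluorescence; the default
    upper bound 2500 a.f.u. is the level below which 99.9% of experimental
    OCT4 values fall.  Absorbing boundaries terminate the series (the cell
    is removed); reflecting boundaries fold the value back into the
    interior, v -> 2*bound - v.
    """

    kind: str = "reflecting"
    low: float = 0.0
    high: float = 2500.0

    def __post_init__(self) -> None:
        if self.kind not in ("absorbing", "reflecting"):
            raise ValueError("boundary kind must be 'absorbing' or 'reflecting'")
        if not self.low < self.high:
            raise ValueError("boundary requires low < high")


def _const(value: float) -> Schedule:
    return Schedule((0.0,), (float(value),))


@dataclass(frozen=True)
class ModelSpec:
    """A dynamics model plus all of its parameters and time schedules.

    Parameters
    ----------
    model : Model
        Which equation to integrate.
    r : Schedule
        Growth/regulation rate per 5-minute frame (ignored by FBM_WALK).
    K : Schedule
        Carrying capacity in a.f.u.
    sigma_A : Schedule
        Additive-noise scale in a.f.u. per frame.
    sigma_M : Schedule
        Multiplicative-noise scale (dimensionless, acts on ln O).
    hurst : float
        Hurst exponent of the driving fGn streams.
    allee_A : float, optional
        Allee threshold in a.f.u. (SLE_ALLEE only).
    allee_on_time : float, optional
        Time in hours at which the Allee term switches on, e.g. the moment
        the differentiation agent is added.
    boundary : BoundarySpec, optional
        Confinement for FBM_WALK; ignored by the SLE models.
    """

    model: Model
    r: Schedule = field(default_factory=lambda: _const(0.0))
    K: Schedule = field(default_factory=lambda: _const(1290.0))
    sigma_A: Schedule = field(default_factory=lambda: _const(0.0))
    sigma_M: Schedule = field(default_factory=lambda: _const(0.0))
    hurst: float = 0.38
    allee_A: float | None = None
    allee_on_time: float | None = None
    boundary: BoundarySpec | None = None

    def __post_init__(self) -> None:
        for name in ("r", "K", "sigma_A", "sigma_M"):
            val = getattr(self, name)
            if isinstance(val, (int, float)):
                object.__setattr__(self, name, _const(val))
        if any(v < 0 for v in self.r.values):
            raise ValueError("r must be >= 0 at all times")
        if not (0.0 < self.hurst < 1.0):
            raise ValueError("hurst must lie in (0, 1)")
        if any(v <= 0 for v in self.K.values):
            raise ValueError("carrying capacity must be positive at all times")
        if any(v < 0 for v in self.sigma_A.values) or any(
            v < 0 for v in self.sigma_M.values
        ):
            raise ValueError("noise scales must be non-negative")
        if self.model is Model.SLE_ALLEE:
            if self.allee_A is None or self.allee_on_time is None:
                raise ValueError("SLE_ALLEE requires allee_A and allee_on_time")
            if self.allee_A < 0:
                raise ValueError("allee_A must be >= 0")
        if self.model is Model.SLE_MULTIPLICATIVE and any(
            v != 0 for v in self.sigma_A.values
        ):
            raise ValueError("SLE_MULTIPLICATIVE uses sigma_M only; set sigma_A to 0")

    @property
    def uses_fgn2(self) -> bool:
        """Whether the model consumes a second (multiplicative) noise stream."""
        return self.model is not Model.FBM_WALK and any(
            v != 0 for v in self.sigma_M.values
        )

    # -- JSON config round-trip -------------------------------------------

    def to_dict(self) -> dict:
        def sched(s: Schedule):
            return s.values[0] if s.is_constant and len(s.times) == 1 else s.breakpoints()

        out = {
            "model": self.model.value,
            "r": sched(self.r),
            "K_breakpoints": self.K.breakpoints(),
            "sigmaA_breakpoints": self.sigma_A.breakpoints(),
            "sigmaM_breakpoints": self.sigma_M.breakpoints(),
            "hurst": self.hurst,
            "allee_A": self.allee_A,
            "allee_on_time_h": self.allee_on_time,
            "boundary": None,
        }
        if self.boundary is not None:
            out["boundary"] = {
                "kind": self.boundary.kind,
                "low": self.boundary.low,
                "high": self.boundary.high,
            }
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        boundary = None
        if d.get("boundary"):
            boundary = BoundarySpec(**d["boundary"])
        r = d.get("r", 0.0)
        return cls(
            model=Model(d["model"]),
            r=make_schedule(r if isinstance(r, (int, float)) else [tuple(p) for p in r]),
            K=make_schedule([tuple(p) for p in d["K_breakpoints"]]),
            sigma_A=make_schedule([tuple(p) for p in d["sigmaA_breakpoints"]]),
            sigma_M=make_schedule([tuple(p) for p in d["sigmaM_breakpoints"]]),
            hurst=float(d.get("hurst", 0.38)),
            allee_A=None if d.get("allee_A") is None else float(d["allee_A"]),
            allee_on_time=(
                None if d.get("allee_on_time_h") is None else float(d["allee_on_time_h"])
            ),
            boundary=boundary,
        )


def simulate_fbm_walk(
    start: float,
    spec: ModelSpec,
    n_frames: int,
    noise: NoisePack,
    t0_hours: float = 0.0,
) -> tuple[np.ndarray, str]:
    """Pure fBm walk O(t) = start + sigma_A * B_H(t), optionally bounded.

    Returns ``(series, status)`` where status is ``"completed"``,
    ``"absorbed_low"`` or ``"absorbed_high"``.  With an absorbing boundary
    the series is truncated at the first crossing frame (recorded at the
    boundary value); a reflecting boundary folds crossing values back into
    the interior, iterated until the value lies inside.
    """
    if n_frames < 0:
        raise ValueError("n_frames must be >= 0")
    if noise.length < n_frames:
        raise ValueError("noise pack shorter than the requested series")
    bnd = spec.boundary
    if bnd is not None and not (bnd.low < start < bnd.high):
        raise ValueError(
            f"start {start} outside the open boundary interval ({bnd.low}, {bnd.high})"
        )
    series = np.empty(n_frames + 1)
    series[0] = start
    v = float(start)
    for k in range(n_frames):
        t = t0_hours + k / FRAMES_PER_HOUR
        v = v + spec.sigma_A(t) * float(noise.increments[k])
        if bnd is not None:
            if bnd.kind == "absorbing":
                if v <= bnd.low:
                    series[k + 1] = bnd.low
                    return series[: k + 2].copy(), "absorbed_low"
                if v >= bnd.high:
                    series[k + 1] = bnd.high
                    return series[: k + 2].copy(), "absorbed_high"
            else:  # reflecting
                while v < bnd.low or v > bnd.high:
                    v = 2.0 * bnd.low - v if v < bnd.low else 2.0 * bnd.high - v
        series[k + 1] = v
    return series, "completed"


def integrate_sle(
    start: float,
    spec: ModelSpec,
    n_frames: int,
    noise1: NoisePack,
    noise2: NoisePack | None = None,
    t0_hours: float = 0.0,
) -> tuple[np.ndarray, str]:
    """Integrate one cell's stochastic-logistic OCT4 series.

    One explicit Euler step per 5-minute frame; ``noise1`` drives the
    additive term, ``noise2`` the multiplicative term (only required when
    sigma_M is non-zero somewhere).

    SLE_ADDITIVE integrates in O-space and stops at an absorbing floor at 0
    (status ``"absorbed_low"``); all other variants integrate X = ln O and
    return status ``"completed"``.  X is capped at ln(1e6 a.f.u.) with a
    warning rather than overflowing silently.
    """
    if n_frames < 0:
        raise ValueError("n_frames must be >= 0")
    if spec.model is Model.FBM_WALK:
        raise ValueError("use simulate_fbm_walk for the FBM_WALK model")
    if noise1.length < n_frames:
        raise ValueError("noise1 shorter than the requested series")
    if start <= 0:
        raise ValueError("SLE models require a positive starting value")

    if spec.model is Model.SLE_ADDITIVE:
        series = np.empty(n_frames + 1)
        series[0] = start
        o = float(start)
        for k in range(n_frames):
            t = t0_hours + k / FRAMES_PER_HOUR
            o = o + spec.r(t) * o * (1.0 - o / spec.K(t)) + spec.sigma_A(t) * float(
                noise1.increments[k]
            )
            if o <= 0.0:
                series[k + 1] = 0.0
                return series[: k + 2].copy(), "absorbed_low"
            series[k + 1] = o
        return series, "completed"

    if spec.uses_fgn2:
        if noise2 is None:
            raise ValueError("sigma_M > 0 requires a second noise pack")
        if noise2.length < n_frames:
            raise ValueError("noise2 shorter than the requested series")

    allee = spec.model is Model.SLE_ALLEE
    x_cap = np.log(OCT4_CAP)
    x_floor = np.log(1e-12)  # numerically zero expression, keeps X finite
    series = np.empty(n_frames + 1)
    series[0] = start
    x = float(np.log(start))
    capped = False
    for k in range(n_frames):
        t = t0_hours + k / FRAMES_PER_HOUR
        K = spec.K(t)
        o = np.exp(x)
        g = 1.0
        if allee and t >= spec.allee_on_time:
            g = (o - spec.allee_A) / K
        x = x + spec.r(t) * (1.0 - o / K) * g
        sm = spec.sigma_M(t)
        if sm != 0.0:
            x = x + sm * float(noise2.increments[k])
        sa = spec.sigma_A(t)
        if sa != 0.0:
            # The additive term sigma_A e^{-X} xi is the first-order
            # expansion of ln(O + sigma_A xi) - ln(O); stepping it exactly
            # in O keeps the same model but stays stable when O is small
            # (the linearised kick diverges as e^{-X}).
            o_new = np.exp(x) + sa * float(noise1.increments[k])
            x = np.log(max(o_new, 1e-12))
        if x > x_cap:
            x = x_cap
            capped = True
        elif x < x_floor:
            x = x_floor
        series[k + 1] = np.exp(x)
    if capped:
        warnings.warn(
            "log-space OCT4 hit the 1e6 a.f.u. overflow cap and was clipped",
            RuntimeWarning,
            stacklevel=2,
        )
    return series, "completed"


# ---------------------------------------------------------------------------
# Published parameter presets
# ---------------------------------------------------------------------------

_H = 0.38


def _fig3_additive() -> dict[str, ModelSpec]:
    spec = ModelSpec(
        model=Model.SLE_ADDITIVE,
        r=make_schedule(0.02),
        K=make_schedule(1290.0),
        sigma_A=make_schedule(90.0),
        hurst=_H,
    )
    return {"pluripotent": spec, "differentiated": spec}


def _fig3_multiplicative() -> dict[str, ModelSpec]:
    spec = ModelSpec(
        model=Model.SLE_MULTIPLICATIVE,
        r=make_schedule(0.005),
        K=make_schedule(1290.0),
        sigma_M=make_schedule(0.0045),
        hurst=_H,
    )
    return {"pluripotent": spec, "differentiated": spec}


def _fig4_noise_switch() -> dict[str, ModelSpec]:
    # Pluripotent cells: additive noise before 20 h, multiplicative after;
    # differentiated cells keep additive noise and a lower K throughout.
    plur = ModelSpec(
        model=Model.SLE_COMBINED,
        r=make_schedule(0.01),
        K=make_schedule(1290.0),
        sigma_A=make_schedule([(0.0, 90.0), (20.0, 0.0)]),
        sigma_M=make_schedule([(0.0, 0.0), (20.0, 0.05)]),
        hurst=_H,
    )
    diff = ModelSpec(
        model=Model.SLE_COMBINED,
        r=make_schedule(0.01),
        K=make_schedule(1000.0),
        sigma_A=make_schedule(90.0),
        sigma_M=make_schedule(0.0),
        hurst=_H,
    )
    return {"pluripotent": plur, "differentiated": diff}


def _fig5_time_K() -> dict[str, ModelSpec]:
    plur = ModelSpec(
        model=Model.SLE_TIME_K,
        r=make_schedule(0.015),
        K=make_schedule([(0.0, 1500.0), (25.0, 1000.0)]),
        sigma_A=make_schedule(30.0),
        sigma_M=make_schedule(0.035),
        hurst=_H,
    )
    diff = ModelSpec(
        model=Model.SLE_TIME_K,
        r=make_schedule(0.015),
        K=make_schedule([(0.0, 1100.0), (25.0, 1000.0)]),
        sigma_A=make_schedule(20.0),
        sigma_M=make_schedule(0.03),
        hurst=_H,
    )
    return {"pluripotent": plur, "differentiated": diff}


def _fig6_time_K_differentiation() -> dict[str, ModelSpec]:
    # Differentiation by carrying-capacity collapse: the differentiated
    # group's K drops to 300 a.f.u. when the differentiation agent arrives
    # at 43 h, with a slower regulation rate (r = 0.008) thereafter.
    plur = ModelSpec(
        model=Model.SLE_TIME_K,
        r=make_schedule(0.015),
        K=make_schedule([(0.0, 1500.0), (25.0, 1000.0)]),
        sigma_A=make_schedule(30.0),
        sigma_M=make_schedule(0.035),
        hurst=_H,
    )
    diff = ModelSpec(
        model=Model.SLE_TIME_K,
        r=make_schedule([(0.0, 0.015), (43.0, 0.008)]),
        K=make_schedule([(0.0, 1100.0), (25.0, 1000.0), (43.0, 300.0)]),
        sigma_A=make_schedule(20.0),
        sigma_M=make_schedule(0.03),
        hurst=_H,
    )
    return {"pluripotent": plur, "differentiated": diff}


def _fig6_allee() -> dict[str, ModelSpec]:
    # Fates are outcomes of the Allee mechanism, not inputs: every cell is
    # simulated identically and classified after the run.
    spec = ModelSpec(
        model=Model.SLE_ALLEE,
        r=make_schedule(0.025),
        K=make_schedule(1290.0),
        sigma_A=make_schedule(35.0),
        sigma_M=make_schedule(0.035),
        hurst=_H,
        allee_A=1000.0,
        allee_on_time=43.0,
    )
    return {"pluripotent": spec, "differentiated": spec, "unknown": spec}


_PRESETS = {
    "fig3_additive": _fig3_additive,
    "fig3_multiplicative": _fig3_multiplicative,
    "fig4_noise_switch": _fig4_noise_switch,
    "fig5_time_K": _fig5_time_K,
    "fig6_time_K_differentiation": _fig6_time_K_differentiation,
    "fig6_allee": _fig6_allee,
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str) -> dict[str, ModelSpec]:
    """Return the published per-fate parameter set with the given name."""
    try:
        return _PRESETS[name]()
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None


def classify_fates_allee(
    traj: "ColonyTrajectory",
    threshold: float | None = None,
    apply: bool = True,
) -> dict[int, str]:
    """Classify terminal cells by end-of-run OCT4 under the Allee model.

    A terminal (leaf) cell whose final OCT4 lies below ``threshold``
    (default: the Allee threshold A) has collapsed and is labelled
    ``differentiated``; the rest are ``pluripotent``.  Labels are
    back-propagated to ancestors as pro-fates: an ancestor whose leaf
    descendants all share one fate inherits it; mixed clones are labelled
    ``unknown``.  Trajectories not produced by the Allee model are refused,
    since the classification would be meaningless there.
    """
    specs = traj.model_specs
    spec_list = list(specs.values()) if isinstance(specs, Mapping) else [specs]
    allee_specs = [
        s for s in spec_list if s is not None and s.model is Model.SLE_ALLEE
    ]
    if not allee_specs:
        raise ValueError(
            "fate classification requires a trajectory simulated with the "
            "Allee model (SLE_ALLEE)"
        )
    if threshold is None:
        threshold = min(s.allee_A for s in allee_specs)
    if threshold <= 0:
        raise ValueError("threshold must be positive")

    children: dict[int, list[int]] = {}
    for c in traj.cells:
        if c.parent_id is not None:
            children.setdefault(c.parent_id, []).append(c.cell_id)
            if c.parent_id >= c.cell_id:
                raise ValueError("lineage ids must increase from mother to daughter")

    fates: dict[int, str] = {}
    leaf_fates: dict[int, frozenset[str]] = {}
    # Daughters always carry larger ids than their mothers, so one reverse
    # sweep resolves every subtree before its root.
    for c in sorted(traj.cells, key=lambda c: c.cell_id, reverse=True):
        kids = children.get(c.cell_id)
        if not kids:
            label = "differentiated" if c.series[-1] < threshold else "pluripotent"
            fates[c.cell_id] = label
            leaf_fates[c.cell_id] = frozenset({label})
        else:
            pooled = frozenset().union(*(leaf_fates[k] for k in kids))
            fates[c.cell_id] = next(iter(pooled)) if len(pooled) == 1 else "unknown"
            leaf_fates[c.cell_id] = pooled

    if apply:
        for c in traj.cells:
            c.fate = fates.get(c.cell_id, c.fate)
    return fates
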