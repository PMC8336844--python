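"""Agent-based colony model: probabilistic cell cycles and division inheritance.

The base model grows a lineage forest from a configurable number of initial
cells.  Each cell draws an initial OCT4 level and a cell-cycle duration from
samplers (kernel-density fits to experimental distributions, or parametric
stand-ins from :mod:`ptfsim.fixtures`), simulates its OCT4 series over its
cycle with one of the dynamics models, and divides into two daughters that
both inherit the mother's pre-division OCT4 value exactly.  The simulation
budget counts division events, not time steps: the run ends once the
requested number of mitoses has occurred, and frames outside the window of
interest are removed afterwards with :func:`truncate_to_window`.

All series live on a common 5-minute frame grid; real-valued division times
are rounded up to the next frame so mother and daughters share a grid point.
A single root seed drives every random draw through per-cell substreams, so
results are reproducible regardless of queue iteration order.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    FRAMES_PER_HOUR,
    Model,
    ModelSpec,
    integrate_sle,
    simulate_fbm_walk,
)
from .fbm import generate_fgn

__all__ = [
    "Sampler",
    "KDESampler",
    "ParametricSampler",
    "kde_sampler",
    "Cell",
    "ColonyTrajectory",
    "init_colony",
    "run_colony",
    "truncate_to_window",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

FATES = ("pluripotent", "differentiated", "unknown")


def _substream_seed(*keys: int) -> int:
    """Deterministic 31-bit seed derived from a tuple of integer keys."""
    state = np.random.SeedSequence([int(k) for k in keys]).generate_state(1)[0]
    return int(state) % (2**31)


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------


class Sampler:
    """Seed-deterministic scalar sampler with a hard support interval.

    Subclasses implement ``_draw_batch(n, rng)``; the public :meth:`draw`
    rejection-resamples until every value lies inside ``support`` and uses
    either the sampler's own generator (seeded at construction) or a caller
    supplied one (for per-cell substreams).
    """

    kind: str = "abstract"

    def __init__(self, support: tuple[float, float], seed: int) -> None:
        low, high = float(support[0]), float(support[1])
        if not low < high:
            raise ValueError(f"support must satisfy low < high, got ({low}, {high})")
        self.support = (low, high)
        self.seed = int(seed)
        self._rng = np.random.Generator(np.random.PCG64(self.seed))

    def _draw_batch(self, n: int, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def draw(
        self, size: int | None = None, rng: np.random.Generator | None = None
    ) -> float | np.ndarray:
        """Draw values, rejection-resampled into the support interval."""
        n = 1 if size is None else int(size)
        use = self._rng if rng is None else rng
        low, high = self.support
        out = np.empty(n)
        filled = 0
        for _ in range(1000):  # rejection rounds; each keeps in-support draws
            batch = self._draw_batch(n - filled, use)
            keep = batch[(batch >= low) & (batch <= high)]
            out[filled : filled + keep.size] = keep
            filled += keep.size
            if filled == n:
                break
        else:  # pragma: no cover - pathological support/distribution mismatch
            raise RuntimeError("rejection sampling failed to fill the support")
        return float(out[0]) if size is None else out


class KDESampler(Sampler):
    """Gaussian-kernel density sampler over an empirical data column.

    Draws resample a datum uniformly and add Gaussian kernel noise with
    Silverman's rule-of-thumb bandwidth, rejected back into the support.
    This reproduces draws from the kernel density estimate restricted to
    the support interval.
    """

    kind = "kde"

    def __init__(
        self,
        values: Sequence[float],
        support: tuple[float, float],
        seed: int,
        bandwidth: float | None = None,
    ) -> None:
        super().__init__(support, seed)
        vals = np.asarray(values, dtype=float)
        if vals.ndim != 1 or vals.size < 5:
            raise ValueError("KDE sampling needs at least 5 values")
        low, high = self.support
        if np.any(vals < low) or np.any(vals > high):
            raise ValueError("input values fall outside the stated support")
        self.values = vals
        if bandwidth is None:
            sd = float(np.std(vals, ddof=1))
            iqr = float(np.subtract(*np.percentile(vals, [75, 25])))
            spread = min(sd, iqr / 1.34) if iqr > 0 else sd
            if spread == 0.0:
                spread = max(abs(float(np.mean(vals))), 1.0) * 1e-9
            bandwidth = 0.9 * spread * vals.size ** (-0.2)
        if bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        self.bandwidth = float(bandwidth)
        self.parameters = {"n": int(vals.size)}

    def _draw_batch(self, n: int, rng: np.random.Generator) -> np.ndarray:
        picks = rng.choice(self.values, size=n, replace=True)
        return picks + rng.normal(0.0, self.bandwidth, size=n)


class ParametricSampler(Sampler):
    """Sampler over a frozen scipy distribution truncated to the support.

    Truncation is exact: draws invert the CDF on the uniform interval
    [F(low), F(high)], so no probability mass ever falls outside.
    """

    kind = "parametric"

    def __init__(self, frozen_dist, support: tuple[float, float], seed: int) -> None:
        super().__init__(support, seed)
        self._dist = frozen_dist
        low, high = self.support
        self._cdf_low = float(frozen_dist.cdf(low))
        self._cdf_high = float(frozen_dist.cdf(high))
        if not self._cdf_high > self._cdf_low:
            raise ValueError("distribution has no mass on the support interval")
        self.bandwidth = None
        self.parameters = {
            "dist": getattr(getattr(frozen_dist, "dist", None), "name", "frozen"),
            "args": tuple(float(a) for a in getattr(frozen_dist, "args", ())),
            "kwds": {k: float(v) for k, v in getattr(frozen_dist, "kwds", {}).items()},
        }

    def _draw_batch(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.uniform(self._cdf_low, self._cdf_high, size=n)
        return np.asarray(self._dist.ppf(u), dtype=float)


def kde_sampler(
    values: Sequence[float], support: tuple[float, float], seed: int
) -> KDESampler:
    """Kernel-density sampler emulating the experimental-distribution fits."""
    return KDESampler(values, support, seed)


# ---------------------------------------------------------------------------
# Cells and trajectories
# ---------------------------------------------------------------------------


@dataclass
class Cell:
    """One simulated cell: identity, lineage, timing and its OCT4 series.

    ``series[k]`` is the OCT4 value at frame ``birth_frame + k``; a
    daughter's ``series[0]`` equals its mother's last value exactly.
    ``cycle_frames`` is the planned number of frames to division;
    absorbed cells carry a shorter series and a matching status.
    """

    cell_id: int
    parent_id: int | None
    fate: str
    birth_frame: int
    cycle_frames: int
    start_oct4: float
    series: np.ndarray | None = None
    status: str = "pending"

    def __post_init__(self) -> None:
        if self.fate not in FATES:
            raise ValueError(f"fate must be one of {FATES}, got {self.fate!r}")
        if self.birth_frame < 0 or self.cycle_frames < 1:
            raise ValueError("birth_frame must be >= 0 and cycle_frames >= 1")

    @property
    def birth_time(self) -> float:
        """Birth time in hours."""
        return self.birth_frame / FRAMES_PER_HOUR

    @property
    def n_frames(self) -> int:
        """Number of recorded 5-minute steps (series length minus one)."""
        if self.series is None:
            return 0
        return len(self.series) - 1

    @property
    def division_frame(self) -> int:
        return self.birth_frame + self.cycle_frames

    @property
    def cycle_duration(self) -> float:
        """Recorded cycle span in hours (birth to division or absorption)."""
        frames = self.n_frames if self.series is not None else self.cycle_frames
        return frames / FRAMES_PER_HOUR

    def times(self) -> np.ndarray:
        """Frame times of the recorded series, in hours."""
        if self.series is None:
            raise ValueError("cell has not been simulated yet")
        return (self.birth_frame + np.arange(len(self.series))) / FRAMES_PER_HOUR


@dataclass
class ColonyTrajectory:
    """The lineage-resolved ensemble of per-cell OCT4 series.

    ``cells`` holds every lineage record (initial cells, divided mothers
    and daughters): E division events from N0 initial cells leave
    ``N0 + 2 E`` records but ``N0 + E`` cells alive at the end (each
    division replaces one cell with two).
    """

    cells: list[Cell]
    n_division_events: int
    seed: int
    frame_interval_min: float = 5.0
    model_specs: Mapping[str, ModelSpec] | ModelSpec | None = None

    @property
    def n_initial_cells(self) -> int:
        return sum(1 for c in self.cells if c.parent_id is None)

    @property
    def n_final_cells(self) -> int:
        """Cells alive at the end of the run (lineage leaves)."""
        mothers = {c.parent_id for c in self.cells if c.parent_id is not None}
        return sum(1 for c in self.cells if c.cell_id not in mothers)

    def leaves(self) -> list[Cell]:
        mothers = {c.parent_id for c in self.cells if c.parent_id is not None}
        return [c for c in self.cells if c.cell_id not in mothers]

    def by_id(self) -> dict[int, Cell]:
        return {c.cell_id: c for c in self.cells}

    def max_frame(self) -> int:
        return max(c.birth_frame + c.n_frames for c in self.cells)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per cell per frame."""
        records = []
        for c in self.cells:
            if c.series is None:
                raise ValueError(f"cell {c.cell_id} has not been simulated")
            t = c.times()
            records.append(
                pd.DataFrame(
                    {
                        "cell_id": c.cell_id,
                        "parent_id": (
                            np.nan if c.parent_id is None else c.parent_id
                        ),
                        "fate": c.fate,
                        "t_hours": t,
                        "oct4_afu": c.series,
                    }
                )
            )
        return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# Base-model steps 1-3: initialisation
# ---------------------------------------------------------------------------


def init_colony(
    n_pluripotent: int,
    n_differentiated: int,
    oct4_sampler: Sampler,
    cycle_sampler: Sampler,
    phase_mode: str = "asynchronous",
    seed: int = 0,
) -> list[Cell]:
    """Create the initial cells at t = 0.

    Each cell draws an initial OCT4 value and a cell-cycle duration; in
    asynchronous mode an elapsed-phase fraction ~ Uniform(0, 1) places the
    cell mid-cycle so its first division occurs after the remaining
    ``(1 - phase) * duration``; synchronised mode starts every cell at
    phase 0 (all first divisions coincide when durations are equal).
    """
    if n_pluripotent < 0 or n_differentiated < 0:
        raise ValueError("cell counts must be non-negative")
    if n_pluripotent + n_differentiated < 1:
        raise ValueError("the colony needs at least one initial cell")
    if phase_mode not in ("asynchronous", "synchronised"):
        raise ValueError("phase_mode must be 'asynchronous' or 'synchronised'")

    fates = ["pluripotent"] * n_pluripotent + ["differentiated"] * n_differentiated
    cells = []
    for cell_id, fate in enumerate(fates):
        rng = np.random.Generator(
            np.random.PCG64(_substream_seed(seed, cell_id, 2))
        )
        oct4_0 = float(oct4_sampler.draw(rng=rng))
        duration = float(cycle_sampler.draw(rng=rng))
        phase = float(rng.uniform()) if phase_mode == "asynchronous" else 0.0
        remaining_h = (1.0 - phase) * duration
        cycle_frames = max(1, math.ceil(remaining_h * FRAMES_PER_HOUR - 1e-6))
        cells.append(
            Cell(
                cell_id=cell_id,
                parent_id=None,
                fate=fate,
                birth_frame=0,
                cycle_frames=cycle_frames,
                start_oct4=oct4_0,
            )
        )
    return cells


# ---------------------------------------------------------------------------
# Base-model steps 4-6: simulate, divide, repeat
# ---------------------------------------------------------------------------


def _resolve_spec(
    model: ModelSpec | Mapping[str, ModelSpec], fate: str
) -> ModelSpec:
    if isinstance(model, ModelSpec):
        return model
    try:
        return model[fate]
    except KeyError:
        raise ValueError(f"no model bound to fate {fate!r}") from None


def _simulate_cell(cell: Cell, spec: ModelSpec, root_seed: int) -> None:
    n = cell.cycle_frames
    t0 = cell.birth_frame / FRAMES_PER_HOUR
    pack1 = generate_fgn(n, spec.hurst, _substream_seed(root_seed, cell.cell_id, 0))
    if spec.model is Model.FBM_WALK:
        series, status = simulate_fbm_walk(
            cell.start_oct4, spec, n, pack1, t0_hours=t0
        )
    else:
        pack2 = None
        if spec.uses_fgn2:
            pack2 = generate_fgn(
                n, spec.hurst, _substream_seed(root_seed, cell.cell_id, 1)
            )
        series, status = integrate_sle(
            cell.start_oct4, spec, n, pack1, pack2, t0_hours=t0
        )
    cell.series = series
    cell.status = status


def run_colony(
    initial_cells: Iterable[Cell],
    model: ModelSpec | Mapping[str, ModelSpec],
    n_division_events: int,
    seed: int,
    cycle_sampler: Sampler,
) -> ColonyTrajectory:
    """Grow the colony for a fixed budget of division events.

    Cells are processed in division-time order (ties broken by id).  Each
    cell's OCT4 series is simulated over its remaining cycle with the
    dynamics model bound to its fate; at its division frame — while the
    event budget lasts — it is replaced by two daughters starting exactly
    at its final OCT4 value, with freshly sampled cycle durations.  Cells
    absorbed at a boundary do not divide.  The budget counts completed
    divisions, never frames.
    """
    if n_division_events < 0:
        raise ValueError("n_division_events must be >= 0")
    cells = [
        Cell(
            cell_id=c.cell_id,
            parent_id=c.parent_id,
            fate=c.fate,
            birth_frame=c.birth_frame,
            cycle_frames=c.cycle_frames,
            start_oct4=c.start_oct4,
        )
        for c in initial_cells
    ]
    if not cells:
        raise ValueError("need at least one initial cell")
    if len({c.cell_id for c in cells}) != len(cells):
        raise ValueError("initial cell ids must be unique")

    queue: list[tuple[int, int]] = []
    for cell in cells:
        _simulate_cell(cell, _resolve_spec(model, cell.fate), seed)
        if cell.status == "completed":
            heapq.heappush(queue, (cell.division_frame, cell.cell_id))

    by_id = {c.cell_id: c for c in cells}
    next_id = max(by_id) + 1
    events = 0
    while queue and events < n_division_events:
        _, mother_id = heapq.heappop(queue)
        mother = by_id[mother_id]
        events += 1
        for _ in range(2):
            child_id = next_id
            next_id += 1
            rng = np.random.Generator(
                np.random.PCG64(_substream_seed(seed, child_id, 2))
            )
            duration = float(cycle_sampler.draw(rng=rng))
            daughter = Cell(
                cell_id=child_id,
                parent_id=mother_id,
                fate=mother.fate,
                birth_frame=mother.division_frame,
                cycle_frames=max(
                    1, math.ceil(duration * FRAMES_PER_HOUR - 1e-6)
                ),
                start_oct4=float(mother.series[-1]),
            )
            _simulate_cell(daughter, _resolve_spec(model, daughter.fate), seed)
            cells.append(daughter)
            by_id[child_id] = daughter
            if daughter.status == "completed":
                heapq.heappush(queue, (daughter.division_frame, child_id))

    return ColonyTrajectory(
        cells=cells,
        n_division_events=events,
        seed=seed,
        model_specs=model,
    )


def truncate_to_window(traj: ColonyTrajectory, t_max: float) -> ColonyTrajectory:
    """Clip all series to [0, t_max] hours and drop cells born afterwards.

    A 68-hour window at 5-minute frames keeps frames 0..816, i.e. 817
    distinct frame times.
    """
    if t_max < 0:
        raise ValueError("t_max must be >= 0")
    max_frame = math.floor(t_max * FRAMES_PER_HOUR + 1e-9)
    kept: list[Cell] = []
    surviving = set()
    for c in traj.cells:
        if c.birth_frame > max_frame:
            continue
        n_keep = min(c.n_frames, max_frame - c.birth_frame)
        clipped = Cell(
            cell_id=c.cell_id,
            parent_id=c.parent_id,
            fate=c.fate,
            birth_frame=c.birth_frame,
            cycle_frames=c.cycle_frames,
            start_oct4=c.start_oct4,
            series=c.series[: n_keep + 1].copy(),
            status=c.status if n_keep == c.n_frames else "completed",
        )
        kept.append(clipped)
        surviving.add(c.cell_id)
    for c in kept:  # orphan guard: parents must survive the window
        if c.parent_id is not None and c.parent_id not in surviving:
            raise RuntimeError("truncation dropped a mother before its daughter")
    return ColonyTrajectory(
        cells=kept,
        n_division_events=traj.n_division_events,
        seed=traj.seed,
        frame_interval_min=traj.frame_interval_min,
        model_specs=traj.model_specs,
    )


# ---------------------------------------------------------------------------
# Trajectory CSV round-trip
# ---------------------------------------------------------------------------


def write_trajectory_csv(traj: ColonyTrajectory, path) -> None:
    """Write the long-format trajectory CSV.

    Header ``cell_id,parent_id,fate,t_hours,oct4_afu``; one row per cell
    per frame; OCT4 written with 6 significant digits; the lineage is
    recoverable from ``parent_id`` (empty for initial cells).
    """
    df = traj.to_frame()
    df["parent_id"] = df["parent_id"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    df["t_hours"] = df["t_hours"].map(lambda v: f"{v:.6f}")
    df["oct4_afu"] = df["oct4_afu"].map(lambda v: f"{v:.6g}")
    df.to_csv(path, index=False)


def read_trajectory_csv(path) -> ColonyTrajectory:
    """Read a trajectory CSV back, validating grid spacing and inheritance."""
    df = pd.read_csv(path, dtype={"parent_id": "Int64"})
    required = ["cell_id", "parent_id", "fate", "t_hours", "oct4_afu"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV is missing columns: {missing}")
    if df.empty:
        raise ValueError("trajectory CSV contains no rows")
    cells: list[Cell] = []
    for cell_id, group in df.groupby("cell_id", sort=True):
        group = group.sort_values("t_hours")
        t = group["t_hours"].to_numpy(dtype=float)
        frames = np.rint(t * FRAMES_PER_HOUR).astype(int)
        if not np.array_equal(np.diff(frames), np.ones(len(frames) - 1, dtype=int)):
            raise ValueError(
                f"cell {cell_id}: series is not on a contiguous 5-minute grid"
            )
        parent_raw = group["parent_id"].iloc[0]
        parent_id = None if pd.isna(parent_raw) else int(parent_raw)
        series = group["oct4_afu"].to_numpy(dtype=float)
        cells.append(
            Cell(
                cell_id=int(cell_id),
                parent_id=parent_id,
                fate=str(group["fate"].iloc[0]),
                birth_frame=int(frames[0]),
                cycle_frames=max(1, len(series) - 1),
                start_oct4=float(series[0]),
                series=series,
                status="completed",
            )
        )
    by_id = {c.cell_id: c for c in cells}
    for c in cells:
        if c.parent_id is not None:
            if c.parent_id not in by_id:
                raise ValueError(f"cell {c.cell_id}: unknown parent {c.parent_id}")
            mother = by_id[c.parent_id]
            if c.birth_frame != mother.birth_frame + mother.n_frames:
                raise ValueError(
                    f"cell {c.cell_id}: birth frame does not match its "
                    "mother's division frame"
                )
    n_initial = sum(1 for c in cells if c.parent_id is None)
    mothers = {c.parent_id for c in cells if c.parent_id is not None}
    return ColonyTrajectory(
        cells=cells,
        n_division_events=len(mothers),
        seed=-1,
        model_specs=None,
    )
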