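import numpy as np
import pytest

from ptfsim import colony, fixtures


@pytest.fixture(scope="session")
def fixture_cfg():
    return fixtures.FixtureConfig()


@pytest.fixture(scope="session")
def oct4_sampler(fixture_cfg):
    return fixtures.make_initial_oct4_sampler(fixture_cfg)


@pytest.fixture(scope="session")
def cycle_sampler(fixture_cfg):
    return fixtures.make_cycle_sampler(fixture_cfg)


def make_cell(cell_id, series, fate="pluripotent", parent_id=None, birth_frame=0):
    """Hand-built cell for analysis tests."""
    series = np.asarray(series, dtype=float)
    return colony.Cell(
        cell_id=cell_id,
        parent_id=parent_id,
        fate=fate,
        birth_frame=birth_frame,
        cycle_frames=max(1, len(series) - 1),
        start_oct4=float(series[0]),
        series=series,
        status="completed",
    )


def make_traj(cells, seed=0):
    return colony.ColonyTrajectory(
        cells=list(cells), n_division_events=0, seed=seed
    )
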