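"""Shared fixtures: small grids and programmatic log builders."""

from __future__ import annotations

import pytest

from gazeloc import CellTrajectory, FixationEvent, GazeEventLog, GridGeometry

# The textbook 2x2 illustration: ten fixations whose transition tallies
# form the printed matrix.  Cells in (row, col); the display labels are
# a1=(0,0), b1=(0,1), a2=(1,0), b2=(1,1) (letter = column, number = row).
WORKED_PATH = [
    (1, 0),
    (0, 0),
    (0, 0),
    (1, 0),
    (0, 1),
    (0, 0),
    (1, 1),
    (1, 1),
    (1, 0),
    (0, 1),
]


@pytest.fixture
def grid2() -> GridGeometry:
    return GridGeometry(n_rows=2, n_cols=2)


@pytest.fixture
def grid15() -> GridGeometry:
    return GridGeometry()


def make_log(
    cells,
    grid: GridGeometry,
    durations_ms=None,
    subject_id: str = "S01",
    trial_id: int = 1,
    gap_ms: float = 20.0,
) -> GazeEventLog:
    """Build a single-trial log fixating each cell center in turn."""
    durations_ms = durations_ms or [100.0] * len(cells)
    fixations = []
    t = 0.0
    for cell, dur in zip(cells, durations_ms):
        x, y = grid.cell_center(cell)
        fixations.append(
            FixationEvent(
                subject_id=subject_id,
                trial_id=trial_id,
                start_ms=t,
                end_ms=t + dur,
                x_px=x,
                y_px=y,
            )
        )
        t += dur + gap_ms
    return GazeEventLog(fixations, grid)


def merge_logs(*logs: GazeEventLog) -> GazeEventLog:
    fixations = [f for log in logs for f in log.fixations]
    return GazeEventLog(fixations, logs[0].grid)


@pytest.fixture
def worked_log(grid2) -> GazeEventLog:
    return make_log(WORKED_PATH, grid2)


@pytest.fixture
def worked_traj(grid2) -> CellTrajectory:
    return CellTrajectory(cells=list(WORKED_PATH), dt=0.1, shape=(2, 2), trial_breaks=[0])
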