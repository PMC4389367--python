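"""Resampling fixation sequences into constant-step cell trajectories.

Each in-grid fixation is expanded into ``max(1, floor(duration/dt))``
consecutive samples of its cell, so a long dwell contributes within-cell
(self) transitions on the same footing as between-cell transitions.
Saccade gaps between fixations are elided; trial boundaries break the
chain, because each trial presents a different screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .grid import Cell, GridGeometry
from .io import GazeEventLog


@dataclass
class CellTrajectory:
    """Time-resampled cell sequence with trial segmentation.

    ``trial_breaks`` holds the start index of every trial segment
    (the first entry is always 0 for a nonempty trajectory).
    """

    cells: list[Cell]
    dt: float
    shape: tuple[int, int]
    trial_breaks: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cells)

    def segments(self) -> list[list[Cell]]:
        """Cell runs of each trial segment, in order."""
        bounds = list(self.trial_breaks) + [len(self.cells)]
        return [self.cells[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


def sample_trajectory(
    log: GazeEventLog,
    grid: GridGeometry | None = None,
    dt: float = 0.1,
    break_on_trial: bool = True,
) -> CellTrajectory:
    """Resample a log's fixations into a cell trajectory at step ``dt`` (s).

    Fixations whose center falls outside the matrix contribute nothing.
    With ``break_on_trial`` (the default) a new (subject, trial) starts a
    new segment and no transition is ever counted across it.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    grid = grid or log.grid

    cells: list[Cell] = []
    breaks: list[int] = []
    current_key: tuple[str, int] | None = None
    for fix in log.fixations:
        cell = fix.cell(grid)
        if cell is None:
            continue
        key = (fix.subject_id, fix.trial_id)
        if current_key is None or (break_on_trial and key != current_key):
            breaks.append(len(cells))
            current_key = key
        elif not break_on_trial:
            current_key = key
        n_samples = max(1, int(fix.duration_ms / (dt * 1000.0)))
        cells.extend([cell] * n_samples)
    if not cells:
        raise ValueError("empty trajectory: log contains no in-grid fixation")
    return CellTrajectory(cells=cells, dt=dt, shape=grid.shape, trial_breaks=breaks)
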