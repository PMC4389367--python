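"""First-order Markov transition model over grid cells and its entropy map.

The fixation trajectory is treated as the output of a Markov process on
the cell lattice.  Transition counts are tallied between consecutive
samples within a trial segment, normalized row-wise into transition
probabilities P(source -> destination), and each source cell is scored by
the Shannon entropy (in nats) of its outgoing distribution — its
"out-entropy".  Cells the eye leaves in many different directions score
high; cells it never visits, or always leaves the same way, score zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import Cell, GridGeometry, cell_label
from .trajectory import CellTrajectory


@dataclass
class TransitionModel:
    """Sparse per-cell transition counts/probabilities.

    ``counts`` maps (source, destination) cell pairs to tally integers;
    ``probs`` holds the row-normalized transition probabilities and
    ``row_totals`` the per-source normalizer Z.  Unvisited and terminal
    cells have Z = 0 and an (implicit) all-zero probability row.
    """

    shape: tuple[int, int]
    counts: dict[tuple[Cell, Cell], int] = field(default_factory=dict)
    probs: dict[tuple[Cell, Cell], float] | None = None
    row_totals: dict[Cell, int] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.shape[0] * self.shape[1]

    def _flat(self, cell: Cell) -> int:
        return cell[0] * self.shape[1] + cell[1]

    def to_dense(self, which: str = "probs") -> np.ndarray:
        """Dense (n_cells x n_cells) matrix in row-major cell order."""
        data = self.probs if which == "probs" else self.counts
        if data is None:
            raise ValueError("probabilities not computed; call normalize() first")
        out = np.zeros((self.n_cells, self.n_cells))
        for (src, dst), v in data.items():
            out[self._flat(src), self._flat(dst)] = v
        return out


def count_transitions(traj: CellTrajectory) -> TransitionModel:
    """Tally transitions between consecutive samples within each segment.

    The last sample of a segment emits no transition; nothing is counted
    across trial breaks.
    """
    counts: dict[tuple[Cell, Cell], int] = {}
    totals: dict[Cell, int] = {}
    n_transitions = 0
    for seg in traj.segments():
        for src, dst in zip(seg[:-1], seg[1:]):
            counts[(src, dst)] = counts.get((src, dst), 0) + 1
            totals[src] = totals.get(src, 0) + 1
            n_transitions += 1
    if n_transitions == 0:
        raise ValueError("trajectory contains no transition to count")
    return TransitionModel(shape=traj.shape, counts=counts, row_totals=totals)


def normalize(model: TransitionModel) -> TransitionModel:
    """Fill row-stochastic probabilities P[src, dst] = counts/Z per source."""
    probs = {
        (src, dst): n / model.row_totals[src] for (src, dst), n in model.counts.items()
    }
    return TransitionModel(
        shape=model.shape,
        counts=dict(model.counts),
        probs=probs,
        row_totals=dict(model.row_totals),
    )


def entropy_map(model: TransitionModel) -> np.ndarray:
    """Per-cell out-entropy H = -sum p ln p (nats), 0*ln 0 := 0.

    Unvisited/terminal cells (Z = 0) get H = 0.  Returns an array of the
    grid's shape.
    """
    if model.probs is None:
        model = normalize(model)
    H = np.zeros(model.shape)
    for (src, _dst), p in model.probs.items():
        if p > 0:
            H[src] -= p * np.log(p)
    # clip tiny negative round-off on deterministic rows
    H[np.abs(H) < 1e-15] = 0.0
    return H


def entropy_map_from_trajectory(traj: CellTrajectory) -> np.ndarray:
    return entropy_map(normalize(count_transitions(traj)))


def entropy_to_frame(H: np.ndarray, grid: GridGeometry | None = None) -> pd.DataFrame:
    """Labeled DataFrame (rows 1..n, columns A..) for CSV export."""
    grid = grid or GridGeometry(n_rows=H.shape[0], n_cols=H.shape[1])
    cols = [cell_label((0, c), grid)[0] for c in range(H.shape[1])]
    rows = [r + 1 for r in range(H.shape[0])]
    return pd.DataFrame(H, index=rows, columns=cols)
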