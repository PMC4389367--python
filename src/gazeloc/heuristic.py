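"""First-fixation fallback search.

When the entropy predictor misses, the first few fixations of the very
first screen still carry signal: the serial plan examines the first
fixation's cell, then its 8 neighbors, then the second fixation's cell,
and so on, counting how many cells must be examined before the target is
found.
"""

from __future__ import annotations

from dataclasses import dataclass

from .grid import Cell, GridGeometry, chebyshev, neighbors8
from .io import GazeEventLog

#: Returned by :func:`plan_cost` when the target is not in the plan.
NOT_FOUND = None


@dataclass
class SearchPlan:
    """Ordered, duplicate-free cells to examine, with provenance: each
    entry records which fixation (1-based) produced it and whether it is
    the fixated cell itself or one of its neighbors."""

    cells: list[Cell]
    provenance: list[tuple[int, str]]

    def __len__(self) -> int:
        return len(self.cells)


def first_fixation_plan(
    log: GazeEventLog, grid: GridGeometry | None = None, k: int = 3
) -> SearchPlan:
    """Serial search plan from the first ``k`` in-grid fixations of the
    first trial: fix1, its neighbors (row-major), fix2, its neighbors, ...
    Duplicates keep their earliest position."""
    grid = grid or log.grid
    trials = log.trials()
    if not trials:
        return SearchPlan([], [])
    subject, first_trial = trials[0]

    cells: list[Cell] = []
    provenance: list[tuple[int, str]] = []
    seen: set[Cell] = set()

    def push(cell: Cell, prov: tuple[int, str]) -> None:
        if cell not in seen:
            seen.add(cell)
            cells.append(cell)
            provenance.append(prov)

    n_used = 0
    for fix in log.fixations_for(subject, first_trial):
        cell = fix.cell(grid)
        if cell is None:
            continue
        n_used += 1
        push(cell, (n_used, "fixation"))
        for nb in neighbors8(cell, grid):
            push(nb, (n_used, "neighbor"))
        if n_used == k:
            break
    return SearchPlan(cells, provenance)


def plan_cost(plan: SearchPlan, truth: Cell, tolerance: int = 0) -> int | None:
    """1-based position of the first plan cell within Chebyshev
    ``tolerance`` of the target, or :data:`NOT_FOUND`."""
    for pos, cell in enumerate(plan.cells, start=1):
        if chebyshev(cell, truth) <= tolerance:
            return pos
    return NOT_FOUND
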