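"""Screen-to-cell geometry for the stimulus matrix.

The stimulus is an ``n_rows x n_cols`` matrix of cells drawn on screen with
a label band (column letters along the top, row numbers down the left side).
Cells are addressed internally by 0-based ``(row, col)`` tuples and
externally by labels such as ``"A1"`` (column letter + 1-based row number).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterator

import yaml

#: Sentinel for a pixel that falls outside the cell matrix (label band or
#: margin).  Kept as a module-level name so callers can test identity.
OUT_OF_GRID = None

Cell = tuple[int, int]


@dataclass(frozen=True)
class GridGeometry:
    """Pixel layout of the stimulus matrix.

    Defaults describe a 15x15 matrix of 105x65 px cells on a 1680x1050
    screen, offset by one cell so the label row/column occupy the first
    band of the screen.
    """

    n_rows: int = 15
    n_cols: int = 15
    cell_w_px: float = 105.0
    cell_h_px: float = 65.0
    origin_x_px: float = 105.0
    origin_y_px: float = 65.0
    screen_w_px: float = 1680.0
    screen_h_px: float = 1050.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_w_px <= 0 or self.cell_h_px <= 0:
            raise ValueError("cell dimensions must be positive")
        if self.origin_x_px + self.n_cols * self.cell_w_px > self.screen_w_px:
            raise ValueError("grid exceeds screen width")
        if self.origin_y_px + self.n_rows * self.cell_h_px > self.screen_h_px:
            raise ValueError("grid exceeds screen height")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cells(self) -> Iterator[Cell]:
        """All cells in row-major order."""
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                yield (r, c)

    def contains(self, cell: Cell) -> bool:
        r, c = cell
        return 0 <= r < self.n_rows and 0 <= c < self.n_cols

    def cell_center(self, cell: Cell) -> tuple[float, float]:
        """Pixel coordinates of a cell's center."""
        r, c = cell
        x = self.origin_x_px + (c + 0.5) * self.cell_w_px
        y = self.origin_y_px + (r + 0.5) * self.cell_h_px
        return (x, y)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name}: {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_file(cls, path: str | Path) -> "GridGeometry":
        """Read a flat ``key: value`` geometry config."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(raw, dict):
            raise ValueError(f"grid config {path} is not a key: value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown grid config keys: {sorted(unknown)}")
        return cls(**raw)


def pixel_to_cell(x: float, y: float, grid: GridGeometry) -> Cell | None:
    """Map a screen pixel to its grid cell with half-open bins.

    col = floor((x - origin_x)/cell_w), row = floor((y - origin_y)/cell_h);
    pixels in the label band or past the last cell map to :data:`OUT_OF_GRID`.
    """
    if not (0 <= x <= grid.screen_w_px and 0 <= y <= grid.screen_h_px):
        raise ValueError(f"pixel ({x}, {y}) outside screen bounds")
    fx = x - grid.origin_x_px
    fy = y - grid.origin_y_px
    if fx < 0 or fy < 0:
        return OUT_OF_GRID
    col = int(fx // grid.cell_w_px)
    row = int(fy // grid.cell_h_px)
    if row >= grid.n_rows or col >= grid.n_cols:
        return OUT_OF_GRID
    return (row, col)


def cell_label(cell: Cell, grid: GridGeometry | None = None) -> str:
    """Display label for a cell: column letter (A..) + 1-based row number."""
    grid = grid or GridGeometry()
    r, c = cell
    if not grid.contains(cell):
        raise ValueError(f"cell {cell} outside {grid.n_rows}x{grid.n_cols} grid")
    if c >= 26:
        raise ValueError("label scheme supports at most 26 columns")
    return f"{chr(ord('A') + c)}{r + 1}"


def label_to_cell(label: str, grid: GridGeometry | None = None) -> Cell:
    """Inverse of :func:`cell_label`."""
    grid = grid or GridGeometry()
    if len(label) < 2 or not label[0].isalpha():
        raise ValueError(f"malformed cell label {label!r}")
    col = ord(label[0].upper()) - ord("A")
    row = int(label[1:]) - 1
    cell = (row, col)
    if not grid.contains(cell):
        raise ValueError(f"label {label!r} outside {grid.n_rows}x{grid.n_cols} grid")
    return cell


def neighbors8(cell: Cell, grid: GridGeometry) -> list[Cell]:
    """Valid 8-connected (Chebyshev-1) neighbors in row-major order."""
    r, c = cell
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            n = (r + dr, c + dc)
            if grid.contains(n):
                out.append(n)
    return out


def chebyshev(a: Cell, b: Cell) -> int:
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))
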