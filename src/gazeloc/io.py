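"""Fixation-event log I/O.

Event logs are tab-separated text with header::

    subject_id  trial_id  event  start_ms  end_ms  x_px  y_px  disp_x  disp_y  pupil

``event`` is one of FIX, SAC, BLINK.  Only FIX rows are analyzed; SAC/BLINK
rows are parsed (x/y may be blank) and kept in a side list.  Files are
UTF-8, LF-terminated, ``.`` decimal separator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .grid import GridGeometry, pixel_to_cell

COLUMNS = [
    "subject_id",
    "trial_id",
    "event",
    "start_ms",
    "end_ms",
    "x_px",
    "y_px",
    "disp_x",
    "disp_y",
    "pupil",
]

EVENT_TYPES = {"FIX", "SAC", "BLINK"}


@dataclass(frozen=True)
class FixationEvent:
    """One fixation: start/end time and average gaze position in pixels.

    ``disp_x``/``disp_y`` (gaze dispersion) and ``pupil`` are carried
    through unchanged but never analyzed.
    """

    subject_id: str
    trial_id: int
    start_ms: float
    end_ms: float
    x_px: float
    y_px: float
    disp_x: float = 0.0
    disp_y: float = 0.0
    pupil: float = 0.0

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms

    def cell(self, grid: GridGeometry):
        return pixel_to_cell(self.x_px, self.y_px, grid)


@dataclass
class GazeEventLog:
    """Time-ordered fixations grouped by (subject, trial), plus the screen
    geometry they were recorded on.  Non-fixation rows ride along in
    ``other_events`` and are never analyzed."""

    fixations: list[FixationEvent]
    grid: GridGeometry
    other_events: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fixations.sort(key=lambda f: (f.subject_id, f.trial_id, f.start_ms))

    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.fixations:
            seen.setdefault(f.subject_id, None)
        return list(seen)

    def trials(self, subject_id: str | None = None) -> list[tuple[str, int]]:
        """Distinct (subject, trial) keys in log order."""
        seen: dict[tuple[str, int], None] = {}
        for f in self.fixations:
            if subject_id is None or f.subject_id == subject_id:
                seen.setdefault((f.subject_id, f.trial_id), None)
        return list(seen)

    def fixations_for(self, subject_id: str, trial_id: int | None = None) -> list[FixationEvent]:
        return [
            f
            for f in self.fixations
            if f.subject_id == subject_id
            and (trial_id is None or f.trial_id == trial_id)
        ]

    def subset(self, subject_id: str) -> "GazeEventLog":
        return GazeEventLog(self.fixations_for(subject_id), self.grid)


def _parse_float(value: str, column: str, lineno: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(f"line {lineno}: malformed {column} value {value!r}") from None


def read_event_log(path: str | Path, grid: GridGeometry) -> GazeEventLog:
    """Parse a fixation-event TSV.

    Malformed rows raise with their line number; a fixation whose gaze
    position lies outside the screen raises naming the event.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    fixations: list[FixationEvent] = []
    others: list[dict] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        lineno = idx + 2  # header is line 1
        event = getattr(row, "event")
        if event not in EVENT_TYPES:
            raise ValueError(f"line {lineno}: unknown event type {event!r}")
        if event != "FIX":
            others.append({c: getattr(row, c) for c in COLUMNS})
            continue
        try:
            trial_id = int(getattr(row, "trial_id"))
        except ValueError:
            raise ValueError(
                f"line {lineno}: malformed trial_id {getattr(row, 'trial_id')!r}"
            ) from None
        start = _parse_float(getattr(row, "start_ms"), "start_ms", lineno)
        end = _parse_float(getattr(row, "end_ms"), "end_ms", lineno)
        if end <= start:
            raise ValueError(f"line {lineno}: end_ms {end} not after start_ms {start}")
        x = _parse_float(getattr(row, "x_px"), "x_px", lineno)
        y = _parse_float(getattr(row, "y_px"), "y_px", lineno)
        if not (0 <= x <= grid.screen_w_px and 0 <= y <= grid.screen_h_px):
            raise ValueError(
                f"fixation at line {lineno} (subject {getattr(row, 'subject_id')}, "
                f"trial {trial_id}, {start}-{end} ms): gaze ({x}, {y}) outside screen"
            )
        aux = {}
        for col in ("disp_x", "disp_y", "pupil"):
            raw = getattr(row, col)
            aux[col] = _parse_float(raw, col, lineno) if raw not in ("", None) else 0.0
        fixations.append(
            FixationEvent(
                subject_id=str(getattr(row, "subject_id")),
                trial_id=trial_id,
                start_ms=start,
                end_ms=end,
                x_px=x,
                y_px=y,
                **aux,
            )
        )
    return GazeEventLog(fixations, grid, others)


def _fmt(v: float) -> str:
    return f"{v:g}" if not (isinstance(v, float) and math.isnan(v)) else ""


def write_event_log(log: GazeEventLog, path: str | Path) -> None:
    """Write a canonical fixation-event TSV (fixations then side events,
    each in time order)."""
    rows = []
    for f in log.fixations:
        rows.append(
            {
                "subject_id": f.subject_id,
                "trial_id": f.trial_id,
                "event": "FIX",
                "start_ms": _fmt(f.start_ms),
                "end_ms": _fmt(f.end_ms),
                "x_px": _fmt(f.x_px),
                "y_px": _fmt(f.y_px),
                "disp_x": _fmt(f.disp_x),
                "disp_y": _fmt(f.disp_y),
                "pupil": _fmt(f.pupil),
            }
        )
    rows.extend(log.other_events)
    df = pd.DataFrame(rows, columns=COLUMNS)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
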