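"""Synthetic interrogation sessions with known ground truth.

Each trial shows the grid split by a random horizontal/vertical segmenting
line; the simulated subject scans a short run of line-adjacent cells in
reading order (the overt task), occasionally glances at a stray cell, and
— depending on strategy — betrays the concealed target through brief
approach-and-flee excursions:

* ``avoider_slip``: with probability ``slip_rate`` per trial the gaze slips
  into the target's Chebyshev-1 ring for one brief fixation, then flees to
  a uniformly random distant cell.  The approach is habitual — most slips
  land on a subject-specific preferred ring cell (the eye approaches the
  hiding place from the same direction), the rest on a uniform ring cell —
  so across trials the preferred cell accumulates many distinct flee
  exits: a high and spatially *narrow* out-entropy peak, the two
  signatures the selection rule looks for.
* ``decoy_fixator``: same slips, but additionally parks long repeated
  fixations on a deliberately chosen decoy cell (a counter-strategy; these
  subjects are expected algorithm failures).
* ``random_scanner``: task scanning only, no excursions (null model).

Fixation pixel positions are cell centers plus isotropic Gaussian jitter
(sigma = 10 px).  Everything is driven by a seeded generator; identical
seeds reproduce byte-identical logs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid import Cell, GridGeometry, cell_label, chebyshev
from .io import FixationEvent, GazeEventLog

STRATEGIES = ("avoider_slip", "decoy_fixator", "random_scanner")

# Baseline behavior constants (session-condition defaults; see docs/methods.md)
SCAN_LENGTH = 6  # line-adjacent cells scanned per trial
GLANCE_RATE = 0.25  # probability of one stray glance per trial
BRIEF_DWELL_MEAN_MS = 70.0  # slip/glance dwell: brief grazing fixation
BRIEF_DWELL_SD_MS = 10.0
HABITUAL_SLIP_RATE = 0.7  # fraction of slips landing on the preferred ring cell
DECOY_DWELL_MEAN_MS = 400.0
DECOY_DWELL_SD_MS = 100.0
SACCADE_GAP_MS = 30.0
JITTER_SD_PX = 10.0
FLEE_MIN_CHEBYSHEV = 4  # flee destinations stay this far from the target


@dataclass(frozen=True)
class SubjectProfile:
    """Ground truth and behavioral strategy of one simulated subject."""

    target: Cell
    strategy: str = "avoider_slip"
    slip_rate: float = 0.5
    decoy: Cell | None = None
    dwell_mean_ms: float = 90.0
    dwell_sd_ms: float = 25.0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0.0 <= self.slip_rate <= 1.0:
            raise ValueError("slip_rate must lie in [0, 1]")
        if self.strategy == "decoy_fixator" and self.decoy is None:
            raise ValueError("decoy_fixator requires a decoy cell")


@dataclass(frozen=True)
class SessionConfig:
    """Session structure: grid, trial count and optional exposure cap
    (ms per trial; None = self-paced)."""

    grid: GridGeometry = field(default_factory=GridGeometry)
    n_trials: int = 28
    exposure_ms: float | None = None

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class SubjectRecord:
    subject_id: str
    log: GazeEventLog
    truth: Cell
    strategy: str
    seed: int


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Draw from a log-normal with the given distribution mean and sd."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _ring_cells(target: Cell, grid: GridGeometry) -> list[Cell]:
    return [
        c
        for c in grid.cells()
        if chebyshev(c, target) == 1
    ]


def _distant_cells(target: Cell, grid: GridGeometry) -> list[Cell]:
    far = [c for c in grid.cells() if chebyshev(c, target) >= FLEE_MIN_CHEBYSHEV]
    if not far:  # tiny grids: anything off the ring will do
        far = [c for c in grid.cells() if chebyshev(c, target) > 1]
    return far


def _scan_cells(grid: GridGeometry, rng: np.random.Generator) -> list[Cell]:
    """Reading-order run of cells hugging a random segmenting line."""
    horizontal = bool(rng.random() < 0.5)
    if horizontal:
        boundary = int(rng.integers(1, grid.n_rows))  # line above this row
        row = boundary - 1 if rng.random() < 0.5 else boundary
        length = min(SCAN_LENGTH, grid.n_cols)
        start = int(rng.integers(0, grid.n_cols - length + 1))
        return [(row, start + k) for k in range(length)]
    boundary = int(rng.integers(1, grid.n_cols))
    col = boundary - 1 if rng.random() < 0.5 else boundary
    length = min(SCAN_LENGTH, grid.n_rows)
    start = int(rng.integers(0, grid.n_rows - length + 1))
    return [(start + k, col) for k in range(length)]


def _trial_script(
    profile: SubjectProfile,
    grid: GridGeometry,
    rng: np.random.Generator,
    preferred_ring: Cell,
) -> list[tuple[Cell, float]]:
    """(cell, dwell_ms) sequence for one trial.

    Event order encodes the behavioral model: the involuntary
    approach-and-flee slip is an exogenous-attention capture at screen
    onset, so it opens the trial; a stray glance, when it happens, is a
    re-orientation that precedes engaging the line-scanning task.  Decoy
    dwells interrupt the scan at arbitrary points — parking on the decoy
    is an intentional, self-paced counter-strategy.
    """
    script: list[tuple[Cell, float]] = [
        (c, _lognormal(rng, profile.dwell_mean_ms, profile.dwell_sd_ms))
        for c in _scan_cells(grid, rng)
    ]

    if profile.strategy == "decoy_fixator":
        for _ in range(2):
            pos = int(rng.integers(0, len(script) + 1))
            script[pos:pos] = [
                (profile.decoy, _lognormal(rng, DECOY_DWELL_MEAN_MS, DECOY_DWELL_SD_MS))
            ]

    if rng.random() < GLANCE_RATE:
        glance = (int(rng.integers(0, grid.n_rows)), int(rng.integers(0, grid.n_cols)))
        script[0:0] = [(glance, _lognormal(rng, BRIEF_DWELL_MEAN_MS, BRIEF_DWELL_SD_MS))]

    if profile.strategy in ("avoider_slip", "decoy_fixator"):
        if rng.random() < profile.slip_rate:
            if rng.random() < HABITUAL_SLIP_RATE:
                slip = preferred_ring
            else:
                ring = _ring_cells(profile.target, grid)
                slip = ring[int(rng.integers(0, len(ring)))]
            distant = _distant_cells(profile.target, grid)
            flee = distant[int(rng.integers(0, len(distant)))]
            script[0:0] = [
                (slip, _lognormal(rng, BRIEF_DWELL_MEAN_MS, BRIEF_DWELL_SD_MS)),
                (flee, _lognormal(rng, profile.dwell_mean_ms, profile.dwell_sd_ms)),
            ]
    return script


def simulate_session(
    profile: SubjectProfile,
    config: SessionConfig,
    rng: np.random.Generator,
    subject_id: str = "S01",
) -> tuple[GazeEventLog, Cell]:
    """Simulate one multi-trial session; returns the log and the true cell."""
    grid = config.grid
    if not grid.contains(profile.target):
        raise ValueError(f"target {profile.target} outside grid")
    ring = _ring_cells(profile.target, grid)
    preferred_ring = ring[int(rng.integers(0, len(ring)))]  # habitual approach
    fixations: list[FixationEvent] = []
    for trial in range(1, config.n_trials + 1):
        t = 0.0
        for i, (cell, dwell) in enumerate(_trial_script(profile, grid, rng, preferred_ring)):
            if i > 0 and config.exposure_ms is not None and t >= config.exposure_ms:
                break
            cx, cy = grid.cell_center(cell)
            x = float(np.clip(cx + rng.normal(0.0, JITTER_SD_PX), 0.0, grid.screen_w_px))
            y = float(np.clip(cy + rng.normal(0.0, JITTER_SD_PX), 0.0, grid.screen_h_px))
            fixations.append(
                FixationEvent(
                    subject_id=subject_id,
                    trial_id=trial,
                    start_ms=round(t, 1),
                    end_ms=round(t + dwell, 1),
                    x_px=round(x, 1),
                    y_px=round(y, 1),
                )
            )
            t += dwell + SACCADE_GAP_MS
    return GazeEventLog(fixations, grid), profile.target


def _largest_remainder_counts(proportions: list[float], n: int) -> list[int]:
    """Deterministic apportionment of n slots to proportions."""
    quotas = [p * n for p in proportions]
    counts = [int(math.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(quotas)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def generate_cohort(
    n_subjects: int,
    strategy_mix: dict[str, float] | None = None,
    base_seed: int = 0,
    config: SessionConfig | None = None,
    slip_rate: float = 0.5,
    dwell_mean_ms: float = 90.0,
    dwell_sd_ms: float = 25.0,
) -> list[SubjectRecord]:
    """Simulate a cohort with deterministic per-subject seeds and uniform
    random targets.  ``strategy_mix`` proportions must sum to 1; fractional
    subject counts are apportioned largest-remainder."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    mix = strategy_mix or {"avoider_slip": 0.6, "decoy_fixator": 0.2, "random_scanner": 0.2}
    for s in mix:
        if s not in STRATEGIES:
            raise ValueError(f"unknown strategy {s!r} in mix")
    props = list(mix.values())
    if any(p < 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
        raise ValueError("strategy mix proportions must be nonnegative and sum to 1")
    config = config or SessionConfig()
    grid = config.grid

    names = list(mix)
    counts = _largest_remainder_counts(props, n_subjects)
    strategies = [s for s, k in zip(names, counts) for _ in range(k)]

    children = np.random.SeedSequence(base_seed).spawn(n_subjects)
    records: list[SubjectRecord] = []
    for i, (strategy, child) in enumerate(zip(strategies, children)):
        seed = int(child.generate_state(1)[0])
        rng = np.random.default_rng(child)
        target = (int(rng.integers(0, grid.n_rows)), int(rng.integers(0, grid.n_cols)))
        decoy = None
        if strategy == "decoy_fixator":
            far = [c for c in grid.cells() if chebyshev(c, target) > 1]
            decoy = far[int(rng.integers(0, len(far)))]
        profile = SubjectProfile(
            target=target,
            strategy=strategy,
            slip_rate=slip_rate,
            decoy=decoy,
            dwell_mean_ms=dwell_mean_ms,
            dwell_sd_ms=dwell_sd_ms,
        )
        subject_id = f"S{i + 1:02d}"
        log, truth = simulate_session(profile, config, rng, subject_id=subject_id)
        records.append(SubjectRecord(subject_id, log, truth, strategy, seed))
    return records


def merge_cohort_log(records: list[SubjectRecord]) -> GazeEventLog:
    """Single log holding every subject's fixations (shared grid)."""
    grid = records[0].log.grid
    fixations = [f for rec in records for f in rec.log.fixations]
    return GazeEventLog(fixations, grid)


def write_truth_sidecar(records: list[SubjectRecord], path) -> None:
    """TSV sidecar: subject_id, target label, strategy, seed."""
    import pandas as pd

    grid = records[0].log.grid
    pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "target": [cell_label(r.truth, grid) for r in records],
            "strategy": [r.strategy for r in records],
            "seed": [r.seed for r in records],
        }
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")
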