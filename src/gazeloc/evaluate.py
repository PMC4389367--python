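"""Hit criteria, chance baselines, binomial significance, cohort reports.

A prediction counts as a (tolerant) hit when it lands on the true cell or
within Chebyshev distance 1 of it.  The matching chance baseline on a
15x15 grid is 1/225 ~ 0.004 exact and 9/225 = 0.04 with one-cell
tolerance for an interior target; cohort hit counts are tested against it
with an exact one-sided binomial tail.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

from .grid import Cell, GridGeometry, cell_label, chebyshev
from .heuristic import first_fixation_plan, plan_cost
from .io import GazeEventLog
from .locator import TargetLocator
from .simulate import SubjectRecord


def is_hit(pred: Cell, truth: Cell, tolerance: int = 1) -> bool:
    """True iff the prediction is within Chebyshev ``tolerance`` of truth."""
    return chebyshev(pred, truth) <= tolerance


def random_baseline(
    grid: GridGeometry, tolerance: int = 1, mode: str = "interior"
) -> float:
    """Probability that a uniform random guess hits within ``tolerance``.

    ``exact``: 1/#cells regardless of tolerance.
    ``interior``: (2*tol+1)^2/#cells, the full-square neighborhood of an
    interior target (capped at 1).
    ``average``: mean over all target positions of the clipped
    neighborhood size / #cells — honest at edges and corners.
    """
    n = grid.n_cells
    if mode == "exact":
        return 1.0 / n
    if mode == "interior":
        return min(1.0, (2 * tolerance + 1) ** 2 / n)
    if mode == "average":
        total = 0
        for tr, tc in grid.cells():
            rows = min(grid.n_rows - 1, tr + tolerance) - max(0, tr - tolerance) + 1
            cols = min(grid.n_cols - 1, tc + tolerance) - max(0, tc - tolerance) + 1
            total += rows * cols
        return total / (n * n)
    raise ValueError(f"unknown baseline mode {mode!r}")


def binomial_pvalue(hits: int, n: int, p0: float) -> float:
    """Exact upper-tail P(X >= hits) for X ~ Binomial(n, p0)."""
    if not 0 <= hits <= n:
        raise ValueError("hits must lie in [0, n]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    return float(stats.binom.sf(hits - 1, n, p0))


@dataclass
class SubjectResult:
    subject_id: str
    predicted: Cell
    predicted_label: str
    truth: Cell
    truth_label: str
    hit: bool
    rescued: bool
    fallback_cost: int | None  # tolerant matching inside the plan
    fallback_cost_exact: int | None
    strategy: str | None = None


@dataclass
class CohortReport:
    """Cohort-level summary of the entropy predictor plus fallback."""

    subjects: list[SubjectResult]
    tolerance: int
    hit_rate: float
    combined_rate: float
    mean_extra_cells: float | None
    mean_extra_fraction: float | None
    baseline: float
    baseline_average: float
    p_value: float
    p_value_combined: float
    params: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.subjects)

    def to_dict(self) -> dict:
        d = asdict(self)
        for s in d["subjects"]:
            s["predicted"] = list(s["predicted"])
            s["truth"] = list(s["truth"])
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame([asdict(s) for s in self.subjects]).to_csv(
            path, sep="\t", index=False, lineterminator="\n"
        )


def _as_triples(cohort) -> list[tuple[str | None, GazeEventLog, Cell, str | None]]:
    out = []
    for i, item in enumerate(cohort):
        if isinstance(item, SubjectRecord):
            out.append((item.subject_id, item.log, item.truth, item.strategy))
        else:
            log, truth = item
            out.append((f"S{i + 1:02d}", log, truth, None))
    return out


def evaluate_cohort(
    cohort,
    grid: GridGeometry | None = None,
    dt: float = 0.1,
    n_peaks: int = 3,
    rel_threshold: float = 0.25,
    alpha: float = 0.1,
    tolerance: int = 1,
    heuristic_k: int = 3,
    baseline_mode: str = "interior",
) -> CohortReport:
    """Run the full pipeline per subject; on a miss, try the
    first-fixation fallback plan and record its search cost."""
    triples = _as_triples(cohort)
    if not triples:
        raise ValueError("empty cohort")
    locator = TargetLocator(
        dt=dt, n_peaks=n_peaks, rel_threshold=rel_threshold, alpha=alpha, grid=grid
    )

    results: list[SubjectResult] = []
    for subject_id, log, truth, strategy in triples:
        g = grid or log.grid
        fitted = TargetLocator(**locator.get_params()).fit(log)
        pred = fitted.target_cell_
        hit = is_hit(pred, truth, tolerance)
        cost = cost_exact = None
        rescued = False
        if not hit:
            plan = first_fixation_plan(log, g, k=heuristic_k)
            cost = plan_cost(plan, truth, tolerance=tolerance)
            cost_exact = plan_cost(plan, truth, tolerance=0)
            rescued = cost is not None
        results.append(
            SubjectResult(
                subject_id=subject_id,
                predicted=pred,
                predicted_label=cell_label(pred, g),
                truth=truth,
                truth_label=cell_label(truth, g),
                hit=hit,
                rescued=rescued,
                fallback_cost=cost,
                fallback_cost_exact=cost_exact,
                strategy=strategy,
            )
        )

    g = grid or triples[0][1].grid
    n = len(results)
    hits = sum(r.hit for r in results)
    combined = sum(r.hit or r.rescued for r in results)
    rescue_costs = [r.fallback_cost for r in results if r.rescued]
    mean_extra = sum(rescue_costs) / len(rescue_costs) if rescue_costs else None
    p0 = random_baseline(g, tolerance, baseline_mode)
    return CohortReport(
        subjects=results,
        tolerance=tolerance,
        hit_rate=hits / n,
        combined_rate=combined / n,
        mean_extra_cells=mean_extra,
        mean_extra_fraction=(mean_extra / g.n_cells) if mean_extra is not None else None,
        baseline=p0,
        baseline_average=random_baseline(g, tolerance, "average"),
        p_value=binomial_pvalue(hits, n, p0),
        p_value_combined=binomial_pvalue(combined, n, p0),
        params={
            "dt": dt,
            "n_peaks": n_peaks,
            "rel_threshold": rel_threshold,
            "alpha": alpha,
            "tolerance": tolerance,
            "heuristic_k": heuristic_k,
            "baseline_mode": baseline_mode,
        },
    )
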