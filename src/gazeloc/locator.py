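"""The end-to-end target locator as a scikit-learn style estimator."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, clone

from .clustering import (
    build_cluster_map,
    predict_target,
    selection_score,
)
from .grid import Cell, GridGeometry, cell_label
from .io import GazeEventLog
from .markov import count_transitions, entropy_map, normalize
from .trajectory import CellTrajectory, sample_trajectory


class TargetLocator(BaseEstimator):
    """Locate a concealed grid cell from one subject's fixation log.

    The pipeline: resample fixations into a cell trajectory at step ``dt``,
    estimate the Markov cell-transition model, compute the per-cell
    out-entropy map, cluster its dominant peaks (flood-fill above
    ``rel_threshold`` of each peak), and score every cell with
    ``S = H * exp(-alpha * C)`` where C is the cell's cluster size.  The
    argmax of S is the predicted target.

    Parameters
    ----------
    dt : float, default 0.1
        Trajectory sampling step in seconds (~one average fixation).
    n_peaks : int, default 3
        Number of dominant entropy peaks to cluster.
    rel_threshold : float, default 0.25
        Cluster membership threshold relative to the seeding peak's entropy.
    alpha : float, default 0.1
        Cluster-size penalty coefficient in the selection score.
    grid : GridGeometry or None
        Screen geometry; None takes the geometry carried by the fitted log.

    Attributes (after :meth:`fit`)
    ------------------------------
    trajectory_ : CellTrajectory
    transition_model_ : TransitionModel with probabilities filled
    entropy_map_ : ndarray, per-cell out-entropy in nats
    cluster_map_ : ClusterMap
    score_map_ : ndarray of selection scores
    prediction_ : Prediction (top cell, full ranking, top score)
    target_cell_ : (row, col) of the predicted target
    target_label_ : its display label, e.g. ``"G7"``
    """

    def __init__(
        self,
        dt: float = 0.1,
        n_peaks: int = 3,
        rel_threshold: float = 0.25,
        alpha: float = 0.1,
        grid: GridGeometry | None = None,
    ):
        self.dt = dt
        self.n_peaks = n_peaks
        self.rel_threshold = rel_threshold
        self.alpha = alpha
        self.grid = grid

    def _validate_params(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_peaks < 0:
            raise ValueError("n_peaks must be nonnegative")
        if not 0.0 <= self.rel_threshold <= 1.0:
            raise ValueError("rel_threshold must lie in [0, 1]")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")

    def fit(self, X: GazeEventLog | CellTrajectory, y=None) -> "TargetLocator":
        """Run the pipeline on one session (a log or a pre-sampled
        trajectory) and store every intermediate map."""
        self._validate_params()
        if isinstance(X, CellTrajectory):
            traj = X
            grid = self.grid or GridGeometry(n_rows=X.shape[0], n_cols=X.shape[1])
        elif isinstance(X, GazeEventLog):
            grid = self.grid or X.grid
            traj = sample_trajectory(X, grid, dt=self.dt)
        else:
            raise TypeError(f"cannot fit on {type(X).__name__}")
        self.grid_ = grid
        self.trajectory_ = traj
        self.transition_model_ = normalize(count_transitions(traj))
        self.entropy_map_ = entropy_map(self.transition_model_)
        self.cluster_map_ = build_cluster_map(
            self.entropy_map_, n_peaks=self.n_peaks, rel_threshold=self.rel_threshold
        )
        self.score_map_ = selection_score(self.entropy_map_, self.cluster_map_, self.alpha)
        self.prediction_ = predict_target(self.score_map_)
        self.target_cell_ = self.prediction_.top_cell
        self.target_label_ = cell_label(self.target_cell_, grid)
        return self

    def fit_predict(self, X, y=None) -> Cell:
        return self.fit(X).target_cell_

    def predict(self, X) -> list[Cell]:
        """Predict the target cell for each session in ``X`` (a single
        log/trajectory or an iterable of them) without mutating self."""
        if isinstance(X, (GazeEventLog, CellTrajectory)):
            X = [X]
        return [clone(self).fit_predict(session) for session in X]

    def ranking_labels(self, top: int | None = None) -> list[str]:
        """Descending-score cell labels (search order)."""
        cells = self.prediction_.ranking
        if top is not None:
            cells = cells[:top]
        return [cell_label(c, self.grid_) for c in cells]


def locate_target(log: GazeEventLog, **params) -> Cell:
    """Functional one-shot wrapper over :class:`TargetLocator`."""
    return TargetLocator(**params).fit_predict(log)
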