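"""Entropy-peak clustering and the cluster-size-penalized selection score.

Two regularities drive target selection: the concealed cell tends to sit
under a *high* entropy peak, and that peak tends to be *narrow*.  The map
is therefore segmented into a few dominant peak clusters (recursive
flood-fill above a threshold relative to the seeding peak) plus one large
background cluster, and each cell is scored

    S = H * exp(-alpha * C)

where C is the size of the cell's cluster.  The background cluster's size
annihilates its members' scores; among peaks, narrow beats broad.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import Cell

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


@dataclass
class ClusterMap:
    """Per-cell cluster assignment.

    ``labels``: 0 for the background cluster, 1..K for peak clusters in
    peak (dominance) order.  ``sizes``: C, the number of cells sharing
    each cell's cluster.  ``peaks``: the seeding peak of each cluster.
    """

    labels: np.ndarray
    sizes: np.ndarray
    peaks: list[Cell]


@dataclass
class Prediction:
    """Result of the selection rule: the argmax cell of the score map and
    the full descending ranking (for search-cost accounting)."""

    top_cell: Cell
    ranking: list[Cell]
    score: float


def _local_max_mask(H: np.ndarray) -> np.ndarray:
    """Cells with H > 0 that are >= all 8-neighbors."""
    neighborhood_max = ndimage.maximum_filter(H, footprint=_EIGHT, mode="constant", cval=-np.inf)
    return (H > 0) & (H >= neighborhood_max)


def find_local_peaks(
    H: np.ndarray,
    n_peaks: int = 3,
    exclude: np.ndarray | None = None,
) -> list[Cell]:
    """Up to ``n_peaks`` dominant local maxima, descending by H, ties
    broken row-major.  Cells flagged in ``exclude`` (e.g. already absorbed
    into an earlier peak's cluster) are skipped."""
    mask = _local_max_mask(H)
    if exclude is not None:
        mask &= ~exclude
    cand = [(int(r), int(c)) for r, c in np.argwhere(mask)]
    cand.sort(key=lambda rc: (-H[rc], rc))
    return cand[:n_peaks]


def grow_cluster(peak: Cell, H: np.ndarray, rel_threshold: float = 0.25) -> set[Cell]:
    """Flood-fill from ``peak`` over 8-connected cells with
    H >= rel_threshold * H(peak).  The peak always belongs."""
    if H[peak] <= 0:
        raise ValueError(f"peak {peak} has no positive entropy")
    mask = H >= rel_threshold * H[peak]
    labeled, _ = ndimage.label(mask, structure=_EIGHT)
    comp = labeled == labeled[peak]
    return {(int(r), int(c)) for r, c in np.argwhere(comp)}


def build_cluster_map(
    H: np.ndarray,
    n_peaks: int = 3,
    rel_threshold: float = 0.25,
) -> ClusterMap:
    """Grow clusters for the dominant peaks; pool the rest as background.

    Clusters are grown in peak order and never overlap: a cell keeps the
    label of the first (more dominant) cluster that claims it, and
    flood-fill does not pass through already-claimed cells.
    """
    labels = np.zeros(H.shape, dtype=int)
    peaks: list[Cell] = []
    for k in range(1, n_peaks + 1):
        claimed = labels > 0
        found = find_local_peaks(H, n_peaks=1, exclude=claimed)
        if not found:
            break
        peak = found[0]
        mask = (H >= rel_threshold * H[peak]) & ~claimed
        labeled, _ = ndimage.label(mask, structure=_EIGHT)
        labels[labeled == labeled[peak]] = k
        peaks.append(peak)

    sizes = np.empty(H.shape, dtype=int)
    for lab in np.unique(labels):
        members = labels == lab
        sizes[members] = members.sum()
    return ClusterMap(labels=labels, sizes=sizes, peaks=peaks)


def selection_score(
    H: np.ndarray, clusters: ClusterMap, alpha: float = 0.1
) -> np.ndarray:
    """S = H * exp(-alpha * C) elementwise."""
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    if clusters.sizes.shape != H.shape:
        raise ValueError("entropy map and cluster map shapes differ")
    return H * np.exp(-alpha * clusters.sizes)


def predict_target(S: np.ndarray) -> Prediction:
    """Argmax of the score map, ties broken row-major, with full ranking."""
    order = sorted(
        ((int(r), int(c)) for r, c in np.ndindex(*S.shape)),
        key=lambda rc: (-S[rc], rc),
    )
    top = order[0]
    return Prediction(top_cell=top, ranking=order, score=float(S[top]))
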