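"""Peak finding, cluster growth, selection scoring, and prediction."""

import math

import numpy as np
import pytest

from gazeloc import (
    CellTrajectory,
    build_cluster_map,
    count_transitions,
    entropy_map,
    find_local_peaks,
    grow_cluster,
    normalize,
    predict_target,
    selection_score,
)


def H_of(values_4x4):
    return np.array(values_4x4, dtype=float)


class TestLocalPeaks:
    def test_single_positive_cell(self):
        H = np.zeros((4, 4))
        H[2, 1] = 0.5
        assert find_local_peaks(H) == [(2, 1)]

    def test_ordered_by_height(self):
        H = np.zeros((4, 4))
        H[0, 0], H[3, 3] = 1.0, 0.8
        assert find_local_peaks(H) == [(0, 0), (3, 3)]

    def test_uniform_plateau_ties_break_row_major(self):
        H = np.full((3, 3), 0.7)
        assert find_local_peaks(H, n_peaks=1) == [(0, 0)]

    def test_all_zero_map_has_no_peaks(self):
        assert find_local_peaks(np.zeros((4, 4))) == []

    def test_exclusion_skips_absorbed_cells(self):
        H = np.zeros((4, 4))
        H[0, 0], H[3, 3] = 1.0, 0.8
        exclude = np.zeros((4, 4), dtype=bool)
        exclude[0, 0] = True
        assert find_local_peaks(H, exclude=exclude) == [(3, 3)]


class TestGrowCluster:
    def test_relative_threshold_includes_and_excludes(self):
        H = np.zeros((4, 4))
        H[1, 1], H[1, 2], H[2, 1] = 1.0, 0.3, 0.2
        assert grow_cluster((1, 1), H, 0.25) == {(1, 1), (1, 2)}

    def test_isolated_peak_is_singleton(self):
        H = np.zeros((4, 4))
        H[2, 2] = 1.0
        assert grow_cluster((2, 2), H) == {(2, 2)}

    def test_plateau_floods_entirely(self):
        H = np.full((3, 3), 0.4)
        assert grow_cluster((1, 1), H) == {(r, c) for r in range(3) for c in range(3)}

    def test_zero_peak_rejected(self):
        with pytest.raises(ValueError):
            grow_cluster((0, 0), np.zeros((3, 3)))


class TestClusterMap:
    def test_two_disjoint_peaks_and_background(self):
        H = np.zeros((4, 4))
        H[0, 0], H[0, 1] = 1.0, 0.4
        H[3, 3] = 0.8
        cm = build_cluster_map(H)
        assert cm.peaks == [(0, 0), (3, 3)]
        assert cm.labels[0, 0] == cm.labels[0, 1] == 1
        assert cm.labels[3, 3] == 2
        assert (cm.labels == 0).sum() == 16 - 2 - 1
        assert cm.sizes[0, 0] == 2 and cm.sizes[3, 3] == 1
        assert cm.sizes[2, 2] == 13  # background size

    def test_all_zero_map_is_one_background_cluster(self):
        cm = build_cluster_map(np.zeros((4, 4)))
        assert cm.peaks == []
        assert np.all(cm.labels == 0) and np.all(cm.sizes == 16)

    def test_labels_partition_grid(self):
        rng = np.random.default_rng(3)
        H = rng.uniform(0, 2, size=(8, 8))
        cm = build_cluster_map(H)
        total = sum((cm.labels == lab).sum() for lab in np.unique(cm.labels))
        assert total == 64
        for lab in np.unique(cm.labels):
            assert np.all(cm.sizes[cm.labels == lab] == (cm.labels == lab).sum())

    def test_worked_example_cluster_seeded_at_a1(self, worked_traj):
        H = entropy_map(normalize(count_transitions(worked_traj)))
        cm = build_cluster_map(H)
        assert cm.peaks[0] == (0, 0)  # a1
        assert cm.labels[0, 0] == 1


class TestSelectionScore:
    def test_alpha_zero_is_identity(self):
        H = np.array([[1.0, 0.5], [0.2, 0.0]])
        cm = build_cluster_map(H)
        np.testing.assert_allclose(selection_score(H, cm, alpha=0.0), H)

    def test_known_penalty_value(self):
        H = np.zeros((4, 4))
        H[1, 1], H[1, 2], H[2, 2] = 1.0, 0.3, 0.28
        cm = build_cluster_map(H)
        assert cm.sizes[1, 1] == 3
        S = selection_score(H, cm, alpha=0.1)
        assert S[1, 1] == pytest.approx(math.exp(-0.3), abs=1e-4)  # 0.7408

    def test_background_annihilated(self):
        from gazeloc import ClusterMap

        H = np.full((15, 15), 0.5)
        cm = ClusterMap(
            labels=np.zeros((15, 15), dtype=int),
            sizes=np.full((15, 15), 200, dtype=int),
            peaks=[],
        )
        S = selection_score(H, cm, alpha=0.1)
        assert np.all(S < 1e-8 * H)  # e^{-20} wipes a 200-cell cluster

    def test_monotone_in_cluster_size_and_entropy(self):
        H = np.zeros((6, 6))
        H[0, 0] = H[5, 5] = 1.0
        H[0, 1] = 0.9  # size-2 cluster at the top-left peak
        cm = build_cluster_map(H)
        S = selection_score(H, cm, alpha=0.1)
        assert S[5, 5] > S[0, 0]  # equal H, smaller cluster wins
        assert S[0, 0] > S[0, 1]  # same cluster, higher H wins


class TestPrediction:
    def test_worked_example_alpha_zero_selects_a1(self, worked_traj):
        H = entropy_map(normalize(count_transitions(worked_traj)))
        pred = predict_target(selection_score(H, build_cluster_map(H), alpha=0.0))
        assert pred.top_cell == (0, 0)

    def test_tie_breaks_row_major(self):
        pred = predict_target(np.full((3, 3), 0.5))
        assert pred.top_cell == (0, 0)
        assert pred.ranking[0] == (0, 0) and len(pred.ranking) == 9

    def test_agrees_with_bruteforce_argmax(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            S = rng.uniform(size=(5, 5))
            best = max(((r, c) for r in range(5) for c in range(5)), key=lambda rc: S[rc])
            assert predict_target(S).top_cell == best

    def test_narrow_peak_preferred_at_equal_entropy(self):
        """Two equal peaks; the one in the smaller cluster ranks first."""
        H = np.zeros((8, 8))
        H[1, 1] = 1.0  # singleton
        H[6, 1:6] = [0.5, 0.5, 1.0, 0.5, 0.5]  # 5-cell ridge
        cm = build_cluster_map(H)
        for alpha in (0.01, 0.1, 1.0):
            S = selection_score(H, cm, alpha=alpha)
            assert S[1, 1] > S[6, 3]

    def test_end_to_end_equivariance_under_grid_symmetries(self):
        """Rotating/flipping the trajectory rotates/flips the prediction."""
        rng = np.random.default_rng(17)
        n = 5
        # dense enough that the top score is unique: with an exact tie the
        # row-major tie-break rightly breaks symmetry
        cells = [(int(r), int(c)) for r, c in rng.integers(0, n, size=(400, 2))]

        def transform(cell, k, flip):
            r, c = cell
            for _ in range(k):
                r, c = c, n - 1 - r  # 90-degree rotation
            if flip:
                c = n - 1 - c
            return (r, c)

        def score_map(cs):
            traj = CellTrajectory(cells=cs, dt=0.1, shape=(n, n), trial_breaks=[0])
            H = entropy_map(normalize(count_transitions(traj)))
            return selection_score(H, build_cluster_map(H))

        S = score_map(cells)
        top2 = np.sort(S.ravel())[::-1][:2]
        assert top2[0] - top2[1] > 1e-9  # precondition: unique argmax

        base = predict_target(S).top_cell
        for k in range(4):
            for flip in (False, True):
                got = predict_target(score_map([transform(c, k, flip) for c in cells])).top_cell
                assert got == transform(base, k, flip)
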