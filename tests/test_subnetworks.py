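"""Region co-expression clustering and virtual lesions.

Ward clustering is checked merge-for-merge against a naive O(n^3)
Lance-Williams implementation written from the recurrence, independent of
scipy's linkage code.
"""

import numpy as np
import pytest

from brainsig.bootstrap import (
    BootstrapResult,
    Region,
    extract_regions,
    threshold_map,
)
from brainsig.core import BetaImageSet, BrainMask, WeightMap
from brainsig.expression import pattern_response
from brainsig.subnetworks import (
    RegionResponseMatrix,
    cluster_regions,
    rank_normalize,
    region_trial_responses,
    virtual_lesion,
)


def naive_ward_linkage(X):
    """Brute-force agglomerative Ward linkage (Lance-Williams recurrence),
    returning the scipy-style merge table."""
    n = X.shape[0]
    d2 = np.full((2 * n - 1, 2 * n - 1), np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            d2[i, j] = d2[j, i] = np.sum((X[i] - X[j]) ** 2)
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    merges = []
    nxt = n
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if i < j and (best is None or d2[i, j] < best[0]):
                    best = (d2[i, j], i, j)
        dij, i, j = best
        si, sj = sizes[i], sizes[j]
        for k in sorted(active - {i, j}):
            sk = sizes[k]
            d2[nxt, k] = d2[k, nxt] = (
                (si + sk) * d2[i, k] + (sj + sk) * d2[j, k] - sk * dij
            ) / (si + sj + sk)
        merges.append((min(i, j), max(i, j), np.sqrt(dij), si + sj))
        sizes[nxt] = si + sj
        active -= {i, j}
        active.add(nxt)
        nxt += 1
    return merges


def _trial_set(data, subjects, mask):
    n = data.shape[0]
    return BetaImageSet(data, subjects, np.arange(n) % 5 + 1, mask,
                        trial_id=np.arange(n))


def _make_tmap(weights_vec, mask, support=None):
    support = weights_vec != 0 if support is None else support
    p = np.where(support, 1e-6, 1.0)
    res = BootstrapResult(
        mean=weights_vec, sd=np.ones(len(weights_vec)),
        z=np.zeros(len(weights_vec)), p=p, n_resamples=2, unit="row",
        degenerate=np.zeros(len(weights_vec), bool),
    )
    wmap = WeightMap(weights_vec, 0.5, mask)
    return threshold_map(res, wmap, rule="p:0.001", extent_k=1)


class TestRegionTrialResponses:
    @pytest.fixture()
    def setup(self):
        mask = BrainMask(inclusion=np.ones((6, 6, 4), bool))
        rng = np.random.default_rng(0)
        w = np.zeros(mask.n_voxels)
        vol = mask.devectorize(w)
        vol[0:2, 0:2, 0:2] = rng.standard_normal((2, 2, 2))
        vol[4:6, 4:6, 0:2] = rng.standard_normal((2, 2, 2))
        w = mask.vectorize(vol)
        tmap = _make_tmap(w, mask)
        regions = extract_regions(tmap)
        data = rng.standard_normal((12, mask.n_voxels))
        trials = _trial_set(data, np.repeat(["a", "b"], 6), mask)
        return mask, tmap, regions, trials

    def test_regional_responses_sum_to_whole_map_minus_intercept(self, setup):
        mask, tmap, regions, trials = setup
        rrm = region_trial_responses(regions, trials, tmap.weights)
        whole = pattern_response(tmap.weights, trials)
        total = rrm.values.sum(axis=1) + tmap.weights.intercept
        assert np.allclose(total, whole, atol=1e-10)

    def test_zero_weight_region_gives_zero_column(self, setup):
        mask, tmap, regions, trials = setup
        zeroed = WeightMap(np.zeros(mask.n_voxels), 0.0, mask)
        rrm = region_trial_responses(regions, trials, zeroed)
        assert np.all(rrm.values == 0)

    def test_two_region_hand_example(self):
        inc = np.zeros((4, 2, 1), bool)
        inc[:, 0, 0] = True
        mask = BrainMask(inclusion=inc)
        w = np.array([1.0, 2.0, 0.0, -1.0])
        regions = [
            Region(voxel_index=np.array([0, 1]), size=2, sign=1, peak_index=1),
            Region(voxel_index=np.array([3]), size=1, sign=-1, peak_index=3),
        ]
        parent = WeightMap(w, 0.0, mask)
        data = np.array([[1.0, 1.0, 9.0, 2.0], [0.5, -1.0, 9.0, 4.0]])
        trials = _trial_set(data, ["a", "a"], mask)
        rrm = region_trial_responses(regions, trials, parent)
        # region 1: 1*1 + 2*1 = 3 and 1*0.5 + 2*(-1) = -1.5; region 2: -2, -4
        assert np.allclose(rrm.values, [[3.0, -2.0], [-1.5, -4.0]])


class TestRankNormalize:
    def _matrix(self, values, subjects):
        return RegionResponseMatrix(np.asarray(values, float),
                                    np.asarray(subjects),
                                    [f"region_{i:02d}" for i in
                                     range(np.asarray(values).shape[1])])

    def test_rank_order_within_subject(self):
        m = self._matrix([[0.3], [0.1], [0.2]], ["a", "a", "a"])
        out = rank_normalize(m)
        # ranks (3,1,2) z-scored
        expected = (np.array([3.0, 1.0, 2.0]) - 2.0) / np.std([3, 1, 2])
        assert np.allclose(out.values[:, 0], expected)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((10, 3))
        subj = np.repeat(["a", "b"], 5)
        out1 = rank_normalize(self._matrix(vals, subj))
        out2 = rank_normalize(self._matrix(np.exp(2 * vals), subj))
        assert np.allclose(out1.values, out2.values)

    def test_ties_get_average_rank(self):
        m = self._matrix([[1.0], [1.0], [2.0]], ["a", "a", "a"])
        out = rank_normalize(m)
        ranks = np.array([1.5, 1.5, 3.0])
        expected = (ranks - ranks.mean()) / ranks.std()
        assert np.allclose(out.values[:, 0], expected)

    def test_single_trial_subject_rejected(self):
        m = self._matrix([[1.0], [2.0]], ["a", "b"])
        with pytest.raises(ValueError, match="fewer than 2 trials"):
            rank_normalize(m)


class TestClusterRegions:
    def _matrix(self, X, n_trials=None):
        X = np.asarray(X, float)
        return RegionResponseMatrix(
            X, np.array(["s0"] * X.shape[0]),
            [f"region_{i:02d}" for i in range(X.shape[1])],
        )

    def test_two_separated_groups_give_two_clusters(self):
        rng = np.random.default_rng(2)
        base1 = rng.standard_normal(20)
        base2 = rng.standard_normal(20) + 50
        X = np.column_stack([
            base1 + rng.normal(0, .1, 20), base1 + rng.normal(0, .1, 20),
            base2 + rng.normal(0, .1, 20), base2 + rng.normal(0, .1, 20),
        ])
        sol = cluster_regions(self._matrix(X), cut_fraction=0.5)
        assert sol.n_clusters == 2
        assert sol.assignment[0] == sol.assignment[1]
        assert sol.assignment[2] == sol.assignment[3]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_naive_ward_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((6, 15))  # 6 regions, 15 trials
        sol = cluster_regions(self._matrix(X.T), cut_fraction=0.31)
        oracle = naive_ward_linkage(X)
        Z = sol.linkage_matrix
        for row, (i, j, h, size) in zip(Z, oracle):
            assert {int(row[0]), int(row[1])} == {i, j}
            assert row[2] == pytest.approx(h)
            assert int(row[3]) == size

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 8))
        sol = cluster_regions(self._matrix(X))
        heights = sol.linkage_matrix[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_invariant_to_region_order(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((25, 7))
        perm = rng.permutation(7)
        sol1 = cluster_regions(self._matrix(X))
        sol2 = cluster_regions(self._matrix(X[:, perm]))
        # same partition after undoing the permutation
        from itertools import combinations

        def pairs(assign):
            return {(i, j) for i, j in combinations(range(7), 2)
                    if assign[i] == assign[j]}

        inv = np.empty(7, int)
        inv[perm] = np.arange(7)
        remapped = sol2.assignment[inv]
        assert pairs(sol1.assignment) == pairs(remapped)

    def test_three_subnetwork_recovery(self):
        """Regions driven by three latent trial signals cluster into the
        three generating groups (adjusted Rand > 0.9)."""
        rng = np.random.default_rng(7)
        n_trials = 120
        latents = rng.standard_normal((n_trials, 3))
        truth_labels = np.repeat([0, 1, 2], 4)
        X = np.column_stack([
            latents[:, g] + rng.normal(0, 0.3, n_trials) for g in truth_labels
        ])
        subj = np.repeat([f"s{i}" for i in range(6)], 20)
        m = RegionResponseMatrix(X, subj, [f"region_{i:02d}" for i in range(12)])
        sol = cluster_regions(rank_normalize(m), cut_fraction=0.31)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth_labels, sol.assignment) > 0.9


class TestVirtualLesion:
    @pytest.fixture()
    def setup(self):
        mask = BrainMask(inclusion=np.ones((8, 6, 4), bool))
        rng = np.random.default_rng(8)
        vol = np.zeros(mask.grid_shape)
        vol[0:2, 0:2, 0:2] = 1.0 + rng.random((2, 2, 2))
        vol[6:8, 4:6, 0:2] = -1.0 - rng.random((2, 2, 2))
        w = mask.vectorize(vol)
        tmap = _make_tmap(w, mask)
        regions = extract_regions(tmap)
        n = 20
        data = rng.standard_normal((n, mask.n_voxels))
        trials = _trial_set(data, np.repeat(["a", "b"], n // 2), mask)
        rrm = rank_normalize(region_trial_responses(regions, trials, tmap.weights))
        sol = cluster_regions(rrm, cut_fraction=0.9)
        return mask, tmap, regions, trials, sol

    def test_remove_plus_only_equals_full_response(self, setup):
        mask, tmap, regions, trials, sol = setup
        labels = np.unique(sol.assignment)
        removed = virtual_lesion(tmap, regions, sol, mode="remove")
        only = virtual_lesion(tmap, regions, sol, mode="only")
        full = pattern_response(tmap.weights, trials)
        for c in labels:
            lhs = (pattern_response(removed[c], trials)
                   + pattern_response(only[c], trials)
                   - tmap.weights.intercept)  # intercept counted once
            assert np.max(np.abs(lhs - full)) < 1e-10

    def test_sum_of_only_responses_equals_full(self, setup):
        mask, tmap, regions, trials, sol = setup
        only = virtual_lesion(tmap, regions, sol, mode="only")
        total = sum(pattern_response(m, trials) - tmap.weights.intercept
                    for m in only.values()) + tmap.weights.intercept
        assert np.allclose(total, pattern_response(tmap.weights, trials),
                           atol=1e-10)

    def test_lesioning_zero_weight_cluster_changes_nothing(self, setup):
        mask, tmap, regions, trials, sol = setup
        # add a spurious region with zero weight as its own cluster
        zero_region = Region(voxel_index=np.array([50]), size=1, sign=0.0,
                             peak_index=50)
        regions2 = regions + [zero_region]
        sol2 = type(sol)(
            linkage_matrix=sol.linkage_matrix, cut_fraction=sol.cut_fraction,
            assignment=np.append(sol.assignment, sol.assignment.max() + 1),
            region_names=sol.region_names + ["region_zz"],
        )
        lesioned = virtual_lesion(tmap, regions2, sol2, mode="remove")
        new_label = sol2.assignment.max()
        assert np.allclose(
            pattern_response(lesioned[new_label], trials),
            pattern_response(tmap.weights, trials),
        )

    def test_unknown_cluster_id_rejected(self, setup):
        from brainsig.subnetworks import lesion_maps

        mask, tmap, regions, trials, sol = setup
        with pytest.raises(ValueError, match="unknown cluster"):
            lesion_maps(tmap, regions, sol, cluster=999)

    def test_lesioning_sole_signal_cluster_drops_accuracy_to_chance(self):
        """One-subnetwork simulation: removing the only signal cluster
        leaves a map that cannot separate high from low ratings."""
        from brainsig.evaluate import single_interval
        from brainsig.simulate import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(grid_shape=(12, 14, 12), n_subjects=16,
                               n_true_regions=1, region_size=40,
                               noise_sd=0.5, seed=30)
        images, _, gt = simulate_dataset(cfg)
        mask = images.mask
        w = gt.true_weights.weights
        tmap = _make_tmap(w, mask)
        regions = extract_regions(tmap)
        assert len(regions) == 1
        from brainsig.subnetworks import ClusterSolution, lesion_maps

        sol = ClusterSolution(
            linkage_matrix=np.zeros((0, 4)), cut_fraction=0.31,
            assignment=np.array([1]), region_names=["region_00"],
        )
        lesioned = lesion_maps(tmap, regions, sol, cluster=1, mode="remove")
        labels = images.rating
        keep = (labels == labels.max()) | (labels == labels.min())
        full_resp = pattern_response(tmap.weights, images)[keep]
        les_resp = pattern_response(lesioned, images)[keep]
        is_high = labels[keep] == labels.max()
        full_acc = single_interval(full_resp, is_high).accuracy
        les_acc = single_interval(les_resp, is_high).accuracy
        assert full_acc > 0.9
        assert abs(les_acc - 0.5) < 0.2
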