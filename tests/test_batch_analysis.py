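"""Stage-2: distance matrix, clustering, cut, validity, ranking, selection."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import random_loop
from oracles import loop_coords, naive_linkage, symdiff_area_scanline

from ligqc import synth
from ligqc.batch_analysis import (ClusterInfo, DistanceMatrix, analyze_batch,
                                  auto_cut_k, cut_clusters, detect_outliers,
                                  hierarchical_cluster, pairwise_distances,
                                  rank_clusters, select_replicates,
                                  valid_clusters)
from ligqc.precheck import precheck_batch


def _dm(values, ids=None):
    values = np.asarray(values, dtype=float)
    return DistanceMatrix(ids or [f"e{i}" for i in range(values.shape[0])], values)


def _random_dm(rng, n):
    v = rng.uniform(1.0, 100.0, size=(n, n))
    v = np.triu(v, 1)
    return _dm(v + v.T)


class TestDistanceMatrix:
    def test_identical_pair_has_zero_off_diagonal(self, rng):
        a = random_loop(rng)
        b = random_loop(rng)
        dm = pairwise_distances([a, a, b], ids=["a1", "a2", "b"])
        assert dm.values[0, 1] == 0.0
        assert dm.values[0, 2] > 0.0

    def test_matrix_is_symmetric_with_zero_diagonal(self, rng):
        dm = pairwise_distances([random_loop(rng) for _ in range(4)],
                                ids=list("abcd"))
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0.0)

    def test_entries_match_scanline_oracle(self, rng):
        loops = [random_loop(rng) for _ in range(5)]
        dm = pairwise_distances(loops, ids=[f"e{i}" for i in range(5)])
        for i in range(5):
            for j in range(i + 1, 5):
                oracle = symdiff_area_scanline(loop_coords(loops[i]),
                                               loop_coords(loops[j]))
                assert dm.values[i, j] == pytest.approx(oracle, rel=5e-3)

    def test_rejected_representative_refused(self, rng):
        with pytest.raises(ValueError, match="precheck"):
            pairwise_distances([random_loop(rng), None])

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            _dm([[0, 1], [2, 0]])

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            _dm([[0, -1], [-1, 0]])


class TestHierarchicalCluster:
    def test_first_merge_is_closest_pair(self):
        dm = _dm([[0, 1, 10], [1, 0, 10], [10, 10, 0]], ids=["A", "B", "C"])
        tree = hierarchical_cluster(dm, "complete")
        assert sorted(tree.Z[0, :2].astype(int).tolist()) == [0, 1]
        assert tree.Z[0, 2] == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["complete", "average", "single"])
    def test_merge_history_matches_naive_oracle(self, rng, method):
        for n in (5, 6, 8):
            dm = _random_dm(rng, n)
            tree = hierarchical_cluster(dm, method)
            oracle = naive_linkage(dm.values, method)
            assert np.allclose(np.sort(tree.Z[:, :2], axis=1),
                               np.sort(oracle[:, :2], axis=1))
            assert tree.Z[:, 2] == pytest.approx(oracle[:, 2])

    def test_complete_and_single_linkage_differ_on_chain(self):
        # chain A-B-C-D: single linkage absorbs the chain early, complete
        # linkage keeps the two tight pairs separate until the very end
        d = np.array([[0.0, 1.0, 3.0, 4.0],
                      [1.0, 0.0, 1.5, 3.5],
                      [3.0, 1.5, 0.0, 1.0],
                      [4.0, 3.5, 1.0, 0.0]])
        dm = _dm(d, ids=list("ABCD"))
        single = hierarchical_cluster(dm, "single")
        complete = hierarchical_cluster(dm, "complete")
        assert single.Z[-1, 2] == pytest.approx(1.5)   # chain link
        assert complete.Z[-1, 2] == pytest.approx(4.0)  # farthest pair

    def test_nan_distance_rejected(self):
        with pytest.raises(ValueError):
            _dm([[0, np.nan], [np.nan, 0]])

    def test_newick_serialization_contains_all_leaves(self):
        dm = _dm([[0, 1, 10], [1, 0, 10], [10, 10, 0]], ids=["A", "B", "C"])
        nwk = hierarchical_cluster(dm).to_newick()
        assert nwk.endswith(";")
        for leaf in "ABC":
            assert leaf in nwk


class TestCutClusters:
    def test_k_equals_n_gives_singletons(self, rng):
        dm = _random_dm(rng, 5)
        tree = hierarchical_cluster(dm)
        labels = cut_clusters(tree, k=5)
        assert len(set(labels.values())) == 5

    def test_k_equals_one_gives_single_cluster(self, rng):
        dm = _random_dm(rng, 5)
        labels = cut_clusters(hierarchical_cluster(dm), k=1)
        assert set(labels.values()) == {1}

    def test_labels_follow_dendrogram_left_to_right(self, rng):
        dm = _random_dm(rng, 6)
        tree = hierarchical_cluster(dm)
        labels = cut_clusters(tree, k=3)
        seen = []
        for leaf in tree.leaf_order():
            lab = labels[tree.ids[leaf]]
            if lab not in seen:
                seen.append(lab)
        assert seen == sorted(seen)

    def test_invalid_k_rejected(self, rng):
        tree = hierarchical_cluster(_random_dm(rng, 4))
        with pytest.raises(ValueError):
            cut_clusters(tree, k=0)
        with pytest.raises(ValueError):
            cut_clusters(tree, k=5)

    def test_auto_cut_finds_planted_group_count(self, separated_templates):
        batch, labels = synth.make_batch(separated_templates, [4, 4, 4],
                                         within_jitter=0.01, seed=5)
        pre = precheck_batch(batch)
        dm = pairwise_distances(pre.representatives(),
                                [r.electrode_id for r in pre.passed])
        assert auto_cut_k(hierarchical_cluster(dm)) == 3


class TestPlantedRecovery:
    @pytest.mark.parametrize("method", ["complete", "average", "single"])
    def test_planted_partition_recovered(self, separated_templates, method):
        batch, truth = synth.make_batch(separated_templates, [4, 4, 4],
                                        within_jitter=0.01, seed=11)
        pre = precheck_batch(batch)
        ids = [r.electrode_id for r in pre.passed]
        dm = pairwise_distances(pre.representatives(), ids)
        labels = cut_clusters(hierarchical_cluster(dm, method), k=3)
        predicted = [labels[i] for i in ids]
        assert adjusted_rand_score(truth, predicted) == 1.0

    def test_assignments_invariant_to_input_permutation(self, separated_templates, rng):
        batch, _ = synth.make_batch(separated_templates, [4, 3, 3],
                                    within_jitter=0.01, seed=13)
        pre = precheck_batch(batch)
        ids = [r.electrode_id for r in pre.passed]
        reps = pre.representatives()

        def partition(order):
            dm = pairwise_distances([reps[i] for i in order],
                                    [ids[i] for i in order])
            labels = cut_clusters(hierarchical_cluster(dm), k=3)
            groups = {}
            for eid, lab in labels.items():
                groups.setdefault(lab, set()).add(eid)
            return frozenset(frozenset(g) for g in groups.values())

        base = partition(list(range(len(ids))))
        for _ in range(3):
            perm = rng.permutation(len(ids)).tolist()
            assert partition(perm) == base


class TestValidityRankingSelection:
    def test_validity_flags_by_size(self):
        assignments = {f"e{i}": lab for i, lab in
                       enumerate([1] * 4 + [2] * 3 + [3] * 2 + [4])}
        feats = {f"e{i}": 1.0 for i in range(10)}
        clusters = valid_clusters(assignments, feats, feats, min_size=3)
        validity = {c.label: c.valid for c in clusters}
        assert validity == {1: True, 2: True, 3: False, 4: False}

    def test_dominating_cluster_ranks_first(self):
        clusters = [
            ClusterInfo(1, ["a", "b", "c"], mean_abc=100.0, mean_peak=150.0, valid=True),
            ClusterInfo(2, ["d", "e", "f"], mean_abc=300.0, mean_peak=400.0, valid=True),
        ]
        assert [c.label for c in rank_clusters(clusters)] == [2, 1]

    def test_rank_sum_tie_broken_by_mean_abc(self):
        clusters = [
            ClusterInfo(1, ["a"] * 3, mean_abc=300.0, mean_peak=100.0, valid=True),
            ClusterInfo(2, ["b"] * 3, mean_abc=100.0, mean_peak=300.0, valid=True),
        ]
        assert [c.label for c in rank_clusters(clusters)] == [1, 2]

    def test_member_drop_keeps_cluster_valid_at_min_size(self):
        ranking = [ClusterInfo(1, ["a", "b", "c", "d"], 100.0, 300.0, True)]
        peaks = {"a": 250.0, "b": 260.0, "c": 240.0, "d": 180.0}
        selection, dropped = select_replicates(ranking, peaks, 200.0, 1, 3)
        assert selection == [1]
        assert dropped == {1: ["d"]}

    def test_member_drop_invalidates_small_cluster(self):
        ranking = [ClusterInfo(1, ["a", "b", "c"], 100.0, 300.0, True),
                   ClusterInfo(2, ["d", "e", "f"], 90.0, 250.0, True)]
        peaks = {"a": 250.0, "b": 260.0, "c": 180.0,
                 "d": 250.0, "e": 230.0, "f": 220.0}
        selection, dropped = select_replicates(ranking, peaks, 200.0, 2, 3)
        assert selection == [2]
        assert dropped == {1: ["c"]}

    def test_partial_selection_when_not_enough_clusters(self):
        ranking = [ClusterInfo(1, ["a", "b", "c"], 100.0, 300.0, True)]
        peaks = {"a": 250.0, "b": 260.0, "c": 240.0}
        selection, _ = select_replicates(ranking, peaks, 200.0, 3, 3)
        assert selection == [1]


class TestOutliers:
    def test_isolated_electrode_flagged(self, separated_templates):
        # one singleton template far from three tight groups
        far = synth.LoopTemplate(capacitive_halfwidth=400.0)
        batch, _ = synth.make_batch(separated_templates + [far], [4, 4, 4, 1],
                                    within_jitter=0.01, seed=17)
        pre = precheck_batch(batch)
        dm = pairwise_distances(pre.representatives(),
                                [r.electrode_id for r in pre.passed])
        tree = hierarchical_cluster(dm)
        assert detect_outliers(tree) == ["E13"]


def test_analyze_batch_selects_top_templates(separated_templates):
    batch, truth = synth.make_batch(separated_templates, [4, 4, 4],
                                    within_jitter=0.01, seed=19)
    pre = precheck_batch(batch)
    report = analyze_batch(pre.representatives(),
                           [r.electrode_id for r in pre.passed], k=3)
    assert len(report.selection) == 3
    # the top-ranked cluster holds the largest-template electrodes (E09-E12)
    top = next(c for c in report.clusters if c.label == report.selection[0])
    assert set(top.members) == {"E09", "E10", "E11", "E12"}
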