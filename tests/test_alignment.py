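"""Clustering, flow-network matching (vs. exhaustive enumeration), pipeline."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage

from gwalign import (AlignConfig, DriftParams, FeatureSet, GWDParams,
                     align, assemble_consensus, build_flow_network,
                     cluster_centroids, generate_chromatogram, match_two,
                     simulate_drift, solve_matching)
from gwalign.alignment import ClusterAssignment, Matching, _scale_cost
from gwalign.transport import DistanceCache

from conftest import make_feature, make_set


# ---------------------------------------------------------------------------
# Exhaustive-enumeration oracles (independent of the flow-network path)
# ---------------------------------------------------------------------------

def brute_force_matching(l_ids, candidates, cluster_of_r, c_int):
    """Minimum total integer cost over all feasible assignments.

    Each L feature takes one of its candidate R features (distinct R, distinct
    clusters) or the trash at cost c_int.  Returns the optimal cost.
    """
    best = [None]

    def rec(i, used_r, used_k, acc):
        if best[0] is not None and acc >= best[0]:
            return
        if i == len(l_ids):
            best[0] = acc if best[0] is None else min(best[0], acc)
            return
        rec(i + 1, used_r, used_k, acc + c_int)  # trash
        for r, cost in candidates.get(l_ids[i], []):
            k = cluster_of_r[r]
            if r in used_r or k in used_k:
                continue
            rec(i + 1, used_r | {r}, used_k | {k}, acc + cost)

    rec(0, frozenset(), frozenset(), 0)
    return best[0]


def random_instance(rng, max_side=5):
    n = int(rng.integers(1, max_side + 1))
    m = int(rng.integers(1, max_side + 1))
    s = int(rng.integers(1, m + 1))
    l_ids = [f"L{i}" for i in range(n)]
    r_keys = [("pool", f"R{j}") for j in range(m)]
    cluster_of_r = {r: int(rng.integers(0, s)) for r in r_keys}
    cache = DistanceCache()
    candidates = {}
    for li in l_ids:
        for r in r_keys:
            if rng.random() < 0.7:
                cost = float(rng.uniform(0, 3))
                cache.entries[(li, r)] = cost
                candidates.setdefault(li, []).append(
                    (r, _scale_cost(cost, 1e4)))
    return l_ids, r_keys, cluster_of_r, cache, candidates


def build_sets(rng, l_ids, r_keys):
    L = FeatureSet(source_id="target", features=[
        make_feature(li, float(rng.uniform(0, 100)), 500.0) for li in l_ids])
    pool = [(make_feature(fid, float(rng.uniform(0, 100)), 500.0), src)
            for src, fid in r_keys]
    return L, pool


class TestSolveMatching:
    def test_diagonal_instance_prefers_cheap_pairs(self):
        cache = DistanceCache()
        cache.entries = {("L0", ("p", "R0")): 1.0, ("L0", ("p", "R1")): 10.0,
                         ("L1", ("p", "R0")): 10.0, ("L1", ("p", "R1")): 1.0}
        clusters = ClusterAssignment(
            labels={("p", "R0"): 0, ("p", "R1"): 1}, s=2)
        rng = np.random.default_rng(0)
        L, pool = build_sets(rng, ["L0", "L1"], [("p", "R0"), ("p", "R1")])
        net = build_flow_network(L, pool, clusters, cache, c=100.0)
        matching = solve_matching(net)
        assert matching.pairs == [("L0", 0), ("L1", 1)]
        assert matching.flow_cost == 2 * 10**4

    def test_cheap_trash_discards_everything(self):
        cache = DistanceCache()
        cache.entries = {("L0", ("p", "R0")): 1.0, ("L0", ("p", "R1")): 10.0,
                         ("L1", ("p", "R0")): 10.0, ("L1", ("p", "R1")): 1.0}
        clusters = ClusterAssignment(
            labels={("p", "R0"): 0, ("p", "R1"): 1}, s=2)
        rng = np.random.default_rng(0)
        L, pool = build_sets(rng, ["L0", "L1"], [("p", "R0"), ("p", "R1")])
        net = build_flow_network(L, pool, clusters, cache, c=0.4)
        matching = solve_matching(net)
        assert matching.pairs == []
        assert sorted(matching.unmatched) == ["L0", "L1"]
        assert matching.flow_cost == 2 * 4000

    def test_swapped_feature_costs_pick_corresponding_pairs(self):
        # dissimilarity structure of an order-swapped pair: corresponding
        # costs (0.3, 80.3), crossed (46.3, 46.3); global optimum takes the
        # corresponding pairs since 80.6 < 92.6
        cache = DistanceCache()
        cache.entries = {("L0", ("p", "R0")): 0.3, ("L0", ("p", "R1")): 46.3,
                         ("L1", ("p", "R0")): 46.3, ("L1", ("p", "R1")): 80.3}
        clusters = ClusterAssignment(
            labels={("p", "R0"): 0, ("p", "R1"): 1}, s=2)
        rng = np.random.default_rng(0)
        L, pool = build_sets(rng, ["L0", "L1"], [("p", "R0"), ("p", "R1")])
        net = build_flow_network(L, pool, clusters, cache, c=1000.0)
        matching = solve_matching(net)
        assert matching.pairs == [("L0", 0), ("L1", 1)]

    def test_optimal_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            l_ids, r_keys, cluster_of_r, cache, candidates = \
                random_instance(rng)
            clusters = ClusterAssignment(
                labels=dict(cluster_of_r),
                s=max(cluster_of_r.values()) + 1)
            L, pool = build_sets(rng, l_ids, r_keys)
            c = float(rng.uniform(0.2, 3.0))
            net = build_flow_network(L, pool, clusters, cache, c=c)
            matching = solve_matching(net)
            expected = brute_force_matching(
                l_ids, candidates, cluster_of_r, _scale_cost(c, 1e4))
            assert matching.flow_cost == expected

    def test_matched_costs_never_exceed_trash_cost(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            l_ids, r_keys, cluster_of_r, cache, _ = random_instance(rng)
            clusters = ClusterAssignment(
                labels=dict(cluster_of_r), s=max(cluster_of_r.values()) + 1)
            L, pool = build_sets(rng, l_ids, r_keys)
            c = 1.5
            net = build_flow_network(L, pool, clusters, cache, c=c)
            matching = solve_matching(net)
            assert all(cost <= c + 1e-9
                       for cost in matching.costs.values())

    def test_feature_without_candidates_is_trashed(self):
        cache = DistanceCache()  # empty: the pair was pruned
        clusters = ClusterAssignment(labels={("p", "R0"): 0}, s=1)
        rng = np.random.default_rng(0)
        L, pool = build_sets(rng, ["L0"], [("p", "R0")])
        net = build_flow_network(L, pool, clusters, cache, c=5.0)
        matching = solve_matching(net)
        assert matching.unmatched == ["L0"]

    def test_integer_cost_rounding(self):
        assert _scale_cost(0.31342, 1e4) == 3134


class TestMatchTwo:
    def test_identical_sets_identity_matching(self):
        specs = [(f"f{i}", 100.0 * i, 500.0 + 10 * i) for i in range(5)]
        a, b = make_set("a", specs), make_set("b", specs)
        pairs = match_two(a, b, GWDParams(lam=50.0), c=90.0)
        assert pairs == [(f"f{i}", f"f{i}") for i in range(5)]

    def test_far_apart_sets_all_unmatched(self):
        a = make_set("a", [("f1", 0.0, 500.0)])
        b = make_set("b", [("g1", 0.0, 900.0)])
        assert match_two(a, b, GWDParams(lam=10.0), c=0.5) == []

    def test_optimal_vs_enumeration(self):
        from gwalign.transport import pairwise_costs
        rng = np.random.default_rng(3)
        for _ in range(20):
            n, m = rng.integers(1, 6, size=2)
            a = make_set("a", [(f"f{i}", float(rng.uniform(0, 30)),
                                float(rng.uniform(500, 504)))
                               for i in range(n)])
            b = make_set("b", [(f"g{j}", float(rng.uniform(0, 30)),
                                float(rng.uniform(500, 504)))
                               for j in range(m)])
            p = GWDParams(lam=20.0)
            c = float(rng.uniform(2, 30))
            pairs = match_two(a, b, p, c)
            cache = pairwise_costs(a, b, p)
            c_int = _scale_cost(c, 1e4)
            candidates = {}
            for (fa, key), cost in cache.entries.items():
                candidates.setdefault(fa, []).append(
                    (key, _scale_cost(cost, 1e4)))
            cluster_of_r = {key: j
                            for j, key in enumerate(
                                sorted({k for _, k in cache.entries}))}
            expected = brute_force_matching(
                [f.id for f in a.features], candidates, cluster_of_r, c_int)
            realized = sum(
                _scale_cost(cache.entries[(fa, ("b", fb))], 1e4)
                for fa, fb in pairs) + c_int * (n - len(pairs))
            assert realized == expected


class TestClusterCentroids:
    def _points(self, arr, src="a"):
        return [(np.asarray(p, dtype=float), src, f"f{i}")
                for i, p in enumerate(arr)]

    def test_two_far_blobs_give_two_pure_clusters(self):
        pts = [[0.0, 0.0]] * 5 + [[100.0, 100.0]] * 5
        ca = cluster_centroids(self._points(pts), AlignConfig(lam=1.0),
                               n_chromatograms=2)
        assert ca.s == 2
        blob1 = {ca.labels[("a", f"f{i}")] for i in range(5)}
        blob2 = {ca.labels[("a", f"f{i}")] for i in range(5, 10)}
        assert len(blob1) == 1 and len(blob2) == 1 and blob1 != blob2

    def test_identical_points_collapse_to_one_cluster(self):
        pts = [[5.0, 5.0]] * 6
        ca = cluster_centroids(self._points(pts), AlignConfig(),
                               n_chromatograms=3)
        assert ca.s == 1

    def test_four_separated_groups_match_single_linkage_and_are_stable(self):
        rng = np.random.default_rng(8)
        centers = np.array([[0, 0], [50, 0], [0, 50], [50, 50]], dtype=float)
        pts = np.concatenate([c + rng.uniform(-0.5, 0.5, size=(5, 2))
                              for c in centers])
        ref = fcluster(linkage(pts, method="single"), t=4.0,
                       criterion="distance")
        partitions = []
        for seed in range(5):
            ca = cluster_centroids(self._points(pts),
                                   AlignConfig(cluster_cut=4.0, seed=seed),
                                   n_chromatograms=4)
            assert ca.s == 4
            labels = [ca.labels[("a", f"f{i}")] for i in range(len(pts))]
            partitions.append(tuple(sorted(
                tuple(sorted(i for i, l in enumerate(labels) if l == k))
                for k in set(labels))))
        # all seeds give the same partition, equal to single-linkage groups
        assert len(set(partitions)) == 1
        ref_partition = tuple(sorted(
            tuple(int(i) for i in np.flatnonzero(ref == k))
            for k in set(ref)))
        assert partitions[0] == ref_partition


class TestAssembleConsensus:
    def test_cluster_matched_by_three_chromatograms(self):
        matchings = [(src, Matching(pairs=[(f"f_{src}", 7)], costs={},
                                    unmatched=[]))
                     for src in ("a", "b", "c")]
        clusters = ClusterAssignment(labels={}, s=8)
        cons = assemble_consensus(matchings, clusters)
        assert len(cons) == 1
        assert cons[0].members == {("a", "f_a"), ("b", "f_b"), ("c", "f_c")}

    def test_trashed_features_appear_nowhere(self):
        matchings = [
            ("a", Matching(pairs=[("f1", 0)], costs={}, unmatched=["f2"])),
            ("b", Matching(pairs=[("g1", 0)], costs={}, unmatched=[])),
        ]
        cons = assemble_consensus(matchings, ClusterAssignment(labels={}, s=1))
        members = set().union(*(c.members for c in cons))
        assert ("a", "f2") not in members

    def test_singleton_clusters_dropped_by_default_kept_on_request(self):
        matchings = [("a", Matching(pairs=[("f1", 0)], costs={},
                                    unmatched=[]))]
        clusters = ClusterAssignment(labels={}, s=1)
        assert assemble_consensus(matchings, clusters) == []
        kept = assemble_consensus(matchings, clusters, keep_singletons=True)
        assert len(kept) == 1


class TestAlignPipeline:
    def test_two_identical_chromatograms(self):
        specs = [(f"f{i}", 100.0 + 60 * i, 450.0 + 20 * i) for i in range(10)]
        a, b = make_set("a", specs), make_set("b", specs)
        consensus, report = align([a, b], AlignConfig(lam=15.0))
        assert len(consensus) == 10
        assert all(len(c.members) == 2 for c in consensus)
        assert report["n_consensus"] == 10

    def test_small_drift_recovers_pairs(self, small_gen_params):
        import dataclasses
        gen = dataclasses.replace(small_gen_params, n_features=100,
                                  rt_max=2000.0)
        original, _ = generate_chromatogram(gen)
        drifted, pairing = simulate_drift(
            original, DriftParams(rt_range=5.0, mz_range=0.01, seed=5))
        consensus, _ = align([original, drifted], AlignConfig())
        got = {tuple(sorted(c.members)) for c in consensus}
        truth = {tuple(sorted([(original.source_id, a),
                               (drifted.source_id, b)]))
                 for a, b in pairing}
        assert len(got & truth) >= 95

    def test_requires_two_sets(self):
        a = make_set("a", [("f1", 0.0, 500.0)])
        with pytest.raises(ValueError, match="at least 2"):
            align([a])

    def test_empty_chromatogram_skipped_with_warning(self, caplog):
        specs = [(f"f{i}", 100.0 + 80 * i, 450.0 + 30 * i) for i in range(5)]
        sets = [make_set(s, specs) for s in ("a", "b", "c")]
        sets.append(FeatureSet(source_id="empty", features=[]))
        with caplog.at_level("WARNING", logger="gwalign"):
            consensus, report = align(sets, AlignConfig(lam=15.0))
        assert "empty" in caplog.text
        assert all(all(src != "empty" for src, _ in c.members)
                   for c in consensus)
        assert any(len(c.members) == 3 for c in consensus)

    def test_order_permutation_changes_few_memberships(self, small_gen_params):
        original, _ = generate_chromatogram(small_gen_params)
        d1, _ = simulate_drift(original, DriftParams(10.0, 0.02, seed=1))
        d2, _ = simulate_drift(original, DriftParams(10.0, 0.02, seed=2))
        d1 = FeatureSet(source_id="d1", features=d1.features)
        d2 = FeatureSet(source_id="d2", features=d2.features)
        cons_a, _ = align([original, d1, d2], AlignConfig())
        cons_b, _ = align([d2, original, d1], AlignConfig())
        sets_a = {frozenset(c.members) for c in cons_a}
        sets_b = {frozenset(c.members) for c in cons_b}
        union = sets_a | sets_b
        changed = len(union - (sets_a & sets_b))
        assert changed <= 0.1 * len(union) + 1
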