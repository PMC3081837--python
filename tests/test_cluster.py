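import itertools

import networkx as nx
import numpy as np
import pytest

from motupipe import (
    CommunityConfig,
    PairDistance,
    build_preclusters,
    cluster_all_cutoffs,
    cluster_records,
    generate_community,
    motu_count_curve,
    name_and_expand,
    single_linkage,
    truth_partition,
    two_tier,
)

from conftest import rec


def pd(a, b, mismatches, overlap=1.0):
    a, b = sorted((a, b))
    return PairDistance(a, b, mismatches, overlap, 100)


def as_dict(pairs):
    return {p.key: p for p in pairs}


def nx_components(ids, distances, cutoff):
    """Independent oracle: connected components of the thresholded graph."""
    g = nx.Graph()
    g.add_nodes_from(ids)
    g.add_edges_from(
        key for key, p in distances.items() if p.mismatches <= cutoff
    )
    return {frozenset(c) for c in nx.connected_components(g)}


class TestSingleLinkage:
    def test_links_at_or_below_cutoff(self):
        d = as_dict([pd("a", "b", 1), pd("b", "c", 5)])
        part = single_linkage(["a", "b", "c"], d, 1)
        assert set(part.clusters) == {frozenset("ab"), frozenset("c")}

    def test_chains_transitively(self):
        d = as_dict([pd("a", "b", 1), pd("b", "c", 5)])
        part = single_linkage(["a", "b", "c"], d, 5)
        assert set(part.clusters) == {frozenset("abc")}

    def test_matches_graph_component_oracle(self):
        rng = np.random.default_rng(21)
        ids = [f"n{i:03d}" for i in range(100)]
        edges = {}
        for a, b in itertools.combinations(ids, 2):
            if rng.random() < 0.02:
                edges[(a, b)] = pd(a, b, int(rng.integers(0, 15)))
        for cutoff in range(11):
            part = single_linkage(ids, edges, cutoff)
            assert set(part.clusters) == nx_components(ids, edges, cutoff)

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError):
            single_linkage(["a"], {}, -1)

    def test_separation_invariant(self):
        """No stored inter-cluster distance may be <= the cutoff."""
        rng = np.random.default_rng(22)
        ids = [f"n{i:02d}" for i in range(40)]
        edges = {}
        for a, b in itertools.combinations(ids, 2):
            if rng.random() < 0.08:
                edges[(a, b)] = pd(a, b, int(rng.integers(0, 12)))
        for cutoff in (0, 3, 8):
            part = single_linkage(ids, edges, cutoff)
            cluster_of = {m: i for i, c in enumerate(part.clusters) for m in c}
            for (a, b), p in edges.items():
                if cluster_of[a] != cluster_of[b]:
                    assert p.mismatches > cutoff


class TestClusterAllCutoffs:
    def test_counts_non_increasing(self):
        d = as_dict([pd("a", "b", 1), pd("b", "c", 5), pd("c", "d", 9)])
        parts = cluster_all_cutoffs(list("abcd"), d, [0, 2, 12], 12)
        counts = [parts[c].motu_count for c in (0, 2, 12)]
        assert counts == sorted(counts, reverse=True)

    def test_cutoff_zero_with_all_distinct(self):
        d = as_dict([pd("a", "b", 1), pd("b", "c", 2)])
        parts = cluster_all_cutoffs(list("abc"), d, [0], 5)
        assert parts[0].motu_count == 3

    def test_cutoff_above_computed_max_rejected(self):
        with pytest.raises(ValueError):
            cluster_all_cutoffs(["a", "b"], {}, [11], 10)

    def test_nesting_refinement(self, small_community):
        _config, records, _truth, _refs = small_community
        parts = cluster_records(records, range(0, 11)).partitions
        for c1, c2 in itertools.pairwise(sorted(parts)):
            coarser = parts[c2].expanded
            for fine in parts[c1].expanded:
                assert sum(fine <= coarse for coarse in coarser) == 1


class TestNameAndExpand:
    def test_names_by_decreasing_expanded_size(self):
        records = [rec("a", "AAAACCCC"), rec("a2", "AAAACCCC"),
                   rec("a3", "AACC"), rec("b", "GGGGTTTT")]
        pcs = build_preclusters(records)
        part = single_linkage(
            [pc.rep_id for pc in pcs], {}, 0
        )
        named = name_and_expand(part, pcs)
        assert named.names == ["0bp_MOTU0001", "0bp_MOTU0002"]
        assert named.expanded[0] == frozenset({"a", "a2", "a3"})
        assert named.expanded[1] == frozenset({"b"})

    def test_singletons_named_in_id_order(self):
        records = [rec(x, base * 4) for x, base in
                   zip("dcba", ("AAAG", "CCCA", "GGGT", "TTTC"))]
        pcs = build_preclusters(records)
        named = name_and_expand(
            single_linkage([pc.rep_id for pc in pcs], {}, 0), pcs
        )
        assert [min(m) for m in named.expanded] == ["a", "b", "c", "d"]

    def test_expanded_sizes_sum_to_input(self, small_community):
        _config, records, _truth, _refs = small_community
        parts = cluster_records(records, [0, 2, 4]).partitions
        for part in parts.values():
            assert sum(part.expanded_sizes()) == len(records)

    def test_missing_precluster_rejected(self):
        part = single_linkage(["ghost"], {}, 0)
        with pytest.raises(KeyError):
            name_and_expand(part, [])


class TestOrderInvariance:
    def test_permutation_gives_identical_names_and_members(self, small_community):
        _config, records, _truth, _refs = small_community
        rng = np.random.default_rng(13)
        shuffled = list(records)
        rng.shuffle(shuffled)
        a = cluster_records(records, [0, 3]).partitions
        b = cluster_records(shuffled, [0, 3]).partitions
        for cutoff in (0, 3):
            assert a[cutoff].names == b[cutoff].names
            assert a[cutoff].expanded == b[cutoff].expanded


class TestMotuCountCurve:
    def test_single_partition(self):
        d = as_dict([pd("a", "b", 1)])
        parts = cluster_all_cutoffs(list("abcde"), d, [2], 2)
        assert motu_count_curve(parts) == [(2, 4)]

    def test_non_increasing_over_range(self, small_community):
        _config, records, _truth, _refs = small_community
        parts = cluster_records(records, range(0, 41)).partitions
        curve = motu_count_curve(parts)
        counts = [n for _c, n in curve]
        assert counts == sorted(counts, reverse=True)

    def test_zero_cutoff_counts_zero_distance_classes(self, small_community):
        """At cutoff 0 the MOTU are the equivalence classes of distance 0."""
        _config, records, _truth, _refs = small_community
        result = cluster_records(records, [0])
        ids = sorted(r.id for r in records)
        oracle = compute_all(records)
        g = nx.Graph()
        g.add_nodes_from(ids)
        g.add_edges_from(k for k, p in oracle.items() if p.mismatches == 0)
        assert result.partitions[0].motu_count == nx.number_connected_components(g)


def compute_all(records):
    from motupipe import compute_distances
    pairs = itertools.combinations(sorted(r.id for r in records), 2)
    return compute_distances(records, pairs, min_overlap=0.90)


class TestTwoTier:
    def test_single_batch_same_cutoffs_degenerates(self, small_community):
        _config, records, _truth, _refs = small_community
        t = 3
        single = cluster_records(records, [t]).partitions[t]
        result = two_tier([records], t, t)
        assert sorted(result.carried_counts.values()) == sorted(
            single.expanded_sizes()
        )

    def test_disjoint_batches_add(self):
        cfg1 = CommunityConfig(n_species=3, reads_per_species=5, seed=31,
                               id_prefix="b1", fragment_fraction=0.0)
        cfg2 = CommunityConfig(n_species=3, reads_per_species=5, seed=32,
                               id_prefix="b2", fragment_fraction=0.0)
        r1, _t1, _ = generate_community(cfg1)
        r2, _t2, _ = generate_community(cfg2)
        result = two_tier([r1, r2], 3, 4)
        per_batch = (
            cluster_records(r1, [4]).partitions[4].motu_count
            + cluster_records(r2, [4]).partitions[4].motu_count
        )
        assert result.partition.motu_count == per_batch
        assert sum(result.carried_counts.values()) == len(r1) + len(r2)

    def test_second_tier_unions_whole_first_tier_motu(self):
        batches = []
        total = 0
        for b in range(3):
            cfg = CommunityConfig(
                n_species=4, reads_per_species=6, seed=41 + b,
                id_prefix=f"batch{b}",
            )
            records, _truth, _refs = generate_community(cfg)
            batches.append(records)
            total += len(records)
        result = two_tier(batches, 3, 4)
        # every second-tier MOTU is a disjoint union of first-tier MOTU
        for i, name in enumerate(result.partition.names):
            reps = result.partition.expanded[i]
            member_sets = [result.first_tier_members[r] for r in reps]
            union = frozenset().union(*member_sets)
            assert sum(len(s) for s in member_sets) == len(union)
            assert result.carried_counts[name] == len(union)
        assert sum(result.carried_counts.values()) == total

    def test_t1_above_t2_rejected(self):
        with pytest.raises(ValueError):
            two_tier([], 5, 3)
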