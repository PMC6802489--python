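"""Bipartite network construction and degree statistics."""

import random

import pytest

from herbnet.errors import InputError, PartitionConflictError
from herbnet.io import InteractionRecord
from herbnet.networks import (
    build_bipartite,
    network_summary,
    nodes_with_min_degree,
    per_herb_disease_counts,
    targets_hit_by_min_herbs,
)


def _edges(pairs, kind="compound-target"):
    return [InteractionRecord(left_id=l, right_id=r, kind=kind) for l, r in pairs]


def _k23():
    return build_bipartite(
        _edges([(c, t) for c in ("c1", "c2") for t in ("t1", "t2", "t3")]),
        "compound", "target",
    )


class TestBuildBipartite:
    def test_complete_k23(self):
        net = _k23()
        summ = network_summary(net)
        assert (summ.n_left, summ.n_right, summ.n_nodes, summ.n_edges) == (2, 3, 5, 6)

    def test_duplicate_pairs_collapse(self):
        net = build_bipartite(_edges([("c1", "t1"), ("c1", "t1")]), "compound", "target")
        assert len(net.edges) == 1
        assert net.degree("c1") == 1

    def test_id_in_both_partitions_is_a_conflict(self):
        with pytest.raises(PartitionConflictError, match="x"):
            build_bipartite(_edges([("x", "t1"), ("c1", "x")]), "compound", "target")

    def test_isolated_nodes_only_when_injected(self):
        net = build_bipartite(_edges([("c1", "t1")]), "compound", "target",
                              extra_left={"lonely"})
        assert "lonely" in net.left
        assert net.degree("lonely") == 0

    def test_kind_mismatch_rejected(self):
        with pytest.raises(InputError, match="kind"):
            build_bipartite(_edges([("t", "d")], kind="target-disease"),
                            "compound", "target")


class TestDegree:
    def test_left_nodes_of_k23_have_degree_three(self):
        net = _k23()
        assert net.degree("c1") == 3 and net.degree("c2") == 3
        assert net.degree("t2") == 2

    def test_unknown_node_is_a_lookup_error(self):
        with pytest.raises(InputError, match="ghost"):
            _k23().degree("ghost")


class TestNetworkSummary:
    def test_empty_network_is_all_zeros(self):
        summ = network_summary(build_bipartite([], "compound", "target"))
        assert (summ.n_left, summ.n_right, summ.n_nodes, summ.n_edges) == (0, 0, 0, 0)

    def test_degree_table_sorted_desc_then_id(self):
        net = build_bipartite(
            _edges([("a", "t1"), ("a", "t2"), ("b", "t1"), ("c", "t1")]),
            "compound", "target",
        )
        table = network_summary(net).degree_table
        assert table[0] == ("t1", 3)
        degrees = [d for _, d in table]
        assert degrees == sorted(degrees, reverse=True)
        assert table == tuple(sorted(table, key=lambda kv: (-kv[1], kv[0])))

    def test_counts_match_brute_force_recount(self, rng):
        pairs = {(f"c{rng.integers(8)}", f"t{rng.integers(12)}") for _ in range(40)}
        net = build_bipartite(_edges(sorted(pairs)), "compound", "target")
        summ = network_summary(net)
        assert summ.n_edges == len(pairs)
        assert summ.n_left == len({c for c, _ in pairs})
        assert summ.n_right == len({t for _, t in pairs})
        for node, deg in summ.degree_table:
            assert deg == sum(1 for p in pairs if node in p)


class TestHandshakeAndOrderIndependence:
    def test_handshake_identity_on_random_graphs(self):
        rnd = random.Random(3)
        for trial in range(30):
            pairs = sorted({
                (f"c{rnd.randrange(10)}", f"t{rnd.randrange(15)}")
                for _ in range(rnd.randrange(1, 60))
            })
            net = build_bipartite(_edges(pairs), "compound", "target")
            left_sum = sum(net.degree(n) for n in net.left)
            right_sum = sum(net.degree(n) for n in net.right)
            assert left_sum == right_sum == len(net.edges)

    def test_shuffled_edge_list_builds_identical_network(self):
        rnd = random.Random(9)
        pairs = [(f"c{i % 5}", f"t{i % 7}") for i in range(25)]
        net_a = build_bipartite(_edges(pairs), "compound", "target")
        shuffled = pairs[:]
        rnd.shuffle(shuffled)
        net_b = build_bipartite(_edges(shuffled), "compound", "target")
        assert net_a.edges == net_b.edges
        assert net_a.left == net_b.left and net_a.right == net_b.right


class TestNodesWithMinDegree:
    def test_k0_returns_whole_partition(self):
        assert set(nodes_with_min_degree(_k23(), "right", 0)) == {"t1", "t2", "t3"}

    def test_right_side_of_k23_has_no_degree_three_node(self):
        assert nodes_with_min_degree(_k23(), "right", 3) == []

    def test_k1_equals_whole_partition_without_isolates(self):
        net = _k23()
        assert set(nodes_with_min_degree(net, "left", 1)) == net.left

    def test_negative_k_rejected(self):
        with pytest.raises(InputError):
            nodes_with_min_degree(_k23(), "left", -1)


class TestPerHerbDiseaseCounts:
    def _ct(self):
        edges = _edges([("c1", "t1"), ("c1", "t2"), ("c2", "t2"), ("c2", "t3")])
        attrs = {"c1": {"herb_ids": ["h1"]}, "c2": {"herb_ids": ["h1"]}}
        return build_bipartite(edges, "compound", "target", node_attrs=attrs)

    def test_hand_enumerated_single_herb_counts(self):
        td = _edges([("t2", "obesity"), ("t3", "obesity")], kind="target-disease")
        counts = per_herb_disease_counts(self._ct(), td)
        by = counts.set_index(["disease", "herb"])["n_targets"]
        assert by[("obesity", "h1")] == 2
        assert by[("obesity", "__total__")] == 2

    def test_disease_with_no_network_targets_has_zero_row(self):
        td = _edges([("ghost", "cancer")], kind="target-disease")
        counts = per_herb_disease_counts(self._ct(), td)
        assert (counts[counts.disease == "cancer"]["n_targets"] == 0).all()

    def test_per_herb_counts_bounded_by_totals(self, small_study):
        from herbnet.pipeline import analyze

        res = analyze(
            small_study.compounds,
            reference_library=small_study.reference_library,
            predictions=list(small_study.predictions),
            disease_annotations=list(small_study.disease_annotations),
        )
        counts = res["herb_disease_counts"]
        n_targets = res["ct_summary"].n_right
        for disease, grp in counts.groupby("disease"):
            total = grp.loc[grp.herb == "__total__", "n_targets"].iloc[0]
            assert total <= n_targets
            assert (grp.loc[grp.herb != "__total__", "n_targets"] <= total).all()

    def test_missing_herb_attribute_is_an_error(self):
        net = build_bipartite(_edges([("c1", "t1")]), "compound", "target")
        with pytest.raises(InputError, match="herb"):
            per_herb_disease_counts(net, _edges([("t1", "obesity")],
                                                kind="target-disease"))


def test_targets_hit_by_min_herbs_alternative_mode():
    edges = _edges([("c1", "t1"), ("c2", "t1"), ("c2", "t2")])
    attrs = {"c1": {"herb_ids": ["h1"]}, "c2": {"herb_ids": ["h2"]}}
    net = build_bipartite(edges, "compound", "target", node_attrs=attrs)
    assert targets_hit_by_min_herbs(net, 2) == ["t1"]
    assert set(targets_hit_by_min_herbs(net, 1)) == {"t1", "t2"}
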