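"""Fold plans, fundamental networks, and the >=7-of-10 stability filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from histone_bn.consensus import (ConsensusNetwork, build_consensus,
                                  consensus_protocol,
                                  learn_fundamental_networks, make_folds)
from histone_bn.correlation import correlation_matrix
from histone_bn.structure import DAGStructure, LearnConfig

from conftest import make_matrix


class TestMakeFolds:
    def test_even_split(self):
        plan = make_folds(100, k=10, seed=1)
        assert np.bincount(plan.assignments).tolist() == [10] * 10

    def test_uneven_split_sizes_differ_by_at_most_one(self):
        plan = make_folds(105, k=10, seed=1)
        counts = sorted(np.bincount(plan.assignments).tolist())
        assert counts == [10] * 5 + [11] * 5

    def test_same_seed_identical_assignments(self):
        assert make_folds(57, seed=4).assignments == \
            make_folds(57, seed=4).assignments

    def test_different_seed_differs(self):
        assert make_folds(100, seed=1).assignments != \
            make_folds(100, seed=2).assignments

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            make_folds(9, k=10, seed=0)

    def test_holdout_mask_excludes_exactly_one_fold(self):
        plan = make_folds(50, k=10, seed=3)
        mask = plan.holdout_mask(0)
        assert mask.sum() == 45
        assert all(plan.assignments[i] != 0 for i in np.flatnonzero(mask))


class TestFundamentalNetworks:
    def test_copy_edge_found_in_all_ten_networks(self, copy_pair_matrix):
        plan = make_folds(copy_pair_matrix.n_samples, seed=5)
        nets = learn_fundamental_networks(copy_pair_matrix, plan)
        assert len(nets) == 10
        pair = frozenset({"A", "B"})
        for net in nets:
            assert net.is_acyclic()
            assert pair in net.skeleton()

    def test_deterministic_given_data_folds_config(self, copy_pair_matrix):
        plan = make_folds(copy_pair_matrix.n_samples, seed=6)
        a = learn_fundamental_networks(copy_pair_matrix, plan)
        b = learn_fundamental_networks(copy_pair_matrix, plan)
        assert [n.edges for n in a] == [n.edges for n in b]

    def test_mismatched_fold_plan_rejected(self, copy_pair_matrix):
        with pytest.raises(ValueError, match="fold plan"):
            learn_fundamental_networks(copy_pair_matrix, make_folds(99, seed=0))


def nets_with_edge_in(k, n=10, nodes=("A", "B", "C")):
    """k networks containing A->B, the rest empty."""
    out = []
    for i in range(n):
        edges = {("A", "B")} if i < k else set()
        out.append(DAGStructure(nodes, edges))
    return out


class TestBuildConsensus:
    def test_edge_in_seven_of_ten_retained(self):
        net = build_consensus(nets_with_edge_in(7), threshold=7)
        assert net.skeleton() == frozenset({frozenset({"A", "B"})})
        assert net.edges[0].stability_count == 7

    def test_edge_in_six_of_ten_dropped(self):
        net = build_consensus(nets_with_edge_in(6), threshold=7)
        assert net.n_edges == 0

    def test_unanimity_reproduces_the_common_network(self):
        dag = DAGStructure(["A", "B", "C"], {("A", "B"), ("B", "C")})
        net = build_consensus([dag] * 10, threshold=7)
        assert net.to_dag().edges == dag.edges
        assert all(e.stability_count == 10 for e in net.edges)

    def test_direction_resolved_by_majority(self):
        nets = ([DAGStructure(["A", "B"], {("A", "B")})] * 6
                + [DAGStructure(["A", "B"], {("B", "A")})] * 4)
        net = build_consensus(nets, threshold=7)
        assert net.n_edges == 1
        edge = net.edges[0]
        assert (edge.parent, edge.child) == ("A", "B")
        assert edge.stability_count == 10
        assert edge.directed_counts == (6, 4)
        assert not edge.direction_tie

    def test_direction_tie_goes_lexicographic_and_is_flagged(self):
        nets = ([DAGStructure(["B", "A"], {("A", "B")})] * 5
                + [DAGStructure(["B", "A"], {("B", "A")})] * 5)
        net = build_consensus(nets, threshold=7)
        edge = net.edges[0]
        assert (edge.parent, edge.child) == ("A", "B")
        assert edge.direction_tie

    def test_correlation_sign_annotation(self, copy_pair_matrix):
        cm = correlation_matrix(copy_pair_matrix)
        net = build_consensus(nets_with_edge_in(10, nodes=("A", "B")),
                              threshold=7, cm=cm)
        assert net.edges[0].correlation_sign == "+"
        assert net.edges[0].correlation_value == pytest.approx(1.0)

    def test_majority_cycle_is_repaired_and_flagged(self):
        # directed majorities A->B (7), B->C (7), C->A (6) form a cycle even
        # though every input network is acyclic
        t1 = DAGStructure("ABC", {("A", "B"), ("B", "C"), ("A", "C")})
        t2 = DAGStructure("ABC", {("B", "C"), ("C", "A"), ("B", "A")})
        t3 = DAGStructure("ABC", {("C", "A"), ("A", "B"), ("C", "B")})
        net = build_consensus([t1] * 4 + [t2] * 3 + [t3] * 3, threshold=7)
        assert net.to_dag().is_acyclic()
        assert net.skeleton() == frozenset(
            {frozenset("AB"), frozenset("BC"), frozenset({"C", "A"})})
        assert any(e.cycle_repaired for e in net.edges) or net.dropped_cycle_edges

    def test_mismatched_node_sets_rejected(self):
        with pytest.raises(ValueError, match="node set"):
            build_consensus([DAGStructure(["A", "B"], set()),
                             DAGStructure(["A", "C"], set())], threshold=1)

    def test_threshold_outside_range_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            build_consensus(nets_with_edge_in(5), threshold=11)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_raising_threshold_never_adds_edges(self, seed):
        rng = np.random.default_rng(seed)
        nodes = ("A", "B", "C", "D")
        pool = [(u, v) for u in nodes for v in nodes if u < v]
        nets = []
        for _ in range(10):
            chosen = [pool[i] for i in rng.choice(len(pool), size=3,
                                                  replace=False)]
            nets.append(DAGStructure(nodes, set(chosen)))
        prev = None
        for t in range(1, 11):
            skel = build_consensus(nets, threshold=t).skeleton()
            if prev is not None:
                assert skel <= prev
            prev = skel


class TestConsensusProtocol:
    def test_full_protocol_recovers_copy_edge(self, copy_pair_matrix):
        net, fundamentals, plans = consensus_protocol(
            copy_pair_matrix, threshold=7, seed=2)
        assert len(fundamentals) == 10 and len(plans) == 1
        assert net.skeleton() == frozenset({frozenset({"A", "B"})})
        assert net.edges[0].correlation_sign == "+"

    def test_multi_round_pools_networks_with_scaled_threshold(self, copy_pair_matrix):
        net, fundamentals, plans = consensus_protocol(
            copy_pair_matrix, threshold=7, seed=2, n_rounds=2)
        assert len(fundamentals) == 20 and len(plans) == 2
        assert net.threshold == 14
        assert net.skeleton() == frozenset({frozenset({"A", "B"})})
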