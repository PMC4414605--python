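"""Balanced partitioning: greedy rule, components, graph atomicity."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from dispatchmap.io_formats import TargetSeq
from dispatchmap.partition import (
    AdjacencyGraph,
    MalformedGraphError,
    best_fit_decreasing,
    connected_components,
    plan_partitions,
    read_manifest,
    write_partition_fastas,
)
from dispatchmap.io_formats import read_fasta


def optimal_makespan(weights, P):
    """Exhaustive oracle over all P^n assignments."""
    best = sum(weights)
    for assign in itertools.product(range(P), repeat=len(weights)):
        loads = [0] * P
        for w, p in zip(weights, assign):
            loads[p] += w
        best = min(best, max(loads))
    return best


class TestBestFitDecreasing:
    def test_single_bin(self):
        plan = best_fit_decreasing([("c1", 100)], 1)
        assert plan.assignment == {"c1": 0}
        assert plan.loads == [100]

    def test_equal_weights_spread_one_per_partition(self):
        items = [(f"c{i}", 10) for i in range(4)]
        plan = best_fit_decreasing(items, 4)
        assert sorted(plan.assignment.values()) == [0, 1, 2, 3]
        assert plan.loads == [10, 10, 10, 10]

    def test_hand_simulated_greedy(self):
        # decreasing weights 9,7,6,5,4,3 into 3 partitions:
        # 9->p0, 7->p1, 6->p2, 5->p2(11), 4->p1(11), 3->p0(12)
        items = list(zip("abcdef", [9, 7, 6, 5, 4, 3]))
        plan = best_fit_decreasing(items, 3)
        assert sorted(plan.loads) == [11, 11, 12]
        assert plan.assignment["a"] == plan.assignment["f"]  # 9 with 3
        assert plan.assignment["b"] == plan.assignment["e"]  # 7 with 4
        assert plan.assignment["c"] == plan.assignment["d"]  # 6 with 5
        assert plan.makespan() == optimal_makespan([9, 7, 6, 5, 4, 3], 3)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            best_fit_decreasing([("a", 1)], 0)
        with pytest.raises(ValueError):
            best_fit_decreasing([("a", 0)], 1)
        with pytest.raises(ValueError):
            best_fit_decreasing([("a", 1), ("a", 2)], 1)

    def test_empty_items(self):
        plan = best_fit_decreasing([], 3)
        assert plan.loads == [0, 0, 0]

    @given(
        weights=st.lists(st.integers(1, 1000), min_size=1, max_size=20),
        P=st.integers(1, 6),
    )
    @settings(deadline=None)
    def test_conservation_and_determinism(self, weights, P):
        items = [(f"t{i:03d}", w) for i, w in enumerate(weights)]
        plan = best_fit_decreasing(items, P)
        assert set(plan.assignment) == {i for i, _ in items}
        assert sum(plan.loads) == sum(weights)
        for p in range(P):
            assert plan.loads[p] == sum(w for i, w in items if plan.assignment[i] == p)
        again = best_fit_decreasing(list(reversed(items)), P)
        assert again.assignment == plan.assignment

    @given(
        weights=st.lists(st.integers(1, 50), min_size=1, max_size=8),
        P=st.integers(1, 3),
    )
    @settings(deadline=None, max_examples=40)
    def test_lpt_style_makespan_guarantee(self, weights, P):
        """Greedy makespan is within 4/3 of the exhaustive optimum."""
        items = [(f"t{i}", w) for i, w in enumerate(weights)]
        plan = best_fit_decreasing(items, P)
        assert plan.makespan() * 3 <= 4 * optimal_makespan(weights, P)


class TestConnectedComponents:
    def brute_components(self, nodes, edges):
        """Oracle: transitive closure by repeated merging."""
        comps = [{n} for n in nodes]
        changed = True
        while changed:
            changed = False
            for e in edges:
                u, v = tuple(e)
                cu = next(c for c in comps if u in c)
                cv = next(c for c in comps if v in c)
                if cu is not cv:
                    comps.remove(cv)
                    cu.update(cv)
                    changed = True
        return sorted(comps, key=min)

    def test_no_edges(self):
        g = AdjacencyGraph(nodes={"a", "b", "c"})
        assert connected_components(g) == [{"a"}, {"b"}, {"c"}]

    def test_chain(self):
        g = AdjacencyGraph(
            nodes={"a", "b", "c"},
            edges={frozenset("ab"), frozenset("bc")},
        )
        assert connected_components(g) == [{"a", "b", "c"}]

    def test_two_pairs_matches_brute_force(self):
        nodes = {"a", "b", "c", "d"}
        edges = {frozenset("ab"), frozenset("cd")}
        g = AdjacencyGraph(nodes=nodes, edges=edges)
        assert connected_components(g) == self.brute_components(nodes, edges)
        assert connected_components(g) == [{"a", "b"}, {"c", "d"}]

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(MalformedGraphError):
            AdjacencyGraph(nodes={"a"}, edges={frozenset(("a", "zz"))})

    @given(
        n=st.integers(1, 12),
        edge_idx=st.lists(st.tuples(st.integers(0, 11), st.integers(0, 11)), max_size=20),
    )
    @settings(deadline=None, max_examples=100)
    def test_random_graphs_match_brute_force(self, n, edge_idx):
        nodes = {f"n{i}" for i in range(n)}
        edges = {
            frozenset((f"n{u % n}", f"n{v % n}"))
            for u, v in edge_idx
            if u % n != v % n
        }
        g = AdjacencyGraph(nodes=nodes, edges=edges)
        assert connected_components(g) == self.brute_components(nodes, edges)


class TestPlanPartitions:
    def targets(self, spec):
        return [TargetSeq(i, "A" * w) for i, w in spec]

    def test_no_graph_reduces_to_bfd(self):
        spec = [("a", 40), ("b", 30), ("c", 20), ("d", 10)]
        plan = plan_partitions(self.targets(spec), 2)
        assert plan.assignment == best_fit_decreasing(spec, 2).assignment

    def test_component_copartitioned(self):
        ts = self.targets([("a", 50), ("b", 50), ("c", 60)])
        g = AdjacencyGraph(nodes={"a", "b"}, edges={frozenset("ab")})
        plan = plan_partitions(ts, 2, g)
        assert plan.assignment["a"] == plan.assignment["b"]
        assert plan.assignment["c"] != plan.assignment["a"]
        assert sorted(plan.loads) == [60, 100]

    def test_unknown_graph_node_fails_loudly(self):
        ts = self.targets([("a", 10)])
        g = AdjacencyGraph(nodes={"a", "ghost"}, edges=set())
        with pytest.raises(MalformedGraphError):
            plan_partitions(ts, 2, g)

    def test_more_partitions_than_items_warns_and_leaves_empty(self, caplog):
        ts = self.targets([("a", 10), ("b", 20)])
        with caplog.at_level("WARNING"):
            plan = plan_partitions(ts, 4)
        assert sum(l == 0 for l in plan.loads) == 2
        assert sum(plan.loads) == 30

    @given(
        n=st.integers(1, 10),
        edge_idx=st.lists(st.tuples(st.integers(0, 9), st.integers(0, 9)), max_size=15),
        lengths=st.lists(st.integers(1, 100), min_size=10, max_size=10),
        P=st.integers(1, 4),
    )
    @settings(deadline=None, max_examples=150)
    def test_graph_edges_never_split(self, n, edge_idx, lengths, P):
        ts = self.targets([(f"n{i}", lengths[i]) for i in range(n)])
        edges = {
            frozenset((f"n{u % n}", f"n{v % n}"))
            for u, v in edge_idx
            if u % n != v % n
        }
        g = AdjacencyGraph(nodes={t.id for t in ts}, edges=edges)
        plan = plan_partitions(ts, P, g)
        for e in edges:
            u, v = tuple(e)
            assert plan.assignment[u] == plan.assignment[v]
        assert sum(plan.loads) == sum(t.length for t in ts)


class TestPartitionFiles:
    def test_fasta_and_manifest_round_trip(self, tmp_path):
        ts = [TargetSeq("a", "ACGT" * 5), TargetSeq("b", "TTTT"), TargetSeq("c", "GGCC")]
        plan = plan_partitions(ts, 2)
        paths = write_partition_fastas(ts, plan, tmp_path)
        # conservation: union of partition FASTAs == input records
        recs = [r for p in paths for r in read_fasta(p)]
        assert sorted((r.id, r.seq) for r in recs) == sorted((t.id, t.seq) for t in ts)
        # each partition holds exactly its assigned targets
        for p, path in enumerate(paths):
            assert [r.id for r in read_fasta(path)] == [
                t.id for t in ts if plan.assignment[t.id] == p
            ]
        reloaded, rows = read_manifest(tmp_path / "partitions.tsv")
        assert reloaded.assignment == plan.assignment
        assert reloaded.loads == plan.loads
        assert [r[0] for r in rows] == [t.id for t in ts]

    def test_single_partition_preserves_input(self, tmp_path):
        ts = [TargetSeq("x", "ACGTACGT"), TargetSeq("y", "CCCC")]
        plan = plan_partitions(ts, 1)
        (path,) = write_partition_fastas(ts, plan, tmp_path)
        assert [(r.id, r.seq) for r in read_fasta(path)] == [(t.id, t.seq) for t in ts]
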