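"""Directed graph construction, dead-end removal, st search, intervals and
subpath-constraint derivation."""

import networkx as nx
import pytest

from phagepaths.annotations import UnitigAnnotation
from phagepaths.components import Case, PhageComponent
from phagepaths.flow_model import (
    ConstraintOrigin,
    DirectedComponentGraph,
    UnresolvableComponent,
    build_directed_graph,
    build_flow_network,
    derive_subpath_constraints,
    find_st_vertex,
    remove_dead_ends,
    SOURCE,
    SINK,
)
from phagepaths.graph_io import AssemblyGraph, EdgeEvidence, OrientedLink, Unitig


def dcg(arcs, lengths=None, coverages=None):
    """DirectedComponentGraph from arc list [(u, v)] with optional attrs."""
    g = nx.DiGraph()
    verts = {v for a in arcs for v in a}
    coverages = coverages or {v: 10.0 for v in verts}
    lengths = lengths or {v: 1000 for v in verts}
    g.add_nodes_from(verts)
    for u, v in arcs:
        g.add_edge(u, v, we=min(coverages[u], coverages[v]),
                   orients=("+", "+"), overlap=0)
    return DirectedComponentGraph(digraph=g, lengths=lengths, coverages=coverages)


FIG3_ARCS = [("1", "2"), ("2", "3"), ("2", "4"), ("3", "1"),
             ("4", "1"), ("1", "5"), ("5", "1")]


class TestBuildDirectedGraph:
    def test_weight_is_minimum_endpoint_coverage(self, figure3):
        ann_comp = PhageComponent(
            "0", tuple(sorted(figure3.graph.unitigs)), Case.CASE3, 9.0
        )
        g = build_directed_graph(ann_comp, figure3.graph)
        assert g.digraph.edges["2", "3"]["we"] == 4.0  # min(cov 8, cov 4)
        assert sorted(g.digraph.edges) == sorted(FIG3_ARCS)

    def test_equal_coverages_give_that_weight(self):
        g = dcg([("a", "b")], coverages={"a": 7.0, "b": 7.0})
        assert g.digraph.edges["a", "b"]["we"] == 7.0

    def test_weight_symmetric_for_twin_direction(self):
        g = dcg([("a", "b"), ("b", "a")], coverages={"a": 3.0, "b": 9.0})
        assert g.we("a", "b") == g.we("b", "a") == 3.0


class TestRemoveDeadEnds:
    def test_stub_removed(self):
        g = dcg([("1", "2"), ("2", "3"), ("3", "1"), ("3", "4")])
        out = remove_dead_ends(g)
        assert set(out.digraph.nodes) == {"1", "2", "3"}

    def test_cascading_chain_removed(self):
        g = dcg([("1", "2"), ("2", "3"), ("3", "1"), ("3", "4"), ("4", "5")])
        out = remove_dead_ends(g)
        assert set(out.digraph.nodes) == {"1", "2", "3"}

    def test_pure_cycle_unchanged_and_idempotent(self):
        g = dcg([("1", "2"), ("2", "1")])
        once = remove_dead_ends(g)
        twice = remove_dead_ends(once)
        assert sorted(once.digraph.edges) == sorted(g.digraph.edges)
        assert sorted(twice.digraph.edges) == sorted(once.digraph.edges)

    def test_result_has_no_dead_ends(self):
        g = dcg([("1", "2"), ("2", "3"), ("3", "1"), ("3", "4"), ("0", "1")])
        out = remove_dead_ends(g).digraph
        assert min(d for _, d in out.in_degree()) >= 1
        assert min(d for _, d in out.out_degree()) >= 1

    def test_emptied_graph_raises(self):
        g = dcg([("1", "2"), ("2", "3")])  # a pure chain: everything dies
        with pytest.raises(UnresolvableComponent):
            remove_dead_ends(g)


class TestFindStVertex:
    def test_worked_example_layering(self):
        """In the five-unitig example the BFS from vertex 1 ends at layer
        {3, 4}, whose successors are all {1}, so 1 is the st vertex."""
        lengths = {"1": 4000, "2": 3000, "3": 2500, "4": 2600, "5": 3500}
        g = dcg(FIG3_ARCS, lengths=lengths)
        assert find_st_vertex(g) == "1"

    def test_tie_broken_by_unitig_length(self):
        g = dcg([("a", "b"), ("b", "a")], lengths={"a": 10000, "b": 1000})
        assert find_st_vertex(g) == "a"
        g2 = dcg([("a", "b"), ("b", "a")], lengths={"a": 1000, "b": 10000})
        assert find_st_vertex(g2) == "b"

    def test_dag_with_true_sink_has_no_st(self):
        g = dcg([("a", "b"), ("b", "c")])
        assert find_st_vertex(g) is None

    def test_invariant_under_relabelling(self):
        lengths = {"1": 4000, "2": 3000, "3": 2500, "4": 2600, "5": 3500}
        ren = {"1": "x9", "2": "x3", "3": "x5", "4": "x1", "5": "x7"}
        arcs = [(ren[u], ren[v]) for u, v in FIG3_ARCS]
        g = dcg(arcs, lengths={ren[k]: v for k, v in lengths.items()})
        assert find_st_vertex(g) == ren["1"]


class TestBuildFlowNetwork:
    def test_interval_from_worked_example(self):
        """we = 4 with alpha = 1.2 and covmax = 9 gives the interval [4, 10]."""
        g = dcg(FIG3_ARCS, coverages={"1": 9.0, "2": 8.0, "3": 4.0, "4": 6.0, "5": 2.0})
        net = build_flow_network(g, "1", alpha=1.2, covmax=9)
        assert net.lower("2", "3") == 4
        assert net.upper("2", "3") == 10

    def test_degenerate_exact_flow_at_alpha_one(self):
        g = dcg([("a", "b"), ("b", "a")], coverages={"a": 7.0, "b": 7.0})
        net = build_flow_network(g, "a", alpha=1.0)
        assert net.lower(SOURCE, "b") == net.upper(SOURCE, "b") == 7

    def test_zero_weight_arc_allowed(self):
        g = dcg([("a", "b"), ("b", "a")], coverages={"a": 0.0, "b": 5.0})
        net = build_flow_network(g, "a", covmax=5.0)
        assert net.lower(SOURCE, "b") == 0
        assert net.upper(SOURCE, "b") == 6

    def test_lower_never_exceeds_upper_when_alpha_ge_one(self):
        g = dcg(FIG3_ARCS, coverages={"1": 9.0, "2": 8.0, "3": 4.0, "4": 6.0, "5": 2.0})
        for alpha in (1.0, 1.2, 2.0):
            net = build_flow_network(g, "1", alpha=alpha)
            assert all(net.lower(u, v) <= net.upper(u, v) for u, v in net.arcs())

    def test_st_split_has_clean_source_and_sink(self):
        g = dcg(FIG3_ARCS)
        net = build_flow_network(g, "1")
        assert net.digraph.in_degree(SOURCE) == 0
        assert net.digraph.out_degree(SINK) == 0
        assert nx.is_directed_acyclic_graph(net.digraph)

    def test_residual_cycle_raises(self):
        # cycle 2<->3 survives the split at 1
        g = dcg([("1", "2"), ("2", "3"), ("3", "2"), ("3", "1")])
        with pytest.raises(UnresolvableComponent):
            build_flow_network(g, "1")


class TestSubpathConstraints:
    def make(self, ce=None, cp=None):
        ev = EdgeEvidence()
        for (u, v), c in (ce or {}).items():
            ev.add_pair(u, v, c)
        for (t, u, v), c in (cp or {}).items():
            ev.add_triple(t, u, v, c)
        return ev

    def test_pair_constraint_at_mincov(self):
        g = dcg([("2", "3"), ("3", "2")])
        cons = derive_subpath_constraints(
            g, self.make(ce={("2", "3"): 10}), mincov=10, covtolerance=0
        )
        assert (("2", "3"), ConstraintOrigin.PAIR_EVIDENCE) in [
            (c.vertex_list, c.origin) for c in cons
        ]

    def test_pair_below_mincov_excluded(self):
        g = dcg([("2", "3"), ("3", "2")])
        cons = derive_subpath_constraints(
            g, self.make(ce={("2", "3"): 9}), mincov=10, covtolerance=0
        )
        assert not any(c.origin is ConstraintOrigin.PAIR_EVIDENCE for c in cons)

    def test_balanced_coverage_adds_triple_without_read_support(self):
        g = dcg(
            [("t", "u"), ("u", "v"), ("v", "t")],
            coverages={"t": 50.0, "u": 60.0, "v": 60.0},
        )
        # |we(t,u) - we(u,v)| = |50 - 60| = 10 < 100
        cons = derive_subpath_constraints(g, self.make(), mincov=10, covtolerance=100)
        assert (("t", "u", "v"), ConstraintOrigin.COVERAGE_BALANCE) in [
            (c.vertex_list, c.origin) for c in cons
        ]

    def test_triple_through_st_vertex_dropped(self):
        g = dcg([("t", "u"), ("u", "v"), ("v", "t")])
        cons = derive_subpath_constraints(g, self.make(), mincov=10,
                                          covtolerance=100, st="u")
        assert ("t", "u", "v") not in [c.vertex_list for c in cons]

    def test_monotone_in_evidence(self):
        """Adding read pairs never removes a constraint."""
        g = dcg(FIG3_ARCS)
        base = self.make(ce={("2", "3"): 10})
        more = self.make(ce={("2", "3"): 10, ("2", "4"): 12}, cp={("1", "2", "3"): 15})
        c1 = {c.vertex_list for c in derive_subpath_constraints(g, base, 10, 0)}
        c2 = {c.vertex_list for c in derive_subpath_constraints(g, more, 10, 0)}
        assert c1 <= c2
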