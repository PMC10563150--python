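"""Turn a branching phage component into a source-sink inexact flow network.

The pipeline for a multi-unitig (Case 3) component is:

1. ``build_directed_graph`` — one arc per GFA link, weighted by the minimum
   of the endpoint unitigs' mean coverages (``we``).
2. ``remove_dead_ends`` — recursively strip vertices with no incoming or no
   outgoing arcs so every remaining path closes into a cycle.
3. ``find_st_vertex`` — locate a vertex common to all cyclic paths via
   breadth-first layering; it is split into source ``s`` and sink ``t``.
4. ``build_flow_network`` — assign each arc the flow interval
   [⌊we⌋, ⌊α·covmax⌋] where covmax is the maximum unitig coverage among the
   surviving vertices and α ≥ 1 relaxes the upper bound.
5. ``derive_subpath_constraints`` — short paths (pairs/triples of unitigs)
   that paired-end evidence or coverage balance says must appear inside at
   least one decomposed genome.

Coverage is not conserved exactly in real data (uneven sequencing depth), so
edges carry intervals instead of exact flow values; the decomposition solver
then finds the fewest weighted s-t paths whose superposition fits every
interval.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .components import PhageComponent
from .graph_io import AssemblyGraph, EdgeEvidence, OrientedLink

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 1.2  # coverage multiplier for the interval upper bound
DEFAULT_MINCOV = 10  # minimum spanning read pairs for an evidence constraint
DEFAULT_COVTOLERANCE = 100.0  # max |we difference| for coverage-balance triples

#: Sentinel vertex names for the split source/sink.
SOURCE = "__source__"
SINK = "__sink__"


class UnresolvableComponent(Exception):
    """The component cannot be modelled as a flow network; reason in args."""


class ConstraintOrigin(enum.Enum):
    PAIR_EVIDENCE = "pair_evidence"
    TRIPLE_EVIDENCE = "triple_evidence"
    COVERAGE_BALANCE = "coverage_balance"


@dataclass(frozen=True)
class SubpathConstraint:
    """A 2- or 3-vertex path that must be a subpath of some decomposed path."""

    vertex_list: Tuple[str, ...]
    origin: ConstraintOrigin

    def arcs(self) -> List[Tuple[str, str]]:
        return list(zip(self.vertex_list, self.vertex_list[1:]))


@dataclass
class DirectedComponentGraph:
    """Unitig-level digraph of one component with edge weights ``we``.

    Each GFA link becomes a single arc in its written direction; the arc
    carries the orientation pair (d1, d2) and the overlap, and stands for the
    link together with its reverse-complement twin.  The weight of an arc is
    min(coverage(u), coverage(v)), identical for both traversal senses of the
    junction.
    """

    digraph: nx.DiGraph
    lengths: Dict[str, int]
    coverages: Dict[str, float]

    def we(self, u: str, v: str) -> float:
        return min(self.coverages[u], self.coverages[v])

    @property
    def vertices(self) -> List[str]:
        return list(self.digraph.nodes)

    def covmax(self) -> float:
        return max(self.coverages[v] for v in self.digraph.nodes)


@dataclass
class InexactFlowNetwork:
    """DAG from ``s`` to ``t`` with per-arc integer flow intervals."""

    digraph: nx.DiGraph  # arc attrs: lower, upper, we, orients, overlap
    st_vertex: str
    alpha: float
    covmax: float
    source: str = SOURCE
    sink: str = SINK

    def arcs(self) -> List[Tuple[str, str]]:
        return list(self.digraph.edges)

    def lower(self, u: str, v: str) -> int:
        return self.digraph.edges[u, v]["lower"]

    def upper(self, u: str, v: str) -> int:
        return self.digraph.edges[u, v]["upper"]


def build_directed_graph(
    component: PhageComponent, graph: AssemblyGraph
) -> DirectedComponentGraph:
    """Unitig-level digraph for a component, weighted by minimum coverage."""
    members = set(component.unitig_ids)
    dg = nx.DiGraph()
    dg.add_nodes_from(component.unitig_ids)
    for link in graph.links:
        if link.from_id not in members or link.to_id not in members:
            continue
        u, v = link.from_id, link.to_id
        w = min(graph.coverage(u), graph.coverage(v))
        if dg.has_edge(u, v):
            logger.debug("parallel link %s->%s; keeping first orientation pair", u, v)
            continue
        dg.add_edge(
            u,
            v,
            we=w,
            orients=(link.from_orient, link.to_orient),
            overlap=link.overlap_bp,
        )
    return DirectedComponentGraph(
        digraph=dg,
        lengths={uid: graph.length(uid) for uid in component.unitig_ids},
        coverages={uid: graph.coverage(uid) for uid in component.unitig_ids},
    )


def remove_dead_ends(g: DirectedComponentGraph) -> DirectedComponentGraph:
    """Recursively remove vertices with no incoming or no outgoing arcs.

    Removing a dead-end can expose another, so removal iterates to a
    fixpoint.  Raises :class:`UnresolvableComponent` if nothing survives.
    """
    dg = g.digraph.copy()
    removed: List[str] = []
    while True:
        dead = [v for v in dg.nodes if dg.in_degree(v) == 0 or dg.out_degree(v) == 0]
        if not dead:
            break
        dg.remove_nodes_from(dead)
        removed.extend(dead)
    if removed:
        logger.info("removed %d dead-end unitig(s): %s", len(removed), sorted(removed))
    if dg.number_of_nodes() == 0:
        raise UnresolvableComponent("dead-end removal emptied the component")
    return DirectedComponentGraph(
        digraph=dg,
        lengths={v: g.lengths[v] for v in dg.nodes},
        coverages={v: g.coverages[v] for v in dg.nodes},
    )


def find_st_vertex(g: DirectedComponentGraph) -> Optional[str]:
    """Vertex common to the cyclic paths, found by breadth-first layering.

    For each candidate start vertex the BFS layer iterator is computed; the
    candidate qualifies when every vertex in the final layer has its
    successor set equal to {candidate}, i.e. all paths close back onto it.
    Candidates are tried from the longest unitig down (ties broken by id), so
    the first qualifier is the longest qualifying unitig.
    """
    dg = g.digraph
    candidates = sorted(dg.nodes, key=lambda v: (-g.lengths[v], v))
    for cand in candidates:
        layers = list(nx.bfs_layers(dg, cand))
        last = layers[-1]
        if all(set(dg.successors(v)) == {cand} for v in last):
            return cand
    return None


def build_flow_network(
    g: DirectedComponentGraph,
    st: str,
    alpha: float = DEFAULT_ALPHA,
    covmax: Optional[float] = None,
) -> InexactFlowNetwork:
    """Split ``st`` into source and sink and assign flow intervals.

    Every arc gets lower = ⌊we⌋ and upper = ⌊alpha × covmax⌋.  ``covmax``
    defaults to the maximum coverage among the (dead-end-free) component's
    unitigs.  The result must be a DAG; residual cycles avoiding s/t mean the
    component cannot be modelled and raise :class:`UnresolvableComponent`.
    """
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    if covmax is None:
        covmax = g.covmax()
    upper = math.floor(alpha * covmax)
    net = nx.DiGraph()
    net.add_node(SOURCE)
    net.add_node(SINK)
    for u, v, attrs in g.digraph.edges(data=True):
        nu = SOURCE if u == st else u
        nv = SINK if v == st else v
        net.add_edge(
            nu,
            nv,
            lower=math.floor(attrs["we"]),
            upper=upper,
            we=attrs["we"],
            orients=attrs["orients"],
            overlap=attrs["overlap"],
        )
    if not nx.is_directed_acyclic_graph(net):
        raise UnresolvableComponent(
            "residual cycle avoiding the st vertex; component left unresolved"
        )
    return InexactFlowNetwork(
        digraph=net, st_vertex=st, alpha=alpha, covmax=covmax
    )


def derive_subpath_constraints(
    g: DirectedComponentGraph,
    evidence: EdgeEvidence,
    mincov: int = DEFAULT_MINCOV,
    covtolerance: float = DEFAULT_COVTOLERANCE,
    st: Optional[str] = None,
) -> List[SubpathConstraint]:
    """Subpath constraints from paired-end evidence and coverage balance.

    * Pair (u, v): for every arc with ce(u, v) ≥ mincov.
    * Triple (t, u, v): for every 2-arc path through a junction u (non-zero
      in- and out-degree) with cp(t, u, v) ≥ mincov, or with
      |we(t→u) − we(u→v)| < covtolerance (balanced coverage suggests the two
      junction arcs carry the same genome).

    When the st vertex is known, triples with st as the middle vertex are
    dropped: after the source/sink split such a path cannot be a subpath of
    any s-t path (it wraps around the cut point).
    """
    dg = g.digraph
    out: List[SubpathConstraint] = []
    seen: Set[Tuple[str, ...]] = set()

    def add(vlist: Tuple[str, ...], origin: ConstraintOrigin) -> None:
        if vlist not in seen:
            seen.add(vlist)
            out.append(SubpathConstraint(vertex_list=vlist, origin=origin))

    for u, v in dg.edges:
        if evidence.ce(u, v) >= mincov:
            add((u, v), ConstraintOrigin.PAIR_EVIDENCE)
    for u in dg.nodes:
        if dg.in_degree(u) == 0 or dg.out_degree(u) == 0:
            continue  # not a junction
        if st is not None and u == st:
            continue  # wraps around the source/sink split
        for t in dg.predecessors(u):
            for v in dg.successors(u):
                if evidence.cp(t, u, v) >= mincov:
                    add((t, u, v), ConstraintOrigin.TRIPLE_EVIDENCE)
                elif abs(g.we(t, u) - g.we(u, v)) < covtolerance:
                    add((t, u, v), ConstraintOrigin.COVERAGE_BALANCE)
    return out


def constraint_in_network(
    constraint: SubpathConstraint, st: str
) -> Optional[Tuple[str, ...]]:
    """Rewrite a constraint's vertices into the split network's namespace.

    The st vertex at the start of the path becomes the source, at the end the
    sink.  A constraint with st strictly inside is not representable in the
    DAG and yields None.
    """
    vl = list(constraint.vertex_list)
    if st in vl[1:-1]:
        return None
    if vl[0] == st:
        vl[0] = SOURCE
    if vl[-1] == st:
        vl[-1] = SINK
    return tuple(vl)


def prepare_case3(
    component: PhageComponent,
    graph: AssemblyGraph,
    evidence: EdgeEvidence,
    alpha: float = DEFAULT_ALPHA,
    mincov: int = DEFAULT_MINCOV,
    covtolerance: float = DEFAULT_COVTOLERANCE,
) -> Tuple[InexactFlowNetwork, List[SubpathConstraint]]:
    """Full Case-3 modelling: digraph → dead-end removal → st → network.

    Raises :class:`UnresolvableComponent` when no st vertex exists or the
    split graph is not a DAG.
    """
    g = build_directed_graph(component, graph)
    g = remove_dead_ends(g)
    st = find_st_vertex(g)
    if st is None:
        raise UnresolvableComponent("no st vertex found")
    network = build_flow_network(g, st, alpha=alpha)
    constraints = derive_subpath_constraints(
        g, evidence, mincov=mincov, covtolerance=covtolerance, st=st
    )
    return network, constraints


def dump_network(
    network: InexactFlowNetwork,
    constraints: Sequence[SubpathConstraint],
    edges_path,
    constraints_path,
) -> None:
    """Debug dump: edge-list TSV ``from to lower upper`` plus constraints."""
    with open(edges_path, "w") as fh:
        fh.write("from\tto\tlower\tupper\n")
        for u, v in network.arcs():
            fh.write(f"{u}\t{v}\t{network.lower(u, v)}\t{network.upper(u, v)}\n")
    with open(constraints_path, "w") as fh:
        fh.write("vertices\torigin\n")
        for c in constraints:
            fh.write(f"{','.join(c.vertex_list)}\t{c.origin.value}\n")
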