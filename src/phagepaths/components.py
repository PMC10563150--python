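"""Partition the assembly graph into components and classify phage components.

A connected component (over links, ignoring orientation) is a *phage
component* when none of its unitigs carries a bacterial single-copy marker
gene and at least one unitig carries a structural PHROG (head and packaging,
connector, tail or lysis).  Accepted components fall into three structural
cases:

* Case 1 — a single circular or linear unitig: the unitig is the genome.
* Case 2 — two circular unitigs joined in a cycle: the shorter one is a
  terminal repeat flanking the longer genome unitig.
* Case 3 — more than two unitigs with branching paths: resolved downstream
  by flow decomposition.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import networkx as nx

from .annotations import UnitigAnnotation, STRUCTURAL_CATEGORIES
from .graph_io import AssemblyGraph

logger = logging.getLogger(__name__)

DEFAULT_MINLENGTH = 2000  # bp; approximate lower bound of tailed-phage genome length
DEFAULT_MAX_UNITIGS = 200  # components larger than this are reported, not solved


class Case(enum.Enum):
    CASE1 = "case1"
    CASE2 = "case2"
    CASE3 = "case3"
    UNRESOLVED = "unresolved"


class RejectReason(enum.Enum):
    HAS_SMG = "HAS_SMG"
    NO_STRUCTURAL_PHROG = "NO_STRUCTURAL_PHROG"
    TOO_SHORT = "TOO_SHORT"


@dataclass
class Rejection:
    """A component that failed phage classification, with the reason."""

    component_id: str
    unitig_ids: Tuple[str, ...]
    reason: RejectReason


@dataclass
class PhageComponent:
    component_id: str
    unitig_ids: Tuple[str, ...]  # sorted for determinism
    case: Case
    covmax: float
    evidence: Dict[str, object] = field(default_factory=dict)

    @property
    def n_unitigs(self) -> int:
        return len(self.unitig_ids)


def find_components(graph: AssemblyGraph) -> List[Set[str]]:
    """Connected components over links, ignoring orientation and direction.

    Returned sets partition all unitigs; isolated unitigs form singletons.
    Components are ordered by their smallest member id for determinism.
    """
    g = nx.Graph()
    g.add_nodes_from(graph.unitigs)
    for l in graph.links:
        g.add_edge(l.from_id, l.to_id)
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: min(c))
    return comps


def _is_circular(graph: AssemblyGraph, unitig_id: str) -> bool:
    """A unitig is circular when the GFA links it to itself (ends overlap)."""
    return unitig_id in graph.self_loops


def assign_case(
    unitig_ids: Sequence[str],
    graph: AssemblyGraph,
    minlength: int = DEFAULT_MINLENGTH,
) -> Case:
    """Structural case of an accepted component (see module docstring)."""
    ids = list(unitig_ids)
    if len(ids) == 1:
        return Case.CASE1
    if len(ids) == 2:
        u, v = ids
        both_self_looped = _is_circular(graph, u) and _is_circular(graph, v)
        inter = graph.links_between(u, v)
        closes_cycle = (both_self_looped and len(inter) >= 1) or len(inter) >= 2
        long_enough = max(graph.length(u), graph.length(v)) > minlength
        if closes_cycle and long_enough:
            return Case.CASE2
        logger.info(
            "2-unitig component {%s, %s} does not match the Case-2 cycle pattern", u, v
        )
        return Case.UNRESOLVED
    return Case.CASE3


def case2_repeat_and_core(
    component: PhageComponent, graph: AssemblyGraph
) -> Tuple[str, str]:
    """(terminal repeat id, core genome id) for a Case-2 component.

    The shorter unitig is the terminal repeat; on a length tie the
    lexicographically smaller id is taken as the repeat (logged).
    """
    u, v = component.unitig_ids
    lu, lv = graph.length(u), graph.length(v)
    if lu == lv:
        logger.info("Case-2 length tie between %s and %s; %s taken as repeat", u, v, min(u, v))
        repeat = min(u, v)
    else:
        repeat = u if lu < lv else v
    core = v if repeat == u else u
    return repeat, core


def classify_component(
    unitig_ids: Iterable[str],
    annotations: Dict[str, UnitigAnnotation],
    graph: AssemblyGraph,
    minlength: int = DEFAULT_MINLENGTH,
    component_id: str = "0",
) -> Union[PhageComponent, Rejection]:
    """Accept a component as phage-like or reject it with a reason code.

    Acceptance requires: no member unitig carries an SMG; some member carries
    a structural PHROG category; and a single-unitig component must be longer
    than ``minlength``.  Missing annotation entries mean "no hits".
    """
    ids = tuple(sorted(unitig_ids))
    anns = [annotations.get(uid, UnitigAnnotation()) for uid in ids]
    if any(a.smg_count > 0 for a in anns):
        return Rejection(component_id, ids, RejectReason.HAS_SMG)
    categories: Set[str] = set()
    for a in anns:
        categories |= a.phrog_categories
    if not categories & STRUCTURAL_CATEGORIES:
        return Rejection(component_id, ids, RejectReason.NO_STRUCTURAL_PHROG)
    if len(ids) == 1 and graph.length(ids[0]) <= minlength:
        return Rejection(component_id, ids, RejectReason.TOO_SHORT)
    covmax = max(graph.coverage(uid) for uid in ids)
    case = assign_case(ids, graph, minlength)
    return PhageComponent(
        component_id=component_id,
        unitig_ids=ids,
        case=case,
        covmax=covmax,
        evidence={
            "phrog_categories": sorted(categories),
            "smg_free": True,
        },
    )


def classify_all(
    graph: AssemblyGraph,
    annotations: Dict[str, UnitigAnnotation],
    minlength: int = DEFAULT_MINLENGTH,
) -> Tuple[List[PhageComponent], List[Rejection]]:
    """Classify every connected component; returns (accepted, rejected)."""
    accepted: List[PhageComponent] = []
    rejected: List[Rejection] = []
    for i, comp in enumerate(find_components(graph)):
        result = classify_component(
            comp, annotations, graph, minlength, component_id=str(i)
        )
        if isinstance(result, PhageComponent):
            accepted.append(result)
        else:
            rejected.append(result)
    return accepted, rejected
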