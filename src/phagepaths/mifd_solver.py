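"""Minimum inexact flow decomposition (MIFD) with subpath constraints.

Given a DAG with per-arc flow intervals [lower, upper] and a set of required
subpaths R, find the minimum number k of s-t paths P1..Pk with positive
integer weights w1..wk such that

* for every arc (u,v):  lower ≤ Σ_{i: (u,v) ∈ Pi} wi ≤ upper, and
* every Rj ∈ R is a contiguous subpath of at least one Pi.

Minimality is obtained by solving a feasibility ILP for k = 1, 2, … and
returning the first feasible k.  Within the optimal k the weights are pinned
by a secondary objective: minimise the total absolute deviation of the
superposed flow from each arc's observed edge weight ``we``, which makes the
reported coverages track the read data as closely as the intervals allow.
The path-arc/weight product is linearised with big-M = max upper bound, and
path weights are ordered non-increasingly to break permutation symmetry.

The ILP is solved with HiGHS via :func:`scipy.optimize.milp`.  For tiny
instances :func:`oracle_mifd` enumerates all path multisets and weight
vectors exhaustively and serves as an independent reference.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import networkx as nx
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csc_matrix

from .flow_model import (
    SINK,
    SOURCE,
    InexactFlowNetwork,
    SubpathConstraint,
    constraint_in_network,
)

logger = logging.getLogger(__name__)


@dataclass
class FlowDecomposition:
    """A solved set of weighted s-t paths."""

    paths: Tuple[Tuple[str, ...], ...]  # each starts at SOURCE, ends at SINK
    weights: Tuple[int, ...]
    deviation: float = 0.0  # Σ per-arc |superposed flow − we|

    @property
    def k(self) -> int:
        return len(self.paths)

    def unitig_paths(self, st: str) -> List[Tuple[str, ...]]:
        """Paths in unitig namespace: source mapped back to st, sink dropped."""
        out = []
        for p in self.paths:
            out.append(tuple(st if v == SOURCE else v for v in p[:-1]))
        return out


@dataclass
class Infeasible:
    """No decomposition exists within the explored k range."""

    k_max: int
    reason: str
    diagnostics: List[str] = field(default_factory=list)


MifdResult = Union[FlowDecomposition, Infeasible]


class OracleOutOfRange(Exception):
    """The exhaustive oracle was asked for an instance beyond its limits."""


def _network_constraints(
    network: InexactFlowNetwork, constraints: Sequence[SubpathConstraint]
) -> List[Tuple[Tuple[str, str], ...]]:
    """Constraint arc lists in the split network's namespace.

    Constraints wrapping around the st split (st strictly inside) are
    dropped with a log message; constraints whose arcs are absent from the
    DAG are dropped likewise.
    """
    arcs = set(network.digraph.edges)
    out = []
    for c in constraints:
        vl = constraint_in_network(c, network.st_vertex)
        if vl is None:
            logger.debug("constraint %s wraps the st split; dropped", c.vertex_list)
            continue
        arc_list = tuple(zip(vl, vl[1:]))
        if not all(a in arcs for a in arc_list):
            logger.warning("constraint %s uses arcs absent from network; dropped", vl)
            continue
        out.append(arc_list)
    # dedupe, keep order
    seen, uniq = set(), []
    for a in out:
        if a not in seen:
            seen.add(a)
            uniq.append(a)
    return uniq


def is_subpath(sub: Sequence[str], path: Sequence[str]) -> bool:
    """True when ``sub`` occurs as a contiguous run of vertices in ``path``."""
    n, m = len(path), len(sub)
    return any(tuple(path[i : i + m]) == tuple(sub) for i in range(n - m + 1))


def check_decomposition(
    network: InexactFlowNetwork,
    constraints: Sequence[SubpathConstraint],
    decomposition: FlowDecomposition,
) -> List[str]:
    """Independently replay the MIFD conditions; returns violation messages.

    Checks path validity (s to t along arcs), positive integer weights, the
    per-arc interval condition on the superposed flow, and subpath coverage.
    """
    errors: List[str] = []
    dg = network.digraph
    if len(decomposition.paths) != len(decomposition.weights):
        errors.append("paths/weights length mismatch")
    for p, w in zip(decomposition.paths, decomposition.weights):
        if not (isinstance(w, (int, np.integer)) and w >= 1):
            errors.append(f"weight {w} is not a positive integer")
        if p[0] != network.source or p[-1] != network.sink:
            errors.append(f"path {p} does not run source→sink")
        for u, v in zip(p, p[1:]):
            if not dg.has_edge(u, v):
                errors.append(f"path {p} uses missing arc ({u},{v})")
    flow: Dict[Tuple[str, str], int] = {a: 0 for a in dg.edges}
    for p, w in zip(decomposition.paths, decomposition.weights):
        for a in zip(p, p[1:]):
            if a in flow:
                flow[a] += int(w)
    for (u, v), f in flow.items():
        lo, hi = dg.edges[u, v]["lower"], dg.edges[u, v]["upper"]
        if not lo <= f <= hi:
            errors.append(f"arc ({u},{v}): superposed flow {f} outside [{lo},{hi}]")
    for arc_list in _network_constraints(network, constraints):
        verts = [arc_list[0][0]] + [a[1] for a in arc_list]
        if not any(is_subpath(verts, p) for p in decomposition.paths):
            errors.append(f"required subpath {verts} covered by no path")
    return errors


def _solve_fixed_k(
    network: InexactFlowNetwork,
    constraint_arcs: List[Tuple[Tuple[str, str], ...]],
    k: int,
    time_limit: Optional[float],
    relax_lower: bool = False,
) -> Optional[Tuple[FlowDecomposition, List[str]]]:
    """Feasibility/deviation ILP for a fixed number of paths.

    With ``relax_lower`` the interval lower bounds and subpath-coverage
    requirements get slack variables whose sum is minimised instead; used for
    diagnostics when the instance is infeasible at k_max.
    """
    dg = network.digraph
    arcs = sorted(dg.edges)
    m = len(arcs)
    arc_idx = {a: e for e, a in enumerate(arcs)}
    l = len(constraint_arcs)
    bigM = max((dg.edges[a]["upper"] for a in arcs), default=1)

    off_x = 0
    off_w = k * m
    off_z = off_w + k
    off_r = off_z + k * m
    off_d = off_r + l * k
    n_slack = (m + l) if relax_lower else 0
    off_s = off_d + m
    n_vars = off_s + n_slack

    def xi(i: int, e: int) -> int:
        return off_x + i * m + e

    def wi(i: int) -> int:
        return off_w + i

    def zi(i: int, e: int) -> int:
        return off_z + i * m + e

    def rji(j: int, i: int) -> int:
        return off_r + j * k + i

    lb = np.zeros(n_vars)
    ub = np.full(n_vars, np.inf)
    integrality = np.zeros(n_vars)
    ub[off_x : off_x + k * m] = 1
    integrality[off_x : off_x + k * m] = 1
    lb[off_w : off_w + k] = 1
    ub[off_w : off_w + k] = bigM
    integrality[off_w : off_w + k] = 1
    ub[off_z : off_z + k * m] = bigM
    ub[off_r : off_r + l * k] = 1
    integrality[off_r : off_r + l * k] = 1
    if relax_lower:
        ub[off_s:] = bigM

    rows: List[int] = []
    cols: List[int] = []
    vals: List[float] = []
    c_lo: List[float] = []
    c_hi: List[float] = []
    nrow = 0

    def add_row(entries: List[Tuple[int, float]], lo: float, hi: float) -> None:
        nonlocal nrow
        for col, val in entries:
            rows.append(nrow)
            cols.append(col)
            vals.append(val)
        c_lo.append(lo)
        c_hi.append(hi)
        nrow += 1

    out_s = [arc_idx[a] for a in dg.out_edges(SOURCE)]
    in_t = [arc_idx[a] for a in dg.in_edges(SINK)]
    internal = [v for v in dg.nodes if v not in (SOURCE, SINK)]

    for i in range(k):
        add_row([(xi(i, e), 1.0) for e in out_s], 1, 1)
        add_row([(xi(i, e), 1.0) for e in in_t], 1, 1)
        for v in internal:
            ent = [(xi(i, arc_idx[a]), 1.0) for a in dg.in_edges(v)]
            ent += [(xi(i, arc_idx[a]), -1.0) for a in dg.out_edges(v)]
            add_row(ent, 0, 0)
        for e in range(m):
            add_row([(zi(i, e), 1.0), (xi(i, e), -float(bigM))], -np.inf, 0)
            add_row([(zi(i, e), 1.0), (wi(i), -1.0)], -np.inf, 0)
            add_row(
                [(zi(i, e), 1.0), (wi(i), -1.0), (xi(i, e), -float(bigM))],
                -float(bigM),
                np.inf,
            )
    for e, a in enumerate(arcs):
        ent = [(zi(i, e), 1.0) for i in range(k)]
        lo = float(dg.edges[a]["lower"])
        if relax_lower:
            ent_lo = ent + [(off_s + e, 1.0)]
            add_row(ent_lo, lo, np.inf)
            add_row(ent, -np.inf, float(dg.edges[a]["upper"]))
        else:
            add_row(ent, lo, float(dg.edges[a]["upper"]))
    for j, arc_list in enumerate(constraint_arcs):
        for i in range(k):
            ent = [(xi(i, arc_idx[a]), 1.0) for a in arc_list]
            ent.append((rji(j, i), -float(len(arc_list))))
            add_row(ent, 0, np.inf)
        ent = [(rji(j, i), 1.0) for i in range(k)]
        if relax_lower:
            ent.append((off_s + m + j, 1.0))
        add_row(ent, 1, np.inf)
    for i in range(k - 1):
        add_row([(wi(i), 1.0), (wi(i + 1), -1.0)], 0, np.inf)
    for e, a in enumerate(arcs):
        we = float(dg.edges[a]["we"])
        ent = [(off_d + e, 1.0)] + [(zi(i, e), -1.0) for i in range(k)]
        add_row(ent, -we, np.inf)
        ent = [(off_d + e, 1.0)] + [(zi(i, e), 1.0) for i in range(k)]
        add_row(ent, we, np.inf)

    obj = np.zeros(n_vars)
    if relax_lower:
        obj[off_s:] = 1.0
    else:
        obj[off_d : off_d + m] = 1.0

    A = csc_matrix((vals, (rows, cols)), shape=(nrow, n_vars))
    options = {}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        c=obj,
        constraints=LinearConstraint(A, np.array(c_lo), np.array(c_hi)),
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options=options,
    )
    if res.status == 1:
        raise TimeoutError(f"MILP time limit reached at k={k}")
    if res.status != 0 or res.x is None:
        return None

    x = res.x
    paths: List[Tuple[str, ...]] = []
    weights: List[int] = []
    for i in range(k):
        path = [SOURCE]
        cur = SOURCE
        while cur != SINK:
            nxt = None
            for a in dg.out_edges(cur):
                if x[xi(i, arc_idx[a])] > 0.5:
                    nxt = a[1]
                    break
            if nxt is None:  # should not happen for a valid solution
                return None
            path.append(nxt)
            cur = nxt
        paths.append(tuple(path))
        weights.append(int(round(x[wi(i)])))

    # merge duplicate paths, summing weights
    merged: Dict[Tuple[str, ...], int] = {}
    for p, w in zip(paths, weights):
        merged[p] = merged.get(p, 0) + w
    order = sorted(merged, key=lambda p: (-merged[p], p))
    deviation = float(sum(x[off_d : off_d + m]))
    decomp = FlowDecomposition(
        paths=tuple(order),
        weights=tuple(merged[p] for p in order),
        deviation=deviation,
    )
    slack_msgs: List[str] = []
    if relax_lower:
        for e, a in enumerate(arcs):
            s = x[off_s + e]
            if s > 1e-6:
                slack_msgs.append(
                    f"arc {a}: lower bound {dg.edges[a]['lower']} missed by {s:.1f}"
                )
        for j, arc_list in enumerate(constraint_arcs):
            if x[off_s + m + j] > 1e-6:
                slack_msgs.append(f"subpath constraint {arc_list} uncoverable")
    return decomp, slack_msgs


def default_k_max(network: InexactFlowNetwork) -> int:
    """Path-count cap: a small multiple of the source's branching factor."""
    out_deg = network.digraph.out_degree(SOURCE)
    return min(32, max(4, 4 * out_deg))


def solve_mifd(
    network: InexactFlowNetwork,
    constraints: Sequence[SubpathConstraint],
    k_max: Optional[int] = None,
    time_limit: Optional[float] = None,
) -> MifdResult:
    """Minimum inexact flow decomposition via iterative-k feasibility ILPs.

    Solves for k = 1, 2, … and returns the first feasible decomposition,
    which is minimal by construction.  On exhaustion of ``k_max`` an
    :class:`Infeasible` result carries slack-relaxation diagnostics saying
    which lower bounds or subpath constraints cannot be met.
    """
    if k_max is None:
        k_max = default_k_max(network)
    constraint_arcs = _network_constraints(network, constraints)
    for k in range(1, k_max + 1):
        try:
            solved = _solve_fixed_k(network, constraint_arcs, k, time_limit)
        except TimeoutError as e:
            logger.warning("%s", e)
            return Infeasible(k_max=k, reason="timeout", diagnostics=[str(e)])
        if solved is not None:
            decomp, _ = solved
            return decomp
    diagnostics: List[str] = []
    try:
        relaxed = _solve_fixed_k(
            network, constraint_arcs, k_max, time_limit, relax_lower=True
        )
        if relaxed is not None:
            diagnostics = relaxed[1]
    except TimeoutError:
        diagnostics = ["diagnostic relaxation timed out"]
    return Infeasible(
        k_max=k_max, reason=f"no feasible decomposition with k <= {k_max}",
        diagnostics=diagnostics,
    )


def oracle_mifd(
    network: InexactFlowNetwork,
    constraints: Sequence[SubpathConstraint],
    k_limit: int = 4,
    weight_limit: int = 12,
) -> MifdResult:
    """Exhaustive MIFD reference for tiny instances.

    Enumerates every multiset of up to ``k_limit`` s-t paths and every
    integer weight vector with entries in [1, weight_limit], returning the
    first feasible decomposition; minimal by exhaustion.  Instances beyond
    roughly 10 vertices / 14 arcs / 30 paths raise
    :class:`OracleOutOfRange`.
    """
    dg = network.digraph
    if dg.number_of_nodes() > 10 or dg.number_of_edges() > 14:
        raise OracleOutOfRange("instance too large for the exhaustive oracle")
    all_paths = sorted(tuple(p) for p in nx.all_simple_paths(dg, SOURCE, SINK))
    if len(all_paths) > 30:
        raise OracleOutOfRange("too many s-t paths for the exhaustive oracle")
    constraint_arcs = _network_constraints(network, constraints)
    req_verts = [
        [al[0][0]] + [a[1] for a in al] for al in constraint_arcs
    ]
    arcs = sorted(dg.edges)
    lowers = {a: dg.edges[a]["lower"] for a in arcs}
    uppers = {a: dg.edges[a]["upper"] for a in arcs}

    for k in range(1, k_limit + 1):
        for combo in itertools.combinations_with_replacement(range(len(all_paths)), k):
            chosen = [all_paths[i] for i in combo]
            if not all(
                any(is_subpath(rv, p) for p in chosen) for rv in req_verts
            ):
                continue
            path_arcs = [set(zip(p, p[1:])) for p in chosen]
            for wvec in itertools.product(range(1, weight_limit + 1), repeat=k):
                ok = True
                for a in arcs:
                    f = sum(w for pa, w in zip(path_arcs, wvec) if a in pa)
                    if not lowers[a] <= f <= uppers[a]:
                        ok = False
                        break
                if ok:
                    merged: Dict[Tuple[str, ...], int] = {}
                    for p, w in zip(chosen, wvec):
                        merged[p] = merged.get(p, 0) + w
                    order = sorted(merged, key=lambda p: (-merged[p], p))
                    dev = 0.0
                    for a in arcs:
                        f = sum(w for pa, w in zip(path_arcs, wvec) if a in pa)
                        dev += abs(f - dg.edges[a]["we"])
                    return FlowDecomposition(
                        paths=tuple(order),
                        weights=tuple(merged[p] for p in order),
                        deviation=dev,
                    )
    return Infeasible(k_max=k_limit, reason="exhausted oracle limits")
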