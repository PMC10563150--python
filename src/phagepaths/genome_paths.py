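"""Translate resolved components into genome sequences with metadata.

Case 1 emits the unitig itself (circular unitigs lose the terminal
self-overlap).  Case 2 places the terminal repeat at both ends of the long
unitig.  Case 3 walks each decomposed flow path, reverse-complementing
unitigs as the link orientations dictate and trimming each traversed link's
overlap from the downstream sequence; because s and t are the same vertex,
the trailing sink is dropped and the wrap-around overlap is trimmed once from
the start, so the emitted string is one full traversal of the circular
genome starting at the st unitig.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .components import Case, PhageComponent, Rejection, case2_repeat_and_core
from .flow_model import SOURCE, InexactFlowNetwork
from .graph_io import AssemblyGraph
from .mifd_solver import FlowDecomposition

logger = logging.getLogger(__name__)

DEFAULT_MINCOV = 10

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _oriented(seq: str, orient: str) -> str:
    return seq if orient == "+" else reverse_complement(seq)


def compute_gc(sequence: str) -> Optional[float]:
    """GC fraction over unambiguous bases; None when no A/C/G/T present."""
    gc = sum(sequence.count(b) for b in "GC")
    denom = sum(sequence.count(b) for b in "ACGT")
    if denom == 0:
        return None
    return gc / denom


@dataclass
class GenomicPath:
    """One resolved genome: ordered oriented unitigs plus sequence metadata."""

    genome_id: str
    component_id: str
    member_unitigs: List[Tuple[str, str]]  # (unitig id, orientation)
    sequence: str
    coverage: float
    case: Case
    repeat_length: Optional[int] = None  # Case 2 only

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> Optional[float]:
        return compute_gc(self.sequence)


def _steps_from(graph: AssemblyGraph, u: str, u_orient: str):
    """Oriented traversal steps available from unitig ``u`` in ``u_orient``.

    A link (a, d1) -> (b, d2) can be walked as written when we sit on a in
    orientation d1, or via its reverse-complement twin (b, -d2) -> (a, -d1).
    Yields (next unitig, next orientation, overlap).
    """
    flip = {"+": "-", "-": "+"}
    for l in graph.links:
        if l.from_id == u and l.from_orient == u_orient:
            yield l.to_id, l.to_orient, l.overlap_bp
        if l.to_id == u and l.to_orient == flip[u_orient]:
            yield l.from_id, flip[l.from_orient], l.overlap_bp


def _step(graph: AssemblyGraph, u: str, u_orient: str, v: str):
    """First traversal step from (u, u_orient) to unitig ``v``, or None."""
    for nid, norient, ovl in _steps_from(graph, u, u_orient):
        if nid == v:
            return norient, ovl
    return None


def resolve_case1(component: PhageComponent, graph: AssemblyGraph) -> GenomicPath:
    """Single-unitig genome; circular unitigs lose the terminal self-overlap."""
    uid = component.unitig_ids[0]
    unitig = graph.unitigs[uid]
    seq = unitig.sequence
    self_link = graph.self_link(uid)
    if self_link is not None and self_link.overlap_bp > 0:
        seq = seq[: -self_link.overlap_bp]
    return GenomicPath(
        genome_id=f"phage_comp_{component.component_id}_path_0",
        component_id=component.component_id,
        member_unitigs=[(uid, "+")],
        sequence=seq,
        coverage=unitig.mean_coverage,
        case=Case.CASE1,
    )


def resolve_case2(component: PhageComponent, graph: AssemblyGraph) -> GenomicPath:
    """Terminal-repeat genome: repeat + core + repeat, overlap-trimmed.

    The shorter unitig (the repeat) is attached to both ends of the longer
    unitig; coverage is the longer unitig's mean coverage.  Orientation of
    the core and of the trailing repeat copy follows the link orientations.
    """
    repeat_id, core_id = case2_repeat_and_core(component, graph)
    repeat_seq = graph.unitigs[repeat_id].sequence
    step1 = _step(graph, repeat_id, "+", core_id)
    if step1 is None:  # repeat not traversable in '+': enter via '-'
        step1 = _step(graph, repeat_id, "-", core_id)
        if step1 is None:
            raise ValueError(
                f"Case-2 component {component.component_id}: no traversable "
                f"link {repeat_id} -> {core_id}"
            )
        repeat_start = reverse_complement(repeat_seq)
    else:
        repeat_start = repeat_seq
    core_orient, ovl1 = step1
    step2 = _step(graph, core_id, core_orient, repeat_id)
    if step2 is None:
        raise ValueError(
            f"Case-2 component {component.component_id}: no traversable "
            f"link {core_id} -> {repeat_id} closing the cycle"
        )
    repeat_end_orient, ovl2 = step2
    core_seq = _oriented(graph.unitigs[core_id].sequence, core_orient)
    seq = (
        repeat_start
        + core_seq[ovl1:]
        + _oriented(repeat_seq, repeat_end_orient)[ovl2:]
    )
    return GenomicPath(
        genome_id=f"phage_comp_{component.component_id}_path_0",
        component_id=component.component_id,
        member_unitigs=[
            (repeat_id, "+" if repeat_start == repeat_seq else "-"),
            (core_id, core_orient),
            (repeat_id, repeat_end_orient),
        ],
        sequence=seq,
        coverage=graph.coverage(core_id),
        case=Case.CASE2,
        repeat_length=graph.length(repeat_id),
    )


def resolve_case3(
    component: PhageComponent,
    decomposition: FlowDecomposition,
    network: InexactFlowNetwork,
    graph: AssemblyGraph,
    minlength: int = 2000,
    mincov: float = DEFAULT_MINCOV,
) -> List[GenomicPath]:
    """Genomes from the flow decomposition of a branching component.

    Each s-t path is walked in unitig space (source mapped back to the st
    unitig, sink dropped); unitig sequences are concatenated honouring link
    orientations, each traversed link's overlap trimmed from the downstream
    unitig, and the wrap-around overlap (last unitig back onto the st unitig)
    trimmed from the start.  Paths shorter than ``minlength`` or with weight
    below ``mincov`` are dropped; coverage is the path weight.
    """
    st = network.st_vertex
    genomes: List[GenomicPath] = []
    dg = network.digraph
    for idx, (net_path, weight) in enumerate(
        zip(decomposition.paths, decomposition.weights)
    ):
        if weight < mincov:
            logger.info(
                "component %s path %d: weight %d below mincov %s; dropped",
                component.component_id, idx, weight, mincov,
            )
            continue
        vertices = [st if v == SOURCE else v for v in net_path[:-1]]
        arcs = list(zip(net_path, net_path[1:]))  # network namespace
        # orientation chain: start with the first arc's upstream orientation
        first_orients = dg.edges[arcs[0]]["orients"]
        orient = first_orients[0]
        members: List[Tuple[str, str]] = [(vertices[0], orient)]
        seq = _oriented(graph.unitigs[vertices[0]].sequence, orient)
        ok = True
        wrap_overlap = 0
        for pos, a in enumerate(arcs):
            d1, d2 = dg.edges[a]["orients"]
            ovl = dg.edges[a]["overlap"]
            if orient != d1:
                logger.error(
                    "component %s path %d: inconsistent orientation chain at %s; "
                    "path skipped", component.component_id, idx, a,
                )
                ok = False
                break
            if pos == len(arcs) - 1:  # arc back into the st unitig (the sink)
                wrap_overlap = ovl
            else:
                v = vertices[pos + 1]
                seq += _oriented(graph.unitigs[v].sequence, d2)[ovl:]
                members.append((v, d2))
            orient = d2
        if not ok:
            continue
        seq = seq[wrap_overlap:]
        if len(seq) <= minlength:
            logger.info(
                "component %s path %d: length %d below minlength %d; dropped",
                component.component_id, idx, len(seq), minlength,
            )
            continue
        genomes.append(
            GenomicPath(
                genome_id=f"phage_comp_{component.component_id}_path_{idx}",
                component_id=component.component_id,
                member_unitigs=members,
                sequence=seq,
                coverage=float(weight),
                case=Case.CASE3,
            )
        )
    return genomes


@dataclass
class AuditRow:
    """One line of the component audit: what happened to each component."""

    component_id: str
    n_unitigs: int
    case_or_reason: str
    covmax: float
    phrog_categories: str


def audit_rows(
    accepted: Sequence[PhageComponent],
    rejected: Sequence[Rejection],
    statuses: Optional[Dict[str, str]] = None,
) -> List[AuditRow]:
    """Audit table rows; ``statuses`` may override an accepted component's
    case label (e.g. SKIPPED_TOO_LARGE, UNRESOLVED)."""
    statuses = statuses or {}
    rows = []
    for comp in accepted:
        label = statuses.get(comp.component_id, comp.case.name)
        rows.append(
            AuditRow(
                component_id=comp.component_id,
                n_unitigs=comp.n_unitigs,
                case_or_reason=label,
                covmax=comp.covmax,
                phrog_categories=";".join(comp.evidence.get("phrog_categories", [])),
            )
        )
    for rej in rejected:
        rows.append(
            AuditRow(
                component_id=rej.component_id,
                n_unitigs=len(rej.unitig_ids),
                case_or_reason=rej.reason.value,
                covmax=0.0,
                phrog_categories="",
            )
        )
    rows.sort(key=lambda r: int(r.component_id))
    return rows


def write_outputs(
    genomes: Sequence[GenomicPath],
    audit: Sequence[AuditRow],
    outdir: str | Path,
) -> Dict[str, Path]:
    """Write genomes FASTA, genome-info TSV and the component audit TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "resolved_genomes.fasta"
    info = outdir / "genome_info.tsv"
    audit_path = outdir / "component_audit.tsv"
    with open(fasta, "w") as fh:
        for g in genomes:
            case_n = {"case1": 1, "case2": 2, "case3": 3}.get(g.case.value, 0)
            fh.write(f">{g.genome_id} length={g.length} coverage={g.coverage:g} case={case_n}\n")
            for i in range(0, len(g.sequence), 80):
                fh.write(g.sequence[i : i + 80] + "\n")
    with open(info, "w") as fh:
        fh.write(
            "genome_id\tcomponent_id\tlength\tcoverage\tgc\tn_unitigs\tunitigs\n"
        )
        for g in genomes:
            gc = g.gc_fraction
            gc_s = f"{gc:.4f}" if gc is not None else "NA"
            unitigs = ",".join(f"{uid}{o}" for uid, o in g.member_unitigs)
            fh.write(
                f"{g.genome_id}\t{g.component_id}\t{g.length}\t{g.coverage:g}\t"
                f"{gc_s}\t{len(g.member_unitigs)}\t{unitigs}\n"
            )
    with open(audit_path, "w") as fh:
        fh.write("component_id\tn_unitigs\tcase_or_reason\tcovmax\tphrog_categories\n")
        for row in audit:
            fh.write(
                f"{row.component_id}\t{row.n_unitigs}\t{row.case_or_reason}\t"
                f"{row.covmax:g}\t{row.phrog_categories}\n"
            )
    return {"fasta": fasta, "genome_info": info, "component_audit": audit_path}
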