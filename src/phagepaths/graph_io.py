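"""Assembly-graph I/O: GFA 1.0 parsing, coverage tables and paired-end spanning evidence.

The in-memory model is deliberately small: a unitig graph is a set of
:class:`Unitig` segments plus oriented :class:`OrientedLink` records taken
straight from the GFA ``L`` lines.  Each link states that the suffix of
``from`` (in orientation ``from_orient``) overlaps the prefix of ``to`` (in
orientation ``to_orient``) by ``overlap_bp`` bases.  A link and its
reverse-complement twin describe the same physical junction and are stored
once, as written in the GFA.

Paired-end evidence is kept separately as :class:`EdgeEvidence`: counts of
read pairs spanning a unitig pair (edge confidence, ``ce``) or bracketing a
junction unitig (path confidence, ``cp``).  Pair counts are symmetric — a
spanning pair supports the junction irrespective of which mate landed on
which unitig — so they are stored on unordered pairs; triple counts keep
their direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set, Tuple

logger = logging.getLogger(__name__)


class GFAParseError(ValueError):
    """Raised when a GFA record cannot be interpreted."""


@dataclass
class Unitig:
    """A graph segment: one non-branching assembly path."""

    id: str
    sequence: str
    mean_coverage: float = 0.0

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrientedLink:
    """A GFA ``L`` record: oriented overlap between two unitig ends."""

    from_id: str
    from_orient: str  # '+' or '-'
    to_id: str
    to_orient: str
    overlap_bp: int

    def key(self) -> Tuple[str, str, str, str]:
        return (self.from_id, self.from_orient, self.to_id, self.to_orient)


@dataclass
class AssemblyGraph:
    """Unitigs plus oriented links; ``self_loops`` marks circular unitigs."""

    unitigs: Dict[str, Unitig] = field(default_factory=dict)
    links: List[OrientedLink] = field(default_factory=list)

    @property
    def self_loops(self) -> Set[str]:
        return {l.from_id for l in self.links if l.from_id == l.to_id}

    def coverage(self, unitig_id: str) -> float:
        return self.unitigs[unitig_id].mean_coverage

    def length(self, unitig_id: str) -> int:
        return self.unitigs[unitig_id].length

    def neighbours(self, unitig_id: str) -> Set[str]:
        """Unitigs sharing a link with ``unitig_id`` (undirected, excl. self)."""
        out = set()
        for l in self.links:
            if l.from_id == unitig_id and l.to_id != unitig_id:
                out.add(l.to_id)
            elif l.to_id == unitig_id and l.from_id != unitig_id:
                out.add(l.from_id)
        return out

    def are_linked(self, u: str, v: str) -> bool:
        return any(
            (l.from_id == u and l.to_id == v) or (l.from_id == v and l.to_id == u)
            for l in self.links
        )

    def links_between(self, u: str, v: str) -> List[OrientedLink]:
        """All link records joining ``u`` and ``v``, in either written direction."""
        return [
            l
            for l in self.links
            if (l.from_id == u and l.to_id == v) or (l.from_id == v and l.to_id == u)
        ]

    def self_link(self, u: str) -> Optional[OrientedLink]:
        for l in self.links:
            if l.from_id == u and l.to_id == u:
                return l
        return None


def _cigar_match_length(cigar: str) -> int:
    """Overlap length from a GFA overlap CIGAR: sum of M/=/X operations.

    A ``*`` (unspecified) overlap counts as 0.
    """
    if cigar == "*" or cigar == "":
        return 0
    total = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if not num:
                raise GFAParseError(f"malformed CIGAR {cigar!r}")
            if ch in "M=X":
                total += int(num)
            elif ch not in "IDNSHP":
                raise GFAParseError(f"unknown CIGAR operation {ch!r} in {cigar!r}")
            num = ""
    if num:
        raise GFAParseError(f"malformed CIGAR {cigar!r}: trailing number")
    return total


def parse_gfa(path: str | Path) -> AssemblyGraph:
    """Read a GFA 1.0 file into an :class:`AssemblyGraph`.

    Only ``S`` (segment) and ``L`` (link) records are interpreted; headers and
    other record types are ignored.  Segments must carry explicit sequences —
    a ``*`` placeholder is rejected because downstream genome reconstruction
    needs the nucleotides.  GFA 2.0 ``E`` records are rejected.
    """
    path = Path(path)
    graph = AssemblyGraph()
    pending_links: List[Tuple[int, OrientedLink]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag == "S":
                if len(fields) < 3:
                    raise GFAParseError(f"{path}:{lineno}: S record needs id and sequence")
                seg_id, seq = fields[1], fields[2]
                if seq == "*":
                    raise GFAParseError(
                        f"{path}:{lineno}: segment {seg_id!r} has no sequence ('*'); "
                        "supply a GFA with explicit segment sequences"
                    )
                if seg_id in graph.unitigs:
                    raise GFAParseError(f"{path}:{lineno}: duplicate segment id {seg_id!r}")
                graph.unitigs[seg_id] = Unitig(id=seg_id, sequence=seq.upper())
            elif tag == "L":
                if len(fields) < 6:
                    raise GFAParseError(f"{path}:{lineno}: L record needs 5 fields")
                fr, fo, to, to_o, cigar = fields[1:6]
                if fo not in "+-" or to_o not in "+-":
                    raise GFAParseError(f"{path}:{lineno}: bad orientation in L record")
                try:
                    overlap = _cigar_match_length(cigar)
                except GFAParseError as e:
                    raise GFAParseError(f"{path}:{lineno}: {e}") from None
                pending_links.append((lineno, OrientedLink(fr, fo, to, to_o, overlap)))
            elif tag == "E":
                raise GFAParseError(
                    f"{path}:{lineno}: GFA 2.0 'E' record found; only GFA 1.0 is supported"
                )
    seen = set()
    for lineno, link in pending_links:
        for end in (link.from_id, link.to_id):
            if end not in graph.unitigs:
                raise GFAParseError(
                    f"{path}:{lineno}: link references unknown segment {end!r}"
                )
        if link.key() in seen:  # duplicate L record, keep one
            continue
        seen.add(link.key())
        graph.links.append(link)
    return graph


def write_gfa(graph: AssemblyGraph, path: str | Path) -> None:
    """Write the graph back out as GFA 1.0 (used by the fixture generators)."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for uid in graph.unitigs:
            fh.write(f"S\t{uid}\t{graph.unitigs[uid].sequence}\n")
        for l in graph.links:
            fh.write(
                f"L\t{l.from_id}\t{l.from_orient}\t{l.to_id}\t{l.to_orient}\t{l.overlap_bp}M\n"
            )


def load_coverage(path: str | Path, graph: AssemblyGraph) -> AssemblyGraph:
    """Attach mean read coverage (reads per base) to each unitig from a TSV.

    Two columns: unitig id, mean coverage.  Unitigs absent from the table get
    coverage 0 with a warning; table rows naming unknown unitigs are skipped
    with a warning; negative coverage is an error.
    """
    table: Dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'unitig_id<TAB>coverage'")
            uid, cov = parts[0], float(parts[1])
            if cov < 0:
                raise ValueError(f"{path}:{lineno}: negative coverage for {uid!r}")
            table[uid] = table.get(uid, 0.0) + cov if uid in table else cov
    for uid, cov in table.items():
        if uid not in graph.unitigs:
            logger.warning("coverage table names unknown unitig %r; row ignored", uid)
            continue
        graph.unitigs[uid].mean_coverage = cov
    missing = [uid for uid in graph.unitigs if uid not in table]
    for uid in missing:
        graph.unitigs[uid].mean_coverage = 0.0
    if missing:
        logger.warning(
            "%d unitig(s) missing from coverage table; coverage set to 0", len(missing)
        )
    return graph


@dataclass
class EdgeEvidence:
    """Paired-end spanning counts: ``ce`` on unordered pairs, ``cp`` on triples."""

    pair_confidence: Dict[Tuple[str, str], int] = field(default_factory=dict)
    triple_confidence: Dict[Tuple[str, str, str], int] = field(default_factory=dict)

    @staticmethod
    def _pair_key(u: str, v: str) -> Tuple[str, str]:
        return (u, v) if u <= v else (v, u)

    def ce(self, u: str, v: str) -> int:
        """Read pairs spanning the junction between ``u`` and ``v`` (symmetric)."""
        return self.pair_confidence.get(self._pair_key(u, v), 0)

    def cp(self, t: str, u: str, v: str) -> int:
        """Read pairs bracketing junction unitig ``u`` on the path t→u→v."""
        return self.triple_confidence.get((t, u, v), 0)

    def add_pair(self, u: str, v: str, count: int = 1) -> None:
        key = self._pair_key(u, v)
        self.pair_confidence[key] = self.pair_confidence.get(key, 0) + count

    def add_triple(self, t: str, u: str, v: str, count: int = 1) -> None:
        key = (t, u, v)
        self.triple_confidence[key] = self.triple_confidence.get(key, 0) + count


def load_spanning_evidence(path: str | Path) -> EdgeEvidence:
    """Read spanning-evidence TSV rows ``u v count`` or ``t u v count``.

    Repeated rows are summed; counts must be non-negative integers.
    """
    ev = EdgeEvidence()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (3, 4):
                raise ValueError(
                    f"{path}:{lineno}: expected 3 (pair) or 4 (triple) columns"
                )
            try:
                count = int(parts[-1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: count {parts[-1]!r} is not an integer")
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            if len(parts) == 3:
                ev.add_pair(parts[0], parts[1], count)
            else:
                ev.add_triple(parts[0], parts[1], parts[2], count)
    return ev


def write_spanning_evidence(ev: EdgeEvidence, path: str | Path) -> None:
    with open(path, "w") as fh:
        for (u, v), c in sorted(ev.pair_confidence.items()):
            fh.write(f"{u}\t{v}\t{c}\n")
        for (t, u, v), c in sorted(ev.triple_confidence.items()):
            fh.write(f"{t}\t{u}\t{v}\t{c}\n")


def compute_spanning_evidence(
    alignment_path: str | Path, graph: AssemblyGraph
) -> EdgeEvidence:
    """Derive spanning evidence from a SAM/BAM of paired reads mapped to unitigs.

    Counts every primary, mapped, properly paired alignment whose two mates
    map to different unitigs as one spanning pair.  A pair whose mates land on
    ``t`` and ``v`` additionally supports the triple (t, u, v) for every
    junction unitig ``u`` linked to both — i.e. the pair flanks ``u``; the
    insert is not required to cover ``u`` end to end.
    """
    import pysam

    ev = EdgeEvidence()
    missing_refs = set()
    with pysam.AlignmentFile(str(alignment_path), "r", check_sq=False) as af:
        for read in af:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or not read.is_paired
                or read.mate_is_unmapped
                or not read.is_read1  # count each pair once, from mate 1
            ):
                continue
            t, v = read.reference_name, read.next_reference_name
            if t is None or v is None:
                continue
            for ref in (t, v):
                if ref not in graph.unitigs and ref not in missing_refs:
                    missing_refs.add(ref)
                    logger.warning("alignment reference %r not in graph", ref)
            if t == v or t not in graph.unitigs or v not in graph.unitigs:
                continue
            ev.add_pair(t, v)
            # junction unitigs flanked by this pair
            for u in graph.neighbours(t) & graph.neighbours(v):
                ev.add_triple(t, u, v)
    return ev


def write_coverage(graph: AssemblyGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for uid, unitig in graph.unitigs.items():
            fh.write(f"{uid}\t{unitig.mean_coverage}\n")
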