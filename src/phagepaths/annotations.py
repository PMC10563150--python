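"""Filter protein-homology hits into per-unitig phage/bacterial annotation flags.

Two evidence streams decide whether a graph component looks like a phage:

* PHROG hits — matches of predicted genes against the PHROG viral protein
  families.  Hits surviving an identity/e-value filter contribute their
  functional category to the unitig.  Four structural categories ("head and
  packaging", "connector", "tail", "lysis") mark a component as phage-like.
* Bacterial single-copy marker genes (SMGs) — conserved genes present once
  per bacterial genome.  Any surviving SMG hit disqualifies the component,
  which is taken to be bacterial (e.g. a prophage-carrying host contig).

The raw hit tables come from external search tools; this module only applies
the thresholds and aggregates per unitig.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Set

logger = logging.getLogger(__name__)

#: PHROG categories of conserved phage structural proteins.
STRUCTURAL_CATEGORIES = frozenset(
    {"head and packaging", "connector", "tail", "lysis"}
)

#: Full PHROG functional category vocabulary (data-driven; unknown categories
#: are kept verbatim, so this set is informational only).
KNOWN_CATEGORIES = STRUCTURAL_CATEGORIES | {
    "DNA, RNA and nucleotide metabolism",
    "integration and excision",
    "moron, auxiliary metabolic gene and host takeover",
    "transcription regulation",
    "other",
    "unknown function",
}

DEFAULT_MIN_IDENTITY = 30.0  # percent
DEFAULT_MAX_EVALUE = 1e-10
DEFAULT_SMG_MIN_FRACTION = 0.5


@dataclass(frozen=True)
class PhrogHit:
    unitig_id: str
    phrog_id: str
    category: str
    identity: float  # percent, 0-100
    evalue: float


@dataclass(frozen=True)
class SmgHit:
    unitig_id: str
    marker_name: str
    aligned_fraction: float  # aligned length / full gene length, 0-1


@dataclass
class UnitigAnnotation:
    """Per-unitig summary: surviving PHROG categories and SMG count."""

    phrog_categories: Set[str] = field(default_factory=set)
    smg_count: int = 0

    @property
    def has_structural_phrog(self) -> bool:
        return bool(self.phrog_categories & STRUCTURAL_CATEGORIES)


def filter_phrog_hits(
    hits: Iterable[PhrogHit],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> Dict[str, UnitigAnnotation]:
    """Keep hits with identity ≥ ``min_identity`` and e-value < ``max_evalue``.

    The identity boundary is inclusive and the e-value boundary strict.
    Retained hits contribute their category to the unitig's set; category
    strings outside the known vocabulary are kept verbatim (the vocabulary is
    data-driven) and logged once.
    """
    out: Dict[str, UnitigAnnotation] = {}
    unknown_logged = False
    for hit in hits:
        if hit.identity < min_identity or not hit.evalue < max_evalue:
            continue
        if hit.category not in KNOWN_CATEGORIES and not unknown_logged:
            logger.info("unrecognised PHROG category %r retained verbatim", hit.category)
            unknown_logged = True
        out.setdefault(hit.unitig_id, UnitigAnnotation()).phrog_categories.add(
            hit.category
        )
    return out


def filter_smg_hits(
    hits: Iterable[SmgHit], min_fraction: float = DEFAULT_SMG_MIN_FRACTION
) -> Dict[str, int]:
    """Count SMG hits with aligned_fraction strictly above ``min_fraction``.

    A marker counts as present only when more than ``min_fraction`` of the
    gene length aligns to the unitig.
    """
    counts: Dict[str, int] = {}
    for hit in hits:
        if not 0.0 <= hit.aligned_fraction <= 1.0:
            raise ValueError(
                f"aligned_fraction {hit.aligned_fraction} outside [0, 1] "
                f"for {hit.unitig_id}/{hit.marker_name}"
            )
        if hit.aligned_fraction > min_fraction:
            counts[hit.unitig_id] = counts.get(hit.unitig_id, 0) + 1
    return counts


def build_annotations(
    phrog_hits: Iterable[PhrogHit],
    smg_hits: Iterable[SmgHit],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    smg_min_fraction: float = DEFAULT_SMG_MIN_FRACTION,
) -> Dict[str, UnitigAnnotation]:
    """Merge both filters into one per-unitig annotation map."""
    ann = filter_phrog_hits(phrog_hits, min_identity, max_evalue)
    for uid, n in filter_smg_hits(smg_hits, smg_min_fraction).items():
        ann.setdefault(uid, UnitigAnnotation()).smg_count = n
    return ann


def load_phrog_hits(path: str | Path) -> list[PhrogHit]:
    """Read PHROG hits TSV: unitig_id, phrog_id, category, identity, evalue."""
    hits = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            hits.append(
                PhrogHit(
                    unitig_id=parts[0],
                    phrog_id=parts[1],
                    category=parts[2],
                    identity=float(parts[3]),
                    evalue=float(parts[4]),
                )
            )
    return hits


def load_smg_hits(path: str | Path) -> list[SmgHit]:
    """Read SMG hits TSV: unitig_id, marker_name, aligned_fraction."""
    hits = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            hits.append(
                SmgHit(
                    unitig_id=parts[0],
                    marker_name=parts[1],
                    aligned_fraction=float(parts[2]),
                )
            )
    return hits
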