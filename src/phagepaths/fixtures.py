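"""Synthetic assembly-graph scenarios with known ground truth.

Every generator plants a set of (circular) genomes, collapses their shared
sequence modules into a unitig graph, and emits exactly the on-disk formats
the pipeline consumes (GFA, coverage/annotation/spanning TSVs), so all I/O
paths are exercised.  Per-unitig coverage is the sum of the weights of the
genomes containing the unitig, so the planted path weights are a valid
(and, in the scenarios generated here, the deviation-minimal) flow
decomposition.

Scenarios:

* ``make_figure3_component`` — a five-unitig branching component with three
  planted genomes and a bridged junction, the canonical worked example for
  the flow model.
* ``make_mosaic_scenario`` — n variant genomes sharing backbone modules with
  variant-specific modules in between (the mosaic structure of closely
  related phages); default weights 200/400 emulate a pair of Staphylococcus
  phage variants.
* ``make_case2_scenario`` — a terminal-repeat component: a short repeat
  unitig closing a cycle with a long core unitig.
* ``make_mixed_scenario`` — phage components plus decoys (SMG-bearing,
  too-short, oversized) for classification and audit tests.
* ``make_simphage_scenario`` — two single-unitig genomes plus a two-variant
  mosaic, mimicking a small simulated-community assembly graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotations import PhrogHit, SmgHit
from .graph_io import (
    AssemblyGraph,
    EdgeEvidence,
    OrientedLink,
    Unitig,
    write_coverage,
    write_gfa,
    write_spanning_evidence,
)

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


@dataclass
class PlantedScenario:
    """A generated graph plus the ground truth needed to verify recovery."""

    name: str
    graph: AssemblyGraph
    evidence: EdgeEvidence
    phrog_hits: List[PhrogHit]
    smg_hits: List[SmgHit]
    genomes: List[Tuple[str, int]]  # (sequence, weight/coverage)
    expected: Dict[str, object]
    config: Dict[str, object] = field(default_factory=dict)
    rng_seed: int = 0

    def write(self, outdir: str | Path) -> Dict[str, Path]:
        """Emit GFA + TSVs + a ground-truth manifest into ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gfa": outdir / "assembly.gfa",
            "coverage": outdir / "coverage.tsv",
            "phrog": outdir / "phrog_hits.tsv",
            "smg": outdir / "smg_hits.tsv",
            "spanning": outdir / "spanning.tsv",
            "manifest": outdir / "manifest.json",
        }
        write_gfa(self.graph, paths["gfa"])
        write_coverage(self.graph, paths["coverage"])
        with open(paths["phrog"], "w") as fh:
            for h in self.phrog_hits:
                fh.write(
                    f"{h.unitig_id}\t{h.phrog_id}\t{h.category}\t{h.identity}\t{h.evalue}\n"
                )
        with open(paths["smg"], "w") as fh:
            for h in self.smg_hits:
                fh.write(f"{h.unitig_id}\t{h.marker_name}\t{h.aligned_fraction}\n")
        write_spanning_evidence(self.evidence, paths["spanning"])
        manifest = {
            "name": self.name,
            "rng_seed": self.rng_seed,
            "config": self.config,
            "expected": self.expected,
            "genome_lengths": [len(s) for s, _ in self.genomes],
            "genome_weights": [w for _, w in self.genomes],
        }
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        return paths


def make_figure3_component() -> PlantedScenario:
    """Five-unitig branching component with three planted genomes.

    Unitig 1 is the longest and is the st vertex; the junction edge (2→3)
    carries 10 spanning read pairs.  Coverages are chosen so that the edge
    weight we(2→3) = 4 and the component's maximum coverage is 9, giving the
    flow interval [4, ⌊1.2 × 9⌋] = [4, 10] on every edge upper bound.  The
    decomposition is uniquely k = 3: paths 1→2→3 (weight 4), 1→2→4 (6) and
    1→5 (2).  The bundled config lowers mincov to 2 because the toy coverage
    scale sits below the real-data default of 10.
    """
    rng = np.random.default_rng(1403)
    lengths = {"1": 4000, "2": 3000, "3": 2500, "4": 2600, "5": 3500}
    coverages = {"1": 9.0, "2": 8.0, "3": 4.0, "4": 6.0, "5": 2.0}
    graph = AssemblyGraph()
    for uid, n in lengths.items():
        graph.unitigs[uid] = Unitig(id=uid, sequence=_random_seq(rng, n),
                                    mean_coverage=coverages[uid])
    for u, v in [("1", "2"), ("2", "3"), ("2", "4"), ("3", "1"),
                 ("4", "1"), ("1", "5"), ("5", "1")]:
        graph.links.append(OrientedLink(u, "+", v, "+", 0))
    evidence = EdgeEvidence()
    evidence.add_pair("2", "3", 10)
    phrog = [PhrogHit("1", "phrog_7", "tail", 85.0, 1e-30)]
    seqs = {u: graph.unitigs[u].sequence for u in lengths}
    genomes = [
        (seqs["1"] + seqs["2"] + seqs["3"], 4),
        (seqs["1"] + seqs["2"] + seqs["4"], 6),
        (seqs["1"] + seqs["5"], 2),
    ]
    expected = {
        "case": "CASE3",
        "st_vertex": "1",
        "covmax": 9.0,
        "alpha": 1.2,
        "interval_2_3": [4, 10],
        "k": 3,
        "paths": [["1", "2", "3"], ["1", "2", "4"], ["1", "5"]],
        "weights": [4, 6, 2],
    }
    return PlantedScenario(
        name="figure3",
        graph=graph,
        evidence=evidence,
        phrog_hits=phrog,
        smg_hits=[],
        genomes=genomes,
        expected=expected,
        config={"mincov": 2},
        rng_seed=1403,
    )


def default_mosaic_weights(n_variants: int) -> List[int]:
    """Geometric coverages 200, 400, 800, … — far enough apart that the
    coverage-balance rule never links branches of different variants."""
    return [200 * 2**i for i in range(n_variants)]


def make_mosaic_scenario(
    n_variants: int = 2,
    genome_length: int = 40000,
    n_shared_modules: int = 2,
    weights: Optional[Sequence[int]] = None,
    seed: int = 0,
    overlap: int = 25,
) -> PlantedScenario:
    """Variant genomes sharing backbone modules, collapsed into a unitig graph.

    Each of the ``n_variants`` circular genomes traverses the same
    ``n_shared_modules`` backbone unitigs in order, with a variant-specific
    unitig between consecutive backbones (a bubble per junction site).
    Coverage of a unitig is the summed weight of the genomes through it, and
    paired-end evidence is planted on every true junction (20 pairs per
    edge, 15 per backbone-bracketing triple).  With one variant the genome
    collapses to a single circular unitig.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    weights = list(weights) if weights is not None else default_mosaic_weights(n_variants)
    if len(weights) != n_variants or any(w <= 0 for w in weights):
        raise ValueError("need one positive weight per variant")
    rng = np.random.default_rng(seed)
    graph = AssemblyGraph()
    evidence = EdgeEvidence()

    if n_variants == 1:
        if overlap >= genome_length:
            raise ValueError("overlap must be shorter than the genome")
        core = _random_seq(rng, genome_length - overlap)
        seq = core + core[:overlap]
        graph.unitigs["m0"] = Unitig("m0", seq, float(weights[0]))
        graph.links.append(OrientedLink("m0", "+", "m0", "+", overlap))
        expected = {"case": "CASE1", "k": 1, "weights": weights}
        return PlantedScenario(
            name="mosaic",
            graph=graph,
            evidence=evidence,
            phrog_hits=[PhrogHit("m0", "phrog_2", "head and packaging", 80.0, 1e-25)],
            smg_hits=[],
            genomes=[(core, weights[0])],
            expected=expected,
            rng_seed=seed,
        )

    m = n_shared_modules
    if m < 1:
        raise ValueError("need at least one shared module")
    module_len = genome_length // (2 * m)
    unique_core_len = module_len - 2 * overlap
    if unique_core_len < 1:
        raise ValueError("modules shorter than the link overlap")

    backbone_ids = [f"b{j}" for j in range(m)]
    backbone_len = {j: module_len + (500 if j == 0 else 0) for j in range(m)}
    backbones = {j: _random_seq(rng, backbone_len[j]) for j in range(m)}
    total_w = sum(weights)
    for j in range(m):
        graph.unitigs[backbone_ids[j]] = Unitig(
            backbone_ids[j], backbones[j], float(total_w)
        )
    unique_ids: Dict[Tuple[int, int], str] = {}
    for j in range(m):
        nxt = (j + 1) % m
        for g in range(n_variants):
            uid = f"u{j}v{g}"
            unique_ids[(j, g)] = uid
            core = _random_seq(rng, unique_core_len)
            seq = backbones[j][-overlap:] + core if overlap else core
            seq = seq + (backbones[nxt][:overlap] if overlap else "")
            graph.unitigs[uid] = Unitig(uid, seq, float(weights[g]))
            graph.links.append(OrientedLink(backbone_ids[j], "+", uid, "+", overlap))
            graph.links.append(OrientedLink(uid, "+", backbone_ids[nxt], "+", overlap))
            evidence.add_pair(backbone_ids[j], uid, 20)
            evidence.add_pair(uid, backbone_ids[nxt], 20)
    for j in range(m):
        prev = (j - 1) % m
        for g in range(n_variants):
            evidence.add_triple(
                unique_ids[(prev, g)], backbone_ids[j], unique_ids[(j, g)], 15
            )

    genomes: List[Tuple[str, int]] = []
    expected_paths: List[List[str]] = []
    for g in range(n_variants):
        seq = backbones[0]
        path = [backbone_ids[0]]
        for j in range(m):
            uid = unique_ids[(j, g)]
            seq += graph.unitigs[uid].sequence[overlap:]
            path.append(uid)
            if j + 1 < m:
                seq += backbones[j + 1][overlap:]
                path.append(backbone_ids[j + 1])
        seq = seq[overlap:] if overlap else seq  # wrap-around trim at the start
        genomes.append((seq, weights[g]))
        expected_paths.append(path)

    expected = {
        "case": "CASE3",
        "st_vertex": backbone_ids[0],
        "covmax": float(total_w),
        "k": n_variants,
        "paths": expected_paths,
        "weights": list(weights),
    }
    return PlantedScenario(
        name="mosaic",
        graph=graph,
        evidence=evidence,
        phrog_hits=[PhrogHit(backbone_ids[0], "phrog_2", "head and packaging", 80.0, 1e-25)],
        smg_hits=[],
        genomes=genomes,
        expected=expected,
        rng_seed=seed,
    )


def make_case2_scenario(
    repeat_len: int = 600,
    core_len: int = 38000,
    coverage: float = 30.0,
    overlap: int = 0,
    seed: int = 0,
) -> PlantedScenario:
    """Terminal-repeat component: short repeat closing a cycle with the core.

    The planted genome is repeat + core + repeat (overlap-trimmed at both
    junctions); the repeat's coverage is twice the core's, as it occurs
    twice per virion chromosome.  Default repeat length 600 bp matches the
    scale of terminal repeats seen in environmental phages.
    """
    if repeat_len >= core_len:
        raise ValueError("repeat must be shorter than the core")
    if overlap and overlap >= repeat_len:
        raise ValueError("overlap must be shorter than the repeat")
    rng = np.random.default_rng(seed)
    repeat = _random_seq(rng, repeat_len)
    middle = _random_seq(rng, core_len - 2 * overlap)
    core = (repeat[-overlap:] if overlap else "") + middle + (repeat[:overlap] if overlap else "")
    graph = AssemblyGraph()
    graph.unitigs["1"] = Unitig("1", core, coverage)
    graph.unitigs["2"] = Unitig("2", repeat, 2 * coverage)
    graph.links.append(OrientedLink("2", "+", "1", "+", overlap))
    graph.links.append(OrientedLink("1", "+", "2", "+", overlap))
    genome = repeat + core[overlap:] + repeat[overlap:]
    expected = {
        "case": "CASE2",
        "repeat_id": "2",
        "core_id": "1",
        "repeat_length": repeat_len,
        "genome_length": len(genome),
        "coverage": coverage,
    }
    return PlantedScenario(
        name="case2",
        graph=graph,
        evidence=EdgeEvidence(),
        phrog_hits=[PhrogHit("1", "phrog_5", "connector", 70.0, 1e-20)],
        smg_hits=[],
        genomes=[(genome, int(coverage))],
        expected=expected,
        rng_seed=seed,
    )


def make_mixed_scenario(seed: int = 0, giant_size: int = 250) -> PlantedScenario:
    """Mixed graph for classification/audit tests.

    Components, in audit order: a good 5 kb circular phage (CASE1), an
    SMG-bearing decoy (HAS_SMG), a 1.5 kb phage-like singleton (TOO_SHORT),
    a no-structural-PHROG pair (NO_STRUCTURAL_PHROG), and a ``giant_size``-
    unitig cycle that classifies CASE3 but exceeds the solvable-size cap
    (SKIPPED_TOO_LARGE in the pipeline audit).
    """
    rng = np.random.default_rng(seed)
    graph = AssemblyGraph()
    phrog: List[PhrogHit] = []
    smg: List[SmgHit] = []

    graph.unitigs["a1"] = Unitig("a1", _random_seq(rng, 5000), 50.0)
    graph.links.append(OrientedLink("a1", "+", "a1", "+", 0))
    phrog.append(PhrogHit("a1", "phrog_7", "tail", 88.0, 1e-40))

    for uid in ("b1", "b2"):
        graph.unitigs[uid] = Unitig(uid, _random_seq(rng, 4000), 30.0)
    graph.links.append(OrientedLink("b1", "+", "b2", "+", 0))
    phrog.append(PhrogHit("b1", "phrog_9", "tail", 60.0, 1e-15))
    smg.append(SmgHit("b2", "rpsC", 0.8))

    graph.unitigs["c1"] = Unitig("c1", _random_seq(rng, 1500), 25.0)
    phrog.append(PhrogHit("c1", "phrog_4", "connector", 55.0, 1e-12))

    for uid in ("d1", "d2"):
        graph.unitigs[uid] = Unitig(uid, _random_seq(rng, 3000), 20.0)
    graph.links.append(OrientedLink("d1", "+", "d2", "+", 0))

    giant_ids = [f"g{i:03d}" for i in range(giant_size)]
    for uid in giant_ids:
        graph.unitigs[uid] = Unitig(uid, _random_seq(rng, 300), 40.0)
    for i, uid in enumerate(giant_ids):
        graph.links.append(
            OrientedLink(uid, "+", giant_ids[(i + 1) % giant_size], "+", 0)
        )
    phrog.append(PhrogHit(giant_ids[0], "phrog_2", "head and packaging", 75.0, 1e-22))

    expected = {
        "audit": {
            "0": "CASE1",
            "1": "HAS_SMG",
            "2": "TOO_SHORT",
            "3": "NO_STRUCTURAL_PHROG",
            "4": "SKIPPED_TOO_LARGE",
        },
        "n_genomes": 1,
    }
    return PlantedScenario(
        name="mixed",
        graph=graph,
        evidence=EdgeEvidence(),
        phrog_hits=phrog,
        smg_hits=smg,
        genomes=[(graph.unitigs["a1"].sequence, 50)],
        expected=expected,
        rng_seed=seed,
    )


def _merge_into(
    dst: PlantedScenario, src: PlantedScenario, prefix: str
) -> None:
    """Copy ``src``'s graph/evidence/hits into ``dst`` with prefixed ids."""
    ren = {uid: f"{prefix}{uid}" for uid in src.graph.unitigs}
    for uid, unitig in src.graph.unitigs.items():
        dst.graph.unitigs[ren[uid]] = Unitig(ren[uid], unitig.sequence, unitig.mean_coverage)
    for l in src.graph.links:
        dst.graph.links.append(
            OrientedLink(ren[l.from_id], l.from_orient, ren[l.to_id], l.to_orient, l.overlap_bp)
        )
    for (u, v), c in src.evidence.pair_confidence.items():
        dst.evidence.add_pair(ren[u], ren[v], c)
    for (t, u, v), c in src.evidence.triple_confidence.items():
        dst.evidence.add_triple(ren[t], ren[u], ren[v], c)
    for h in src.phrog_hits:
        dst.phrog_hits.append(
            PhrogHit(ren[h.unitig_id], h.phrog_id, h.category, h.identity, h.evalue)
        )
    for h in src.smg_hits:
        dst.smg_hits.append(SmgHit(ren[h.unitig_id], h.marker_name, h.aligned_fraction))
    dst.genomes.extend(src.genomes)


def make_simphage_scenario(seed: int = 0) -> PlantedScenario:
    """Small simulated-community graph: two single-unitig phage genomes plus
    a two-variant mosaic pair (weights 200 and 400), giving three connected
    components and four planted genomes."""
    rng = np.random.default_rng(seed)
    combined = PlantedScenario(
        name="simphage",
        graph=AssemblyGraph(),
        evidence=EdgeEvidence(),
        phrog_hits=[],
        smg_hits=[],
        genomes=[],
        expected={},
        rng_seed=seed,
    )
    circular = make_mosaic_scenario(
        n_variants=1, genome_length=8000, seed=int(rng.integers(2**31))
    )
    circular.genomes = [(circular.genomes[0][0], 100)]
    circular.graph.unitigs["m0"].mean_coverage = 100.0
    _merge_into(combined, circular, "p_")

    linear_seq = _random_seq(rng, 10000)
    combined.graph.unitigs["t_0"] = Unitig("t_0", linear_seq, 150.0)
    combined.phrog_hits.append(PhrogHit("t_0", "phrog_3", "lysis", 65.0, 1e-18))
    combined.genomes.append((linear_seq, 150))

    mosaic = make_mosaic_scenario(
        n_variants=2, genome_length=30000, n_shared_modules=2,
        weights=[200, 400], seed=int(rng.integers(2**31)),
    )
    _merge_into(combined, mosaic, "s_")

    combined.expected = {
        "n_components": 3,
        "n_genomes": 4,
        "mosaic_weights": [200, 400],
        "mosaic_paths": [["s_" + v for v in p] for p in mosaic.expected["paths"]],
        "coverages": [100, 150, 200, 400],
    }
    combined.genomes.sort(key=lambda g: g[1])
    return combined


def write_evidence_sam(
    graph: AssemblyGraph, evidence: EdgeEvidence, path: str | Path
) -> None:
    """Emit a SAM whose primary read-1 records reproduce the evidence counts.

    One record per spanning pair (mate position information is nominal); a
    triple (t, u, v) is emitted as cp additional pairs with mates on t and
    v, which the SAM-derived counting will attribute to every junction
    unitig linked to both.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for uid, unitig in graph.unitigs.items():
            fh.write(f"@SQ\tSN:{uid}\tLN:{unitig.length}\n")
        n = 0

        def emit(u: str, v: str, count: int) -> None:
            nonlocal n
            rl = min(50, graph.length(u))
            for _ in range(count):
                fh.write(
                    f"r{n:07d}\t67\t{u}\t1\t60\t{rl}M\t{v}\t1\t0\t{'A' * rl}\t*\n"
                )
                n += 1

        for (u, v), c in sorted(evidence.pair_confidence.items()):
            emit(u, v, c)
        for (t, u, v), c in sorted(evidence.triple_confidence.items()):
            emit(t, v, c)
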