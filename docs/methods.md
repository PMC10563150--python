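# Methods

## Model

`phagepaths` treats a viral metagenome assembly graph as a superposition of
circular phage genomes. A connected component containing several variant
genomes shows the classic mosaic signature: long shared unitigs carrying
the summed coverage of all variants, with variant-specific unitigs
branching off and rejoining. The resolution problem is cast as **minimum
inexact flow decomposition with subpath constraints (MIFD)**: find the
fewest source-to-sink paths with positive integer weights whose
superposed flow lies inside every edge's interval and which jointly cover
every evidence-supported subpath.

Key modelling choices and their rationale:

* **Edge weights.** w_e(u→v) = min(cov(u), cov(v)). The minimum is robust
  against the inflated coverage of shared unitigs: at a junction where a
  high-coverage backbone meets a variant-specific unitig, the minimum
  equals the variant's own coverage, which is the flow the edge actually
  carries.
* **Inexact intervals.** Sequencing depth is uneven, so exact flow
  conservation rarely holds. Each edge is constrained to
  [⌊w_e⌋, ⌊α·covmax⌋] with α ≥ 1 (default 1.2) and covmax the maximum
  unitig coverage in the (dead-end-free) component. The lower bound is
  floored so the integer feasible region is never smaller than the
  real-valued one.
* **Orientation handling.** Each GFA link is one unitig-level arc carrying
  its orientation pair (d1, d2); the reverse-complement twin is identified
  with that arc rather than added as a separate reversed arc. Adding
  unitig-level reverse twins would make every digraph symmetric and
  destroy the BFS-layering st-vertex criterion, which relies on the link
  directions as written. Orientations are replayed during sequence
  reconstruction; a path whose orientation chain cannot be made consistent
  is skipped with an error log.
* **st vertex.** For each candidate vertex (longest unitig first, ties by
  id) the BFS layer iterator is computed; the candidate qualifies when
  every final-layer vertex has successor set exactly {candidate}. The
  split reattaches the st vertex's out-arcs to s and in-arcs to t. A
  residual cycle avoiding s/t, or the absence of a qualifying vertex,
  leaves the component UNRESOLVED rather than heuristically edited.
* **Subpath constraints.** Pairs (u,v) with ≥ `mincov` spanning read
  pairs; triples (t,u,v) through a junction u with ≥ `mincov` bracketing
  pairs *or* |w_e(t→u) − w_e(u→v)| < `covtolerance` (balanced coverage
  implies the same genome continues straight through). Triples whose
  middle vertex is the st vertex wrap around the source/sink cut and are
  dropped — they are not expressible as subpaths of any s–t path.

## ILP formulation

For fixed k, per path i: binary arc indicators x_ie forming one unit of
s→t flow (out(s) = 1, in(t) = 1, conservation elsewhere — in a DAG this
forces a single simple path), an integer weight w_i ≥ 1, and linearised
products z_ie = x_ie·w_i via big-M = max upper bound. Per arc:
lower ≤ Σ_i z_ie ≤ upper. Per constraint R_j: binary r_ji with
Σ_{e∈R_j} x_ie ≥ |R_j|·r_ji and Σ_i r_ji ≥ 1. Weights are ordered
non-increasingly to break path-permutation symmetry. k is increased from 1
until feasible, so the returned k is minimal by construction; this keeps
each ILP small and mirrors the iterative scheme standard for minimum flow
decomposition ILPs.

The interval conditions pin k but usually not the weights. As a canonical
tie-break the objective at the feasible k minimises
Σ_e |Σ_i z_ie − w_e|, the total deviation of the superposed flow from the
observed edge weights. On coverage-consistent data this recovers the
planted weights exactly and makes output deterministic (HiGHS via
`scipy.optimize.milp` is deterministic for a fixed instance; identical
decomposed paths are merged post hoc with summed weights). An infeasible
instance at k_max (default min(32, 4·outdeg(s))) is re-solved with slack
variables on the lower bounds and constraint coverage, and the positive
slacks are reported as diagnostics.

`oracle_mifd` is an independent reference for tiny instances (≤ 10
vertices, ≤ 14 arcs, ≤ 30 s–t paths): it enumerates every path multiset up
to k_limit and every weight vector up to weight_limit and replays the
conditions directly. It shares no code path with the ILP and is used to
validate minimality on randomized instances.

## Parameters

| name | default | meaning |
|---|---|---|
| `minlength` | 2000 bp | minimum genome (and single-unitig component) length; approximate lower bound for tailed-phage genomes |
| `mincov` | 10 | minimum spanning read pairs for a subpath constraint, and minimum path weight (coverage) for an emitted genome |
| `alpha` | 1.2 | coverage multiplier for interval upper bounds; larger values tolerate more uneven depth but admit more decompositions |
| `covtolerance` | 100 | coverage-balance window for junction triples; branch coverages closer than this are assumed to continue the same genome |
| `max_unitigs` | 200 | largest component handed to the ILP; larger components are audited as SKIPPED_TOO_LARGE |
| `phrog_min_identity` | 30 % | PHROG hit identity cutoff (inclusive) |
| `phrog_max_evalue` | 1e-10 | PHROG hit e-value cutoff (strict) |
| `smg_min_fraction` | 0.5 | fraction of a marker gene that must align (strict) for an SMG to count |
| `time_limit` | 300 s | per-ILP solve budget; timeout leaves the component UNRESOLVED |

Boundary semantics are deliberate and tested: identity ≥ 30 retained,
e-value must be strictly below the cutoff, SMG aligned fraction strictly
above 0.5, genome length strictly above `minlength`, path weight ≥
`mincov`.

## Synthetic scenarios

The fixture generators emit the same on-disk formats the pipeline consumes
(GFA 1.0, coverage/PHROG/SMG/spanning TSVs) plus a ground-truth manifest,
so every I/O path is exercised. They emulate the *structure* of real
viral assembly graphs — module sharing, terminal repeats, coverage
superposition — not the read-level noise process:

* **figure3** — the five-unitig worked example. Coverages {9, 8, 4, 6, 2}
  reproduce the canonical quantities (w_e(2→3) = 4, covmax = 9, interval
  [4, 10], st = 1) and force a unique k = 3 decomposition with weights
  (4, 6, 2): the s→2 interval [8, 10] saturates against the branch lower
  bounds 4 and 6. The bundle's recommended `mincov` is 2 because the toy
  coverage scale sits below the real-data default of 10 — with mincov 10
  no path in a covmax-9 component could pass the coverage filter.
* **mosaic** — n variant circular genomes traversing m shared backbone
  modules with variant-specific modules in between. Unitig coverage is the
  exact sum of the weights of the genomes through it, so the planted
  decomposition has zero deviation and is the unique optimum; default
  weights 200·2^i keep variant coverages ≥ `covtolerance` apart so the
  coverage-balance rule never bridges different variants (with closer
  weights the model itself — not this implementation — admits spurious
  cross-variant constraints). Links carry a 25 bp overlap by default,
  exercising overlap trimming.
* **case2** — a 600 bp terminal repeat (the scale observed in
  environmental phage assemblies) closing a cycle with a 38 kb core; the
  repeat's coverage is twice the core's, as it occurs twice per virion
  chromosome.
* **mixed** — classification decoys: an SMG-bearing component, a 1.5 kb
  singleton, a component without structural PHROGs, and a 250-unitig cycle
  exceeding `max_unitigs`.
* **simphage** — two single-unitig genomes (coverages 100 and 150) plus a
  two-variant mosaic (200 and 400), a small multi-component community.

Because coverages are exactly consistent and spanning evidence noise-free,
passing tests demonstrate correctness of the graph model, the ILP and the
sequence reconstruction — not robustness to chimeric links, coverage
dispersion or mapping artefacts in real data.

The SAM emitted by `write_evidence_sam` contains one primary read-1 record
per planted spanning pair with nominal coordinates; it exercises the
alignment-counting path, whose triple attribution counts a pair toward
every junction unitig linked to both mates (the flanking interpretation —
the insert is not required to cover the junction unitig end to end).

## Numerical and degenerate-input choices

* Lower bounds ⌊w_e⌋; upper ⌊α·covmax⌋; weights and flows are integers.
* covmax is computed after dead-end removal so pruned stubs cannot inflate
  the upper bound.
* Case-2 repeat choice: shorter unitig; length ties go to the
  lexicographically smaller id (logged).
* Case-3 genomes are emitted starting at the st unitig; comparisons to
  reference genomes should be rotation- and strand-invariant.
* Overlap trimming removes each traversed link's CIGAR match length from
  the downstream unitig; the wrap-around overlap is trimmed once from the
  sequence start. Genome length is exactly Σ member lengths − Σ traversed
  overlaps (the Case-2 repeat counted twice).
* GC content excludes ambiguous bases from the denominator; an all-N
  sequence reports missing GC.
* Empty coverage tables, absent evidence entries and annotation-free
  unitigs default to 0 / empty with warnings, not errors.

## Limitations

* One genome family per component and a single st vertex: components whose
  cycles share no common vertex are reported UNRESOLVED, as are those with
  residual cycles after the split.
* Plasmids that encode phage-homologous proteins ("phage-plasmids") can
  pass the classification filters; downstream screening is the user's
  responsibility.
* The coverage-balance triple rule is a heuristic: variants with coverages
  closer than `covtolerance` can receive cross-variant constraints, which
  may inflate k. Distinguishing such variants needs read evidence
  (`cp` counts) rather than coverage.
* Prophage excision, multi-sample coverage matrices and long-read graphs
  are out of scope.
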