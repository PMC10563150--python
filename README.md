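# phagepaths

Resolve complete bacteriophage genomes from fragmented viral metagenome
assemblies.

Phage populations are mosaic: closely related variant genomes share long
sequence modules and differ in others. De Bruijn assemblers collapse the
shared modules into single unitigs, so each phage "species" ends up as a
tangle of branching paths in the assembly graph rather than as one contig,
and per-contig viral identification tools recover only fragments.
`phagepaths` works on the graph instead of on individual sequences: it
finds phage-like connected components, models each as a flow network whose
edge capacities come from read coverage, and decomposes the network into
the minimum number of weighted source-to-sink paths — one per variant
genome.

## Method

For each connected component of the GFA unitig graph:

1. **Classification.** A component is *phage-like* when none of its unitigs
   carries a bacterial single-copy marker gene (SMG) and at least one
   carries a structural PHROG (head and packaging, connector, tail, lysis).
   Single-unitig components must exceed `minlength` (2000 bp).
2. **Cases.** One unitig → the unitig is the genome (Case 1). Two unitigs
   closing a cycle → the shorter is a terminal repeat, attached to both
   ends of the longer (Case 2). More than two unitigs → flow decomposition
   (Case 3).
3. **Flow model (Case 3).** Each edge u→v gets weight
   w_e(u→v) = min(cov(u), cov(v)). Dead-ends are removed recursively, a
   source/sink vertex *st* common to all cyclic paths is found by BFS
   layering and split into s and t, and each edge receives the flow
   interval [w_e, ⌊α·covmax⌋] (α = 1.2, covmax = the component's maximum
   unitig coverage). Read pairs spanning adjacent unitigs (≥ `mincov`
   pairs) and coverage-balanced junction triples (|Δw_e| < `covtolerance`)
   become *subpath constraints* R.
4. **MIFD.** Find the minimum k and paths P₁..P_k with weights
   w_i ∈ ℤ⁺ such that for every edge
   f_uv ≤ Σ_{i:(u,v)∈P_i} w_i ≤ f̄_uv and every R_j ∈ R is a subpath of
   some P_i. Solved as a feasibility ILP for k = 1, 2, … (HiGHS via
   `scipy.optimize.milp`); among feasible solutions at the optimal k the
   superposed flow's total deviation from the edge weights is minimised,
   which pins canonical path weights.
5. **Genomes.** Each retained path (length > `minlength`, weight ≥
   `mincov`) is translated to a sequence by orientation-aware
   concatenation with link-overlap trimming; the path weight is reported
   as the genome's coverage, together with length and GC content.

## Worked example

The bundled five-unitig component has edges 1→2, 2→3, 2→4, 3→1, 4→1, 1→5,
5→1, coverages {1: 9, 2: 8, 3: 4, 4: 6, 5: 2} and 10 read pairs spanning
(2,3). Vertex 1 is the st vertex; the edge (2→3) has weight
min(8, 4) = 4 and interval [4, ⌊1.2 × 9⌋] = [4, 10].

```bash
phagepaths simulate figure3 --outdir demo/in
phagepaths run --gfa demo/in/assembly.gfa --coverage demo/in/coverage.tsv \
    --phrog-hits demo/in/phrog_hits.tsv --smg-hits demo/in/smg_hits.tsv \
    --spanning demo/in/spanning.tsv --outdir demo/out --mincov 2
# 3 genome(s) resolved from 1 phage component(s)
cat demo/out/genome_info.tsv
```

```
genome_id            component_id  length  coverage  gc      n_unitigs  unitigs
phage_comp_0_path_0  0             9600    6         0.4989  3          1+,2+,4+
phage_comp_0_path_1  0             9500    4         0.4972  3          1+,2+,3+
phage_comp_0_path_2  0             7500    2         0.4932  2          1+,5+
```

The decomposition is uniquely k = 3: paths 1→2→3, 1→2→4 and 1→5 with
weights 4, 6 and 2 — three variant genomes sharing unitig 1 (and 2), each
emitted with its flow value as coverage. (`--mincov 2` scales the
evidence/coverage threshold down to this toy component's coverage range;
real data uses the default 10.)

Other generators: `simulate mosaic --variants 3` (variant genomes sharing
backbone modules), `simulate case2 --repeat 600` (terminal-repeat
component), `simulate simphage` (a small multi-component community),
`simulate mixed` (classification decoys). Each bundle includes a
`manifest.json` with the planted ground truth.

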