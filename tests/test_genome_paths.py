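"""Sequence reconstruction for all three cases, GC content and outputs."""

import pytest
from Bio import SeqIO

from conftest import circular_equal
from phagepaths import fixtures
from phagepaths.annotations import build_annotations
from phagepaths.components import Case, PhageComponent, classify_all
from phagepaths.flow_model import prepare_case3
from phagepaths.genome_paths import (
    AuditRow,
    audit_rows,
    compute_gc,
    resolve_case1,
    resolve_case2,
    resolve_case3,
    reverse_complement,
    write_outputs,
)
from phagepaths.graph_io import AssemblyGraph, OrientedLink, Unitig
from phagepaths.mifd_solver import solve_mifd


@pytest.mark.parametrize(
    "seq,expected",
    [("ATGC", 0.5), ("GGGG", 1.0), ("ATNN", 0.0), ("AATT", 0.0)],
)
def test_gc_fraction(seq, expected):
    assert compute_gc(seq) == pytest.approx(expected)


def test_gc_undefined_for_all_ambiguous():
    assert compute_gc("NNNN") is None


def test_reverse_complement_round_trip():
    s = "ATGCCGTAN"
    assert reverse_complement(reverse_complement(s)) == s
    assert reverse_complement("ATGC") == "GCAT"


class TestCase1:
    def test_linear_unitig_is_the_genome(self):
        g = AssemblyGraph()
        g.unitigs["1"] = Unitig("1", "ACGT" * 1000, 42.0)
        comp = PhageComponent("0", ("1",), Case.CASE1, 42.0)
        path = resolve_case1(comp, g)
        assert path.sequence == g.unitigs["1"].sequence
        assert path.coverage == 42.0

    def test_circular_unitig_trims_terminal_self_overlap(self):
        core = "ACGTACGATTTTGGGCACA" * 20
        seq = core + core[:55]
        g = AssemblyGraph()
        g.unitigs["1"] = Unitig("1", seq, 10.0)
        g.links.append(OrientedLink("1", "+", "1", "+", 55))
        comp = PhageComponent("0", ("1",), Case.CASE1, 10.0)
        path = resolve_case1(comp, g)
        assert path.length == len(seq) - 55
        assert path.sequence == core


class TestCase2:
    def test_repeat_flanks_core_with_zero_overlaps(self, case2_scenario):
        sc = case2_scenario
        comp = PhageComponent("0", tuple(sorted(sc.graph.unitigs)), Case.CASE2, 60.0)
        path = resolve_case2(comp, sc.graph)
        repeat = sc.graph.unitigs["2"].sequence
        core = sc.graph.unitigs["1"].sequence
        assert path.sequence == repeat + core + repeat
        assert path.length == len(core) + 2 * len(repeat)
        assert path.coverage == sc.graph.coverage("1")
        assert path.repeat_length == 600

    def test_overlaps_trimmed_at_both_junctions(self):
        sc = fixtures.make_case2_scenario(repeat_len=600, core_len=5000,
                                          overlap=40, seed=2)
        comp = PhageComponent("0", ("1", "2"), Case.CASE2, 60.0)
        path = resolve_case2(comp, sc.graph)
        assert path.length == 600 + (5000 - 40) + (600 - 40)
        assert path.sequence == sc.genomes[0][0]

    def test_negative_link_orientation_reverse_complements(self):
        # cycle traversed r+ -> c- -> r+: the core enters reverse-complemented
        repeat = "ACGTTGCA" * 10
        core_fwd = "ATGCATCCGGTT" * 50
        g = AssemblyGraph()
        g.unitigs["r"] = Unitig("r", repeat, 20.0)
        g.unitigs["c"] = Unitig("c", core_fwd, 10.0)
        g.links.append(OrientedLink("r", "+", "c", "-", 0))
        g.links.append(OrientedLink("c", "-", "r", "+", 0))
        comp = PhageComponent("0", ("c", "r"), Case.CASE2, 20.0)
        path = resolve_case2(comp, g)
        assert path.sequence == repeat + reverse_complement(core_fwd) + repeat


class TestCase3:
    def solve(self, scenario, mincov):
        ann = build_annotations(scenario.phrog_hits, scenario.smg_hits)
        accepted, _ = classify_all(scenario.graph, ann)
        comp = accepted[0]
        net, cons = prepare_case3(comp, scenario.graph, scenario.evidence,
                                  mincov=mincov)
        decomp = solve_mifd(net, cons)
        return comp, net, decomp

    def test_weight_below_mincov_dropped(self, figure3):
        comp, net, decomp = self.solve(figure3, mincov=2)
        kept = resolve_case3(comp, decomp, net, figure3.graph, mincov=10)
        # only weights >= 10 survive; the toy component has none
        assert kept == []
        all_kept = resolve_case3(comp, decomp, net, figure3.graph, mincov=2)
        assert len(all_kept) == 3

    def test_path_sequences_concatenate_members(self, figure3):
        comp, net, decomp = self.solve(figure3, mincov=2)
        paths = resolve_case3(comp, decomp, net, figure3.graph, mincov=2)
        seqs = {g.sequence for g in paths}
        for planted, _ in figure3.genomes:
            assert planted in seqs

    def test_length_accounting_with_overlaps(self):
        sc = fixtures.make_mosaic_scenario(n_variants=2, seed=11, overlap=30)
        comp, net, decomp = self.solve(sc, mincov=10)
        paths = resolve_case3(comp, decomp, net, sc.graph, mincov=10)
        for g in paths:
            member_total = sum(
                len(sc.graph.unitigs[uid].sequence) for uid, _ in g.member_unitigs
            )
            n_traversed_links = len(g.member_unitigs)  # incl. the wrap-around
            assert g.length == member_total - 30 * n_traversed_links

    def test_planted_genomes_recovered_up_to_rotation(self):
        sc = fixtures.make_mosaic_scenario(n_variants=2, seed=11, overlap=30)
        comp, net, decomp = self.solve(sc, mincov=10)
        paths = resolve_case3(comp, decomp, net, sc.graph, mincov=10)
        by_cov = {g.coverage: g.sequence for g in paths}
        for planted, w in sc.genomes:
            assert circular_equal(by_cov[w], planted)


class TestOutputs:
    def test_empty_inputs_give_valid_empty_files(self, tmp_path):
        files = write_outputs([], [], tmp_path)
        assert list(SeqIO.parse(files["fasta"], "fasta")) == []
        assert files["genome_info"].read_text().count("\n") == 1  # header only

    def test_fasta_round_trip_and_headers(self, tmp_path, figure3):
        ann = build_annotations(figure3.phrog_hits, figure3.smg_hits)
        accepted, rejected = classify_all(figure3.graph, ann)
        comp = accepted[0]
        net, cons = prepare_case3(comp, figure3.graph, figure3.evidence, mincov=2)
        decomp = solve_mifd(net, cons)
        genomes = resolve_case3(comp, decomp, net, figure3.graph, mincov=2)
        files = write_outputs(genomes, audit_rows(accepted, rejected), tmp_path)
        records = {r.id: r for r in SeqIO.parse(files["fasta"], "fasta")}
        assert len(records) == len(genomes)
        for g in genomes:
            assert str(records[g.genome_id].seq) == g.sequence
            assert f"coverage={g.coverage:g}" in records[g.genome_id].description
        info_lines = files["genome_info"].read_text().strip().splitlines()
        assert len(info_lines) - 1 == len(genomes)

    def test_emitted_genomes_pass_their_own_filters(self, tmp_path):
        """Re-check each emitted genome against its case's predicates."""
        sc = fixtures.make_mosaic_scenario(n_variants=3, seed=5)
        ann = build_annotations(sc.phrog_hits, sc.smg_hits)
        accepted, _ = classify_all(sc.graph, ann)
        comp = accepted[0]
        net, cons = prepare_case3(comp, sc.graph, sc.evidence)
        decomp = solve_mifd(net, cons)
        genomes = resolve_case3(comp, decomp, net, sc.graph,
                                minlength=2000, mincov=10)
        assert genomes
        for g in genomes:
            assert g.length > 2000
            assert g.coverage >= 10
            assert g.length == len(g.sequence)
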