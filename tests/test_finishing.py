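"""Scaffolding, zero-mismatch gap closure, and assembly assessment."""
import numpy as np
import pytest

import plastomekit as pk
from plastomekit import finishing as fin
from plastomekit import seq as sq
from plastomekit import synthetic as syn
from plastomekit.synthetic import Contig, ContigSet


class TestScaffoldContigs:
    def test_ir_boundary_contigs_recover_truth_order(self, plastome_full):
        cs = syn.fragment_plastome(plastome_full, "at_IR_boundaries")
        sc = fin.scaffold_contigs(cs, plastome_full)
        assert [p.contig_id for p in sc.placements] == \
            [c.id for c in cs.contigs]
        assert [p.ref_start for p in sc.placements] == \
            [c.origin_start for c in cs.contigs]
        assert all(p.strand == "+" for p in sc.placements)
        assert sc.gaps == [0, 0, 0, 0]

    def test_single_full_contig_places_with_zero_gap(self, plastome_full):
        cs = ContigSet([Contig("c", plastome_full.sequence, 0,
                               len(plastome_full))], len(plastome_full))
        sc = fin.scaffold_contigs(cs, plastome_full)
        assert len(sc.placements) == 1
        assert sc.placements[0].ref_start == 0
        assert sc.gaps == [0]

    def test_reverse_complement_contig_placed_on_minus(self, plastome_full):
        lsc = plastome_full.region_seq("LSC")
        cs = ContigSet([Contig("c", sq.revcomp(lsc), 0, 0)],
                       len(plastome_full))
        sc = fin.scaffold_contigs(cs, plastome_full)
        assert sc.placements[0].strand == "-"
        assert sc.placements[0].ref_start == 0

    def test_foreign_contig_reported_unplaced(self, plastome_full, rng):
        cs = ContigSet([
            Contig("good", plastome_full.region_seq("SSC"), 0, 0),
            Contig("foreign", sq.random_dna(3000, 0.6, rng), 0, 0)],
            len(plastome_full))
        sc = fin.scaffold_contigs(cs, plastome_full)
        assert sc.unplaced == ["foreign"]

    def test_nothing_placeable_raises(self, plastome_full, rng):
        cs = ContigSet([Contig("x", sq.random_dna(2000, 0.5, rng), 0, 0)],
                       len(plastome_full))
        with pytest.raises(fin.UnscaffoldableError):
            fin.scaffold_contigs(cs, plastome_full)

    def test_small_anchor_k_rejected(self, plastome_full):
        cs = syn.fragment_plastome(plastome_full, "at_IR_boundaries")
        with pytest.raises(ValueError):
            fin.scaffold_contigs(cs, plastome_full, anchor_k=10)


class TestCloseGaps:
    def test_round_trip_recovers_truth_circle(self, plastome_full, read_set):
        cs = syn.fragment_plastome(plastome_full, "at_IR_boundaries")
        sc = fin.scaffold_contigs(cs, plastome_full)
        res = fin.close_gaps(sc, cs, read_set)
        assert res.closed
        assert sq.circularly_equal(res.plastome.sequence,
                                   plastome_full.sequence)

    def test_overlap_below_threshold_rejected(self):
        """A 19 bp perfect overlap must not be used at min_overlap=20."""
        rng = np.random.default_rng(8)
        genome = sq.random_dna(2000, 0.5, rng)
        left, right = genome[:1000], genome[1000:]
        cs = ContigSet([Contig("a", left, 0, 1000),
                        Contig("b", right, 1000, 2000)], 2000)
        sc = fin.Scaffold(
            placements=[fin.Placement("a", 0, 0, 1000, "+", 99),
                        fin.Placement("b", 1, 1000, 2000, "+", 99)],
            gaps=[0, 0], unplaced=[], ref_len=2000)
        # single bridging read whose overlap with the left flank is 19 bp
        read = genome[981:1081]
        reads = syn.ReadSet([syn.Read("r1", read, "I" * 100, 981, "+")],
                            read_len=100, genome_len=2000)
        res = fin.close_gaps(sc, cs, reads, min_overlap=20)
        assert "a->b" in res.open_gaps
        res2 = fin.close_gaps(sc, cs, reads, min_overlap=19)
        assert "a->b" not in res2.open_gaps

    def test_one_mismatch_in_overlap_rejected(self):
        """25 bp overlap with a single mismatch violates the zero-mismatch rule."""
        rng = np.random.default_rng(9)
        genome = sq.random_dna(2000, 0.5, rng)
        cs = ContigSet([Contig("a", genome[:1000], 0, 1000),
                        Contig("b", genome[1000:], 1000, 2000)], 2000)
        sc = fin.Scaffold(
            placements=[fin.Placement("a", 0, 0, 1000, "+", 99),
                        fin.Placement("b", 1, 1000, 2000, "+", 99)],
            gaps=[0, 0], unplaced=[], ref_len=2000)
        read = list(genome[975:1075])
        read[10] = "A" if read[10] != "A" else "C"   # inside the 25 bp overlap
        reads = syn.ReadSet([syn.Read("r1", "".join(read), "I" * 100, 975, "+")],
                            read_len=100, genome_len=2000)
        res = fin.close_gaps(sc, cs, reads, min_overlap=20)
        assert "a->b" in res.open_gaps

    def test_min_overlap_monotonicity(self, plastome_full):
        """Raising min_overlap never increases the number of closed gaps."""
        cs = syn.fragment_plastome(plastome_full, "at_IR_boundaries")
        sc = fin.scaffold_contigs(cs, plastome_full)
        reads = syn.simulate_reads(plastome_full, coverage=3, seed=13)
        closed = []
        for mo in (20, 40, 80):
            res = fin.close_gaps(sc, cs, reads, min_overlap=mo)
            n_open = len(res.open_gaps) + len(res.ambiguities)
            closed.append(len(sc.placements) - n_open)
        assert closed == sorted(closed, reverse=True)

    def test_no_reads_leaves_gaps_open(self, plastome_full):
        cs = syn.fragment_plastome(plastome_full, "at_IR_boundaries")
        sc = fin.scaffold_contigs(cs, plastome_full)
        res = fin.close_gaps(sc, cs, reads=None)
        assert not res.closed
        assert res.open_gaps


class TestAssessAssembly:
    def test_truth_reads_give_zero_inconsistencies(self, plastome_full,
                                                   read_set):
        rep = fin.assess_assembly(plastome_full, read_set)
        assert rep.inconsistencies == []
        assert rep.n_mapped == len(read_set.reads)

    def test_single_corrupted_base_is_recovered(self, plastome_full):
        reads = syn.simulate_reads(plastome_full, coverage=30, seed=21)
        pos = 60_000
        s = plastome_full.sequence
        corrupted = s[:pos] + ("A" if s[pos] != "A" else "C") + s[pos + 1:]
        rep = fin.assess_assembly(corrupted, reads)
        assert len(rep.inconsistencies) == 1
        found_pos, ref_base, majority, depth = rep.inconsistencies[0]
        assert found_pos == pos
        assert majority == s[pos]
        assert depth > 0

    def test_mean_depth_is_total_mapped_bases_over_length(self, plastome_full,
                                                          read_set):
        rep = fin.assess_assembly(plastome_full, read_set)
        expect = rep.n_mapped * read_set.read_len / len(plastome_full)
        assert rep.mean_depth == pytest.approx(expect)
        assert rep.mean_depth == pytest.approx(
            float(rep.per_position_depth.mean()))

    def test_empty_read_set_gives_zero_depth(self, plastome_full):
        empty = syn.ReadSet([], genome_len=len(plastome_full))
        rep = fin.assess_assembly(plastome_full, empty)
        assert rep.mean_depth == 0.0
        assert not rep.per_position_depth.any()
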