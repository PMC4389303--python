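"""The synthetic-data generator: genomes, variants, reads, contigs."""
import numpy as np
import pytest

import plastomekit as pk
from plastomekit import seq as sq
from plastomekit import synthetic as syn
from plastomekit.finishing import assess_assembly


class TestGeneratePlastome:
    def test_acidosasa_sized_spec_total_length(self):
        # printed region lengths of a real temperate bamboo plastome
        spec = pk.PlastomeSpec(lsc_len=83_273, ssc_len=12_834, ir_len=21_795,
                               seed=1)
        assert spec.total_len == 139_697
        p = pk.generate_plastome(spec)
        assert len(p) == 139_697
        assert p.region_lengths() == {"LSC": 83_273, "IRb": 21_795,
                                      "SSC": 12_834, "IRa": 21_795}

    def test_region_sum_and_ir_mirror(self, plastome_full):
        p = plastome_full
        rl = p.region_lengths()
        assert sum(rl.values()) == len(p)
        assert p.is_ir_mirrored()
        p.validate()

    def test_base_composition_within_one_percent(self, plastome_full):
        assert sq.at_fraction(plastome_full.sequence) == pytest.approx(
            0.61, abs=0.01)

    def test_pure_at_composition(self):
        p = pk.generate_plastome(pk.PlastomeSpec(
            lsc_len=8000, ssc_len=2000, ir_len=2500, at_fraction=1.0,
            n_genes=0, seed=0))
        assert set(p.sequence) <= {"A", "T"}

    def test_seeded_determinism(self):
        a = pk.generate_plastome(pk.PlastomeSpec(seed=5))
        b = pk.generate_plastome(pk.PlastomeSpec(seed=5))
        c = pk.generate_plastome(pk.PlastomeSpec(seed=6))
        assert a.sequence == b.sequence
        assert a.features == b.features
        assert a.sequence != c.sequence

    def test_features_non_overlapping_with_spacers(self, plastome_full):
        feats = plastome_full.features_sorted()
        assert len(feats) == 94        # 80 genes + 14 IR-duplicated copies
        for f, g in zip(feats, feats[1:]):
            assert g.start > f.end     # at least one spacer base between

    def test_named_marker_spacers_resolve(self, plastome_full):
        for locus in ("rpl23-ndhB", "rps16-trnQ", "trnD-psbM", "petA-psbJ"):
            s, e = plastome_full.spacer(locus)
            assert 0 <= s < e <= len(plastome_full)

    def test_infeasible_spec_raises(self):
        with pytest.raises(syn.InfeasibleSpecError):
            pk.generate_plastome(pk.PlastomeSpec(
                lsc_len=5000, ssc_len=2000, ir_len=3000, seed=0))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            pk.PlastomeSpec(at_fraction=1.5).validate()
        with pytest.raises(ValueError):
            pk.PlastomeSpec(ir_len=0).validate()


class TestPlantVariants:
    def test_empty_spec_list_is_identity(self, plastome_full):
        out, truth = syn.plant_variants(plastome_full, [], seed=0)
        assert out.sequence == plastome_full.sequence
        assert truth == []

    def test_insertion_increases_length_by_payload(self, plastome_full):
        out, truth = syn.plant_variants(
            plastome_full,
            [syn.VariantSpec("insertion", "rps16-trnQ", 2706)], seed=0)
        assert len(out) - len(plastome_full) == 2706
        (rec,) = truth
        assert rec.length == 2706 and rec.end - rec.start == 2706
        # planted payload sits exactly at the recorded interval
        assert out.sequence[:rec.start] == plastome_full.sequence[:rec.start]

    def test_ir_insertion_is_mirrored_into_both_copies(self, plastome_full):
        out, truth = syn.plant_variants(
            plastome_full,
            [syn.VariantSpec("insertion", "rpl23-ndhB", 2706)], seed=1)
        assert len(out) - len(plastome_full) == 2 * 2706
        assert len(truth) == 2
        assert out.is_ir_mirrored()
        a, b = truth
        assert (sq.revcomp(out.sequence[b.start:b.end])
                == out.sequence[a.start:a.end])

    def test_inversion_involution_restores_sequence(self, plastome_full):
        out, truth = syn.plant_variants(
            plastome_full,
            [syn.VariantSpec("inversion", "trnD-psbM", 150)], seed=2)
        (rec,) = truth
        s = out.sequence
        restored = (s[:rec.start] + sq.revcomp(s[rec.start:rec.end])
                    + s[rec.end:])
        assert restored == plastome_full.sequence

    def test_inversion_flank_motifs_planted(self, plastome_full):
        out, truth = syn.plant_variants(
            plastome_full,
            [syn.VariantSpec("inversion", "trnD-psbM", 150,
                             flank_repeat="CCYTTTTY")], seed=2)
        (rec,) = truth
        assert out.sequence[rec.start - 8:rec.start] == "CCYTTTTY"
        assert out.sequence[rec.end:rec.end + 8] == sq.revcomp("CCYTTTTY")
        assert len(out) - len(plastome_full) == 16

    def test_planted_at_contrast_for_large_inserts(self, plastome_full):
        out, truth = syn.plant_variants(
            plastome_full,
            [syn.VariantSpec("insertion", "petA-psbJ", 2000,
                             payload_at_fraction=0.55)], seed=3)
        (rec,) = truth
        insert_at = sq.at_fraction(out.sequence[rec.start:rec.end])
        background = sq.at_fraction(plastome_full.sequence)
        assert background - insert_at >= 0.04

    def test_overlapping_variants_rejected(self, plastome_full):
        s, _ = plastome_full.spacer("petA-psbJ")
        specs = [syn.VariantSpec("deletion", s, 500),
                 syn.VariantSpec("insertion", s + 100, 200)]
        with pytest.raises(ValueError, match="overlap"):
            syn.plant_variants(plastome_full, specs, seed=0)

    def test_unknown_locus_raises(self, plastome_full):
        with pytest.raises(KeyError):
            syn.plant_variants(
                plastome_full,
                [syn.VariantSpec("insertion", "nad7-cox1", 100)], seed=0)

    def test_features_shift_past_edits(self, plastome_full):
        out, truth = syn.plant_variants(
            plastome_full,
            [syn.VariantSpec("insertion", "rps16-trnQ", 500)], seed=0)
        (rec,) = truth
        for f_in, f_out in zip(plastome_full.features_sorted(),
                               out.features_sorted()):
            shift = 500 if f_in.start >= rec.start else 0
            assert f_out.start == f_in.start + shift
            assert out.sequence[f_out.start:f_out.end] == \
                plastome_full.sequence[f_in.start:f_in.end]


class TestSimulateReads:
    def test_read_count_matches_coverage(self):
        genome = "ACGT" * 35_000      # 140 kb
        rs = syn.simulate_reads(genome, coverage=50, read_len=100, seed=0)
        assert len(rs) == 70_000

    def test_error_free_reads_are_substrings_of_doubled_circle(
            self, plastome_full):
        rs = syn.simulate_reads(plastome_full, coverage=0.05, seed=1)
        g2 = plastome_full.sequence * 2
        for r in rs.reads:
            assert r.sequence in g2 or sq.revcomp(r.sequence) in g2

    def test_mapped_depth_matches_requested_coverage(self, plastome_full,
                                                     read_set):
        report = assess_assembly(plastome_full, read_set)
        assert report.mean_depth == pytest.approx(25, rel=0.05)

    def test_paired_reads_have_matching_mates(self, plastome_full):
        rs = syn.simulate_reads(plastome_full, coverage=0.2, pairing="paired",
                                seed=2)
        n = len(plastome_full)
        g2 = plastome_full.sequence * 2
        for m1, m2 in rs.pairs():
            assert m1.id[:-2] == m2.id[:-2]
            fwd = m1 if m1.origin_strand == "+" else m2
            rev = m2 if m1.origin_strand == "+" else m1
            gap = (rev.origin_start - fwd.origin_start) % n + rs.read_len
            assert abs(gap - rs.insert_size) <= 4 * rs.insert_sd

    def test_error_rate_produces_mismatches(self, plastome_full):
        rs = syn.simulate_reads(plastome_full, coverage=0.05,
                                error_rate=0.01, seed=3)
        g2 = plastome_full.sequence * 2
        exact = sum(r.sequence in g2 or sq.revcomp(r.sequence) in g2
                    for r in rs.reads)
        assert exact < len(rs)

    def test_bad_parameters_rejected(self, plastome_full):
        with pytest.raises(ValueError):
            syn.simulate_reads(plastome_full, coverage=0)
        with pytest.raises(ValueError):
            syn.simulate_reads(plastome_full, coverage=1, error_rate=0.2)
        with pytest.raises(ValueError):
            syn.simulate_reads("ACGT" * 10, coverage=1, read_len=100)


class TestFragmentPlastome:
    def test_ir_boundary_breaks_coincide_with_regions(self, plastome_full):
        cs = syn.fragment_plastome(plastome_full, "at_IR_boundaries")
        assert len(cs) == 4
        starts = [c.origin_start for c in cs.contigs]
        assert starts == [plastome_full.region(r)[0]
                          for r in ("LSC", "IRb", "SSC", "IRa")]

    def test_single_random_break_yields_rotation(self, plastome_full):
        cs = syn.fragment_plastome(plastome_full, "random_k", seed=5, k=1)
        assert len(cs) == 1
        assert sq.circularly_equal(cs.contigs[0].sequence,
                                   plastome_full.sequence)

    @pytest.mark.parametrize("overlap", [0, 50])
    def test_reassembly_round_trip(self, plastome_full, overlap):
        cs = syn.fragment_plastome(plastome_full, "random_k", seed=6, k=7,
                                   overlap=overlap)
        assert sq.circularly_equal(syn.reassemble_contigs(cs),
                                   plastome_full.sequence)

    def test_contigs_partition_the_circle(self, plastome_full):
        cs = syn.fragment_plastome(plastome_full, "at_IR_boundaries")
        total = sum(c.origin_end - c.origin_start for c in cs.contigs)
        assert total == len(plastome_full)
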