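"""Anchor alignment, indel/inversion detection, flank motifs, synapomorphies."""
import numpy as np
import pytest

from plastomekit import seq as sq
from tests.oracles import brute_force_flank, clades_brute_force, random_tree
from plastomekit import synthetic as syn
from plastomekit import variants as va


class TestAnchorAlign:
    def test_identical_sequences_single_block(self, rng):
        s = sq.random_dna(5000, 0.6, rng)
        chain = va.anchor_align(s, s)
        assert len(chain.blocks) == 1
        b = chain.blocks[0]
        assert (b.qstart, b.qend, b.tstart, b.tend) == (0, 5000, 0, 5000)
        assert chain.gaps() == []

    def test_revcomp_gives_single_minus_block(self, rng):
        s = sq.random_dna(5000, 0.6, rng)
        chain = va.anchor_align(sq.revcomp(s), s)
        assert chain.blocks == [] or chain.query_coverage() < 0.05
        assert len(chain.minus_blocks) == 1
        m = chain.minus_blocks[0]
        assert (m.qstart, m.qend, m.tstart, m.tend) == (0, 5000, 0, 5000)

    def test_deletion_appears_as_target_side_gap(self, rng):
        s = sq.random_dna(20_000, 0.6, rng)
        q = s[:8000] + s[9500:]
        chain = va.anchor_align(q, s)
        gaps = [(qg, tg) for _, _, qg, tg in chain.gaps()
                if tg > 100 or qg > 100]
        assert len(gaps) == 1
        qg, tg = gaps[0]
        assert tg - qg == 1500

    def test_coverage_high_for_variant_only_differences(self, marker_sample):
        ref, sample, _ = marker_sample
        chain = va.anchor_align(sample.sequence, ref.sequence)
        assert chain.query_coverage() >= 0.95

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            va.anchor_align("ACGT", "ACGTACGTACGTACGTACGTACGT")


class TestDetectIndels:
    def test_marker_events_recovered_with_exact_lengths(self, marker_sample):
        ref, sample, truth = marker_sample
        chain = va.anchor_align(sample.sequence, ref.sequence)
        detected = va.detect_indels(chain, ref.features)
        by_locus = {r.locus: r for r in detected}
        ins = by_locus["rpl23-ndhB"]
        assert ins.kind == "insertion" and ins.length == 2706
        small = by_locus["rps16-trnQ"]
        assert small.kind == "insertion" and small.length == 500
        dele = by_locus["petA-psbJ"]
        assert dele.kind == "deletion" and dele.length == 1500
        # IR-mirrored copy of the big insertion is also called
        assert by_locus["ndhB-rpl23"].length == 2706

    def test_endpoints_match_truth_within_two_bases(self, marker_sample):
        ref, sample, truth = marker_sample
        chain = va.anchor_align(sample.sequence, ref.sequence)
        detected = va.detect_indels(chain, ref.features) + \
            va.detect_inversions(sample.sequence, ref.sequence,
                                 annotations=ref.features, chain=chain)
        for t in truth:
            match = [d for d in detected if d.kind == t.kind
                     and d.length == t.length and abs(d.start - t.start) <= 2]
            assert match, f"{t.kind} {t.locus} not recovered"

    def test_gap_below_min_len_not_reported(self, rng):
        s = sq.random_dna(20_000, 0.6, rng)
        q = s[:10_000] + sq.random_dna(99, 0.5, rng) + s[10_000:]
        chain = va.anchor_align(q, s)
        assert va.detect_indels(chain, min_len=100) == []
        assert len(va.detect_indels(chain, min_len=99)) == 1


class TestDetectInversions:
    def test_planted_inversion_recovered(self, marker_sample):
        ref, sample, truth = marker_sample
        recs = va.detect_inversions(sample.sequence, ref.sequence,
                                    annotations=ref.features)
        t = next(r for r in truth if r.kind == "inversion")
        assert len(recs) == 1
        r = recs[0]
        assert r.length == 150
        assert r.locus == "trnD-psbM"
        assert abs(r.start - t.start) <= 2

    def test_no_inversion_gives_empty_list(self, rng):
        s = sq.random_dna(20_000, 0.6, rng)
        q = s[:10_000] + sq.random_dna(500, 0.5, rng) + s[10_000:]
        assert va.detect_inversions(q, s) == []

    def test_reinverting_detected_interval_restores_collinearity(
            self, marker_sample):
        ref, sample, _ = marker_sample
        (r,) = va.detect_inversions(sample.sequence, ref.sequence)
        s = sample.sequence
        fixed = s[:r.start] + sq.revcomp(s[r.start:r.end]) + s[r.end:]
        assert va.detect_inversions(fixed, ref.sequence) == []


class TestFindInvertedFlanks:
    def test_published_motif_pair_scores_eight(self):
        rng = np.random.default_rng(4)
        core = sq.random_dna(150, 0.5, rng)
        s = (sq.random_dna(300, 0.5, rng) + "CCYTTTTY" + core + "GAAAAAGG"
             + sq.random_dna(300, 0.5, rng))
        start = 308
        f, (up, down) = va.find_inverted_flanks(s, (start, start + 150))
        assert f == 8
        assert (up, down) == ("CCYTTTTY", "GAAAAAGG")

    def test_exact_palindromic_flanks(self):
        s = "GGGG" + "AAAA" + "CCCCCC" + "TTTT" + "GGGG"
        f, _ = va.find_inverted_flanks(s, (8, 14))
        assert f == 4

    def test_agrees_with_brute_force_on_random_iupac(self):
        rng = np.random.default_rng(12)
        codes = np.array(list("ACGTRYSWKMN"))
        for _ in range(300):
            n = int(rng.integers(40, 120))
            s = "".join(rng.choice(codes, size=n))
            start = int(rng.integers(10, n - 20))
            end = int(rng.integers(start + 1, n - 9))
            got, _ = va.find_inverted_flanks(s, (start, end), max_flank=10)
            assert got == brute_force_flank(s, start, end, 10)


class TestMapSynapomorphies:
    def test_parianinae_insert_marks_clade_branch(self):
        tree = "((A,B),((Eremitis_sp,Pariana_radiciflora),(C,D)));"
        rec = va.VariantRecord(kind="insertion", locus="rpl23-ndhB",
                               start=0, end=2706, length=2706,
                               taxa=("Eremitis_sp", "Pariana_radiciflora"))
        (a,) = va.map_synapomorphies([rec], tree)
        assert a.status == "synapomorphy"
        assert set(a.clade) == {"Eremitis_sp", "Pariana_radiciflora"}

    def test_single_taxon_is_autapomorphy(self):
        tree = "((A,B),(C,D));"
        rec = va.VariantRecord(kind="deletion", locus="x", start=0, end=0,
                               length=10, taxa=("C",))
        (a,) = va.map_synapomorphies([rec], tree)
        assert a.status == "autapomorphy"
        assert a.clade == ("C",)

    def test_straddling_taxa_flagged_conflicting(self):
        tree = "((A,B),(C,D));"
        rec = va.VariantRecord(kind="insertion", locus="x", start=0, end=10,
                               length=10, taxa=("A", "C"))
        (a,) = va.map_synapomorphies([rec], tree)
        assert a.status == "homoplastic/conflicting"
        assert set(a.clade) == {"A", "B", "C", "D"}

    def test_unknown_taxon_raises(self):
        with pytest.raises(KeyError):
            va.map_synapomorphies(
                [va.VariantRecord(kind="insertion", locus="x", start=0,
                                  end=1, length=1, taxa=("nope",))],
                "((A,B),(C,D));")

    def test_agrees_with_exhaustive_clade_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            nwk = random_tree(rng)
            clades = clades_brute_force(nwk)
            size = int(rng.integers(1, 6))
            taxa = tuple(f"T{i}" for i in
                         rng.choice(10, size=size, replace=False))
            rec = va.VariantRecord(kind="insertion", locus="x", start=0,
                                   end=1, length=1, taxa=taxa)
            (a,) = va.map_synapomorphies([rec], nwk)
            is_clade = frozenset(taxa) in clades or len(taxa) == 1
            if is_clade:
                assert a.status in ("synapomorphy", "autapomorphy")
                assert set(a.clade) == set(taxa)
            else:
                assert a.status == "homoplastic/conflicting"
                covering = [c for c in clades if set(taxa) <= c]
                minimal = min(covering, key=len)
                assert set(a.clade) == set(minimal)
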