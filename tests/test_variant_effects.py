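import numpy as np
import pytest
from Bio.Seq import Seq

from gvpop.io_formats import OrfAnnotation
from gvpop.variant_effects import (
    Effect,
    EffectCall,
    classify_indel,
    classify_microsatellite,
    classify_snv,
    orf_length_variant_summary,
    scan_hrs,
    HR_MOTIF,
)

# Hand-built 64-bp genome:
#   0-3   TTTT            intergenic
#   4-15  ATGAAACCCTAA    orfP (+): Met Lys Pro Stop
#   16-19 GACT            intergenic
#   20-31 TTAGGAACCCAT    orfM (-): coding ATGGGTTCCTAA
#   32-35 CCCC            intergenic
#   36-59 ATG AAAAAA ACGACGACG CCC TAA   orfR (+) with microsatellite tracts
#   60-63 GGGG            intergenic
GENOME = "TTTT" + "ATGAAACCCTAA" + "GACT" + "TTAGGAACCCAT" + "CCCC" + "ATGAAAAAAACGACGACGCCCTAA" + "GGGG"
ORFS = [
    OrfAnnotation("orfP", 4, 16, "+"),
    OrfAnnotation("orfM", 20, 32, "-"),
    OrfAnnotation("orfR", 36, 60, "+"),
]


def single(calls):
    assert len(calls) == 1
    return calls[0]


class TestEffectTaxonomy:
    """Twelve hand-built codon cases spanning the full variant taxonomy."""

    @pytest.mark.parametrize(
        "pos, ref, alt, expected_orf, expected_effect",
        [
            (9, "A", "G", "orfP", Effect.SYNONYMOUS_SNV),  # AAA->AAG, Lys
            (8, "A", "C", "orfP", Effect.NONSYNONYMOUS_SNV),  # AAA->ACA
            (6, "G", "A", "orfP", Effect.TRANSLATION_START_SITE_SNV),  # ATG->ATA
            (13, "T", "C", "orfP", Effect.TERMINATION_SITE_SNV),  # TAA->CAA
            (0, "T", "A", None, Effect.INTERGENIC),
            (26, "A", "G", "orfM", Effect.SYNONYMOUS_SNV),  # GGT->GGC on '-'
            (28, "C", "T", "orfM", Effect.NONSYNONYMOUS_SNV),  # GGT->AGT on '-'
        ],
    )
    def test_snv_cases(self, pos, ref, alt, expected_orf, expected_effect):
        call = single(classify_snv(pos, ref, alt, ORFS, GENOME))
        assert call.orf == expected_orf
        assert call.effect is expected_effect

    @pytest.mark.parametrize(
        "pos, ref, alt, expected_orf, expected_effect, unit",
        [
            (6, "GAAA", "G", "orfP", Effect.INFRAME_DELETION, None),  # 3 bp
            (12, "CTA", "C", "orfP", Effect.FRAMESHIFT_DELETION, None),  # 2 bp
            (0, "T", "TGGGG", None, Effect.INTERGENIC, None),  # 4 bp intergenic
            (39, "AA", "A", "orfR", Effect.MICROSATELLITE_FRAMESHIFT_DEL, 1),
            (44, "A", "AACG", "orfR", Effect.MICROSATELLITE_INS, 3),
        ],
    )
    def test_indel_cases(self, pos, ref, alt, expected_orf, expected_effect, unit):
        call = single(classify_indel(pos, ref, alt, ORFS, GENOME))
        assert call.orf == expected_orf
        assert call.effect is expected_effect
        assert call.repeat_unit_length == unit

    def test_ref_base_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            classify_snv(9, "C", "G", ORFS, GENOME)

    def test_microsatellite_category_requires_unit_length(self):
        with pytest.raises(ValueError):
            EffectCall(position=0, orf="x", effect=Effect.MICROSATELLITE_INS)


class TestMicrosatellite:
    def test_single_nucleotide_repeat_deletion(self):
        # deletion of "A" inside the AAAAAA tract (Type I)
        assert classify_microsatellite(39, "AA", "A", GENOME) == 1

    def test_trinucleotide_repeat_insertion(self):
        # insertion of "ACG" adjacent to ACGACGACG (Type III)
        assert classify_microsatellite(44, "A", "AACG", GENOME) == 3

    def test_non_repetitive_context_is_null(self):
        # deletion of "AC" with no flanking tandem copies
        assert classify_microsatellite(16, "GAC", "G", GENOME) is None

    def test_min_copies_threshold(self):
        genome = "TTTT" + "ACAC" + "TTTT"  # only 2 flanking copies
        assert classify_microsatellite(3, "TAC", "T", genome, min_copies=3) is None
        assert classify_microsatellite(3, "TAC", "T", genome, min_copies=1) == 2


class TestStrandConsistency:
    def test_minus_strand_equals_plus_on_reverse_complement(self):
        """Classifying a '-' ORF equals classifying its reverse complement as '+'."""
        L = len(GENOME)
        rc = str(Seq(GENOME).reverse_complement())
        orf_m = ORFS[1]
        orf_flip = OrfAnnotation("orfM", L - orf_m.end, L - orf_m.start, "+")
        rng = np.random.default_rng(0)
        for _ in range(30):
            pos = int(rng.integers(orf_m.start, orf_m.end))
            ref = GENOME[pos]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            fwd = single(classify_snv(pos, ref, alt, [orf_m], GENOME))
            pos2 = L - 1 - pos
            ref2 = str(Seq(ref).complement())
            alt2 = str(Seq(alt).complement())
            rev = single(classify_snv(pos2, ref2, alt2, [orf_flip], rc))
            assert fwd.effect is rev.effect


class TestHrScan:
    def test_motif_is_its_own_reverse_complement(self):
        assert str(Seq(HR_MOTIF).reverse_complement()) == HR_MOTIF

    def test_motif_free_sequence_yields_nothing(self):
        seq = "AC" * 500  # no window within 1 mismatch of the motif
        assert scan_hrs(seq) == []

    def test_three_planted_motifs_make_one_region(self):
        rng = np.random.default_rng(5)
        # AC-repeat background cannot contain near-motif windows
        seq = list("AC" * 1000)
        for off in (100, 220, 340):
            seq[off : off + 10] = HR_MOTIF
        seq = "".join(seq)
        regions = scan_hrs(seq)
        assert len(regions) == 1
        r = regions[0]
        assert r.n_repeats == 3
        assert r.hit_positions == (100, 220, 340)
        assert r.start == 100 and r.end == 350

    def test_exact_hits_are_subset_of_one_mismatch_hits(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        seq = seq[:1000] + HR_MOTIF + seq[1000:2000] + "TTTACGTAAC" + seq[2000:]
        exact = {p for r in scan_hrs(seq, max_mismatches=0, min_repeats=1) for p in r.hit_positions}
        fuzzy = {p for r in scan_hrs(seq, max_mismatches=1, min_repeats=1) for p in r.hit_positions}
        assert exact <= fuzzy

    def test_min_repeats_drops_singletons(self):
        seq = "AC" * 200 + HR_MOTIF + "AC" * 200
        assert scan_hrs(seq, min_repeats=2) == []
        assert len(scan_hrs(seq, min_repeats=1)) == 1

    def test_non_palindromic_motif_warns(self):
        with pytest.warns(UserWarning, match="reverse complement"):
            scan_hrs("ACGT" * 100, motif="AAAAAAAAAA")


class TestWaterfall:
    def test_empty_when_no_length_changing_variants(self):
        calls = {"iso1": classify_snv(9, "A", "G", ORFS, GENOME)}
        table = orf_length_variant_summary(calls, ORFS)
        assert table.empty

    def test_single_cell_counts(self):
        calls = {"iso1": classify_indel(12, "CTA", "C", ORFS, GENOME)}
        table = orf_length_variant_summary(calls, ORFS)
        assert len(table) == 1
        assert table.groupby("orf").size().to_dict() == {"orfP": 1}
        assert table.groupby("sample_id").size().to_dict() == {"iso1": 1}

    def test_marginals_equal_brute_force_recount(self):
        rng = np.random.default_rng(2)
        calls = {}
        for i in range(8):
            sid = f"iso{i}"
            cs = []
            for _ in range(int(rng.integers(0, 4))):
                pos = int(rng.choice([6, 12, 39, 44]))
                ref, alt = {6: ("GAAA", "G"), 12: ("CTA", "C"), 39: ("AA", "A"), 44: ("A", "AACG")}[pos]
                cs.extend(classify_indel(pos, ref, alt, ORFS, GENOME))
            calls[sid] = cs
        table = orf_length_variant_summary(calls, ORFS)
        # brute force: recount distinct (orf, sample, effect) triples
        triples = set()
        for sid, cs in calls.items():
            for c in cs:
                if c.orf is not None and c.effect is not Effect.INTERGENIC:
                    triples.add((c.orf, sid, c.effect.value))
        assert set(map(tuple, table.to_numpy())) == triples
        assert len(table) == len(triples)
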