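import pytest
from Bio.Seq import Seq

from denovotx.orf_screen import (
    CodonAlignmentPair,
    Disabler,
    OrfCall,
    assess_reliability,
    call_orf_status,
    detect_disablers,
    paralog_screen,
    peptide_evidence,
    shared_ancestral_disablers,
)


def pair(focal, outgroup, species="rhesus"):
    return CodonAlignmentPair(
        focal_id="gene1", outgroup_species=species,
        focal_seq=focal, outgroup_seq=outgroup,
    )


class TestAlignmentPair:
    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            pair("ATGTAA", "ATGTA")

    def test_focal_length_must_be_codon_multiple(self):
        with pytest.raises(ValueError):
            pair("ATGTA-", "ATGTAA")

    def test_coverage_identity_recomputable(self):
        # 9 focal bases, 6 aligned, 5 matching
        aln = pair("ATGAAATGA", "ATGAA---C")
        assert aln.coverage == pytest.approx(6 / 9)
        assert aln.identity == pytest.approx(5 / 6)


class TestReliability:
    def test_reliable(self):
        aln = pair("ATG" * 9 + "TAA", "ATG" * 9 + "TAA")
        assert aln.coverage == 1.0 and aln.identity == 1.0
        assert assess_reliability(aln) == "reliable"

    def test_thresholds_inclusive(self):
        # synthetic alignment with coverage exactly 0.70, identity 0.50:
        # 30 focal codons (90 nt), 63 aligned columns of which 31 or 32 match
        focal = "ATGAAACCCGGG" * 7 + "TTT" + "TAA"  # 90 nt
        # out-group: first 63 columns aligned, rest gap; flip bases so
        # exactly ceil(63*0.5) match is awkward — use explicit construction
        aligned = 63
        matches = 32  # 32/63 >= 0.5
        out = []
        for i in range(90):
            if i < aligned:
                out.append(focal[i] if i < matches else _other(focal[i]))
            else:
                out.append("-")
        aln = pair(focal, "".join(out))
        assert aln.coverage == pytest.approx(0.70)
        assert aln.identity >= 0.50
        assert assess_reliability(aln) == "reliable"

    def test_low_coverage_ambiguous(self):
        focal = "ATG" + "AAA" * 28 + "TAA"  # 90 nt
        out = focal[:62] + "-" * 28  # coverage 62/90 = 0.689
        aln = pair(focal, out)
        assert aln.coverage < 0.70
        assert assess_reliability(aln) == "ambiguous"


def _other(base):
    return {"A": "C", "C": "A", "G": "T", "T": "G"}[base]


class TestDetectDisablers:
    def test_premature_stop_read_off(self):
        aln = pair("ATGAAATGGTAA", "ATGTAATGGTAA")
        assert detect_disablers(aln) == [
            Disabler(2, "premature_stop", "TAA")
        ]

    def test_single_nt_deletion(self):
        aln = pair("ATGAAATGGTAA", "ATGA-ATGGTAA")
        [d] = detect_disablers(aln)
        assert d.kind == "frameshift_indel"
        assert d.focal_codon == 2
        assert d.detail == "1"

    def test_identical_sequences_no_disablers(self):
        aln = pair("ATGAAATGGTAA", "ATGAAATGGTAA")
        assert detect_disablers(aln) == []

    def test_in_frame_deletion_is_not_a_disabler(self):
        # 60 focal codons, out-group with one 3-nt deletion
        focal = "ATG" + "GAA" * 58 + "TAA"
        out = focal[:30] + "---" + focal[33:]
        aln = pair(focal, out)
        assert detect_disablers(aln) == []
        # cross-check: the gapless out-group still translates stop-free
        ungapped = out.replace("-", "")
        protein = str(Seq(ungapped).translate())
        assert "*" not in protein[:-1]

    def test_terminal_stop_not_premature(self):
        aln = pair("ATGAAATGGTAA", "ATGAAATGGTAA")
        assert all(d.focal_codon < 4 for d in detect_disablers(aln))

    def test_insertion_frameshift(self):
        # out-group carries a 1-nt insertion between focal codons 2 and 3
        aln = pair("ATGAAA-TGGTAA", "ATGAAACTGGTAA")
        [d] = detect_disablers(aln)
        assert d == Disabler(3, "frameshift_indel", "1")

    def test_offset_stability_prepend_codon_block(self):
        focal = "ATGAAATGGTAA"
        out = "ATGTAATGGTAA"
        base = detect_disablers(pair(focal, out))
        for n in (1, 2, 5):
            shifted = detect_disablers(
                pair("GCC" * n + focal, "GCC" * n + out)
            )
            assert [d.focal_codon for d in shifted] == [
                d.focal_codon + n for d in base
            ]
            assert [d.kind for d in shifted] == [d.kind for d in base]

    def test_two_nt_gap_is_frameshift(self):
        aln = pair("ATGAAATGGTAA", "ATGA--TGGTAA")
        [d] = detect_disablers(aln)
        assert d.kind == "frameshift_indel" and d.detail == "2"


def _aln_with_stops(n_codons, stop_codons):
    """Focal ORF of ``n_codons`` codons; out-group stops at the given
    1-based codons."""
    focal = "ATG" + "GAA" * (n_codons - 2) + "TAA"
    out = list(focal)
    for c in stop_codons:
        out[(c - 1) * 3 : c * 3] = "TAA"
    return pair(focal, "".join(out))


class TestCallOrfStatus:
    def test_mid_orf_stop_absent(self):
        aln = _aln_with_stops(100, [50])
        call = call_orf_status(aln, detect_disablers(aln))
        assert call.max_peptide_fraction == pytest.approx(49 / 99)
        assert call.status == "absent"

    def test_late_stop_still_present(self):
        aln = _aln_with_stops(100, [85])
        call = call_orf_status(aln, detect_disablers(aln))
        assert call.max_peptide_fraction == pytest.approx(84 / 99)
        assert call.status == "present"
        assert len(call.disablers) == 1

    def test_no_disablers_fraction_one(self):
        aln = _aln_with_stops(100, [])
        call = call_orf_status(aln, [])
        assert call.max_peptide_fraction == 1.0
        assert call.status == "present"

    def test_stricter_threshold(self):
        aln = _aln_with_stops(100, [50])
        call = call_orf_status(aln, detect_disablers(aln),
                               max_fraction_threshold=0.50)
        assert call.status == "absent"  # 0.495 < 0.50
        aln2 = _aln_with_stops(100, [48])
        disablers2 = detect_disablers(aln2)
        call2 = call_orf_status(aln2, disablers2, max_fraction_threshold=0.50)
        assert call2.max_peptide_fraction == pytest.approx(51 / 99)
        assert call2.status == "present"

    @pytest.mark.parametrize("stops", [[10], [30], [50, 70], [20, 40, 60]])
    def test_threshold_monotonicity(self, stops):
        """Raising the threshold never flips absent -> present."""
        aln = _aln_with_stops(100, stops)
        disablers = detect_disablers(aln)
        previous_absent = False
        for threshold in (0.1, 0.3, 0.5, 0.7, 0.9):
            status = call_orf_status(aln, disablers, threshold).status
            if previous_absent:
                assert status == "absent"
            previous_absent = status == "absent"


class TestSharedDisablers:
    def test_same_site_same_kind_shared(self):
        calls = [
            OrfCall("chimp", "absent", 0.3,
                    (Disabler(37, "premature_stop", "TAA"),)),
            OrfCall("rhesus", "absent", 0.3,
                    (Disabler(37, "premature_stop", "TGA"),)),
        ]
        [shared] = shared_ancestral_disablers(calls)
        assert shared.focal_codon == 37
        assert shared.species == frozenset({"chimp", "rhesus"})

    def test_kind_mismatch_not_shared(self):
        calls = [
            OrfCall("chimp", "absent", 0.3,
                    (Disabler(37, "premature_stop", "TAA"),)),
            OrfCall("rhesus", "absent", 0.3,
                    (Disabler(37, "frameshift_indel", "1"),)),
        ]
        assert shared_ancestral_disablers(calls) == []


HIT = ["gene1", "other", 98.0, 100, 2, 0, 1, 100, 1, 100, "EVALUE", 180.0]


def _hits(evalue):
    row = list(HIT)
    row[10] = evalue
    return [row]


class TestParalogScreen:
    def test_significant_evalue_fails(self):
        result = paralog_screen("gene1", "MKV", _hits(1e-7))
        assert not result.passed
        assert "E-value" in result.reason

    def test_weak_evalue_but_good_alignment_fails(self):
        protein = "MKVLLAGRSTWEQPHILKNDFY" * 3
        result = paralog_screen(
            "gene1", protein, _hits(1e-5), other_proteins={"other": protein}
        )
        assert not result.passed
        assert "aligns well" in result.reason

    def test_empty_table_passes(self):
        result = paralog_screen("gene1", "MKVLLAGRSTW", [],
                                other_proteins={"other": "WWWWPPPPGGGG"})
        assert result.passed

    def test_malformed_rows_skipped(self):
        rows = [["gene1", "other"], _hits(1e-3)[0]]
        assert paralog_screen("gene1", "MKV", rows).passed


class TestPeptideEvidence:
    def test_unique_exact_match_convincing(self):
        assert peptide_evidence("MKVLLA", "XXMKVLLAYY", []) == "convincing"

    def test_second_best_two_mismatches_convincing(self):
        assert peptide_evidence(
            "MKVLLA", "XXMKVLLAYY", ["XXMKVPPAYY"]
        ) == "convincing"

    def test_second_best_one_mismatch_rejected(self):
        assert peptide_evidence(
            "MKVLLA", "XXMKVLLAYY", ["XXMKVPLAYY"]
        ) == "rejected"

    def test_no_target_match_rejected(self):
        assert peptide_evidence("MKVLLA", "XXYYZZ", []) == "rejected"

    def test_short_peptide_error(self):
        with pytest.raises(ValueError):
            peptide_evidence("MKVLL", "MKVLL", [])
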