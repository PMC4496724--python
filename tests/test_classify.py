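import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampedit import (
    AlleleClass,
    AlleleCount,
    MosaicismCall,
    build_profile,
    classify_allele,
    digest,
    make_allele_set,
    probe_match,
)
from ampedit.classify import DEFAULT_ENZYMES, AlleleCall, RestrictionSite
from ampedit.simulate import EditSpec


class TestClassifyAllele:
    def test_wildtype_identity(self, locus, templates):
        call = classify_allele(locus.window_seq("A"), locus, templates)
        assert call.allele_class is AlleleClass.WT_A
        assert call.edits == ()
        call = classify_allele(locus.window_seq("B"), locus, templates)
        assert call.allele_class is AlleleClass.WT_B

    def test_intended_templates_match_exactly(self, locus, templates):
        for t in templates:
            call = classify_allele(t.window_seq, locus, templates)
            assert call.allele_class is AlleleClass.INTENDED_EDIT
            assert call.label == t.label
            assert call.background == t.background

    def test_24bp_deletion_on_A(self, locus, templates):
        edit = EditSpec("DEL", locus.cut_site - 12, length=24, background="A")
        allele = make_allele_set(locus, [edit])[2]
        call = classify_allele(allele.window_seq, locus, templates)
        assert call.label == "24 bp DEL-A"
        assert call.allele_class is AlleleClass.INDEL

    def test_single_transversion_label(self, locus, templates):
        pos = locus.cut_site + 2
        ref = locus.wt_seq("A")[pos]
        alt = {"A": "T", "T": "A", "C": "G", "G": "C"}[ref]
        allele = make_allele_set(locus, [EditSpec("SUB", pos, bases=alt, background="A")])[2]
        call = classify_allele(allele.window_seq, locus, templates)
        assert call.label == f"{ref}-{alt} TV-A"
        assert call.allele_class is AlleleClass.POINT

    def test_roundtrip_over_full_allele_set(self, locus, templates):
        cut = locus.cut_site
        wt_a = locus.wt_seq("A")
        sub_alt = {"A": "T", "T": "A", "C": "G", "G": "C"}[wt_a[cut + 2]]
        edits = list(templates_edits(locus)) + [
            EditSpec("DEL", cut - 12, length=24, background="A"),
            EditSpec("DEL", cut - 2, length=4, background="B"),
            EditSpec("INS", cut, bases="G", background="A"),
            EditSpec("SUB", cut + 2, bases=sub_alt, background="A"),
        ]
        for allele in make_allele_set(locus, edits):
            call = classify_allele(allele.window_seq, locus, templates)
            assert call.allele_class is allele.allele_class, allele.label
            assert call.label == allele.label
            assert call.background == allele.background

    def test_indel_plus_substitution_is_complex(self, locus, templates):
        t = next(t for t in templates if t.label == "9 bp DEL-B")
        seq = list(t.window_seq)
        # put a substitution far from the deletion so it cannot be absorbed
        seq[3] = "A" if seq[3] != "A" else "G"
        call = classify_allele("".join(seq), locus, templates)
        assert call.allele_class is AlleleClass.COMPLEX
        assert "DEL" in call.label

    def test_template_plus_subs_flag(self, locus, templates):
        t = next(t for t in templates if t.label == "9 bp DEL-B")
        seq = list(t.window_seq)
        seq[3] = "A" if seq[3] != "A" else "G"
        call = classify_allele(
            "".join(seq), locus, templates, include_template_plus_subs=True
        )
        assert call.allele_class is AlleleClass.INTENDED_EDIT
        assert call.label == t.label

    def test_background_ambiguous_when_sites_deleted_and_scores_tie(self, locus, templates):
        ws, we = locus.key_region
        # deleting the entire region covering all polymorphic sites leaves
        # nothing to distinguish A from B
        positions = [p - ws for p, _, _ in locus.poly_sites]
        lo, hi = min(positions), max(positions) + 1
        wt = locus.window_seq("B")
        seq = wt[:lo] + wt[hi:]
        call = classify_allele(seq, locus, templates)
        assert call.background == "ambiguous"

    def test_empty_sequence_raises(self, locus, templates):
        with pytest.raises(ValueError):
            classify_allele("", locus, templates)


def templates_edits(locus):
    from ampedit import example_templates

    return example_templates(locus)


class TestBuildProfile:
    def _counts_calls(self, locus, templates, spec):
        counts, calls = [], []
        for seq, frac in spec:
            counts.append(AlleleCount(seq, int(frac * 1000), frac))
            calls.append(classify_allele(seq, locus, templates))
        return counts, calls

    def test_pure_intended_is_non_mosaic_biallelic(self, locus, templates):
        t = templates[0]
        counts, calls = self._counts_calls(locus, templates, [(t.window_seq, 1.0)])
        profile = build_profile(counts, calls, "e1")
        assert profile.pct_intended == pytest.approx(100.0)
        assert profile.mosaicism_call is MosaicismCall.NON_MOSAIC_BIALLELIC

    def test_63_37_mixture_is_mosaic(self, locus, templates):
        t = templates[0]
        counts, calls = self._counts_calls(
            locus, templates, [(t.window_seq, 0.63), (locus.window_seq("B"), 0.37)]
        )
        profile = build_profile(counts, calls, "z6")
        assert profile.pct_intended == pytest.approx(63.0)
        assert profile.pct_wt == pytest.approx(37.0)
        assert profile.mosaicism_call is MosaicismCall.MOSAIC_EDITED

    def test_pure_wildtype_is_unedited(self, locus, templates):
        counts, calls = self._counts_calls(locus, templates, [(locus.window_seq("B"), 1.0)])
        profile = build_profile(counts, calls, "wt")
        assert profile.pct_wt == pytest.approx(100.0)
        assert profile.mosaicism_call is MosaicismCall.UNEDITED

    def test_threshold_is_strict(self, locus, templates):
        t = templates[0]
        counts, calls = self._counts_calls(
            locus, templates, [(t.window_seq, 0.96), (locus.window_seq("B"), 0.04)]
        )
        # 96% is not > 96%
        assert build_profile(counts, calls).mosaicism_call is MosaicismCall.MOSAIC_EDITED
        counts, calls = self._counts_calls(
            locus, templates, [(t.window_seq, 0.961), (locus.window_seq("B"), 0.039)]
        )
        assert build_profile(counts, calls).mosaicism_call is MosaicismCall.NON_MOSAIC_BIALLELIC

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            build_profile([], [])


class TestDigest:
    def test_single_cut_partitions_length(self):
        seq = "A" * 100 + "TCTAGA" + "C" * 344
        res = digest(seq)["XbaI"]
        assert res.positions == (100,)
        assert res.fragment_lengths == (100, 350)
        assert sum(res.fragment_lengths) == len(seq)

    def test_no_motif_single_fragment(self):
        seq = "ACGT" * 25
        res = digest(seq, [RestrictionSite("XbaI", "TCTAGA")])["XbaI"]
        assert res.positions == ()
        assert res.fragment_lengths == (100,)

    def test_intended_insertion_gains_one_xbai(self, locus, alleles_by_label):
        for bg in ("A", "B"):
            wt = digest(alleles_by_label[f"WT-{bg}"].seq)
            ins = digest(alleles_by_label[f"5 bp INS-{bg}"].seq)
            assert len(ins["XbaI"].positions) - len(wt["XbaI"].positions) == 1

    def test_intended_deletion_loses_one_sfoi(self, locus, alleles_by_label):
        for bg in ("A", "B"):
            wt = digest(alleles_by_label[f"WT-{bg}"].seq)
            dele = digest(alleles_by_label[f"9 bp DEL-{bg}"].seq)
            assert len(wt["SfoI"].positions) - len(dele["SfoI"].positions) == 1

    @given(st.text(alphabet="ACGT", min_size=0, max_size=200))
    @settings(max_examples=100, deadline=None)
    def test_fragments_always_partition_sequence(self, seq):
        for res in digest(seq, DEFAULT_ENZYMES).values():
            assert sum(res.fragment_lengths) == len(seq)


class TestProbeMatch:
    def test_degenerate_y_matches_both_pyrimidines(self):
        assert probe_match("GGACCGTGG", "ACYGT")
        assert probe_match("GGACTGTGG", "ACYGT")
        assert not probe_match("AAAAAAAAA", "ACYGT")

    def test_reverse_complement_matched(self):
        from ampedit import revcomp

        assert probe_match(revcomp("GGACCGTGG"), "ACYGT")

    def test_insertion_at_probe_site_abolishes_match(self, locus, alleles_by_label):
        cut = locus.cut_site
        # probe straddles the insertion point (cut - 11)
        probe = locus.wt_seq("B")[cut - 18 : cut - 4]
        assert probe_match(alleles_by_label["WT-B"].seq, probe)
        assert not probe_match(alleles_by_label["5 bp INS-B"].seq, probe)

    def test_empty_sequence_no_match(self):
        assert not probe_match("", "ACGT")

    def test_invalid_iupac_raises(self):
        with pytest.raises(ValueError):
            probe_match("ACGT", "ACZ")

    def test_empty_probe_raises(self):
        with pytest.raises(ValueError):
            probe_match("ACGT", "")
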