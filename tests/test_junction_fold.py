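"""Folding, helix extraction, junction-hairpin detection, conditionality."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snosplice import annotation as ann
from snosplice import junction_fold as jf
from snosplice import synthetic as syn
from snosplice.errors import AnnotationError, FoldInputError

RC = jf.reverse_complement


def _window(spliced, offset, intron="G" * 40):
    """Hand-built junction window (intron inserted at the offset)."""
    return jf.JunctionWindow(
        transcript_id="t", junction_index=1,
        spliced_seq=spliced,
        unspliced_seq=spliced[:offset] + intron + spliced[offset:],
        junction_offset=offset, intron_span=(offset, offset + len(intron)),
        flank_used=(offset, len(spliced) - offset),
    )


#: GC-only 20-mer arm in an A-only context: the flanks cannot pair with
#: anything, so the MFE structure is exactly the planted duplex
GC_ARM = "GGCCGCGGCCGGCGCCGGCC"


class TestWindowExtraction:
    def test_junction_splits_at_annotated_splice_site(self, mam_locus,
                                                      mam_window):
        truth = mam_locus.truth
        w = mam_window
        assert w.junction_offset == w.flank_used[0]
        assert w.genomic_positions[w.junction_offset] == \
            truth.rel_to_genomic(0)
        assert w.genomic_positions[w.junction_offset - 1] == \
            truth.rel_to_genomic(-1)

    def test_intron_removal_reproduces_spliced(self, mam_window):
        i0, i1 = mam_window.intron_span
        assert (mam_window.unspliced_seq[:i0] + mam_window.unspliced_seq[i1:]
                == mam_window.spliced_seq)

    def test_short_exons_clip_the_flanks(self):
        fasta = ">c\n" + "A" * 120 + "\n"
        gff = ("##gff-version 3\n"
               "c\tt\tgene\t1\t120\t.\t+\t.\tID=g;biotype=lncRNA\n"
               "c\tt\ttranscript\t1\t120\t.\t+\t.\tID=t;Parent=g;biotype=lncRNA\n"
               "c\tt\texon\t1\t10\t.\t+\t.\tID=e1;Parent=t\n"
               "c\tt\texon\t61\t70\t.\t+\t.\tID=e2;Parent=t\n")
        assets = ann.parse_annotation(gff, fasta)
        model, = ann.build_transcript_models(assets)
        w = jf.extract_junction_window(model, assets, W=150)
        assert w.flank_used == (10, 10)
        assert len(w.spliced_seq) == 20

    def test_junction_index_out_of_range(self, mam_models, mam_assets):
        with pytest.raises(AnnotationError, match="out of range"):
            jf.extract_junction_window(mam_models[0], mam_assets,
                                       junction_index=2)

    def test_minus_strand_window_is_reverse_complement_of_plus(self):
        plus = syn.make_locus(syn.LocusSpec(seed=6))
        minus = syn.make_locus(syn.LocusSpec(seed=6, strand="-"))
        seqs = []
        for locus in (plus, minus):
            assets = ann.parse_annotation(locus.gff3, locus.fasta)
            model, = [m for m in ann.build_transcript_models(assets)
                      if m.id == locus.truth.host_transcript_id]
            seqs.append(jf.extract_junction_window(model, assets).spliced_seq)
        assert seqs[0] == seqs[1]


class TestFold:
    def test_homopolymer_has_no_structure(self):
        s = jf.fold("A" * 30)
        assert s.pairing == {} and s.delta_g == 0.0

    def test_non_acgu_named_by_position(self):
        with pytest.raises(FoldInputError, match="position 3"):
            jf.fold("ACGNACG")

    def test_deterministic(self, mam_window):
        a = jf.fold(mam_window.spliced_seq)
        b = jf.fold(mam_window.spliced_seq)
        assert a.dot_bracket == b.dot_bracket and a.delta_g == b.delta_g

    def test_planted_inverted_repeat_recovers_most_pairs(self):
        rng = np.random.default_rng(8)
        arm = syn.random_arm(rng, 25)
        seq = arm + "UUCG" + RC(arm)
        assert jf.nussinov_oracle(seq) >= 25
        structure = jf.fold(seq)
        helix = max(jf.extract_helices(structure), key=lambda h: h.stem_length)
        assert helix.stem_length >= 20

    def test_delta_g_nonpositive(self, mam_window):
        assert jf.fold(mam_window.spliced_seq).delta_g < 0


class TestHelices:
    @pytest.mark.parametrize("db,tol,lengths", [
        ("((((....))))", 3, [4]),
        ("((((..((((....))))))))", 3, [8]),
        ("((((..((((....))))))))", 1, [4, 4]),
        ("((((.((((....))))..))))", 2, [8]),
    ])
    def test_merge_rule(self, db, tol, lengths):
        structure = jf.SecondaryStructure(
            "A" * len(db), jf.pairing_from_dot_bracket(db), db, -1.0)
        assert [h.stem_length for h in jf.extract_helices(structure, tol)] \
            == lengths


class TestDetection:
    def test_planted_arms_at_minus20(self):
        # arms -20..-1 and +30..+49 in an unpairable A-only context
        spliced = "A" * 100 + GC_ARM + "A" * 29 + RC(GC_ARM) + "A" * 51
        w = _window(spliced, 120)
        h = jf.detect_junction_hairpin(w)
        assert h is not None
        assert h.crossing_pairs == 20
        assert h.span_upstream == 20
        assert h.span_downstream == 49

    def test_locality_under_poly_a_padding(self):
        spliced = "A" * 60 + GC_ARM + "A" * 29 + RC(GC_ARM) + "A" * 31
        w1 = _window(spliced, 80)
        pad = "A" * 40
        w2 = _window(pad + spliced + pad, 120)
        h1 = jf.detect_junction_hairpin(w1)
        h2 = jf.detect_junction_hairpin(w2)
        rel = lambda h, w: {(i - w.junction_offset, j - w.junction_offset)
                            for i, j in h.stem_pairs}
        assert rel(h1, w1) == rel(h2, w2)

    @pytest.mark.parametrize("arm_len,expect", [(20, True), (25, True),
                                                (30, True), (10, False)])
    def test_planted_stem_length_threshold(self, arm_len, expect):
        spec = syn.LocusSpec(seed=11, hairpin=syn.HairpinSpec(
            arm_length=arm_len, upstream_arm_end=min(15, arm_len // 2)))
        locus = syn.make_locus(spec)
        assets = ann.parse_annotation(locus.gff3, locus.fasta)
        model, = [m for m in ann.build_transcript_models(assets)
                  if m.id == locus.truth.host_transcript_id]
        w = jf.extract_junction_window(model, assets)
        h = jf.detect_junction_hairpin(w, min_stem=20)
        assert (h is not None) is expect

    def test_shuffled_windows_rarely_have_hairpins(self, mam_window):
        rng = np.random.default_rng(1234)
        hits = 0
        for _ in range(100):
            shuffled = syn.shuffle_sequence(mam_window.spliced_seq, rng)
            w = _window(shuffled, mam_window.junction_offset)
            if jf.detect_junction_hairpin(w) is not None:
                hits += 1
        assert hits <= 5

    def test_mam_fixture_matches_planted_truth(self, mam_locus, mam_window,
                                               mam_hairpin):
        truth = mam_locus.truth.hairpin
        assert mam_hairpin.crossing_pairs >= 1
        # the MFE stem contains every planted pair (it may extend outward)
        planted = {(mam_window.junction_offset + i,
                    mam_window.junction_offset + j)
                   for i, j in truth.rel_pairs}
        assert planted <= set(mam_hairpin.stem_pairs)
        assert mam_hairpin.span_upstream >= truth.span_upstream


class TestConditionality:
    def test_mam_fixture_is_conditional(self, mam_window, mam_hairpin):
        assert jf.conditionality_test(mam_window, mam_hairpin) \
            == jf.CONDITIONAL

    def test_intron_outside_hairpin_is_constitutive(self):
        # hairpin wholly downstream of the junction: splicing-independent
        spliced = "A" * 100 + GC_ARM + "AAAA" + RC(GC_ARM) + "A" * 40
        w = _window(spliced, 60)
        h = jf.detect_junction_hairpin(w, require_crossing=False)
        assert h is not None and h.crossing_pairs == 0
        assert jf.conditionality_test(w, h) == jf.CONSTITUTIVE

    def test_constitutive_stem_mutant(self):
        from conftest import FIXTURE_SEED, analyze_locus
        locus = syn.make_locus(syn.LocusSpec(seed=FIXTURE_SEED,
                                             mutant=syn.MUTANT_CONSTITUTIVE))
        _, hairpin, verdict = analyze_locus(locus)
        assert hairpin is not None
        assert verdict == jf.CONSTITUTIVE


class TestNussinov:
    @pytest.mark.parametrize("seq,expected", [
        ("GGGGAAAACCCC", 4),
        ("AAAA", 0),
        ("ACGUACGUACGU", 4),   # (0,11)(1,10)(2,9)(3,8), 4-nt loop
    ])
    def test_known_values(self, seq, expected):
        assert jf.nussinov_oracle(seq) == expected

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.text(alphabet="ACGU", min_size=8, max_size=90))
    def test_mfe_pair_count_bounded_by_oracle(self, seq):
        structure = jf.fold(seq)
        assert structure.n_pairs <= jf.nussinov_oracle(seq)

    def test_bound_holds_on_planted_windows(self, mam_window):
        seq = mam_window.spliced_seq[:180]
        assert jf.fold(seq).n_pairs <= jf.nussinov_oracle(seq)
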