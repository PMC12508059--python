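"""Annotation parsing, snoRNA placement and mixed-cluster calling."""

import pytest

from snosplice import annotation as ann
from snosplice import synthetic as syn
from snosplice.errors import AnnotationError

GFF_HEADER = "##gff-version 3\n"
TOY_FASTA = ">chr1\n" + "A" * 400 + "\n"


def _gff(*rows):
    return GFF_HEADER + "\n".join(rows) + "\n"


def _row(ftype, start, end, attrs, strand="+", chrom="chr1"):
    return "\t".join([chrom, "t", ftype, str(start), str(end), ".",
                      strand, ".", attrs])


TOY_GFF = _gff(
    _row("gene", 1, 300, "ID=g1;biotype=lncRNA"),
    _row("transcript", 1, 300, "ID=t1;Parent=g1;biotype=lncRNA"),
    _row("exon", 1, 100, "ID=t1.e1;Parent=t1"),
    _row("exon", 201, 300, "ID=t1.e2;Parent=t1"),
)


class TestParseAnnotation:
    def test_one_based_inclusive_becomes_zero_based_half_open(self):
        assets = ann.parse_annotation(TOY_GFF, TOY_FASTA)
        exons = sorted((r.start, r.end) for r in assets.of_kind("exon"))
        assert exons == [(0, 100), (200, 300)]

    def test_reversed_coordinates_name_the_line(self):
        bad = _gff(_row("gene", 50, 40, "ID=g1;biotype=lncRNA"))
        with pytest.raises(AnnotationError, match="line 2"):
            ann.parse_annotation(bad, TOY_FASTA)

    def test_orphan_exons_are_listed(self):
        bad = _gff(
            _row("gene", 1, 300, "ID=g1;biotype=lncRNA"),
            _row("exon", 1, 100, "ID=lost.e1;Parent=ghost"),
        )
        with pytest.raises(AnnotationError, match="lost.e1"):
            ann.parse_annotation(bad, TOY_FASTA)

    def test_missing_biotype_defaults_to_unknown(self):
        gff = _gff(_row("gene", 1, 300, "ID=g1"))
        assets = ann.parse_annotation(gff, TOY_FASTA)
        assert assets.records[0].biotype == "unknown"

    def test_record_outside_chromosome_rejected(self):
        gff = _gff(_row("gene", 1, 1000, "ID=g1;biotype=lncRNA"))
        with pytest.raises(AnnotationError, match="past end"):
            ann.parse_annotation(gff, TOY_FASTA)

    def test_synthetic_genome_round_trips(self):
        locus = syn.make_locus(syn.LocusSpec(seed=3))
        assets = ann.parse_annotation(locus.gff3, locus.fasta)
        again = ann.parse_annotation(ann.write_gff3(assets),
                                     ann.write_fasta(assets))
        assert assets == again


class TestTranscriptModels:
    def test_minus_strand_exons_sorted_five_to_three(self):
        gff = _gff(
            _row("gene", 1, 300, "ID=g1;biotype=lncRNA", "-"),
            _row("transcript", 1, 300, "ID=t1;Parent=g1;biotype=lncRNA", "-"),
            _row("exon", 1, 100, "ID=e1;Parent=t1", "-"),
            _row("exon", 201, 300, "ID=e2;Parent=t1", "-"),
        )
        model, = ann.build_transcript_models(
            ann.parse_annotation(gff, TOY_FASTA))
        assert model.exons == [(200, 300), (0, 100)]
        assert model.introns == [(100, 200)]

    def test_single_exon_model(self):
        gff = _gff(
            _row("gene", 1, 100, "ID=g1;biotype=lncRNA"),
            _row("transcript", 1, 100, "ID=t1;Parent=g1;biotype=lncRNA"),
            _row("exon", 1, 100, "ID=e1;Parent=t1"),
        )
        model, = ann.build_transcript_models(
            ann.parse_annotation(gff, TOY_FASTA))
        assert len(model.exons) == 1 and model.introns == []

    def test_overlapping_exons_name_the_transcript(self):
        gff = _gff(
            _row("gene", 1, 300, "ID=g1;biotype=lncRNA"),
            _row("transcript", 1, 300, "ID=t1;Parent=g1;biotype=lncRNA"),
            _row("exon", 1, 100, "ID=e1;Parent=t1"),
            _row("exon", 50, 200, "ID=e2;Parent=t1"),
        )
        with pytest.raises(AnnotationError, match="t1"):
            ann.build_transcript_models(ann.parse_annotation(gff, TOY_FASTA))

    def test_spliced_length_matches_planted_exons(self):
        spec = syn.LocusSpec(seed=1, exon_lengths=(100, 80, 120),
                             intron_lengths=(60, 70),
                             sno_specs=(syn.SnoSpec("intronic", 0, 10, 40),
                                        syn.SnoSpec("exonic", 2, 10, 40)),
                             hairpin=None)
        locus = syn.make_locus(spec)
        model, = ann.build_transcript_models(
            ann.parse_annotation(locus.gff3, locus.fasta))
        assert model.spliced_length == 300


def _toy_host():
    """Host with exons [0,100) and [200,300); intron [100,200)."""
    return ann.TranscriptModel(id="t1", gene_id="g1", chrom="chr1",
                               strand="+", exons=[(0, 100), (200, 300)],
                               biotype="lncRNA")


def _sno(start, end, strand="+"):
    return ann.AnnotationRecord(id="sno1", kind="gene", parent_id=None,
                                chrom="chr1", start=start, end=end,
                                strand=strand, biotype="snoRNA")


class TestPlacement:
    @pytest.mark.parametrize("interval,expected", [
        ((120, 180), ann.INTRONIC),
        ((220, 280), ann.EXONIC),
        ((200, 300), ann.EXONIC),          # coincident with a full exon
        ((90, 130), ann.JUNCTION_OVERLAPPING),
    ])
    def test_geometry(self, interval, expected):
        placement = ann.classify_placement(_sno(*interval), _toy_host())
        assert placement.placement == expected

    def test_opposite_strand_is_not_a_host(self):
        with pytest.raises(AnnotationError, match="strand"):
            ann.classify_placement(_sno(120, 180, strand="-"), _toy_host())

    def test_outside_span_rejected(self):
        with pytest.raises(AnnotationError, match="not contained"):
            ann.classify_placement(_sno(350, 380), _toy_host())

    def test_retained_intron_only_evidence_is_ambiguous(self):
        host = _toy_host()
        retained = ann.TranscriptModel(id="t2", gene_id="g1", chrom="chr1",
                                       strand="+", exons=[(0, 300)],
                                       biotype="retained_intron")
        placement = ann.classify_placement(_sno(120, 180), host,
                                           [host, retained])
        assert placement.placement == ann.AMBIGUOUS_RETAINED
        assert placement.counts_as_intronic

    def test_never_exonic_from_retained_intron_alone(self):
        retained = ann.TranscriptModel(id="t2", gene_id="g1", chrom="chr1",
                                       strand="+", exons=[(0, 300)],
                                       biotype="retained_intron")
        placement = ann.classify_placement(_sno(120, 180), retained,
                                           [retained, _toy_host()])
        assert placement.placement != ann.EXONIC


class TestClusters:
    def test_mixed_locus_gives_last_exonic_cluster(self, mam_locus,
                                                   mam_assets):
        _, _, clusters = ann.classify_genome(mam_assets)
        cluster, = clusters
        assert cluster.sno_ids == mam_locus.truth.sno_order
        assert cluster.architecture == ann.LAST_EXONIC

    def test_intronic_only_host_is_not_a_cluster(self):
        spec = syn.LocusSpec(seed=2, hairpin=None,
                             exon_lengths=(200, 150, 200),
                             intron_lengths=(150, 150),
                             sno_specs=(syn.SnoSpec("intronic", 0, 20, 90),
                                        syn.SnoSpec("intronic", 1, 20, 90)))
        locus = syn.make_locus(spec)
        assets = ann.parse_annotation(locus.gff3, locus.fasta)
        _, _, clusters = ann.classify_genome(assets)
        assert clusters == []

    def test_planted_genome_recovers_exactly_the_mixed_hosts(self):
        fasta, gff3, truths = syn.make_genome(syn.scenario_suite(7))
        assets = ann.parse_annotation(gff3, fasta)
        _, placements, clusters = ann.classify_genome(assets)
        called = {c.host_gene_id for c in clusters}
        expected = {t.host_gene_id for t in truths if t.expected_cluster}
        assert called == expected
        for cluster in clusters:
            truth = next(t for t in truths
                         if t.host_gene_id == cluster.host_gene_id)
            assert cluster.sno_ids == truth.sno_order
            assert cluster.architecture == truth.expected_architecture
            assert [p.placement for p in cluster.placements] == \
                [truth.sno_placements[s] for s in truth.sno_order]

    def test_mixed_invariant_enforced(self):
        ps = [ann.SnoPlacement("a", "t1", ann.INTRONIC, 0),
              ann.SnoPlacement("b", "t1", ann.INTRONIC, 1)]
        with pytest.raises(AnnotationError, match="exonic"):
            ann.ClusterCall(host_gene_id="g", host_transcript_id="t1",
                            sno_ids=["a", "b"], placements=ps)


class TestArchitecture:
    @pytest.mark.parametrize("labels,expected", [
        ([ann.INTRONIC, ann.EXONIC], ann.LAST_EXONIC),
        ([ann.EXONIC, ann.INTRONIC], ann.OTHER),
        ([ann.INTRONIC, ann.INTRONIC, ann.EXONIC], ann.LAST_EXONIC),
        ([ann.AMBIGUOUS_RETAINED, ann.EXONIC], ann.LAST_EXONIC),
        ([ann.INTRONIC, ann.EXONIC, ann.INTRONIC, ann.EXONIC], ann.OTHER),
    ])
    def test_label_rule(self, labels, expected):
        ps = [ann.SnoPlacement(f"s{i}", "t1", l, i)
              for i, l in enumerate(labels)]
        cluster = ann.ClusterCall(host_gene_id="g", host_transcript_id="t1",
                                  sno_ids=[p.sno_id for p in ps],
                                  placements=ps)
        assert ann.cluster_architecture(cluster) == expected


class TestStrandSymmetry:
    @pytest.mark.parametrize("seed", [0, 4, 9])
    def test_flip_preserves_placements_and_architecture(self, seed):
        plus = syn.make_locus(syn.LocusSpec(seed=seed))
        minus = syn.make_locus(syn.LocusSpec(seed=seed, strand="-"))
        results = []
        for locus in (plus, minus):
            assets = ann.parse_annotation(locus.gff3, locus.fasta)
            _, placements, clusters = ann.classify_genome(assets)
            results.append((
                sorted((p.sno_id, p.placement) for p in placements),
                [(c.sno_ids, c.architecture) for c in clusters]))
        assert results[0] == results[1]

    def test_translation_invariance(self):
        near = syn.make_locus(syn.LocusSpec(seed=5, flank=200))
        far = syn.make_locus(syn.LocusSpec(seed=5, flank=450))
        calls = []
        for locus in (near, far):
            assets = ann.parse_annotation(locus.gff3, locus.fasta)
            _, placements, clusters = ann.classify_genome(assets)
            calls.append((
                sorted((p.sno_id, p.placement) for p in placements),
                [(c.sno_ids, c.architecture) for c in clusters]))
        assert calls[0] == calls[1]
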