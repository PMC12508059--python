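"""Host-gene architecture of snoRNA clusters.

Parses a genome (FASTA) plus its annotation (Ensembl-dialect GFF3) into
transcript models, assigns each snoRNA gene to the host precursor(s) that
contain it, classifies the snoRNA as intronic / exonic / junction-overlapping
(with the retained-intron ambiguity rule), and calls *mixed* clusters: host
precursors carrying at least one intronic and at least one exonic snoRNA.

Coordinates are 0-based half-open internally; GFF3 I/O converts to and from
the 1-based inclusive convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import gffutils
import pandas as pd
from Bio import SeqIO

from .errors import AnnotationError

INTRONIC = "intronic"
EXONIC = "exonic"
AMBIGUOUS_RETAINED = "ambiguous-retained-intron"
JUNCTION_OVERLAPPING = "junction-overlapping"

LAST_EXONIC = "last-exonic"
OTHER = "other"

RETAINED_INTRON = "retained_intron"

#: placements that count as intronic when typing a cluster
_INTRONIC_LIKE = {INTRONIC, AMBIGUOUS_RETAINED}

#: GFF3 feature types that are neither genes, transcripts nor exons
_SKIP_TYPES = {
    "cds", "five_prime_utr", "three_prime_utr", "start_codon", "stop_codon",
    "chromosome", "region", "biological_region", "scaffold", "supercontig",
}

_KIND_RANK = {"gene": 0, "transcript": 1, "exon": 2}


@dataclass(frozen=True)
class AnnotationRecord:
    id: str
    kind: str                    # gene | transcript | exon
    parent_id: str | None
    chrom: str
    start: int                   # 0-based
    end: int                     # half-open
    strand: str                  # '+' | '-'
    biotype: str = "unknown"

    def __post_init__(self):
        if self.start >= self.end:
            raise AnnotationError(
                f"record {self.id}: start {self.start} >= end {self.end}"
            )

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class GenomeAssets:
    """A genome's sequences and its annotation records."""

    sequences: dict[str, str]
    records: list[AnnotationRecord]

    def __post_init__(self):
        for rec in self.records:
            if rec.chrom not in self.sequences:
                raise AnnotationError(
                    f"record {rec.id} on unknown chromosome {rec.chrom!r}"
                )
            if rec.end > len(self.sequences[rec.chrom]):
                raise AnnotationError(
                    f"record {rec.id} extends past end of {rec.chrom} "
                    f"({rec.end} > {len(self.sequences[rec.chrom])})"
                )

    def of_kind(self, kind: str) -> list[AnnotationRecord]:
        return [r for r in self.records if r.kind == kind]

    def __eq__(self, other):
        if not isinstance(other, GenomeAssets):
            return NotImplemented
        return self.sequences == other.sequences and sorted(
            self.records, key=lambda r: r.id
        ) == sorted(other.records, key=lambda r: r.id)


@dataclass
class TranscriptModel:
    """A host precursor: ordered exons on a strand.

    ``exons`` are genomic ``(start, end)`` intervals listed in transcript
    5'→3' order: ascending genomic start on '+', descending on '-'.
    """

    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "unknown"

    def __post_init__(self):
        if not self.exons:
            raise AnnotationError(f"transcript {self.id} has no exons")
        starts = [s for s, _ in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered or len(set(starts)) != len(starts):
            raise AnnotationError(f"transcript {self.id}: exons not in 5'->3' order")
        by_pos = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(by_pos, by_pos[1:]):
            if s2 < e1:
                raise AnnotationError(f"transcript {self.id}: overlapping exons")

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals in transcript 5'→3' order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1, s2))
            else:
                out.append((e2, s1))
        return out

    @property
    def n_junctions(self) -> int:
        return len(self.exons) - 1


@dataclass(frozen=True)
class SnoPlacement:
    sno_id: str
    host_transcript_id: str
    placement: str
    order_index: int = -1        # rank of the snoRNA 5'->3' along the host

    @property
    def counts_as_intronic(self) -> bool:
        return self.placement in _INTRONIC_LIKE


@dataclass
class ClusterCall:
    """A mixed snoRNA cluster on one host precursor."""

    host_gene_id: str
    host_transcript_id: str
    sno_ids: list[str]           # 5'->3'
    placements: list[SnoPlacement]
    architecture: str = OTHER

    def __post_init__(self):
        if len(self.sno_ids) < 2:
            raise AnnotationError("a cluster needs at least two snoRNAs")
        labels = [p.placement for p in self.placements]
        if not any(l in _INTRONIC_LIKE for l in labels) or EXONIC not in labels:
            raise AnnotationError(
                "a mixed cluster needs >=1 intronic and >=1 exonic snoRNA"
            )


# ---------------------------------------------------------------------------
# parsing / writing

def _prevalidate_gff3(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            raise AnnotationError(f"GFF3 line {lineno}: expected 9 columns")
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError as exc:
            raise AnnotationError(f"GFF3 line {lineno}: non-integer coordinate") from exc
        if start > end:
            raise AnnotationError(
                f"GFF3 line {lineno}: start {start} > end {end}"
            )


def parse_annotation(gff3_content: str, fasta_content: str) -> GenomeAssets:
    """Parse GFF3 + FASTA text into :class:`GenomeAssets`.

    GFF3 1-based inclusive coordinates become 0-based half-open. Feature
    types are collapsed to the three kinds gene / transcript / exon: any
    ``*gene`` feature is a gene, ``exon`` is an exon, and every other
    non-structural feature carrying a Parent is a transcript (Ensembl writes
    ncRNA transcripts as e.g. ``snoRNA`` or ``lnc_RNA`` features). Records
    without a biotype attribute get biotype ``"unknown"``.
    """
    sequences = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(io.StringIO(fasta_content), "fasta")
    }
    _prevalidate_gff3(gff3_content)
    has_features = any(line.strip() and not line.startswith("#")
                       for line in gff3_content.splitlines())
    if not has_features:
        return GenomeAssets(sequences=sequences, records=[])
    db = gffutils.create_db(
        gff3_content, dbfn=":memory:", from_string=True, force=True,
        keep_order=True, merge_strategy="create_unique",
    )
    records: list[AnnotationRecord] = []
    for feat in db.all_features():
        ftype = feat.featuretype.lower()
        if ftype in _SKIP_TYPES:
            continue
        parent = feat.attributes.get("Parent", [None])[0]
        if ftype == "exon":
            kind = "exon"
        elif ftype.endswith("gene"):
            kind = "gene"
        elif parent is not None:
            kind = "transcript"
        else:
            # a parentless non-gene feature (e.g. a standalone ncRNA line)
            kind = "gene"
        biotype = feat.attributes.get("biotype", ["unknown"])[0]
        records.append(AnnotationRecord(
            id=feat.id, kind=kind, parent_id=parent, chrom=feat.seqid,
            start=feat.start - 1, end=feat.end, strand=feat.strand,
            biotype=biotype,
        ))
    records.sort(key=lambda r: (r.chrom, r.start, _KIND_RANK[r.kind], r.id))

    transcript_ids = {r.id for r in records if r.kind == "transcript"}
    orphans = [
        r.id for r in records
        if r.kind == "exon" and r.parent_id not in transcript_ids
    ]
    if orphans:
        raise AnnotationError(
            "exons with unknown parent transcript: " + ", ".join(sorted(orphans))
        )
    return GenomeAssets(sequences=sequences, records=records)


def write_gff3(assets: GenomeAssets) -> str:
    """Serialize annotation records back to Ensembl-dialect GFF3 text."""
    lines = ["##gff-version 3"]
    kind_to_type = {"gene": "gene", "transcript": "transcript", "exon": "exon"}
    for rec in sorted(assets.records,
                      key=lambda r: (r.chrom, r.start, _KIND_RANK[r.kind], r.id)):
        attrs = [f"ID={rec.id}"]
        if rec.parent_id:
            attrs.append(f"Parent={rec.parent_id}")
        attrs.append(f"biotype={rec.biotype}")
        lines.append("\t".join([
            rec.chrom, "snosplice", kind_to_type[rec.kind],
            str(rec.start + 1), str(rec.end), ".", rec.strand, ".",
            ";".join(attrs),
        ]))
    return "\n".join(lines) + "\n"


def write_fasta(assets: GenomeAssets, width: int = 70) -> str:
    chunks = []
    for name, seq in assets.sequences.items():
        chunks.append(f">{name}")
        chunks.extend(seq[i:i + width] for i in range(0, len(seq), width))
    return "\n".join(chunks) + "\n"


# ---------------------------------------------------------------------------
# transcript models

def build_transcript_models(assets: GenomeAssets) -> list[TranscriptModel]:
    """One model per transcript record that owns at least one exon."""
    exons_by_tx: dict[str, list[AnnotationRecord]] = {}
    for rec in assets.records:
        if rec.kind == "exon":
            exons_by_tx.setdefault(rec.parent_id, []).append(rec)
    models = []
    for tx in assets.of_kind("transcript"):
        exons = exons_by_tx.get(tx.id)
        if not exons:
            continue
        ivals = sorted((e.start, e.end) for e in exons)
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise AnnotationError(
                    f"transcript {tx.id}: overlapping exons {s1}-{e1} and {s2}-{e2}"
                )
        if tx.strand == "-":
            ivals = ivals[::-1]
        models.append(TranscriptModel(
            id=tx.id, gene_id=tx.parent_id or tx.id, chrom=tx.chrom,
            strand=tx.strand, exons=ivals, biotype=tx.biotype,
        ))
    return models


# ---------------------------------------------------------------------------
# placement classification

def _contained(inner: tuple[int, int], outer: tuple[int, int]) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def _geometric_placement(sno: AnnotationRecord, host: TranscriptModel) -> str:
    """Containment geometry only: intronic / exonic / junction-overlapping."""
    for exon in host.exons:
        if _contained(sno.interval, exon):
            return EXONIC
    for intron in host.introns:
        if _contained(sno.interval, intron):
            return INTRONIC
    return JUNCTION_OVERLAPPING


def _is_retained(model: TranscriptModel) -> bool:
    return model.biotype.lower() == RETAINED_INTRON


def classify_placement(
    sno: AnnotationRecord,
    host: TranscriptModel,
    gene_transcripts: list[TranscriptModel] | None = None,
) -> SnoPlacement:
    """Classify one snoRNA's relationship to a host precursor.

    ``gene_transcripts`` are all isoforms of the host gene; exonic evidence
    that exists *only* in retained_intron isoforms downgrades the call to
    ambiguous-retained-intron (treated as intronic for cluster typing),
    because in that situation the snoRNA is more plausibly intronic, the
    retained-intron isoform being an annotation of incomplete splicing.
    """
    if sno.strand != host.strand:
        raise AnnotationError(
            f"snoRNA {sno.id} on opposite strand from host {host.id}"
        )
    if not _contained(sno.interval, host.span):
        raise AnnotationError(
            f"snoRNA {sno.id} not contained in span of host {host.id}"
        )
    geometric = _geometric_placement(sno, host)
    isoforms = gene_transcripts or [host]
    exonic_in = [
        m for m in isoforms
        if m.strand == sno.strand and _contained(sno.interval, m.span)
        and _geometric_placement(sno, m) == EXONIC
    ]
    if exonic_in and all(_is_retained(m) for m in exonic_in):
        placement = AMBIGUOUS_RETAINED
    else:
        placement = geometric
    return SnoPlacement(sno_id=sno.id, host_transcript_id=host.id,
                        placement=placement)


# ---------------------------------------------------------------------------
# cluster calling

def cluster_architecture(cluster: ClusterCall) -> str:
    """last-exonic iff the 3'-most snoRNA is exonic and every snoRNA
    upstream of it is intronic (ambiguous-retained-intron counts as
    intronic)."""
    labels = [p.placement for p in cluster.placements]
    if labels[-1] == EXONIC and all(l in _INTRONIC_LIKE for l in labels[:-1]):
        return LAST_EXONIC
    return OTHER


def _tx_position_key(sno_interval: tuple[int, int], strand: str):
    # 5'-most genomic coordinate of the snoRNA along the transcript
    return sno_interval[0] if strand == "+" else -sno_interval[1]


def call_mixed_clusters(
    placements: list[SnoPlacement],
    models: list[TranscriptModel],
    sno_records: dict[str, AnnotationRecord] | None = None,
) -> list[ClusterCall]:
    """Call mixed clusters: hosts with >=1 intronic and >=1 exonic snoRNA.

    When a gene has several isoforms, one call is made per gene, on the
    isoform hosting the most snoRNAs (ties: longest spliced length, then
    lexicographic id); retained_intron isoforms are never chosen as host.
    junction-overlapping snoRNAs count as neither intronic nor exonic and
    are dropped from the cluster.
    """
    by_tx: dict[str, list[SnoPlacement]] = {}
    for p in placements:
        by_tx.setdefault(p.host_transcript_id, []).append(p)
    model_by_id = {m.id: m for m in models}

    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        if m.id in by_tx and not _is_retained(m):
            by_gene.setdefault(m.gene_id, []).append(m)

    clusters = []
    for gene_id, isoforms in sorted(by_gene.items()):
        best = max(isoforms, key=lambda m: (len(by_tx[m.id]), m.spliced_length,
                                            [-ord(c) for c in m.id]))
        host = model_by_id[best.id]
        ps = [p for p in by_tx[best.id] if p.placement != JUNCTION_OVERLAPPING]
        if not any(p.counts_as_intronic for p in ps):
            continue
        if not any(p.placement == EXONIC for p in ps):
            continue
        if len(ps) < 2:
            continue
        if sno_records:
            ps.sort(key=lambda p: _tx_position_key(
                sno_records[p.sno_id].interval, host.strand))
        ps = [replace(p, order_index=i) for i, p in enumerate(ps)]
        cluster = ClusterCall(
            host_gene_id=gene_id, host_transcript_id=host.id,
            sno_ids=[p.sno_id for p in ps], placements=ps,
        )
        cluster.architecture = cluster_architecture(cluster)
        clusters.append(cluster)
    return clusters


# ---------------------------------------------------------------------------
# genome-level convenience

def find_sno_genes(
    assets: GenomeAssets, sno_biotypes: set[str] | frozenset[str] = frozenset({"snorna"}),
) -> list[AnnotationRecord]:
    wanted = {b.lower() for b in sno_biotypes}
    return [r for r in assets.of_kind("gene") if r.biotype.lower() in wanted]


def classify_genome(
    assets: GenomeAssets,
    models: list[TranscriptModel] | None = None,
    sno_biotypes: set[str] | frozenset[str] = frozenset({"snorna"}),
) -> tuple[list[TranscriptModel], list[SnoPlacement], list[ClusterCall]]:
    """Full annotation stage: models, per-host placements, mixed clusters."""
    if models is None:
        models = build_transcript_models(assets)
    snos = find_sno_genes(assets, sno_biotypes)
    sno_gene_ids = {s.id for s in snos}
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)

    placements: list[SnoPlacement] = []
    for sno in snos:
        for m in models:
            if m.gene_id in sno_gene_ids or m.biotype.lower() in {b.lower() for b in sno_biotypes}:
                continue  # a snoRNA's own transcript is not a host
            if m.chrom != sno.chrom or m.strand != sno.strand:
                continue
            if not _contained(sno.interval, m.span):
                continue
            placements.append(
                classify_placement(sno, m, by_gene.get(m.gene_id)))
    sno_records = {s.id: s for s in snos}
    clusters = call_mixed_clusters(placements, models, sno_records)
    return models, placements, clusters


def clusters_to_frame(clusters: list[ClusterCall], species_tag: str = "") -> pd.DataFrame:
    rows = [{
        "host_gene": c.host_gene_id,
        "host_transcript": c.host_transcript_id,
        "species_tag": species_tag,
        "n_sno": len(c.sno_ids),
        "sno_ids": ",".join(c.sno_ids),
        "placements": ",".join(p.placement for p in c.placements),
        "architecture": c.architecture,
    } for c in clusters]
    return pd.DataFrame(rows, columns=[
        "host_gene", "host_transcript", "species_tag", "n_sno",
        "sno_ids", "placements", "architecture",
    ])


def placements_to_bed(
    placements: list[SnoPlacement], assets: GenomeAssets,
) -> str:
    """BED6 of snoRNA placements (name = sno_id|placement)."""
    by_id = {r.id: r for r in assets.of_kind("gene")}
    lines = []
    for p in placements:
        rec = by_id[p.sno_id]
        lines.append("\t".join([
            rec.chrom, str(rec.start), str(rec.end),
            f"{p.sno_id}|{p.placement}", "0", rec.strand,
        ]))
    return "\n".join(lines) + ("\n" if lines else "")
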