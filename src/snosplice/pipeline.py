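"""Survey orchestration: annotation -> clusters -> junction folding ->
conditionality -> optional degradome and covariation, with report writers.

Per-locus failures are quarantined into an errors table and the run
continues; the run manifest records the folding engine and parameter set
so any report can be reproduced.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import DataError
from . import annotation as ann
from . import junction_fold as jf
from . import degradome as dg
from . import covariation as cov


@dataclass
class SurveyConfig:
    fasta_path: str
    gff3_path: str
    out_dir: str
    degradome_plus: str | None = None
    degradome_minus: str | None = None
    alignments: str | None = None
    reference_tag: str = "ref"
    W: int = 150
    min_stem: int = 20
    bulge_tol: int = 1
    retention_threshold: float = 0.2
    min_count: int = 5
    min_enrichment: float = 5.0
    flank: int = 25
    tolerance: int = 1
    seed: int = 0
    species_tag: str = ""
    sno_biotypes: tuple[str, ...] = ("snoRNA",)

    def __post_init__(self):
        for name in ("W", "min_stem", "bulge_tol", "min_count", "flank"):
            if getattr(self, name) < 1:
                raise DataError(f"parameter {name} must be positive")


@dataclass
class SurveyReport:
    clusters: pd.DataFrame
    hairpins: pd.DataFrame
    cleavage_sites: pd.DataFrame
    cleavage_pairs: pd.DataFrame
    covariation: pd.DataFrame
    errors: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _hairpin_row(cluster, window, hairpin) -> dict:
    row = {
        "host_gene": cluster.host_gene_id,
        "host_transcript": cluster.host_transcript_id,
        "junction_index": window.junction_index if window else "",
        "span": "no hairpin", "delta_g": "", "stem_length": "",
        "crossing_pairs": "", "conditional": "no hairpin",
    }
    if hairpin is not None:
        row.update({
            "span": f"-{hairpin.span_upstream}/+{hairpin.span_downstream}",
            "delta_g": hairpin.delta_g,
            "stem_length": hairpin.total_stem_length,
            "crossing_pairs": hairpin.crossing_pairs,
            "conditional": hairpin.conditional,
        })
    return row


def run_survey(config: SurveyConfig) -> SurveyReport:
    """Run the full survey and write TSV/JSON reports to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fasta_text = Path(config.fasta_path).read_text()
    gff3_text = Path(config.gff3_path).read_text()
    assets = ann.parse_annotation(gff3_text, fasta_text)
    models, placements, clusters = ann.classify_genome(
        assets, sno_biotypes=set(config.sno_biotypes))
    model_by_id = {m.id: m for m in models}

    pileups: dict[str, dg.EndPileup] = {}
    for strand, path in (("+", config.degradome_plus),
                         ("-", config.degradome_minus)):
        if path:
            pileups[strand] = dg.load_end_pileup(
                Path(path).read_text(), strand,
                known_chroms=set(assets.sequences))

    hairpin_rows, site_rows, pair_rows, error_rows = [], [], [], []
    bed_chunks = []
    for cluster in clusters:
        window = hairpin = None
        try:
            model = model_by_id[cluster.host_transcript_id]
            window = jf.extract_junction_window(model, assets, None, config.W)
            hairpin = jf.detect_junction_hairpin(
                window, config.min_stem, config.bulge_tol,
                require_crossing=False)
            if hairpin is not None:
                jf.conditionality_test(window, hairpin,
                                       config.retention_threshold,
                                       config.min_stem)
            pileup = pileups.get(model.strand)
            if pileup is not None and hairpin is not None:
                sites = dg.call_cleavage_sites(
                    pileup, window, config.min_count,
                    config.min_enrichment, config.flank)
                pairs = dg.match_rnase3_pairs(sites, hairpin, config.tolerance)
                sf = dg.sites_to_frame(sites)
                sf.insert(0, "host_gene", cluster.host_gene_id)
                site_rows.append(sf)
                pf = dg.pairs_to_frame(pairs)
                pf.insert(0, "host_gene", cluster.host_gene_id)
                pair_rows.append(pf)
                bed_chunks.append(dg.sites_to_bed(sites, model.chrom))
        except DataError as exc:
            error_rows.append({"host_gene": cluster.host_gene_id,
                               "stage": "junction", "error": str(exc)})
        hairpin_rows.append(_hairpin_row(cluster, window, hairpin))

    cov_frame = pd.DataFrame()
    if config.alignments:
        try:
            aln = cov.read_aligned_fasta(Path(config.alignments).read_text(),
                                         config.reference_tag)
            ref_structure = jf.fold(aln.reference_ungapped)
            calls = cov.call_pair_columns(aln, ref_structure)
            cov_frame = cov.covariation_summary(calls)
        except DataError as exc:
            error_rows.append({"host_gene": "", "stage": "covariation",
                               "error": str(exc)})

    cluster_frame = ann.clusters_to_frame(clusters, config.species_tag)
    hairpin_frame = pd.DataFrame(hairpin_rows, columns=[
        "host_gene", "host_transcript", "junction_index", "span", "delta_g",
        "stem_length", "crossing_pairs", "conditional"])
    site_rows = [f for f in site_rows if not f.empty]
    pair_rows = [f for f in pair_rows if not f.empty]
    site_frame = (pd.concat(site_rows, ignore_index=True) if site_rows
                  else pd.DataFrame(columns=["host_gene", "window_pos",
                                             "genomic_pos", "strand",
                                             "count", "enrichment"]))
    pair_frame = (pd.concat(pair_rows, ignore_index=True) if pair_rows
                  else pd.DataFrame(columns=["host_gene", "u", "v", "offset",
                                             "signature", "score"]))
    error_frame = pd.DataFrame(error_rows,
                               columns=["host_gene", "stage", "error"])

    manifest = {
        "tool": f"snosplice {__version__}",
        "engine": jf.ENGINE_ID,
        "python": platform.python_version(),
        "config": asdict(config),
    }

    cluster_frame.to_csv(out / "clusters.tsv", sep="\t", index=False)
    hairpin_frame.to_csv(out / "hairpins.tsv", sep="\t", index=False)
    site_frame.to_csv(out / "cleavage_sites.tsv", sep="\t", index=False)
    pair_frame.to_csv(out / "cleavage_pairs.tsv", sep="\t", index=False)
    cov_frame.to_csv(out / "covariation.tsv", sep="\t", index=False)
    error_frame.to_csv(out / "errors.tsv", sep="\t", index=False)
    (out / "cleavage_sites.bed").write_text("".join(bed_chunks))
    (out / "snoRNA_placements.bed").write_text(
        ann.placements_to_bed(placements, assets))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return SurveyReport(
        clusters=cluster_frame, hairpins=hairpin_frame,
        cleavage_sites=site_frame, cleavage_pairs=pair_frame,
        covariation=cov_frame, errors=error_frame, manifest=manifest)
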