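"""Degradome 5'-end pileups and RNase III staggered-cut signatures.

Degradome-seq captures 5'-monophosphate RNA ends, so a pileup of read 5'
ends marks endonucleolytic cleavage positions at nucleotide resolution.
RNase III enzymes (Pac1, Rnt1, Drosha) cut both strands of a hairpin stem
leaving 2-nt 3' overhangs; in 5'-end coordinates on the pairing map P this
geometry reads v = P(u) + 3 for the upstream-arm site u and downstream-arm
site v (each product then carries a 2-nt 3' overhang).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .errors import DataError
from .junction_fold import JunctionHairpin, JunctionWindow

#: expected site offset, in 5'-end coordinates, for a 2-nt 3' overhang
SIGNATURE_OFFSET = 3


@dataclass
class EndPileup:
    """Counts of read 5' ends keyed by (chromosome, strand, 0-based pos)."""

    counts: dict[tuple[str, str, int], int]

    def get(self, chrom: str, strand: str, pos: int) -> int:
        return self.counts.get((chrom, strand, pos), 0)

    def add(self, chrom: str, strand: str, pos: int, n: int = 1) -> None:
        key = (chrom, strand, pos)
        self.counts[key] = self.counts.get(key, 0) + n


@dataclass(frozen=True)
class CleavageSite:
    window_pos: int            # 0-based within the spliced window
    genomic_pos: int
    strand: str
    count: int
    enrichment: float          # fold over median of flanking window


@dataclass(frozen=True)
class CleavagePair:
    upstream_site: CleavageSite
    downstream_site: CleavageSite
    overhang_offset: int
    is_rnase3_signature: bool

    @property
    def score(self) -> int:
        return min(self.upstream_site.count, self.downstream_site.count)


def load_bedgraph(text: str, strand: str,
                  known_chroms: set[str] | None = None) -> EndPileup:
    """Parse a 4-column, 0-based half-open bedGraph into a pileup.

    Counts are spread per position across each interval. Lines on unknown
    chromosomes (when ``known_chroms`` is given) are skipped.
    """
    pileup = EndPileup(counts={})
    if not text.strip():
        return pileup
    df = pd.read_csv(io.StringIO(text), sep=r"\s+", comment="#", header=None,
                     names=["chrom", "start", "end", "count"],
                     dtype={"chrom": str})
    for chrom, start, end, count in df.itertuples(index=False):
        if known_chroms is not None and chrom not in known_chroms:
            continue
        if int(count) <= 0:
            continue
        for pos in range(int(start), int(end)):
            pileup.add(chrom, strand, pos, int(count))
    return pileup


def load_alignment_5p(path: str, known_chroms: set[str] | None = None
                      ) -> EndPileup:
    """Pile up read 5' ends from a SAM/BAM file (primary alignments only).

    For a '-'-strand read the 5' end is the rightmost aligned coordinate.
    """
    pileup = EndPileup(counts={})
    with pysam.AlignmentFile(path, check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            chrom = read.reference_name
            if known_chroms is not None and chrom not in known_chroms:
                continue
            if read.is_reverse:
                pileup.add(chrom, "-", read.reference_end - 1)
            else:
                pileup.add(chrom, "+", read.reference_start)
    return pileup


def load_end_pileup(source: str, strand: str = "+",
                    known_chroms: set[str] | None = None,
                    kind: str = "bedgraph") -> EndPileup:
    """Load a strand-specific 5'-end pileup.

    ``kind='bedgraph'`` treats ``source`` as bedGraph text; ``kind='sam'``
    treats it as a path to a SAM/BAM file (strand taken per read).
    """
    if kind == "bedgraph":
        return load_bedgraph(source, strand, known_chroms)
    if kind == "sam":
        return load_alignment_5p(source, known_chroms)
    raise DataError(f"unknown pileup source kind {kind!r}")


def mask_pileup(pileup: EndPileup,
                intervals: list[tuple[str, str, int, int]]) -> EndPileup:
    """Drop positions inside mature snoRNA intervals
    (chrom, strand, start, end) — potential contaminant reads."""
    masked = {}
    for (chrom, strand, pos), n in pileup.counts.items():
        if any(c == chrom and s == strand and a <= pos < b
               for c, s, a, b in intervals):
            continue
        masked[(chrom, strand, pos)] = n
    return EndPileup(counts=masked)


def call_cleavage_sites(
    pileup: EndPileup,
    window: JunctionWindow,
    min_count: int = 5,
    min_enrichment: float = 5.0,
    flank: int = 25,
) -> list[CleavageSite]:
    """Call 5'-end peaks along the spliced window.

    A site needs ``count >= min_count`` and
    ``count >= min_enrichment * median`` over the counts at +-``flank``
    window positions (zeros included, the site itself excluded).
    """
    positions = window.genomic_positions
    counts = np.array([pileup.get(window.chrom, window.strand, g)
                       for g in positions], dtype=float)
    sites = []
    for k, c in enumerate(counts):
        if c < min_count:
            continue
        lo, hi = max(0, k - flank), min(len(counts), k + flank + 1)
        neighborhood = np.concatenate([counts[lo:k], counts[k + 1:hi]])
        med = float(np.median(neighborhood)) if neighborhood.size else 0.0
        if c < min_enrichment * med:
            continue
        enrichment = c / med if med > 0 else float("inf")
        sites.append(CleavageSite(
            window_pos=k, genomic_pos=positions[k], strand=window.strand,
            count=int(c), enrichment=enrichment,
        ))
    return sites


def _nearest_paired(pos: int, pairing: dict[int, int], tolerance: int
                    ) -> int | None:
    if pos in pairing:
        return pos
    for d in range(1, tolerance + 1):
        for cand in (pos - d, pos + d):
            if cand in pairing:
                return cand
    return None


def match_rnase3_pairs(
    sites: list[CleavageSite],
    hairpin: JunctionHairpin,
    tolerance: int = 1,
) -> list[CleavagePair]:
    """Pair up sites on opposite hairpin arms and test the staggered-cut
    geometry.

    For a 5'-arm site u with stem partner w = P(u), a 3'-arm site v forms
    the RNase III signature iff ``|  (v - w) - 3 | <= tolerance`` (offset 3
    in 5'-end coordinates is the 2-nt 3' overhang; the tolerance absorbs
    bulged stems). Unpaired u snaps to the nearest paired position within
    the tolerance. Pairs are sorted by score (min of the two counts),
    descending.
    """
    pairing = hairpin.pairing
    if not pairing:
        raise DataError("hairpin has no pairing map")
    pairs_sorted = hairpin.stem_pairs
    arm5_hi = max(i for i, _ in pairs_sorted)
    arm3_lo = min(j for _, j in pairs_sorted)
    upstream = [s for s in sites if s.window_pos <= arm5_hi + tolerance]
    downstream = [s for s in sites if s.window_pos >= arm3_lo - tolerance]

    out = []
    for u in upstream:
        anchor = _nearest_paired(u.window_pos, pairing, tolerance)
        if anchor is None or pairing[anchor] < anchor:
            continue  # not on the 5' arm
        w = pairing[anchor]
        for v in downstream:
            if v.window_pos == u.window_pos:
                continue
            offset = v.window_pos - w
            out.append(CleavagePair(
                upstream_site=u, downstream_site=v, overhang_offset=offset,
                is_rnase3_signature=abs(offset - SIGNATURE_OFFSET) <= tolerance,
            ))
    out.sort(key=lambda p: -p.score)
    return out


def sites_to_frame(sites: list[CleavageSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"window_pos": s.window_pos, "genomic_pos": s.genomic_pos,
          "strand": s.strand, "count": s.count, "enrichment": s.enrichment}
         for s in sites],
        columns=["window_pos", "genomic_pos", "strand", "count", "enrichment"])


def pairs_to_frame(pairs: list[CleavagePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"u": p.upstream_site.window_pos, "v": p.downstream_site.window_pos,
          "offset": p.overhang_offset, "signature": p.is_rnase3_signature,
          "score": p.score} for p in pairs],
        columns=["u", "v", "offset", "signature", "score"])


def sites_to_bed(sites: list[CleavageSite], chrom: str) -> str:
    lines = ["\t".join([chrom, str(s.genomic_pos), str(s.genomic_pos + 1),
                        f"cleavage|{s.window_pos}", str(s.count), s.strand])
             for s in sites]
    return "\n".join(lines) + ("\n" if lines else "")
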