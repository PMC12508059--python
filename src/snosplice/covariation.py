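"""Covariation of junction hairpins across homologs.

Given a gapped alignment of homologous junction regions anchored on a
reference species whose structure is known, every base-paired column pair
is classified per species as conserved, compensatory (both sides changed,
pairing kept), base-pair-neutral (one side changed, pairing kept — e.g.
U->C opposite G, a wobble-preserving change), disruptive, or gapped.
GU wobble counts as pairing throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import pandas as pd
from Bio import AlignIO

from .errors import AlignmentError
from .junction_fold import SecondaryStructure, is_canonical_pair

CONSERVED = "conserved"
COMPENSATORY = "compensatory"
NEUTRAL = "base-pair-neutral"
DISRUPTIVE = "disruptive"
GAPPED = "gapped"

CLASSES = [CONSERVED, COMPENSATORY, NEUTRAL, DISRUPTIVE, GAPPED]

REGIONS = ["basal", "mid", "apical"]


@dataclass
class AlignedJunctionSet:
    """Equal-length gapped RNA rows keyed by species tag."""

    alignment: dict[str, str]
    reference_tag: str

    def __post_init__(self):
        if self.reference_tag not in self.alignment:
            raise AlignmentError(
                f"reference {self.reference_tag!r} not in alignment")
        lengths = {len(s) for s in self.alignment.values()}
        if len(lengths) != 1:
            raise AlignmentError("alignment rows differ in gapped length")

    @property
    def column_map(self) -> list[int]:
        """reference ungapped position -> alignment column."""
        return [col for col, c in enumerate(self.alignment[self.reference_tag])
                if c != "-"]

    @property
    def reference_ungapped(self) -> str:
        return self.alignment[self.reference_tag].replace("-", "")


@dataclass(frozen=True)
class PairColumnCall:
    pair: tuple[int, int]          # reference ungapped positions
    species_tag: str
    observed: tuple[str, str]
    klass: str
    pair_rank: int = 0             # 0 = outermost (basal) pair


def read_aligned_fasta(text: str, reference_tag: str) -> AlignedJunctionSet:
    aln = AlignIO.read(io.StringIO(text), "fasta")
    rows = {rec.id: str(rec.seq).upper().replace("T", "U") for rec in aln}
    return AlignedJunctionSet(alignment=rows, reference_tag=reference_tag)


def map_alignment_to_pairs(
    aln: AlignedJunctionSet, structure: SecondaryStructure,
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Map each reference base pair (i, j) to its two alignment columns.

    Returns ``[((i, j), (col_i, col_j)), ...]`` in outermost-first order.
    """
    ref = aln.reference_ungapped
    if ref != structure.sequence:
        for k, (a, b) in enumerate(zip(ref, structure.sequence)):
            if a != b:
                raise AlignmentError(
                    f"reference row disagrees with structure sequence at "
                    f"ungapped position {k}: {a!r} vs {b!r}")
        raise AlignmentError(
            f"reference row length {len(ref)} != structure length "
            f"{len(structure.sequence)}")
    cmap = aln.column_map
    return [((i, j), (cmap[i], cmap[j])) for i, j in structure.pairs()]


def classify_substitution(ref_pair: tuple[str, str],
                          obs_pair: tuple[str, str]) -> str:
    """Decision table for one species at one base-paired column pair."""
    if not is_canonical_pair(*ref_pair):
        raise AlignmentError(
            f"reference pair {ref_pair} is not canonical (WC or GU)")
    a, b = obs_pair
    if a == "-" or b == "-":
        return GAPPED
    if obs_pair == ref_pair:
        return CONSERVED
    changed = (a != ref_pair[0]) + (b != ref_pair[1])
    if is_canonical_pair(a, b):
        return COMPENSATORY if changed == 2 else NEUTRAL
    return DISRUPTIVE


def call_pair_columns(
    aln: AlignedJunctionSet, structure: SecondaryStructure,
    pairs: list[tuple[int, int]] | None = None,
) -> list[PairColumnCall]:
    """Classify every (species, base pair) combination.

    ``pairs`` restricts the analysis to a stem of interest (e.g. the
    junction hairpin's merged helix); by default all reference pairs are
    used. Pair rank follows 5' position, outermost first.
    """
    mapped = map_alignment_to_pairs(aln, structure)
    if pairs is not None:
        wanted = set(pairs)
        mapped = [m for m in mapped if m[0] in wanted]
    ref = structure.sequence
    calls = []
    for rank, ((i, j), (ci, cj)) in enumerate(sorted(mapped)):
        ref_pair = (ref[i], ref[j])
        for tag, row in aln.alignment.items():
            if tag == aln.reference_tag:
                continue
            obs = (row[ci], row[cj])
            calls.append(PairColumnCall(
                pair=(i, j), species_tag=tag, observed=obs,
                klass=classify_substitution(ref_pair, obs), pair_rank=rank,
            ))
    return calls


def _region_of(rank: int, n_pairs: int) -> str:
    third = max(1, -(-n_pairs // 3))          # ceil
    if rank < third:
        return "basal"
    if rank >= n_pairs - third:
        return "apical"
    return "mid"


def covariation_summary(
    calls: list[PairColumnCall],
    region_masks: dict[str, set[int]] | None = None,
) -> pd.DataFrame:
    """Per-species, per-region class fractions.

    Regions default to basal / mid / apical thirds of the stem by pair
    rank (outermost pairs are basal); ``region_masks`` may override with
    explicit ``{region: set of pair ranks}``. An ``all`` region aggregates
    every pair. Fractions per (species, region) row sum to 1.
    """
    if not calls:
        return pd.DataFrame(columns=["species", "region", "n_pairs"] + CLASSES)
    n_pairs = max(c.pair_rank for c in calls) + 1
    if region_masks is None:
        region_masks = {r: {k for k in range(n_pairs)
                            if _region_of(k, n_pairs) == r} for r in REGIONS}
    region_masks = {"all": set(range(n_pairs)), **region_masks}

    rows = []
    species = sorted({c.species_tag for c in calls})
    for tag in species:
        mine = [c for c in calls if c.species_tag == tag]
        for region, ranks in region_masks.items():
            sub = [c for c in mine if c.pair_rank in ranks]
            if not sub:
                continue
            row = {"species": tag, "region": region, "n_pairs": len(sub)}
            for klass in CLASSES:
                row[klass] = sum(c.klass == klass for c in sub) / len(sub)
            rows.append(row)
    return pd.DataFrame(rows, columns=["species", "region", "n_pairs"] + CLASSES)
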