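"""Junction-spanning hairpin detection.

Reconstructs spliced and unspliced sequence windows around an exon-exon
junction of a host precursor, folds them with a nearest-neighbor MFE engine
(ViennaRNA, Turner parameters, 37 °C), extracts bulge-tolerant helix
segments, and decides whether a hairpin (a) satisfies the RNase III
substrate contract (stem of >= ``min_stem`` pairs tolerating small bulges)
while crossing the junction and (b) is splicing-conditional, i.e. the stem
is disrupted when the intervening intron is restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import RNA
from numba import njit

from .errors import AnnotationError, FoldInputError
from .annotation import GenomeAssets, TranscriptModel

ENGINE_ID = f"ViennaRNA {RNA.__version__} (Turner 2004, 37C, min-loop 3)"

CONDITIONAL = "conditional"
CONSTITUTIVE = "constitutive"
NOT_EVALUATED = "not-evaluated"

_RC = str.maketrans("ACGU", "UGCA")
_CANONICAL = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"),
              ("G", "U"), ("U", "G")}


def reverse_complement(seq: str) -> str:
    return seq[::-1].translate(_RC)


def is_canonical_pair(a: str, b: str) -> bool:
    """Watson-Crick or GU wobble."""
    return (a, b) in _CANONICAL


# ---------------------------------------------------------------------------
# windows

@dataclass
class JunctionWindow:
    """Spliced/unspliced sequence context around one exon-exon junction.

    ``junction_offset`` is the index (within ``spliced_seq``) of the first
    nucleotide of the downstream exon. ``genomic_positions[k]`` is the
    genomic coordinate of spliced-window position ``k``.
    """

    transcript_id: str
    junction_index: int                   # 1 = first junction
    spliced_seq: str
    unspliced_seq: str
    junction_offset: int
    intron_span: tuple[int, int]          # within unspliced_seq
    flank_used: tuple[int, int]
    chrom: str = ""
    strand: str = "+"
    genomic_positions: tuple[int, ...] = ()

    def __post_init__(self):
        i0, i1 = self.intron_span
        if self.unspliced_seq[:i0] + self.unspliced_seq[i1:] != self.spliced_seq:
            raise AnnotationError(
                f"window {self.transcript_id}: removing the intron does not "
                "reproduce the spliced sequence")

    @property
    def intron_length(self) -> int:
        return self.intron_span[1] - self.intron_span[0]

    def spliced_to_unspliced(self, pos: int) -> int:
        if not 0 <= pos < len(self.spliced_seq):
            raise IndexError(f"position {pos} outside spliced window")
        return pos if pos < self.junction_offset else pos + self.intron_length


def transcript_sequence(model: TranscriptModel, assets: GenomeAssets
                        ) -> tuple[str, list[int]]:
    """Spliced 5'->3' RNA sequence and per-position genomic coordinates."""
    chrom_seq = assets.sequences[model.chrom]
    seq_parts: list[str] = []
    positions: list[int] = []
    for s, e in model.exons:
        block = chrom_seq[s:e].replace("T", "U")
        if model.strand == "+":
            seq_parts.append(block)
            positions.extend(range(s, e))
        else:
            seq_parts.append(reverse_complement(block))
            positions.extend(range(e - 1, s - 1, -1))
    return "".join(seq_parts), positions


def extract_junction_window(
    model: TranscriptModel,
    assets: GenomeAssets,
    junction_index: int | None = None,
    W: int = 150,
) -> JunctionWindow:
    """Cut a window of up to ``W`` nt on each side of a junction.

    The upstream flank may cross earlier junctions (it follows the spliced
    transcript); the unspliced variant re-inserts only the intron at the
    focal junction. Minus-strand models are reverse-complemented so both
    sequences read 5'->3' in transcript orientation.
    """
    if model.n_junctions < 1:
        raise AnnotationError(f"transcript {model.id} has a single exon")
    if junction_index is None:
        junction_index = model.n_junctions
    if not 1 <= junction_index <= model.n_junctions:
        raise AnnotationError(
            f"junction index {junction_index} out of range for {model.id} "
            f"({model.n_junctions} junction(s))")
    if W < 1:
        raise ValueError("W must be >= 1")

    spliced, positions = transcript_sequence(model, assets)
    junction = sum(e - s for s, e in model.exons[:junction_index])
    up = min(W, junction)
    down = min(W, len(spliced) - junction)
    window_seq = spliced[junction - up:junction + down]
    window_pos = tuple(positions[junction - up:junction + down])

    i0, i1 = model.introns[junction_index - 1]
    intron_block = assets.sequences[model.chrom][i0:i1].replace("T", "U")
    if model.strand == "-":
        intron_block = reverse_complement(intron_block)
    unspliced = window_seq[:up] + intron_block + window_seq[up:]

    return JunctionWindow(
        transcript_id=model.id, junction_index=junction_index,
        spliced_seq=window_seq, unspliced_seq=unspliced,
        junction_offset=up, intron_span=(up, up + len(intron_block)),
        flank_used=(up, down), chrom=model.chrom, strand=model.strand,
        genomic_positions=window_pos,
    )


# ---------------------------------------------------------------------------
# folding

@dataclass
class SecondaryStructure:
    sequence: str
    pairing: dict[int, int]               # symmetric, 0-based
    dot_bracket: str
    delta_g: float                        # kcal/mol at 37 C

    @property
    def n_pairs(self) -> int:
        return sum(1 for i, j in self.pairing.items() if i < j)

    def pairs(self) -> list[tuple[int, int]]:
        return sorted((i, j) for i, j in self.pairing.items() if i < j)


def pairing_from_dot_bracket(db: str) -> dict[int, int]:
    pairing: dict[int, int] = {}
    stack: list[int] = []
    for k, c in enumerate(db):
        if c == "(":
            stack.append(k)
        elif c == ")":
            i = stack.pop()
            pairing[i] = k
            pairing[k] = i
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return pairing


def fold(seq: str) -> SecondaryStructure:
    """Pseudoknot-free MFE structure (nearest-neighbor model, 37 °C).

    Deterministic for a fixed input; IUPAC ambiguity codes are rejected.
    """
    if not seq:
        raise FoldInputError("empty sequence")
    for k, c in enumerate(seq):
        if c not in "ACGU":
            raise FoldInputError(
                f"non-ACGU character {c!r} at position {k}")
    db, mfe = RNA.fold(seq)
    pairing = pairing_from_dot_bracket(db)
    delta_g = 0.0 if not pairing else round(float(mfe), 2)
    return SecondaryStructure(sequence=seq, pairing=pairing,
                              dot_bracket=db, delta_g=delta_g)


# ---------------------------------------------------------------------------
# helix extraction

@dataclass
class HelixSegment:
    """A run of stacked pairs, merged across small interruptions."""

    pairs: list[tuple[int, int]]          # i ascending, j descending
    bulge_profile: list[tuple[int, int]] = field(default_factory=list)

    @property
    def stem_length(self) -> int:
        return len(self.pairs)

    @property
    def i_range(self) -> tuple[int, int]:
        return (self.pairs[0][0], self.pairs[-1][0])

    @property
    def j_range(self) -> tuple[int, int]:
        return (self.pairs[-1][1], self.pairs[0][1])


def extract_helices(structure: SecondaryStructure, bulge_tol: int = 1
                    ) -> list[HelixSegment]:
    """Maximal stacked-pair runs, merged across interruptions where the
    number of skipped nucleotides on *both* sides is <= ``bulge_tol``."""
    pairs = structure.pairs()
    segments: list[HelixSegment] = []
    current: list[tuple[int, int]] = []
    bulges: list[tuple[int, int]] = []
    for p in pairs:
        if not current:
            current = [p]
            bulges = []
            continue
        pi, pj = current[-1]
        di, dj = p[0] - pi - 1, pj - p[1] - 1
        if dj >= 0 and di <= bulge_tol and dj <= bulge_tol:
            if di or dj:
                bulges.append((di, dj))
            current.append(p)
        else:
            segments.append(HelixSegment(current, bulges))
            current, bulges = [p], []
    if current:
        segments.append(HelixSegment(current, bulges))
    return segments


# ---------------------------------------------------------------------------
# junction hairpins

@dataclass
class JunctionHairpin:
    """A stemloop detected at an exon-exon junction.

    Spans follow the junction-relative convention: ``span_upstream = n``
    means the outermost pair reaches n nt into the upstream exon (reported
    -n), ``span_downstream = m`` means it reaches m nt into the downstream
    exon (reported +m, 1-based from the junction).
    """

    window: JunctionWindow
    helices: list[HelixSegment]
    structure: SecondaryStructure
    delta_g: float
    span_upstream: int
    span_downstream: int
    crossing_pairs: int
    conditional: str = NOT_EVALUATED

    @property
    def stem_pairs(self) -> list[tuple[int, int]]:
        return [p for h in self.helices for p in h.pairs]

    @property
    def total_stem_length(self) -> int:
        return sum(h.stem_length for h in self.helices)

    @property
    def pairing(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.stem_pairs:
            out[i] = j
            out[j] = i
        return out


def _crossing_count(segment: HelixSegment, junction: int) -> int:
    return sum(1 for i, j in segment.pairs if i < junction <= j)


def detect_junction_hairpin(
    window: JunctionWindow,
    min_stem: int = 20,
    bulge_tol: int = 1,
    require_crossing: bool = True,
) -> JunctionHairpin | None:
    """Fold the spliced window and pick the junction hairpin, if any.

    Candidates are merged helix segments with >= ``min_stem`` pairs.
    Preference: most junction-crossing pairs, then 5'-most. With
    ``require_crossing`` (default) a candidate without a crossing pair is
    rejected; without it, the segment closest to the junction is returned
    (used to recognize constitutive stems sitting wholly inside one exon).
    """
    structure = fold(window.spliced_seq)
    junction = window.junction_offset
    candidates = [h for h in extract_helices(structure, bulge_tol)
                  if h.stem_length >= min_stem]
    if not candidates:
        return None
    crossing = [h for h in candidates if _crossing_count(h, junction) > 0]
    if crossing:
        best = max(crossing,
                   key=lambda h: (_crossing_count(h, junction), -h.i_range[0]))
    elif require_crossing:
        return None
    else:
        def distance(h: HelixSegment) -> int:
            lo, hi = h.i_range[0], h.j_range[1]
            if lo <= junction <= hi:
                return 0
            return min(abs(junction - lo), abs(junction - hi))
        best = min(candidates, key=distance)
    return JunctionHairpin(
        window=window, helices=[best], structure=structure,
        delta_g=structure.delta_g,
        span_upstream=junction - best.i_range[0],
        span_downstream=best.j_range[1] - junction + 1,
        crossing_pairs=_crossing_count(best, junction),
    )


def conditionality_test(
    window: JunctionWindow,
    hairpin: JunctionHairpin,
    retention_threshold: float = 0.2,
    min_stem: int = 20,
) -> str:
    """Is the hairpin splicing-conditional?

    Folds the unspliced window and maps every stem pair through the intron
    insertion. The hairpin is constitutive when a cleavable substrate
    survives: at least ``min_stem`` stem pairs keep the same partner in
    the unspliced fold (this is what a stem sitting wholly inside one exon
    does, the intron leaving it untouched). Otherwise the verdict rests on
    the junction-crossing pairs, the part of the stem splicing creates:
    conditional iff the fraction of crossing pairs retained in the
    unspliced structure is <= ``retention_threshold``. A hairpin with no
    crossing pair falls back to retention over all stem pairs.
    """
    unspliced = fold(window.unspliced_seq)

    def retained(pairs):
        n = 0
        for i, j in pairs:
            mi = window.spliced_to_unspliced(i)
            mj = window.spliced_to_unspliced(j)
            if unspliced.pairing.get(mi) == mj:
                n += 1
        return n

    if retained(hairpin.stem_pairs) >= min_stem:
        hairpin.conditional = CONSTITUTIVE
        return CONSTITUTIVE
    basis = [(i, j) for i, j in hairpin.stem_pairs
             if i < window.junction_offset <= j] or hairpin.stem_pairs
    fraction = retained(basis) / len(basis)
    verdict = CONDITIONAL if fraction <= retention_threshold else CONSTITUTIVE
    hairpin.conditional = verdict
    return verdict


# ---------------------------------------------------------------------------
# Nussinov oracle

@njit(cache=False)
def _nussinov_dp(enc: np.ndarray, min_loop: int) -> int:  # pragma: no cover
    n = enc.shape[0]
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i][j - 1]
            for k in range(i, j - min_loop):
                s = enc[k] + enc[j]
                if s == 3 or s == 5:  # AU/CG (sum 3) or GU (sum 5)
                    left = dp[i][k - 1] if k > i else 0
                    inner = dp[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    val = left + 1 + inner
                    if val > best:
                        best = val
            dp[i][j] = best
    return int(dp[0][n - 1])


_ENCODE = {"A": 0, "C": 1, "G": 2, "U": 3}


def nussinov_oracle(seq: str, min_loop: int = 3) -> int:
    """Exact maximum number of nested canonical+GU pairs (hairpin loops
    >= ``min_loop``), by dynamic programming. Independent of the MFE
    engine; used as an upper bound on any structure's pair count."""
    if len(seq) < min_loop + 2:
        return 0
    try:
        enc = np.array([_ENCODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise FoldInputError(f"non-ACGU character {exc.args[0]!r}") from exc
    return _nussinov_dp(enc, min_loop)
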