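"""Synthetic genomes with planted, machine-readable truth.

Generates the study conditions offline: multi-exon host precursors carrying
intronic and exonic snoRNAs, complementary hairpin arms planted across the
last exon-exon junction, an intronic decoy that occupies the upstream arm
in the unspliced isoform (the stand-in for the branched structure an intron
produces in real precursors, which is what makes the planted hairpin
splicing-conditional), degradome 5'-end tracks with staggered-cut signal,
and gapless homolog alignments with controlled compensatory substitution.

Every generator is deterministic under its seed: identical seed, identical
bytes.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import SimulationError
from .junction_fold import reverse_complement

MUTANT_NONE = "none"
MUTANT_STEM_DEAD = "stem-dead"
MUTANT_CONSTITUTIVE = "constitutive-stem"
MUTANT_COMPENSATORY = "compensatory-double"

_DNA = str.maketrans("U", "T")
_TO_RNA = str.maketrans("T", "U")
#: pair-breaking transversions (new base cannot pair the old partner,
#: not even as a GU wobble)
_TRANSVERSION = {"A": "C", "C": "A", "G": "U", "U": "G"}
_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: number of pair-breaking point mutations in a stem-dead mutant
N_SD_MUTATIONS = 8
#: nucleotides of exon-1 sequence duplicated in a constitutive-stem mutant
CS_DUPLICATION = 15


@dataclass(frozen=True)
class SnoSpec:
    placement: str            # 'intronic' | 'exonic'
    index: int                # which intron / exon (0-based)
    offset: int
    length: int


@dataclass(frozen=True)
class HairpinSpec:
    arm_length: int = 25
    upstream_arm_end: int = 15     # nt of the 5' arm upstream of the junction
    loop_length: int = 30
    bulges: tuple[tuple[int, int], ...] = ()   # (arm3 insert index, size)
    placement: str = "junction-spanning"       # or 'exon2-only'
    exon2_offset: int = 10         # arm start within the last exon (exon2-only)


@dataclass(frozen=True)
class LocusSpec:
    """One host locus. Defaults mirror the fission-yeast arrangement:
    a two-exon lncRNA precursor, a snoRNA in the unique intron, a second
    snoRNA in the last exon, and 25-bp complementary arms whose 5' arm
    reaches 15 nt into exon 1 across the last junction."""

    name: str = "locus1"
    exon_lengths: tuple[int, ...] = (220, 320)
    intron_lengths: tuple[int, ...] = (170,)
    sno_specs: tuple[SnoSpec, ...] = (
        SnoSpec("intronic", 0, 45, 90),
        SnoSpec("exonic", 1, 110, 100),
    )
    hairpin: HairpinSpec | None = HairpinSpec()
    mutant: str = MUTANT_NONE
    seed: int = 0
    strand: str = "+"
    host_biotype: str = "lncRNA"
    retained_intron_isoform: bool = False
    flank: int = 200
    decoy_offset: int = 8          # decoy start within the intron

    def __post_init__(self):
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise SimulationError(
                f"{self.name}: need one intron length per junction")


@dataclass
class HairpinTruth:
    junction_index: int
    rel_pairs: list[tuple[int, int]]   # junction-relative (i<0 upstream)
    span_upstream: int
    arm_sequence: str                  # 5' arm, 5'->3'
    expected_crossing: bool
    expected_detectable: bool = True
    expected_conditional: str | None = None


@dataclass
class TruthTable:
    """Planted truth for one locus; serializable to JSON."""

    name: str
    chrom: str
    strand: str
    host_gene_id: str
    host_transcript_id: str
    sno_order: list[str]
    sno_placements: dict[str, str]
    expected_cluster: bool
    expected_architecture: str | None
    hairpin: HairpinTruth | None
    up_anchor: int                     # junction anchors for rel->genomic
    down_anchor: int
    mutant: str = MUTANT_NONE
    edits: list[tuple[int, str, str]] = field(default_factory=list)
    cleavage_sites: list[dict] = field(default_factory=list)

    def rel_to_genomic(self, rel: int) -> int:
        if self.strand == "+":
            return (self.up_anchor + rel) if rel < 0 else (self.down_anchor + rel)
        if rel < 0:
            return self.up_anchor - rel - 1
        return self.down_anchor - 1 - rel

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


@dataclass
class SyntheticLocus:
    fasta: str
    gff3: str
    truth: TruthTable
    spec: LocusSpec

    def __iter__(self):
        return iter((self.fasta, self.gff3, self.truth))


# ---------------------------------------------------------------------------
# sequence helpers

def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, n)])


def random_arm(rng: np.random.Generator, n: int) -> str:
    """A random arm with GC fraction >= 0.5 (stable planted stems)."""
    while True:
        arm = random_rna(rng, n)
        if (arm.count("G") + arm.count("C")) / n >= 0.5:
            return arm


def shuffle_sequence(seq: str, rng: np.random.Generator) -> str:
    """Mononucleotide shuffle (composition-preserving permutation)."""
    chars = np.array(list(seq))
    rng.shuffle(chars)
    return "".join(chars)


def _fasta(name: str, seq_rna: str, width: int = 70) -> str:
    dna = seq_rna.translate(_DNA)
    body = "\n".join(dna[i:i + width] for i in range(0, len(dna), width))
    return f">{name}\n{body}\n"


# ---------------------------------------------------------------------------
# locus construction (always on '+', optionally flipped afterwards)

def _check_overlaps(features: list[tuple[str, int, int]]) -> None:
    by_pos = sorted(features, key=lambda f: f[1])
    for (n1, s1, e1), (n2, s2, e2) in zip(by_pos, by_pos[1:]):
        if s2 < e1:
            raise SimulationError(
                f"planted features overlap: {n1} [{s1},{e1}) and {n2} [{s2},{e2})")


def make_locus(spec: LocusSpec) -> SyntheticLocus:
    """Emit FASTA + GFF3 text and the planted :class:`TruthTable`."""
    rng = np.random.default_rng(spec.seed)
    locus = _build_plus(spec, rng)
    if spec.mutant != MUTANT_NONE:
        locus = apply_mutant(locus, spec.mutant)
    if spec.strand == "-":
        locus = flip_locus(locus)
    return locus


def _build_plus(spec: LocusSpec, rng: np.random.Generator) -> SyntheticLocus:
    F = spec.flank
    n_exons = len(spec.exon_lengths)
    # genomic block boundaries
    exon_iv: list[tuple[int, int]] = []
    intron_iv: list[tuple[int, int]] = []
    pos = F
    for k, L in enumerate(spec.exon_lengths):
        exon_iv.append((pos, pos + L))
        pos += L
        if k < n_exons - 1:
            intron_iv.append((pos, pos + spec.intron_lengths[k]))
            pos += spec.intron_lengths[k]
    gene_start, gene_end = F, pos
    total = pos + F

    seq = list(random_rna(rng, total))
    planted: list[tuple[str, int, int]] = []

    # --- hairpin ---------------------------------------------------------
    hairpin_truth = None
    hp = spec.hairpin
    if hp is not None:
        junction = n_exons - 1                      # last junction, 1-based
        up_exon = exon_iv[-2]
        down_exon = exon_iv[-1]
        L, U = hp.arm_length, hp.upstream_arm_end
        arm5 = random_arm(rng, L)
        arm3 = list(reverse_complement(arm5))
        # bulge insertions into the 3' arm (pairing unchanged, positions shift)
        shifts = [0] * (L + 1)
        for at, size in sorted(hp.bulges, reverse=True):
            arm3[at:at] = list(random_rna(rng, size))
            for m in range(at, L + 1):
                shifts[m] += size

        if hp.placement == "junction-spanning":
            if not 0 < U <= min(L, up_exon[1] - up_exon[0]):
                raise SimulationError(
                    f"{spec.name}: upstream arm end {U} infeasible")
            arm5_g0 = up_exon[1] - U                # exon-1 portion
            down_needed = (L - U) + hp.loop_length + len(arm3)
            if down_needed > down_exon[1] - down_exon[0]:
                raise SimulationError(f"{spec.name}: hairpin exceeds last exon")
            for k in range(U):
                seq[arm5_g0 + k] = arm5[k]
            for k in range(U, L):
                seq[down_exon[0] + k - U] = arm5[k]
            arm3_g0 = down_exon[0] + (L - U) + hp.loop_length
            for m, c in enumerate(arm3):
                seq[arm3_g0 + m] = c
            planted += [("arm5-up", arm5_g0, up_exon[1]),
                        ("arm5-down", down_exon[0], down_exon[0] + L - U),
                        ("arm3", arm3_g0, arm3_g0 + len(arm3))]
            # intronic decoy: revcomp of the exon-1 arm portion, so the
            # unspliced isoform sequesters it in a tight local hairpin
            decoy = reverse_complement(arm5[:U])
            d0 = intron_iv[-1][0] + spec.decoy_offset
            if d0 + U > intron_iv[-1][1]:
                raise SimulationError(f"{spec.name}: decoy exceeds intron")
            for m, c in enumerate(decoy):
                seq[d0 + m] = c
            planted.append(("decoy5", d0, d0 + U))
            # second decoy near the intron 3' end sequesters the exon-2 arm
            # portion, so neither split arm half can reach across the intron
            decoy2 = reverse_complement(arm5[U:])
            d2 = intron_iv[-1][1] - spec.decoy_offset - len(decoy2)
            if d2 < d0 + U:
                raise SimulationError(f"{spec.name}: decoys overlap in intron")
            for m, c in enumerate(decoy2):
                seq[d2 + m] = c
            planted.append(("decoy3", d2, d2 + len(decoy2)))
            rel_pairs = []
            for k in range(L):
                rel_i = k - U
                m = L - 1 - k
                rel_j = (L - U) + hp.loop_length + m + shifts[m]
                rel_pairs.append((rel_i, rel_j))
            hairpin_truth = HairpinTruth(
                junction_index=junction, rel_pairs=rel_pairs,
                span_upstream=U, arm_sequence=arm5, expected_crossing=True,
                expected_conditional="conditional")
        elif hp.placement == "exon2-only":
            g0 = down_exon[0] + hp.exon2_offset
            need = L + hp.loop_length + len(arm3)
            if hp.exon2_offset + need > down_exon[1] - down_exon[0]:
                raise SimulationError(f"{spec.name}: hairpin exceeds last exon")
            for k in range(L):
                seq[g0 + k] = arm5[k]
            arm3_g0 = g0 + L + hp.loop_length
            for m, c in enumerate(arm3):
                seq[arm3_g0 + m] = c
            planted += [("arm5", g0, g0 + L),
                        ("arm3", arm3_g0, arm3_g0 + len(arm3))]
            rel0 = hp.exon2_offset
            rel_pairs = []
            for k in range(L):
                m = L - 1 - k
                rel_pairs.append(
                    (rel0 + k, rel0 + L + hp.loop_length + m + shifts[m]))
            hairpin_truth = HairpinTruth(
                junction_index=junction, rel_pairs=rel_pairs,
                span_upstream=-hp.exon2_offset, arm_sequence=arm5,
                expected_crossing=False,
                expected_conditional="constitutive")
        else:
            raise SimulationError(
                f"{spec.name}: unknown hairpin placement {hp.placement!r}")

    # --- snoRNAs ---------------------------------------------------------
    sno_records = []       # (id, start, end, expected placement)
    for i, s in enumerate(spec.sno_specs):
        if s.placement == "intronic":
            block = intron_iv[s.index]
        elif s.placement == "exonic":
            block = exon_iv[s.index]
        else:
            raise SimulationError(
                f"{spec.name}: snoRNA placement {s.placement!r} unsupported")
        g0 = block[0] + s.offset
        if g0 + s.length > block[1]:
            raise SimulationError(
                f"{spec.name}: sno{i + 1} does not fit its {s.placement} block")
        expected = s.placement
        if s.placement == "intronic" and spec.retained_intron_isoform:
            expected = "ambiguous-retained-intron"
        sno_id = f"{spec.name}.sno{i + 1}"
        sno_records.append((sno_id, g0, g0 + s.length, expected))
        planted.append((sno_id, g0, g0 + s.length))
    _check_overlaps(planted)

    # --- annotation ------------------------------------------------------
    gene_id = f"gene:{spec.name}"
    tx_id = f"transcript:{spec.name}.t1"
    lines = ["##gff-version 3"]

    def row(ftype, start, end, attrs):
        lines.append("\t".join([spec.name, "snosplice", ftype,
                                str(start + 1), str(end), ".", "+", ".",
                                attrs]))

    row("gene", gene_start, gene_end,
        f"ID={gene_id};biotype={spec.host_biotype}")
    row("transcript", gene_start, gene_end,
        f"ID={tx_id};Parent={gene_id};biotype={spec.host_biotype}")
    for k, (s, e) in enumerate(exon_iv):
        row("exon", s, e, f"ID={tx_id}.e{k + 1};Parent={tx_id}")
    if spec.retained_intron_isoform:
        ri_id = f"transcript:{spec.name}.t2"
        row("transcript", gene_start, gene_end,
            f"ID={ri_id};Parent={gene_id};biotype=retained_intron")
        row("exon", gene_start, gene_end, f"ID={ri_id}.e1;Parent={ri_id}")
    for sno_id, s, e, _ in sno_records:
        row("gene", s, e, f"ID={sno_id};biotype=snoRNA")
    gff3 = "\n".join(lines) + "\n"

    # --- truth -----------------------------------------------------------
    placements = {sid: exp for sid, _, _, exp in sno_records}
    order = [sid for sid, s, _, _ in sorted(sno_records, key=lambda r: r[1])]
    labels = [placements[s] for s in order]
    intronic_like = {"intronic", "ambiguous-retained-intron"}
    mixed = any(l in intronic_like for l in labels) and "exonic" in labels
    arch = None
    if mixed:
        arch = ("last-exonic"
                if labels[-1] == "exonic"
                and all(l in intronic_like for l in labels[:-1])
                else "other")
    truth = TruthTable(
        name=spec.name, chrom=spec.name, strand="+",
        host_gene_id=gene_id, host_transcript_id=tx_id,
        sno_order=order, sno_placements=placements,
        expected_cluster=mixed, expected_architecture=arch,
        hairpin=hairpin_truth,
        up_anchor=exon_iv[-2][1], down_anchor=exon_iv[-1][0],
    )
    return SyntheticLocus(fasta=_fasta(spec.name, "".join(seq)),
                          gff3=gff3, truth=truth, spec=spec)


# ---------------------------------------------------------------------------
# mutants

def _locus_sequence(locus: SyntheticLocus) -> list[str]:
    body = "".join(locus.fasta.split("\n")[1:]).translate(_TO_RNA)
    return list(body)


def apply_mutant(locus: SyntheticLocus, mutant: str) -> SyntheticLocus:
    """Derive a mutant locus; returns a new locus with an edit list.

    stem-dead: 8 pair-breaking transversions spread along the 3' arm.
    compensatory-double: the same 8 plus complementary edits in the 5' arm,
    restoring every planted pair with a different sequence.
    constitutive-stem: the last 15 nt of exon 1 duplicated at the start of
    exon 2, uncoupling the hairpin from splicing.
    """
    truth = locus.truth
    if truth.hairpin is None:
        raise SimulationError(f"{truth.name}: mutant on a hairpin-free locus")
    if truth.strand == "-":
        return flip_locus(apply_mutant(flip_locus(locus), mutant))

    seq = _locus_sequence(locus)
    new_truth = copy.deepcopy(truth)
    new_truth.mutant = mutant
    hp = new_truth.hairpin
    L = len(hp.rel_pairs)

    if mutant in (MUTANT_STEM_DEAD, MUTANT_COMPENSATORY):
        step = max(1, L // N_SD_MUTATIONS)
        targets = [1 + k * step for k in range(N_SD_MUTATIONS)]
        targets = [t for t in targets if t < L][:N_SD_MUTATIONS]
        edits = []
        new_arm = list(hp.arm_sequence)
        for t in targets:
            rel_i, rel_j = hp.rel_pairs[t]
            gj = truth.rel_to_genomic(rel_j)
            old_j = seq[gj]
            seq[gj] = _TRANSVERSION[old_j]
            edits.append((gj, old_j, seq[gj]))
            if mutant == MUTANT_COMPENSATORY:
                gi = truth.rel_to_genomic(rel_i)
                old_i = seq[gi]
                seq[gi] = _WC[seq[gj]]
                new_arm[t] = seq[gi]
                edits.append((gi, old_i, seq[gi]))
        new_truth.edits = edits
        if mutant == MUTANT_STEM_DEAD:
            # <= L-8 intact pairs: below the 20-pair substrate minimum
            hp.expected_detectable = False
            hp.expected_conditional = None
        else:
            hp.arm_sequence = "".join(new_arm)
            hp.expected_conditional = None   # decoy pairing partly broken
        return SyntheticLocus(
            fasta=_fasta(truth.chrom, "".join(seq)), gff3=locus.gff3,
            truth=new_truth, spec=locus.spec)

    if mutant == MUTANT_CONSTITUTIVE:
        if hp.span_upstream > CS_DUPLICATION:
            raise SimulationError(
                f"{truth.name}: upstream arm ({hp.span_upstream} nt) exceeds "
                f"the {CS_DUPLICATION}-nt duplicated block")
        ins_at = truth.down_anchor
        copied = "".join(seq[truth.up_anchor - CS_DUPLICATION:truth.up_anchor])
        seq[ins_at:ins_at] = list(copied)
        edits = [(ins_at, "", copied)]
        # break the original exon-1 arm portion (every other pair), so the
        # duplicated block is the only way to close the stem and the hairpin
        # folds wholly downstream of the 3' splice site — the constitutive
        # construct is built in a disrupted-upstream-arm background, which
        # is also how it can act unconditionally in vivo
        for rel_i, _ in (p for p in hp.rel_pairs if p[0] < 0):
            gi = truth.rel_to_genomic(rel_i)
            old = seq[gi]
            seq[gi] = _TRANSVERSION[old]
            edits.append((gi, old, seq[gi]))
        new_truth.edits = edits
        gff3 = _shift_gff3(locus.gff3, ins_at, CS_DUPLICATION)
        # hairpin now lies wholly within the last exon: a stem position at
        # old junction-relative rel maps to rel + 15, whether it sat in the
        # duplicated exon-1 block (rel < 0) or was shifted by the insertion
        hp.rel_pairs = sorted((ri + CS_DUPLICATION, rj + CS_DUPLICATION)
                              for ri, rj in hp.rel_pairs)
        hp.span_upstream = 0
        hp.expected_crossing = False
        hp.expected_conditional = "constitutive"
        return SyntheticLocus(
            fasta=_fasta(truth.chrom, "".join(seq)), gff3=gff3,
            truth=new_truth, spec=locus.spec)

    raise SimulationError(f"unknown mutant kind {mutant!r}")


def _shift_gff3(gff3: str, ins_at: int, n: int) -> str:
    out = []
    for line in gff3.splitlines():
        if not line or line.startswith("#"):
            out.append(line)
            continue
        cols = line.split("\t")
        s, e = int(cols[3]) - 1, int(cols[4])
        # a feature starting exactly at the insertion point absorbs the
        # inserted block (the duplication goes to the start of exon 2)
        if s > ins_at:
            s += n
        if e > ins_at:
            e += n
        cols[3], cols[4] = str(s + 1), str(e)
        out.append("\t".join(cols))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# strand flip

def flip_locus(locus: SyntheticLocus) -> SyntheticLocus:
    """Mirror a locus: reverse-complement the chromosome and reflect every
    annotation interval. Placements and cluster truth are strand-invariant."""
    seq = "".join(_locus_sequence(locus))
    n = len(seq)
    flipped_seq = reverse_complement(seq)

    out = []
    for line in locus.gff3.splitlines():
        if not line or line.startswith("#"):
            out.append(line)
            continue
        cols = line.split("\t")
        s, e = int(cols[3]) - 1, int(cols[4])
        cols[3], cols[4] = str(n - e + 1), str(n - s)
        cols[6] = "-" if cols[6] == "+" else "+"
        out.append("\t".join(cols))

    truth = copy.deepcopy(locus.truth)
    new_strand = "-" if truth.strand == "+" else "+"
    if truth.strand == "+":
        # '+' anchors: up=end(half-open) of upstream exon, down=start of
        # downstream exon.  '-' anchors: up=genomic start of upstream exon,
        # down=genomic end of downstream exon.
        truth.up_anchor = n - truth.up_anchor
        truth.down_anchor = n - truth.down_anchor
    else:
        truth.up_anchor = n - truth.up_anchor
        truth.down_anchor = n - truth.down_anchor
    truth.strand = new_strand
    truth.edits = [
        ((n - g, "", reverse_complement(new)) if old == "" else
         (n - g - len(old), reverse_complement(old), reverse_complement(new)))
        for g, old, new in truth.edits]

    return SyntheticLocus(fasta=_fasta(truth.chrom, flipped_seq),
                          gff3="\n".join(out) + "\n",
                          truth=truth, spec=locus.spec)


# ---------------------------------------------------------------------------
# genomes

def make_genome(specs: list[LocusSpec]) -> tuple[str, str, list[TruthTable]]:
    """Concatenate loci (one chromosome each) into a genome."""
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise SimulationError("locus names must be unique")
    fastas, gffs, truths = [], [], []
    for spec in specs:
        locus = make_locus(spec)
        fastas.append(locus.fasta)
        body = [l for l in locus.gff3.splitlines() if not l.startswith("#")]
        gffs.extend(body)
        truths.append(locus.truth)
    gff3 = "##gff-version 3\n" + "\n".join(gffs) + "\n"
    return "".join(fastas), gff3, truths


def scenario_suite(seed: int) -> list[LocusSpec]:
    """The standard mixed-cluster recovery genome: mixed last-exonic hosts
    on both strands, a mixed 'other' architecture, intronic-only and
    exonic-only non-clusters, and a retained-intron trap."""
    return [
        LocusSpec(name="mixA", seed=seed),
        LocusSpec(name="mixB_minus", seed=seed + 1, strand="-"),
        LocusSpec(name="mixC_other", seed=seed + 2, sno_specs=(
            SnoSpec("exonic", 0, 30, 80), SnoSpec("intronic", 0, 45, 90))),
        LocusSpec(name="introniconly", seed=seed + 3, hairpin=None,
                  exon_lengths=(220, 200, 320), intron_lengths=(170, 170),
                  sno_specs=(SnoSpec("intronic", 0, 45, 90),
                             SnoSpec("intronic", 1, 45, 90))),
        LocusSpec(name="exoniconly", seed=seed + 4, hairpin=None,
                  sno_specs=(SnoSpec("exonic", 0, 30, 80),
                             SnoSpec("exonic", 1, 110, 100))),
        LocusSpec(name="ritrap", seed=seed + 5, retained_intron_isoform=True),
        LocusSpec(name="ritrap_minus", seed=seed + 6, strand="-",
                  retained_intron_isoform=True),
    ]


# ---------------------------------------------------------------------------
# degradome simulation

def simulate_degradome(
    truth: TruthTable,
    signal_counts: int = 50,
    background_rate: float = 0.1,
    offset: int = 3,
    seed: int = 0,
    cut_pair_index: int = 6,
    chrom_length: int | None = None,
) -> tuple[str, TruthTable]:
    """bedGraph 5'-end track: Poisson background plus one planted cut pair.

    The upstream-arm site u sits on stem pair ``cut_pair_index``; the
    downstream site is v = P(u) + ``offset`` (offset 3 = the RNase III
    2-nt 3' overhang signature; other values make decoys).
    """
    if truth.hairpin is None:
        raise SimulationError(f"{truth.name}: no hairpin to cut")
    rel_pairs = truth.hairpin.rel_pairs
    if not 0 <= cut_pair_index < len(rel_pairs):
        raise SimulationError(f"cut pair index {cut_pair_index} out of range")
    rel_u, rel_w = rel_pairs[cut_pair_index]
    rel_v = rel_w + offset
    g_u = truth.rel_to_genomic(rel_u)
    g_v = truth.rel_to_genomic(rel_v)

    rng = np.random.default_rng(seed)
    n = chrom_length if chrom_length is not None else (
        max(truth.rel_to_genomic(max(r for _, r in rel_pairs)),
            truth.up_anchor, truth.down_anchor) + 400)
    counts = rng.poisson(background_rate, n)
    counts[g_u] += signal_counts
    counts[g_v] += signal_counts

    lines = [f"{truth.chrom}\t{p}\t{p + 1}\t{c}"
             for p, c in enumerate(counts) if c > 0]
    new_truth = copy.deepcopy(truth)
    new_truth.cleavage_sites = [
        {"rel": rel_u, "genomic": int(g_u), "count": int(counts[g_u]),
         "arm": "5p"},
        {"rel": rel_v, "genomic": int(g_v), "count": int(counts[g_v]),
         "arm": "3p", "offset": offset},
    ]
    return "\n".join(lines) + "\n", new_truth


# ---------------------------------------------------------------------------
# homolog simulation

def simulate_homologs(
    reference_seq: str,
    pairing: dict[int, int],
    n_species: int = 10,
    sub_rate: float = 0.05,
    compensatory_fraction: float = 0.5,
    seed: int = 0,
    reference_tag: str = "ref",
) -> tuple[str, dict]:
    """Gapless homolog alignment with controlled compensatory substitution.

    Each position mutates with probability ``sub_rate``; a mutation hitting
    a paired position is made compensatory (partner co-mutated to the
    Watson-Crick complement) with probability ``compensatory_fraction``,
    otherwise only one side changes. Each pair mutates at most once per
    species, so the planted event counts are unambiguous. Returns aligned
    FASTA text and a truth dict with per-species planted event counts.
    """
    rng = np.random.default_rng(seed)
    others = {"A": "CGU", "C": "AGU", "G": "ACU", "U": "ACG"}
    rows = {reference_tag: reference_seq}
    truth: dict[str, dict[str, int]] = {}
    for s in range(n_species):
        tag = f"sp{s + 1:02d}"
        seq = list(reference_seq)
        consumed: set[int] = set()
        n_comp = n_single = 0
        for pos in range(len(seq)):
            if pos in consumed or rng.random() >= sub_rate:
                continue
            new = others[seq[pos]][rng.integers(0, 3)]
            if pos in pairing:
                partner = pairing[pos]
                consumed.add(partner)
                if rng.random() < compensatory_fraction:
                    # both sides must change: skip the one candidate whose
                    # WC complement is the current partner base (relevant
                    # when the reference pair is a GU wobble)
                    candidates = [c for c in others[seq[pos]]
                                  if _WC[c] != seq[partner]]
                    new = candidates[rng.integers(0, len(candidates))]
                    seq[pos] = new
                    seq[partner] = _WC[new]
                    n_comp += 1
                else:
                    seq[pos] = new
                    n_single += 1
            else:
                seq[pos] = new
            consumed.add(pos)
        rows[tag] = "".join(seq)
        truth[tag] = {"compensatory": n_comp, "single": n_single}
    fasta = "".join(f">{tag}\n{row}\n" for tag, row in rows.items())
    return fasta, {"species": truth,
                   "compensatory_fraction": compensatory_fraction,
                   "sub_rate": sub_rate, "seed": seed}
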