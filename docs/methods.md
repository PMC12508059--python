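# Methods

## Model and procedure

The package operationalises a specific biological claim: in a host
precursor carrying a mixed snoRNA cluster (≥ 1 intronic, ≥ 1 exonic
snoRNA), an RNA stem whose arms lie on either side of an exon–exon
junction can only fold after splicing, and a folded stem of ≥ 20 base
pairs is an RNase III substrate cleaved with two staggered cuts leaving
2-nt 3′ overhangs. The pipeline therefore answers four questions per
locus: *is there a mixed cluster? does a qualifying stem cross the last
junction of the spliced precursor? is that stem splicing-conditional?
do degradome 5′-end data show the staggered-cut signature on it?*

### Cluster calling

Internal coordinates are 0-based half-open; GFF3 I/O converts to and from
1-based inclusive. A snoRNA gene is assigned to a host transcript when it
lies on the same strand fully inside the transcript's genomic span
(same-strandedness is the biological norm for processed co-hosted
snoRNAs). Placement is pure interval geometry: intronic (inside one
intron), exonic (inside one exon), junction-overlapping (straddling a
boundary; excluded from cluster typing as ambiguous). If a snoRNA's only
exonic evidence comes from isoforms annotated with biotype
`retained_intron`, the call is `ambiguous-retained-intron` and counts as
intronic: a retained-intron isoform documents unspliced pre-mRNA, not an
independent exonic context. For the same reason retained_intron isoforms
are never selected as the host. When a gene has several isoforms, one
call is made per gene on the isoform hosting the most snoRNAs (ties:
longest spliced length, then lexicographically greatest id). Architecture
is `last-exonic` iff the 3′-most snoRNA is exonic and everything upstream
is intronic — the arrangement under which conditional cleavage enforces
sequential processing.

### Junction folding

Windows take up to W = 150 nt of spliced sequence on each side of the
junction (the default covers the −15/+121 span of the motivating locus
with margin; configurable). The unspliced variant re-inserts the full
intervening intron at the junction offset, so removing the intron span
always reproduces the spliced window byte-for-byte (a structural
invariant checked at construction).

Folding is delegated to the ViennaRNA 2.7.2 MFE engine (Turner 2004
parameters, 37 °C, minimum hairpin loop 3 nt); the engine and parameter
set are recorded in every report manifest, because MFE structures are
only reproducible relative to a parameter set. Sequences must be plain
A/C/G/U; IUPAC ambiguity codes are rejected rather than sampled, and the
synthetic generator never emits them. GU wobble counts as a canonical
pair throughout (folding, helix extraction, covariation) — the
wobble-preserving U↔C substitution opposite G is the canonical example of
a base-pair-neutral change.

Helix segments are maximal runs of stacked pairs merged across
interruptions of at most `bulge_tol` skipped nucleotides on *both* sides.
The default is `bulge_tol = 1`. This value is pinned by the empirical
null the package itself states: ≥ 95 % of mononucleotide-shuffled windows
must yield no hairpin at default thresholds. Measured on shuffles of the
standard window, a crossing ≥ 20-pair merged stem appears in ~2 % of
shuffles at tolerance 1, ~16 % at 2, and ~30 % at 3 — generous merging
converts random interleaved helices into long "stems". Tolerance 1 still
merges single-nucleotide bulges and 1×1 internal loops (small bulges in
the substrate sense); larger symmetric bulges can be admitted per run via
configuration.

A junction hairpin is the merged segment with ≥ `min_stem` (default 20,
the RNase III substrate minimum) pairs and at least one junction-crossing
pair, preferring most crossing pairs, then the 5′-most candidate. The
pipeline also uses a relaxed mode (`require_crossing=False`) so that a
qualifying stem sitting wholly inside one exon — a constitutive cleavage
signal — is still reported and classified rather than dropped. Spans are
reported junction-relative: −n = nt into the upstream exon, +m = nt into
the downstream exon (1-based from the junction).

### Conditionality

The unspliced window is folded and every stem pair is mapped through the
intron insertion. The verdict is `constitutive` when ≥ `min_stem` stem
pairs keep the same partner in the unspliced fold — a cleavable substrate
persists without splicing (this covers both a stem wholly inside one exon
and a stem the intron fails to disrupt). Otherwise the junction-crossing
pairs decide: `conditional` iff the retained fraction of crossing pairs
is ≤ `retention_threshold` (default 0.2; the motivating contrast is
all-or-nothing, so any value well below 0.5 behaves identically, and the
threshold is exposed in configuration). A hairpin without crossing pairs
falls back to retention over all stem pairs. The substrate-persistence
clause is deliberately checked first: a single fortuitous crossing pair
merged into an otherwise intra-exonic stem must not flip a constitutive
signal to conditional.

### Degradome geometry

Degradome-seq reads start at 5′-monophosphate ends, so a read 5′ end
marks the nucleotide immediately downstream of a cut. On a duplex with
pairing map P, enumerating all cut pairs on a toy 10-bp stem shows that
both products carry 2-nt 3′ overhangs exactly when the two 5′-end sites
satisfy v = P(u) + 3; this offset-3 rule is the module's contract and is
re-derived by enumeration in the test suite and the acceptance script.
A ±1 tolerance absorbs bulged stems. Site calling is deliberately simple:
a position is a site when its count is ≥ `min_count` (5) and
≥ `min_enrichment` (5×) times the median count over ± 25 nt (zeros
included). These thresholds are this package's choices, exposed in
configuration and echoed in reports. Reads inside mature snoRNA intervals
can be masked as likely contaminants (`mask_pileup`).

### Covariation

Homolog alignments are consumed, not computed (any standard multiple
aligner produces them). Substitutions at reference base-paired columns
classify as: `gapped` (either side a gap), `conserved` (identical),
`compensatory` (both sides changed, pairing kept, GU included),
`base-pair-neutral` (one side changed, pairing kept), `disruptive`
(otherwise). Stem regions are summarised per species and per basal / mid /
apical tertile of pair rank (outermost pair = basal rank 0); the tertile
boundary is configurable because the basal-vs-apical contrast is
qualitative.

## The synthetic generator

`synthetic.LocusSpec` defaults define the study conditions: a two-exon
lncRNA host (exons 220 and 320 nt, intron 170 nt, 200-nt flanks), an
intronic snoRNA (90 nt), an exonic snoRNA in the last exon (100 nt), and
25-bp exactly reverse-complementary arms (GC ≥ 50 % for stem stability)
whose 5′ arm reaches 15 nt into exon 1 across the junction — the
arrangement and −15 span of the motivating locus. Background sequence is
drawn uniformly from a seeded RNG; identical seeds give identical bytes.

Two intronic decoys are planted alongside a junction-spanning hairpin:
reverse complements of the upstream and downstream arm portions placed
near the intron's 5′ and 3′ ends. They emulate the branched structure a
real intron forms in the unspliced precursor: without them, a free-energy
minimiser happily pairs the split arm halves across a loop-ed-out intron
and the planted structure would not be splicing-conditional at all.

Mutants mirror the engineered strains that establish causality:

- **stem-dead** — 8 pair-breaking transversions spread along the 3′ arm
  (each new base cannot pair its old partner, even as GU), leaving at
  most 17 intact pairs, below the 20-pair substrate minimum.
- **compensatory-double** — the same 8 plus complementary edits on the
  5′ arm: every pair restored with different sequence, discriminating
  structure- from sequence-dependence.
- **constitutive-stem** — the last 15 nt of exon 1 duplicated at the
  start of exon 2 *and* the original exon-1 arm portion disrupted, so the
  stem folds wholly downstream of the 3′ splice site, uncoupled from
  splicing. (The duplication alone leaves two identical 15-mers competing
  for one partner, and an MFE engine resolves the tie arbitrarily; the
  corresponding in-vivo experiment is likewise read out in a
  disrupted-upstream-arm background.)

`simulate_degradome` adds two 5′-end signal positions (u on the 5′ arm,
v = P(u) + offset; offset 3 = signature, others = decoys) of 50 counts
each over Poisson background (0.1 per nt), written as bedGraph.
`simulate_homologs` mutates each position with probability 0.05 per
species; mutations at paired positions become compensatory with a
configured probability (partner co-mutated to the Watson–Crick
complement, both sides guaranteed to change), each pair mutating at most
once per species so planted event counts are exact.

### What the generator does not emulate

Real introns have splice-site and branch-point constraints; real
backgrounds are not uniform-random; real degradome libraries have
coverage biases and contaminating mature-snoRNA reads; homolog alignments
contain indels (the simulator is gapless). Passing tests therefore
demonstrate correctness of the *computational contract* — coordinate
arithmetic, folding-based discrimination under the planted conditions,
cut-geometry matching, classification — not performance on real genomes.

A quantified limitation: in a 300-nt random-background window, the MFE
fold contains a ≥ 20-pair merged junction-crossing stem in roughly 2–5 %
of draws. Consequently a few generator seeds produce loci where detection
reports a genuine (but unplanted) background stem, and occasionally the
unspliced MFE rescues cross-intron pairing despite the decoys, making a
planted "conditional" hairpin fold constitutively. Mutant-discrimination
expectations are therefore stated for the recorded fixture seed (0),
where all four outcomes were verified on both strands; planted-stem
detection rates in the acceptance script measure this background floor
honestly rather than hiding it.

## Problem sizes

Tests and the acceptance script run desk-scale by design: 20 synthetic
genomes of 7 loci for cluster recovery, 50 degradome simulations, 200
sequences for the MFE-vs-Nussinov bound (≤ 100 nt, where the exhaustive
DP oracle is fast), 100 shuffles for the null, 10 replicate homolog sets.
The whole suite folds a few thousand ≤ 500-nt windows, well within a
minute of CPU.

## Numerical choices

- ΔG values are reported to 0.01 kcal/mol; comparisons across engine
  parameter-set revisions should allow ± 1.5 kcal/mol.
- Spans and coordinates are exact integers; no tolerance.
- The Nussinov oracle (numba DP, canonical + GU pairs, min loop 3) is an
  independent upper bound on any structure's pair count; it shares no
  code with the MFE path.
- Tie-breaks: candidate hairpins by most crossing pairs then 5′-most;
  isoforms by snoRNA count, spliced length, then id; cleavage pairs
  sorted by score (min of the two site counts) descending.
- Degenerate inputs: empty annotation yields an empty report with exit 0;
  windows clipped at transcript ends record the flank actually used;
  an all-zero pileup yields no sites; a homopolymer folds to the open
  chain with ΔG 0.

## Known limitations

- Junction analysis defaults to the *last* junction (the mixed-cluster
  architecture of interest); other junctions are reachable via
  `junction_index` but the survey does not scan all junctions.
- Conditionality is an MFE-level statement; suboptimal ensembles
  (partition-function base-pair probabilities) are not consulted.
- Cleavage-site calling has no replicate or library-size model beyond
  local enrichment.
- The covariation module anchors pairing on the reference structure only;
  it does not re-fold homologs or compute a consensus structure.
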