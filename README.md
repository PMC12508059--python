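# snosplice

Detection of splice-junction-conditional RNase III cleavage signals in
mixed snoRNA host transcripts.

## The problem

Small nucleolar RNAs (snoRNAs) are processed out of longer capped,
polyadenylated precursors, usually by excision from an intron or by
endonucleolytic cleavage of the exonic precursor. Some host genes carry a
*mixed* cluster: at least one intronic snoRNA and at least one exonic
snoRNA on the same precursor. For such a precursor the order of maturation
events matters — cleaving the exonic snoRNA free before the intron is
spliced can expose the 3′ splice site to exonucleolytic trimming and trap
the intronic snoRNA.

A resolution to this conflict is a hairpin whose two arms are encoded on
either side of an exon–exon junction. Only after splicing joins the exons
can the stem fold; the folded stem is then a substrate for an RNase III
enzyme (Pac1 in fission yeast, Drosha in mammals), which cleaves double-
stranded stems of roughly ≥ 20 base pairs with two staggered cuts leaving
2-nt 3′ overhangs. The junction-spanning arrangement makes cleavage
*conditional on splicing* and thereby enforces sequential processing:
splice first, cleave second.

`snosplice` implements the computational side of this analysis as a
reusable, offline-testable pipeline:

1. **annotation** — parse genome FASTA + GFF3, build transcript models,
   classify each snoRNA as intronic / exonic / junction-overlapping
   (with a retained-intron ambiguity rule), and call mixed clusters and
   their architecture (`last-exonic` when a single exonic snoRNA follows
   one or more intronic ones).
2. **junction_fold** — reconstruct spliced and unspliced windows around a
   junction, fold them (ViennaRNA MFE, Turner parameters, 37 °C), extract
   bulge-tolerant helix segments, detect junction-crossing stems of
   ≥ 20 pairs, and test splicing-conditionality by refolding with the
   intron restored.
3. **degradome** — pile up degradome-seq read 5′ ends, call cleavage
   sites, and match site pairs on the stem to the staggered-cut geometry:
   with pairing map *P*, sites *u*, *v* satisfy *v − P(u) = 3* in 5′-end
   coordinates exactly when both products carry 2-nt 3′ overhangs.
4. **covariation** — classify substitutions at base-paired alignment
   columns of homologous junction regions as conserved / compensatory /
   base-pair-neutral / disruptive (GU wobble counts as pairing).
5. **synthetic** — seeded generators for genomes, degradome tracks,
   engineered stem mutants and homolog alignments with machine-readable
   planted truth, so every stage is testable without downloads.
6. **pipeline / CLI** — a survey orchestrator plus a `snosplice` command
   with `classify`, `survey`, `fold-junction`, `degradome-scan`,
   `covary` and `simulate` subcommands.

## Worked example

Generate a synthetic host locus — a two-exon lncRNA precursor with a
snoRNA in its intron, a second snoRNA in the last exon, and 25-bp
complementary arms planted across the junction, the 5′ arm reaching 15 nt
into exon 1 — and analyse it:

```
$ snosplice simulate --seed 11 --out-dir demo
$ snosplice fold-junction --fasta demo/genome.fa \
      --gff3 demo/annotation.gff3 --transcript transcript:locus1.t1
span    -15/+65
delta_g -125.6
stem_length     26
crossing_pairs  15
conditional     conditional
engine  ViennaRNA 2.7.2 (Turner 2004, 37C, min-loop 3)
```

The detected stemloop runs from 15 nt before the junction to 65 nt into
the downstream exon, 15 of its pairs cross the junction, and it is
*conditional*: refolding the window with the intron restored disrupts the
junction-crossing pairs. Cluster calling and the degradome scan on the
simulated 5′-end track:

```
$ snosplice classify --fasta demo/genome.fa --gff3 demo/annotation.gff3
host_gene    host_transcript       species_tag  n_sno  sno_ids                  placements       architecture
gene:locus1  transcript:locus1.t1               2      locus1.sno1,locus1.sno2  intronic,exonic  last-exonic

$ snosplice degradome-scan --fasta demo/genome.fa --gff3 demo/annotation.gff3 \
      --transcript transcript:locus1.t1 \
      --bedgraph-plus demo/degradome_locus1_plus.bedgraph
...
u    v    offset  signature  score
141  211  3       True       50
```

The two cleavage sites sit on opposite arms of the stem at offset 3 in
5′-end coordinates — the 2-nt 3′-overhang signature of an RNase III
staggered cut — with pair score 50 (the smaller of the two site counts).

Real genomes are analysed the same way: `snosplice survey --fasta genome.fa
--gff3 annotation.gff3 --out-dir out` writes `clusters.tsv`,
`hairpins.tsv`, cleavage tables and a run manifest recording the engine
and all parameters.

## Scope

Wet-lab assays, raw read processing (basecalling, mapping, CAGE/nano-COP
pipelines) and conservation-track computation are out of scope; the
package consumes standard formats (FASTA, GFF3, bedGraph, SAM, aligned
FASTA) that upstream tools produce.
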