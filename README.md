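# synann

Synteny-aware annotation of compact yeast genomes from a curated
homology-pillar database.

## The problem

De novo genome projects for budding yeasts (Saccharomycotina) produce
assemblies faster than anyone can annotate them. Yeast genomes are unusually
friendly to comparative annotation: almost all genes are intronless, gene
order is conserved over long distances, and for the family
Saccharomycetaceae a curated database of *homology pillars* exists — columns
of orthologous genes (and paralogs retained from the whole-genome
duplication, WGD) across reference species, arranged along an inferred
ancestral gene order. `synann` exploits that structure: any region of a new
genome can be mapped onto the ancestral order, and the genes expected there
— with their intron/exon structures — can be projected onto the new
sequence.

The pipeline targets users annotating a new assembly (scaffolds FASTA, and
optionally the contigs and primary reads) against a pillar database, and
developers who need a fully synthetic, ground-truthed world to test every
stage without touching external data.

## The method

For each pillar *P* the member protein *Q* with the lowest translated-search
E-value against the genome marks the pillar's primary locus (initial store:
E < 1e-05). Weaker loci of *Q* are kept only when the exponent of their
E-value is below −30 **and** below half the exponent of the best hit's
E-value — a best hit at 1e-100 retains secondaries below 1e-50. When
paralogy makes several pillars claim one locus *L*, the nearest
unambiguously placed neighbours (*P*<sub>left</sub>, *P*<sub>right</sub>)
define an interval in the ancestral order, and a candidate wins only if it —
alone — falls inside that interval; E-values play no role. A post-WGD run
allows two loci per pillar, a non-WGD run one; tandem duplicates are split
into derived copy pillars.

Gene models come from the geometry of consecutive HSPs of the chosen
reference gene *R* (preferring *R* from the target's species group, then
intron-bearing members): pairs are classified as **frameshift** (different
frames, similar query/subject gaps), **low similarity** (same frame, similar
gaps, no stop between), **intron** (dissimilar gaps, considered only when
the pillar's species group has an intron-bearing member), or **duplication**
(two models). Seeds are extended to the furthest upstream in-frame ATG not
blocked by a stop (falling back to a 45 nt scan inside the seed, then a
manual-check tag) and downstream to the first in-frame stop. Introns are
located by exhaustive enumeration of canonical yeast motifs — donors
GTATGT, GTCAGT, GTTCGT, GTACGT, GTAAGT, GCATGT, GTATGA, GTATGC;
branchpoints ACTAAC, GCTAAC, ATTAAC; acceptors CAG/TAG — constrained to
in-frame, stop-free spliced products, at most one intron per gene.

Frameshift sequencing errors (the HSP-pair class above) are repaired by
read voting: reads aligning to a ±50 bp window around the break (E < 1e-30)
vote on exact indels; the most common indel seen in ≥2 reads that restores
an intact ORF is applied to the assembly, which is then re-annotated once.
Without reads, 1–2 N bases restore the frame at the estimated site. Three
rescue passes follow: a thresholdless protein-vs-gap alignment for divergent
genes in conserved locations, a sweep for unannotated ORFs ≥ 150 aa, and
propagation of retrotransposon (Ty) labels (hit at E < 1e-5 ⇒ tagged,
singleton). Scaffold integrity is checked separately from paired reads via
a contig-link support matrix.

## Worked example

Generate a synthetic 40-gene world with five planted frameshift errors and
20× simulated paired reads, then annotate it:

```sh
synann fixture --seed 7 --out fx --n-pillars 40 --frameshift-count 5 \
    --read-coverage 20 --intron-fraction 0.08
synann run --scaffolds fx/scaffolds.fasta --pillars fx/pillars.json \
    --reads fx/reads.fasta --fix-frameshifts reads \
    --out annot --prefix NEW --wgd non
```

prints

```
40 gene models -> annot
  initial_models: 40
  frameshift_detections: 5
  corrections_applied: 5
  models_after_repair: 40
  searchdogs_models: 0
  large_orf_models: 0
```

All 40 planted genes are modeled; all five frameshift HSP-pairs were
detected and all five assembly edits were applied (each supported by the
reads, see `annot/corrections.tsv` — e.g. `chr1 6846 insert G 21 1`: an
insertion of G at chr1:6846 supported by 21 reads, applied). The GFF3
starts:

```
##gff-version 3
##sequence-region chr1 1 36641
chr1  synann  gene  576  1200  .  -  .  ID=NEW1.0001;pillar=P0001;...
chr1  synann  CDS   576  1014  .  -  1  ID=NEW1.0001.CDS;...
chr1  synann  CDS  1079  1200  .  -  0  ID=NEW1.0001.CDS;...
```

`NEW1.0001` is a minus-strand two-exon (single-intron) gene assigned to
pillar P0001. Output also includes `assignments.tsv` (locus → pillar,
evidence, E-value), per-tag gene lists under `tags/`, the corrected
scaffolds, and `searchdogs.txt` / `large_orfs.txt` for the rescue passes.

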