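# Methods

## Scope and model

`synann` annotates protein-coding genes in a newly assembled yeast genome
by projection from a curated pillar database: each pillar is a column of
orthologous (and WGD-paralogous) genes across reference species, split into
a post-WGD and a non-WGD species group and indexed by an ancestral gene
order. The working assumptions are the classic ones for Saccharomycetaceae:
genes are almost always single-exon (defaults assume ~4% intron-bearing,
all single-intron), gene order is locally conserved against the ancestral
arrangement, and a post-WGD genome carries at most two syntenic copies of
an ancestral locus where a non-WGD genome carries one. Outside these
assumptions (intron-rich fungi, heavily rearranged genomes) the projection
logic degrades and the tool is not appropriate.

## Translated search

The built-in engine translates all six frames, indexes them with amino-acid
5-mers, and extends seeds ungapped under BLOSUM62 with an X-drop of 20.
Bitscores and E-values use the ungapped Karlin–Altschul parameters for
BLOSUM62 (λ = 0.3176, K = 0.134) with search space = query length × total
translated length. The engine is deterministic and dependency-free but
makes no claim of reproducing any external search tool's E-values; for real
genomes a user can substitute any translated search via `--hits` (a
13-column tabular dialect; coordinates are normalized to 0-based half-open
forward-strand internally — GFF3 conversion happens only in the writers).
Initial hit storage uses E < 1e-05. Secondary loci of the best query are
retained iff exponent(E) < −30 and exponent(E) < exponent(E_best)/2, with
exponent(e) = floor(log10 e) and E = 0.0 mapped to exponent −324 (float
underflow), so an underflowed best hit still admits secondaries. HSPs are
grouped into candidate loci by single-linkage with a 5 kb gap — above the
span introns and small indels can add, below typical tandem-gene spacing.

## Locus assignment

Overlapping candidate loci merge into sites whose candidate set is the set
of pillars hitting them. Single-candidate sites are unambiguous anchors;
multi-candidate sites are resolved by the neighbour-interval test: scan up
to 10 loci left and right for anchors, and accept the unique candidate
lying strictly between the anchors' ancestral positions (same ancestral
chromosome only; cross-chromosome anchors never resolve, which avoids
spurious calls at rearrangement breakpoints). At a scaffold end a single
anchor suffices if the candidate is within 10 ancestral positions of it.
Resolution iterates in synchronous rounds — every decision in a round sees
only the previous round's anchors — so the outcome is independent of scan
direction; the test suite asserts mirror-symmetry under scaffold
reverse-complementation. Unresolvable sites are annotated as singletons.
Tandem groups (adjacent same-pillar loci) keep one copy on the pillar —
chosen by outside-flank ancestral adjacency, then 5'-most — and move the
rest to derived `.tN` pillars; copy-number caps (2 post-WGD / 1 non-WGD)
demote excess loci, preferring synteny evidence, then lower E-value.

## Gene models

The reference gene R for a locus is chosen by tiered preference
(same-group intron-bearing → same-group → intron-bearing → any; ties by
E-value, bitscore, gene id). R's HSPs at the locus are evaluated pairwise
in location order on the coding strand:

* frameshift — frames differ, |Δq − Δs| ≤ 30 nt;
* low similarity — same frame, |Δq − Δs| ≤ 30 nt, no in-frame stop between;
* intron — |Δq − Δs| > 30 nt, query gap ≤ 30 nt-equivalents, subject gap
  ≥ 40 nt, and the pillar's target species group contains an intron-bearing
  member;
* duplication — everything else; the chain is split into separate models.

Because X-drop extension drifts past a frameshift or splice junction in the
wrong frame, consecutive HSPs of one gene routinely overlap by 20–30 aa on
the query. Overlaps up to 40 aa are trimmed off the upstream HSP before gap
geometry is measured; only larger overlaps are treated as duplicated
segments. (With the overlap cut at 15 aa and no trimming, planted
frameshifts are misread as duplications at an appreciable rate; the suite
covers this regression.)

Start codons follow a four-step rule: keep an ATG-initial seed; else extend
in frame to the furthest upstream ATG not blocked by a stop (bounded by 3×
the pillar's mean group protein length, computed per species group, to
forbid absurd extensions); else scan the first 45 nt inside the seed; else
keep the seed start and tag `manual-check`. Stops: an in-frame stop inside
the seed trims the model, otherwise the first downstream in-frame stop ends
it (stop codon included in the CDS). Walking into an N run tags
`runs-into-N`. Models whose final CDS is not a clean ATG…stop frame get
`manual-check`.

## Introns

At most one intron per gene is ever predicted; evidence for a second adds
`manual-check`. Between two intron-classified HSPs, all combinations of
donor (8 motifs), branchpoint (3 motifs, required between donor and
acceptor) and acceptor (CAG/TAG) with intron length 40–1000 nt are
enumerated; a combination is valid when the spliced product is in frame and
stop-free. Ranking prefers the combination whose implied protein length is
closest to R's (this separates competing acceptors one codon apart), then
the donor closest to the upstream HSP's end. Search windows carry ±45 nt of
slack because HSP ends overrun splice sites. When only the exon-2 HSP
exists and R is intron-bearing, a first exon is reconstructed upstream
(600 nt scan window): acceptor ← branchpoint ← donor ← ATG, requiring
reconstructed protein length within ±20% of R's; the plain single-exon
extension competes and the better length agreement wins. The branchpoint's
distance to the acceptor is unconstrained beyond ordering — a known
divergence from canonical yeast geometry (~10–60 nt) that widens the
candidate set slightly.

## Frameshift repair

A frameshift call yields a window from 50 bp upstream of the first HSP's
(trimmed) end to 50 bp downstream of the second's start. In reads mode,
each read (either orientation) is aligned with the window as an infix
(edlib); alignments passing an E < 1e-30 gate vote on exact
(offset, op, bases) indels; candidates seen in <2 reads are dropped. In
support order, the first candidate that both restores the reading frame
((d + Δlength) ≡ 0 mod 3) and leaves the inter-HSP span stop-free in the
upstream frame is applied. Candidate reads are prefiltered by exact 25-mer
flank matching — a pure speedup, since reads that fail it cannot contain
the full window. Without reads, (3 − d) mod 3 ∈ {1, 2} N bases are inserted
at the in-frame midpoint of the inter-HSP gap. All accepted edits are
batched, the scaffolds rewritten, and the annotation re-run once on the
edited assembly; models overlapping applied edit sites are tagged
`frameshift-corrected`, detected-but-unfixed sites stay
`frameshift-uncorrected`. With repair disabled the same sites are still
detected and reported.

## Rescue passes and QC

Rescue only adds models, never edits accepted ones. The syntenic-gap pass
targets ancestral loci whose two nearest placed neighbours flank an
unannotated gap on one scaffold: intronless member proteins are aligned
(biopython PairwiseAligner, local, BLOSUM62, no E-value threshold) against
every ATG→stop ORF ≥ 30 codons in the gap; a hit covering ≥ 50% of the
shortest member protein yields a `searchdogs`-tagged model. The large-ORF
pass emits unannotated maximal ATG→stop ORFs ≥ 150 aa (stop excluded) with
zero feature overlap on either strand. Ty-labelled reference hits at
E < 1e-5 tag overlapping models `ty` and remove them from the pillar system.
Protein-coding models are never allowed to overlap a tRNA feature (the tRNA
track is ingested from a precomputed GFF3 rather than by invoking an
external predictor).

Scaffold QC places each paired read at its unique exact occurrence
(fixture reads are error-free, so exact-match uniqueness substitutes for a
score-margin rule), maps placements to contigs located inside the
scaffolds, and reports a symmetric contig-link matrix in scaffold order.
Adjacent-band cells under 3 supporting pairs are flagged weak; off-band
cells at ≥ 3 are listed as alternatives. The tool reports; it never breaks
joins itself.

## Synthetic worlds

The fixture generator emulates the study conditions end to end: pillars
with ≥2 species per group (uniform-composition proteins, lognormal length
with mean 450 codons, 5% inter-species divergence), ~4% intron-bearing
pillars with motif-compliant planted introns (half with first exons of
9–21 nt to exercise exon-1 recovery), local order shuffles and single-gene
inversions, optional WGD duplication with configurable ohnolog retention,
tandem and Ty duplications, planted highly divergent short genes (60%
divergence — below the seeded search's sensitivity, recoverable only
through the syntenic-gap pass) and novel large ORFs. Frameshift injection
places 1 bp indels inside coding regions, biased to homopolymer runs
(deletions 70% — mirroring the dominance of missing bases in pyrosequencing
assemblies); paired reads are simulated error-free from the pre-error
sequence so that read voting is isolated from any sequencing-error model.
Every output is a deterministic function of the seed.

What passing tests on these worlds does **not** show: robustness to read
errors and quality values, realistic amino-acid composition or
phylogenetically correlated divergence, multi-intron genes, pseudogenes,
and assembler-specific artifacts. Real-genome accuracy therefore cannot be
inferred from fixture recovery rates; the fixtures verify the logic, not
the biology.

## Problem sizes and numerical choices

The acceptance suite uses 200-pillar worlds (~0.5 Mb genomes) for recovery,
60 pillars with 50 planted indels at 20× coverage for repair, and 80
pillars for WGD copy-number checks — sizes chosen so each property is
measured on hundreds of events while the whole suite stays desk-scale.
Degenerate inputs are handled explicitly: empty FASTA/pillar files and
malformed tabular rows raise named errors; pillars with no hits are
skipped; loci whose reference gene has no usable HSPs are dropped; seeds
shorter than one codon are rejected. Ties everywhere break
deterministically (E-value, then bitscore, then lexical id; 5'-most for
tandem keepers), and a rerun on identical inputs is byte-identical.
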