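"""Post-annotation rescue passes.

Three passes run after the main annotation and only ever add tagged models:

* a thresholdless syntenic-gap search that recovers small, highly divergent
  genes missed by the E-value-gated search, provided the surrounding gene
  order pins down where the gene is expected (conserved genomic location,
  intronless candidates only);
* a sweep for unannotated large ORFs (>= 150 aa, no overlap with any
  feature on either strand);
* propagation of retrotransposon (Ty) labels: models hit by a Ty-flagged
  reference protein at E < 1e-5 are tagged and left outside the pillar
  system as singletons.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .core import (
    GeneModel,
    Genome,
    Hsp,
    Pillar,
    START_CODON,
    STOP_CODONS,
    StrandView,
    TAG_LARGE_ORF,
    TAG_SEARCHDOGS,
    TAG_TY,
    TrnaFeature,
    revcomp,
)
from .synteny import LocusAssignment

#: Minimum candidate length for the syntenic-gap pass (codons) and minimum
#: alignment coverage of the shortest pillar protein.  "No threshold" on
#: similarity still needs sanity constraints to bound false positives.
GAP_MIN_CODONS = 30
GAP_MIN_COVERAGE = 0.5

LARGE_ORF_MIN_AA = 150


@dataclass(frozen=True)
class Orf:
    """A maximal ATG->stop open reading frame (forward-strand coords)."""

    scaffold_id: str
    strand: str
    start: int
    end: int  # includes the stop codon

    @property
    def aa_length(self) -> int:
        return (self.end - self.start) // 3 - 1  # stop codon excluded


def _scan_orfs(view: StrandView, min_aa: int,
               region: tuple[int, int] | None = None) -> list[Orf]:
    """Maximal ATG->stop ORFs of one strand view, optionally restricted to a
    view-coordinate region."""
    seq = view.seq
    lo, hi = region if region else (0, len(seq))
    orfs = []
    for frame in range(3):
        first = lo + ((frame - lo) % 3)
        start_atg: int | None = None
        for p in range(first, hi - 2, 3):
            codon = seq[p:p + 3]
            if codon in STOP_CODONS:
                if start_atg is not None:
                    orf_len_aa = (p - start_atg) // 3
                    if orf_len_aa >= min_aa:
                        s, e = view.to_forward(start_atg, p + 3)
                        orfs.append(Orf(view.scaffold_id, view.strand, s,
                                        e))
                    start_atg = None
            elif codon == START_CODON and start_atg is None:
                start_atg = p
    return orfs


def _overlaps_any(scaffold: str, start: int, end: int,
                  features: dict[str, list[tuple[int, int]]]) -> bool:
    for s, e in features.get(scaffold, []):
        if start < e and s < end:
            return True
    return False


def _feature_index(models: list[GeneModel],
                   trna: list[TrnaFeature]) -> dict[str, list[tuple[int, int]]]:
    feats: dict[str, list[tuple[int, int]]] = {}
    for m in models:
        s, e = m.span
        feats.setdefault(m.scaffold_id, []).append((s, e))
    for t in trna:
        feats.setdefault(t.scaffold_id, []).append((t.start, t.end))
    return feats


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "local"
    return aligner


def syntenic_gap_search(assignments: list[LocusAssignment],
                        models: list[GeneModel],
                        pillars_by_id: dict[str, Pillar],
                        ancestral, genome: Genome,
                        trna: list[TrnaFeature],
                        min_codons: int = GAP_MIN_CODONS,
                        min_coverage: float = GAP_MIN_COVERAGE
                        ) -> list[GeneModel]:
    """Recover divergent genes expected in syntenic gaps.

    For each ancestral locus whose two nearest annotated neighbours flank an
    unannotated intergenic gap on one scaffold, every intronless member
    protein of the missing pillar is aligned (no E-value threshold) against
    the ORFs of the gap; the best ATG->stop candidate of plausible length
    and coverage becomes a new model tagged searchdogs.  Candidates
    overlapping a tRNA feature are rejected.
    """
    placed: dict[str, LocusAssignment] = {}
    for a in assignments:
        if a.pillar_id in pillars_by_id and a.pillar_id not in placed:
            placed[a.pillar_id] = a
    features = _feature_index(models, trna)
    aligner = _protein_aligner()
    new_models: list[GeneModel] = []
    for chrom, loci in ancestral.ordered_loci.items():
        for i, pid in enumerate(loci):
            if pid in placed or pid not in pillars_by_id:
                continue
            pillar = pillars_by_id[pid]
            if pillar.is_ty:
                continue
            candidates = [m for m in pillar.members if not m.has_intron]
            if not candidates:
                continue  # intron-bearing genes are out of this pass's scope
            left = next((placed[loci[j]] for j in range(i - 1, -1, -1)
                         if loci[j] in placed), None)
            right = next((placed[loci[j]] for j in range(i + 1, len(loci))
                          if loci[j] in placed), None)
            if (left is None or right is None
                    or left.scaffold_id != right.scaffold_id):
                continue
            gap_lo = min(left.end, right.end)
            gap_hi = max(left.start, right.start)
            if gap_hi - gap_lo < 3 * (min_codons + 1):
                continue
            shortest = min(len(m.protein) for m in candidates)
            best: tuple | None = None
            for strand in "+-":
                view = StrandView(genome, left.scaffold_id, strand)
                vlo, vhi = view.from_forward(gap_lo, gap_hi)
                for orf in _scan_orfs(view, min_codons, (vlo, vhi)):
                    if _overlaps_any(orf.scaffold_id, orf.start, orf.end,
                                     {t.scaffold_id: [(t.start, t.end)]
                                      for t in trna}):
                        continue
                    if _overlaps_any(orf.scaffold_id, orf.start, orf.end,
                                     features):
                        continue
                    sub = genome.fetch(orf.scaffold_id, orf.start, orf.end)
                    if strand == "-":
                        sub = revcomp(sub)
                    orf_prot = str(Seq(sub[:-3]).translate())
                    for member in candidates:
                        try:
                            aln = aligner.align(member.protein, orf_prot)
                        except ValueError:
                            continue
                        if len(aln) == 0:
                            continue
                        top = aln[0]
                        qspan = top.aligned[0]
                        covered = sum(e - s for s, e in qspan)
                        if covered < min_coverage * shortest:
                            continue
                        key = (-top.score, member.gene_id)
                        if best is None or key < best[0]:
                            best = (key, orf, strand, member.gene_id)
            if best is not None:
                _, orf, strand, ref_gene = best
                exons = [(orf.start, orf.end)]
                new_models.append(GeneModel(
                    model_id=f"{pid}.sdg", scaffold_id=orf.scaffold_id,
                    strand=strand, exons=exons, pillar_id=pid,
                    tags={TAG_SEARCHDOGS}, source_reference_gene=ref_gene,
                    evidence="syntenic-gap"))
                s, e = orf.start, orf.end
                features.setdefault(orf.scaffold_id, []).append((s, e))
    return new_models


def find_large_orfs(genome: Genome, models: list[GeneModel],
                    trna: list[TrnaFeature],
                    min_len_aa: int = LARGE_ORF_MIN_AA) -> list[GeneModel]:
    """Unannotated large ORFs: maximal ATG->stop frames of at least
    ``min_len_aa`` residues (stop excluded) with zero overlap against any
    feature on either strand, emitted as large-orf singletons."""
    features = _feature_index(models, trna)
    out: list[GeneModel] = []
    n = 0
    for scaffold in sorted(genome.sequences):
        for strand in "+-":
            view = StrandView(genome, scaffold, strand)
            for orf in _scan_orfs(view, min_len_aa):
                if orf.aa_length < min_len_aa:
                    continue
                if _overlaps_any(scaffold, orf.start, orf.end, features):
                    continue
                n += 1
                out.append(GeneModel(
                    model_id=f"orf{n:04d}", scaffold_id=scaffold,
                    strand=strand, exons=[(orf.start, orf.end)],
                    pillar_id=None, tags={TAG_LARGE_ORF},
                    evidence="large-orf"))
                features.setdefault(scaffold, []).append((orf.start, orf.end))
    return out


def propagate_ty_flags(models: list[GeneModel], ty_hsps: list[Hsp],
                       evalue_cutoff: float = 1e-5) -> list[GeneModel]:
    """Flag models hit by a Ty-labelled reference protein (E < 1e-5) as
    Ty-like: they keep their coordinates but are tagged and removed from the
    pillar system (left as singletons)."""
    strong = [h for h in ty_hsps if h.evalue < evalue_cutoff]
    for model in models:
        s, e = model.span
        for h in strong:
            if (h.scaffold_id == model.scaffold_id
                    and s < h.subj_end and h.subj_start < e):
                model.tags.add(TAG_TY)
                model.pillar_id = None
                model.evidence = "ty-like"
                break
    return models
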