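"""Domain types shared by every pipeline stage.

Coordinate convention: all internal coordinates are 0-based half-open on the
forward strand of the scaffold they refer to.  Conversion to the 1-based
inclusive convention of GFF3 happens only inside the writers in
:mod:`synann.io`.  Gene-model logic runs on the coding strand through
:class:`StrandView`, which maps view coordinates back to forward-strand
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DNA_ALPHABET = frozenset("ACGTN")
# 20 canonical residues plus X (unknown, e.g. translated over an N run)
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

POST_WGD = "post-WGD"
NON_WGD = "non-WGD"
SPECIES_GROUPS = (POST_WGD, NON_WGD)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SynannError(Exception):
    """Base class for user-facing errors."""


@dataclass
class Genome:
    """A set of scaffold sequences (uppercase A/C/G/T/N)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise SynannError(
                    f"scaffold {name!r} contains characters outside A/C/G/T/N: "
                    f"{sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, scaffold_id: str, start: int | None = None,
              end: int | None = None) -> str:
        seq = self.sequences[scaffold_id]
        if start is None:
            return seq
        return seq[max(0, start):end]

    def __contains__(self, scaffold_id: str) -> bool:
        return scaffold_id in self.sequences


@dataclass(frozen=True)
class RefGene:
    """One annotated gene from the reference pillar database."""

    gene_id: str
    species: str
    species_group: str
    protein: str
    exon_count: int = 1
    is_ty: bool = False

    def __post_init__(self) -> None:
        if not self.protein:
            raise SynannError(f"reference gene {self.gene_id!r}: empty protein")
        if self.species_group not in SPECIES_GROUPS:
            raise SynannError(
                f"reference gene {self.gene_id!r}: unknown species group "
                f"{self.species_group!r}"
            )
        bad = set(self.protein) - AA_ALPHABET
        if bad:
            raise SynannError(
                f"reference gene {self.gene_id!r}: invalid residues {sorted(bad)}"
            )
        if self.exon_count < 1:
            raise SynannError(f"reference gene {self.gene_id!r}: exon_count < 1")

    @property
    def has_intron(self) -> bool:
        return self.exon_count > 1


@dataclass
class Pillar:
    """A curated column of homologous genes across the reference species.

    The pillar is the unit of ortholog assignment: each one holds the
    orthologs (and post-WGD paralogs) of a single ancestral gene.
    """

    pillar_id: str
    members: list[RefGene]
    ancestral_locus: str | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise SynannError(f"pillar {self.pillar_id!r} has no members")
        ids = [m.gene_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise SynannError(f"pillar {self.pillar_id!r}: duplicate member ids")
        ty = {m.is_ty for m in self.members}
        if ty == {True, False}:
            raise SynannError(
                f"pillar {self.pillar_id!r} mixes Ty and non-Ty genes"
            )

    @property
    def is_ty(self) -> bool:
        return self.members[0].is_ty

    def members_in_group(self, group: str) -> list[RefGene]:
        return [m for m in self.members if m.species_group == group]

    def get_member(self, gene_id: str) -> RefGene:
        for m in self.members:
            if m.gene_id == gene_id:
                return m
        raise KeyError(gene_id)


@dataclass
class AncestralOrder:
    """Pre-WGD gene order: per-chromosome ordered lists of pillar ids."""

    ordered_loci: dict[str, list[str]]

    def __post_init__(self) -> None:
        self._position: dict[str, tuple[str, int]] = {}
        for chrom, loci in self.ordered_loci.items():
            for idx, pid in enumerate(loci):
                if pid in self._position:
                    raise SynannError(
                        f"pillar {pid!r} appears twice in the ancestral order"
                    )
                self._position[pid] = (chrom, idx)

    def position(self, pillar_id: str) -> tuple[str, int] | None:
        return self._position.get(pillar_id)

    def between(self, candidate: str, left: str, right: str) -> bool:
        """True if candidate lies strictly between left and right on one
        ancestral chromosome (orientation-agnostic)."""
        pc, pl, pr = (self.position(candidate), self.position(left),
                      self.position(right))
        if pc is None or pl is None or pr is None:
            return False
        if not (pc[0] == pl[0] == pr[0]):
            return False
        lo, hi = sorted((pl[1], pr[1]))
        return lo < pc[1] < hi


@dataclass(frozen=True)
class Hsp:
    """One high-scoring pair from a translated protein-vs-genome search.

    Query coordinates are 1-based inclusive amino-acid positions; subject
    coordinates are 0-based half-open on the forward strand.  ``frame`` is the
    offset (0/1/2) of the HSP's first codon on the coding strand.
    """

    query_id: str
    scaffold_id: str
    query_start: int
    query_end: int
    subj_start: int
    subj_end: int
    strand: str
    frame: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.query_start > self.query_end:
            raise SynannError("Hsp: query_start > query_end")
        if self.subj_start >= self.subj_end:
            raise SynannError("Hsp: subj_start >= subj_end")
        if self.strand not in "+-":
            raise SynannError(f"Hsp: bad strand {self.strand!r}")
        if self.evalue < 0:
            raise SynannError("Hsp: negative E-value")

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start + 1


# Tags a gene model may carry; mirrored into GFF3 attributes and tag files.
TAG_MANUAL_CHECK = "manual-check"
TAG_TY = "ty"
TAG_FS_CORRECTED = "frameshift-corrected"
TAG_FS_UNCORRECTED = "frameshift-uncorrected"
TAG_SEARCHDOGS = "searchdogs"
TAG_LARGE_ORF = "large-orf"
TAG_RUNS_INTO_N = "runs-into-N"
ALL_TAGS = frozenset({
    TAG_MANUAL_CHECK, TAG_TY, TAG_FS_CORRECTED, TAG_FS_UNCORRECTED,
    TAG_SEARCHDOGS, TAG_LARGE_ORF, TAG_RUNS_INTO_N,
})


@dataclass
class GeneModel:
    """A predicted protein-coding gene.

    ``exons`` are forward-strand intervals ordered 5'->3' on the coding
    strand (so descending start for minus-strand genes).  At most two exons:
    the annotator searches for a single intron per gene.
    """

    model_id: str
    scaffold_id: str
    strand: str
    exons: list[tuple[int, int]]
    pillar_id: str | None = None
    tags: set[str] = field(default_factory=set)
    source_reference_gene: str | None = None
    frameshift_sites: list[int] = field(default_factory=list)
    evidence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise SynannError(f"model {self.model_id!r}: bad strand")
        if not self.exons:
            raise SynannError(f"model {self.model_id!r}: no exons")
        if len(self.exons) > 2:
            raise SynannError(
                f"model {self.model_id!r}: more than two exons"
            )
        for s, e in self.exons:
            if s >= e:
                raise SynannError(f"model {self.model_id!r}: empty exon")
        unknown = self.tags - ALL_TAGS
        if unknown:
            raise SynannError(
                f"model {self.model_id!r}: unknown tags {sorted(unknown)}"
            )

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)

    @property
    def has_intron(self) -> bool:
        return len(self.exons) == 2

    def coding_sequence(self, genome: Genome) -> str:
        """Spliced CDS on the coding strand."""
        parts = [genome.fetch(self.scaffold_id, s, e) for s, e in self.exons]
        if self.strand == "-":
            parts = [revcomp(p) for p in parts]
        return "".join(parts)


@dataclass(frozen=True)
class TrnaFeature:
    """A tRNA gene from an externally computed feature track."""

    feature_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str


@dataclass
class Correction:
    """One proposed assembly edit (forward-strand coordinates)."""

    scaffold_id: str
    position: int
    op: str  # "insert" | "delete"
    bases: str
    read_support: int = 0
    applied: bool = False

    def __post_init__(self) -> None:
        if self.op not in ("insert", "delete"):
            raise SynannError(f"correction: bad op {self.op!r}")
        if not self.bases:
            raise SynannError("correction: empty bases")

    @property
    def length_delta(self) -> int:
        return len(self.bases) if self.op == "insert" else -len(self.bases)

    @property
    def end(self) -> int:
        """Forward-strand end of the affected region."""
        return self.position + (len(self.bases) if self.op == "delete" else 0)


class StrandView:
    """Coding-strand view of one scaffold.

    View coordinates are 0-based half-open along the coding strand; for the
    minus strand the view is the reverse complement of the scaffold.
    """

    def __init__(self, genome: Genome, scaffold_id: str, strand: str):
        if strand not in "+-":
            raise SynannError(f"bad strand {strand!r}")
        self.scaffold_id = scaffold_id
        self.strand = strand
        fwd = genome.sequences[scaffold_id]
        self.length = len(fwd)
        self.seq = fwd if strand == "+" else revcomp(fwd)

    def to_forward(self, start: int, end: int) -> tuple[int, int]:
        if self.strand == "+":
            return start, end
        return self.length - end, self.length - start

    def from_forward(self, start: int, end: int) -> tuple[int, int]:
        # involution: the same arithmetic maps either way
        return self.to_forward(start, end)

    def to_forward_point(self, pos: int) -> int:
        """Map a view insertion point to the equivalent forward insertion
        point (the position in front of which bases would be inserted)."""
        if self.strand == "+":
            return pos
        return self.length - pos
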