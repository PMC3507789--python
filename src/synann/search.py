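"""Translated homology search and hit-retention rules.

HSPs of every pillar protein against the genome come either from an external
translated-search run supplied as a tabular file, or from the built-in
desk-scale engine here: a six-frame translation of the genome, k-mer seeded
ungapped extensions scored with BLOSUM62, and E-values from the standard
Karlin-Altschul formula.  The engine is deterministic and needs no external
binary; it is not intended to reproduce any particular search tool's
E-values bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .core import Genome, Hsp, Pillar, SynannError, revcomp

# Ungapped Karlin-Altschul parameters for BLOSUM62
_LAMBDA = 0.3176
_K = 0.134
_LN2 = math.log(2.0)

#: Initial E-value cutoff for storing hits.
DEFAULT_EVALUE_CUTOFF = 1e-5

#: Default single-linkage gap when grouping HSPs into candidate loci;
#: exceeds intron and small-indel spans but separates tandem paralogs.
DEFAULT_LOCUS_GAP = 5000

_MIN_EXPONENT = -324  # E = 0.0 underflows every exponent comparison


def _blosum62_dict() -> dict[tuple[str, str], int]:
    mat = substitution_matrices.load("BLOSUM62")
    alphabet = mat.alphabet
    scores: dict[tuple[str, str], int] = {}
    for a in alphabet:
        for b in alphabet:
            scores[(a, b)] = int(mat[a, b])
    # '*' (stop in a translated frame) against anything: strongly negative
    for a in set(alphabet) | {"*"}:
        scores[(a, "*")] = scores[("*", a)] = -4
    scores[("*", "*")] = 1
    return scores


_B62 = _blosum62_dict()


def exponent10(evalue: float) -> int:
    """Power-of-ten exponent of an E-value: floor(log10 e), with 0.0 mapped
    to -324 so an underflowed E always passes any exponent comparison."""
    if evalue < 0:
        raise SynannError("negative E-value")
    if evalue == 0.0:
        return _MIN_EXPONENT
    k = math.floor(math.log10(evalue))
    # guard against log10 rounding at exact powers of ten
    while 10.0 ** k > evalue:
        k -= 1
    while k + 1 <= 0 and 10.0 ** (k + 1) <= evalue:
        k += 1
    return k


@dataclass
class Locus:
    """A candidate genomic locus: one single-linkage cluster of HSPs."""

    scaffold_id: str
    strand: str
    start: int
    end: int
    hsps: list[Hsp] = field(default_factory=list)

    @property
    def evalue(self) -> float:
        return min(h.evalue for h in self.hsps)

    @property
    def bitscore(self) -> float:
        return max(h.bitscore for h in self.hsps)

    def overlaps(self, other: "Locus") -> bool:
        return (self.scaffold_id == other.scaffold_id
                and self.start < other.end and other.start < self.end)


def cluster_hsps_to_loci(hsps: list[Hsp],
                         max_gap_nt: int = DEFAULT_LOCUS_GAP) -> list[Locus]:
    """Single-linkage clustering of one query's HSPs into candidate loci.

    HSPs on the same scaffold and strand whose genomic gap is at most
    ``max_gap_nt`` join one locus.
    """
    groups: dict[tuple[str, str], list[Hsp]] = {}
    for h in hsps:
        groups.setdefault((h.scaffold_id, h.strand), []).append(h)
    loci: list[Locus] = []
    for (scaffold, strand), group in groups.items():
        group.sort(key=lambda h: h.subj_start)
        current = Locus(scaffold, strand, group[0].subj_start,
                        group[0].subj_end, [group[0]])
        for h in group[1:]:
            if h.subj_start - current.end <= max_gap_nt:
                current.end = max(current.end, h.subj_end)
                current.hsps.append(h)
            else:
                loci.append(current)
                current = Locus(scaffold, strand, h.subj_start, h.subj_end, [h])
        loci.append(current)
    loci.sort(key=lambda l: l.evalue)
    return loci


@dataclass
class BestQuery:
    """The pillar member whose best hit has the lowest E-value."""

    gene_id: str
    evalue: float
    loci: list[Locus]

    @property
    def best_locus(self) -> Locus:
        return self.loci[0]


def best_query_for_pillar(pillar: Pillar,
                          hsps_by_query: dict[str, list[Hsp]],
                          max_gap_nt: int = DEFAULT_LOCUS_GAP) -> BestQuery | None:
    """Pick the member protein Q with the lowest E-value against the genome.

    Ties on E-value are broken by higher bitscore, then lexical gene id.
    Returns None when no member has a stored hit.
    """
    best: tuple | None = None
    for member in pillar.members:
        hsps = hsps_by_query.get(member.gene_id)
        if not hsps:
            continue
        e = min(h.evalue for h in hsps)
        bits = max(h.bitscore for h in hsps)
        key = (e, -bits, member.gene_id)
        if best is None or key < best[0]:
            best = (key, member.gene_id, hsps)
    if best is None:
        return None
    _, gene_id, hsps = best
    loci = cluster_hsps_to_loci(hsps, max_gap_nt)
    return BestQuery(gene_id=gene_id, evalue=loci[0].evalue, loci=loci)


def retain_secondary_loci(loci: list[Locus],
                          e_best: float | None = None) -> list[Locus]:
    """Keep the strongest locus plus secondaries passing the retention rule.

    A weaker locus with E-value e is retained iff exponent10(e) < -30 and
    exponent10(e) < exponent10(E_best) / 2 — e.g. with E_best = 1e-100 only
    secondaries with E < 1e-50 survive.
    """
    if not loci:
        return []
    ordered = sorted(loci, key=lambda l: (l.evalue, -l.bitscore))
    if e_best is None:
        e_best = ordered[0].evalue
    half_best = exponent10(e_best) / 2.0
    kept = [ordered[0]]
    for locus in ordered[1:]:
        exp = exponent10(locus.evalue)
        if exp < -30 and exp < half_best:
            kept.append(locus)
    return kept


# ---------------------------------------------------------------------------
# Tabular hits file
#
# Columns (tab-separated, 13 mandatory):
#   query_id subject_id pident length mismatch gapopen qstart qend sstart
#   send evalue bitscore frame
# qstart/qend are 1-based inclusive amino-acid coordinates; sstart/send are
# 1-based inclusive genomic coordinates with sstart > send on the minus
# strand; frame is the coding-strand codon offset 0/1/2.

def parse_search_tabular(path: str,
                         evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
                         ) -> list[Hsp]:
    hsps: list[Hsp] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 13:
                raise SynannError(
                    f"{path}:{lineno}: expected >=13 tab-separated columns, "
                    f"got {len(cols)}"
                )
            try:
                qid, sid = cols[0], cols[1]
                qstart, qend = int(cols[6]), int(cols[7])
                sstart, send = int(cols[8]), int(cols[9])
                evalue, bitscore = float(cols[10]), float(cols[11])
                frame = int(cols[12])
            except ValueError as exc:
                raise SynannError(f"{path}:{lineno}: malformed row: {exc}")
            if sstart <= send:
                strand, lo, hi = "+", sstart - 1, send
            else:
                strand, lo, hi = "-", send - 1, sstart
            if evalue >= evalue_cutoff:
                continue
            hsps.append(Hsp(
                query_id=qid, scaffold_id=sid, query_start=qstart,
                query_end=qend, subj_start=lo, subj_end=hi, strand=strand,
                frame=frame % 3, evalue=evalue, bitscore=bitscore))
    return hsps


def write_search_tabular(hsps: list[Hsp], path: str) -> None:
    """Serialize HSPs in the tabular dialect accepted by parse_search_tabular."""
    with open(path, "w") as fh:
        for h in hsps:
            if h.strand == "+":
                sstart, send = h.subj_start + 1, h.subj_end
            else:
                sstart, send = h.subj_end, h.subj_start + 1
            alen = h.query_span
            fh.write("\t".join(map(str, [
                h.query_id, h.scaffold_id, "100.0", alen, 0, 0,
                h.query_start, h.query_end, sstart, send,
                f"{h.evalue:.6g}", f"{h.bitscore:.6g}", h.frame])) + "\n")


# ---------------------------------------------------------------------------
# Built-in translated search engine

@dataclass
class _Frame:
    scaffold_id: str
    strand: str
    offset: int
    aa: str
    scaffold_len: int


class SixFrameIndex:
    """Six-frame translation of a genome with a k-mer seed index."""

    def __init__(self, genome: Genome, k: int = 5):
        self.k = k
        self.frames: list[_Frame] = []
        index: dict[str, list[tuple[int, int]]] = {}
        for scaffold_id, fwd in genome.sequences.items():
            L = len(fwd)
            for strand in "+-":
                seq = fwd if strand == "+" else revcomp(fwd)
                for offset in range(3):
                    n = (L - offset) // 3
                    if n <= 0:
                        continue
                    aa = str(Seq(seq[offset:offset + 3 * n]).translate())
                    fi = len(self.frames)
                    self.frames.append(
                        _Frame(scaffold_id, strand, offset, aa, L))
                    for p in range(len(aa) - k + 1):
                        kmer = aa[p:p + k]
                        if "*" in kmer or "X" in kmer:
                            continue
                        index.setdefault(kmer, []).append((fi, p))
        self.index = index
        self.search_space = sum(len(f.aa) for f in self.frames)

    # -- alignment ---------------------------------------------------------

    def _extend(self, query: str, aa: str, qp: int, sp: int,
                xdrop: int) -> tuple[int, int, int, int]:
        """Ungapped X-drop extension of a k-mer seed at (qp, sp).

        Returns (q_lo, q_hi, s_lo, score) with q coordinates half-open on the
        query and s_lo the subject aa start.
        """
        k = self.k
        score = 0
        for i in range(k):
            score += _B62[(query[qp + i], aa[sp + i])]
        # right extension
        best = score
        run = score
        qi, si = qp + k, sp + k
        q_hi = qp + k
        nq, ns = len(query), len(aa)
        while qi < nq and si < ns:
            run += _B62[(query[qi], aa[si])]
            if run > best:
                best = run
                q_hi = qi + 1
            elif best - run > xdrop:
                break
            qi += 1
            si += 1
        # left extension
        run = best
        score = best
        qi, si = qp - 1, sp - 1
        q_lo = qp
        while qi >= 0 and si >= 0:
            run += _B62[(query[qi], aa[si])]
            if run > score:
                score = run
                q_lo = qi
            elif score - run > xdrop:
                break
            qi -= 1
            si -= 1
        s_lo = sp - (qp - q_lo)
        return q_lo, q_hi, s_lo, score

    def _score_to_hit(self, frame: _Frame, query_id: str, q_lo: int,
                      q_hi: int, s_lo: int, score: int,
                      query_len: int) -> Hsp:
        bits = (_LAMBDA * score - math.log(_K)) / _LN2
        evalue = query_len * self.search_space * 2.0 ** (-bits)
        length = q_hi - q_lo
        v_start = frame.offset + 3 * s_lo
        v_end = frame.offset + 3 * (s_lo + length)
        if frame.strand == "+":
            subj_start, subj_end = v_start, v_end
        else:
            subj_start = frame.scaffold_len - v_end
            subj_end = frame.scaffold_len - v_start
        return Hsp(
            query_id=query_id, scaffold_id=frame.scaffold_id,
            query_start=q_lo + 1, query_end=q_hi,
            subj_start=subj_start, subj_end=subj_end,
            strand=frame.strand, frame=frame.offset,
            evalue=evalue, bitscore=bits)

    def search(self, protein: str, query_id: str = "query",
               evalue_cutoff: float | None = DEFAULT_EVALUE_CUTOFF,
               xdrop: int = 20, min_score: int = 35) -> list[Hsp]:
        """Seeded ungapped search of one protein against all six frames."""
        if len(protein) < 10:
            raise SynannError("builtin search requires protein length >= 10")
        k = self.k
        seeds: dict[tuple[int, int], list[tuple[int, int]]] = {}
        get = self.index.get
        for qp in range(len(protein) - k + 1):
            hits = get(protein[qp:qp + k])
            if not hits:
                continue
            for fi, sp in hits:
                seeds.setdefault((fi, sp - qp), []).append((qp, sp))
        results: list[Hsp] = []
        for (fi, _diag), seedlist in seeds.items():
            frame = self.frames[fi]
            covered: list[tuple[int, int]] = []
            for qp, sp in sorted(seedlist):
                if any(lo <= qp < hi for lo, hi in covered):
                    continue
                q_lo, q_hi, s_lo, score = self._extend(
                    protein, frame.aa, qp, sp, xdrop)
                covered.append((q_lo, q_hi))
                if score < min_score:
                    continue
                hsp = self._score_to_hit(frame, query_id, q_lo, q_hi, s_lo,
                                         score, len(protein))
                if evalue_cutoff is None or hsp.evalue < evalue_cutoff:
                    results.append(hsp)
        results.sort(key=lambda h: (h.evalue, -h.bitscore,
                                    h.scaffold_id, h.subj_start))
        return self._dedup(results)

    @staticmethod
    def _dedup(hsps: list[Hsp]) -> list[Hsp]:
        """Drop HSPs contained within a stronger HSP on the same frame."""
        kept: list[Hsp] = []
        for h in hsps:
            contained = False
            for other in kept:
                if (other.scaffold_id == h.scaffold_id
                        and other.strand == h.strand
                        and other.frame == h.frame
                        and other.subj_start <= h.subj_start
                        and h.subj_end <= other.subj_end):
                    contained = True
                    break
            if not contained:
                kept.append(h)
        return kept


def builtin_translated_search(protein: str, genome: Genome,
                              min_evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
                              query_id: str = "query") -> list[Hsp]:
    """One-shot convenience wrapper: index the genome, search one protein."""
    return SixFrameIndex(genome).search(protein, query_id=query_id,
                                        evalue_cutoff=min_evalue_cutoff)


def search_all(pillars: list[Pillar], index: SixFrameIndex,
               evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
               ) -> dict[str, list[Hsp]]:
    """Search every member protein of every pillar; HSPs keyed by gene id."""
    hsps_by_query: dict[str, list[Hsp]] = {}
    for pillar in pillars:
        for member in pillar.members:
            hits = index.search(member.protein, query_id=member.gene_id,
                                evalue_cutoff=evalue_cutoff)
            if hits:
                hsps_by_query[member.gene_id] = hits
    return hsps_by_query
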