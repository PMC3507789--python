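"""Single-intron prediction from splice-site motifs.

Yeast introns are rare (~4% of genes) and almost always single, so the
annotator searches for at most one intron per gene, and only when the
pillar's species group already contains an intron-bearing member.  Introns
are located by exhaustive enumeration of canonical motif combinations:
a 5' donor from an eight-motif list, a branchpoint from a three-motif list
and a CAG/TAG 3' acceptor, constrained so that the spliced product is
in frame and stop-free.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import STOP_CODONS, START_CODON, SynannError
from .modeling import ViewHsp

DONOR_MOTIFS = ("GTATGT", "GTCAGT", "GTTCGT", "GTACGT", "GTAAGT", "GCATGT",
                "GTATGA", "GTATGC")
BRANCH_MOTIFS = ("ACTAAC", "GCTAAC", "ATTAAC")
ACCEPTOR_MOTIFS = ("CAG", "TAG")

#: Intron length search bounds (nt); cover known yeast intron biology while
#: bounding the combinatorial search.
INTRON_MIN_LEN = 40
INTRON_MAX_LEN = 1000
#: How far upstream of a single exon-2 HSP to look for a missing exon 1.
EXON1_SCAN_WINDOW = 600
#: Accepted deviation of the reconstructed protein length from the
#: reference protein length when recovering a missing exon 1.
LENGTH_TOLERANCE = 0.20


@dataclass(frozen=True)
class IntronCall:
    """A predicted intron in coding-strand view coordinates.

    ``donor`` is the first intron base, ``acceptor_end`` one past the last
    (the G of the CAG/TAG acceptor); ``branch`` is the branchpoint motif
    start.  donor < branch < acceptor_end always holds.
    """

    donor: int
    branch: int
    acceptor_end: int
    donor_motif: str
    branch_motif: str
    acceptor_motif: str

    def __post_init__(self) -> None:
        if not (self.donor < self.branch < self.acceptor_end):
            raise SynannError("intron call: splice order violated")
        if self.donor_motif not in DONOR_MOTIFS:
            raise SynannError(f"unknown donor motif {self.donor_motif!r}")
        if self.branch_motif not in BRANCH_MOTIFS:
            raise SynannError(f"unknown branch motif {self.branch_motif!r}")
        if self.acceptor_motif not in ACCEPTOR_MOTIFS:
            raise SynannError(f"unknown acceptor motif {self.acceptor_motif!r}")

    @property
    def length(self) -> int:
        return self.acceptor_end - self.donor


def _find_motifs(seq: str, motifs, lo: int, hi: int) -> list[tuple[int, str]]:
    """All motif occurrences with start position in [lo, hi)."""
    out = []
    lo = max(0, lo)
    for motif in motifs:
        p = seq.find(motif, lo)
        while 0 <= p < hi:
            out.append((p, motif))
            p = seq.find(motif, p + 1)
    return sorted(out)


def _splice_ok(view_seq: str, exon1_start: int, donor: int,
               acceptor_end: int, exon2_ref: int, exon2_end: int) -> bool:
    """Is the spliced product in frame and stop-free through the junction?

    ``exon2_ref`` is any view position known to sit on a codon boundary of
    exon 2's reading frame (e.g. the HSP's subject start).
    """
    exon1_len = donor - exon1_start
    # codon phase must carry across the junction
    if (exon1_len + (exon2_ref - acceptor_end)) % 3 != 0:
        return False
    spliced = view_seq[exon1_start:donor] + view_seq[acceptor_end:exon2_end]
    for p in range(0, len(spliced) - 2, 3):
        if spliced[p:p + 3] in STOP_CODONS:
            return False
    return True


def intron_between_hsps(h1: ViewHsp, h2: ViewHsp, view_seq: str,
                        ref_protein_len: int | None = None,
                        slack: int = 45) -> IntronCall | None:
    """Locate an intron between two HSPs classified as exon matches.

    Donors are searched from just before h1's 3' end to h2's start (HSP
    extension can overrun a splice site by a few codons, hence the slack);
    acceptors up to slack past h2's start; branchpoints are required
    between donor and acceptor.  Among combinations whose spliced product
    is in frame and stop-free, ranking prefers (when a reference length is
    given) the combination whose implied protein length is closest to the
    reference protein's — this separates competing acceptors a codon apart
    — then the donor closest to h1's end, then the shortest intron.
    Returns None when no valid combination exists.
    """
    lo = max(0, h1.s_end - slack)
    hi = min(len(view_seq), h2.s_start + slack)
    donors = _find_motifs(view_seq, DONOR_MOTIFS, lo, hi)
    if not donors:
        return None
    acceptors = [
        (p, m) for p, m in _find_motifs(view_seq, ACCEPTOR_MOTIFS, lo, hi + 3)
    ]
    best: tuple | None = None
    for dpos, dmot in donors:
        for apos, amot in acceptors:
            acc_end = apos + 3
            length = acc_end - dpos
            if not (INTRON_MIN_LEN <= length <= INTRON_MAX_LEN):
                continue
            branches = _find_motifs(view_seq, BRANCH_MOTIFS, dpos + 1,
                                    apos)
            if not branches:
                continue
            if not _splice_ok(view_seq, h1.s_start, dpos, acc_end,
                              h2.s_start, h2.s_end):
                continue
            if ref_protein_len is not None:
                pred_aa = (((dpos - h1.s_start) + (h2.s_end - acc_end)) // 3
                           + (h1.query_start - 1)
                           + (ref_protein_len - h2.query_end))
                length_penalty = abs(pred_aa - ref_protein_len)
            else:
                length_penalty = 0
            key = (length_penalty, abs(dpos - h1.s_end), length, dpos)
            if best is None or key < best[0]:
                bpos, bmot = branches[-1]  # branchpoint nearest the acceptor
                best = (key, IntronCall(dpos, bpos, acc_end, dmot, bmot, amot))
    return None if best is None else best[1]


def recover_missing_exon1(h2: ViewHsp, view_seq: str, ref_protein_len: int,
                          scan_window: int = EXON1_SCAN_WINDOW,
                          tolerance: float = LENGTH_TOLERANCE
                          ) -> tuple[tuple[int, int], IntronCall] | None:
    """Reconstruct a small first exon upstream of a lone exon-2 HSP.

    Yeast first exons are often too short to seed a translated-search hit,
    so an intron-bearing reference with a single HSP triggers this scan:
    upstream of the HSP we look for acceptor <- branchpoint <- donor, then an
    ATG-initiated exon 1 upstream of the donor, such that the reconstructed
    protein length is within ``tolerance`` of the reference protein length.
    Returns ((exon1_start, donor), IntronCall) or None.

    Only invoked when the chosen reference gene carries an intron.
    """
    hs = h2.s_start
    lo = max(0, hs - scan_window - INTRON_MAX_LEN)
    # HSP extension can overrun the acceptor into the intron, so the
    # acceptor window straddles the HSP start
    acceptors = _find_motifs(view_seq, ACCEPTOR_MOTIFS, max(0, hs - 60),
                             min(len(view_seq), hs + 45))
    exon2_aa = (h2.s_end - hs) // 3 + (ref_protein_len - h2.query_end)
    best: tuple | None = None
    for apos, amot in sorted(acceptors, reverse=True):
        acc_end = apos + 3
        donors = _find_motifs(view_seq, DONOR_MOTIFS,
                              max(lo, acc_end - INTRON_MAX_LEN),
                              max(0, acc_end - INTRON_MIN_LEN))
        for dpos, dmot in donors:
            branches = _find_motifs(view_seq, BRANCH_MOTIFS, dpos + 1, apos)
            if not branches:
                continue
            # exon 1 must start with ATG upstream of the donor, with the
            # junction phase keeping exon 2 in frame
            max_e1 = int(3 * ref_protein_len * (1 + tolerance))
            e1_lo = max(0, dpos - max_e1)
            for pos in range(dpos - 3, e1_lo - 1, -1):
                if view_seq[pos:pos + 3] != START_CODON:
                    continue
                if ((dpos - pos) + (hs - acc_end)) % 3 != 0:
                    continue
                if not _splice_ok(view_seq, pos, dpos, acc_end, hs,
                                  h2.s_end):
                    continue
                pred_len = (((dpos - pos) + (hs - acc_end)) // 3
                            + exon2_aa)
                target = ref_protein_len
                if abs(pred_len - target) <= tolerance * target:
                    key = (abs(pred_len - target), hs - acc_end,
                           abs(dpos - pos))
                    if best is None or key < best[0]:
                        bpos, bmot = branches[-1]
                        best = (key, (pos, dpos),
                                IntronCall(dpos, bpos, acc_end, dmot,
                                           bmot, amot))
    if best is None:
        return None
    return best[1], best[2]


def cap_one_intron(intron_calls: list[IntronCall]
                   ) -> tuple[IntronCall | None, bool]:
    """Enforce the single-intron limit.

    Returns (retained call, flagged) — with two or more candidate introns
    only the first is kept and the model must be tagged for manual checking,
    since genuine two-intron genes cannot be represented.
    """
    if not intron_calls:
        return None, False
    if len(intron_calls) == 1:
        return intron_calls[0], False
    return intron_calls[0], True
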