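"""Frameshift sequencing-error repair.

Pyrosequencing assemblies carry occasional 1-2 bp indels, usually at
homopolymer runs, that split a gene's translated-search hit into two HSPs in
different frames.  Repair takes one of two routes: with primary reads
available, reads overlapping the frameshift window vote on the indel and the
most common indel that restores an intact ORF is applied to the assembly;
without reads, one or two N bases are inserted at the estimated site so the
downstream frame is restored (the N codon translates as X).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib

from .core import (
    Correction,
    STOP_CODONS,
    StrandView,
    SynannError,
    revcomp,
)
from .modeling import ViewHsp

#: Flank (bp) around the inter-HSP region used as the voting window.
WINDOW_FLANK = 50
#: Read-vs-window alignments must be stronger than this E-value to vote.
READ_EVALUE_CUTOFF = 1e-30
#: An indel must be seen in at least this many reads to be considered.
MIN_READ_SUPPORT = 2

# ungapped nucleotide Karlin-Altschul constants (match/mismatch +2/-3)
_NT_LAMBDA = 1.33
_NT_K = 0.621


def extract_fs_window(h1: ViewHsp, h2: ViewHsp, view: StrandView
                      ) -> tuple[int, int]:
    """Voting window: 50 bp upstream of the first HSP's end to 50 bp
    downstream of the second HSP's start, clamped to the scaffold, in view
    coordinates."""
    lo = max(0, h1.s_end - WINDOW_FLANK)
    hi = min(view.length, h2.s_start + WINDOW_FLANK)
    if lo >= hi:
        raise SynannError("empty frameshift window")
    return lo, hi


@dataclass(frozen=True)
class IndelVote:
    """One candidate assembly edit keyed by exact (offset, op, bases)."""

    offset: int   # position within the window
    op: str       # correction to the assembly: "insert" | "delete"
    bases: str
    support: int


def _alignment_votes(window: str, read: str) -> list[tuple[int, str, str]] | None:
    """Indels implied by aligning the window inside one read.

    Returns None when the alignment fails the E-value gate.  The cigar is
    read with the window as query: a base present only in the read means the
    assembly needs an insertion, a base present only in the window means the
    assembly needs a deletion.
    """
    res = edlib.align(window, read, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["cigar"]:
        return None
    dist = res["editDistance"]
    matches = len(window) - dist
    score = 2 * matches - 3 * dist
    bits = (_NT_LAMBDA * score - math.log(_NT_K)) / math.log(2)
    evalue = len(window) * len(read) * 2.0 ** (-bits)
    if evalue >= READ_EVALUE_CUTOFF:
        return None
    read_start = res["locations"][0][0]
    votes: list[tuple[int, str, str]] = []
    qpos = 0         # window offset
    tpos = read_start
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=XM":
            qpos += n
            tpos += n
        elif ch == "D":   # read-only bases: assembly is missing them
            votes.append((qpos, "insert", read[tpos:tpos + n]))
            tpos += n
        elif ch == "I":   # window-only bases: assembly has extra bases
            votes.append((qpos, "delete", window[qpos:qpos + n]))
            qpos += n
    return votes


def vote_indels(window_seq: str, reads: dict[str, str],
                min_support: int = MIN_READ_SUPPORT) -> list[IndelVote]:
    """Count, across qualifying reads, every exact indel seen when aligning
    the window against the reads; candidates supported by fewer than
    ``min_support`` reads are dropped.  Sorted by support (descending), then
    window offset."""
    counts: dict[tuple[int, str, str], int] = {}
    for read in reads.values():
        for oriented in (read, revcomp(read)):
            votes = _alignment_votes(window_seq, oriented)
            if votes is None:
                continue
            for key in votes:
                counts[key] = counts.get(key, 0) + 1
            break  # a read votes once; its better orientation aligned
    out = [IndelVote(offset=k[0], op=k[1], bases=k[2], support=n)
           for k, n in counts.items() if n >= min_support]
    out.sort(key=lambda v: (-v.support, v.offset, v.op, v.bases))
    return out


@dataclass
class FrameshiftContext:
    """Everything needed to test whether an edit yields an intact ORF."""

    view: StrandView
    h1: ViewHsp
    h2: ViewHsp
    window_start: int  # view coordinate of the voting window's first base


def _orf_intact(ctx: FrameshiftContext, edited_span: str,
                delta: int) -> bool:
    """Does the edit restore the frame and leave the inter-HSP span
    translating stop-free in h1's frame through h2's end?

    ``edited_span`` replaces view[h1.s_start : h2.s_end]; h1.s_start sits on
    a codon boundary, so translation starts at offset 0.
    """
    d = (ctx.h2.frame - ctx.h1.frame) % 3
    if (d + delta) % 3 != 0:
        return False
    p = 0
    while p + 3 <= len(edited_span):
        if edited_span[p:p + 3] in STOP_CODONS:
            return False
        p += 3
    return True


def apply_first_fixing_indel(candidates: list[IndelVote],
                             ctx: FrameshiftContext) -> Correction | None:
    """Walk the vote list and apply the first indel that restores an intact
    ORF spanning both HSPs; None when every candidate fails (the gene is
    then tagged frameshift-uncorrected by the caller)."""
    span_lo = ctx.h1.s_start
    span_hi = ctx.h2.s_end
    original = ctx.view.seq[span_lo:span_hi]
    for cand in candidates:
        vpos = ctx.window_start + cand.offset
        if not (span_lo <= vpos <= span_hi):
            continue
        rel = vpos - span_lo
        if cand.op == "insert":
            edited = original[:rel] + cand.bases + original[rel:]
        else:
            if original[rel:rel + len(cand.bases)] != cand.bases:
                continue
            edited = original[:rel] + original[rel + len(cand.bases):]
        delta = len(cand.bases) if cand.op == "insert" else -len(cand.bases)
        if not _orf_intact(ctx, edited, delta):
            continue
        # convert the edit to forward-strand coordinates
        if ctx.view.strand == "+":
            pos, bases = vpos, cand.bases
        else:
            bases = revcomp(cand.bases)
            if cand.op == "insert":
                pos = ctx.view.to_forward_point(vpos)
            else:
                pos, _ = ctx.view.to_forward(vpos, vpos + len(cand.bases))
        return Correction(scaffold_id=ctx.view.scaffold_id, position=pos,
                          op=cand.op, bases=bases,
                          read_support=cand.support, applied=True)
    return None


def insert_placeholder_Ns(h1: ViewHsp, h2: ViewHsp,
                          view: StrandView) -> Correction:
    """Reads-free fallback: insert (3 - d) mod 3 in {1, 2} N bases at the
    estimated frameshift site (the in-frame midpoint of the inter-HSP gap)
    so the downstream frame is restored."""
    d = (h2.frame - h1.frame) % 3
    if d == 0:
        raise SynannError("HSP pair is not frameshifted")
    k = (3 - d) % 3
    mid = (h1.s_end + max(h1.s_end, h2.s_start)) // 2
    mid = mid - ((mid - h1.s_start) % 3)  # align to h1's codon boundary
    mid = max(h1.s_start, min(mid, view.length))
    pos = view.to_forward_point(mid)
    return Correction(scaffold_id=view.scaffold_id, position=pos,
                      op="insert", bases="N" * k, read_support=0,
                      applied=True)
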