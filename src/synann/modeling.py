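"""Gene-model construction from retained HSP chains.

For each locus kept by the synteny stage, a reference gene is chosen from
the pillar (preferring the target's species group and intron-bearing
members), the reference's consecutive HSPs are classified pairwise into
frameshift / low-similarity / intron / duplication, seed coordinates are
derived from the classified chain, and the seeds are extended outward to a
start and a stop codon.

All geometry here lives in coding-strand view coordinates (see
:class:`synann.core.StrandView`); callers convert back to forward-strand
coordinates when building :class:`synann.core.GeneModel` exons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    NON_WGD,
    POST_WGD,
    START_CODON,
    STOP_CODONS,
    Hsp,
    Pillar,
    RefGene,
    StrandView,
    SynannError,
    TAG_MANUAL_CHECK,
    TAG_RUNS_INTO_N,
)

KIND_FRAMESHIFT = "frameshift"
KIND_LOW_SIMILARITY = "low-similarity"
KIND_INTRON = "intron"
KIND_DUPLICATION = "duplication"

#: "similar distance" tolerance between query and subject gaps, in nt.
#: Tolerates small indels while excluding real introns (yeast introns are
#: rarely shorter than ~50 nt).
DEFAULT_GAP_TOL = 30
#: Query-side overlap (aa) beyond which a pair is treated as a duplication.
#: X-drop extension drifts past a frameshift or splice site in the wrong
#: frame, so consecutive HSPs of one gene routinely overlap by 20-30 aa on
#: the query; smaller overlaps are trimmed away before gap geometry is
#: measured, and only larger ones indicate a genuine duplicated segment.
DEFAULT_OVERLAP_TOL = 40
#: Smallest subject gap considered a plausible intron.
DEFAULT_INTRON_MIN = 40
#: Largest query gap (nt equivalents) still compatible with an intron call
#: (both exons should account for nearly all of the query).
DEFAULT_QUERY_GAP_MAX = 30
#: Fig-style start trim budget inside the seed when upstream extension fails.
START_TRIM_NT = 45


# ---------------------------------------------------------------------------
# Reference-gene choice

def select_reference_gene(pillar: Pillar, species_group: str,
                          hit_ranking: dict[str, tuple[float, float]]
                          ) -> RefGene:
    """Choose the reference gene R used as the basis for the model.

    ``hit_ranking`` maps member gene ids to (evalue, bitscore) of their best
    hit at the locus.  Preference for a target in group g: same-group
    intron-bearing member, then same-group member, then any intron-bearing
    member, then any member — each tier ranked by lowest E, then highest
    bitscore, then gene id.
    """
    if species_group not in (POST_WGD, NON_WGD):
        raise SynannError(f"unknown species group {species_group!r}")
    with_hits = [m for m in pillar.members if m.gene_id in hit_ranking]
    if not with_hits:
        raise SynannError(
            f"pillar {pillar.pillar_id!r}: no member has a hit at this locus")

    def rank(m: RefGene):
        e, bits = hit_ranking[m.gene_id]
        return (e, -bits, m.gene_id)

    tiers = [
        [m for m in with_hits
         if m.species_group == species_group and m.has_intron],
        [m for m in with_hits if m.species_group == species_group],
        [m for m in with_hits if m.has_intron],
        with_hits,
    ]
    for tier in tiers:
        if tier:
            return min(tier, key=rank)
    raise AssertionError("unreachable")


def mean_group_lengths(pillar: Pillar) -> tuple[float | None, float | None]:
    """Arithmetic mean protein length of the non-WGD and post-WGD members.

    Returns (mean non-WGD, mean post-WGD); an absent group yields None.
    """
    out = []
    for group in (NON_WGD, POST_WGD):
        members = pillar.members_in_group(group)
        if members:
            out.append(sum(len(m.protein) for m in members) / len(members))
        else:
            out.append(None)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# View-space HSPs and pair classification

@dataclass(frozen=True)
class ViewHsp:
    """An HSP mapped into coding-strand view coordinates.

    ``s_start``/``s_end`` are half-open nt positions along the view;
    ``frame`` is s_start % 3.  Query coordinates stay 1-based inclusive aa.
    """

    query_start: int
    query_end: int
    s_start: int
    s_end: int

    @property
    def frame(self) -> int:
        return self.s_start % 3


def to_view(hsp: Hsp, view: StrandView) -> ViewHsp:
    s, e = view.from_forward(hsp.subj_start, hsp.subj_end)
    return ViewHsp(hsp.query_start, hsp.query_end, s, e)


@dataclass
class HspPairCall:
    kind: str
    pair: tuple[ViewHsp, ViewHsp]
    # per-kind payload
    frameshift_site: int | None = None     # estimated view position
    frame_offset: int | None = None        # downstream frame shift (1 or 2)
    intron_window: tuple[int, int] | None = None


def _has_inframe_stop(view_seq: str, start: int, end: int, frame: int) -> bool:
    """Any stop codon at positions congruent to ``frame`` within [start, end)?"""
    first = start + ((frame - start) % 3)
    for p in range(first, end - 2, 3):
        if view_seq[p:p + 3] in STOP_CODONS:
            return True
    return False


def classify_hsp_pair(h1: ViewHsp, h2: ViewHsp, view_seq: str,
                      intron_allowed: bool,
                      gap_tol: int = DEFAULT_GAP_TOL,
                      overlap_tol: int = DEFAULT_OVERLAP_TOL,
                      intron_min: int = DEFAULT_INTRON_MIN,
                      query_gap_max: int = DEFAULT_QUERY_GAP_MAX
                      ) -> HspPairCall:
    """Classify two consecutive HSPs (h1 upstream of h2 on the coding strand).

    Decision tree:
      (i)  frameshift: different frames, query and subject gaps similar;
      (ii) low similarity: same frame, gaps similar, no in-frame stop between;
      (iii) intron: gaps dissimilar, query gap small, subject gap intron-sized,
            and the pillar's species group contains an intron-bearing gene;
      (iv) duplication otherwise.
    """
    if h2.s_start < h1.s_start:
        raise SynannError("classify_hsp_pair: HSPs out of order")
    q_gap_aa = h2.query_start - h1.query_end - 1
    if -q_gap_aa > overlap_tol:
        return HspPairCall(KIND_DUPLICATION, (h1, h2))
    if q_gap_aa < 0:
        # trim the extension overrun off h1's 3' end so gap geometry is
        # measured between the truly distinct aligned segments
        trim = -q_gap_aa
        h1 = ViewHsp(h1.query_start, h1.query_end - trim,
                     h1.s_start, h1.s_end - 3 * trim)
        if h1.s_end <= h1.s_start:
            return HspPairCall(KIND_DUPLICATION, (h1, h2))
        q_gap_aa = 0
    dq = q_gap_aa * 3
    ds = h2.s_start - h1.s_end
    similar = abs(dq - ds) <= gap_tol
    if similar and h1.frame != h2.frame:
        mid = (h1.s_end + max(h1.s_end, h2.s_start)) // 2
        offset = (h2.frame - h1.frame) % 3
        return HspPairCall(KIND_FRAMESHIFT, (h1, h2), frameshift_site=mid,
                           frame_offset=offset)
    if similar and h1.frame == h2.frame:
        if ds <= 0 or not _has_inframe_stop(view_seq, h1.s_end, h2.s_start,
                                            h1.frame):
            return HspPairCall(KIND_LOW_SIMILARITY, (h1, h2))
        return HspPairCall(KIND_DUPLICATION, (h1, h2))
    if (not similar and intron_allowed and dq <= query_gap_max
            and ds >= intron_min):
        window = (max(0, h1.s_end - START_TRIM_NT),
                  min(len(view_seq), h2.s_start + START_TRIM_NT))
        return HspPairCall(KIND_INTRON, (h1, h2), intron_window=window)
    return HspPairCall(KIND_DUPLICATION, (h1, h2))


# ---------------------------------------------------------------------------
# Seed derivation

@dataclass
class SeedGroup:
    """One gene-model seed: the outer edges of a merged HSP run, plus the
    pair calls (frameshift sites, intron windows) that fall inside it."""

    hsps: list[ViewHsp]
    calls: list[HspPairCall] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.hsps[0].s_start

    @property
    def end(self) -> int:
        return max(h.s_end for h in self.hsps)

    @property
    def frame(self) -> int:
        return self.hsps[0].frame

    def calls_of(self, kind: str) -> list[HspPairCall]:
        return [c for c in self.calls if c.kind == kind]


def seed_coordinates(hsps: list[ViewHsp], calls: list[HspPairCall]
                     ) -> list[SeedGroup]:
    """Derive model seeds from a classified HSP chain.

    Consecutive pairs are merged left to right; a duplication call closes
    the current model and opens a new one, so a chain with calls
    (low-sim, duplication) yields seeds {HSP1 u HSP2} and {HSP3}.
    """
    if not hsps:
        return []
    if len(hsps) - 1 != len(calls):
        raise SynannError("seed_coordinates: need one call per adjacent pair")
    groups = [SeedGroup(hsps=[hsps[0]])]
    for h, call in zip(hsps[1:], calls):
        if call.kind == KIND_DUPLICATION:
            groups.append(SeedGroup(hsps=[h]))
        else:
            groups[-1].hsps.append(h)
            groups[-1].calls.append(call)
    return groups


def classify_chain(hsps: list[ViewHsp], view_seq: str, intron_allowed: bool,
                   **kwargs) -> list[HspPairCall]:
    """Classify every consecutive pair of a location-sorted HSP chain."""
    ordered = sorted(hsps, key=lambda h: (h.s_start, h.s_end))
    return [classify_hsp_pair(a, b, view_seq, intron_allowed, **kwargs)
            for a, b in zip(ordered, ordered[1:])]


# ---------------------------------------------------------------------------
# Start / stop extension

@dataclass
class Extension:
    start: int
    end: int           # half-open; includes the stop codon when one was found
    tags: set[str] = field(default_factory=set)


def extend_start(seed_start: int, seed_end: int, view_seq: str,
                 max_upstream: int | None = None) -> tuple[int, set[str]]:
    """Find the model start for an in-frame seed.

    If the seed begins with ATG it is kept.  Otherwise the model is extended
    in frame to the furthest upstream ATG that is not separated from the
    seed by an in-frame stop (optionally capped at ``max_upstream`` nt of
    extension).  If a stop, an N run, the sequence edge or the cap
    intervenes before any ATG, the first 45 nt inside the seed are scanned
    for an ATG; failing that the seed start is kept and the model is tagged
    for manual checking.
    """
    tags: set[str] = set()
    if view_seq[seed_start:seed_start + 3] == START_CODON:
        return seed_start, tags
    furthest_atg: int | None = None
    lower = 0 if max_upstream is None else max(0, seed_start - max_upstream)
    pos = seed_start - 3
    while pos >= lower:
        codon = view_seq[pos:pos + 3]
        if "N" in codon:
            tags.add(TAG_RUNS_INTO_N)
            break
        if codon in STOP_CODONS:
            break
        if codon == START_CODON:
            furthest_atg = pos
        pos -= 3
    if furthest_atg is not None:
        return furthest_atg, tags
    # no ATG reachable upstream: scan the first 45 nt of the seed
    for off in range(0, min(START_TRIM_NT, seed_end - seed_start - 2), 3):
        if view_seq[seed_start + off:seed_start + off + 3] == START_CODON:
            return seed_start + off, tags
    tags.add(TAG_MANUAL_CHECK)
    return seed_start, tags


def extend_stop(scan_start: int, seed_end: int,
                view_seq: str) -> tuple[int, set[str]]:
    """Find the model end (inclusive of the stop codon) for an in-frame seed.

    Scans in frame from ``scan_start``: an in-frame stop inside the seed
    trims the model to it, otherwise the walk continues past the seed to the
    first downstream stop.  Walking into an N run past the seed tags the
    model runs-into-N; reaching the sequence edge without a stop tags it for
    manual checking.
    """
    tags: set[str] = set()
    n = len(view_seq)
    pos = scan_start
    while pos + 3 <= n:
        codon = view_seq[pos:pos + 3]
        if "N" in codon and pos >= seed_end:
            tags.add(TAG_RUNS_INTO_N)
            return pos, tags
        if codon in STOP_CODONS:
            return pos + 3, tags
        pos += 3
    frame = scan_start % 3
    tags.add(TAG_MANUAL_CHECK)
    return n - ((n - frame) % 3), tags


def extend_to_start_stop(seed_start: int, seed_end: int, view_seq: str,
                         max_upstream: int | None = None) -> Extension:
    """Extend an in-frame single-exon seed to a start and a stop codon."""
    if seed_end - seed_start < 3:
        raise SynannError("seed shorter than one codon")
    start, start_tags = extend_start(seed_start, seed_end, view_seq,
                                     max_upstream)
    end, stop_tags = extend_stop(start, seed_end, view_seq)
    return Extension(start=start, end=end, tags=start_tags | stop_tags)
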