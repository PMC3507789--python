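"""Assign candidate genomic loci to pillars.

Paralogous genes make several pillars hit the same genomic locus.  The
disambiguation here is purely positional: the nearest unambiguously placed
neighbours on the scaffold define an interval in the ancestral gene order,
and a candidate pillar wins only if it is the single candidate falling
inside that interval — E-values play no role in the decision.  Copy-number
caps (two loci per pillar after the whole-genome duplication, one in a
non-WGD species) and tandem-duplication splitting are enforced afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import AncestralOrder

EVIDENCE_UNIQUE = "unique-hit"
EVIDENCE_SYNTENY = "synteny-resolved"
EVIDENCE_SINGLETON = "unresolved-singleton"
EVIDENCE_TANDEM = "tandem-copy"

#: How far (in intervening loci) to scan for an unambiguous flanking
#: assignment on each side.
DEFAULT_NEIGHBOR_RADIUS = 10


@dataclass
class LocusAssignment:
    """One candidate locus and its (possibly unresolved) pillar assignment."""

    scaffold_id: str
    start: int
    end: int
    strand: str
    candidates: list[str]
    pillar_id: str | None = None
    evidence: str = EVIDENCE_SINGLETON
    evalue: float = float("inf")
    payload: object = None  # carried through untouched (locus or model)

    @property
    def resolved(self) -> bool:
        return self.pillar_id is not None and self.evidence in (
            EVIDENCE_UNIQUE, EVIDENCE_SYNTENY)


def _scan_flank(ordered: list[LocusAssignment], idx: int, step: int,
                radius: int) -> str | None:
    """Nearest unambiguous pillar within `radius` loci in one direction."""
    j = idx + step
    seen = 0
    while 0 <= j < len(ordered) and seen < radius:
        a = ordered[j]
        if a.resolved:
            return a.pillar_id
        seen += 1
        j += step
    return None


def resolve_by_synteny(ordered: list[LocusAssignment], idx: int,
                       ancestral: AncestralOrder,
                       radius: int = DEFAULT_NEIGHBOR_RADIUS) -> str | None:
    """Resolve the multi-candidate locus at position ``idx`` of a scaffold's
    ordered assignment list.

    The candidate pillar wins iff it — and no other candidate — occurs in the
    ancestral-order interval between the nearest unambiguous left and right
    neighbours.  At a scaffold end (only one flank available) a candidate
    qualifies if it lies within ``radius`` ancestral positions of that flank
    on the same ancestral chromosome.
    """
    target = ordered[idx]
    left = _scan_flank(ordered, idx, -1, radius)
    right = _scan_flank(ordered, idx, +1, radius)
    if left is None and right is None:
        return None
    winners = []
    for cand in target.candidates:
        pc = ancestral.position(cand)
        if pc is None:
            continue
        if left is not None and right is not None:
            ok = ancestral.between(cand, left, right)
        else:
            flank = left if left is not None else right
            pf = ancestral.position(flank)
            ok = (pf is not None and pf[0] == pc[0]
                  and 0 < abs(pf[1] - pc[1]) <= radius)
        if ok:
            winners.append(cand)
    if len(winners) == 1:
        return winners[0]
    return None


def resolve_assignments(assignments: list[LocusAssignment],
                        ancestral: AncestralOrder,
                        radius: int = DEFAULT_NEIGHBOR_RADIUS
                        ) -> list[LocusAssignment]:
    """Iteratively resolve multi-candidate loci until a fixed point.

    Single-candidate loci are unambiguous from the start (unique-hit
    evidence); each pass may unlock further resolutions by providing new
    flanking anchors.  Unresolvable loci become unresolved singletons.
    """
    for a in assignments:
        if len(a.candidates) == 1 and a.pillar_id is None:
            a.pillar_id = a.candidates[0]
            a.evidence = EVIDENCE_UNIQUE
    by_scaffold: dict[str, list[LocusAssignment]] = {}
    for a in assignments:
        by_scaffold.setdefault(a.scaffold_id, []).append(a)
    for ordered in by_scaffold.values():
        ordered.sort(key=lambda a: (a.start, a.end))
    # synchronous rounds: every decision in a round sees only the previous
    # round's anchors, so the outcome is independent of scan direction
    changed = True
    while changed:
        changed = False
        decisions: list[tuple[LocusAssignment, str]] = []
        for ordered in by_scaffold.values():
            for idx, a in enumerate(ordered):
                if a.resolved or len(a.candidates) < 2:
                    continue
                winner = resolve_by_synteny(ordered, idx, ancestral, radius)
                if winner is not None:
                    decisions.append((a, winner))
        for a, winner in decisions:
            a.pillar_id = winner
            a.evidence = EVIDENCE_SYNTENY
            changed = True
    for a in assignments:
        if not a.resolved:
            annotate_unplaced(a)
    return assignments


def annotate_unplaced(assignment: LocusAssignment) -> LocusAssignment:
    """A locus whose candidates stayed ambiguous (or that had none) is still
    annotated as a gene, but as a singleton outside the pillar system."""
    assignment.pillar_id = None
    assignment.evidence = EVIDENCE_SINGLETON
    return assignment


def handle_tandem_duplicates(assignments: list[LocusAssignment],
                             ancestral: AncestralOrder,
                             ) -> list[LocusAssignment]:
    """Split tandem arrays: only one copy keeps the original pillar.

    Adjacent loci (same scaffold, no unrelated assigned locus between them,
    strand-agnostic) mapped to one pillar form a tandem group.  The copy
    whose outside flank matches an ancestral neighbour of the pillar keeps
    the assignment; if that is ambiguous the 5'-most copy keeps it.  Other
    copies move to a derived tandem-copy pillar.
    """
    by_scaffold: dict[str, list[LocusAssignment]] = {}
    for a in assignments:
        by_scaffold.setdefault(a.scaffold_id, []).append(a)
    for ordered in by_scaffold.values():
        ordered.sort(key=lambda a: (a.start, a.end))
        idx = 0
        while idx < len(ordered):
            a = ordered[idx]
            if a.pillar_id is None or a.evidence == EVIDENCE_TANDEM:
                idx += 1
                continue
            group = [idx]
            j = idx + 1
            while j < len(ordered):
                b = ordered[j]
                if b.pillar_id == a.pillar_id:
                    group.append(j)
                    j += 1
                elif b.pillar_id is None:
                    # unassigned locus between copies does not break adjacency
                    j += 1
                else:
                    break
            if len(group) > 1:
                keeper = _tandem_keeper(ordered, group, a.pillar_id, ancestral)
                copy_n = 0
                for g in group:
                    if g == keeper:
                        continue
                    copy_n += 1
                    ordered[g].pillar_id = f"{a.pillar_id}.t{copy_n}"
                    ordered[g].evidence = EVIDENCE_TANDEM
            idx = group[-1] + 1
    return assignments


def _tandem_keeper(ordered: list[LocusAssignment], group: list[int],
                   pillar_id: str, ancestral: AncestralOrder) -> int:
    """Pick which tandem copy keeps the pillar: outside-flank ancestral
    adjacency first, then the 5'-most copy."""
    pos = ancestral.position(pillar_id)
    if pos is not None:
        chrom, p = pos

        def flank_matches(idx: int, step: int) -> bool:
            j = idx + step
            while 0 <= j < len(ordered):
                other = ordered[j]
                if j in group or other.pillar_id is None:
                    j += step
                    continue
                po = ancestral.position(other.pillar_id)
                return (po is not None and po[0] == chrom
                        and abs(po[1] - p) <= 2)
            return False

        left_ok = flank_matches(group[0], -1)
        right_ok = flank_matches(group[-1], +1)
        if left_ok and not right_ok:
            return group[0]
        if right_ok and not left_ok:
            return group[-1]
    return group[0]


def enforce_copy_number(assignments: list[LocusAssignment],
                        wgd_mode: str) -> list[LocusAssignment]:
    """Cap loci per pillar: two in a post-WGD run, one otherwise.

    The strongest loci by synteny evidence, then lowest E-value, keep the
    pillar; excess loci are demoted to unresolved singletons.
    """
    cap = 2 if wgd_mode in ("post", "post-WGD") else 1
    by_pillar: dict[str, list[LocusAssignment]] = {}
    for a in assignments:
        if a.pillar_id is not None and a.evidence != EVIDENCE_TANDEM:
            by_pillar.setdefault(a.pillar_id, []).append(a)
    strength = {EVIDENCE_SYNTENY: 0, EVIDENCE_UNIQUE: 1}
    for group in by_pillar.values():
        if len(group) <= cap:
            continue
        group.sort(key=lambda a: (strength.get(a.evidence, 2), a.evalue,
                                  a.scaffold_id, a.start))
        for a in group[cap:]:
            annotate_unplaced(a)
    return assignments


@dataclass
class AssignmentResult:
    assignments: list[LocusAssignment] = field(default_factory=list)

    def for_pillar(self, pillar_id: str) -> list[LocusAssignment]:
        return [a for a in self.assignments if a.pillar_id == pillar_id]


def assign_loci(candidate_loci: list[tuple[str, object]],
                ancestral: AncestralOrder, wgd_mode: str,
                radius: int = DEFAULT_NEIGHBOR_RADIUS) -> AssignmentResult:
    """Full assignment pass over (pillar_id, Locus) candidates.

    Overlapping loci on one scaffold are merged into a single site whose
    candidate list is the set of pillars hitting it; the site then goes
    through synteny resolution, tandem splitting and copy-number capping.
    """
    sites: list[LocusAssignment] = []
    items = sorted(candidate_loci,
                   key=lambda t: (t[1].scaffold_id, t[1].start, t[1].end))
    for pillar_id, locus in items:
        merged = False
        for site in sites:
            if (site.scaffold_id == locus.scaffold_id
                    and site.start < locus.end and locus.start < site.end):
                if pillar_id not in site.candidates:
                    site.candidates.append(pillar_id)
                site.start = min(site.start, locus.start)
                site.end = max(site.end, locus.end)
                site.evalue = min(site.evalue, locus.evalue)
                merged = True
                break
        if not merged:
            sites.append(LocusAssignment(
                scaffold_id=locus.scaffold_id, start=locus.start,
                end=locus.end, strand=locus.strand,
                candidates=[pillar_id], evalue=locus.evalue, payload=locus))
    resolve_assignments(sites, ancestral, radius)
    handle_tandem_duplicates(sites, ancestral)
    enforce_copy_number(sites, wgd_mode)
    return AssignmentResult(assignments=sites)
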