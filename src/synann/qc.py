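"""Scaffold-integrity checking from paired primary reads.

Each read of a pair is placed at its unique exact occurrence in the
scaffolds; pairs whose mates land on different contigs support the physical
link between those contigs.  The result is a symmetric contig-link matrix
ordered by scaffold position: cells on the adjacent-in-scaffold band are the
joins asserted by the assembly, so a band cell with weak support flags a
questionable join, while strong off-band cells suggest alternatives.  The
tool only reports; breaking joins is left to the user.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Genome, SynannError, revcomp

#: Pair-naming conventions: suffix /1 and /2, or .f and .r
PAIR_PATTERNS = (
    re.compile(r"^(?P<frag>.+)/(?P<mate>[12])$"),
    re.compile(r"^(?P<frag>.+)\.(?P<mate>[fr])$"),
)
_MATE_MAP = {"1": 0, "2": 1, "f": 0, "r": 1}

#: Adjacent joins supported by fewer pairs than this are flagged.
DEFAULT_FLAG_THRESHOLD = 3


def parse_pair_name(read_id: str) -> tuple[str, int] | None:
    """Split a read id into (fragment id, mate index 0/1); None if the id
    follows no known pairing convention."""
    for pat in PAIR_PATTERNS:
        m = pat.match(read_id)
        if m:
            return m.group("frag"), _MATE_MAP[m.group("mate")]
    return None


def locate_contigs(genome: Genome,
                   contigs: dict[str, str]) -> dict[str, list[tuple[int, int, str]]]:
    """Find each contig's position inside the scaffolds (exact match, either
    orientation).  Returns {scaffold: sorted [(start, end, contig_id)]}."""
    layout: dict[str, list[tuple[int, int, str]]] = {s: []
                                                     for s in genome.sequences}
    for cid, cseq in contigs.items():
        placed = False
        for scaffold, seq in genome.sequences.items():
            for probe in (cseq, revcomp(cseq)):
                p = seq.find(probe)
                if p >= 0:
                    layout[scaffold].append((p, p + len(cseq), cid))
                    placed = True
                    break
            if placed:
                break
        if not placed:
            raise SynannError(f"contig {cid!r} not found in any scaffold")
    for spans in layout.values():
        spans.sort()
    return layout


def _unique_hit(read: str, genome: Genome) -> tuple[str, int] | None:
    """The single exact occurrence of a read in the genome (either strand);
    None when absent or repeated."""
    found: tuple[str, int] | None = None
    for scaffold, seq in genome.sequences.items():
        for probe in (read, revcomp(read)):
            start = 0
            while True:
                p = seq.find(probe, start)
                if p < 0:
                    break
                if found is not None and found != (scaffold, p):
                    return None
                found = (scaffold, p)
                start = p + 1
    return found


@dataclass
class PairPlacements:
    """Unique read placements grouped by fragment, plus conservation counts."""

    placements: dict[str, dict[int, tuple[str, int, int]]]  # frag -> mate -> (scaffold, pos, len)
    n_reads: int = 0
    n_placed: int = 0
    n_nonunique: int = 0
    n_unpaired: int = 0


def map_read_pairs(reads: dict[str, str], contigs: dict[str, str],
                   genome: Genome) -> PairPlacements:
    """Place every uniquely-mapping paired read on the scaffolds.

    Reads whose ids follow no pairing convention are counted as unpaired and
    ignored; reads with zero or multiple exact hits are counted non-unique.
    """
    unparseable = [rid for rid in reads if parse_pair_name(rid) is None]
    if unparseable and len(unparseable) == len(reads):
        raise SynannError(
            "no read ids follow a known pairing convention; offenders "
            f"include {sorted(unparseable)[:5]}"
        )
    out = PairPlacements(placements={}, n_reads=len(reads))
    for rid, seq in reads.items():
        parsed = parse_pair_name(rid)
        if parsed is None:
            out.n_unpaired += 1
            continue
        frag, mate = parsed
        hit = _unique_hit(seq, genome)
        if hit is None:
            out.n_nonunique += 1
            continue
        scaffold, pos = hit
        out.placements.setdefault(frag, {})[mate] = (scaffold, pos, len(seq))
        out.n_placed += 1
    return out


@dataclass
class LinkMatrix:
    contig_order: list[str]                   # ordered by scaffold position
    contig_scaffold: dict[str, str]
    matrix: np.ndarray                        # symmetric pair counts
    flagged_joins: list[tuple[str, str, int]] = field(default_factory=list)
    alternatives: list[tuple[str, str, int]] = field(default_factory=list)

    def support(self, a: str, b: str) -> int:
        i, j = self.contig_order.index(a), self.contig_order.index(b)
        return int(self.matrix[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.contig_order,
                            columns=self.contig_order)

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def write_flagged_report(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("kind\tcontig_a\tcontig_b\tpairs\n")
            for a, b, n in self.flagged_joins:
                fh.write(f"weak-join\t{a}\t{b}\t{n}\n")
            for a, b, n in self.alternatives:
                fh.write(f"alternative\t{a}\t{b}\t{n}\n")


def contig_link_matrix(placements: PairPlacements,
                       layout: dict[str, list[tuple[int, int, str]]],
                       flag_threshold: int = DEFAULT_FLAG_THRESHOLD
                       ) -> LinkMatrix:
    """Count read pairs supporting each contig-contig connection.

    Contigs are ordered as they occur in the scaffolds; cells adjacent in
    that order (within one scaffold) are the joins the assembly asserts.
    Band cells below ``flag_threshold`` become flagged weak joins; off-band
    cells at or above it are reported as possible alternatives.
    """
    order: list[str] = []
    contig_scaffold: dict[str, str] = {}
    for scaffold in sorted(layout):
        for _s, _e, cid in layout[scaffold]:
            order.append(cid)
            contig_scaffold[cid] = scaffold
    idx = {cid: i for i, cid in enumerate(order)}
    n = len(order)
    matrix = np.zeros((n, n), dtype=int)

    def contig_of(scaffold: str, pos: int) -> str | None:
        for s, e, cid in layout.get(scaffold, []):
            if s <= pos < e:
                return cid
        return None

    for frag, mates in placements.placements.items():
        if len(mates) != 2:
            continue
        cids = []
        for scaffold, pos, ln in mates.values():
            cid = contig_of(scaffold, pos + ln // 2)
            if cid is None:
                break
            cids.append(cid)
        if len(cids) != 2 or cids[0] == cids[1]:
            continue
        i, j = idx[cids[0]], idx[cids[1]]
        matrix[i, j] += 1
        matrix[j, i] += 1

    flagged, alternatives = [], []
    band = set()
    for a, b in zip(order, order[1:]):
        if contig_scaffold[a] != contig_scaffold[b]:
            continue
        i, j = idx[a], idx[b]
        band.add((min(i, j), max(i, j)))
        support = int(matrix[i, j])
        if support < flag_threshold:
            flagged.append((a, b, support))
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in band:
                continue
            if matrix[i, j] >= flag_threshold:
                alternatives.append((order[i], order[j], int(matrix[i, j])))
    return LinkMatrix(contig_order=order, contig_scaffold=contig_scaffold,
                      matrix=matrix, flagged_joins=flagged,
                      alternatives=alternatives)
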