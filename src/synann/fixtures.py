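"""Ground-truthed synthetic test worlds.

The generator emulates the pipeline's study conditions end to end: a pillar
database with an ancestral gene order across two reference species groups, a
derived target genome (optionally post-WGD) with planted genes, rare introns
carrying canonical splice motifs, tandem and retrotransposon duplications,
injected homopolymer frameshift errors, and error-free simulated paired
reads drawn from the true (pre-error) sequence.  Every output is fully
determined by the seed.

What the generator does not emulate: phylogenetically correlated sequence
evolution (substitutions are i.i.d.), realistic pyrosequencing flowgram
noise (reads are error-free by design so that read voting is isolated from
a sequencing-error model), and realistic amino-acid composition (uniform).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .core import (
    Correction,
    GeneModel,
    Genome,
    NON_WGD,
    POST_WGD,
    Pillar,
    AncestralOrder,
    RefGene,
    revcomp,
)
from . import io as sio
from .introns import ACCEPTOR_MOTIFS, BRANCH_MOTIFS, DONOR_MOTIFS

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
STOPS = ("TAA", "TAG", "TGA")

#: Reference species per group.
POST_SPECIES = ("SpostA", "SpostB")
NON_SPECIES = ("SnonA", "SnonB")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic world.

    Defaults reflect the study conditions the pipeline targets: compact
    yeast-like genomes where ~4% of genes carry a single intron, proteins
    average ~450 codons, and assemblies carry occasional 1-2 bp
    homopolymer indels.
    """

    seed: int
    n_pillars: int = 60
    wgd: bool = False
    wgd_retention: float = 0.2
    intron_fraction: float = 0.04
    frameshift_count: int = 0
    tandem_count: int = 0
    ty_copies: int = 0
    divergence: float = 0.0
    member_divergence: float = 0.05
    read_coverage: float = 0.0
    read_length: int = 300
    paralog_pairs: int = 0
    novel_orf_count: int = 0
    divergent_gene_count: int = 0
    mean_protein_aa: int = 450
    n_chromosomes: int = 2
    shuffle_prob: float = 0.05
    inversion_prob: float = 0.05

    def __post_init__(self) -> None:
        for name in ("wgd_retention", "intron_fraction", "divergence",
                     "member_divergence", "shuffle_prob", "inversion_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_pillars", "frameshift_count", "tandem_count",
                     "ty_copies", "paralog_pairs", "novel_orf_count",
                     "divergent_gene_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# sequence helpers

def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "M" + "".join(rng.choice(list(AA20), size=length - 1))


def mutate_protein(protein: str, rate: float,
                   rng: np.random.Generator) -> str:
    """i.i.d. amino-acid substitutions; the initiator methionine is kept."""
    out = list(protein)
    for i in range(1, len(out)):
        if rng.random() < rate:
            choices = [a for a in AA20 if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """CDS without stop codon; synonymous codons drawn uniformly."""
    return "".join(
        _CODONS_BY_AA[aa][rng.integers(len(_CODONS_BY_AA[aa]))]
        for aa in protein
    )


def make_intron(rng: np.random.Generator) -> str:
    """A canonical intron: donor ... branchpoint ... short gap ... acceptor."""
    donor = DONOR_MOTIFS[rng.integers(len(DONOR_MOTIFS))]
    branch = BRANCH_MOTIFS[rng.integers(len(BRANCH_MOTIFS))]
    acceptor = ACCEPTOR_MOTIFS[rng.integers(len(ACCEPTOR_MOTIFS))]
    total = int(rng.integers(60, 401))
    tail_gap = int(rng.integers(6, 31))
    filler_len = total - len(donor) - len(branch) - tail_gap - len(acceptor)
    filler_len = max(filler_len, 4)

    def quiet_dna(n: int) -> str:
        # avoid spawning competing donor/branch motifs inside the intron
        seq = random_dna(rng, n)
        for motif in DONOR_MOTIFS + BRANCH_MOTIFS:
            while motif in seq:
                seq = seq.replace(motif, random_dna(rng, len(motif)), 1)
        return seq

    return donor + quiet_dna(filler_len) + branch + quiet_dna(tail_gap) + acceptor


# ---------------------------------------------------------------------------
# world (reference database)

@dataclass
class PlannedGene:
    """Per-pillar plan shared by the database and the target genome."""

    pillar_id: str
    ancestral_protein: str
    has_intron: bool
    kind: str = "gene"       # gene | paralog | divergent | ty
    paralog_of: str | None = None


@dataclass
class World:
    spec: FixtureSpec
    pillars: list[Pillar]
    ancestral: AncestralOrder
    plans: dict[str, PlannedGene]
    ty_pillar_id: str | None = None


def build_reference_world(spec: FixtureSpec) -> World:
    """Pillar database + ancestral order, deterministic under the seed."""
    rng = np.random.default_rng([spec.seed, 0])
    plans: dict[str, PlannedGene] = {}
    pillar_ids = [f"P{i + 1:04d}" for i in range(spec.n_pillars)]

    # choose special roles among ordinary pillars; divergent (rescue-target)
    # genes need both ancestral neighbours, so chromosome edges are excluded
    per_chrom = max(1, spec.n_pillars // spec.n_chromosomes)
    edge = set()
    for c in range(spec.n_chromosomes):
        chunk = list(range(c * per_chrom,
                           min((c + 1) * per_chrom, spec.n_pillars)))
        edge.update(chunk[:2] + chunk[-2:])
    special = rng.permutation(spec.n_pillars)
    n_par = min(spec.paralog_pairs * 2, spec.n_pillars // 2)
    paralog_slots = list(special[:n_par])
    divergent_slots = []
    for idx in special[n_par:]:
        if len(divergent_slots) >= spec.divergent_gene_count:
            break
        if idx not in edge:
            divergent_slots.append(idx)

    for i, pid in enumerate(pillar_ids):
        if i in divergent_slots:
            length = int(rng.integers(42, 56))
        else:
            length = int(np.clip(rng.lognormal(
                math.log(spec.mean_protein_aa), 0.35), 80, 1500))
        protein = random_protein(rng, length)
        has_intron = (rng.random() < spec.intron_fraction
                      and i not in divergent_slots)
        plans[pid] = PlannedGene(pid, protein, has_intron)
        if i in divergent_slots:
            plans[pid].kind = "divergent"
    # paralog pairs: the second pillar of a pair reuses a diverged copy of
    # the first pillar's protein
    for a_idx, b_idx in zip(paralog_slots[0::2], paralog_slots[1::2]):
        a, b = pillar_ids[a_idx], pillar_ids[b_idx]
        plans[b].ancestral_protein = mutate_protein(
            plans[a].ancestral_protein, 0.10, rng)
        plans[b].kind = "paralog"
        plans[b].paralog_of = a
        plans[b].has_intron = False
        plans[a].has_intron = False

    pillars: list[Pillar] = []
    for pid in pillar_ids:
        plan = plans[pid]
        members = []
        exon_count = 2 if plan.has_intron else 1
        for group, species in ((POST_WGD, POST_SPECIES),
                               (NON_WGD, NON_SPECIES)):
            for sp in species:
                members.append(RefGene(
                    gene_id=f"{sp}_{pid}", species=sp, species_group=group,
                    protein=mutate_protein(plan.ancestral_protein,
                                           spec.member_divergence, rng),
                    exon_count=exon_count))
        pillars.append(Pillar(pillar_id=pid, members=members,
                              ancestral_locus=f"ANC_{pid}"))

    ty_pillar_id = None
    if spec.ty_copies > 0:
        ty_pillar_id = "PTY01"
        ty_protein = random_protein(rng, 300)
        pillars.append(Pillar(
            pillar_id=ty_pillar_id,
            members=[RefGene(gene_id="SpostA_TY1", species="SpostA",
                             species_group=POST_WGD, protein=ty_protein,
                             is_ty=True)]))
        plans[ty_pillar_id] = PlannedGene(ty_pillar_id, ty_protein, False,
                                          kind="ty")

    per_chrom = max(1, spec.n_pillars // spec.n_chromosomes)
    ordered: dict[str, list[str]] = {}
    for c in range(spec.n_chromosomes):
        chrom = f"anc{c + 1}"
        ordered[chrom] = pillar_ids[c * per_chrom:(c + 1) * per_chrom]
    # any remainder joins the last chromosome
    rest = pillar_ids[spec.n_chromosomes * per_chrom:]
    if rest:
        ordered[f"anc{spec.n_chromosomes}"].extend(rest)
    return World(spec=spec, pillars=pillars,
                 ancestral=AncestralOrder(ordered), plans=plans,
                 ty_pillar_id=ty_pillar_id)


# ---------------------------------------------------------------------------
# target genome

@dataclass
class TruthGene:
    pillar_id: str | None
    scaffold_id: str
    strand: str
    exons: list[tuple[int, int]]   # forward coords, coding order
    kind: str                      # gene | paralog | divergent | tandem-copy
                                   # | ty | novel-orf
    has_intron: bool = False

    @property
    def span(self) -> tuple[int, int]:
        ss = [s for s, _ in self.exons]
        es = [e for _, e in self.exons]
        return min(ss), max(es)


@dataclass
class TargetGenome:
    genome: Genome                 # true (error-free) assembly
    truth: list[TruthGene]
    ohnolog_pairs: list[str] = field(default_factory=list)  # pillar ids


@dataclass
class _Cassette:
    pillar_id: str | None
    kind: str
    strand: str
    exon_parts: list[str]          # coding-strand pieces: [cds] or [e1, e2]
    intron: str | None = None

    @property
    def seq(self) -> str:
        if self.intron is None:
            coding = self.exon_parts[0]
        else:
            coding = self.exon_parts[0] + self.intron + self.exon_parts[1]
        return coding if self.strand == "+" else revcomp(coding)


def _gene_cassette(plan: PlannedGene, spec: FixtureSpec,
                   rng: np.random.Generator, kind: str | None = None,
                   divergence: float | None = None) -> _Cassette:
    if divergence is not None:
        div = divergence
    elif plan.kind == "divergent":
        # planted below the search's seeding sensitivity: only the
        # syntenic-gap rescue pass can recover these
        div = 0.6
    else:
        div = spec.divergence
    protein = mutate_protein(plan.ancestral_protein, div, rng)
    cds = back_translate(protein, rng) + STOPS[rng.integers(len(STOPS))]
    strand = "-" if rng.random() < spec.inversion_prob else "+"
    if plan.has_intron:
        # half the intron genes get a first exon too small to seed a
        # translated-search hit, exercising exon-1 recovery
        if rng.random() < 0.5:
            e1 = int(rng.integers(9, 22))
        else:
            e1 = int(rng.integers(90, 301))
        e1 = min(e1, len(cds) - 90)
        return _Cassette(plan.pillar_id, kind or plan.kind, strand,
                         [cds[:e1], cds[e1:]], make_intron(rng))
    return _Cassette(plan.pillar_id, kind or plan.kind, strand, [cds])


def _assemble(scaffold_id: str, cassettes: list[_Cassette],
              rng: np.random.Generator) -> tuple[str, list[TruthGene]]:
    parts: list[str] = []
    truth: list[TruthGene] = []
    pos = 0

    def spacer() -> str:
        return random_dna(rng, int(rng.integers(200, 601)))

    for cas in cassettes:
        sp = spacer()
        parts.append(sp)
        pos += len(sp)
        seq = cas.seq
        start, end = pos, pos + len(seq)
        if cas.intron is None:
            exons = [(start, end)]
        else:
            e1 = len(cas.exon_parts[0])
            il = len(cas.intron)
            if cas.strand == "+":
                exons = [(start, start + e1), (start + e1 + il, end)]
            else:
                exons = [(end - e1, end), (start, end - e1 - il)]
        truth.append(TruthGene(
            pillar_id=cas.pillar_id, scaffold_id=scaffold_id,
            strand=cas.strand, exons=exons, kind=cas.kind,
            has_intron=cas.intron is not None))
        parts.append(seq)
        pos = end
    tail = spacer()
    parts.append(tail)
    return "".join(parts), truth


def derive_target_genome(world: World,
                         spec: FixtureSpec | None = None) -> TargetGenome:
    """Plant the world's genes along scaffolds in (locally shuffled)
    ancestral order; in WGD mode each chromosome yields two scaffolds with
    ohnolog pairs retained at ``wgd_retention``."""
    spec = spec or world.spec
    rng = np.random.default_rng([spec.seed, 1])
    plans = world.plans
    sequences: dict[str, str] = {}
    truth: list[TruthGene] = []
    ohnologs: list[str] = []

    tandem_todo = set()
    candidates = [pid for pid, plan in plans.items()
                  if plan.kind == "gene" and not plan.has_intron]
    rng.shuffle(candidates)
    tandem_todo = set(candidates[:spec.tandem_count])

    for chrom, order in world.ancestral.ordered_loci.items():
        order = list(order)
        for i in range(len(order) - 1):
            if rng.random() < spec.shuffle_prob:
                order[i], order[i + 1] = order[i + 1], order[i]
        if spec.wgd:
            copies: dict[str, list[str]] = {"A": [], "B": []}
            for pid in order:
                if rng.random() < spec.wgd_retention:
                    copies["A"].append(pid)
                    copies["B"].append(pid)
                    ohnologs.append(pid)
                else:
                    copies["A" if rng.random() < 0.5 else "B"].append(pid)
            tracks = [(f"{chrom}{t}", pids) for t, pids in copies.items()]
        else:
            tracks = [(chrom.replace("anc", "chr"), order)]
        for scaffold_id, pids in tracks:
            cassettes = []
            for pid in pids:
                cassettes.append(_gene_cassette(plans[pid], spec, rng))
                if pid in tandem_todo and not spec.wgd:
                    cassettes.append(_gene_cassette(
                        plans[pid], spec, rng, kind="tandem-copy",
                        divergence=0.02))
            seq, scaffold_truth = _assemble(scaffold_id, cassettes, rng)
            sequences[scaffold_id] = seq
            truth.extend(scaffold_truth)

    # Ty cassettes and novel ORFs appended at scaffold ends: mobile or
    # species-specific sequence outside the ancestral order
    extra: list[tuple[str, str | None]] = []
    if world.ty_pillar_id is not None:
        for _ in range(spec.ty_copies):
            extra.append(("ty", world.ty_pillar_id))
    for _ in range(spec.novel_orf_count):
        extra.append(("novel-orf", None))
    scaffold_ids = sorted(sequences)
    for kind, pid in extra:
        if pid is not None:
            cassette = _gene_cassette(plans[pid], spec, rng, kind=kind,
                                      divergence=0.02)
        else:
            protein = random_protein(rng, 200)
            cds = back_translate(protein, rng) + STOPS[rng.integers(3)]
            strand = "+" if rng.random() < 0.5 else "-"
            cassette = _Cassette(None, kind, strand, [cds])
        target = scaffold_ids[rng.integers(len(scaffold_ids))]
        sp = random_dna(rng, int(rng.integers(200, 401)))
        base = len(sequences[target]) + len(sp)
        seq = cassette.seq
        sequences[target] = sequences[target] + sp + seq
        truth.append(TruthGene(
            pillar_id=pid, scaffold_id=target, strand=cassette.strand,
            exons=[(base, base + len(seq))], kind=kind))
    return TargetGenome(genome=Genome(sequences), truth=truth,
                        ohnolog_pairs=ohnologs)


# ---------------------------------------------------------------------------
# frameshift injection and read simulation

@dataclass
class InjectedWorld:
    edited_genome: Genome          # assembly handed to the pipeline
    true_genome: Genome            # pre-error sequence (reads come from it)
    reads: dict[str, str]
    truth_edits: list[Correction]  # corrections that undo the errors
                                   # (positions in edited coordinates)


def _homopolymer_site(cds_region: str, rng: np.random.Generator
                      ) -> tuple[int, str] | None:
    """Offset and base of a homopolymer run (>=3) in the region interior."""
    runs = []
    i = 90
    while i < len(cds_region) - 93:
        j = i
        while j < len(cds_region) and cds_region[j] == cds_region[i]:
            j += 1
        if j - i >= 3:
            runs.append((i, cds_region[i]))
        i = max(j, i + 1)
    if not runs:
        return None
    return runs[rng.integers(len(runs))]


def inject_frameshifts_and_reads(target: TargetGenome,
                                 spec: FixtureSpec) -> InjectedWorld:
    """Place 1 bp indels inside coding regions (homopolymer-biased) and
    simulate error-free paired reads from the pre-error sequence."""
    rng = np.random.default_rng([spec.seed, 2])
    eligible = [t for t in target.truth
                if t.kind == "gene" and not t.has_intron
                and (t.span[1] - t.span[0]) >= 400]
    rng.shuffle(eligible)
    chosen = eligible[:spec.frameshift_count]

    # plan errors in true coordinates
    errors: dict[str, list[tuple[int, str, str]]] = {}
    for gene in chosen:
        s, e = gene.span
        region = target.genome.fetch(gene.scaffold_id, s, e)
        site = _homopolymer_site(region, rng)
        if site is None:
            off = int(rng.integers(90, (e - s) - 93))
            base = region[off]
        else:
            off, base = site
        pos = s + off
        if rng.random() < 0.7:
            errors.setdefault(gene.scaffold_id, []).append(
                (pos, "error-del", base))     # assembly lost a base
        else:
            errors.setdefault(gene.scaffold_id, []).append(
                (pos, "error-ins", base))     # assembly gained a base

    edited_sequences = dict(target.genome.sequences)
    truth_edits: list[Correction] = []
    for scaffold, elist in errors.items():
        elist.sort()
        shift = 0
        seq = target.genome.sequences[scaffold]
        out = []
        prev = 0
        for pos, op, base in elist:
            out.append(seq[prev:pos])
            if op == "error-del":
                prev = pos + 1                # drop the true base
                truth_edits.append(Correction(
                    scaffold_id=scaffold, position=pos + shift,
                    op="insert", bases=base, applied=False))
                shift -= 1
            else:
                out.append(base)              # duplicate the base
                truth_edits.append(Correction(
                    scaffold_id=scaffold, position=pos + shift,
                    op="delete", bases=base, applied=False))
                prev = pos
                shift += 1
        out.append(seq[prev:])
        edited_sequences[scaffold] = "".join(out)

    reads: dict[str, str] = {}
    if spec.read_coverage > 0:
        rl = spec.read_length
        frag = 0
        for scaffold in sorted(target.genome.sequences):
            seq = target.genome.sequences[scaffold]
            L = len(seq)
            n_pairs = int(spec.read_coverage * L / (2 * rl))
            for _ in range(n_pairs):
                insert = int(max(2 * rl + 20,
                                 rng.normal(3 * rl, 0.2 * rl)))
                if insert >= L:
                    insert = L - 1
                p = int(rng.integers(0, L - insert))
                frag += 1
                reads[f"frag{frag}/1"] = seq[p:p + rl]
                reads[f"frag{frag}/2"] = revcomp(
                    seq[p + insert - rl:p + insert])
    return InjectedWorld(
        edited_genome=Genome(edited_sequences),
        true_genome=target.genome, reads=reads, truth_edits=truth_edits)


# ---------------------------------------------------------------------------
# QC fixture (contigs / scaffold mis-join)

@dataclass
class QcFixture:
    scaffolds: Genome
    contigs: dict[str, str]
    reads: dict[str, str]
    misjoin: tuple[str, str] | None   # the asserted-but-false adjacency


def make_qc_fixture(seed: int, n_contigs: int = 6, contig_len: int = 6000,
                    coverage: float = 25.0, read_length: int = 80,
                    insert: int = 600, misjoin: bool = True) -> QcFixture:
    """True arrangement c1..cN on one chromosome; the scaffolds assert one
    false join by relocating a contig, so exactly that join lacks spanning
    read pairs."""
    rng = np.random.default_rng([seed, 3])
    contigs = {f"c{i + 1}": random_dna(rng, contig_len)
               for i in range(n_contigs)}
    order = [f"c{i + 1}" for i in range(n_contigs)]
    true_seq = "".join(contigs[c] for c in order)
    gap = "N" * 50
    if misjoin and n_contigs >= 6:
        scaffold_a = order[:3] + [order[5]]      # c1 c2 c3 c6: c3-c6 is false
        scaffold_b = order[3:5]                  # c4 c5
        mis = (order[2], order[5])
    else:
        scaffold_a, scaffold_b, mis = order, [], None
    sequences = {"scafA": gap.join(contigs[c] for c in scaffold_a)}
    if scaffold_b:
        sequences["scafB"] = gap.join(contigs[c] for c in scaffold_b)
    reads: dict[str, str] = {}
    L = len(true_seq)
    n_pairs = int(coverage * L / (2 * read_length))
    for i in range(n_pairs):
        p = int(rng.integers(0, L - insert))
        reads[f"pair{i + 1}/1"] = true_seq[p:p + read_length]
        reads[f"pair{i + 1}/2"] = revcomp(
            true_seq[p + insert - read_length:p + insert])
    return QcFixture(scaffolds=Genome(sequences), contigs=contigs,
                     reads=reads, misjoin=mis)


# ---------------------------------------------------------------------------
# materialization and evaluation helpers

def truth_to_models(truth: list[TruthGene]) -> list[GeneModel]:
    models = []
    for i, t in enumerate(truth, 1):
        models.append(GeneModel(
            model_id=f"truth{i:04d}", scaffold_id=t.scaffold_id,
            strand=t.strand, exons=list(t.exons),
            pillar_id=t.pillar_id, evidence=t.kind))
    return models


def materialize_fixture(spec: FixtureSpec, outdir: str) -> dict[str, str]:
    """Write a complete fixture directory; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    world = build_reference_world(spec)
    target = derive_target_genome(world)
    injected = inject_frameshifts_and_reads(target, spec)
    paths = {
        "scaffolds": os.path.join(outdir, "scaffolds.fasta"),
        "pillars": os.path.join(outdir, "pillars.json"),
        "truth_gff3": os.path.join(outdir, "truth.gff3"),
        "truth_edits": os.path.join(outdir, "truth_edits.tsv"),
    }
    sio.write_fasta(injected.edited_genome.sequences, paths["scaffolds"])
    sio.write_pillar_db(world.pillars, world.ancestral, paths["pillars"])
    sio.write_gff3(truth_to_models(target.truth), [], paths["truth_gff3"],
                   target.genome)
    sio.write_corrections_report(injected.truth_edits, paths["truth_edits"])
    if injected.reads:
        paths["reads"] = os.path.join(outdir, "reads.fasta")
        sio.write_fasta(injected.reads, paths["reads"])
    return paths


@dataclass
class RecoveryStats:
    n_truth: int
    n_exact: int
    n_intron_truth: int
    n_intron_exact: int

    @property
    def exact_fraction(self) -> float:
        return self.n_exact / self.n_truth if self.n_truth else float("nan")


def structure_recovery(models: list[GeneModel], truth: list[TruthGene],
                       kinds: tuple[str, ...] = ("gene", "paralog"),
                       min_exon2_nt: int = 0) -> RecoveryStats:
    """Fraction of planted genes recovered with exact coordinates.

    A truth gene counts as exact when some model on the same scaffold and
    strand has the identical exon list.  Intron genes whose second exon is
    shorter than ``min_exon2_nt`` are excluded from the intron tally.
    """
    by_site: dict[tuple[str, str], set[tuple[tuple[int, int], ...]]] = {}
    for m in models:
        by_site.setdefault((m.scaffold_id, m.strand), set()).add(
            tuple(sorted(m.exons)))
    n_truth = n_exact = n_it = n_ie = 0
    for t in truth:
        if t.kind not in kinds:
            continue
        if t.has_intron and min_exon2_nt:
            exon2 = sorted(t.exons)[-1] if t.strand == "+" else sorted(t.exons)[0]
            if exon2[1] - exon2[0] < min_exon2_nt:
                continue
        n_truth += 1
        hit = tuple(sorted(t.exons)) in by_site.get(
            (t.scaffold_id, t.strand), set())
        n_exact += hit
        if t.has_intron:
            n_it += 1
            n_ie += hit
    return RecoveryStats(n_truth, n_exact, n_it, n_ie)


def _apply_one(seq: str, c: Correction) -> str | None:
    if c.op == "insert":
        return seq[:c.position] + c.bases + seq[c.position:]
    if seq[c.position:c.position + len(c.bases)] != c.bases:
        return None
    return seq[:c.position] + seq[c.position + len(c.bases):]


def correction_reverses_edit(found: Correction, truth: Correction,
                             edited_genome: Genome) -> bool:
    """Does a proposed correction undo an injected error exactly?

    Homopolymer indels have equivalent representations (deleting any base of
    a run gives the same sequence), so equivalence is judged by applying
    both edits to the assembly and comparing the results locally, not by
    comparing coordinates.
    """
    if found.scaffold_id != truth.scaffold_id:
        return False
    if abs(found.position - truth.position) > 30:
        return False
    seq = edited_genome.sequences[found.scaffold_id]
    via_found = _apply_one(seq, found)
    via_truth = _apply_one(seq, truth)
    if via_found is None or via_truth is None:
        return False
    lo = max(0, min(found.position, truth.position) - 50)
    hi = max(found.position, truth.position) + 50
    return via_found[lo:hi] == via_truth[lo:hi]
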