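"""End-to-end annotation pipeline.

Stage order: optional tRNA track ingest -> translated homology search ->
pillar/locus assignment by synteny -> gene modeling with intron search ->
frameshift detection and repair (reads voting, N insertion, or report-only)
-> one re-annotation on the edited assembly when corrections were applied ->
rescue passes (syntenic-gap search, large ORFs, Ty propagation) -> writers.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

from .core import (
    GeneModel,
    Genome,
    Hsp,
    NON_WGD,
    POST_WGD,
    Pillar,
    AncestralOrder,
    START_CODON,
    STOP_CODONS,
    StrandView,
    SynannError,
    TAG_FS_CORRECTED,
    TAG_FS_UNCORRECTED,
    TAG_MANUAL_CHECK,
    TrnaFeature,
)
from . import io as sio
from .frameshift import (
    FrameshiftContext,
    apply_first_fixing_indel,
    extract_fs_window,
    insert_placeholder_Ns,
    vote_indels,
)
from .introns import intron_between_hsps, recover_missing_exon1
from .modeling import (
    KIND_FRAMESHIFT,
    KIND_INTRON,
    ViewHsp,
    classify_chain,
    extend_start,
    extend_stop,
    extend_to_start_stop,
    mean_group_lengths,
    seed_coordinates,
    select_reference_gene,
    to_view,
)
from .search import (
    DEFAULT_EVALUE_CUTOFF,
    DEFAULT_LOCUS_GAP,
    SixFrameIndex,
    best_query_for_pillar,
    parse_search_tabular,
    retain_secondary_loci,
    search_all,
)
from .synteny import (
    LocusAssignment,
    assign_loci,
    enforce_copy_number,
    handle_tandem_duplicates,
)
from . import rescue

log = logging.getLogger("synann")


@dataclass
class PipelineConfig:
    scaffolds: str
    pillars: str
    out: str
    prefix: str = "GEN"
    wgd: str = "non"                  # "post" | "non"
    contigs: str | None = None
    reads: str | None = None
    trna_track: str | None = None
    hits: str | None = None
    fix_frameshifts: str = "off"      # "reads" | "n-insert" | "off"
    seed: int = 0
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
    locus_gap: int = DEFAULT_LOCUS_GAP

    def __post_init__(self) -> None:
        if self.wgd not in ("post", "non"):
            raise SynannError("--wgd must be 'post' or 'non'")
        if self.fix_frameshifts not in ("reads", "n-insert", "off"):
            raise SynannError(
                "--fix-frameshifts must be 'reads', 'n-insert' or 'off'")
        if self.fix_frameshifts == "reads" and not self.reads:
            raise SynannError(
                "--fix-frameshifts reads requires a --reads file")

    @property
    def target_group(self) -> str:
        return POST_WGD if self.wgd == "post" else NON_WGD


@dataclass
class FsDetection:
    """One frameshift-classified HSP pair, with its repair context."""

    scaffold_id: str
    strand: str
    h1: ViewHsp
    h2: ViewHsp
    window: tuple[int, int]         # view coordinates
    fwd_site: int                   # forward-strand estimated shift site
    model_key: int


@dataclass
class AnnotationPass:
    models: list[GeneModel]
    assignments: list[LocusAssignment]
    detections: list[FsDetection]
    hsps_by_query: dict[str, list[Hsp]]
    index: SixFrameIndex
    ty_hsps: list[Hsp] = field(default_factory=list)


def _hit_ranking(members, hsps_by_query, scaffold, lo, hi
                 ) -> dict[str, tuple[float, float]]:
    ranking: dict[str, tuple[float, float]] = {}
    for m in members:
        best = None
        for h in hsps_by_query.get(m.gene_id, ()):
            if h.scaffold_id != scaffold or h.subj_end <= lo or h.subj_start >= hi:
                continue
            key = (h.evalue, -h.bitscore)
            if best is None or key < best:
                best = key
        if best is not None:
            ranking[m.gene_id] = (best[0], -best[1])
    return ranking


def _region_hsps(gene_id, hsps_by_query, scaffold, strand, lo, hi) -> list[Hsp]:
    return [h for h in hsps_by_query.get(gene_id, ())
            if h.scaffold_id == scaffold and h.strand == strand
            and h.subj_start < hi and h.subj_end > lo]


def _translation_clean(model: GeneModel, genome: Genome) -> bool:
    cds = model.coding_sequence(genome)
    if len(cds) % 3 != 0 or len(cds) < 6:
        return False
    if cds[:3] != START_CODON or cds[-3:] not in STOP_CODONS:
        return False
    for p in range(0, len(cds) - 3, 3):
        if cds[p:p + 3] in STOP_CODONS:
            return False
    return True


def annotate_genome(genome: Genome, pillars: list[Pillar],
                    ancestral: AncestralOrder, config: PipelineConfig,
                    trna: list[TrnaFeature],
                    hsps_by_query: dict[str, list[Hsp]] | None = None
                    ) -> AnnotationPass:
    """One full annotation pass over one (possibly edited) assembly."""
    index = SixFrameIndex(genome)
    if hsps_by_query is None:
        hsps_by_query = search_all(pillars, index,
                                   evalue_cutoff=config.evalue_cutoff)
    pillars_by_id = {p.pillar_id: p for p in pillars}
    ty_hsps = [h for p in pillars if p.is_ty
               for m in p.members for h in hsps_by_query.get(m.gene_id, ())]

    # --- locate candidate loci per pillar
    candidate_loci = []
    for pillar in pillars:
        bq = best_query_for_pillar(pillar, hsps_by_query, config.locus_gap)
        if bq is None:
            continue
        for locus in retain_secondary_loci(bq.loci):
            candidate_loci.append((pillar.pillar_id, locus))
    result = assign_loci(candidate_loci, ancestral, config.wgd)

    # --- build gene models per assignment
    target_group = config.target_group
    records: list[LocusAssignment] = []
    model_data: dict[int, dict] = {}
    detections: list[FsDetection] = []
    permissive_cache: dict[str, list[Hsp]] = {}
    key_counter = 0

    for a in result.assignments:
        base_pillar = a.pillar_id
        if base_pillar is not None and ".t" in base_pillar \
                and base_pillar not in pillars_by_id:
            base_pillar = base_pillar.split(".t")[0]
        if base_pillar is None or base_pillar not in pillars_by_id:
            # unresolved singleton: model from the overall best candidate
            ranking_pillars = [pillars_by_id[c] for c in a.candidates
                               if c in pillars_by_id]
            if not ranking_pillars:
                continue
            base_pillar = min(
                ranking_pillars,
                key=lambda p: min(
                    (h.evalue for m in p.members
                     for h in _region_hsps(m.gene_id, hsps_by_query,
                                           a.scaffold_id, a.strand,
                                           a.start, a.end)),
                    default=float("inf"))).pillar_id
        pillar = pillars_by_id[base_pillar]
        lo, hi = a.start - 500, a.end + 500
        ranking = _hit_ranking(pillar.members, hsps_by_query,
                               a.scaffold_id, lo, hi)
        if not ranking:
            continue
        ref = select_reference_gene(pillar, target_group, ranking)
        r_hsps = _region_hsps(ref.gene_id, hsps_by_query, a.scaffold_id,
                              a.strand, lo, hi)
        if not r_hsps:
            # the chosen reference did not pass the storage cutoff here:
            # search it permissively and keep hits at this locus only
            if ref.gene_id not in permissive_cache:
                permissive_cache[ref.gene_id] = index.search(
                    ref.protein, query_id=ref.gene_id, evalue_cutoff=1e3)
            r_hsps = [h for h in permissive_cache[ref.gene_id]
                      if h.scaffold_id == a.scaffold_id
                      and h.strand == a.strand
                      and h.subj_start < hi and h.subj_end > lo]
        if not r_hsps:
            continue
        view = StrandView(genome, a.scaffold_id, a.strand)
        vhsps = sorted((to_view(h, view) for h in r_hsps),
                       key=lambda h: (h.s_start, h.s_end))
        intron_allowed = any(
            m.has_intron for m in pillar.members_in_group(target_group)
        ) or (not pillar.members_in_group(target_group)
              and any(m.has_intron for m in pillar.members))
        calls = classify_chain(vhsps, view.seq, intron_allowed)
        groups = seed_coordinates(vhsps, calls)
        mean_non, mean_post = mean_group_lengths(pillar)
        mean_aa = (mean_post if target_group == POST_WGD else mean_non) \
            or mean_non or mean_post or len(ref.protein)
        max_up = int(9 * mean_aa)

        for group in groups:
            key_counter += 1
            data = _build_group_model(group, view, ref, intron_allowed,
                                      max_up, detections, key_counter)
            if data is None:
                continue
            fs, fe = view.to_forward(data["view_start"], data["view_end"])
            rec = LocusAssignment(
                scaffold_id=a.scaffold_id, start=fs, end=fe,
                strand=a.strand, candidates=list(a.candidates),
                pillar_id=a.pillar_id, evidence=a.evidence,
                evalue=a.evalue, payload=key_counter)
            records.append(rec)
            model_data[key_counter] = data

    # duplication-split tandem copies and copy-number caps act on the final
    # model records
    handle_tandem_duplicates(records, ancestral)
    enforce_copy_number(records, config.wgd)

    trna_spans: dict[str, list[tuple[int, int]]] = {}
    for t in trna:
        trna_spans.setdefault(t.scaffold_id, []).append((t.start, t.end))

    models: list[GeneModel] = []
    final_assignments: list[LocusAssignment] = []
    for rec in records:
        data = model_data[rec.payload]
        view = data["view"]
        exons_view = data["exons_view"]
        exons_fwd = [view.to_forward(s, e) for s, e in exons_view]
        if rec.strand == "-":
            exons_fwd = [(s, e) for s, e in exons_fwd]
        span_lo = min(s for s, _ in exons_fwd)
        span_hi = max(e for _, e in exons_fwd)
        if any(span_lo < te and ts < span_hi
               for ts, te in trna_spans.get(rec.scaffold_id, [])):
            continue  # protein-coding genes may not overlap tRNA genes
        model = GeneModel(
            model_id=f"m{rec.payload:05d}", scaffold_id=rec.scaffold_id,
            strand=rec.strand, exons=exons_fwd, pillar_id=rec.pillar_id,
            tags=set(data["tags"]),
            source_reference_gene=data["ref_gene"],
            frameshift_sites=data["fs_sites"],
            evidence=rec.evidence)
        if not model.tags and not _translation_clean(model, genome):
            model.tags.add(TAG_MANUAL_CHECK)
        models.append(model)
        rec.payload = model
        final_assignments.append(rec)

    return AnnotationPass(models=models, assignments=final_assignments,
                          detections=detections,
                          hsps_by_query=hsps_by_query, index=index,
                          ty_hsps=ty_hsps)


def _build_group_model(group, view: StrandView, ref, intron_allowed: bool,
                       max_up: int, detections: list[FsDetection],
                       key: int) -> dict | None:
    """Geometry and tags for one seed group, in view coordinates."""
    tags: set[str] = set()
    fs_sites: list[int] = []
    hsps = group.hsps
    seed_start, seed_end = group.start, group.end
    if seed_end - seed_start < 3:
        return None
    exons_view: list[tuple[int, int]] | None = None

    fs_calls = group.calls_of(KIND_FRAMESHIFT)
    intron_calls = group.calls_of(KIND_INTRON)

    if fs_calls:
        # leave the seed as one block; repair happens downstream
        tags.add(TAG_FS_UNCORRECTED)
        for call in fs_calls:
            h1, h2 = call.pair
            window = extract_fs_window(h1, h2, view)
            fwd_site = view.to_forward_point(call.frameshift_site)
            detections.append(FsDetection(
                scaffold_id=view.scaffold_id, strand=view.strand,
                h1=h1, h2=h2, window=window, fwd_site=fwd_site,
                model_key=key))
            fs_sites.append(fwd_site)
        start, s_tags = extend_start(seed_start, seed_end, view.seq, max_up)
        last = hsps[-1]
        end, e_tags = extend_stop(last.s_start, seed_end, view.seq)
        tags |= s_tags | e_tags
        exons_view = [(start, max(end, start + 3))]
    elif intron_calls:
        call = intron_calls[0]
        if len(intron_calls) > 1:
            tags.add(TAG_MANUAL_CHECK)  # a second intron cannot be modeled
        h1, h2 = call.pair
        ic = intron_between_hsps(h1, h2, view.seq,
                                 ref_protein_len=len(ref.protein))
        if ic is None:
            tags.add(TAG_MANUAL_CHECK)
            ext = extend_to_start_stop(seed_start, seed_end, view.seq, max_up)
            tags |= ext.tags
            exons_view = [(ext.start, ext.end)]
        else:
            start, s_tags = extend_start(seed_start, ic.donor, view.seq,
                                         max_up)
            exon1_len = ic.donor - start
            scan = ic.acceptor_end + ((3 - exon1_len % 3) % 3)
            end, e_tags = extend_stop(scan, h2.s_end, view.seq)
            tags |= s_tags | e_tags
            exons_view = [(start, ic.donor), (ic.acceptor_end, end)]
    elif len(hsps) == 1 and ref.has_intron and intron_allowed:
        # a single HSP for an intron-bearing reference: exon 1 may be too
        # small to have seeded a hit.  Build both the plain single-exon
        # model and the exon-1 + intron reconstruction, and keep whichever
        # protein length agrees better with the reference.
        ext = extend_to_start_stop(seed_start, seed_end, view.seq, max_up)
        plain_len = (ext.end - ext.start) // 3 - 1
        plain_diff = abs(plain_len - len(ref.protein))
        rec = recover_missing_exon1(hsps[0], view.seq, len(ref.protein))
        if rec is not None:
            (e1s, donor), ic = rec
            exon1_len = donor - e1s
            scan = ic.acceptor_end + ((3 - exon1_len % 3) % 3)
            end, e_tags = extend_stop(scan, hsps[0].s_end, view.seq)
            rec_len = (exon1_len + (end - ic.acceptor_end)) // 3 - 1
            if ext.tags or abs(rec_len - len(ref.protein)) < plain_diff:
                tags |= e_tags
                exons_view = [(e1s, donor), (ic.acceptor_end, end)]
        if exons_view is None:
            if plain_diff > 0.2 * len(ref.protein):
                tags.add(TAG_MANUAL_CHECK)
            tags |= ext.tags
            exons_view = [(ext.start, ext.end)]
    else:
        ext = extend_to_start_stop(seed_start, seed_end, view.seq, max_up)
        tags |= ext.tags
        exons_view = [(ext.start, ext.end)]

    exons_view = [(s, e) for s, e in exons_view if e - s > 0]
    if not exons_view:
        return None
    return {
        "view": view, "exons_view": exons_view, "tags": tags,
        "ref_gene": ref.gene_id, "fs_sites": fs_sites, "key": key,
        "view_start": min(s for s, _ in exons_view),
        "view_end": max(e for _, e in exons_view),
    }


# ---------------------------------------------------------------------------
# frameshift repair driver

def _candidate_reads(window: str, reads: dict[str, str]) -> dict[str, str]:
    """Cheap prefilter: a read can only vote if it contains one of the
    window's error-free flank k-mers (either orientation)."""
    from .core import revcomp
    probes = [window[:25], window[-25:]]
    probes += [revcomp(p) for p in probes]
    out = {}
    for rid, seq in reads.items():
        if any(p in seq for p in probes):
            out[rid] = seq
    return out


def repair_frameshifts(detections: list[FsDetection], genome: Genome,
                       reads: dict[str, str] | None, mode: str):
    """Propose corrections for every detection.

    Returns (corrections, uncorrected detections).  ``mode`` is "reads"
    (indel voting), "n-insert" (frame-restoring N placeholders) or "off"
    (report only).
    """
    corrections = []
    uncorrected = []
    for det in detections:
        view = StrandView(genome, det.scaffold_id, det.strand)
        if mode == "off":
            uncorrected.append(det)
            continue
        if mode == "n-insert":
            corrections.append(insert_placeholder_Ns(det.h1, det.h2, view))
            continue
        lo, hi = det.window
        window_seq = view.seq[lo:hi]
        votes = vote_indels(window_seq, _candidate_reads(window_seq, reads))
        ctx = FrameshiftContext(view=view, h1=det.h1, h2=det.h2,
                                window_start=lo)
        fix = apply_first_fixing_indel(votes, ctx)
        if fix is None:
            uncorrected.append(det)
        else:
            corrections.append(fix)
    # drop duplicate edits (the same site can be detected from two pillars)
    unique = {}
    for c in corrections:
        unique.setdefault((c.scaffold_id, c.position, c.op, c.bases), c)
    return list(unique.values()), uncorrected


# ---------------------------------------------------------------------------
# full run

@dataclass
class PipelineResult:
    models: list[GeneModel]
    assignments: list[LocusAssignment]
    corrections: list
    detections: list[FsDetection]
    genome: Genome
    out_dir: str
    stage_counts: dict[str, int] = field(default_factory=dict)
    link_matrix: object = None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    os.makedirs(config.out, exist_ok=True)
    genome = sio.read_genome(config.scaffolds)
    pillars, ancestral = sio.read_pillar_db(config.pillars)
    trna = sio.read_trna_track(config.trna_track) if config.trna_track else []
    reads = sio.read_reads(config.reads) if config.reads else None
    counts: dict[str, int] = {}

    link_matrix = None
    if config.contigs and reads:
        from .qc import contig_link_matrix, locate_contigs, map_read_pairs
        contigs = sio.read_fasta(config.contigs)
        layout = locate_contigs(genome, contigs)
        placements = map_read_pairs(reads, contigs, genome)
        link_matrix = contig_link_matrix(placements, layout)
        link_matrix.write_tsv(os.path.join(config.out, "contig_links.tsv"))
        link_matrix.write_flagged_report(
            os.path.join(config.out, "flagged_joins.tsv"))
        counts["reads_placed"] = placements.n_placed
        counts["weak_joins_flagged"] = len(link_matrix.flagged_joins)
        log.info("scaffold QC: %d reads placed, %d weak joins",
                 placements.n_placed, len(link_matrix.flagged_joins))

    hits = None
    if config.hits:
        parsed = parse_search_tabular(config.hits, config.evalue_cutoff)
        hits = {}
        for h in parsed:
            hits.setdefault(h.query_id, []).append(h)

    first = annotate_genome(genome, pillars, ancestral, config, trna,
                            hsps_by_query=hits)
    counts["initial_models"] = len(first.models)
    counts["frameshift_detections"] = len(first.detections)
    log.info("initial pass: %d models, %d frameshift detections",
             len(first.models), len(first.detections))

    corrections, uncorrected = repair_frameshifts(
        first.detections, genome, reads, config.fix_frameshifts)
    counts["corrections_applied"] = len(corrections)
    final = first
    if corrections:
        corrected_path = os.path.join(config.out, "scaffolds.corrected.fasta")
        edited, edited_pos = sio.apply_corrections(genome, corrections)
        sio.write_fasta(edited.sequences, corrected_path)
        genome = edited
        # external hits refer to the uncorrected assembly; re-search
        final = annotate_genome(genome, pillars, ancestral, config, trna)
        corrected_sites = {
            (c.scaffold_id, edited_pos[id(c)]) for c in corrections}
        for model in final.models:
            s, e = model.span
            for scaffold, pos in corrected_sites:
                if scaffold == model.scaffold_id and s - 2 <= pos <= e + 2:
                    model.tags.add(TAG_FS_CORRECTED)
                    model.tags.discard(TAG_FS_UNCORRECTED)
                    break
    counts["models_after_repair"] = len(final.models)

    # rescue passes never touch accepted models; they only add tagged ones
    pillars_by_id = {p.pillar_id: p for p in pillars}
    sdg = rescue.syntenic_gap_search(final.assignments, final.models,
                                     pillars_by_id, ancestral, genome, trna)
    counts["searchdogs_models"] = len(sdg)
    all_models = final.models + sdg
    orfs = rescue.find_large_orfs(genome, all_models, trna)
    counts["large_orf_models"] = len(orfs)
    all_models += orfs
    rescue.propagate_ty_flags(all_models, final.ty_hsps)

    _name_models(all_models, config.prefix)

    sio.write_gff3(all_models, trna,
                   os.path.join(config.out, "annotation.gff3"), genome)
    sio.write_tag_lists(all_models, os.path.join(config.out, "tags"))
    sio.write_assignment_table(final.assignments,
                               os.path.join(config.out, "assignments.tsv"))
    all_corr = corrections + [
        _detection_as_report(d) for d in uncorrected]
    sio.write_corrections_report(
        all_corr, os.path.join(config.out, "corrections.tsv"))
    for tag, fname in (("searchdogs", "searchdogs.txt"),
                       ("large-orf", "large_orfs.txt")):
        with open(os.path.join(config.out, fname), "w") as fh:
            ids = [m.model_id for m in all_models if tag in m.tags]
            fh.write("\n".join(ids) + ("\n" if ids else ""))
    with open(os.path.join(config.out, "summary.txt"), "w") as fh:
        for k, v in counts.items():
            fh.write(f"{k}\t{v}\n")
    return PipelineResult(models=all_models, assignments=final.assignments,
                          corrections=corrections,
                          detections=uncorrected, genome=genome,
                          out_dir=config.out, stage_counts=counts,
                          link_matrix=link_matrix)


def _detection_as_report(det: FsDetection):
    """Report-only record for a detected but uncorrected frameshift."""
    from .core import Correction
    return Correction(scaffold_id=det.scaffold_id, position=det.fwd_site,
                      op="insert", bases="N", read_support=0, applied=False)


def _name_models(models: list[GeneModel], prefix: str) -> None:
    """Gene names: prefix + scaffold ordinal + per-scaffold ordinal."""
    models.sort(key=lambda m: (m.scaffold_id, m.span[0]))
    scaffold_no: dict[str, int] = {}
    counters: dict[str, int] = {}
    for m in models:
        if m.scaffold_id not in scaffold_no:
            scaffold_no[m.scaffold_id] = len(scaffold_no) + 1
        counters[m.scaffold_id] = counters.get(m.scaffold_id, 0) + 1
        m.model_id = (f"{prefix}{scaffold_no[m.scaffold_id]}"
                      f".{counters[m.scaffold_id]:04d}")
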