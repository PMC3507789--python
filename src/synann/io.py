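"""Readers and writers for every on-disk format the pipeline touches.

Formats: FASTA (scaffolds, contigs, reads, proteins), the pillar-database
JSON dialect, GFF3 output (1-based inclusive coordinates), the corrections
report TSV, plain-text tag lists and the locus-assignment table.
"""

from __future__ import annotations

import json
import os
from typing import Iterable

from Bio import SeqIO

from .core import (
    AA_ALPHABET,
    AncestralOrder,
    Correction,
    GeneModel,
    Genome,
    Pillar,
    RefGene,
    SynannError,
    TrnaFeature,
)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into {id: uppercased sequence}.

    The id is the first whitespace-delimited token of the header.  Duplicate
    ids and empty files are errors.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in records:
            raise SynannError(f"{path}: duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise SynannError(f"{path}: no FASTA records found")
    return records


def read_genome(path: str) -> Genome:
    return Genome(read_fasta(path))


def read_reads(path: str) -> dict[str, str]:
    """Read primary reads (FASTA or FASTQ; qualities are ignored)."""
    fmt = "fasta"
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        fmt = "fastq"
    records: dict[str, str] = {}
    for rec in SeqIO.parse(path, fmt):
        if rec.id in records:
            raise SynannError(f"{path}: duplicate read id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise SynannError(f"{path}: no reads found")
    return records


def write_fasta(sequences: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Pillar database (JSON dialect)
#
# {
#   "pillars": [
#     {"pillar_id": ..., "ancestral_locus": ...,
#      "members": [{"gene_id": ..., "species": ..., "species_group": ...,
#                   "protein": ..., "exon_count": 1, "is_ty": false}, ...]},
#     ...],
#   "ancestral_order": {"chr1": [pillar ids in order], ...}
# }

def read_pillar_db(path: str) -> tuple[list[Pillar], AncestralOrder]:
    with open(path) as fh:
        doc = json.load(fh)
    pillars: list[Pillar] = []
    seen_genes: dict[str, str] = {}
    for pdoc in doc.get("pillars", []):
        members = [
            RefGene(
                gene_id=m["gene_id"],
                species=m["species"],
                species_group=m["species_group"],
                protein=m["protein"],
                exon_count=int(m.get("exon_count", 1)),
                is_ty=bool(m.get("is_ty", False)),
            )
            for m in pdoc["members"]
        ]
        pillar = Pillar(
            pillar_id=pdoc["pillar_id"],
            members=members,
            ancestral_locus=pdoc.get("ancestral_locus"),
        )
        for m in members:
            if m.gene_id in seen_genes:
                raise SynannError(
                    f"gene {m.gene_id!r} listed in two pillars "
                    f"({seen_genes[m.gene_id]!r} and {pillar.pillar_id!r})"
                )
            seen_genes[m.gene_id] = pillar.pillar_id
            bad = set(m.protein) - AA_ALPHABET
            if bad:  # RefGene validates too; double check at the file boundary
                raise SynannError(
                    f"gene {m.gene_id!r}: invalid residues {sorted(bad)}"
                )
        pillars.append(pillar)
    if not pillars:
        raise SynannError(f"{path}: pillar database is empty")
    order = AncestralOrder(
        {chrom: list(loci)
         for chrom, loci in doc.get("ancestral_order", {}).items()}
    )
    return pillars, order


def write_pillar_db(pillars: list[Pillar], order: AncestralOrder,
                    path: str) -> None:
    doc = {
        "pillars": [
            {
                "pillar_id": p.pillar_id,
                "ancestral_locus": p.ancestral_locus,
                "members": [
                    {
                        "gene_id": m.gene_id,
                        "species": m.species,
                        "species_group": m.species_group,
                        "protein": m.protein,
                        "exon_count": m.exon_count,
                        "is_ty": m.is_ty,
                    }
                    for m in p.members
                ],
            }
            for p in pillars
        ],
        "ancestral_order": order.ordered_loci,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# GFF3

def _gff_escape(value: str) -> str:
    return (value.replace("%", "%25").replace(";", "%3B")
            .replace("=", "%3D").replace(",", "%2C"))


def write_gff3(models: Iterable[GeneModel],
               trna_features: Iterable[TrnaFeature],
               path: str,
               genome: Genome,
               source: str = "synann") -> None:
    """Write gene models (gene/mRNA/CDS) and tRNA features as GFF3.

    Internal 0-based half-open coordinates are converted to GFF3's 1-based
    inclusive convention here and nowhere else.
    """
    lengths = genome.lengths
    lines: list[tuple[str, int, str]] = []
    for model in models:
        L = lengths.get(model.scaffold_id)
        if L is None:
            raise SynannError(
                f"model {model.model_id!r}: unknown scaffold "
                f"{model.scaffold_id!r}"
            )
        span_s, span_e = model.span
        if span_s < 0 or span_e > L:
            raise SynannError(
                f"model {model.model_id!r}: exon outside scaffold bounds"
            )
        attrs = [f"ID={_gff_escape(model.model_id)}"]
        if model.pillar_id is not None:
            attrs.append(f"pillar={_gff_escape(model.pillar_id)}")
        else:
            attrs.append("pillar=singleton")
        if model.source_reference_gene:
            attrs.append(
                f"reference_gene={_gff_escape(model.source_reference_gene)}")
        if model.evidence:
            attrs.append(f"evidence={_gff_escape(model.evidence)}")
        if model.tags:
            attrs.append("note=" + "%2C".join(sorted(model.tags)))
        gene_attrs = ";".join(attrs)
        mrna_id = model.model_id + ".mRNA"
        block = [
            "\t".join([model.scaffold_id, source, "gene", str(span_s + 1),
                       str(span_e), ".", model.strand, ".", gene_attrs]),
            "\t".join([model.scaffold_id, source, "mRNA", str(span_s + 1),
                       str(span_e), ".", model.strand, ".",
                       f"ID={_gff_escape(mrna_id)};"
                       f"Parent={_gff_escape(model.model_id)}"]),
        ]
        # CDS parts in genomic order; phase of the first coding exon is 0
        exons = sorted(model.exons)
        phase = 0
        ordered = exons if model.strand == "+" else exons[::-1]
        phases = {}
        for s, e in ordered:
            phases[(s, e)] = phase
            phase = (3 - ((e - s) - phase) % 3) % 3
        for i, (s, e) in enumerate(exons, 1):
            block.append("\t".join([
                model.scaffold_id, source, "CDS", str(s + 1), str(e), ".",
                model.strand, str(phases[(s, e)]),
                f"ID={_gff_escape(model.model_id)}.CDS;"
                f"Parent={_gff_escape(mrna_id)}",
            ]))
        lines.append((model.scaffold_id, span_s, "\n".join(block)))
    for t in trna_features:
        L = lengths.get(t.scaffold_id)
        if L is None or t.start < 0 or t.end > L:
            raise SynannError(f"tRNA {t.feature_id!r}: outside scaffold bounds")
        lines.append((t.scaffold_id, t.start, "\t".join([
            t.scaffold_id, source, "tRNA", str(t.start + 1), str(t.end), ".",
            t.strand, ".", f"ID={_gff_escape(t.feature_id)}"])))
    lines.sort(key=lambda x: (x[0], x[1]))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, L in sorted(lengths.items()):
            fh.write(f"##sequence-region {name} 1 {L}\n")
        for _, _, block in lines:
            fh.write(block + "\n")


def read_gff3_models(path: str) -> list[GeneModel]:
    """Parse gene models back out of a GFF3 file written by write_gff3 (or
    a fixture truth file using the same gene/mRNA/CDS layout)."""
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise SynannError(f"{path}: malformed GFF3 line: {line!r}")
            scaffold, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            adict = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    adict[k] = v.replace("%2C", ",").replace("%3B", ";") \
                                .replace("%3D", "=").replace("%25", "%")
            if ftype == "gene":
                pid = adict.get("pillar")
                genes[adict["ID"]] = {
                    "scaffold": scaffold, "strand": strand, "exons": [],
                    "pillar": None if pid in (None, "singleton") else pid,
                    "tags": set(adict.get("note", "").split(","))
                            - {""},
                    "ref": adict.get("reference_gene"),
                    "evidence": adict.get("evidence"),
                }
            elif ftype == "mRNA":
                mrna_parent[adict["ID"]] = adict["Parent"]
            elif ftype == "CDS":
                gene_id = mrna_parent.get(adict.get("Parent", ""),
                                          adict.get("Parent"))
                if gene_id in genes:
                    genes[gene_id]["exons"].append((int(start) - 1, int(end)))
    models = []
    for gid, g in genes.items():
        exons = sorted(g["exons"])
        if g["strand"] == "-":
            exons = exons[::-1]
        models.append(GeneModel(
            model_id=gid, scaffold_id=g["scaffold"], strand=g["strand"],
            exons=exons, pillar_id=g["pillar"], tags=g["tags"],
            source_reference_gene=g["ref"], evidence=g["evidence"],
        ))
    return models


def read_trna_track(path: str) -> list[TrnaFeature]:
    """Read a precomputed tRNA feature track (GFF3 lines of type tRNA)."""
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9 or cols[2] != "tRNA":
                continue
            attrs = dict(item.split("=", 1) for item in cols[8].split(";")
                         if "=" in item)
            feats.append(TrnaFeature(
                feature_id=attrs.get("ID", f"tRNA-{len(feats) + 1}"),
                scaffold_id=cols[0], start=int(cols[3]) - 1, end=int(cols[4]),
                strand=cols[6]))
    return feats


# ---------------------------------------------------------------------------
# Corrections

def apply_corrections(genome: Genome,
                      corrections: list[Correction]) -> tuple[Genome, dict]:
    """Apply assembly edits and return (edited genome, position map).

    The position map gives, for every applied correction, its coordinate in
    the *edited* assembly (downstream edits shift coordinates).  Corrections
    on one scaffold must not overlap; they are applied right-to-left so that
    earlier positions stay valid during editing.
    """
    by_scaffold: dict[str, list[Correction]] = {}
    for c in corrections:
        if not c.applied:
            continue
        if c.scaffold_id not in genome:
            raise SynannError(f"correction on unknown scaffold {c.scaffold_id!r}")
        by_scaffold.setdefault(c.scaffold_id, []).append(c)
    new_sequences = dict(genome.sequences)
    edited_positions: dict[int, int] = {}
    for scaffold, clist in by_scaffold.items():
        clist.sort(key=lambda c: c.position)
        for a, b in zip(clist, clist[1:]):
            if a.end > b.position:
                raise SynannError(
                    f"overlapping corrections on {scaffold!r} at "
                    f"{a.position} and {b.position}"
                )
        seq = new_sequences[scaffold]
        shift = 0
        for c in clist:
            edited_positions[id(c)] = c.position + shift
            shift += c.length_delta
        for c in reversed(clist):
            if c.op == "insert":
                seq = seq[:c.position] + c.bases + seq[c.position:]
            else:
                removed = seq[c.position:c.position + len(c.bases)]
                if removed != c.bases:
                    raise SynannError(
                        f"deletion at {scaffold}:{c.position} expected "
                        f"{c.bases!r}, found {removed!r}"
                    )
                seq = seq[:c.position] + seq[c.position + len(c.bases):]
        new_sequences[scaffold] = seq
    return Genome(new_sequences), edited_positions


def write_corrections_report(corrections: list[Correction], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold\tposition\top\tbases\tsupport\tapplied\n")
        for c in sorted(corrections, key=lambda c: (c.scaffold_id, c.position)):
            fh.write(f"{c.scaffold_id}\t{c.position}\t{c.op}\t{c.bases}\t"
                     f"{c.read_support}\t{int(c.applied)}\n")


def write_corrected_scaffolds(genome: Genome, corrections: list[Correction],
                              fasta_path: str,
                              report_path: str | None = None) -> Genome:
    """Apply corrections, write the edited scaffolds FASTA (and optionally
    the per-edit report), and return the edited genome."""
    edited, _ = apply_corrections(genome, corrections)
    write_fasta(edited.sequences, fasta_path)
    if report_path:
        write_corrections_report(corrections, report_path)
    return edited


# ---------------------------------------------------------------------------
# Tag lists and assignment table

def write_tag_lists(models: Iterable[GeneModel], outdir: str) -> dict[str, str]:
    """One plain-text file per tag, one gene id per line."""
    os.makedirs(outdir, exist_ok=True)
    by_tag: dict[str, list[str]] = {}
    for model in models:
        for tag in model.tags:
            by_tag.setdefault(tag, []).append(model.model_id)
    paths = {}
    for tag, ids in sorted(by_tag.items()):
        path = os.path.join(outdir, f"{tag}.txt")
        with open(path, "w") as fh:
            fh.write("\n".join(sorted(ids)) + "\n")
        paths[tag] = path
    return paths


def write_assignment_table(assignments, path: str) -> None:
    """TSV: locus coordinates, pillar (or 'singleton'), evidence, E-value."""
    with open(path, "w") as fh:
        fh.write("scaffold\tstart\tend\tstrand\tpillar\tevidence\tevalue\n")
        for a in assignments:
            pid = a.pillar_id if a.pillar_id is not None else "singleton"
            fh.write(f"{a.scaffold_id}\t{a.start}\t{a.end}\t{a.strand}\t"
                     f"{pid}\t{a.evidence}\t{a.evalue:.3g}\n")
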