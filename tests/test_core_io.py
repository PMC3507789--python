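"""Domain types, coordinate conventions and on-disk formats."""

import pytest

from synann.core import (
    Correction,
    GeneModel,
    Genome,
    Pillar,
    RefGene,
    StrandView,
    SynannError,
    revcomp,
)
from synann import io as sio
from synann.fixtures import FixtureSpec, build_reference_world


# --- FASTA -----------------------------------------------------------------

def test_read_fasta_parses_multiline_and_uppercases(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">a desc ignored\nac\ngt\n>b\nNNN\n")
    assert sio.read_fasta(str(p)) == {"a": "ACGT", "b": "NNN"}


def test_read_fasta_single_record(tmp_path):
    p = tmp_path / "s.fasta"
    p.write_text(">s1\nACGT\n")
    assert sio.read_fasta(str(p)) == {"s1": "ACGT"}


@pytest.mark.parametrize("content,msg", [
    (">a\nAC\n>a\nGT\n", "duplicate"),
    ("", "no FASTA"),
])
def test_read_fasta_rejects_bad_input(tmp_path, content, msg):
    p = tmp_path / "bad.fasta"
    p.write_text(content)
    with pytest.raises(SynannError, match=msg):
        sio.read_fasta(str(p))


def test_fasta_roundtrip_identity(tmp_path):
    seqs = {"s1": "ACGT" * 40, "s2": "N" * 10 + "ACGT"}
    path = tmp_path / "rt.fasta"
    sio.write_fasta(seqs, str(path))
    assert sio.read_fasta(str(path)) == seqs


# --- domain invariants -----------------------------------------------------

def test_genome_rejects_foreign_alphabet():
    with pytest.raises(SynannError, match="outside"):
        Genome({"s": "ACGU"})


def test_pillar_rejects_ty_mixing():
    a = RefGene("g1", "sp1", "post-WGD", "MKL")
    b = RefGene("g2", "sp2", "post-WGD", "MKL", is_ty=True)
    with pytest.raises(SynannError, match="Ty"):
        Pillar("p1", [a, b])


def test_refgene_intron_flag_follows_exon_count():
    assert not RefGene("g", "s", "non-WGD", "MK").has_intron
    assert RefGene("g", "s", "non-WGD", "MK", exon_count=2).has_intron
    with pytest.raises(SynannError):
        RefGene("g", "s", "other-group", "MK")


def test_gene_model_caps_exons_at_two():
    with pytest.raises(SynannError, match="two exons"):
        GeneModel("m", "s", "+", [(0, 3), (10, 13), (20, 23)])


def test_strand_view_roundtrip_and_revcomp():
    g = Genome({"s": "AACGTTTT"})
    v = StrandView(g, "s", "-")
    assert v.seq == revcomp("AACGTTTT") == "AAAACGTT"
    # interval mapping is an involution
    assert v.to_forward(*v.from_forward(2, 5)) == (2, 5)
    assert v.to_forward(0, 4) == (4, 8)


# --- pillar DB -------------------------------------------------------------

def test_pillar_db_roundtrip(tmp_path):
    world = build_reference_world(FixtureSpec(seed=7, n_pillars=5,
                                              intron_fraction=0.5))
    path = tmp_path / "db.json"
    sio.write_pillar_db(world.pillars, world.ancestral, str(path))
    pillars, order = sio.read_pillar_db(str(path))
    assert [p.pillar_id for p in pillars] == \
           [p.pillar_id for p in world.pillars]
    assert order.ordered_loci == world.ancestral.ordered_loci
    originals = {m.gene_id: m for p in world.pillars for m in p.members}
    for p in pillars:
        for m in p.members:
            assert m == originals[m.gene_id]


def test_pillar_db_minimal_and_duplicate_gene(tmp_path):
    doc = ('{"pillars": [{"pillar_id": "p1", "members": '
           '[{"gene_id": "g1", "species": "s", "species_group": "non-WGD",'
           ' "protein": "MKL"}]}], "ancestral_order": {"c": ["p1"]}}')
    path = tmp_path / "db.json"
    path.write_text(doc)
    pillars, order = sio.read_pillar_db(str(path))
    assert len(pillars) == 1 and order.position("p1") == ("c", 0)

    dup = doc.replace(']}], "ancestral_order"',
                      ']}, {"pillar_id": "p2", "members": '
                      '[{"gene_id": "g1", "species": "s", '
                      '"species_group": "non-WGD", "protein": "MKL"}]}], '
                      '"ancestral_order"')
    path.write_text(dup)
    with pytest.raises(SynannError, match="two pillars"):
        sio.read_pillar_db(str(path))


# --- GFF3 ------------------------------------------------------------------

def test_gff3_one_based_shift_and_two_exon_layout(tmp_path):
    genome = Genome({"s": "A" * 200})
    single = GeneModel("g1", "s", "+", [(10, 99)])
    double = GeneModel("g2", "s", "-", [(150, 180), (100, 140)],
                       tags={"manual-check"})
    path = tmp_path / "out.gff3"
    sio.write_gff3([single, double], [], str(path), genome)
    lines = [l.split("\t") for l in path.read_text().splitlines()
             if not l.startswith("#")]
    cds = [l for l in lines if l[2] == "CDS"]
    assert (cds[0][3], cds[0][4]) == ("11", "99")
    g2_cds = [l for l in cds if "g2" in l[8]]
    assert len(g2_cds) == 2
    assert {c[8].split("Parent=")[1] for c in g2_cds} == {"g2.mRNA"}
    gene2 = [l for l in lines if l[2] == "gene" and "ID=g2" in l[8]][0]
    assert "note=manual-check" in gene2[8]


def test_gff3_rejects_out_of_bounds_exon(tmp_path):
    genome = Genome({"s": "A" * 50})
    with pytest.raises(SynannError, match="bounds"):
        sio.write_gff3([GeneModel("g", "s", "+", [(10, 60)])], [],
                       str(tmp_path / "x.gff3"), genome)


def test_gff3_parses_with_gffutils_and_roundtrips(tmp_path, small_run):
    gffutils = pytest.importorskip("gffutils")
    _, _, target, result = small_run
    path = f"{result.out_dir}/annotation.gff3"
    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique")
    genes = list(db.features_of_type("gene"))
    assert len(genes) == len(result.models)
    lengths = target.genome.lengths
    for f in db.all_features():
        assert 1 <= f.start <= f.end <= lengths[f.seqid]
    # our own reader inverts our writer
    models = sio.read_gff3_models(path)
    assert {m.model_id for m in models} == {m.model_id for m in result.models}
    by_id = {m.model_id: m for m in models}
    for m in result.models:
        assert sorted(by_id[m.model_id].exons) == sorted(m.exons)
        assert by_id[m.model_id].tags == m.tags


# --- corrections -----------------------------------------------------------

def test_apply_corrections_insert_and_net_length():
    g = Genome({"s": "ACGTACGTAC"})
    ins = Correction("s", 5, "insert", "A", applied=True)
    edited, _ = sio.apply_corrections(g, [ins])
    assert len(edited.sequences["s"]) == 11
    assert edited.sequences["s"] == "ACGTAACGTAC"

    # delete one base then insert two bases downstream: net +1 length, and
    # the insert's original-coordinate position is preserved
    both = [Correction("s", 2, "delete", "G", applied=True),
            Correction("s", 6, "insert", "TT", applied=True)]
    edited, _ = sio.apply_corrections(g, both)
    assert len(edited.sequences["s"]) == 11
    assert edited.sequences["s"] == "ACTACTTGTAC"


def test_apply_corrections_touches_nothing_else():
    g = Genome({"s": "ACGTACGTACGT", "t": "AAAA"})
    c = Correction("s", 4, "insert", "GG", applied=True)
    edited, _ = sio.apply_corrections(g, [c])
    assert edited.sequences["t"] == "AAAA"
    assert edited.sequences["s"][:4] == g.sequences["s"][:4]
    assert edited.sequences["s"][6:] == g.sequences["s"][4:]


def test_apply_corrections_rejects_overlap():
    g = Genome({"s": "ACGTACGTAC"})
    cs = [Correction("s", 2, "delete", "GTA", applied=True),
          Correction("s", 4, "insert", "T", applied=True)]
    with pytest.raises(SynannError, match="overlap"):
        sio.apply_corrections(g, cs)


def test_write_corrected_scaffolds_emits_fasta_and_report(tmp_path):
    g = Genome({"s": "ACGTACGTAC"})
    cs = [Correction("s", 5, "insert", "A", read_support=4, applied=True),
          Correction("s", 9, "insert", "N", applied=False)]
    edited = sio.write_corrected_scaffolds(
        g, cs, str(tmp_path / "out.fasta"), str(tmp_path / "report.tsv"))
    assert edited.sequences["s"] == "ACGTAACGTAC"
    assert sio.read_fasta(str(tmp_path / "out.fasta"))["s"] == "ACGTAACGTAC"
    lines = (tmp_path / "report.tsv").read_text().splitlines()
    assert lines[0].split("\t") == ["scaffold", "position", "op", "bases",
                                    "support", "applied"]
    # every edit is listed, applied or not
    assert len(lines) == 3 and lines[1].endswith("1") and lines[2].endswith("0")
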