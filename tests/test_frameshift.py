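"""Frameshift window extraction, read voting and repair."""

import numpy as np
import pytest

from synann.core import Genome, StrandView, revcomp
from synann.frameshift import (
    FrameshiftContext,
    apply_first_fixing_indel,
    extract_fs_window,
    insert_placeholder_Ns,
    vote_indels,
    IndelVote,
)
from synann.fixtures import correction_reverses_edit
from synann.modeling import ViewHsp


def _view(seq):
    return StrandView(Genome({"s": seq}), "s", "+")


# --- window ---------------------------------------------------------------

def test_window_spans_50bp_flanks():
    view = _view("A" * 400)
    h1 = ViewHsp(1, 30, 10, 100)
    h2 = ViewHsp(31, 60, 130, 220)
    assert extract_fs_window(h1, h2, view) == (50, 180)


def test_window_clamps_at_scaffold_start():
    view = _view("A" * 400)
    h1 = ViewHsp(1, 10, 0, 30)
    h2 = ViewHsp(11, 30, 60, 150)
    lo, hi = extract_fs_window(h1, h2, view)
    assert lo == 0 and hi == 110


def test_window_length_arithmetic():
    view = _view("A" * 1000)
    h1 = ViewHsp(1, 30, 100, 300)
    h2 = ViewHsp(31, 60, 340, 500)
    lo, hi = extract_fs_window(h1, h2, view)
    assert hi - lo == (h2.s_start - h1.s_end) + 100


# --- voting ----------------------------------------------------------------

def _reads_with_indel(window, n_ins=5, n_del=2, seed=0):
    """Reads carrying an extra A at offset 17 (n_ins copies) or missing the
    base at offset 40 (n_del copies), each embedded in true flanking
    sequence so the whole window aligns."""
    rng = np.random.default_rng(seed)
    flank = lambda n: "".join(rng.choice(list("ACGT"), n))
    reads = {}
    with_ins = window[:17] + "A" + window[17:]
    for i in range(n_ins):
        reads[f"ins{i}/1"] = flank(30) + with_ins + flank(30)
    with_del = window[:40] + window[41:]
    for i in range(n_del):
        reads[f"del{i}/1"] = flank(30) + with_del + flank(30)
    return reads


def test_vote_counts_and_ordering():
    rng = np.random.default_rng(3)
    window = "".join(rng.choice(list("ACGT"), 120))
    votes = vote_indels(window, _reads_with_indel(window))
    assert len(votes) == 2
    top, second = votes
    assert (top.offset, top.op, top.bases, top.support) == (17, "insert",
                                                            "A", 5)
    assert (second.op, second.support) == ("delete", 2)


def test_single_read_indel_excluded():
    rng = np.random.default_rng(4)
    window = "".join(rng.choice(list("ACGT"), 120))
    votes = vote_indels(window, _reads_with_indel(window, n_ins=1, n_del=0))
    assert votes == []


def test_reverse_complement_reads_vote_too():
    rng = np.random.default_rng(5)
    window = "".join(rng.choice(list("ACGT"), 120))
    reads = {k: revcomp(v) for k, v in _reads_with_indel(window).items()}
    votes = vote_indels(window, reads)
    assert votes and votes[0].support == 5


def test_votes_reverse_planted_deletion():
    """Reads simulated from the true sequence out-vote a planted 1 bp
    deletion in the assembly."""
    rng = np.random.default_rng(6)
    true = "".join(rng.choice(list("ACGT"), 260))
    pos = 130
    assembly = true[:pos] + true[pos + 1:]       # assembly lost a base
    window = assembly[80:200]
    reads = {f"r{i}/1": true[i * 10:i * 10 + 160] for i in range(12)}
    votes = vote_indels(window, reads)
    assert votes
    top = votes[0]
    assert top.op == "insert"
    # reinserting the voted base restores the true sequence
    fixed = window[:top.offset] + top.bases + window[top.offset:]
    assert fixed in true


# --- applying fixes ---------------------------------------------------------

def _shifted_gene(seed=7):
    """A CDS with a 1 bp deletion; returns (edited seq, deletion pos, base)."""
    rng = np.random.default_rng(seed)
    from synann.fixtures import back_translate, random_protein
    protein = random_protein(rng, 120)
    cds = back_translate(protein, rng) + "TAA"
    flank = "".join(rng.choice(list("ACGT"), 100))
    true = flank + cds + flank
    pos = len(flank) + 180
    edited = true[:pos] + true[pos + 1:]
    return true, edited, pos


def test_apply_first_fixing_indel_restores_orf():
    true, edited, pos = _shifted_gene()
    view = _view(edited)
    gene_start = 100
    h1 = ViewHsp(1, 60, gene_start, gene_start + 180)
    h2 = ViewHsp(61, 120, pos + 2 - (pos + 2 - gene_start) % 3 + 2,
                 gene_start + 360)
    # h2 in shifted frame (one base removed downstream of pos)
    h2 = ViewHsp(61, 120, pos + 2, pos + 2 + 120)
    window_start = pos - 60
    window = edited[window_start:pos + 60]
    good = IndelVote(offset=pos - window_start, op="insert",
                     bases=true[pos], support=5)
    bad = IndelVote(offset=10, op="insert", bases="A", support=9)
    ctx = FrameshiftContext(view=view, h1=h1, h2=h2,
                            window_start=window_start)
    fix = apply_first_fixing_indel([bad, good], ctx)
    assert fix is not None
    assert fix.op == "insert" and fix.position == pos or \
        edited[:fix.position] + fix.bases + edited[fix.position:] == true


def test_apply_returns_none_when_all_fail():
    _, edited, pos = _shifted_gene(8)
    view = _view(edited)
    h1 = ViewHsp(1, 60, 100, 280)
    h2 = ViewHsp(61, 120, pos + 2, pos + 2 + 120)
    # neither candidate can restore the frame ((d + delta) % 3 != 0)
    bad = [IndelVote(offset=5, op="delete", bases=edited[pos - 55],
                     support=4),
           IndelVote(offset=6, op="insert", bases="AAA", support=3)]
    ctx = FrameshiftContext(view=view, h1=h1, h2=h2, window_start=pos - 60)
    assert apply_first_fixing_indel(bad, ctx) is None


# --- N placeholders ---------------------------------------------------------

@pytest.mark.parametrize("offset_nt,expect_n", [(1, 2), (2, 1)])
def test_placeholder_count_restores_frame(offset_nt, expect_n):
    """(3 - d) mod 3 N bases for a downstream frame offset d — checked for
    both possible offsets."""
    view = _view("A" * 600)
    h1 = ViewHsp(1, 50, 0, 150)
    h2 = ViewHsp(51, 100, 180 + offset_nt, 330 + offset_nt)
    c = insert_placeholder_Ns(h1, h2, view)
    assert c.bases == "N" * expect_n
    assert c.op == "insert" and c.applied
    # inserting k Ns at the site makes the downstream frame equal h1's
    assert (h2.frame + len(c.bases)) % 3 == h1.frame


def test_placeholder_modular_arithmetic_all_offsets():
    """Exhaustive oracle over frame offsets: k = (3 - d) mod 3 in {1, 2}."""
    view = _view("A" * 900)
    for d in (1, 2):
        for f1 in range(3):
            s1 = f1
            h1 = ViewHsp(1, 50, s1, s1 + 150)
            s2 = s1 + 150 + 30 + d
            h2 = ViewHsp(51, 100, s2, s2 + 150)
            c = insert_placeholder_Ns(h1, h2, view)
            assert len(c.bases) == (3 - d) % 3
    with pytest.raises(Exception, match="not frameshifted"):
        insert_placeholder_Ns(ViewHsp(1, 50, 0, 150),
                              ViewHsp(51, 100, 180, 330), view)


def test_placeholder_translates_with_x(frameshift_run):
    """On a real run with n-insert mode the patched gene translates through
    the junction with X at the N codon."""
    spec, world, target, injected, _, d = frameshift_run
    from synann.pipeline import PipelineConfig, run_pipeline
    from Bio.Seq import Seq

    config = PipelineConfig(
        scaffolds=str(d / "scaffolds.fasta"), pillars=str(d / "pillars.json"),
        fix_frameshifts="n-insert", out=str(d / "out_n"), wgd="non")
    result = run_pipeline(config)
    n_corr = [c for c in result.corrections if set(c.bases) == {"N"}]
    assert n_corr and all(len(c.bases) in (1, 2) for c in n_corr)
    patched = [m for m in result.models if "frameshift-corrected" in m.tags]
    assert patched
    saw_x = False
    for m in patched:
        cds = m.coding_sequence(result.genome)
        prot = str(Seq(cds[:len(cds) // 3 * 3]).translate())
        saw_x = saw_x or "X" in prot
    assert saw_x


# --- end-to-end reads repair -------------------------------------------------

def test_reads_repair_reverses_planted_edits(frameshift_run):
    spec, world, target, injected, result, _ = frameshift_run
    assert len(injected.truth_edits) == spec.frameshift_count
    reversed_n = sum(
        1 for te in injected.truth_edits
        if any(correction_reverses_edit(c, te, injected.edited_genome)
               for c in result.corrections))
    assert reversed_n == len(injected.truth_edits)
    corrected = [m for m in result.models if "frameshift-corrected" in m.tags]
    assert len(corrected) >= spec.frameshift_count * 0.9


def test_disabled_repair_still_reports(frameshift_run):
    """With repair off: no edits, but every site is still detected and the
    gene calls carry frameshift-uncorrected tags."""
    spec, world, target, injected, reads_result, d = frameshift_run
    from synann.pipeline import PipelineConfig, run_pipeline

    config = PipelineConfig(
        scaffolds=str(d / "scaffolds.fasta"), pillars=str(d / "pillars.json"),
        fix_frameshifts="off", out=str(d / "out_off"), wgd="non")
    result = run_pipeline(config)
    assert result.corrections == []
    assert len(result.detections) == spec.frameshift_count
    uncorrected = [m for m in result.models
                   if "frameshift-uncorrected" in m.tags]
    assert len(uncorrected) == spec.frameshift_count
    # same loci are called either way: per-scaffold model counts agree
    def counts(res):
        out = {}
        for m in res.models:
            out[m.scaffold_id] = out.get(m.scaffold_id, 0) + 1
        return out
    assert counts(result) == counts(reads_result)
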