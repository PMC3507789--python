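"""Translated search, hit retention and locus clustering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synann.core import Genome, Hsp, Pillar, RefGene, revcomp
from synann.fixtures import back_translate, random_protein
from synann.search import (
    Locus,
    SixFrameIndex,
    best_query_for_pillar,
    builtin_translated_search,
    cluster_hsps_to_loci,
    exponent10,
    parse_search_tabular,
    retain_secondary_loci,
    write_search_tabular,
)


def _locus(evalue, start=0, end=100, scaffold="s", strand="+"):
    h = Hsp("q", scaffold, 1, 30, start, end, strand, start % 3,
            evalue, 50 - math.log10(evalue + 1e-300))
    return Locus(scaffold, strand, start, end, [h])


def _embed(protein, seed, flank=3000, strand="+"):
    rng = np.random.default_rng(seed)
    cds = back_translate(protein, rng) + "TAA"
    bg = "".join(rng.choice(list("ACGT"), 2 * flank))
    seq = bg[:flank] + cds + bg[flank:]
    if strand == "-":
        seq = revcomp(seq)
    return Genome({"s1": seq}), flank, flank + len(cds)


# --- exponent rule ---------------------------------------------------------

def test_exponent10_floor_and_underflow():
    assert exponent10(1e-50) == -50
    assert exponent10(3e-7) == -7
    assert exponent10(9.99e-8) == -8
    assert exponent10(0.0) == -324
    assert exponent10(1.0) == 0


def test_retention_reproduces_printed_worked_example():
    """E_best = 1e-100: secondaries survive exactly below 1e-50."""
    primary = _locus(1e-100)
    kept = retain_secondary_loci([primary, _locus(1e-51, start=500, end=600)])
    assert len(kept) == 2
    kept = retain_secondary_loci([primary, _locus(1e-49, start=500, end=600)])
    assert len(kept) == 1
    # the boundary itself is excluded
    kept = retain_secondary_loci([primary, _locus(1e-50, start=500, end=600)])
    assert len(kept) == 1


def test_retention_truth_table_over_exponent_grid():
    """Both conjuncts (exponent < -30 AND < best/2) verified independently
    on a grid of exponent pairs."""
    for best_exp in range(-200, -1, 7):
        primary = _locus(10.0 ** best_exp)
        for sec_exp in range(best_exp + 1, 0, 3):
            kept = retain_secondary_loci(
                [primary, _locus(10.0 ** sec_exp, start=500, end=600)])
            expected = sec_exp < -30 and sec_exp < best_exp / 2
            assert (len(kept) == 2) == expected, (best_exp, sec_exp)


def test_retention_e_zero_always_passes():
    primary = _locus(0.0)
    second = _locus(0.0, start=500, end=600)
    assert len(retain_secondary_loci([primary, second])) == 2


@settings(max_examples=60, deadline=None, derandomize=True)
@given(best=st.integers(-300, -1), sec=st.integers(-323, -1),
       stronger=st.integers(1, 50))
def test_retention_monotone_in_secondary_strength(best, sec, stronger):
    """Lowering a secondary locus's E-value never flips kept -> dropped."""
    primary = _locus(10.0 ** best)
    weak = _locus(10.0 ** sec, start=500, end=600)
    strong = _locus(10.0 ** max(-323, sec - stronger), start=500, end=600)
    kept_weak = len(retain_secondary_loci([primary, weak])) == 2
    kept_strong = len(retain_secondary_loci([primary, strong])) == 2
    assert kept_strong or not kept_weak


# --- built-in engine -------------------------------------------------------

def test_builtin_search_finds_embedded_protein_both_strands():
    protein = random_protein(np.random.default_rng(0), 200)
    for strand in "+-":
        genome, lo, hi = _embed(protein, seed=1, strand=strand)
        hits = builtin_translated_search(protein, genome)
        assert hits, strand
        top = hits[0]
        assert top.strand == strand
        covered = top.query_end - top.query_start + 1
        assert covered >= 0.95 * len(protein)
        L = len(genome.sequences["s1"])
        want = (lo, hi - 3) if strand == "+" else (L - hi + 3, L - lo)
        assert top.subj_start <= want[0] + 30
        assert top.subj_end >= want[1] - 30


def test_builtin_search_null_on_random_genome():
    rng = np.random.default_rng(5)
    protein = random_protein(rng, 120)
    genome = Genome({"s1": "".join(rng.choice(list("ACGT"), 30000))})
    assert builtin_translated_search(protein, genome) == []


def test_builtin_search_self_hit_ranks_true_locus_first():
    rng = np.random.default_rng(9)
    for seed in range(3):
        protein = random_protein(np.random.default_rng(seed), 150)
        genome, lo, hi = _embed(protein, seed=seed + 10)
        hits = builtin_translated_search(protein, genome)
        assert hits[0].subj_start >= lo - 45 and hits[0].subj_end <= hi + 45
    _ = rng


def test_builtin_search_rejects_short_query():
    genome = Genome({"s": "ACGT" * 100})
    with pytest.raises(Exception, match="length"):
        builtin_translated_search("MKLLV", genome)


# --- tabular dialect -------------------------------------------------------

def test_parse_tabular_orientation_cutoff_and_errors(tmp_path):
    rows = [
        "q1\ts1\t100.0\t30\t0\t0\t1\t30\t11\t100\t1e-40\t120\t1",
        "q1\ts1\t100.0\t30\t0\t0\t1\t30\t200\t111\t1e-40\t120\t2",  # minus
        "q2\ts1\t100.0\t30\t0\t0\t1\t30\t11\t100\t1e-4\t40\t0",     # >= cutoff
    ]
    p = tmp_path / "hits.tsv"
    p.write_text("\n".join(rows) + "\n")
    hsps = parse_search_tabular(str(p), evalue_cutoff=1e-5)
    assert len(hsps) == 2
    plus, minus = hsps
    assert (plus.strand, plus.subj_start, plus.subj_end) == ("+", 10, 100)
    assert (minus.strand, minus.subj_start, minus.subj_end) == ("-", 110, 200)

    p.write_text("q1\ts1\tbroken\n")
    with pytest.raises(Exception, match=":1"):
        parse_search_tabular(str(p))

    p.write_text("")
    assert parse_search_tabular(str(p)) == []


def test_tabular_roundtrip_lossless(tmp_path):
    protein = random_protein(np.random.default_rng(3), 150)
    genome, _, _ = _embed(protein, seed=4)
    hsps = builtin_translated_search(protein, genome)
    path = tmp_path / "rt.tsv"
    write_search_tabular(hsps, str(path))
    back = parse_search_tabular(str(path), evalue_cutoff=1e-4)
    assert len(back) == len(hsps)
    for a, b in zip(hsps, back):
        assert (a.query_id, a.scaffold_id, a.query_start, a.query_end,
                a.subj_start, a.subj_end, a.strand, a.frame) == \
               (b.query_id, b.scaffold_id, b.query_start, b.query_end,
                b.subj_start, b.subj_end, b.strand, b.frame)
        assert b.evalue == pytest.approx(a.evalue, rel=1e-4)


# --- best query / clustering ----------------------------------------------

def _pillar_with_hits():
    members = [RefGene("gA", "s1", "post-WGD", "M" + "K" * 30),
               RefGene("gB", "s2", "post-WGD", "M" + "K" * 30),
               RefGene("gC", "s3", "non-WGD", "M" + "K" * 30)]
    return Pillar("p", members)


def test_best_query_argmin_and_score_tiebreak():
    pillar = _pillar_with_hits()
    mk = lambda q, e, bits: Hsp(q, "s", 1, 30, 0, 90, "+", 0, e, bits)
    hsps = {"gA": [mk("gA", 1e-80, 300)], "gB": [mk("gB", 1e-60, 250)]}
    assert best_query_for_pillar(pillar, hsps).gene_id == "gA"
    # equal E = 0.0: the higher bitscore wins
    hsps = {"gA": [mk("gA", 0.0, 700)], "gB": [mk("gB", 0.0, 900)]}
    assert best_query_for_pillar(pillar, hsps).gene_id == "gB"
    assert best_query_for_pillar(pillar, {}) is None


def test_cluster_hsps_gap_rule():
    mk = lambda s, e: Hsp("q", "sc", 1, 30, s, e, "+", s % 3, 1e-50, 100)
    near = [mk(0, 100), mk(300, 400)]
    assert len(cluster_hsps_to_loci(near, max_gap_nt=5000)) == 1
    far = [mk(0, 100), mk(50_300, 50_400)]
    assert len(cluster_hsps_to_loci(far, max_gap_nt=5000)) == 2


@pytest.mark.parametrize("spacing", [1000, 4999, 5001, 20000])
def test_cluster_boundary_sweep(spacing):
    mk = lambda s, e: Hsp("q", "sc", 1, 30, s, e, "+", s % 3, 1e-50, 100)
    loci = cluster_hsps_to_loci([mk(0, 100), mk(100 + spacing,
                                                200 + spacing)],
                                max_gap_nt=5000)
    assert len(loci) == (1 if spacing <= 5000 else 2)


def test_six_frame_index_consistent_with_wrapper():
    protein = random_protein(np.random.default_rng(11), 120)
    genome, _, _ = _embed(protein, seed=12)
    via_index = SixFrameIndex(genome).search(protein)
    via_wrapper = builtin_translated_search(protein, genome)
    assert [(h.subj_start, h.subj_end) for h in via_index] == \
           [(h.subj_start, h.subj_end) for h in via_wrapper]
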