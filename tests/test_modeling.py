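"""Reference-gene choice, HSP-pair classification, seeds and extension."""

import numpy as np
import pytest

from synann.core import Pillar, RefGene, START_CODON, STOP_CODONS
from synann.modeling import (
    KIND_DUPLICATION,
    KIND_FRAMESHIFT,
    KIND_INTRON,
    KIND_LOW_SIMILARITY,
    ViewHsp,
    classify_hsp_pair,
    extend_to_start_stop,
    mean_group_lengths,
    seed_coordinates,
    select_reference_gene,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


# --- reference gene choice -------------------------------------------------

def _pillar(*specs):
    members = [RefGene(gid, gid, group, "M" + "K" * 99, exon_count=ec)
               for gid, group, ec in specs]
    return Pillar("p", members)


def test_reference_prefers_same_group_intron_bearing():
    pillar = _pillar(("a", "post-WGD", 1), ("b", "post-WGD", 2))
    ranking = {"a": (1e-90, 300.0), "b": (1e-70, 250.0)}
    assert select_reference_gene(pillar, "post-WGD", ranking).gene_id == "b"


def test_reference_falls_back_across_groups():
    pillar = _pillar(("a", "non-WGD", 1), ("b", "non-WGD", 1))
    ranking = {"a": (1e-50, 200.0), "b": (1e-80, 300.0)}
    # post-WGD target with only non-WGD members: the overall best hit
    assert select_reference_gene(pillar, "post-WGD", ranking).gene_id == "b"


def test_reference_equal_evalue_uses_bitscore():
    pillar = _pillar(("a", "post-WGD", 1), ("b", "post-WGD", 1))
    ranking = {"a": (0.0, 700.0), "b": (0.0, 900.0)}
    assert select_reference_gene(pillar, "post-WGD", ranking).gene_id == "b"


def test_reference_requires_a_hit():
    pillar = _pillar(("a", "post-WGD", 1))
    with pytest.raises(Exception, match="no member"):
        select_reference_gene(pillar, "post-WGD", {})


def test_mean_group_lengths():
    members = [RefGene("a", "s", "non-WGD", "K" * 100),
               RefGene("b", "s", "non-WGD", "K" * 200),
               ]
    non, post = mean_group_lengths(Pillar("p", members))
    assert non == 150.0 and post is None


def test_mean_group_lengths_fixture_recomputation(small_world):
    _, world, _ = small_world
    pillar = world.pillars[0]
    non, post = mean_group_lengths(pillar)
    by_hand = [len(m.protein) for m in pillar.members
               if m.species_group == "non-WGD"]
    assert non == pytest.approx(sum(by_hand) / len(by_hand))


# --- pair classification ---------------------------------------------------

def _pair(q1, s1, q2, s2, frame_shift=0):
    """Two consecutive HSPs; coordinates chosen so frames come out of the
    subject starts."""
    h1 = ViewHsp(q1[0], q1[1], s1[0], s1[1])
    h2 = ViewHsp(q2[0], q2[1], s2[0], s2[1])
    return h1, h2


def _clean_seq(n):
    # AAA codons only: no stops anywhere in any frame
    return "A" * n


def test_classify_frameshift():
    # frames differ (301 % 3 == 1 vs 0), query gap 10 aa ~ subject gap 31 nt
    h1, h2 = _pair((1, 50), (0, 150), (61, 100), (181, 301))
    call = classify_hsp_pair(h1, h2, _clean_seq(400), intron_allowed=True)
    assert call.kind == KIND_FRAMESHIFT
    assert call.frame_offset == (h2.frame - h1.frame) % 3


def test_classify_low_similarity_needs_no_stop_between():
    h1, h2 = _pair((1, 50), (0, 150), (61, 100), (180, 300))
    seq = _clean_seq(400)
    call = classify_hsp_pair(h1, h2, seq, intron_allowed=True)
    assert call.kind == KIND_LOW_SIMILARITY
    # plant an in-frame stop between the HSPs: no longer mergeable
    stopped = seq[:159] + "TAA" + seq[162:]
    call = classify_hsp_pair(h1, h2, stopped, intron_allowed=True)
    assert call.kind == KIND_DUPLICATION


def test_classify_intron_gated_by_pillar_evidence():
    # query gap 0, subject gap 300
    h1, h2 = _pair((1, 50), (0, 150), (51, 100), (450, 600))
    call = classify_hsp_pair(h1, h2, _clean_seq(700), intron_allowed=True)
    assert call.kind == KIND_INTRON
    call = classify_hsp_pair(h1, h2, _clean_seq(700), intron_allowed=False)
    assert call.kind == KIND_DUPLICATION


def test_classify_large_query_overlap_is_duplication():
    h1, h2 = _pair((1, 100), (0, 300), (10, 100), (400, 673))
    call = classify_hsp_pair(h1, h2, _clean_seq(700), intron_allowed=True)
    assert call.kind == KIND_DUPLICATION


def _oracle(frame1, frame2, dq_aa, ds, stop_between, intron_allowed,
            gap_tol=30, intron_min=40, query_gap_max=30):
    """Literal transcription of the four-way decision tree."""
    dq = dq_aa * 3
    similar = abs(dq - ds) <= gap_tol
    if similar and frame1 != frame2:
        return KIND_FRAMESHIFT
    if similar and frame1 == frame2 and not stop_between:
        return KIND_LOW_SIMILARITY
    if (not similar and intron_allowed and dq <= query_gap_max
            and ds >= intron_min):
        return KIND_INTRON
    return KIND_DUPLICATION


def test_classifier_matches_bruteforce_grid():
    """Exhaustive discretized grid (> 10,000 cases) against a direct
    evaluation of the decision tree."""
    checked = 0
    for frame2 in range(3):
        for dq_aa in range(0, 40, 2):
            for ds in range(0, 400, 7):
                for stop_between in (False, True):
                    for intron_allowed in (False, True):
                        h1 = ViewHsp(1, 50, 0, 150)
                        s2 = 150 + ds
                        s2 += ((frame2 - s2) % 3)
                        ds_eff = s2 - 150
                        h2 = ViewHsp(50 + dq_aa + 1, 90 + dq_aa, s2, s2 + 120)
                        seq = _clean_seq(s2 + 150)
                        if stop_between and ds_eff >= 3:
                            # in-frame (frame 0) stop midway through the gap
                            p = 150 + (ds_eff // 2)
                            p -= p % 3
                            seq = seq[:p] + "TAA" + seq[p + 3:]
                            if p + 3 > s2:
                                continue
                        elif stop_between:
                            continue
                        call = classify_hsp_pair(h1, h2, seq,
                                                 intron_allowed)
                        want = _oracle(0, frame2 % 3, dq_aa, ds_eff,
                                       stop_between, intron_allowed)
                        assert call.kind == want, (frame2, dq_aa, ds_eff,
                                                   stop_between,
                                                   intron_allowed)
                        checked += 1
    assert checked >= 10_000


# --- seeds -----------------------------------------------------------------

def _call(kind, h1, h2):
    from synann.modeling import HspPairCall
    return HspPairCall(kind, (h1, h2))


def test_seed_single_hsp_is_its_own_extent():
    h = ViewHsp(1, 50, 12, 162)
    groups = seed_coordinates([h], [])
    assert len(groups) == 1
    assert (groups[0].start, groups[0].end) == (12, 162)


def test_seed_duplication_splits_models():
    h1, h2 = ViewHsp(1, 50, 0, 150), ViewHsp(1, 50, 300, 450)
    groups = seed_coordinates([h1, h2], [_call(KIND_DUPLICATION, h1, h2)])
    assert [(g.start, g.end) for g in groups] == [(0, 150), (300, 450)]


def test_seed_chain_merge_then_split():
    """(low-sim, duplication) over three HSPs -> {h1 u h2} and {h3}."""
    h1 = ViewHsp(1, 50, 0, 150)
    h2 = ViewHsp(55, 100, 165, 300)
    h3 = ViewHsp(1, 100, 600, 900)
    groups = seed_coordinates(
        [h1, h2, h3],
        [_call(KIND_LOW_SIMILARITY, h1, h2), _call(KIND_DUPLICATION, h2, h3)])
    assert [(g.start, g.end) for g in groups] == [(0, 300), (600, 900)]
    assert groups[0].calls[0].kind == KIND_LOW_SIMILARITY


def test_seed_chain_call_count_enumeration():
    """All 2^2 call patterns over a 3-HSP chain produce the expected
    grouping (merge unless duplication)."""
    hs = [ViewHsp(1, 50, i * 400, i * 400 + 150) for i in range(3)]
    for k1 in (KIND_LOW_SIMILARITY, KIND_DUPLICATION):
        for k2 in (KIND_LOW_SIMILARITY, KIND_DUPLICATION):
            groups = seed_coordinates(
                hs, [_call(k1, hs[0], hs[1]), _call(k2, hs[1], hs[2])])
            expected = 1 + (k1 == KIND_DUPLICATION) + (k2 == KIND_DUPLICATION)
            assert len(groups) == expected


# --- start/stop extension --------------------------------------------------

def test_extension_takes_furthest_atg_before_stop():
    #        TAA ATG ATG xxx(seed) ... TGA
    seq = "".join(["CCC", "TAA", "ATG", "ATG", "AAA" * 10, "TGA", "CCC"])
    seed = (12, 12 + 30)
    ext = extend_to_start_stop(*seed, seq)
    assert ext.start == 6          # the furthest ATG, past the nearer one
    assert seq[ext.end - 3:ext.end] == "TGA"
    assert not ext.tags


def test_extension_scans_45nt_inside_seed_after_stop():
    # stop immediately upstream; first ATG at seed offset +9
    seq = "".join(["TAA", "AAA" * 3, "ATG", "AAA" * 20, "TGA"])
    seed = (3, 3 + 66)
    ext = extend_to_start_stop(*seed, seq)
    assert ext.start == 12
    assert not ext.tags


def test_extension_manual_check_when_no_atg():
    seq = "".join(["TAA", "AAA" * 30, "TGA"])
    seed = (3, 3 + 90)
    ext = extend_to_start_stop(*seed, seq)
    assert ext.start == 3
    assert "manual-check" in ext.tags


def test_extension_trims_internal_stop():
    seq = "".join(["ATG", "AAA" * 5, "TAA", "AAA" * 5, "TGA"])
    seed = (0, len(seq))
    ext = extend_to_start_stop(*seed, seq)
    assert ext.end == 3 + 15 + 3   # trimmed to the internal stop


def test_extension_tags_n_run():
    seq = "".join(["ATG", "AAA" * 5]) + "N" * 30
    ext = extend_to_start_stop(0, 18, seq)
    assert "runs-into-N" in ext.tags


def test_extension_agrees_with_naive_scan_on_random_sequences():
    """Brute-force ATG/stop scan oracle over 1,000 random in-frame seeds."""
    rng = np.random.default_rng(42)

    def naive(seq, s, e):
        # start rule
        if seq[s:s + 3] != START_CODON:
            atgs, stop_hit = [], False
            p = s - 3
            while p >= 0:
                c = seq[p:p + 3]
                if c in STOP_CODONS or "N" in c:
                    stop_hit = True
                    break
                if c == START_CODON:
                    atgs.append(p)
                p -= 3
            if atgs:
                start = atgs[-1]
            else:
                start = None
                for off in range(0, min(45, e - s - 2), 3):
                    if seq[s + off:s + off + 3] == START_CODON:
                        start = s + off
                        break
                if start is None:
                    start = s
            _ = stop_hit
        else:
            start = s
        # stop rule: first in-frame stop at or after start
        end = None
        for p in range(start, len(seq) - 2, 3):
            if seq[p:p + 3] in STOP_CODONS:
                end = p + 3
                break
        return start, end

    for trial in range(1000):
        n = int(rng.integers(120, 400))
        seq = "".join(rng.choice(list("ACGT"), n))
        s = int(rng.integers(15, n - 60))
        s -= s % 3
        e = s + 3 * int(rng.integers(10, (n - s) // 3))
        ext = extend_to_start_stop(s, e, seq)
        want_start, want_end = naive(seq, s, e)
        assert ext.start == want_start, (trial, s, e)
        if want_end is not None and want_end >= e:
            assert ext.end == want_end
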