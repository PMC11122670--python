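"""Seed-and-extend RCM search against exhaustive oracles and planted truth."""

import numpy as np
import pytest

from circlocus.rcm import (RcmParams, RCMHit, alignment_text, annotate_repeats,
                           find_rcm, rank_candidates, score_ops)
from circlocus.seqs import random_dna, revcomp
from circlocus.synthetic import SyntheticLocusSpec, make_locus

SENSITIVE = RcmParams(word_size=5)
UNGAPPED = RcmParams(word_size=8, gapped=False, xdrop=1000, min_score=20,
                     min_length=8, overlap_frac=1.0)


def diagonal_oracle(up, down, p):
    """All maximal ungapped segments, brute force: for every exact word seed,
    the best-scoring segment containing it on its diagonal."""
    b = revcomp(down)
    k = p.word_size
    segments = set()
    for i in range(len(up) - k + 1):
        for j in range(len(b) - k + 1):
            if up[i:i + k] != b[j:j + k] or "N" in up[i:i + k]:
                continue
            lo = min(i, j)
            hi = min(len(up) - i, len(b) - j)
            col = [p.match if up[i + t] == b[j + t] else p.mismatch
                   for t in range(-lo, hi)]
            best = None
            for s in range(lo + 1):
                run = 0
                for e in range(s, len(col)):
                    run += col[e]
                    if e >= lo + k - 1:  # segment contains the seed word
                        cand = (run, e - s)  # ties -> longer, like the extender
                        if best is None or cand > best[0:2]:
                            best = (run, e - s, s, e)
            if best is None:
                continue
            score, _, s, e = best
            i0, j0 = i - lo + s, j - lo + s
            length = e - s + 1
            if score >= p.min_score and length >= p.min_length:
                segments.add((i0, i0 + length,
                              len(down) - (j0 + length), len(down) - j0, score))
    return segments


def test_perfect_inverted_repeat_yields_single_full_length_hit(rng):
    s = random_dna(rng, 300, 0.5)
    hits = find_rcm(s, revcomp(s))
    assert len(hits) == 1
    h = hits[0]
    assert (h.up_start, h.up_end) == (0, 300)
    assert (h.down_start, h.down_end) == (0, 300)
    assert h.identity == 1.0 and h.n_gaps == 0


def test_matches_diagonal_oracle_on_short_sequences(rng):
    """With prohibitive gap penalties the hit set equals the exhaustive
    per-seed maximal-segment oracle."""
    for trial in range(15):
        up = random_dna(rng, int(rng.integers(60, 200)), 0.5)
        down = random_dna(rng, int(rng.integers(60, 200)), 0.5)
        # embed a shared word so most trials actually contain seeds
        word = random_dna(rng, int(rng.integers(8, 16)), 0.5)
        iu = int(rng.integers(0, len(up) - len(word)))
        idn = int(rng.integers(0, len(down) - len(word)))
        up = up[:iu] + word + up[iu + len(word):]
        down = down[:idn] + revcomp(word) + down[idn + len(word):]
        hits = find_rcm(up, down, UNGAPPED)
        got = {(h.up_start, h.up_end, h.down_start, h.down_end, h.score)
               for h in hits}
        assert got == diagonal_oracle(up, down, UNGAPPED)


def test_planted_rcm_recovery_in_synthetic_bundle():
    spec = SyntheticLocusSpec(seed=5, planted_rcms=((150, 0.92, 300, 500),))
    b = make_locus(spec)
    hits = find_rcm(b.up_intron_seq(), b.down_intron_seq(), SENSITIVE)
    (truth,) = b.rcm_truth_local()
    cover = [h for h in hits
             if min(h.up_end, truth.up_interval[1]) - max(h.up_start, truth.up_interval[0])
             >= 0.9 * truth.length]
    assert cover, "planted RCM not recovered"
    assert abs(cover[0].identity - 0.92) <= 0.03


def test_symmetry_of_up_down_roles(bundle):
    a, b = bundle.up_intron_seq(), bundle.down_intron_seq()
    fwd = find_rcm(a, b, SENSITIVE)
    rev = find_rcm(b, a, SENSITIVE)
    key_f = {(h.up_start, h.up_end, h.down_start, h.down_end,
              h.length, round(h.identity, 6), h.score) for h in fwd}
    key_r = {(h.down_start, h.down_end, h.up_start, h.up_end,
              h.length, round(h.identity, 6), h.score) for h in rev}
    assert key_f == key_r


def test_score_recomputable_from_alignment_ops(bundle):
    params = SENSITIVE
    hits = find_rcm(bundle.up_intron_seq(), bundle.down_intron_seq(), params)
    assert hits
    for h in hits:
        assert score_ops(h.ops, params) == h.score
        # ops consume exactly the reported intervals
        up_cols = sum(op in "=XD" for op in h.ops)
        down_cols = sum(op in "=XI" for op in h.ops)
        assert up_cols == h.up_end - h.up_start
        assert down_cols == h.down_end - h.down_start


def test_gapped_alignment_bridges_an_insertion(rng):
    seg = random_dna(rng, 120, 0.5)
    up = random_dna(rng, 200, 0.5) + seg[:60] + "TTTAA" + seg[60:] + random_dna(rng, 200, 0.5)
    down = random_dna(rng, 150, 0.5) + revcomp(seg) + random_dna(rng, 150, 0.5)
    hits = find_rcm(up, down, RcmParams(word_size=11))
    assert hits
    top = hits[0]
    assert top.n_gaps >= 5 and top.length >= 120
    assert score_ops(top.ops, RcmParams()) == top.score


def test_hits_never_extend_outside_introns(rng):
    for _ in range(5):
        up = random_dna(rng, 400, 0.6)
        down = random_dna(rng, 300, 0.6)
        for h in find_rcm(up, down, RcmParams(word_size=5, min_score=12, min_length=6)):
            assert 0 <= h.up_start < h.up_end <= len(up)
            assert 0 <= h.down_start < h.down_end <= len(down)


def test_n_bases_never_seed():
    assert find_rcm("N" * 100, "N" * 100, RcmParams(word_size=5)) == []
    assert find_rcm("ACGT", "ACGTACGTACGT") == []  # shorter than the word


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        find_rcm("", "ACGT")


# --- repeat annotation -------------------------------------------------------


def _hit(us, ue, ds, de):
    return RCMHit(us, ue, ds, de, ue - us, 1.0, 2 * (ue - us), 0, "=" * (ue - us))


def test_repeat_overlap_boundaries():
    hits = [_hit(100, 250, 0, 150)]
    touching = annotate_repeats(hits, up_repeats=[(240, 400, "SINE1")])
    assert touching[0].repeat_overlap == ("SINE1",)
    half_open = annotate_repeats(hits, up_repeats=[(250, 400, "SINE1")])
    assert half_open[0].repeat_overlap == ()


def test_repeat_annotation_matches_all_pairs_oracle(rng):
    hits = [_hit(int(s), int(s) + 30, int(d), int(d) + 30)
            for s, d in rng.integers(0, 500, size=(25, 2))]
    reps_up = [(int(s), int(s + ln), f"u{i}") for i, (s, ln)
               in enumerate(rng.integers(1, 300, size=(15, 2)))]
    reps_dn = [(int(s), int(s + ln), f"d{i}") for i, (s, ln)
               in enumerate(rng.integers(1, 300, size=(15, 2)))]
    out = annotate_repeats(hits, reps_up, reps_dn)
    for h, o in zip(hits, out):
        expected = sorted(
            {n for s, e, n in reps_up if s < h.up_end and h.up_start < e} |
            {n for s, e, n in reps_dn if s < h.down_end and h.down_start < e})
        assert list(o.repeat_overlap) == expected


# --- ranking -----------------------------------------------------------------


def test_ranking_by_length_then_identity():
    hits = [_hit(0, 300, 0, 300), _hit(400, 520, 400, 520), _hit(600, 1400, 600, 1400)]
    assert [h.length for h in rank_candidates(hits, 3)] == [800, 300, 120]
    a = RCMHit(0, 100, 0, 100, 100, 0.88, 150, 0)
    b = RCMHit(200, 300, 200, 300, 100, 0.99, 180, 0)
    assert rank_candidates([a, b], 2)[0].identity == 0.99
    assert rank_candidates([a, b], 0) == []
    assert rank_candidates([a, b], -1) == []


def test_ranked_plants_follow_true_length_order(bundle):
    hits = find_rcm(bundle.up_intron_seq(), bundle.down_intron_seq(), SENSITIVE)
    top = rank_candidates(hits, 5)
    truth_lengths = sorted((t.length for t in bundle.rcm_truth), reverse=True)
    for h, tl in zip(top, truth_lengths):
        assert abs(h.length - tl) <= 0.1 * tl


def test_alignment_text_round_trip(bundle):
    hits = find_rcm(bundle.up_intron_seq(), bundle.down_intron_seq(), SENSITIVE)
    txt = alignment_text(hits[0], bundle.up_intron_seq(), bundle.down_intron_seq())
    lines = txt.splitlines()
    assert "identity=1.000" in lines[0]
    # reassembling the top line (gaps removed) gives the upstream segment
    seq = "".join(lines[i] for i in range(1, len(lines), 4)).replace("-", "")
    assert seq == bundle.up_intron_seq()[hits[0].up_start:hits[0].up_end]
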