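"""Locus model: overlap classification, SA/SD usage, mutation, cryptic
acceptors and RFLP genotyping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circlocus.io import parse_annotation
from circlocus.locus import (CircDef, LocusModel, TranscriptModel, apply_mutations,
                             classify_overlap, cryptic_acceptor_scan,
                             digest_fragments, exon_acceptor, rflp_digest,
                             shift_circ_acceptor, splice_site_usage)
from circlocus.synthetic import rflp_fixture


# --- parsing -----------------------------------------------------------------


def _write_gff(tmp_path, body):
    fa = tmp_path / "g.fa"
    fa.write_text(">chr1\n" + "A" * 500 + "\n")
    gff = tmp_path / "g.gff3"
    gff.write_text("##gff-version 3\n" + body)
    return gff, fa


def test_gff3_one_based_inclusive_converts_to_half_open(tmp_path):
    gff, fa = _write_gff(tmp_path, "\n".join([
        "chr1\t.\tgene\t101\t300\t.\t+\t.\tID=g1",
        "chr1\t.\tmRNA\t101\t300\t.\t+\t.\tID=t1;Parent=g1;canonical=1",
        "chr1\t.\texon\t101\t200\t.\t+\t.\tID=t1.e1;Parent=t1",
        "chr1\t.\texon\t251\t300\t.\t+\t.\tID=t1.e2;Parent=t1",
    ]) + "\n")
    locus = parse_annotation(gff, fa)
    assert locus.transcript("t1").exons == ((100, 200), (250, 300))
    assert locus.canonical_id == "t1"


def test_exon_outside_sequence_bounds_is_rejected(tmp_path):
    gff, fa = _write_gff(tmp_path, "\n".join([
        "chr1\t.\tgene\t1\t9000\t.\t+\t.\tID=g1",
        "chr1\t.\tmRNA\t1\t9000\t.\t+\t.\tID=t1;Parent=g1",
        "chr1\t.\texon\t1\t9000\t.\t+\t.\tID=t1.e1;Parent=t1",
    ]) + "\n")
    with pytest.raises(ValueError, match="outside sequence bounds"):
        parse_annotation(gff, fa)


def test_overlapping_exons_rejected():
    with pytest.raises(ValueError, match="overlapping"):
        TranscriptModel("t", ((0, 100), (50, 150)))


# --- overlap classification --------------------------------------------------


def _circ(chain, strand="+"):
    chain = tuple(chain)
    acc = chain[0][0] if strand == "+" else chain[0][1]
    don = chain[-1][1] if strand == "+" else chain[-1][0]
    return CircDef("chr1", strand, acc, don, chain)


def test_classify_overlap_three_ways():
    circ = _circ([(200, 250), (300, 350)])
    exonic = TranscriptModel("a", ((100, 150), (300, 350), (400, 450)))
    intronic = TranscriptModel("b", ((100, 150), (400, 450)))
    outside = TranscriptModel("c", ((400, 450), (500, 600)))
    assert classify_overlap(exonic, circ) == "exonic"
    assert classify_overlap(intronic, circ) == "intronic"
    assert classify_overlap(outside, circ) == "none"


def test_classify_overlap_rejects_antisense():
    circ = _circ([(200, 250)])
    with pytest.raises(ValueError, match="strand"):
        classify_overlap(TranscriptModel("a", ((0, 100),)), circ, strand="-")


def test_classify_overlap_monotone_under_exon_addition(rng):
    """Adding an exon can only move a transcript toward 'exonic'."""
    order = {"none": 0, "intronic": 1, "exonic": 2}
    circ = _circ([(200, 250), (300, 350)])
    grid = [(i * 60, i * 60 + 40) for i in range(10)]
    for _ in range(200):
        k = rng.integers(1, 9)
        chosen = sorted(rng.choice(10, size=k, replace=False))
        tx = TranscriptModel("t", tuple(grid[i] for i in chosen))
        before = classify_overlap(tx, circ)
        extra = int(rng.integers(10))
        if extra in chosen:
            continue
        tx2 = TranscriptModel("t", tuple(sorted(tx.exons + (grid[extra],))))
        assert order[classify_overlap(tx2, circ)] >= order[before]


# --- splice-site usage -------------------------------------------------------


def test_mimic_usage_rows_and_verdict(bundle):
    report = splice_site_usage(bundle.gene, bundle.circ)
    assert report.verdict == "SA_MUTABLE"
    rows = {r.transcript_id: r for r in report.rows}
    assert {t for t, r in rows.items() if r.uses_sa} == {"TX-202", "TX-203"}
    classes = [r.overlap_class for r in report.rows]
    assert classes.count("exonic") == 4 and classes.count("intronic") == 2
    assert not rows["TX-201"].uses_sa  # canonical keeps its splice sites


def test_verdict_when_protected_transcript_shares_sa(bundle):
    # TX-202 uses both the SA and the SD -> nothing circle-specific to cut
    assert splice_site_usage(bundle.gene, bundle.circ,
                             protected={"TX-202"}).verdict == "SA_SHARED"
    # TX-203 uses the SA but its chain ends at the circ donor -> SD is free
    assert splice_site_usage(bundle.gene, bundle.circ,
                             protected={"TX-203"}).verdict == "SD_MUTABLE"


def test_usage_agrees_with_brute_force_enumeration(rng):
    """Acceptor bookkeeping vs exhaustive (transcript, internal exon) pairs."""
    grid = [(100 + i * 100, 160 + i * 100) for i in range(12)]
    for _ in range(100):
        n_tx = int(rng.integers(2, 6))
        txs = []
        for t in range(n_tx):
            k = int(rng.integers(2, 7))
            chosen = sorted(rng.choice(12, size=k, replace=False))
            txs.append(TranscriptModel(f"t{t}", tuple(grid[i] for i in chosen),
                                       coding=bool(rng.integers(2)),
                                       is_canonical=(t == 0)))
        locus = LocusModel("g", "+", "chr1", tuple(txs), "t0")
        c0 = int(rng.integers(1, 10))
        circ = _circ([grid[c0]])
        report = splice_site_usage(locus, circ, protected=set())
        for row in report.rows:
            tx = locus.transcript(row.transcript_id)
            expected = any(exon_acceptor(e, "+") == circ.acceptor_pos
                           for e in tx.exons[1:])  # first exon = TSS, no acceptor
            assert row.uses_sa == expected


def test_strand_mirror_gives_identical_report(bundle, minus_bundle):
    plus = splice_site_usage(bundle.gene, bundle.circ)
    minus = splice_site_usage(minus_bundle.gene, minus_bundle.circ)
    assert plus.verdict == minus.verdict
    assert [(r.transcript_id, r.uses_sa, r.uses_sd, r.overlap_class)
            for r in plus.rows] == \
        [(r.transcript_id, r.uses_sa, r.uses_sd, r.overlap_class)
         for r in minus.rows]


# --- mutations ---------------------------------------------------------------


def test_apply_mutations_ag_to_tc(bundle):
    a = bundle.circ.acceptor_pos
    g = bundle.genome_sequence
    assert g[a - 2:a] == "AG"
    mutated = apply_mutations(g, [(a - 2, "AG", "TC")])
    assert mutated[a - 2:a] == "TC"
    assert g[a - 2:a] == "AG"  # input untouched
    assert sum(x != y for x, y in zip(g, mutated)) == 2


def test_apply_mutations_counts_and_identity():
    seq = "AAGGTTCC"
    assert apply_mutations(seq, []) == seq
    out = apply_mutations(seq, [(1, "AG", "TC"), (6, "C", "A")])
    assert sum(x != y for x, y in zip(seq, out)) == 3


def test_apply_mutations_errors():
    with pytest.raises(ValueError, match="position 2"):
        apply_mutations("AAAA", [(2, "G", "T")])
    with pytest.raises(ValueError, match="overlapping"):
        apply_mutations("AAGGTT", [(1, "AG", "TC"), (2, "GG", "CC")])


# --- cryptic acceptor --------------------------------------------------------


@pytest.mark.parametrize("exon,lost", [("AGGCTTTT", 2), ("CCAGTTTT", 4)])
def test_cryptic_scan_finds_first_downstream_ag(exon, lost):
    seq = "CCCCTC" + exon  # acceptor at 6, canonical AG already mutated to TC
    res = cryptic_acceptor_scan(seq, 6)
    assert res.found and res.lost_prefix_len == lost
    assert seq[res.cryptic_acceptor_pos - 2:res.cryptic_acceptor_pos] == "AG"


def test_cryptic_scan_no_ag_within_window():
    res = cryptic_acceptor_scan("CCCCTC" + "CT" * 40, 6, window=50)
    assert not res.found and res.status == "NO_CRYPTIC"


def test_cryptic_scan_requires_mutated_acceptor():
    with pytest.raises(ValueError, match="intact"):
        cryptic_acceptor_scan("CCCCAG" + "AGTT", 6)


def test_cryptic_scan_shifts_the_circle(bundle):
    from circlocus.circle import build_circle
    a = bundle.circ.acceptor_pos
    mutated = apply_mutations(bundle.genome_sequence, [(a - 2, "AG", "TC")])
    res = cryptic_acceptor_scan(mutated, a, circ=bundle.circ)
    assert res.lost_prefix_len == bundle.spec.cryptic_ag_offset + 2
    original = build_circle(bundle.genome_sequence, bundle.circ).sequence
    shifted = build_circle(mutated, res.shifted_circ).sequence
    assert shifted == original[res.lost_prefix_len:]


def test_cryptic_scan_strand_mirror(bundle, minus_bundle):
    a = bundle.circ.acceptor_pos
    res_plus = cryptic_acceptor_scan(
        apply_mutations(bundle.genome_sequence, [(a - 2, "AG", "TC")]), a)
    am = minus_bundle.circ.acceptor_pos
    g = minus_bundle.genome_sequence
    res_minus = cryptic_acceptor_scan(
        apply_mutations(g, [(am, g[am:am + 2], "GA")]), am, strand="-")
    assert res_minus.found
    assert res_minus.lost_prefix_len == res_plus.lost_prefix_len


def test_shift_circ_rejects_position_outside_first_exon(bundle):
    with pytest.raises(ValueError, match="outside"):
        shift_circ_acceptor(bundle.circ, bundle.circ.acceptor_pos - 5)


# --- RFLP --------------------------------------------------------------------


def test_single_dde_site_fragments():
    assert digest_fragments("AACTGAGTTT") == (3, 7)


def test_no_site_returns_whole_amplicon():
    assert digest_fragments("A" * 50) == (50,)


def test_rflp_genotyping_646bp_fixture():
    wt, cd = rflp_fixture(seed=4)
    assert len(wt) == len(cd) == 646
    res = rflp_digest(wt, alt_amplicon=cd)
    assert res.allele_fragments["WT"] == (646,)
    assert res.allele_fragments["ALT"] == (446, 200)
    assert res.discriminates
    assert set(res.het_fragments) == {646, 446, 200}


@settings(deadline=None, max_examples=60, derandomize=True)
@given(seq=st.text(alphabet="ACGT", min_size=1, max_size=300),
       motif=st.text(alphabet="ACGTRYSWKMN", min_size=2, max_size=6),
       offset=st.integers(0, 6))
def test_fragments_always_sum_to_amplicon_length(seq, motif, offset):
    if offset > len(motif):
        offset = len(motif)
    frags = digest_fragments(seq, motif, offset)
    assert sum(frags) == len(seq)
    assert all(f > 0 for f in frags)
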