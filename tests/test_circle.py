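"""Circular-topology analyses: junction windows, oligos, primers, ORFs,
seed sites — each checked against a linear-concatenation oracle."""

import re

import pytest
from Bio.Seq import Seq

from circlocus.circle import (CircleSeq, build_circle, check_divergent_primers,
                              compare_n_terminus, design_junction_shrna,
                              find_circular_orfs, junction_window, scan_seed_sites)
from circlocus.locus import CircDef
from circlocus.seqs import random_dna, revcomp


# --- circle construction -----------------------------------------------------


def test_two_exon_circle_concatenation():
    genome = "TT" + "AAA" + "GGGG" + "CCC" + "TT"
    circ = CircDef("c", "+", 2, 12, ((2, 5), (9, 12)))
    assert build_circle(genome, circ).sequence == "AAACCC"


def test_minus_strand_circle_is_reverse_complement():
    genome = "TTTTTTTTTT" + "AAAC" + "TTTT"
    circ = CircDef("c", "-", 14, 10, ((10, 14),))
    assert build_circle(genome, circ).sequence == "GTTT"


def test_mimic_circle_identical_on_both_strands(bundle, minus_bundle):
    plus = build_circle(bundle.genome_sequence, bundle.circ).sequence
    minus = build_circle(minus_bundle.genome_sequence, minus_bundle.circ).sequence
    assert plus == minus


def test_junction_window():
    c = CircleSeq("AAACCC")
    assert junction_window(c, 2) == "CCAA"
    assert junction_window(c, 6) == c.sequence + c.sequence  # full rotation
    with pytest.raises(ValueError):
        junction_window(c, 7)


def test_junction_window_absent_from_linear_mrnas(bundle):
    """The junction seam is circle-specific by construction."""
    circle = build_circle(bundle.genome_sequence, bundle.circ)
    win = junction_window(circle, 12)
    for seq in bundle.linear_mrnas().values():
        assert win not in seq


# --- shRNA design ------------------------------------------------------------


def test_exactly_ten_junction_spanning_frames(bundle):
    circle = build_circle(bundle.genome_sequence, bundle.circ)
    res = design_junction_shrna(circle, [], length=19, min_arm=5,
                                gc_range=(0.0, 1.0))
    assert len(res.oligos) == 19 - 2 * 5 + 1 == 10
    offsets = sorted(o.circ_offset - circle.length for o in res.oligos)
    assert offsets == list(range(-14, -4))
    for o in res.oligos:
        assert o.left_arm >= 5 and o.right_arm >= 5
        assert o.left_arm + o.right_arm == 19


def test_oligos_absent_from_all_linear_mrnas(bundle):
    circle = build_circle(bundle.genome_sequence, bundle.circ)
    mrnas = bundle.linear_mrnas()
    res = design_junction_shrna(circle, mrnas, gc_range=(0.0, 1.0))
    assert res.oligos
    for o in res.oligos:
        assert all(o.sequence not in m for m in mrnas.values())
        assert o.guide == revcomp(o.sequence)


def test_rejection_histogram_when_nothing_survives():
    circle = CircleSeq("ATGC" * 20)
    # the circle sequence itself as "linear mRNA" doubled kills every candidate
    res = design_junction_shrna(circle, [circle.sequence * 2])
    assert res.oligos == ()
    assert res.rejected["linear_match"] == 10


# --- divergent primers -------------------------------------------------------


def test_divergent_pair_amplifies_across_the_junction(rng):
    L = 300
    circ = CircleSeq(random_dna(rng, L, 0.5))
    fwd = circ.sequence[L - 70:L - 50]          # ends 50 nt before the junction
    rev = revcomp(circ.sequence[50:70])          # site starts 50 nt after it
    rep = check_divergent_primers(fwd, rev, circ, {})
    assert rep.status == "OK"
    assert rep.circ_amplicon_len == 100 + len(fwd) + len(rev)
    assert rep.linear_amplicon is None


def test_convergent_pair_in_one_exon_is_not_specific(bundle):
    circle = build_circle(bundle.genome_sequence, bundle.circ)
    s = circle.sequence
    fwd, rev = s[100:120], revcomp(s[150:170])
    rep = check_divergent_primers(fwd, rev, circle, bundle.linear_mrnas())
    assert rep.circ_amplicon_len == 70
    assert rep.linear_amplicon == 70  # exon chain is contiguous in TX-202
    assert rep.linear_hit is not None


def test_mismatched_primer_not_found(rng):
    circ = CircleSeq(random_dna(rng, 200, 0.5))
    fwd = circ.sequence[10:30]
    bad = fwd[:10] + ("A" if fwd[10] != "A" else "C") + fwd[11:]
    assert check_divergent_primers(bad, revcomp(circ.sequence[100:120]),
                                   circ).status == "NOT_FOUND"


# --- circular ORFs -----------------------------------------------------------


def test_junction_spanning_orf_on_tiny_circle():
    orfs = find_circular_orfs(CircleSeq("GAAATAGAT"))
    assert len(orfs) == 1
    o = orfs[0]
    assert (o.start, o.peptide, o.spans_junction, o.classification) == \
        (7, "MK", True, "terminated")
    assert o.laps == 1


def test_stopless_circle_reports_rolling_orf():
    orfs = find_circular_orfs(CircleSeq("ATGAAA"), max_laps=3)
    assert len(orfs) == 1
    o = orfs[0]
    assert o.classification == "rolling"
    assert o.laps == 3
    assert o.peptide == "MK"       # one period of the repeat
    assert o.spans_junction


def orf_oracle(seq, max_laps=3):
    """Translate a 3x concatenation linearly; terminated ORFs with laps <= 2."""
    s3 = seq * 3
    out = set()
    for p in range(len(seq)):
        if s3[p:p + 3] != "ATG":
            continue
        pep = ""
        q = p
        while q + 3 <= min(p + max_laps * len(seq), len(s3)):
            codon = s3[q:q + 3]
            if codon in ("TAA", "TAG", "TGA"):
                out.add((p, pep, q + 3 > len(seq)))
                break
            pep += str(Seq(codon).translate())
            q += 3
    return out


def test_orfs_match_concatenation_oracle(rng):
    for _ in range(40):
        seq = random_dna(rng, int(rng.integers(30, 400)), 0.5)
        got = {(o.start, o.peptide, o.spans_junction)
               for o in find_circular_orfs(CircleSeq(seq))
               if o.classification == "terminated" and o.laps <= 2}
        expected = orf_oracle(seq)
        assert got == expected


def test_orf_set_is_rotation_invariant(rng):
    seq = random_dna(rng, 120, 0.5)
    base = {((o.start) % 120, o.peptide, o.classification)
            for o in find_circular_orfs(CircleSeq(seq))}
    for r in (1, 17, 60):
        rot = seq[r:] + seq[:r]
        shifted = {((o.start + r) % 120, o.peptide, o.classification)
                   for o in find_circular_orfs(CircleSeq(rot))}
        assert shifted == base


def test_mimic_orf_is_the_engineered_95mer(bundle, mimic):
    circle = build_circle(bundle.genome_sequence, bundle.circ)
    spanning = [o for o in find_circular_orfs(circle)
                if o.classification == "terminated" and o.spans_junction]
    best = max(spanning, key=lambda o: o.aa_length)
    assert best.start == mimic.circ_orf_start == 58
    assert best.aa_length == 95
    assert best.peptide == mimic.circ_peptide


# --- N-terminus comparison ---------------------------------------------------


def test_compare_n_terminus():
    assert compare_n_terminus("MKLL", "MKAA") == (2, "LL")
    assert compare_n_terminus("MKLL", "MKLL") == (4, "")
    with pytest.raises(ValueError):
        compare_n_terminus("", "MK")


def test_mimic_shares_84_residues_with_linear_protein(bundle, mimic):
    from circlocus.pipeline import translate_first_orf
    linear = translate_first_orf(bundle.linear_mrnas()["TX-201"])
    shared, suffix = compare_n_terminus(mimic.circ_peptide, linear)
    assert shared == 84
    assert suffix == mimic.circ_peptide[84:]
    assert suffix.endswith("SPSRTFQS")


# --- miRNA seed sites --------------------------------------------------------


def seed_oracle(seq, mirnas, min_rank):
    """Regex scan of the doubled sequence, deduplicated mod length."""
    classes = ("6mer", "7mer-A1", "7mer-m8", "8mer")
    L = len(seq)
    s2 = seq + seq
    out = set()
    for mid, m in mirnas.items():
        core = revcomp(m[1:7])
        m8 = revcomp(m[7])
        for match in re.finditer("(?=" + core + ")", s2):
            p = match.start()
            if p >= L:
                continue
            has_m8 = s2[(p - 1) % L if p == 0 else p - 1] == m8
            has_a1 = s2[p + 6] == "A"
            cls = {(True, True): "8mer", (True, False): "7mer-m8",
                   (False, True): "7mer-A1", (False, False): "6mer"}[(has_m8, has_a1)]
            if classes.index(cls) >= min_rank:
                start = (p - 1) % L if has_m8 else p
                out.add((mid, cls, start))
    return out


def test_planted_8mer_site_spanning_junction(bundle):
    circle = build_circle(bundle.genome_sequence, bundle.circ)
    sites = scan_seed_sites(circle, bundle.mirnas)
    assert len(sites) == 1
    s = sites[0]
    assert s.mirna_id == "syn-miR-junction"
    assert s.site_class == "8mer"
    assert s.spans_junction
    # the site core is the reverse complement of miRNA positions 2-7
    mi = bundle.mirnas["syn-miR-junction"]
    assert revcomp(mi[1:7]) in s.site_sequence


def test_seed_scan_matches_doubling_oracle(rng):
    for _ in range(25):
        L = int(rng.integers(40, 200))
        seq = random_dna(rng, L, 0.5)
        mirnas = {f"m{i}": random_dna(rng, 22, 0.5) for i in range(3)}
        # plant one site across the junction for miRNA m0
        m0 = mirnas["m0"]
        site = revcomp(m0[1:7])
        seq = site[3:] + seq[4:L - 2] + site[:3]  # wraps the 0 boundary
        got = {(s.mirna_id, s.site_class, s.circle_position)
               for s in scan_seed_sites(CircleSeq(seq), mirnas, min_class="6mer")}
        assert got == seed_oracle(seq, mirnas, 0)


def test_min_class_filters_weak_sites(rng):
    seq = random_dna(rng, 100, 0.5)
    m = random_dna(rng, 22, 0.5)
    site6 = revcomp(m[1:7])
    circle = CircleSeq(site6 + "C" + seq[7:])  # no A1 anchor, no m8 pairing
    weak = scan_seed_sites(circle, {"m": m}, min_class="6mer")
    strong = scan_seed_sites(circle, {"m": m}, min_class="7mer-A1")
    assert any(s.circle_position == 0 and s.site_class == "6mer" for s in weak)
    assert all(s.circle_position != 0 for s in strong)
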