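"""Motif scanners and GC statistics: worked examples, brute-force oracle
equivalence, and strand/monotonicity properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles as orc
from nonbcov.motifs import (gc_percent, gc_summary, gc_track, nonb_annotation,
                            scan_dyad, scan_g4, scan_tandem)
from nonbcov.seq import merge_intervals, random_sequence, revcomp

dna = st.text(alphabet="ACGTN", min_size=1, max_size=200)


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seq,expected", [
    ("GGCC", 100.0),
    ("GATC", 50.0),
    ("GCNN", 100.0),   # ambiguity characters excluded from both sides
    ("ATAT", 0.0),
])
def test_gc_percent_examples(seq, expected):
    assert gc_percent(seq) == pytest.approx(expected)

def test_gc_percent_edge_cases():
    with pytest.raises(ValueError):
        gc_percent("")
    assert gc_percent("NNNN") is None

@settings(deadline=None, max_examples=100)
@given(dna)
def test_gc_percent_strand_symmetric(seq):
    assert gc_percent(seq) == gc_percent(revcomp(seq))

def test_gc_summary_examples():
    med, q1, q3 = gc_summary(["GGCC", "GATC", "ATAT"])
    assert med == pytest.approx(50.0)
    med, q1, q3 = gc_summary(["GATC"] * 100)
    assert (med, q1, q3) == (50.0, 50.0, 50.0)

def test_gc_summary_matches_sorted_quantiles(rng):
    seqs = [random_sequence(int(rng.integers(20, 200)),
                            float(rng.uniform(20, 80)), rng)
            for _ in range(57)]
    med, q1, q3 = gc_summary(seqs)
    values = [gc_percent(s) for s in seqs]
    assert med == pytest.approx(orc.quantile_sorted(values, 0.5))
    assert q1 == pytest.approx(orc.quantile_sorted(values, 0.25))
    assert q3 == pytest.approx(orc.quantile_sorted(values, 0.75))

def test_gc_track_length_invariant(rng):
    seq = random_sequence(1000, 50, rng)
    track = gc_track(seq, window=100, step=37)
    assert len(track.values) == (1000 - 100) // 37 + 1
    assert all(0 <= v <= 100 for v in track.values)


# ---------------------------------------------------------------------------
# G4
# ---------------------------------------------------------------------------

def test_g4_minimal_motif():
    hits = scan_g4("GGGAGGGAGGGAGGG")
    assert len(hits) == 1
    h = hits[0]
    assert (h.start, h.end, h.strand) == (0, 15, "+")
    assert h.detail["g_runs"] == [3, 3, 3, 3]
    assert h.detail["loops"] == [1, 1, 1]

def test_g4_minus_strand():
    hits = scan_g4("CCCTCCCTCCCTCCC", both_strands=True)
    assert len(hits) == 1
    assert (hits[0].start, hits[0].end, hits[0].strand) == (0, 15, "-")

def test_g4_no_hit():
    assert scan_g4("ACGTACGTACGT") == []

def test_g4_long_runs_absorbed_greedily():
    # a 5-G run is one run, never split to start the motif earlier
    hits = scan_g4("GGGGGAGGGAGGGAGGG")
    assert len(hits) == 1
    assert hits[0].detail["g_runs"] == [5, 3, 3, 3]

def test_g4_n_breaks_runs_and_loops():
    assert scan_g4("GGGNGGGAGGGAGGG") == []

def test_g4_matches_bruteforce(rng):
    for trial in range(60):
        length = int(rng.integers(100, 2001))
        seq = random_sequence(length, float(rng.uniform(40, 75)), rng)
        if trial % 3 == 0:  # plant a motif so the test is never vacuous
            seq = seq[:31] + "GGGAGGGGTAGGGAGGG" + seq[48:]
        got = [(h.start, h.end, tuple(h.detail["g_runs"]),
                tuple(h.detail["loops"])) for h in scan_g4(seq)]
        expected = [(a, b, tuple(r), tuple(l))
                    for a, b, r, l in orc.brute_g4(seq)]
        assert got == expected

def test_g4_strand_symmetry(rng):
    seq = random_sequence(800, 60, rng) + "GGGAGGGAGGGAGGG" + \
        random_sequence(200, 60, rng)
    n = len(seq)
    fwd = scan_g4(seq, both_strands=True)
    mirrored = sorted((n - h.end, n - h.start, "+-"[h.strand == "+"])
                      for h in fwd)
    rev = sorted((h.start, h.end, h.strand)
                 for h in scan_g4(revcomp(seq), both_strands=True))
    assert mirrored == rev


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------

def test_tandem_dinucleotide_run():
    hits = scan_tandem("ACACACACAC", min_len=10)
    assert len(hits) == 1
    h = hits[0]
    assert (h.start, h.end) == (0, 10)
    assert h.detail["period"] == 2 and h.detail["copies"] == 5

def test_tandem_nine_mer_unit():
    hits = scan_tandem("TTGGGGGGG" * 4)
    assert len(hits) == 1
    h = hits[0]
    assert (h.start, h.end) == (0, 36)
    assert h.detail == {"unit": "TTGGGGGGG", "period": 9, "copies": 4}

def test_tandem_nested_periods_suppressed():
    hits = scan_tandem("A" * 15)
    assert len(hits) == 1
    assert hits[0].detail["period"] == 1

def test_tandem_matches_bruteforce(rng):
    for trial in range(60):
        length = int(rng.integers(100, 2001))
        seq = random_sequence(length, float(rng.uniform(35, 70)), rng)
        if trial % 2 == 0:  # plant a tract
            unit = random_sequence(int(rng.integers(2, 10)), 55, rng)
            tract = unit * int(rng.integers(3, 8))
            if len(tract) < length:
                p = int(rng.integers(0, length - len(tract)))
                seq = seq[:p] + tract + seq[p + len(tract):]
        got = sorted((h.start, h.end, h.detail["period"], h.detail["copies"])
                     for h in scan_tandem(seq))
        assert got == orc.brute_tandem(seq)

def test_tandem_threshold_monotonicity(rng):
    seq = random_sequence(300, 50, rng) + "ACG" * 10 + "TTGGGGGGG" * 5 + \
        random_sequence(300, 50, rng)
    base = {(h.start, h.end) for h in scan_tandem(seq)}
    stricter_copies = {(h.start, h.end)
                       for h in scan_tandem(seq, min_copies=5)}
    stricter_len = {(h.start, h.end) for h in scan_tandem(seq, min_len=30)}
    assert stricter_copies <= base
    assert stricter_len <= base


# ---------------------------------------------------------------------------
# Dyads
# ---------------------------------------------------------------------------

def test_dyad_constructed_palindrome():
    hits = scan_dyad("GGGGGGAAAAACCCCCC")
    assert len(hits) == 1
    h = hits[0]
    assert h.detail == {"arm": 6, "loop": 5, "mismatches": 0}

def test_dyad_below_min_arm():
    assert scan_dyad("ACGTACGT") == []

def test_dyad_matches_bruteforce(rng):
    for trial in range(50):
        length = int(rng.integers(60, 400)) if trial % 10 else 1200
        seq = random_sequence(length, float(rng.uniform(35, 70)), rng)
        if trial % 2 == 0:  # plant an inverted repeat
            arm = random_sequence(int(rng.integers(6, 15)), 55, rng)
            loop = random_sequence(int(rng.integers(0, 20)), 45, rng)
            insert = arm + loop + revcomp(arm)
            if len(insert) < length:
                p = int(rng.integers(0, length - len(insert)))
                seq = seq[:p] + insert + seq[p + len(insert):]
        got = sorted((h.start, h.end, h.detail["arm"], h.detail["loop"],
                      h.detail["mismatches"]) for h in scan_dyad(seq))
        assert got == orc.brute_dyad(seq)

def test_dyad_min_arm_monotonicity(rng):
    arm = "GGATCCGTAC"
    seq = random_sequence(100, 50, rng) + arm + "AAAA" + revcomp(arm) + \
        random_sequence(100, 50, rng)
    base = {(h.start, h.end) for h in scan_dyad(seq, min_arm=6)}
    stricter = {(h.start, h.end) for h in scan_dyad(seq, min_arm=9)}
    assert stricter <= base


# ---------------------------------------------------------------------------
# Combined annotation
# ---------------------------------------------------------------------------

def test_nonb_annotation_no_hits():
    # verified free of G4/tandem/dyad determinants
    ann = nonb_annotation("GTATAGTATATGACCTCTGCCTTGTGCGGCTAATCGCCCT")
    assert ann.fraction == 0.0 and ann.hits == []

def test_merge_interval_arithmetic():
    assert merge_intervals([(0, 20), (10, 30)]) == [(0, 30)]
    assert sum(e - s for s, e in merge_intervals([(0, 20), (10, 30)])) == 30

def test_nonb_fraction_covers_tandem_introns():
    from nonbcov.simulate import generate_gene

    gene = generate_gene(2, 300, ["TTGGGGGGG"], [60], 60, 5)
    ann = nonb_annotation(gene.sequence)
    intron_len = 9 * 60
    assert ann.fraction >= intron_len / len(gene.sequence)
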