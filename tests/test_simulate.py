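"""Synthetic gene construction and structure-aware read simulation."""

import edlib
import numpy as np
import pytest

from nonbcov.seq import merge_intervals, overlap_length, revcomp
from nonbcov.simulate import (GeneArchitecture, SimulationTruth,
                              generate_gene, make_tandem_tract,
                              simulate_long_reads, simulate_short_reads)


# ---------------------------------------------------------------------------
# Tandem tract / gene construction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("motifs,copies,expected_len", [
    (["TTGGGGGGG"], [4], 36),
    (["AC"], [1], 2),
    (["CCCCCCCA", "TTGGGGGGG"], [3, 2], 8 * 3 + 9 * 2),
])
def test_make_tandem_tract_lengths(motifs, copies, expected_len):
    tract = make_tandem_tract(motifs, copies, 0)
    assert len(tract) == expected_len
    assert tract.startswith(motifs[0])

def test_make_tandem_tract_content():
    assert make_tandem_tract(["TTGGGGGGG"], [4], 0) == "TTGGGGGGG" * 4

@pytest.mark.parametrize("motifs,copies", [
    (["A"], [3]),          # motif too short
    (["ACGT"], [0]),       # zero copies
    (["ACGT", "AC"], [1]),  # length mismatch
])
def test_make_tandem_tract_invalid(motifs, copies):
    with pytest.raises(ValueError):
        make_tandem_tract(motifs, copies, 0)

def test_generate_gene_length_and_layout():
    gene = generate_gene(2, 300, ["TTGGGGGGG"], [150], 65, 42)
    assert len(gene) == 2 * 300 + 9 * 150
    assert gene.exons == [(0, 300), (1650, 1950)]
    assert gene.introns == [(300, 1650)]

def test_generate_gene_exon_gc_within_tolerance():
    gene = generate_gene(1, 500, [], [], 65, 3)
    assert gene.gc_percent == pytest.approx(65.0, abs=2.0)

def test_generate_gene_single_exon_degenerate():
    gene = generate_gene(1, 100, [], [], 50, 1)
    assert len(gene) == 100 and gene.exons == [(0, 100)]

def test_generate_gene_deterministic():
    a = generate_gene(2, 300, ["TTGGGGGGG"], [50], 65, 9)
    b = generate_gene(2, 300, ["TTGGGGGGG"], [50], 65, 9)
    assert a.sequence == b.sequence and a.nonb_truth == b.nonb_truth

def test_generate_gene_invalid_parameters():
    with pytest.raises(ValueError):
        generate_gene(2, 300, ["TTGGGGGGG"], [50], 120, 0)
    with pytest.raises(ValueError):
        generate_gene(2, 300, [], [], 50, 0)  # multi-exon needs introns
    with pytest.raises(ValueError):
        generate_gene(0, 300, [], [], 50, 0)

def test_gene_truth_covers_the_tandem_intron():
    gene = generate_gene(2, 200, ["TTGGGGGGG"], [80], 60, 4)
    tandem = merge_intervals([(s, e) for s, e, k in gene.nonb_truth
                              if k == "tandem"])
    intron = gene.introns[0]
    covered = sum(overlap_length(intron, t) for t in tandem)
    assert covered == intron[1] - intron[0]

def test_gene_architecture_validation():
    with pytest.raises(ValueError):
        GeneArchitecture("x", "ACGT", exons=[(0, 10)])
    with pytest.raises(ValueError):
        GeneArchitecture("x", "ACGTACGT", exons=[(0, 4), (2, 6)])


# ---------------------------------------------------------------------------
# Long-read simulation
# ---------------------------------------------------------------------------

def _flat_truth(d=0.0, err=0.0, depth=20.0, seed=0):
    return SimulationTruth(depletion=d, error_rate=err, nonb_error_rate=err,
                           depth=depth, seed=seed)

def test_long_reads_deterministic():
    gene = generate_gene(2, 200, ["TTGGGGGGG"], [40], 60, 1)
    t = _flat_truth(d=0.5, err=0.1, seed=5)
    a = simulate_long_reads(gene, t, read_len_mean=200, flank=200)
    b = simulate_long_reads(gene, t, read_len_mean=200, flank=200)
    assert [r.sequence for r in a.reads] == [r.sequence for r in b.reads]
    assert a.sequence == b.sequence

def test_long_reads_conservation_and_bounds():
    gene = generate_gene(2, 200, ["TTGGGGGGG"], [40], 60, 2)
    ds = simulate_long_reads(gene, _flat_truth(d=0.7, seed=3),
                             read_len_mean=200, flank=200)
    assert len(ds.reads) <= ds.n_candidates
    L = len(ds.sequence)
    for r in ds.reads:
        s, e = r.true_source
        assert 0 <= s < e <= L

def test_long_reads_mean_depth_near_nominal():
    # depletion off, motif-free source: depth within +-15% of 20
    gene = generate_gene(1, 2000, [], [], 50, 6)
    ds = simulate_long_reads(gene, _flat_truth(depth=20, seed=8),
                             read_len_mean=300, flank=300)
    total = sum(e - s for s, e in (r.true_source for r in ds.reads))
    mean_depth = total / len(ds.sequence)
    assert mean_depth == pytest.approx(20, rel=0.15)

def test_long_reads_depletion_acceptance_over_tract():
    # reads well inside a large tandem tract are kept at ~(1-d) of naive
    gene = generate_gene(2, 150, ["TTGGGGGGG"], [500], 55, 10)  # 4.5 kb tract
    d = 0.9
    ds = simulate_long_reads(gene, _flat_truth(d=d, depth=60, seed=12),
                             read_len_mean=300, read_len_sigma=0.05,
                             flank=500)
    tract = merge_intervals([iv for iv in ds.nonb_intervals])
    # measure realised depth over the tract interior from sampling truth
    s0, e0 = tract[0][0] + 300, tract[-1][1] - 300
    covered = sum(overlap_length(r.true_source, (s0, e0)) for r in ds.reads)
    realised = covered / (e0 - s0)
    assert realised == pytest.approx(60 * (1 - d), rel=0.25)

def test_long_reads_error_injection_measured_by_alignment():
    gene = generate_gene(1, 3000, [], [], 60, 21)
    ds = simulate_long_reads(gene, _flat_truth(err=0.12, depth=6, seed=13),
                             read_len_mean=500, flank=0)
    assert len(ds.reads) >= 30
    rates, recorded = [], []
    for r in ds.reads[:50]:
        frag = ds.sequence[r.true_source[0]:r.true_source[1]]
        seq = r.sequence if r.strand == "+" else revcomp(r.sequence)
        res = edlib.align(seq, frag, mode="NW")
        rates.append(res["editDistance"] / (r.true_source[1] - r.true_source[0]))
        recorded.append(r.true_error_rate)
    assert np.mean(rates) == pytest.approx(0.12, abs=0.02)
    # recorded truth must agree with what alignment recovers
    assert np.mean(recorded) == pytest.approx(np.mean(rates), abs=0.01)

def test_truth_parameter_validation():
    with pytest.raises(ValueError):
        SimulationTruth(depletion=1.5)
    with pytest.raises(ValueError):
        SimulationTruth(depth=0)
    with pytest.raises(ValueError):
        SimulationTruth(error_rate=-0.1)


# ---------------------------------------------------------------------------
# Short-read simulation
# ---------------------------------------------------------------------------

def test_short_reads_total_dropout_removes_tract_reads():
    gene = generate_gene(2, 150, ["TTGGGGGGG"], [200], 55, 14)
    ds = simulate_short_reads(gene, read_len=100, depth=10, dropout=1.0,
                              seed=2, flank=300)
    tract = merge_intervals(ds.nonb_intervals)
    for r in ds.reads:
        inside = any(t[0] <= r.true_source[0] and r.true_source[1] <= t[1]
                     for t in tract)
        assert not inside

def test_short_reads_no_dropout_uniform():
    gene = generate_gene(2, 150, ["TTGGGGGGG"], [200], 55, 15)
    ds = simulate_short_reads(gene, read_len=100, depth=30, dropout=0.0,
                              seed=3, flank=300)
    tract = merge_intervals(ds.nonb_intervals)
    covered = sum(overlap_length(r.true_source, t)
                  for r in ds.reads for t in tract)
    tract_len = sum(e - s for s, e in tract)
    assert covered / tract_len == pytest.approx(30, rel=0.15)

def test_short_reads_dropout_expectation():
    # 95% dropout over a ~3 kb tandem intron at 20X leaves ~1X behind
    gene = generate_gene(2, 150, ["TTGGGGGGG"], [333], 55, 16)
    ds = simulate_short_reads(gene, read_len=150, depth=20, dropout=0.95,
                              seed=4, flank=500)
    tract = merge_intervals(ds.nonb_intervals)
    s0, e0 = tract[0][0] + 150, tract[-1][1] - 150  # interior only
    covered = sum(overlap_length(r.true_source, (s0, e0)) for r in ds.reads)
    realised = covered / (e0 - s0)
    assert realised == pytest.approx(20 * 0.05, rel=0.5)
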