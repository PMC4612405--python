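"""Transmission-rate estimator algebra, RPKM, distributions, correlations."""

import numpy as np
import pytest

from graftmrna.genes import GeneIndex, GeneModel
from graftmrna.mobility import DONOR, ClassifiedRead
from graftmrna.rates import (RULE_ALL_PERFECT, TransmissionEstimate, _ReadIndex,
                             count_gene_reads, estimate_rates, gene_rate, rate_at_snp,
                             rate_correlation, rate_distribution, rpkm,
                             transmission_window)

from conftest import make_alignment, make_snp


def donor_reads(n, snp_pos, read_length=10, start=None, label=DONOR, offset=0):
    """n donor-origin reads covering snp_pos, contained in its window."""
    out = []
    for i in range(n):
        s = (snp_pos - read_length // 2 if start is None else start) + (i + offset) % 3
        snp = make_snp(snp_pos, "T", "G", gene_id="g1")
        aln = make_alignment(read_id=f"r{i}", start=s, seq="A" * read_length)
        out.append(ClassifiedRead(aln, ((snp, "T"),), label, True))
    return out


SNP = make_snp(100, "T", "G", gene_id="g1")


def test_window_geometry_and_clipping():
    start, end, clipped = transmission_window(SNP, 101)
    assert (start, end, clipped) == (1, 100 + 101, True)  # start clipped to 1
    snp = make_snp(500, "T", "G")
    assert transmission_window(snp, 101) == (399, 601, False)
    assert transmission_window(snp, 101, contig_length=550) == (399, 550, True)


def test_rate_direct_arithmetic():
    """10 receptor vs 990 donor reads in million-read libraries: rate 0.01."""
    rec = rate_at_snp(SNP, _ReadIndex(donor_reads(990, 100)),
                      _ReadIndex(donor_reads(10, 100)), 10, 1_000_000, 1_000_000)
    assert rec.count_receptor == 10 and rec.count_donor == 990
    assert rec.rate == pytest.approx(10 / (10 + 990))


def test_rate_symmetric_counts_give_half():
    idx = _ReadIndex(donor_reads(25, 100))
    rec = rate_at_snp(SNP, idx, idx, 10, 500_000, 500_000)
    assert rec.rate == pytest.approx(0.5)


def test_rate_zero_receptor_reads_is_zero():
    rec = rate_at_snp(SNP, _ReadIndex(donor_reads(40, 100)), _ReadIndex([]), 10,
                      1_000_000, 1_000_000)
    assert rec.rate == 0.0


def test_rate_undefined_when_both_sides_empty():
    assert rate_at_snp(SNP, _ReadIndex([]), _ReadIndex([]), 10, 1000, 1000) is None


def test_rate_invariant_under_joint_library_scaling():
    d, r = _ReadIndex(donor_reads(300, 100)), _ReadIndex(donor_reads(30, 100))
    base = rate_at_snp(SNP, d, r, 10, 1_000_000, 2_000_000).rate
    scaled = rate_at_snp(SNP, d, r, 10, 5_000_000, 10_000_000).rate
    assert base == pytest.approx(scaled)


def test_doubling_receptor_total_strictly_decreases_rate():
    d, r = _ReadIndex(donor_reads(300, 100)), _ReadIndex(donor_reads(30, 100))
    base = rate_at_snp(SNP, d, r, 10, 1_000_000, 1_000_000).rate
    doubled = rate_at_snp(SNP, d, r, 10, 1_000_000, 2_000_000).rate
    assert doubled < base


def test_window_containment_excludes_straddling_reads():
    # read that covers the SNP but extends past the window edge is excluded
    snp = make_snp(100, "T", "G", gene_id="g1")
    inside = donor_reads(1, 100, read_length=10)
    straddling = [
        ClassifiedRead(make_alignment(read_id="x", start=95, seq="A" * 30),
                       ((snp, "T"),), DONOR, True)
    ]
    idx_in = _ReadIndex(inside)
    idx_out = _ReadIndex(straddling)
    # window of +/- 10 around 100 is [90, 110]; the 30-bp read ends at 124
    assert idx_in.count_in_window("chr1", 100, 90, 110) == 1
    assert idx_out.count_in_window("chr1", 100, 90, 110) == 0


def test_all_perfect_rule_counts_non_covering_reads():
    # a perfectly matching read inside the window but not covering the SNP
    snp = make_snp(100, "T", "G", gene_id="g1")
    aln = make_alignment(read_id="y", start=104, seq="A" * 5)
    cr = ClassifiedRead(aln, (), "uninformative", True)
    assert _ReadIndex([cr]).count_in_window("chr1", 100, 90, 110) == 0
    assert _ReadIndex([cr], RULE_ALL_PERFECT).count_in_window("chr1", 100, 90, 110) == 1


def _rec(rate, count_donor=30, count_receptor=3):
    from graftmrna.rates import SnpRateRecord
    return SnpRateRecord("chr1", 100, "g1", 90, 110, False, count_receptor,
                         count_donor, 1.0, 1.0, rate)


def test_gene_rate_is_unweighted_mean():
    est = gene_rate("g1", "d", [_rec(0.2), _rec(0.4)])
    assert est.gene_rate == pytest.approx(0.3)
    single = gene_rate("g1", "d", [_rec(0.7)])
    assert single.gene_rate == pytest.approx(0.7)


def test_reportable_requires_fifty_donor_reads():
    below = gene_rate("g1", "d", [_rec(0.2, count_donor=49)])
    at = gene_rate("g1", "d", [_rec(0.2, count_donor=50)])
    summed = gene_rate("g1", "d", [_rec(0.2, count_donor=30), _rec(0.4, count_donor=20)])
    assert not below.reportable and at.reportable and summed.reportable


def test_gene_rate_empty_input_errors():
    with pytest.raises(ValueError):
        gene_rate("g1", "d", [])


# ---------------------------------------------------------------- RPKM

def test_rpkm_unit_case():
    df = rpkm({"g1": 1000, "g2": 0}, {"g1": 1000, "g2": 500}, 1_000_000)
    vals = dict(zip(df["gene_id"], df["rpkm"]))
    assert vals["g1"] == pytest.approx(1000.0)
    assert vals["g2"] == 0.0


def test_rpkm_zero_library_total_errors():
    with pytest.raises(ValueError):
        rpkm({"g1": 0}, {"g1": 100}, 0)


def test_gene_counts_match_brute_force_recount(rng):
    genes = [GeneModel(f"g{i}", "chr1", 1 + 50 * i, 30 + 50 * i) for i in range(5)]
    gi = GeneIndex(genes)
    alns = [
        make_alignment(read_id=f"r{i}", start=int(rng.integers(1, 260)),
                       seq="A" * int(rng.integers(5, 20)))
        for i in range(200)
    ]
    counts = count_gene_reads(alns, gi)
    for g in genes:
        brute = sum(1 for a in alns if a.start <= g.end and a.end >= g.start)
        assert counts[g.gene_id] == brute


def test_rpkm_matches_brute_force_on_random_instances(rng):
    for _ in range(20):
        n = int(rng.integers(1, 8))
        counts = {f"g{i}": int(rng.integers(0, 5000)) for i in range(n)}
        lengths = {f"g{i}": int(rng.integers(100, 5000)) for i in range(n)}
        total = int(rng.integers(1, 10_000_000))
        df = rpkm(counts, lengths, total)
        for row in df.itertuples():
            expected = counts[row.gene_id] * 1e9 / (lengths[row.gene_id] * total)
            assert row.rpkm == pytest.approx(expected)


# ---------------------------------------------------------------- summaries

def _estimate(gene, rate, donor=100, reportable=None):
    return TransmissionEstimate(
        gene_id=gene, direction="d", snp_rates=(), gene_rate=rate,
        donor_read_total=donor,
        reportable=(donor >= 50) if reportable is None else reportable)


def test_distribution_all_rates_below_threshold():
    dist = rate_distribution([_estimate(f"g{i}", 0.005) for i in range(10)])
    assert dist.frac_below_0_01 == 1.0
    assert dist.frac_below_0_001 == 0.0
    assert dist.frac_above_0_5 == 0.0
    assert dist.histogram["n_genes"].sum() == 10


def test_distribution_empty_input():
    dist = rate_distribution([])
    assert dist.n == 0 and dist.frac_below_0_01 is None
    assert dist.histogram.empty and dist.scatter.empty


def test_distribution_excludes_non_reportable():
    ests = [_estimate("g1", 0.2), _estimate("g2", 0.9, donor=10)]
    assert rate_distribution(ests).n == 1


def test_correlation_identical_sets():
    ests = [_estimate(f"g{i}", r) for i, r in enumerate([0.1, 0.2, 0.4, 0.05])]
    res = rate_correlation(ests, ests)
    assert res.r == pytest.approx(1.0) and res.n_shared == 4
    assert res.large_difference_genes == ()


def test_correlation_constant_input_is_degenerate():
    a = [_estimate(f"g{i}", 0.3) for i in range(5)]
    b = [_estimate(f"g{i}", 0.1 * (i + 1)) for i in range(5)]
    res = rate_correlation(a, b)
    assert res.degenerate and res.r is None


def test_correlation_insufficient_overlap():
    a = [_estimate("g1", 0.1), _estimate("g2", 0.2)]
    with pytest.raises(ValueError, match="insufficient overlap"):
        rate_correlation(a, a)


def test_correlation_flags_five_fold_differences():
    a = [_estimate("g1", 0.5), _estimate("g2", 0.05), _estimate("g3", 0.2),
         _estimate("g4", 0.1)]
    b = [_estimate("g1", 0.1), _estimate("g2", 0.05), _estimate("g3", 0.21),
         _estimate("g4", 0.0)]
    res = rate_correlation(a, b)
    assert set(res.large_difference_genes) == {"g1", "g4"}
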