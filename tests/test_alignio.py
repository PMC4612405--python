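"""Alignment ingestion, built-in aligner, duplicate removal, pileups."""

from collections import Counter

import numpy as np
import pytest

from graftmrna._dna import random_dna, revcomp
from graftmrna.alignio import (Alignment, default_max_edit, pileup, read_sam,
                               remove_duplicates, write_sam)
from graftmrna.alignio import TestAligner as BuiltinAligner
from graftmrna.alignio import test_align as builtin_align
from graftmrna.simulate import Read, SimConfig, make_genotype_pair, simulate_genomic_reads

from conftest import make_alignment


# ---------------------------------------------------------------- SAM round trip

def _sam_text(records, ref_len=50):
    header = f"@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:{ref_len}\n"
    return header + "".join(records)


def test_read_sam_filters_and_mismatches(tmp_path):
    ref = {"chr1": "ACGTACGTACGTACGTACGT" + "A" * 30}
    rec_mapped = "r1\t0\tchr1\t3\t60\t4M\t*\t0\t0\tGTAC\tIIII\tNM:i:0\tMD:Z:4\n"
    rec_unmapped = "r2\t4\t*\t0\t0\t*\t*\t0\t0\tAAAA\tIIII\n"
    rec_secondary = "r3\t256\tchr1\t3\t60\t4M\t*\t0\t0\tGTAC\tIIII\tNM:i:0\tMD:Z:4\n"
    # one mismatch at reference position 5 (A -> C)
    rec_mm = "r4\t16\tchr1\t5\t60\t4M\t*\t0\t0\tCCGT\tIIII\tNM:i:1\tMD:Z:0A3\n"
    path = tmp_path / "in.sam"
    path.write_text(_sam_text([rec_mapped, rec_unmapped, rec_secondary, rec_mm]))

    alns = list(read_sam(path, library="L"))
    assert [a.read_id for a in alns] == ["r1", "r4"]
    assert alns[0].mismatches == ()
    assert alns[1].mismatches == ((5, "C"),)
    assert alns[1].strand == "-"
    # recomputation against the reference agrees with the MD tag
    alns_ref = list(read_sam(path, library="L", reference=ref))
    assert [a.mismatches for a in alns_ref] == [a.mismatches for a in alns]


def test_read_sam_without_md_or_reference_errors(tmp_path):
    rec = "r1\t0\tchr1\t3\t60\t4M\t*\t0\t0\tGTAC\tIIII\tNM:i:2\n"
    path = tmp_path / "in.sam"
    path.write_text(_sam_text([rec]))
    with pytest.raises(ValueError, match="cannot derive mismatches"):
        list(read_sam(path))


def test_write_sam_read_sam_round_trip(tmp_path, rng):
    ref = {"chr1": random_dna(rng, 2000)}
    cfg = SimConfig(genome_length=2000, n_genes=1, exon_length=150, read_length=101,
                    genomic_depth=3, error_rate=0.01, duplication_rate=0.0, seed=5)
    reads = simulate_genomic_reads(ref["chr1"], cfg, rng=rng)
    alns = builtin_align(reads, ref, library="L")
    path = tmp_path / "out.sam"
    write_sam(alns, ref, path)
    back = list(read_sam(path, library="L"))
    assert [(a.read_id, a.contig, a.start, a.strand, a.seq, a.mismatches) for a in back] \
        == [(a.read_id, a.contig, a.start, a.strand, a.seq, a.mismatches) for a in alns]


# ---------------------------------------------------------------- test aligner

def test_default_max_edit_follows_read_length():
    assert default_max_edit(101) == 4
    assert default_max_edit(151) == 6


def test_error_free_read_aligns_at_true_origin(rng):
    genome = random_dna(rng, 5000)
    start0 = 1234
    read = Read("r", genome[start0:start0 + 101])
    (aln,) = builtin_align([read], genome)
    assert (aln.start, aln.strand, aln.mismatches) == (start0 + 1, "+", ())


def test_reverse_strand_read_recovered(rng):
    genome = random_dna(rng, 5000)
    read = Read("r", revcomp(genome[300:401]))
    (aln,) = builtin_align([read], genome)
    assert (aln.start, aln.strand) == (301, "-")
    assert aln.seq == genome[300:401]  # stored as forward-strand sequence


def test_repeated_sequence_is_dropped(rng):
    """A read matching two genome locations has no single best hit."""
    unit = random_dna(rng, 120)
    genome = unit + random_dna(rng, 500) + unit + random_dna(rng, 500)
    read = Read("r", unit[:101])
    assert builtin_align([read], genome) == []


def test_read_beyond_max_edit_is_unaligned(rng):
    genome = random_dna(rng, 5000)
    seq = list(genome[100:201])
    positions = rng.choice(101, size=5, replace=False)  # 5 > max_edit = 4
    for p in positions:
        seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
    assert builtin_align([Read("r", "".join(seq))], genome, max_edit=4) == []
    assert len(builtin_align([Read("r", "".join(seq))], genome, max_edit=5)) == 1


def test_alignment_recovery_rate_on_error_free_simulation():
    """>= 99.9% of unique-sequence error-free reads map to their true origin."""
    cfg = SimConfig(genome_length=60_000, n_genes=5, error_rate=0.0,
                    duplication_rate=0.0, genomic_depth=5, snp_density=2.0, seed=13)
    pair = make_genotype_pair(cfg)
    hap = pair.haplotypes["A"]
    rng = np.random.default_rng(13)
    reads = simulate_genomic_reads(hap, cfg, rng=rng)
    seq_counts = Counter(min(r.seq, revcomp(r.seq)) for r in reads)
    aligner = BuiltinAligner({"chr1": hap}, cfg.read_length)
    n_unique = n_recovered = 0
    for r in reads:
        if seq_counts[min(r.seq, revcomp(r.seq))] > 1:
            continue  # sequence not unique in the library; origin ambiguous
        n_unique += 1
        hit = aligner.align_read(r.seq)
        if hit is None:
            continue
        true_start = int(r.read_id.rsplit(":", 2)[1])
        if hit[1] + 1 == true_start and hit[4] == 0:
            n_recovered += 1
    assert n_unique > 1000
    assert n_recovered / n_unique >= 0.999


# ---------------------------------------------------------------- deduplication

def test_duplicates_collapse_to_one_representative():
    a1 = make_alignment(read_id="b", start=10)
    a2 = make_alignment(read_id="a", start=10)
    out = remove_duplicates([a1, a2])
    assert len(out) == 1 and out[0].read_id == "a"  # smallest id wins


def test_opposite_strands_both_survive():
    a1 = make_alignment(read_id="r1", start=10, strand="+")
    a2 = make_alignment(read_id="r2", start=10, strand="-")
    assert len(remove_duplicates([a1, a2])) == 2


def test_remove_duplicates_idempotent(rng):
    alns = [
        make_alignment(read_id=f"r{i}", start=int(rng.integers(1, 20)),
                       strand="+-"[int(rng.integers(2))])
        for i in range(50)
    ]
    once = remove_duplicates(alns)
    assert remove_duplicates(once) == once
    assert len(once) <= len(alns)


# ---------------------------------------------------------------- pileup

def test_single_read_pileup():
    ref = {"chr1": "ACGTAAAA"}
    cols = list(pileup([make_alignment(seq="ACGT", start=1)], ref))
    assert len(cols) == 4
    for col, base in zip(cols, "ACGT"):
        assert col.position == "ACGT".index(base) + 1
        assert col.count(base) == 1 and col.depth == 1


def test_stacked_reads_pileup():
    ref = {"chr1": "A" * 10}
    alns = [make_alignment(read_id=f"r{i}", seq="A", start=5) for i in range(7)]
    (col,) = pileup(alns, ref)
    assert col.counts == (7, 0, 0, 0)


def test_pileup_matches_brute_force_tally(rng):
    ref = {"chr1": random_dna(rng, 60)}
    alns = []
    for i in range(40):
        start = int(rng.integers(1, 50))
        length = int(rng.integers(3, 11))
        seq = random_dna(rng, length)
        alns.append(make_alignment(read_id=f"r{i}", start=start, seq=seq))
    expected: dict[int, Counter] = {}
    for a in alns:
        for off, base in enumerate(a.seq):
            expected.setdefault(a.start + off, Counter())[base] += 1
    cols = {c.position: c for c in pileup(alns, ref)}
    assert set(cols) == set(expected)
    for pos, counter in expected.items():
        for j, base in enumerate("ACGT"):
            assert cols[pos].counts[j] == counter.get(base, 0)


def test_pileup_conserves_read_coverage(rng):
    """Column depth equals the number of retained reads covering the position."""
    ref = {"chr1": random_dna(rng, 100)}
    alns = [
        make_alignment(read_id=f"r{i}", start=int(rng.integers(1, 90)),
                       seq=random_dna(rng, 10))
        for i in range(30)
    ]
    for col in pileup(alns, ref):
        covering = sum(1 for a in alns if a.start <= col.position <= a.end)
        assert col.depth == covering
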