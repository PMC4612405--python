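"""Simulator: planted truth, read generation, directional mixing."""

import numpy as np
import pytest

from graftmrna.alignio import TestAligner as BuiltinAligner
from graftmrna.simulate import (SimConfig, make_genotype_pair,
                                simulate_experiment, simulate_genomic_reads,
                                simulate_graft_transcriptomes, write_experiment)


def test_zero_snp_density_gives_identical_haplotypes():
    cfg = SimConfig(genome_length=20_000, n_genes=5, snp_density=0.0, seed=3)
    pair = make_genotype_pair(cfg)
    assert pair.haplotypes["A"] == pair.reference
    assert pair.haplotypes["B"] == pair.reference
    assert len(pair.truth.diagnostic_loci()) == 0


def test_fixed_seed_is_byte_identical(tmp_path):
    cfg = SimConfig(genome_length=15_000, n_genes=4, rnaseq_reads_per_library=500,
                    genomic_depth=2, seed=7)
    d1, d2 = tmp_path / "run1", tmp_path / "run2"
    p1 = write_experiment(simulate_experiment(cfg), d1)
    p2 = write_experiment(simulate_experiment(cfg), d2)
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes(), key


def test_diagnostic_truth_matches_haplotype_recount():
    """Positions where the two haplotypes differ are exactly the diagnostic truth."""
    cfg = SimConfig(genome_length=100_000, n_genes=10, snp_density=1.0,
                    diagnostic_fraction=1.0, seed=11)
    pair = make_genotype_pair(cfg)
    a, b = pair.haplotypes["A"], pair.haplotypes["B"]
    recount = {i + 1 for i in range(len(a)) if a[i] != b[i]}
    truth_pos = set(pair.truth.diagnostic_loci()["position"])
    assert truth_pos == recount


def test_planted_snps_have_unique_positions_and_non_reference_alleles():
    cfg = SimConfig(genome_length=50_000, n_genes=10, snp_density=4.0,
                    diagnostic_fraction=0.5, seed=5)
    truth = make_genotype_pair(cfg).truth
    snps = truth.snps
    assert snps["position"].is_unique
    # every planted SNP differs from the reference in at least one genotype
    assert ((snps["allele_a"] != snps["ref"]) | (snps["allele_b"] != snps["ref"])).all()
    diag = snps["diagnostic"]
    assert (snps.loc[diag, "allele_a"] != snps.loc[diag, "allele_b"]).all()
    assert (snps.loc[~diag, "allele_a"] == snps.loc[~diag, "allele_b"]).all()


def test_genomic_reads_error_free_are_exact_substrings(rng):
    cfg = SimConfig(genome_length=10_000, n_genes=2, error_rate=0.0,
                    duplication_rate=0.0, genomic_depth=3, seed=2)
    pair = make_genotype_pair(cfg)
    hap = pair.haplotypes["A"]
    reads = simulate_genomic_reads(hap, cfg, rng=rng)
    for r in reads[:200]:
        _, _, start, strand = r.read_id.rsplit(":", 3)
        start = int(start)
        expected = hap[start - 1:start - 1 + cfg.read_length]
        if strand == "-":
            from graftmrna._dna import revcomp
            expected = revcomp(expected)
        assert r.seq == expected


def test_genomic_read_count_matches_expected_depth(rng):
    cfg = SimConfig(genome_length=100_000, n_genes=2, genomic_depth=15,
                    duplication_rate=0.0, seed=2)
    pair = make_genotype_pair(cfg)
    reads = simulate_genomic_reads(pair.haplotypes["A"], cfg, rng=rng)
    expected = 15 * 100_000 / 101
    assert abs(len(reads) - expected) / expected < 0.01


def test_duplication_rate_produces_expected_duplicate_pairs(rng):
    cfg = SimConfig(genome_length=50_000, n_genes=2, genomic_depth=4,
                    duplication_rate=0.5, error_rate=0.0, seed=9)
    pair = make_genotype_pair(cfg)
    reads = simulate_genomic_reads(pair.haplotypes["A"], cfg, rng=rng)
    n_dups = sum(1 for r in reads if r.read_id.endswith(":d"))
    n_orig = len(reads) - n_dups
    sd = np.sqrt(n_orig * 0.5 * 0.5)
    assert abs(n_dups - 0.5 * n_orig) < 4 * sd
    # every duplicate shares sequence and origin with its source read
    by_id = {r.read_id: r for r in reads}
    for r in reads:
        if r.read_id.endswith(":d"):
            assert by_id[r.read_id[:-2]].seq == r.seq


def _pair_with_fractions(fractions, n_genes=4, reads=2000, seed=21, **kw):
    cfg = SimConfig(genome_length=n_genes * 2000, n_genes=n_genes, exon_length=202,
                    snps_per_gene=1, snp_density=0.0, error_rate=0.0,
                    duplication_rate=0.0, rnaseq_reads_per_library=reads,
                    transmission_fractions=fractions, seed=seed, **kw)
    pair = make_genotype_pair(cfg)
    return cfg, pair


def _tissue_of_read(read_id):
    return read_id.split(":")[1]


def test_no_mixing_keeps_every_read_home():
    fractions = {f"gene{i:04d}": 0.0 for i in range(4)}
    cfg, pair = _pair_with_fractions(fractions)
    trans = simulate_graft_transcriptomes(pair.truth, pair.haplotypes, cfg)
    for tissue, reads in trans.libraries.items():
        assert all(_tissue_of_read(r.read_id) == tissue for r in reads)
    assert (trans.gene_counts["partner_reads"] == 0).all()


def test_full_mixing_sends_every_read_to_partner():
    fractions = {f"gene{i:04d}": 1.0 for i in range(4)}
    cfg, pair = _pair_with_fractions(fractions)
    trans = simulate_graft_transcriptomes(pair.truth, pair.haplotypes, cfg)
    for tissue, reads in trans.libraries.items():
        assert all(_tissue_of_read(r.read_id) != tissue for r in reads)
    assert (trans.gene_counts["home_reads"] == 0).all()


def test_partial_mixing_is_binomial():
    """With fraction 0.1 and 1000 draws the partner count sits near 100."""
    fractions = {"gene0000": 0.1, "gene0001": 0.0}
    cfg, pair = _pair_with_fractions(fractions, n_genes=2, reads=1000,
                                     expression_sigma=0.0)
    trans = simulate_graft_transcriptomes(pair.truth, pair.haplotypes, cfg)
    row = trans.gene_counts.set_index("gene_id").loc["gene0000"]
    assert row["draws"] == 1000  # only source gene of its genotype
    sd = np.sqrt(1000 * 0.1 * 0.9)
    assert abs(row["partner_reads"] - 100) <= 3 * sd


def test_per_gene_read_conservation():
    cfg = SimConfig(genome_length=30_000, n_genes=10, snps_per_gene=1,
                    rnaseq_reads_per_library=3000, duplication_rate=0.0, seed=4)
    exp = simulate_experiment(cfg)
    counts = exp.transcriptomes.gene_counts
    assert (counts["home_reads"] + counts["partner_reads"] == counts["draws"]).all()
    # library totals match the multinomial draws routed to each tissue
    tallies = {"scion": 0, "rootstock": 0}
    for tissue, reads in exp.rna_libraries.items():
        tallies[tissue] = len(reads)
    assert sum(tallies.values()) == 2 * cfg.rnaseq_reads_per_library


def test_error_free_rna_reads_align_perfectly_to_their_haplotype():
    cfg = SimConfig(genome_length=20_000, n_genes=6, snps_per_gene=2, error_rate=0.0,
                    duplication_rate=0.0, rnaseq_reads_per_library=400, seed=8)
    exp = simulate_experiment(cfg)
    truth = exp.truth.genes.set_index("gene_id")
    aligners = {
        g: BuiltinAligner({exp.pair.contig: exp.pair.haplotypes[g]}, cfg.read_length)
        for g in "AB"
    }
    for tissue, reads in exp.rna_libraries.items():
        for r in reads[:100]:
            gene = r.read_id.split(":")[0]
            source = truth.loc[gene, "source_genotype"]
            hit = aligners[source].align_read(r.seq)
            assert hit is not None and hit[4] == 0, r.read_id


def test_zero_expression_weights_raise():
    cfg = SimConfig(genome_length=10_000, n_genes=2, seed=1)
    pair = make_genotype_pair(cfg)
    pair.truth.genes["expression_weight"] = 0.0
    with pytest.raises(ValueError, match="empty transcriptome"):
        simulate_graft_transcriptomes(pair.truth, pair.haplotypes, cfg)


@pytest.mark.parametrize("field,value", [
    ("error_rate", 1.5),
    ("duplication_rate", -0.1),
    ("read_length", 1),
    ("genome_length", 100),  # < n_genes * exon_length
])
def test_invalid_config_rejected(field, value):
    with pytest.raises(ValueError):
        SimConfig(**{field: value}).validate()
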