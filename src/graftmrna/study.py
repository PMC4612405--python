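"""Self-contained simulation studies exercising the whole pipeline.

Each study generates a synthetic graft experiment under stated conditions,
runs the full analysis, and scores it against the simulator's ground truth.
They are the package's verification experiments: exact diagnostic-SNP
recovery on clean data, absence of false transmitting calls without noise,
recovery of planted transmission fractions, and the replicate-vs-independent
correlation contrast. Problem sizes are desk-scale (tens of kilobases, a few
hundred genes, 10^5-10^6 reads) so every study runs in seconds to a couple of
minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import alignio, genotyping, rates
from .report import analyze_simulation, score_against_truth
from .simulate import (SimConfig, SimulatedExperiment, make_genotype_pair,
                       simulate_experiment, simulate_genomic_reads,
                       simulate_graft_transcriptomes)

RECOVERY_FRACTIONS = (0.001, 0.01, 0.1, 0.5)


def _gene_fractions(n_genes: int, values) -> dict[str, float]:
    return {f"gene{i:04d}": float(values[i % len(values)]) for i in range(n_genes)}


def diagnostic_exactness_study(seed: int = 0, *, genome_length: int = 100_000,
                               genomic_depth: float = 30.0,
                               snp_density: float = 2.0) -> dict:
    """Diagnostic-SNP recall/precision on an error-free genomic simulation.

    Eligible loci are the planted diagnostic SNPs whose realized post-filter
    pileup depth is at least 7 in both genotypes (the homozygous-call floor).
    On clean data both recall over eligible loci and precision over all calls
    should be exact.
    """
    cfg = SimConfig(genome_length=genome_length, n_genes=20, exon_length=202,
                    snp_density=snp_density, diagnostic_fraction=0.7,
                    genomic_depth=genomic_depth, error_rate=0.0,
                    duplication_rate=0.05, rnaseq_reads_per_library=1000, seed=seed)
    pair = make_genotype_pair(cfg)
    reference = {pair.contig: pair.reference}
    ss = np.random.SeedSequence((seed, 2))
    rngs = dict(zip("AB", (np.random.default_rng(s) for s in ss.spawn(2))))
    aligner = alignio.TestAligner(reference, cfg.read_length)
    calls, depth = {}, {}
    for g in "AB":
        reads = simulate_genomic_reads(pair.haplotypes[g], cfg,
                                       library_id=f"genomic{g}", rng=rngs[g])
        deduped = alignio.remove_duplicates(aligner.align(reads, f"genomic{g}"))
        counts = alignio.pileup_counts(deduped, reference)
        arr = counts[(f"genomic{g}", pair.contig)]
        depth[g] = arr.sum(axis=1)
        calls[g] = genotyping.call_genotype_from_counts(counts, g)
    snps = genotyping.diagnostic_snps(calls["A"], calls["B"])

    truth = pair.truth.diagnostic_loci()
    truth_pos = truth["position"].to_numpy()
    eligible = {
        int(p) for p in truth_pos
        if depth["A"][p - 1] >= genotyping.MIN_DOMINANT_DEPTH
        and depth["B"][p - 1] >= genotyping.MIN_DOMINANT_DEPTH
    }
    truth_alleles = {
        int(r.position): (r.allele_a, r.allele_b) for r in truth.itertuples()
    }
    called = {s.position: (s.allele_of("A"), s.allele_of("B")) for s in snps}
    correct = {p for p, alleles in called.items() if truth_alleles.get(p) == alleles}
    recall = len(eligible & correct) / len(eligible) if eligible else float("nan")
    precision = len(correct) / len(called) if called else float("nan")
    return {
        "n_truth_diagnostic": len(truth_pos),
        "n_eligible": len(eligible),
        "n_called": len(called),
        "recall": recall,
        "precision": precision,
    }


def no_noise_study(seed: int = 0, *, n_genes: int = 40,
                   reads_per_library: int = 20_000) -> dict:
    """All transmission fractions 0 and no sequencing error: nothing moves.

    Any transmitting call or rate record here is a false positive of the
    pipeline itself.
    """
    cfg = SimConfig(
        genome_length=n_genes * 1200, n_genes=n_genes, exon_length=202,
        snps_per_gene=1, snp_density=2.0, genomic_depth=25, error_rate=0.0,
        duplication_rate=0.05, rnaseq_reads_per_library=reads_per_library,
        transmission_fractions=_gene_fractions(n_genes, [0.0]), seed=seed)
    exp = simulate_experiment(cfg)
    analysis = analyze_simulation(exp)
    return {
        "n_transmitting": sum(len(ev) for ev in analysis.evidence.values()),
        "n_rate_records": sum(len(e) for e in analysis.estimates.values()),
    }


def parameter_recovery_study(seed: int = 0, *, n_genes: int = 200,
                             draws_per_gene: int = 3000
                             ) -> tuple[dict, pd.DataFrame]:
    """Recovery of planted transmission fractions {0.001, 0.01, 0.1, 0.5}.

    Error-free reads, equal expression weights and equal library sizes
    (``n_genes/2 * draws_per_gene`` per tissue), one central diagnostic SNP
    per gene. Genes alternate source genotype, so fractions are assigned in
    pairs: both genotypes carry the same fraction multiset and the two
    tissues' outgoing read flows (hence library sizes) balance. Returns
    summary metrics and the per-gene estimate/truth table.
    """
    fractions = {
        f"gene{i:04d}": float(RECOVERY_FRACTIONS[(i // 2) % len(RECOVERY_FRACTIONS)])
        for i in range(n_genes)
    }
    cfg = SimConfig(
        genome_length=n_genes * 360, n_genes=n_genes, exon_length=202,
        snps_per_gene=1, snp_density=0.0, genomic_depth=30, error_rate=0.0,
        duplication_rate=0.0, expression_sigma=0.0,
        rnaseq_reads_per_library=(n_genes // 2) * draws_per_gene,
        transmission_fractions=fractions, seed=seed)
    exp = simulate_experiment(cfg)
    analysis = analyze_simulation(exp)
    truth_dir = dict(zip(exp.truth.genes["gene_id"], exp.truth.genes["direction"]))
    rows = []
    for est in analysis.all_estimates():
        if truth_dir[est.gene_id] != est.direction:
            continue
        rows.append((est.gene_id, fractions[est.gene_id], est.gene_rate,
                     est.donor_read_total, est.reportable))
    details = pd.DataFrame(
        rows, columns=["gene_id", "true_fraction", "estimated_rate",
                       "donor_reads", "reportable"])
    strong = details[details["true_fraction"] >= 0.01]
    rel_err = (strong["estimated_rate"] - strong["true_fraction"]).abs() \
        / strong["true_fraction"]
    r = float(np.corrcoef(details["true_fraction"], details["estimated_rate"])[0, 1])
    metrics = {
        "n_genes": n_genes,
        "n_estimated": len(details),
        "n_estimated_f_ge_0.01": len(strong),
        "median_rel_error_f_ge_0.01": float(rel_err.median()),
        "pearson_r_true_vs_estimated": r,
    }
    return metrics, details


def _experiment_with_transcriptome(cfg: SimConfig, pair, genomic, rna_seed: int
                                   ) -> SimulatedExperiment:
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 3, rna_seed)))
    trans = simulate_graft_transcriptomes(pair.truth, pair.haplotypes, cfg, rng=rng)
    return SimulatedExperiment(config=cfg, pair=pair, genomic_reads=genomic,
                               transcriptomes=trans)


def _gene_rate_map(analysis) -> dict[str, float]:
    return {e.gene_id: e.gene_rate for e in analysis.all_estimates() if e.reportable}


def replicate_correlation_study(seed: int = 0, *, n_genes: int = 150,
                                draws_per_gene: int = 2000) -> dict:
    """Gene rates from two replicate RNA draws of one graft correlate highly.

    The genotypes, genomic libraries and planted fractions (log-uniform on
    [0.01, 0.5], all genes mobile) are shared; only the RNA-Seq sampling
    differs between the two replicates.
    """
    cfg = SimConfig(
        genome_length=n_genes * 360, n_genes=n_genes, exon_length=202,
        snps_per_gene=1, snp_density=0.0, genomic_depth=30, error_rate=0.0,
        duplication_rate=0.0, expression_sigma=0.0, mobile_gene_fraction=1.0,
        fraction_range=(0.01, 0.5),
        rnaseq_reads_per_library=(n_genes // 2) * draws_per_gene, seed=seed)
    pair = make_genotype_pair(cfg)
    ss = np.random.SeedSequence((seed, 4))
    rngs = dict(zip("AB", (np.random.default_rng(s) for s in ss.spawn(2))))
    genomic = {
        g: simulate_genomic_reads(pair.haplotypes[g], cfg, library_id=f"genomic{g}",
                                  rng=rngs[g])
        for g in "AB"
    }
    rate_maps = []
    for rep in (1, 2):
        exp = _experiment_with_transcriptome(cfg, pair, genomic, rep)
        rate_maps.append(_gene_rate_map(analyze_simulation(exp)))
    shared = sorted(set(rate_maps[0]) & set(rate_maps[1]))
    if len(shared) < 3:
        raise ValueError("insufficient overlap between replicates")
    x = np.array([rate_maps[0][g] for g in shared])
    y = np.array([rate_maps[1][g] for g in shared])
    return {
        "n_shared": len(shared),
        "pearson_r": float(np.corrcoef(x, y)[0, 1]),
    }


def independent_correlation_study(seed: int = 0, *, n_genes: int = 150,
                                  draws_per_gene: int = 2000) -> dict:
    """Gene rates from two unrelated grafts with independent fractions.

    Same gene ids, same study conditions as the replicate study, but genomes
    and transmission fractions are drawn independently; the rate correlation
    across grafts should be near zero.
    """
    rate_maps = []
    for sub in (1, 2):
        cfg = SimConfig(
            genome_length=n_genes * 360, n_genes=n_genes, exon_length=202,
            snps_per_gene=1, snp_density=0.0, genomic_depth=30, error_rate=0.0,
            duplication_rate=0.0, expression_sigma=0.0, mobile_gene_fraction=1.0,
            fraction_range=(0.01, 0.5),
            rnaseq_reads_per_library=(n_genes // 2) * draws_per_gene,
            seed=int(np.random.SeedSequence((seed, 5, sub)).generate_state(1)[0]
                     % (2**31 - 1)))
        exp = simulate_experiment(cfg)
        rate_maps.append(_gene_rate_map(analyze_simulation(exp)))
    shared = sorted(set(rate_maps[0]) & set(rate_maps[1]))
    if len(shared) < 3:
        raise ValueError("insufficient overlap between grafts")
    x = np.array([rate_maps[0][g] for g in shared])
    y = np.array([rate_maps[1][g] for g in shared])
    return {
        "n_shared": len(shared),
        "pearson_r": float(np.corrcoef(x, y)[0, 1]),
    }


def distribution_study(seed: int = 0, *, n_genes: int = 96,
                       draws_per_gene: int = 3000) -> dict:
    """Rate-distribution summary against a planted fraction mixture.

    Fractions cycle {0.002, 0.05, 0.3} (one third of genes per value, away
    from the summary's bin edges), balanced across the two genotypes;
    error-free with equal library sizes, so every gene is reportable and the
    fraction of gene rates below 0.01 should equal the planted third.
    """
    values = (0.002, 0.05, 0.3)
    fractions = {
        f"gene{i:04d}": float(values[(i // 2) % len(values)]) for i in range(n_genes)
    }
    cfg = SimConfig(
        genome_length=n_genes * 360, n_genes=n_genes, exon_length=202,
        snps_per_gene=1, snp_density=0.0, genomic_depth=30, error_rate=0.0,
        duplication_rate=0.0, expression_sigma=0.0,
        rnaseq_reads_per_library=(n_genes // 2) * draws_per_gene,
        transmission_fractions=fractions, seed=seed)
    exp = simulate_experiment(cfg)
    analysis = analyze_simulation(exp)
    dist = rates.rate_distribution(analysis.all_estimates())
    reportable_genes = [e.gene_id for e in analysis.all_estimates() if e.reportable]
    truth_below = float(np.mean([fractions[g] < 0.01 for g in reportable_genes]))
    return {
        "n_reportable": dist.n,
        "frac_below_0.01": dist.frac_below_0_01,
        "truth_frac_below_0.01": truth_below,
        "frac_above_0.5": dist.frac_above_0_5,
    }


def default_conditions_study(seed: int = 0, *, n_genes: int = 200,
                             reads_per_library: int = 120_000) -> dict:
    """One graft under the generator's default (realistic) conditions.

    Interspecific SNP density, 15x genomic coverage, 0.5% sequencing error,
    5% PCR duplication, a sparse mobile-gene mixture with mostly-low
    fractions. Only the problem size (gene count, library size) is raised
    above the bare defaults, so the reported distribution fractions rest on
    a reasonable number of reportable genes. Reports detection scores and
    the rate-distribution summary.
    """
    cfg = SimConfig(seed=seed, n_genes=n_genes, genome_length=n_genes * 1200,
                    rnaseq_reads_per_library=reads_per_library)
    exp = simulate_experiment(cfg)
    analysis = analyze_simulation(exp)
    score = score_against_truth(analysis, exp)
    dist = rates.rate_distribution(analysis.all_estimates())
    per_direction = {d: len(ev) for d, ev in analysis.evidence.items()}
    return {
        **score,
        "n_transmitting_per_direction": per_direction,
        "n_reportable": dist.n,
        "frac_rates_below_0.01": dist.frac_below_0_01,
        "frac_rates_above_0.5": dist.frac_above_0_5,
    }
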