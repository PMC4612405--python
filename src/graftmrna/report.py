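"""End-to-end orchestration: pipeline runs, summaries, and benchmarks.

The pipeline composes the stages in their natural order: alignment filters
and pileups -> homozygous calls -> diagnostic SNPs -> per-direction read
classification and transmitting-gene calls -> transmission-rate estimates ->
RPKM expression -> summary tables. :func:`analyze` is the in-memory engine;
:func:`run_pipeline` wraps it with file input/output, a structured log of
per-stage read counts, and a machine-readable run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import alignio, genotyping, mobility, rates, simulate
from .alignio import Alignment, TestAligner
from .genes import GeneIndex, GeneModel, read_gff3
from .simulate import SimConfig, SimulatedExperiment, TISSUE_GENOTYPE

logger = logging.getLogger("graftmrna")


@dataclass
class PipelineConfig:
    """File paths and thresholds of one graft's end-to-end run."""

    reference: Path
    gff3: Path
    genomic: dict[str, Path]  # genotype id -> SAM or FASTQ
    rna: dict[str, Path]  # tissue -> SAM or FASTQ
    tissue_genotype: dict[str, str] = field(
        default_factory=lambda: dict(TISSUE_GENOTYPE))
    outdir: Path = Path("graftmrna_out")
    min_dominant_depth: int = genotyping.MIN_DOMINANT_DEPTH
    min_dominant_fraction: float = genotyping.MIN_DOMINANT_FRACTION
    min_donor_reads: int = rates.MIN_DONOR_READS
    read_length: int = 101
    max_edit: int | None = None
    window_rule: str = rates.RULE_INFORMATIVE
    dedup_rna: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("min_dominant_depth", "min_donor_reads", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.min_dominant_fraction < 1:
            raise ValueError("min_dominant_fraction must be in (0, 1)")
        self.reference = Path(self.reference)
        self.gff3 = Path(self.gff3)
        self.genomic = {k: Path(v) for k, v in self.genomic.items()}
        self.rna = {k: Path(v) for k, v in self.rna.items()}
        self.outdir = Path(self.outdir)

    def validate_paths(self) -> None:
        for p in [self.reference, self.gff3, *self.genomic.values(), *self.rna.values()]:
            if not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")

    def to_dict(self) -> dict:
        return {
            "reference": str(self.reference),
            "gff3": str(self.gff3),
            "genomic": {k: str(v) for k, v in self.genomic.items()},
            "rna": {k: str(v) for k, v in self.rna.items()},
            "tissue_genotype": dict(self.tissue_genotype),
            "outdir": str(self.outdir),
            "min_dominant_depth": self.min_dominant_depth,
            "min_dominant_fraction": self.min_dominant_fraction,
            "min_donor_reads": self.min_donor_reads,
            "read_length": self.read_length,
            "max_edit": self.max_edit,
            "window_rule": self.window_rule,
            "dedup_rna": self.dedup_rna,
            "seed": self.seed,
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class GraftAnalysis:
    """In-memory results of one graft's analysis."""

    reference: Mapping[str, str]
    gene_index: GeneIndex
    calls: dict[str, dict]  # genotype -> (contig, pos) -> HomozygousCall
    diagnostic: list[genotyping.DiagnosticSNP]
    rna_alignments: dict[str, list[Alignment]]  # tissue -> deduped alignments
    library_totals: dict[str, int]
    evidence: dict[str, dict[str, mobility.MobileEvidence]]  # direction -> gene -> evidence
    estimates: dict[str, list[rates.TransmissionEstimate]]  # direction -> estimates
    expression: pd.DataFrame
    stage_counts: dict[str, int]

    def transmitting_genes(self) -> dict[str, set[str]]:
        return {d: set(ev) for d, ev in self.evidence.items()}

    def all_estimates(self) -> list[rates.TransmissionEstimate]:
        return [e for d in sorted(self.estimates) for e in self.estimates[d]]


def _partner(tissue: str, tissues: Sequence[str]) -> str:
    others = [t for t in tissues if t != tissue]
    if len(others) != 1:
        raise ValueError("exactly two tissues are required")
    return others[0]


def analyze(reference: Mapping[str, str], gene_models: Sequence[GeneModel],
            genomic_alignments: Mapping[str, Sequence[Alignment]],
            rna_alignments: Mapping[str, Sequence[Alignment]],
            tissue_genotype: Mapping[str, str] | None = None, *,
            min_dominant_depth: int = genotyping.MIN_DOMINANT_DEPTH,
            min_dominant_fraction: float = genotyping.MIN_DOMINANT_FRACTION,
            min_donor_reads: int = rates.MIN_DONOR_READS,
            read_length: int = 101,
            window_rule: str = rates.RULE_INFORMATIVE,
            dedup_rna: bool = False) -> GraftAnalysis:
    """Run the full analysis on already-aligned libraries.

    ``genomic_alignments`` maps the two genotype ids to their genomic
    libraries; ``rna_alignments`` maps the two tissue names to their RNA-Seq
    libraries; ``tissue_genotype`` says which genotype each tissue carries.
    Genomic libraries are PCR-deduplicated here before pileup. RNA libraries
    are kept whole by default: the detection criteria already count unique
    mapping coordinates, while window counts, RPM totals and RPKM use all
    retained mapped reads; ``dedup_rna=True`` deduplicates them too.
    """
    if tissue_genotype is None:
        tissue_genotype = dict(TISSUE_GENOTYPE)
    gene_index = GeneIndex(gene_models)
    stage_counts: dict[str, int] = {}

    calls: dict[str, dict] = {}
    for genotype in sorted(genomic_alignments):
        alns = list(genomic_alignments[genotype])
        stage_counts[f"genomic_{genotype}_aligned"] = len(alns)
        deduped = alignio.remove_duplicates(alns)
        stage_counts[f"genomic_{genotype}_after_dedup"] = len(deduped)
        counts = alignio.pileup_counts(deduped, reference)
        calls[genotype] = genotyping.call_genotype_from_counts(
            counts, genotype,
            min_depth=min_dominant_depth, min_fraction=min_dominant_fraction,
        )
        stage_counts[f"homozygous_calls_{genotype}"] = len(calls[genotype])
        logger.info("genotype %s: %d alignments, %d after dedup, %d homozygous calls",
                    genotype, len(alns), len(deduped), len(calls[genotype]))

    genotypes = sorted(calls)
    if len(genotypes) != 2:
        raise ValueError("exactly two genotypes are required")
    diagnostic = genotyping.diagnostic_snps(calls[genotypes[0]], calls[genotypes[1]],
                                            gene_index)
    stage_counts["diagnostic_snps"] = len(diagnostic)
    logger.info("%d diagnostic SNPs", len(diagnostic))
    snp_index = mobility.SnpIndex(diagnostic)
    variants = {
        g: mobility.VariantIndex(genotyping.variant_map(calls[g], reference))
        for g in genotypes
    }

    tissues = sorted(rna_alignments)
    rna_kept: dict[str, list[Alignment]] = {}
    totals: dict[str, int] = {}
    for tissue in tissues:
        alns = list(rna_alignments[tissue])
        stage_counts[f"rna_{tissue}_aligned"] = len(alns)
        stage_counts[f"rna_{tissue}_unique_coords"] = len(alignio.remove_duplicates(alns))
        rna_kept[tissue] = alignio.remove_duplicates(alns) if dedup_rna else alns
        totals[tissue] = len(rna_kept[tissue])
        stage_counts[f"rna_{tissue}_retained"] = totals[tissue]

    contig_lengths = {name: len(seq) for name, seq in reference.items()}
    snps_by_gene = snp_index.by_gene()
    evidence: dict[str, dict[str, mobility.MobileEvidence]] = {}
    estimates: dict[str, list[rates.TransmissionEstimate]] = {}
    for receptor_tissue in tissues:
        donor_tissue = _partner(receptor_tissue, tissues)
        donor_genotype = tissue_genotype[donor_tissue]
        receptor_genotype = tissue_genotype[receptor_tissue]
        direction = f"{donor_tissue}->{receptor_tissue}"
        receptor_classified = mobility.classify_library(
            rna_kept[receptor_tissue], snp_index, donor_genotype, receptor_genotype,
            variants[donor_genotype], variants[receptor_genotype],
        )
        ev = mobility.detect_transmitting_genes(receptor_classified, direction)
        evidence[direction] = ev
        stage_counts[f"transmitting_{direction}"] = len(ev)
        logger.info("direction %s: %d transmitting genes", direction, len(ev))
        if ev:
            # in the donor tissue the same donor genotype is the "donor" side
            donor_classified = mobility.classify_library(
                rna_kept[donor_tissue], snp_index, donor_genotype, receptor_genotype,
                variants[donor_genotype], variants[receptor_genotype],
            )
            estimates[direction] = rates.estimate_rates(
                receptor_classified, donor_classified, snps_by_gene,
                read_length, totals[receptor_tissue], totals[donor_tissue],
                direction=direction, genes=sorted(ev),
                contig_lengths=contig_lengths, rule=window_rule,
                min_donor_reads=min_donor_reads,
            )
        else:
            estimates[direction] = []

    exon_lengths = gene_index.exon_lengths()
    expr_frames = []
    for tissue in tissues:
        counts = rates.count_gene_reads(rna_kept[tissue], gene_index)
        expr_frames.append(rates.rpkm(counts, exon_lengths, totals[tissue], tissue))
    expression = pd.concat(expr_frames, ignore_index=True) if expr_frames else pd.DataFrame()

    return GraftAnalysis(
        reference=reference, gene_index=gene_index, calls=calls, diagnostic=diagnostic,
        rna_alignments=rna_kept, library_totals=totals, evidence=evidence,
        estimates=estimates, expression=expression, stage_counts=stage_counts,
    )


def align_simulated(exp: SimulatedExperiment, max_edit: int | None = None
                    ) -> tuple[dict[str, list[Alignment]], dict[str, list[Alignment]]]:
    """Map a simulated experiment's FASTQ libraries with the built-in aligner."""
    reference = {exp.pair.contig: exp.pair.reference}
    aligner = TestAligner(reference, exp.config.read_length, max_edit)
    genomic = {
        g: aligner.align(reads, library=f"genomic_{g}")
        for g, reads in sorted(exp.genomic_reads.items())
    }
    rna = {
        t: aligner.align(reads, library=f"rna_{t}")
        for t, reads in sorted(exp.rna_libraries.items())
    }
    return genomic, rna


def analyze_simulation(exp: SimulatedExperiment, *, max_edit: int | None = None,
                       **analyze_kwargs) -> GraftAnalysis:
    """Align a simulated experiment and run the full analysis on it."""
    genomic, rna = align_simulated(exp, max_edit)
    return analyze(
        {exp.pair.contig: exp.pair.reference}, exp.pair.gene_models, genomic, rna,
        read_length=exp.config.read_length, **analyze_kwargs,
    )


def _load_reference(path: Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _load_library(path: Path, reference: Mapping[str, str], library: str,
                  read_length: int, max_edit: int | None) -> list[Alignment]:
    suffix = path.suffix.lower()
    if suffix == ".sam":
        return list(alignio.read_sam(path, library=library, reference=reference))
    if suffix in (".fastq", ".fq"):
        reads = simulate.read_fastq(path)
        return alignio.test_align(reads, reference, max_edit=max_edit, library=library)
    raise ValueError(f"unsupported input format {suffix!r} for {path} (need .sam or .fastq)")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> GraftAnalysis:
    """File-to-file pipeline run: reads inputs, writes every output table.

    Outputs (under ``config.outdir``): homozygous_calls.tsv,
    diagnostic_snps.vcf, evidence.tsv, estimates.tsv, expression.tsv,
    rate_histogram_<direction>.tsv, summary.tsv, manifest.json. Any stage
    error aborts with the stage name; a stale-output marker is written first
    and removed on success.
    """
    config.validate_paths()
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    stale = outdir / "RUN_INCOMPLETE"
    stale.write_text("run in progress or aborted; outputs may be stale\n")

    stage = "load inputs"
    try:
        reference = _load_reference(config.reference)
        gene_models = read_gff3(config.gff3)
        genomic = {
            g: _load_library(p, reference, f"genomic_{g}", config.read_length,
                             config.max_edit)
            for g, p in sorted(config.genomic.items())
        }
        rna = {
            t: _load_library(p, reference, f"rna_{t}", config.read_length, config.max_edit)
            for t, p in sorted(config.rna.items())
        }
        stage = "analysis"
        analysis = analyze(
            reference, gene_models, genomic, rna, config.tissue_genotype,
            min_dominant_depth=config.min_dominant_depth,
            min_dominant_fraction=config.min_dominant_fraction,
            min_donor_reads=config.min_donor_reads,
            read_length=config.read_length,
            window_rule=config.window_rule,
            dedup_rna=config.dedup_rna,
        )
        stage = "write outputs"
        _write_outputs(config, analysis, outdir)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    stale.unlink()
    return analysis


def _write_outputs(config: PipelineConfig, analysis: GraftAnalysis, outdir: Path) -> None:
    all_calls = {}
    for g in sorted(analysis.calls):
        all_calls.update({(g, k): v for k, v in analysis.calls[g].items()})
    frames = [genotyping.calls_to_frame(analysis.calls[g]) for g in sorted(analysis.calls)]
    pd.concat(frames, ignore_index=True).to_csv(
        outdir / "homozygous_calls.tsv", sep="\t", index=False)

    genotyping.write_vcf(analysis.diagnostic, analysis.reference,
                         outdir / "diagnostic_snps.vcf")

    ev_frames = [mobility.evidence_to_frame(analysis.evidence[d])
                 for d in sorted(analysis.evidence)]
    ev = pd.concat(ev_frames, ignore_index=True) if ev_frames else pd.DataFrame(
        columns=["gene_id", "direction", "criteria", "unique_reads", "loci"])
    ev.to_csv(outdir / "evidence.tsv", sep="\t", index=False)

    est = rates.estimates_to_frame(analysis.all_estimates())
    est.to_csv(outdir / "estimates.tsv", sep="\t", index=False)
    analysis.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)

    for direction in sorted(analysis.estimates):
        dist = rates.rate_distribution(analysis.estimates[direction])
        safe = direction.replace("->", "_to_")
        dist.histogram.to_csv(outdir / f"rate_histogram_{safe}.tsv", sep="\t", index=False)
        dist.scatter.to_csv(outdir / f"rate_scatter_{safe}.tsv", sep="\t", index=False)

    per_graft, _ = mobility.direction_summary({"graft": analysis.evidence})
    per_graft.to_csv(outdir / "summary.tsv", sep="\t", index=False)

    config_echo = {k: v for k, v in config.to_dict().items() if k != "outdir"}
    manifest = {
        "config": config_echo,
        "input_checksums": {
            str(p): _sha256(Path(p))
            for p in [config.reference, config.gff3,
                      *config.genomic.values(), *config.rna.values()]
        },
        "stage_counts": analysis.stage_counts,
        "library_totals": analysis.library_totals,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def score_against_truth(analysis: GraftAnalysis, exp: SimulatedExperiment) -> dict:
    """Score detection and rate recovery against the simulator's truth table.

    Detectable movers are truth genes with transmission fraction > 0 and at
    least one diagnostic truth SNP inside the gene. Rate errors compare each
    reportable estimate with its gene's planted fraction.
    """
    truth = exp.truth
    diag = truth.diagnostic_loci()
    genes_with_snp = set(diag.loc[diag["gene_id"] != "", "gene_id"])
    movers = set(truth.genes.loc[truth.genes["transmission_fraction"] > 0, "gene_id"])
    non_movers = set(truth.genes["gene_id"]) - movers
    detectable = movers & genes_with_snp
    detected = set()
    for ev in analysis.evidence.values():
        detected |= set(ev)

    out: dict[str, float | int] = {
        "n_detectable_movers": len(detectable),
        "n_detected": len(detected),
        "true_positives": len(detected & movers),
        "false_positives": len(detected & non_movers),
    }
    out["sensitivity"] = (
        len(detected & detectable) / len(detectable) if detectable else float("nan"))
    out["specificity"] = (
        1.0 - len(detected & non_movers) / len(non_movers) if non_movers else float("nan"))

    truth_frac = dict(zip(truth.genes["gene_id"], truth.genes["transmission_fraction"]))
    errs, rel_errs = [], []
    for est in analysis.all_estimates():
        if not est.reportable:
            continue
        f = truth_frac.get(est.gene_id)
        if f is None or f <= 0:
            continue
        errs.append(est.gene_rate - f)
        rel_errs.append(abs(est.gene_rate - f) / f)
    out["n_rated"] = len(errs)
    out["rate_bias"] = float(np.mean(errs)) if errs else float("nan")
    out["rate_rmse"] = float(np.sqrt(np.mean(np.square(errs)))) if errs else float("nan")
    out["rate_median_rel_error"] = float(np.median(rel_errs)) if rel_errs else float("nan")
    return out


def run_benchmark(configs: Sequence[SimConfig], **analyze_kwargs) -> pd.DataFrame:
    """Simulate and analyze a grid of configurations; score each vs truth.

    Returns one row per grid cell with the simulator knobs that vary
    (transmission setup, depth, error rate) and detection
    sensitivity/specificity plus rate bias/RMSE against the truth table.
    """
    rows = []
    for cfg in configs:
        exp = simulate.simulate_experiment(cfg)
        analysis = analyze_simulation(exp, **analyze_kwargs)
        score = score_against_truth(analysis, exp)
        rows.append({
            "seed": cfg.seed,
            "genomic_depth": cfg.genomic_depth,
            "error_rate": cfg.error_rate,
            "mobile_gene_fraction": cfg.mobile_gene_fraction,
            "rnaseq_reads_per_library": cfg.rnaseq_reads_per_library,
            **score,
        })
    return pd.DataFrame(rows)
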