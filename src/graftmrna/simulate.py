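"""Synthetic grafted-plant sequencing experiments with known ground truth.

The generator emulates the study design behind graft-mobility detection: two
fully homozygous genotypes (``A``, the scion genotype; ``B``, the rootstock
genotype) that differ from a common reference at planted biallelic SNPs, a
set of single-exon genes each expressed in one partner's tissue, and two
RNA-Seq libraries (``scion`` and ``rootstock`` tissue) in which a known
fraction of each gene's transcripts has crossed the graft junction into the
partner tissue's library. Genomic libraries at a chosen fold-coverage,
uniform substitution sequencing error and coordinate-level PCR duplication
complete the picture. Everything is recorded in a :class:`TruthTable` so
every downstream stage can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
import yaml

from ._dna import mutate_base, random_dna, revcomp
from .genes import GeneModel, write_gff3

CONTIG = "chr1"
GENOTYPES = ("A", "B")
#: tissue -> genotype whose genome that tissue carries
TISSUE_GENOTYPE = {"scion": "A", "rootstock": "B"}
GENOTYPE_TISSUE = {g: t for t, g in TISSUE_GENOTYPE.items()}


class Read(NamedTuple):
    """A simulated single-end read (sequence as sequenced, 5'->3')."""

    read_id: str
    seq: str


@dataclass(frozen=True)
class SimConfig:
    """Knobs of a synthetic graft experiment.

    Defaults mirror a desk-scale version of an interspecific grapevine graft:
    101-bp single-end reads, >=15x genomic coverage per genotype, a SNP
    density of a few per kilobase between divergent genotypes, and mostly-low
    transmission fractions for the mobile genes.
    """

    genome_length: int = 120_000
    n_genes: int = 100
    exon_length: int = 202
    snp_density: float = 5.0  # expected planted SNPs per kb
    diagnostic_fraction: float = 0.7  # fraction of planted SNPs where A and B differ
    snps_per_gene: int = 0  # extra diagnostic SNPs forced inside each exon
    read_length: int = 101
    genomic_depth: float = 15.0
    rnaseq_reads_per_library: int = 50_000
    error_rate: float = 0.005
    duplication_rate: float = 0.05
    transmission_fractions: Mapping[str, float] | None = None  # gene id -> fraction
    mobile_gene_fraction: float = 0.3
    fraction_range: tuple[float, float] = (1e-4, 0.6)
    expression_sigma: float = 1.0  # log-normal sigma of expression weights; 0 = equal
    seed: int = 0

    def validate(self) -> None:
        for name in ("snp_density", "diagnostic_fraction", "error_rate", "duplication_rate"):
            v = getattr(self, name)
            if name == "snp_density":
                if v < 0:
                    raise ValueError("snp_density must be >= 0")
                continue
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_length < 2:
            raise ValueError("read_length must be >= 2")
        if self.genome_length < self.n_genes * self.exon_length:
            raise ValueError("genome_length must be >= n_genes * exon_length")
        if self.exon_length < self.read_length:
            raise ValueError("exon_length must be >= read_length")
        if self.transmission_fractions is not None:
            for g, f in self.transmission_fractions.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"transmission fraction for {g} outside [0, 1]")
        if not (0.0 < self.fraction_range[0] <= self.fraction_range[1] <= 1.0):
            raise ValueError("fraction_range must satisfy 0 < lo <= hi <= 1")

    def to_yaml(self, path: str | Path) -> None:
        d = self.__dict__.copy()
        d["fraction_range"] = list(self.fraction_range)
        if d["transmission_fractions"] is not None:
            d["transmission_fractions"] = dict(d["transmission_fractions"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "fraction_range" in d:
            d["fraction_range"] = tuple(d["fraction_range"])
        return cls(**d)


@dataclass
class TruthTable:
    """Ground truth of a simulated experiment.

    ``snps`` columns: contig, position (1-based), ref, allele_a, allele_b,
    diagnostic (bool), gene_id ('' if intergenic).
    ``genes`` columns: gene_id, contig, start, end, strand, source_genotype,
    expression_weight, transmission_fraction, direction
    (e.g. ``scion->rootstock`` for a gene expressed in the scion whose
    transcripts leak into the rootstock library).
    """

    snps: pd.DataFrame
    genes: pd.DataFrame

    def diagnostic_loci(self) -> pd.DataFrame:
        return self.snps[self.snps["diagnostic"]].reset_index(drop=True)

    def mobile_genes(self) -> pd.DataFrame:
        return self.genes[self.genes["transmission_fraction"] > 0].reset_index(drop=True)

    def to_tsv(self, snps_path: str | Path, genes_path: str | Path) -> None:
        self.snps.to_csv(snps_path, sep="\t", index=False)
        self.genes.to_csv(genes_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, snps_path: str | Path, genes_path: str | Path) -> "TruthTable":
        snps = pd.read_csv(snps_path, sep="\t", dtype={"gene_id": str}, keep_default_na=False)
        snps["diagnostic"] = snps["diagnostic"].astype(bool)
        genes = pd.read_csv(genes_path, sep="\t")
        return cls(snps=snps, genes=genes)


@dataclass
class GenotypePair:
    """Reference plus the two homozygous graft-partner haplotypes."""

    reference: str
    haplotypes: dict[str, str]  # genotype id -> sequence
    gene_models: list[GeneModel]
    truth: TruthTable
    contig: str = CONTIG


def _place_genes(config: SimConfig) -> list[GeneModel]:
    """Evenly spaced, non-overlapping single-exon genes on the forward strand."""
    slack = config.genome_length - config.n_genes * config.exon_length
    gap = slack // (config.n_genes + 1)
    genes = []
    pos = gap + 1  # 1-based
    for i in range(config.n_genes):
        start = pos
        end = start + config.exon_length - 1
        genes.append(GeneModel(gene_id=f"gene{i:04d}", contig=CONTIG, start=start, end=end))
        pos = end + gap + 1
    return genes


def _draw_snp_positions(rng: np.random.Generator, config: SimConfig,
                        genes: list[GeneModel]) -> tuple[np.ndarray, np.ndarray]:
    """Return (random density positions, forced per-gene positions), 1-based.

    Collisions are rejected and resampled, never silently dropped.
    """
    forced: list[int] = []
    if config.snps_per_gene:
        for g in genes:
            step = (g.end - g.start + 1) / (config.snps_per_gene + 1)
            for k in range(1, config.snps_per_gene + 1):
                forced.append(g.start + int(round(k * step)) - 1)
    forced_arr = np.array(sorted(forced), dtype=np.int64)
    if len(set(forced)) != len(forced):
        raise ValueError("snps_per_gene placement collided; use fewer SNPs per gene")

    n_random = rng.poisson(config.snp_density * config.genome_length / 1000.0)
    taken = set(forced)
    positions: list[int] = []
    attempts = 0
    while len(positions) < n_random:
        p = int(rng.integers(1, config.genome_length + 1))
        attempts += 1
        if attempts > 100 * max(n_random, 1):
            raise ValueError("snp_density too high: cannot place unique SNP positions")
        if p in taken:
            continue  # collision: resample
        taken.add(p)
        positions.append(p)
    return np.array(sorted(positions), dtype=np.int64), forced_arr


def make_genotype_pair(config: SimConfig) -> GenotypePair:
    """Build a reference genome and two homozygous graft-partner haplotypes.

    Planted SNPs are biallelic substitutions against the reference. A
    ``diagnostic_fraction`` of them carries different non-reference alleles in
    the two genotypes (diagnostic loci); the remainder carries the same
    non-reference allele in both (shared, non-diagnostic). Genes are assigned
    alternately to the two genotypes as their expression source, with
    log-normal expression weights and transmission fractions either supplied
    via the config or drawn from a sparse log-uniform mixture.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_genome, rng_snps, rng_genes = (np.random.default_rng(s) for s in ss.spawn(3))

    reference = random_dna(rng_genome, config.genome_length)
    genes = _place_genes(config)
    gene_index_bounds = [(g.start, g.end, g.gene_id) for g in genes]

    random_pos, forced_pos = _draw_snp_positions(rng_snps, config, genes)
    n_random = len(random_pos)
    diagnostic_flags = np.concatenate(
        [
            rng_snps.random(n_random) < config.diagnostic_fraction,
            np.ones(len(forced_pos), dtype=bool),  # forced per-gene SNPs are diagnostic
        ]
    )
    all_pos = np.concatenate([random_pos, forced_pos])
    order = np.argsort(all_pos)
    all_pos, diagnostic_flags = all_pos[order], diagnostic_flags[order]

    hap_a = list(reference)
    hap_b = list(reference)
    rows = []
    for pos, diag in zip(all_pos.tolist(), diagnostic_flags.tolist()):
        ref_base = reference[pos - 1]
        alt1 = mutate_base(rng_snps, ref_base)
        if diag:
            # second allele differs from both the reference and alt1; one of the
            # two genotypes may keep the reference base only at non-diagnostic
            # loci, so both alleles here are non-reference and distinct
            alt2 = alt1
            while alt2 == alt1:
                alt2 = mutate_base(rng_snps, ref_base)
            a_base, b_base = (alt1, alt2) if rng_snps.random() < 0.5 else (alt2, alt1)
        else:
            a_base = b_base = alt1
        hap_a[pos - 1] = a_base
        hap_b[pos - 1] = b_base
        gene_id = ""
        for s, e, gid in gene_index_bounds:
            if s <= pos <= e:
                gene_id = gid
                break
        rows.append((CONTIG, pos, ref_base, a_base, b_base, diag, gene_id))

    snp_df = pd.DataFrame(
        rows,
        columns=["contig", "position", "ref", "allele_a", "allele_b", "diagnostic", "gene_id"],
    )

    if config.expression_sigma > 0:
        weights = rng_genes.lognormal(mean=0.0, sigma=config.expression_sigma,
                                      size=len(genes))
    else:
        weights = np.ones(len(genes))
    fractions = _assign_fractions(rng_genes, config, genes)
    gene_rows = []
    for i, g in enumerate(genes):
        source = GENOTYPES[i % 2]
        home = GENOTYPE_TISSUE[source]
        partner = "rootstock" if home == "scion" else "scion"
        gene_rows.append(
            (g.gene_id, g.contig, g.start, g.end, g.strand, source,
             float(weights[i]), float(fractions[g.gene_id]), f"{home}->{partner}")
        )
    gene_df = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "contig", "start", "end", "strand", "source_genotype",
                 "expression_weight", "transmission_fraction", "direction"],
    )

    truth = TruthTable(snps=snp_df, genes=gene_df)
    return GenotypePair(
        reference=reference,
        haplotypes={"A": "".join(hap_a), "B": "".join(hap_b)},
        gene_models=genes,
        truth=truth,
    )


def _assign_fractions(rng: np.random.Generator, config: SimConfig,
                      genes: list[GeneModel]) -> dict[str, float]:
    if config.transmission_fractions is not None:
        missing = [g.gene_id for g in genes if g.gene_id not in config.transmission_fractions]
        if missing:
            raise ValueError(f"transmission_fractions missing genes: {missing[:3]}...")
        return {g.gene_id: float(config.transmission_fractions[g.gene_id]) for g in genes}
    lo, hi = config.fraction_range
    out = {}
    for g in genes:
        if rng.random() < config.mobile_gene_fraction:
            out[g.gene_id] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            out[g.gene_id] = 0.0
    return out


def _sequence_read(rng: np.random.Generator, template: str, start0: int, length: int,
                   strand: str, error_rate: float) -> str:
    """Extract a read from template (0-based start), orient, add errors."""
    seq = template[start0:start0 + length]
    if strand == "-":
        seq = revcomp(seq)
    if error_rate > 0:
        n_err = rng.binomial(length, error_rate)
        if n_err:
            chars = list(seq)
            for p in rng.choice(length, size=n_err, replace=False):
                chars[p] = mutate_base(rng, chars[p])
            seq = "".join(chars)
    return seq


def simulate_genomic_reads(haplotype: str, config: SimConfig, *,
                           library_id: str = "genomic",
                           rng: np.random.Generator | None = None) -> list[Read]:
    """Whole-genome shotgun reads at the configured fold-coverage.

    Reads start uniformly along the haplotype, on either strand, with uniform
    substitution errors; each read is emitted a second time (a PCR duplicate)
    with probability ``duplication_rate``. Read ids encode the true origin as
    ``<library>:<n>:<1-based start>:<strand>`` (duplicates get suffix ``:d``).
    """
    if len(haplotype) < config.read_length:
        raise ValueError("haplotype shorter than read length")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.read_length
    n_reads = int(round(config.genomic_depth * len(haplotype) / L))
    starts = rng.integers(0, len(haplotype) - L + 1, size=n_reads)
    strands = np.where(rng.random(n_reads) < 0.5, "+", "-")
    dup = rng.random(n_reads) < config.duplication_rate
    reads: list[Read] = []
    for i in range(n_reads):
        s0, st = int(starts[i]), str(strands[i])
        seq = _sequence_read(rng, haplotype, s0, L, st, config.error_rate)
        rid = f"{library_id}:{i}:{s0 + 1}:{st}"
        reads.append(Read(rid, seq))
        if dup[i]:
            reads.append(Read(rid + ":d", seq))
    return reads


@dataclass
class Transcriptomes:
    """Two-tissue RNA-Seq libraries plus per-gene routing bookkeeping.

    ``gene_counts`` columns: gene_id, draws, home_reads, partner_reads —
    before PCR duplication, so home + partner always equals draws.
    """

    libraries: dict[str, list[Read]]
    gene_counts: pd.DataFrame


def simulate_graft_transcriptomes(truth: TruthTable, haplotypes: Mapping[str, str],
                                  config: SimConfig, *,
                                  rng: np.random.Generator | None = None) -> Transcriptomes:
    """Draw the two tissues' RNA-Seq libraries with directional mixing.

    Each tissue draws ``rnaseq_reads_per_library`` transcripts from the genes
    sourced in its own genotype (multinomially by expression weight, from that
    genotype's haplotype exons); each transcript is then routed to the partner
    tissue's library with the gene's transmission fraction, else kept at home.
    PCR duplication is applied per emitted library.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.read_length
    libraries: dict[str, list[Read]] = {t: [] for t in TISSUE_GENOTYPE}
    count_rows = []
    for tissue, genotype in TISSUE_GENOTYPE.items():
        partner = "rootstock" if tissue == "scion" else "scion"
        hap = haplotypes[genotype]
        sub = truth.genes[truth.genes["source_genotype"] == genotype]
        if len(sub) == 0:
            continue
        weights = sub["expression_weight"].to_numpy(dtype=float)
        if weights.sum() <= 0:
            raise ValueError("empty transcriptome: all expression weights are zero")
        draws = rng.multinomial(config.rnaseq_reads_per_library, weights / weights.sum())
        for (_, gene), n in zip(sub.iterrows(), draws):
            if n == 0:
                count_rows.append((gene["gene_id"], 0, 0, 0))
                continue
            f = float(gene["transmission_fraction"])
            n_partner = int(rng.binomial(n, f)) if 0.0 < f < 1.0 else (n if f >= 1.0 else 0)
            start_lo, start_hi = gene["start"] - 1, gene["end"] - L + 1  # 0-based lo, excl hi
            starts = rng.integers(start_lo, start_hi, size=n)
            strands = np.where(rng.random(n) < 0.5, "+", "-")
            dest = np.array([partner] * n_partner + [tissue] * (n - n_partner))
            for j in range(int(n)):
                seq = _sequence_read(rng, hap, int(starts[j]), L, str(strands[j]),
                                     config.error_rate)
                rid = f"{gene['gene_id']}:{tissue}:{j}:{int(starts[j]) + 1}:{strands[j]}"
                libraries[str(dest[j])].append(Read(rid, seq))
            count_rows.append((gene["gene_id"], int(n), int(n - n_partner), n_partner))
    if all(len(r) == 0 for r in libraries.values()):
        raise ValueError("empty transcriptome: no reads drawn")

    # PCR duplication per final library
    for tissue in libraries:
        reads = libraries[tissue]
        dup = rng.random(len(reads)) < config.duplication_rate
        out = []
        for r, d in zip(reads, dup):
            out.append(r)
            if d:
                out.append(Read(r.read_id + ":d", r.seq))
        libraries[tissue] = out

    counts = pd.DataFrame(count_rows, columns=["gene_id", "draws", "home_reads", "partner_reads"])
    return Transcriptomes(libraries=libraries, gene_counts=counts)


@dataclass
class SimulatedExperiment:
    """A full in-memory synthetic graft experiment."""

    config: SimConfig
    pair: GenotypePair
    genomic_reads: dict[str, list[Read]]  # genotype id -> reads
    transcriptomes: Transcriptomes

    @property
    def truth(self) -> TruthTable:
        return self.pair.truth

    @property
    def rna_libraries(self) -> dict[str, list[Read]]:
        return self.transcriptomes.libraries


def simulate_experiment(config: SimConfig) -> SimulatedExperiment:
    """Generate genotypes, genomic libraries and RNA libraries from one seed."""
    pair = make_genotype_pair(config)
    ss = np.random.SeedSequence((config.seed, 1))
    rng_a, rng_b, rng_rna = (np.random.default_rng(s) for s in ss.spawn(3))
    genomic = {
        "A": simulate_genomic_reads(pair.haplotypes["A"], config, library_id="genomicA",
                                    rng=rng_a),
        "B": simulate_genomic_reads(pair.haplotypes["B"], config, library_id="genomicB",
                                    rng=rng_b),
    }
    trans = simulate_graft_transcriptomes(pair.truth, pair.haplotypes, config, rng=rng_rna)
    return SimulatedExperiment(config=config, pair=pair, genomic_reads=genomic,
                               transcriptomes=trans)


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fastq(reads: Iterable[Read], path: str | Path, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{quality_char * len(r.seq)}\n")


def read_fastq(path: str | Path) -> list[Read]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            reads.append(Read(header.strip()[1:].split()[0], seq))
    return reads


def write_experiment(exp: SimulatedExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated experiment as plain-text files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fa",
        "hap_a": outdir / "genotype_A.fa",
        "hap_b": outdir / "genotype_B.fa",
        "gff3": outdir / "genes.gff3",
        "truth_snps": outdir / "truth_snps.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "genomic_A": outdir / "genomic_A.fastq",
        "genomic_B": outdir / "genomic_B.fastq",
        "rna_scion": outdir / "rna_scion.fastq",
        "rna_rootstock": outdir / "rna_rootstock.fastq",
        "config": outdir / "sim_config.yaml",
    }
    write_fasta({exp.pair.contig: exp.pair.reference}, paths["reference"])
    write_fasta({exp.pair.contig: exp.pair.haplotypes["A"]}, paths["hap_a"])
    write_fasta({exp.pair.contig: exp.pair.haplotypes["B"]}, paths["hap_b"])
    write_gff3(exp.pair.gene_models, paths["gff3"])
    exp.truth.to_tsv(paths["truth_snps"], paths["truth_genes"])
    write_fastq(exp.genomic_reads["A"], paths["genomic_A"])
    write_fastq(exp.genomic_reads["B"], paths["genomic_B"])
    write_fastq(exp.rna_libraries["scion"], paths["rna_scion"])
    write_fastq(exp.rna_libraries["rootstock"], paths["rna_rootstock"])
    exp.config.to_yaml(paths["config"])
    return paths
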