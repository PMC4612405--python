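"""Homozygous genotype calls and diagnostic SNPs between graft partners.

A position is called homozygous in a genotype when its genomic pileup shows
at least ``min_depth`` (default 7) reads supporting the dominant base and the
dominant base's frequency among all covering reads is strictly greater than
``min_fraction`` (default 0.9). Diagnostic SNPs are the loci called
homozygous in *both* partners with different alleles — the positions at which
a single read can be attributed to one partner's genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

from .alignio import PileupColumn
from ._dna import BASES
from .genes import GeneIndex

MIN_DOMINANT_DEPTH = 7
MIN_DOMINANT_FRACTION = 0.9


@dataclass(frozen=True, slots=True)
class HomozygousCall:
    contig: str
    position: int
    allele: str
    depth_dominant: int
    depth_total: int
    genotype: str

    def __post_init__(self):
        if self.depth_dominant < MIN_DOMINANT_DEPTH:
            raise ValueError("homozygous call below the dominant-depth floor")
        if not self.depth_dominant / self.depth_total > MIN_DOMINANT_FRACTION:
            raise ValueError("homozygous call below the dominant-fraction floor")


@dataclass(frozen=True, slots=True)
class DiagnosticSNP:
    """A locus homozygous in both partners for different alleles."""

    contig: str
    position: int
    genotype_1: str
    allele_1: str
    genotype_2: str
    allele_2: str
    gene_id: str | None = None

    def __post_init__(self):
        if self.allele_1 == self.allele_2:
            raise ValueError("diagnostic SNP alleles must differ")

    def allele_of(self, genotype: str) -> str:
        if genotype == self.genotype_1:
            return self.allele_1
        if genotype == self.genotype_2:
            return self.allele_2
        raise KeyError(f"unknown genotype {genotype!r}")


def call_homozygous(column: PileupColumn, genotype: str = "?", *,
                    min_depth: int = MIN_DOMINANT_DEPTH,
                    min_fraction: float = MIN_DOMINANT_FRACTION) -> HomozygousCall | None:
    """Call one pileup column, or return None (no-call).

    The dominant base must be unique (a tie cannot be "the dominant allele"),
    supported by at least ``min_depth`` reads, and its frequency among all
    covering reads must be strictly greater than ``min_fraction``.
    """
    counts = column.counts
    dom = max(counts)
    if dom < min_depth:
        return None
    if counts.count(dom) != 1:
        return None  # tied dominant base
    total = sum(counts)
    if not dom / total > min_fraction:
        return None
    return HomozygousCall(
        contig=column.contig,
        position=column.position,
        allele=BASES[counts.index(dom)],
        depth_dominant=dom,
        depth_total=total,
        genotype=genotype,
    )


def call_genotype(columns: Iterable[PileupColumn], genotype: str, *,
                  min_depth: int = MIN_DOMINANT_DEPTH,
                  min_fraction: float = MIN_DOMINANT_FRACTION
                  ) -> dict[tuple[str, int], HomozygousCall]:
    """Call every pileup column of one genotype's genomic library."""
    calls = {}
    for col in columns:
        call = call_homozygous(col, genotype, min_depth=min_depth, min_fraction=min_fraction)
        if call is not None:
            calls[(col.contig, col.position)] = call
    return calls


def call_genotype_from_counts(arrays: Mapping[tuple[str, str], np.ndarray], genotype: str, *,
                              min_depth: int = MIN_DOMINANT_DEPTH,
                              min_fraction: float = MIN_DOMINANT_FRACTION
                              ) -> dict[tuple[str, int], HomozygousCall]:
    """Vectorized genotype calling from dense pileup count arrays.

    Equivalent to :func:`call_genotype` over the same columns (the per-column
    rule is identical); used for whole-genome libraries where a Python loop
    per position would dominate runtime.
    """
    calls: dict[tuple[str, int], HomozygousCall] = {}
    for (_, contig), arr in sorted(arrays.items()):
        total = arr.sum(axis=1)
        dom = arr.max(axis=1)
        unique_dom = (arr == dom[:, None]).sum(axis=1) == 1
        ok = (dom >= min_depth) & unique_dom & (dom > min_fraction * total)
        for i in np.nonzero(ok)[0].tolist():
            calls[(contig, i + 1)] = HomozygousCall(
                contig=contig,
                position=i + 1,
                allele=BASES[int(arr[i].argmax())],
                depth_dominant=int(dom[i]),
                depth_total=int(total[i]),
                genotype=genotype,
            )
    return calls


def diagnostic_snps(calls_1: Mapping[tuple[str, int], HomozygousCall],
                    calls_2: Mapping[tuple[str, int], HomozygousCall],
                    gene_index: GeneIndex | None = None) -> list[DiagnosticSNP]:
    """Loci homozygous in both genotypes with differing alleles.

    Each SNP is annotated with the overlapping gene model, if any. Sorted by
    (contig, position). Symmetric: swapping the inputs swaps allele labels
    but yields the same locus set.
    """
    snps = []
    for key in sorted(set(calls_1) & set(calls_2)):
        c1, c2 = calls_1[key], calls_2[key]
        if c1.allele == c2.allele:
            continue
        contig, position = key
        gene_id = gene_index.gene_at(contig, position) if gene_index is not None else None
        snps.append(
            DiagnosticSNP(
                contig=contig, position=position,
                genotype_1=c1.genotype, allele_1=c1.allele,
                genotype_2=c2.genotype, allele_2=c2.allele,
                gene_id=gene_id,
            )
        )
    return snps


def variant_map(calls: Mapping[tuple[str, int], HomozygousCall],
                reference: Mapping[str, str]) -> dict[tuple[str, int], str]:
    """Positions where a genotype's called allele differs from the reference.

    This is the genotype's haplotype expressed as substitutions against the
    reference; read classification judges "perfectly aligned to the donor
    genome" against it.
    """
    out = {}
    for (contig, pos), call in calls.items():
        if call.allele != reference[contig][pos - 1].upper():
            out[(contig, pos)] = call.allele
    return out


def calls_to_frame(calls: Mapping[tuple[str, int], HomozygousCall]) -> pd.DataFrame:
    rows = [
        (c.genotype, c.contig, c.position, c.allele, c.depth_dominant, c.depth_total)
        for c in (calls[k] for k in sorted(calls))
    ]
    return pd.DataFrame(
        rows, columns=["genotype", "contig", "position", "allele",
                       "depth_dominant", "depth_total"],
    )


def write_vcf(snps: list[DiagnosticSNP], reference: Mapping[str, str],
              path: str | Path) -> None:
    """Write diagnostic SNPs as minimal VCF 4.2.

    REF is the reference-genome base; ALT collects whichever partner alleles
    differ from it; INFO names each partner's allele (P1/P2 with genotype ids
    G1/G2) and the overlapping gene. Input must be sorted by (contig,
    position).
    """
    keys = [(s.contig, s.position) for s in snps]
    if keys != sorted(keys):
        raise ValueError("diagnostic SNPs must be sorted by (contig, position)")
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for name, seq in reference.items():
        header.contigs.add(name, length=len(seq))
    header.add_line('##INFO=<ID=G1,Number=1,Type=String,Description="Partner 1 genotype id">')
    header.add_line('##INFO=<ID=A1,Number=1,Type=String,Description="Partner 1 allele">')
    header.add_line('##INFO=<ID=G2,Number=1,Type=String,Description="Partner 2 genotype id">')
    header.add_line('##INFO=<ID=A2,Number=1,Type=String,Description="Partner 2 allele">')
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Overlapping gene">')
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for s in snps:
            ref_base = reference[s.contig][s.position - 1].upper()
            alts = [a for a in (s.allele_1, s.allele_2) if a != ref_base]
            rec = vcf.new_record(
                contig=s.contig,
                start=s.position - 1,  # pysam is 0-based
                alleles=(ref_base, *dict.fromkeys(alts)),
            )
            rec.info["G1"] = s.genotype_1
            rec.info["A1"] = s.allele_1
            rec.info["G2"] = s.genotype_2
            rec.info["A2"] = s.allele_2
            if s.gene_id:
                rec.info["GENE"] = s.gene_id
            vcf.write(rec)


def read_vcf(path: str | Path) -> list[DiagnosticSNP]:
    """Read back diagnostic SNPs written by :func:`write_vcf`."""
    snps = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            snps.append(
                DiagnosticSNP(
                    contig=rec.contig,
                    position=rec.pos,
                    genotype_1=info["G1"],
                    allele_1=info["A1"],
                    genotype_2=info["G2"],
                    allele_2=info["A2"],
                    gene_id=info.get("GENE"),
                )
            )
    return snps
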