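"""Allele-of-origin read classification and transmitting-gene calls.

A read from the receptor tissue's RNA library is *donor-origin* when it is
perfectly aligned to the donor genome (its only differences from the
reference are the donor genotype's own homozygous substitutions) and every
diagnostic locus it covers shows the donor allele. A gene is called *graft
transmitting* in a direction when its donor-origin evidence meets at least
one of three criteria:

a. at least one read carrying two or more diagnostic SNP loci of the gene;
b. at least two unique reads covering one (the same) diagnostic SNP locus;
c. at least two unique reads carrying different diagnostic SNP loci.

"Unique reads" are distinct post-deduplication alignments, i.e. distinct
(contig, start, strand) coordinates.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignio import Alignment
from .genotyping import DiagnosticSNP

DONOR = "donor-origin"
RECEPTOR = "receptor-origin"
UNINFORMATIVE = "uninformative"
CONFLICTED = "conflicted"


class SnpIndex:
    """Sorted per-contig index over diagnostic SNPs for range queries."""

    def __init__(self, snps: Sequence[DiagnosticSNP]):
        self.snps = list(snps)
        self._by_contig: dict[str, tuple[list[int], list[DiagnosticSNP]]] = {}
        grouped: dict[str, list[DiagnosticSNP]] = defaultdict(list)
        for s in self.snps:
            grouped[s.contig].append(s)
        for contig, group in grouped.items():
            group.sort(key=lambda s: s.position)
            self._by_contig[contig] = ([s.position for s in group], group)

    def in_range(self, contig: str, start: int, end: int) -> list[DiagnosticSNP]:
        """SNPs with start <= position <= end."""
        entry = self._by_contig.get(contig)
        if entry is None:
            return []
        positions, group = entry
        lo = bisect_left(positions, start)
        hi = bisect_right(positions, end)
        return group[lo:hi]

    def by_gene(self) -> dict[str, list[DiagnosticSNP]]:
        out: dict[str, list[DiagnosticSNP]] = defaultdict(list)
        for s in self.snps:
            if s.gene_id:
                out[s.gene_id].append(s)
        return dict(out)


class VariantIndex:
    """Sorted index over one genotype's substitutions vs the reference."""

    def __init__(self, variants: Mapping[tuple[str, int], str]):
        self.variants = dict(variants)
        self._by_contig: dict[str, tuple[list[int], list[str]]] = {}
        grouped: dict[str, list[tuple[int, str]]] = defaultdict(list)
        for (contig, pos), base in variants.items():
            grouped[contig].append((pos, base))
        for contig, group in grouped.items():
            group.sort()
            self._by_contig[contig] = ([p for p, _ in group], [b for _, b in group])

    def in_range(self, contig: str, start: int, end: int) -> list[tuple[int, str]]:
        entry = self._by_contig.get(contig)
        if entry is None:
            return []
        positions, bases = entry
        lo = bisect_left(positions, start)
        hi = bisect_right(positions, end)
        return list(zip(positions[lo:hi], bases[lo:hi]))


@dataclass(frozen=True, slots=True)
class ClassifiedRead:
    alignment: Alignment
    covered: tuple[tuple[DiagnosticSNP, str], ...]  # (locus, observed base)
    label: str
    perfect_match_donor: bool

    @property
    def unique_key(self) -> tuple[str, int, str]:
        a = self.alignment
        return (a.contig, a.start, a.strand)


def _matches_haplotype(aln: Alignment, variants: VariantIndex) -> bool:
    """True when the read equals the haplotype (reference + substitutions)."""
    expected = dict(variants.in_range(aln.contig, aln.start, aln.end))
    return dict(aln.mismatches) == expected


def classify_read(aln: Alignment, snp_index: SnpIndex, donor: str, receptor: str,
                  donor_variants: VariantIndex,
                  receptor_variants: VariantIndex) -> ClassifiedRead:
    """Label one receptor-library read by its allele of origin.

    ``uninformative``: covers no diagnostic locus, or cannot be attributed to
    either haplotype under the perfect-match rule; ``conflicted``: its covered
    diagnostic loci mix donor and receptor alleles; ``donor-origin`` /
    ``receptor-origin``: all covered loci show that partner's allele and the
    read perfectly matches that partner's haplotype.
    """
    covered_snps = snp_index.in_range(aln.contig, aln.start, aln.end)
    covered = tuple((s, aln.base_at(s.position)) for s in covered_snps)
    perfect_donor = _matches_haplotype(aln, donor_variants)
    if not covered:
        return ClassifiedRead(aln, covered, UNINFORMATIVE, perfect_donor)
    shows_donor = [base == s.allele_of(donor) for s, base in covered]
    shows_receptor = [base == s.allele_of(receptor) for s, base in covered]
    if any(shows_donor) and any(shows_receptor):
        label = CONFLICTED
    elif all(shows_donor) and perfect_donor:
        label = DONOR
    elif all(shows_receptor) and _matches_haplotype(aln, receptor_variants):
        label = RECEPTOR
    else:
        label = UNINFORMATIVE
    return ClassifiedRead(aln, covered, label, perfect_donor)


def classify_library(alignments: Iterable[Alignment], snp_index: SnpIndex,
                     donor: str, receptor: str,
                     donor_variants: VariantIndex,
                     receptor_variants: VariantIndex) -> list[ClassifiedRead]:
    return [
        classify_read(aln, snp_index, donor, receptor, donor_variants, receptor_variants)
        for aln in alignments
    ]


@dataclass(frozen=True)
class MobileEvidence:
    """Donor-origin evidence for one gene in one direction of movement."""

    gene_id: str
    direction: str  # e.g. "B->scion": genotype B transcripts seen in scion tissue
    read_ids: frozenset[str]
    unique_reads: frozenset[tuple[str, int, str]]
    loci: frozenset[int]
    criteria: frozenset[str]  # subset of {"a", "b", "c"}

    @property
    def transmitting(self) -> bool:
        return bool(self.criteria)


def detect_transmitting_genes(classified: Iterable[ClassifiedRead],
                              direction: str) -> dict[str, MobileEvidence]:
    """Call graft transmitting genes from classified receptor-library reads.

    Only donor-origin reads contribute. Evaluates, per gene, the three
    criteria (see module docstring); a gene is returned iff at least one
    criterion holds, with every satisfied criterion recorded.
    """
    per_gene_reads: dict[str, dict[tuple[str, int, str], set[int]]] = defaultdict(dict)
    per_gene_ids: dict[str, set[str]] = defaultdict(set)
    for cr in classified:
        if cr.label != DONOR:
            continue
        loci_by_gene: dict[str, set[int]] = defaultdict(set)
        for snp, _ in cr.covered:
            if snp.gene_id:
                loci_by_gene[snp.gene_id].add(snp.position)
        for gene_id, loci in loci_by_gene.items():
            per_gene_reads[gene_id].setdefault(cr.unique_key, set()).update(loci)
            per_gene_ids[gene_id].add(cr.alignment.read_id)

    out: dict[str, MobileEvidence] = {}
    for gene_id, reads in per_gene_reads.items():
        criteria = set()
        if any(len(loci) >= 2 for loci in reads.values()):
            criteria.add("a")
        locus_cover: dict[int, int] = defaultdict(int)
        for loci in reads.values():
            for p in loci:
                locus_cover[p] += 1
        if any(n >= 2 for n in locus_cover.values()):
            criteria.add("b")
        all_loci = set().union(*reads.values())
        if len(reads) >= 2 and len(all_loci) >= 2:
            criteria.add("c")
        if criteria:
            out[gene_id] = MobileEvidence(
                gene_id=gene_id,
                direction=direction,
                read_ids=frozenset(per_gene_ids[gene_id]),
                unique_reads=frozenset(reads),
                loci=frozenset(all_loci),
                criteria=frozenset(criteria),
            )
    return out


def evidence_to_frame(evidence: Mapping[str, MobileEvidence]) -> pd.DataFrame:
    rows = [
        (e.gene_id, e.direction, "".join(sorted(e.criteria)),
         len(e.unique_reads), len(e.loci))
        for e in (evidence[g] for g in sorted(evidence))
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "direction", "criteria", "unique_reads", "loci"]
    )


def direction_summary(
    evidence_by_graft: Mapping[str, Mapping[str, Mapping[str, MobileEvidence]]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Directional gene counts per graft and pairwise overlaps across grafts.

    ``evidence_by_graft``: graft id -> direction label -> gene evidence.
    Returns (per-graft summary, pairwise overlap counts of transmitting-gene
    sets between grafts).
    """
    rows = []
    union_by_graft: dict[str, set[str]] = {}
    for graft, by_direction in evidence_by_graft.items():
        directions = sorted(by_direction)
        gene_sets = {d: set(by_direction[d]) for d in directions}
        union_by_graft[graft] = set().union(*gene_sets.values()) if gene_sets else set()
        both = set.intersection(*gene_sets.values()) if len(gene_sets) >= 2 else set()
        for d in directions:
            rows.append((graft, d, len(gene_sets[d])))
        rows.append((graft, "both", len(both)))
        rows.append((graft, "total", len(union_by_graft[graft])))
    per_graft = pd.DataFrame(rows, columns=["graft", "direction", "n_genes"])

    overlap_rows = []
    grafts = sorted(union_by_graft)
    for i, g1 in enumerate(grafts):
        for g2 in grafts[i + 1:]:
            overlap_rows.append((g1, g2, len(union_by_graft[g1] & union_by_graft[g2])))
    overlaps = pd.DataFrame(overlap_rows, columns=["graft_1", "graft_2", "shared_genes"])
    return per_graft, overlaps
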