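"""Transmission-rate estimation and RPKM gene expression.

The per-locus transmission rate of a mobile transcript is estimated inside a
window centered on each diagnostic SNP and extended by one read length to
each side: donor-attributable reads falling within the window are counted
separately in the receptor and donor tissues' libraries, each count is
normalized to RPM (reads per million mapped reads of its own library), and

    rate = RPM_receptor / (RPM_receptor + RPM_donor).

The gene-level rate is the unweighted mean of its per-SNP rates; estimates
are flagged reportable only when the gene produced at least
``min_donor_reads`` (default 50) donor-origin reads in the donor tissue, to
reduce small-sample bias. Expression is reported as RPKM (reads per kilobase
of exon model per million mapped reads).
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignio import Alignment
from .genes import GeneIndex
from .genotyping import DiagnosticSNP
from .mobility import DONOR, ClassifiedRead

MIN_DONOR_READS = 50

#: count only donor-origin reads covering the SNP itself (allele-informative)
RULE_INFORMATIVE = "informative"
#: count every read perfectly matching the donor haplotype in the window
RULE_ALL_PERFECT = "all_perfect"


@dataclass(frozen=True, slots=True)
class SnpRateRecord:
    contig: str
    position: int
    gene_id: str | None
    window_start: int
    window_end: int
    clipped: bool
    count_receptor: int
    count_donor: int
    rpm_receptor: float
    rpm_donor: float
    rate: float


@dataclass(frozen=True)
class TransmissionEstimate:
    gene_id: str
    direction: str
    snp_rates: tuple[SnpRateRecord, ...]
    gene_rate: float
    donor_read_total: int
    reportable: bool


class _ReadIndex:
    """Per-contig sorted starts of rate-eligible reads from one library."""

    def __init__(self, classified: Iterable[ClassifiedRead], rule: str = RULE_INFORMATIVE):
        if rule not in (RULE_INFORMATIVE, RULE_ALL_PERFECT):
            raise ValueError(f"unknown window rule {rule!r}")
        self.rule = rule
        grouped: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for cr in classified:
            if rule == RULE_INFORMATIVE:
                if cr.label != DONOR:
                    continue
            elif not cr.perfect_match_donor:
                continue
            a = cr.alignment
            grouped[a.contig].append((a.start, a.end))
        self._by_contig = {}
        for contig, spans in grouped.items():
            spans.sort()
            self._by_contig[contig] = (
                [s for s, _ in spans], [e for _, e in spans]
            )

    def count_in_window(self, contig: str, snp_position: int,
                        window_start: int, window_end: int) -> int:
        """Reads fully contained in the window (and covering the SNP, under
        the informative rule)."""
        entry = self._by_contig.get(contig)
        if entry is None:
            return 0
        starts, ends = entry
        lo = bisect_left(starts, window_start)
        hi = bisect_right(starts, window_end)
        n = 0
        for i in range(lo, hi):
            if ends[i] > window_end:
                continue
            if self.rule == RULE_INFORMATIVE and not starts[i] <= snp_position <= ends[i]:
                continue
            n += 1
        return n


def transmission_window(snp: DiagnosticSNP, read_length: int,
                        contig_length: int | None = None) -> tuple[int, int, bool]:
    """Window centered at the locus, extended by one read length each side.

    Returns (start, end, clipped); the window is clipped at contig bounds and
    flagged when that happens.
    """
    start = snp.position - read_length
    end = snp.position + read_length
    clipped = False
    if start < 1:
        start, clipped = 1, True
    if contig_length is not None and end > contig_length:
        end, clipped = contig_length, True
    return start, end, clipped


def rate_at_snp(snp: DiagnosticSNP, donor_index: _ReadIndex, receptor_index: _ReadIndex,
                read_length: int, donor_total: int, receptor_total: int,
                contig_length: int | None = None) -> SnpRateRecord | None:
    """Per-SNP transmission rate, or None when no donor reads exist at all.

    Raw window counts from each library are normalized by that library's
    total mapped reads (RPM); the rate divides the receptor-tissue RPM by the
    summed RPM of both tissues.
    """
    if donor_total <= 0 or receptor_total <= 0:
        raise ValueError("library mapped-read totals must be positive")
    wstart, wend, clipped = transmission_window(snp, read_length, contig_length)
    n_receptor = receptor_index.count_in_window(snp.contig, snp.position, wstart, wend)
    n_donor = donor_index.count_in_window(snp.contig, snp.position, wstart, wend)
    rpm_receptor = n_receptor / receptor_total * 1e6
    rpm_donor = n_donor / donor_total * 1e6
    if rpm_receptor + rpm_donor == 0:
        return None  # rate undefined at this locus; caller logs and skips
    rate = rpm_receptor / (rpm_receptor + rpm_donor)
    return SnpRateRecord(
        contig=snp.contig, position=snp.position, gene_id=snp.gene_id,
        window_start=wstart, window_end=wend, clipped=clipped,
        count_receptor=n_receptor, count_donor=n_donor,
        rpm_receptor=rpm_receptor, rpm_donor=rpm_donor, rate=rate,
    )


def gene_rate(gene_id: str, direction: str, records: Sequence[SnpRateRecord], *,
              min_donor_reads: int = MIN_DONOR_READS) -> TransmissionEstimate:
    """Gene-level estimate: unweighted mean of the per-SNP rates.

    The donor read total sums raw donor-library window counts over the gene's
    loci; the estimate is reportable when that total reaches
    ``min_donor_reads``.
    """
    if not records:
        raise ValueError(f"no per-SNP rate records for gene {gene_id}")
    rates = [r.rate for r in records]
    donor_total = sum(r.count_donor for r in records)
    return TransmissionEstimate(
        gene_id=gene_id,
        direction=direction,
        snp_rates=tuple(records),
        gene_rate=float(np.mean(rates)),
        donor_read_total=donor_total,
        reportable=donor_total >= min_donor_reads,
    )


def estimate_rates(receptor_classified: Iterable[ClassifiedRead],
                   donor_classified: Iterable[ClassifiedRead],
                   snps_by_gene: Mapping[str, Sequence[DiagnosticSNP]],
                   read_length: int, receptor_total: int, donor_total: int, *,
                   direction: str = "", genes: Iterable[str] | None = None,
                   contig_lengths: Mapping[str, int] | None = None,
                   rule: str = RULE_INFORMATIVE,
                   min_donor_reads: int = MIN_DONOR_READS) -> list[TransmissionEstimate]:
    """Per-gene transmission estimates for the given direction of movement.

    ``genes`` restricts estimation (typically to the transmitting genes); by
    default every gene with diagnostic SNPs is estimated. Loci where neither
    library has an eligible read are skipped.
    """
    receptor_index = _ReadIndex(receptor_classified, rule)
    donor_index = _ReadIndex(donor_classified, rule)
    wanted = sorted(snps_by_gene) if genes is None else sorted(genes)
    out = []
    for gene_id in wanted:
        records = []
        for snp in snps_by_gene.get(gene_id, ()):
            clen = contig_lengths.get(snp.contig) if contig_lengths else None
            rec = rate_at_snp(snp, donor_index, receptor_index, read_length,
                              donor_total, receptor_total, contig_length=clen)
            if rec is not None:
                records.append(rec)
        if records:
            out.append(gene_rate(gene_id, direction, records,
                                 min_donor_reads=min_donor_reads))
    return out


def estimates_to_frame(estimates: Sequence[TransmissionEstimate]) -> pd.DataFrame:
    rows = [
        (e.gene_id, e.direction, e.gene_rate, len(e.snp_rates),
         e.donor_read_total, e.reportable)
        for e in estimates
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "direction", "rate", "n_snps",
                       "donor_reads", "reportable"],
    )


def count_gene_reads(alignments: Iterable[Alignment],
                     gene_index: GeneIndex) -> dict[str, int]:
    """Raw per-gene counts: retained reads overlapping each gene's exons.

    A read overlapping exons of more than one gene counts toward each.
    """
    counts: dict[str, int] = {g.gene_id: 0 for g in gene_index.genes}
    for aln in alignments:
        for gene_id in gene_index.overlapping(aln.contig, aln.start, aln.end):
            counts[gene_id] += 1
    return counts


def rpkm(counts: Mapping[str, int], exon_lengths: Mapping[str, int],
         library_total: int, library: str = "lib") -> pd.DataFrame:
    """Reads per kilobase of exon model per million mapped reads.

    RPKM = raw count x 1e9 / (exon length in bases x total mapped reads).
    """
    if library_total <= 0:
        raise ValueError("library total must be positive")
    rows = []
    for gene_id in sorted(counts):
        n = counts[gene_id]
        length = exon_lengths[gene_id]
        if length <= 0:
            raise ValueError(f"non-positive exon length for {gene_id}")
        rows.append((gene_id, library, n, n * 1e9 / (length * library_total)))
    return pd.DataFrame(rows, columns=["gene_id", "library", "count", "rpkm"])


@dataclass
class RateDistribution:
    n: int
    frac_below_0_01: float | None
    frac_below_0_001: float | None
    frac_above_0_5: float | None
    histogram: pd.DataFrame  # bin_left, bin_right, n_genes
    scatter: pd.DataFrame  # gene_id, rate, log10_donor_reads


def rate_distribution(estimates: Sequence[TransmissionEstimate],
                      bin_edges: Sequence[float] | None = None,
                      reportable_only: bool = True) -> RateDistribution:
    """Binned summary of gene transmission rates (reportable genes only by
    default). Empty input yields an empty summary with no division by zero."""
    kept = [e for e in estimates if e.reportable or not reportable_only]
    if not kept:
        empty_h = pd.DataFrame(columns=["bin_left", "bin_right", "n_genes"])
        empty_s = pd.DataFrame(columns=["gene_id", "rate", "log10_donor_reads"])
        return RateDistribution(0, None, None, None, empty_h, empty_s)
    rates = np.array([e.gene_rate for e in kept])
    if bin_edges is None:
        bin_edges = [0.0, 0.001, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0]
    edges = np.asarray(bin_edges, dtype=float)
    hist, _ = np.histogram(rates, bins=edges)
    histogram = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "n_genes": hist}
    )
    scatter = pd.DataFrame(
        {
            "gene_id": [e.gene_id for e in kept],
            "rate": rates,
            "log10_donor_reads": np.log10([max(e.donor_read_total, 1) for e in kept]),
        }
    )
    n = len(kept)
    return RateDistribution(
        n=n,
        frac_below_0_01=float((rates < 0.01).mean()),
        frac_below_0_001=float((rates < 0.001).mean()),
        frac_above_0_5=float((rates > 0.5).mean()),
        histogram=histogram,
        scatter=scatter,
    )


@dataclass
class CorrelationResult:
    r: float | None  # None when degenerate (a constant input)
    n_shared: int
    degenerate: bool
    large_difference_genes: tuple[str, ...]  # >= 5-fold rate difference
    shared: pd.DataFrame  # gene_id, rate_1, rate_2


def rate_correlation(estimates_1: Sequence[TransmissionEstimate],
                     estimates_2: Sequence[TransmissionEstimate], *,
                     reportable_only: bool = True,
                     fold_threshold: float = 5.0) -> CorrelationResult:
    """Pearson correlation of gene rates over shared (reportable) genes.

    Also lists genes whose rates differ by ``fold_threshold`` or more between
    the two sets. Fewer than 3 shared genes is an error; a constant rate
    vector makes the correlation undefined — flagged, not silently zero.
    """
    r1 = {e.gene_id: e.gene_rate for e in estimates_1 if e.reportable or not reportable_only}
    r2 = {e.gene_id: e.gene_rate for e in estimates_2 if e.reportable or not reportable_only}
    shared_genes = sorted(set(r1) & set(r2))
    if len(shared_genes) < 3:
        raise ValueError("insufficient overlap: fewer than 3 shared genes")
    x = np.array([r1[g] for g in shared_genes])
    y = np.array([r2[g] for g in shared_genes])
    degenerate = bool(np.all(x == x[0]) or np.all(y == y[0]))
    r = None if degenerate else float(stats.pearsonr(x, y)[0])
    large = tuple(
        g for g, a, b in zip(shared_genes, x, y)
        if max(a, b) > 0 and (min(a, b) == 0 or max(a, b) / min(a, b) >= fold_threshold)
    )
    shared = pd.DataFrame({"gene_id": shared_genes, "rate_1": x, "rate_2": y})
    return CorrelationResult(
        r=r, n_shared=len(shared_genes), degenerate=degenerate,
        large_difference_genes=large, shared=shared,
    )
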