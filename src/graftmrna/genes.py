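"""Gene models: GFF3 input/output, exon lengths, and interval lookups.

Coordinates are 1-based and fully closed throughout, matching GFF3/SAM/VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from intervaltree import IntervalTree


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more exons on a single contig."""

    gene_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "+"
    exons: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self):
        if not self.exons:
            object.__setattr__(self, "exons", ((self.start, self.end),))
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid gene interval {self.gene_id}: {self.start}-{self.end}")

    @property
    def exon_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene and exon features as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig}\tgraftmrna\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.contig}\tgraftmrna\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene models (gene + exon features) from a GFF3 file."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    genes = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = tuple(
            (e.start, e.end) for e in db.children(g, featuretype="exon", order_by="start")
        )
        genes.append(
            GeneModel(
                gene_id=g.id,
                contig=g.seqid,
                start=g.start,
                end=g.end,
                strand=g.strand if g.strand in "+-" else "+",
                exons=exons,
            )
        )
    return genes


class GeneIndex:
    """Interval lookups from position ranges to overlapping gene models.

    A position overlaps a gene when it falls inside one of its exons; reads
    overlapping exons of two genes (overlapping models) are assigned to both.
    """

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self.by_id = {g.gene_id: g for g in self.genes}
        if len(self.by_id) != len(self.genes):
            raise ValueError("duplicate gene ids")
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            tree = self._trees.setdefault(g.contig, IntervalTree())
            for s, e in g.exons:
                tree.addi(s, e + 1, g.gene_id)  # intervaltree is half-open

    def overlapping(self, contig: str, start: int, end: int) -> list[str]:
        """Gene ids whose exons overlap the closed interval [start, end]."""
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end + 1)})

    def gene_at(self, contig: str, position: int) -> str | None:
        """First gene id (sorted) whose exons cover the position, if any."""
        hits = self.overlapping(contig, position, position)
        return hits[0] if hits else None

    def exon_lengths(self) -> dict[str, int]:
        return {g.gene_id: g.exon_length for g in self.genes}
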