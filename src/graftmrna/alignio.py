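"""Alignment ingestion, mapping filters and per-position base pileups.

Implements the mapping-side conventions of diagnostic-SNP genotyping from
short reads: only uniquely mapped reads (one single best hit) are used,
potential PCR duplicates are removed on mapping coordinates, and coverage of
every genomic position by base A, C, G and T is tallied per library.

The alignment model is ungapped: an alignment covers a contiguous reference
interval, and its edit distance equals its number of substitutions. Real SAM
from any mapper can be ingested (gapped records are rejected); the built-in
:func:`test_align` maps synthetic FASTQ with no external tool.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pysam

from ._dna import BASE_TO_INDEX, base_indices, encode, revcomp


@dataclass(frozen=True, slots=True)
class Alignment:
    """An ungapped single-end alignment, coordinates 1-based fully closed.

    ``seq`` is the aligned (forward reference strand) sequence; ``mismatches``
    lists (1-based reference position, observed base) for every substitution
    against the reference.
    """

    read_id: str
    library: str
    contig: str
    start: int
    strand: str
    seq: str
    mismatches: tuple[tuple[int, str], ...]
    is_unique_best: bool = True

    def __post_init__(self):
        if self.start < 1:
            raise ValueError("alignment start must be >= 1")

    @property
    def end(self) -> int:
        return self.start + len(self.seq) - 1

    @property
    def edit_distance(self) -> int:
        return len(self.mismatches)

    def base_at(self, position: int) -> str:
        if not self.start <= position <= self.end:
            raise ValueError(f"position {position} outside alignment span")
        return self.seq[position - self.start]


@dataclass(frozen=True, slots=True)
class PileupColumn:
    """Per-position counts of reads supporting each base, for one library."""

    contig: str
    position: int
    counts: tuple[int, int, int, int]  # A, C, G, T
    library: str

    @property
    def depth(self) -> int:
        return sum(self.counts)

    def count(self, base: str) -> int:
        return self.counts[BASE_TO_INDEX[base]]


def default_max_edit(read_length: int) -> int:
    """Mapper edit-distance cap: 4 for reads up to ~100 bp, 6 for longer."""
    return 4 if read_length <= 101 else 6


def read_sam(path: str | Path, *, library: str | None = None,
             reference: Mapping[str, str] | None = None) -> Iterator[Alignment]:
    """Stream ungapped alignments from a SAM file.

    Unmapped, secondary and supplementary records are excluded. Mismatch
    positions are recovered from the MD tag when present, otherwise
    recomputed against ``reference``; with neither available the record is a
    hard error ("cannot derive mismatches"). Records with indels or clipping
    do not fit the ungapped model and raise with their line number.
    """
    path = Path(path)
    lib = library if library is not None else path.stem
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for lineno, rec in enumerate(sam, start=1):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.cigartuples is None or any(op != 0 for op, _ in rec.cigartuples):
                # only M (ungapped, unclipped) records fit the model
                raise ValueError(
                    f"{path}: record {lineno} ({rec.query_name}): non-ungapped CIGAR "
                    f"{rec.cigarstring!r} not supported"
                )
            seq = rec.query_sequence
            if seq is None:
                raise ValueError(f"{path}: record {lineno}: missing sequence")
            seq = seq.upper()
            start = rec.reference_start + 1  # pysam is 0-based
            contig = rec.reference_name
            mismatches = _derive_mismatches(rec, seq, start, contig, reference, path, lineno)
            yield Alignment(
                read_id=rec.query_name,
                library=lib,
                contig=contig,
                start=start,
                strand="-" if rec.is_reverse else "+",
                seq=seq,
                mismatches=mismatches,
            )


def _derive_mismatches(rec, seq, start, contig, reference, path, lineno):
    if rec.has_tag("MD"):
        pairs = rec.get_aligned_pairs(with_seq=True)
        mm = []
        for qpos, rpos, rbase in pairs:
            if qpos is None or rpos is None or rbase is None:
                continue
            if rbase.islower():  # pysam lowercases mismatched reference bases
                mm.append((rpos + 1, seq[qpos]))
        return tuple(mm)
    if reference is not None:
        ref_seq = reference[contig][start - 1:start - 1 + len(seq)]
        return tuple(
            (start + i, seq[i]) for i in range(len(seq)) if seq[i] != ref_seq[i].upper()
        )
    if rec.has_tag("NM") and rec.get_tag("NM") == 0:
        return ()
    raise ValueError(
        f"{path}: record {lineno} ({rec.query_name}): cannot derive mismatches "
        "(no MD tag and no reference provided)"
    )


def write_sam(alignments: Iterable[Alignment], reference: Mapping[str, str],
              path: str | Path) -> None:
    """Write ungapped alignments as SAM with NM and MD tags."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in reference.items()],
    }
    tid = {name: i for i, name in enumerate(reference)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for aln in alignments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = aln.read_id
            rec.reference_id = tid[aln.contig]
            rec.reference_start = aln.start - 1
            rec.query_sequence = aln.seq
            rec.flag = 16 if aln.strand == "-" else 0
            rec.mapping_quality = 60
            rec.cigarstring = f"{len(aln.seq)}M"
            rec.query_qualities = pysam.qualitystring_to_array("I" * len(aln.seq))
            rec.set_tag("NM", len(aln.mismatches))
            rec.set_tag("MD", _md_tag(aln, reference))
            out.write(rec)


def _md_tag(aln: Alignment, reference: Mapping[str, str]) -> str:
    ref = reference[aln.contig][aln.start - 1:aln.end]
    mm_pos = {p - aln.start for p, _ in aln.mismatches}
    md, run = [], 0
    for i in range(len(aln.seq)):
        if i in mm_pos:
            md.append(str(run))
            md.append(ref[i].upper())
            run = 0
        else:
            run += 1
    md.append(str(run))
    return "".join(md)


class TestAligner:
    """Minimal ungapped aligner for synthetic reads (test support).

    Seeds on exact k-mers spaced so that any read within ``max_edit``
    substitutions of a genomic location keeps at least one error-free seed
    (pigeonhole over ``max_edit + 1`` read segments), then verifies candidates
    by Hamming distance on both strands. A read is reported only when a single
    location attains the best score ("one single best hit"); ties are dropped.
    """

    def __init__(self, reference: Mapping[str, str] | str, read_length: int,
                 max_edit: int | None = None):
        if isinstance(reference, str):
            reference = {"chr1": reference}
        self.reference = {name: seq.upper() for name, seq in reference.items()}
        self.read_length = read_length
        self.max_edit = default_max_edit(read_length) if max_edit is None else max_edit
        self.k = max(8, min(32, read_length // (self.max_edit + 1)))
        self._encoded = {name: encode(seq) for name, seq in self.reference.items()}
        self._index: dict[bytes, list[tuple[str, int]]] = {}
        for name, seq in self.reference.items():
            b = seq.encode("ascii")
            for i in range(0, len(b) - self.k + 1):
                self._index.setdefault(b[i:i + self.k], []).append((name, i))

    def _candidates(self, seq: bytes) -> set[tuple[str, int]]:
        cands: set[tuple[str, int]] = set()
        L = len(seq)
        offsets = list(range(0, L - self.k + 1, self.k))
        if offsets and offsets[-1] != L - self.k:
            offsets.append(L - self.k)
        for off in offsets:
            for contig, hit in self._index.get(seq[off:off + self.k], ()):
                start = hit - off
                if 0 <= start <= len(self.reference[contig]) - L:
                    cands.add((contig, start))
        return cands

    def align_read(self, seq: str) -> tuple[str, int, str, str, int] | None:
        """Best unique location for one read.

        Returns (contig, 0-based start, strand, oriented sequence, distance)
        or None when the read is unmapped or has tied best hits.
        """
        seq = seq.upper()
        best: tuple[str, int, str, str] | None = None
        best_dist = self.max_edit + 1
        tied = False
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            arr = encode(oriented)
            for contig, start in self._candidates(oriented.encode("ascii")):
                ref_arr = self._encoded[contig]
                d = int(np.count_nonzero(ref_arr[start:start + len(arr)] != arr))
                if d < best_dist:
                    best_dist, best, tied = d, (contig, start, strand, oriented), False
                elif d == best_dist and best is not None and (contig, start, strand) != best[:3]:
                    tied = True
        if best is None or tied or best_dist > self.max_edit:
            return None
        contig, start, strand, oriented = best
        return contig, start, strand, oriented, best_dist

    def align(self, reads: Iterable, library: str) -> list[Alignment]:
        """Align an iterable of reads (objects with .read_id and .seq)."""
        out = []
        for r in reads:
            hit = self.align_read(r.seq)
            if hit is None:
                continue
            contig, start0, strand, oriented, _ = hit
            ref = self.reference[contig]
            mm = tuple(
                (start0 + 1 + i, oriented[i])
                for i in range(len(oriented))
                if oriented[i] != ref[start0 + i]
            )
            out.append(
                Alignment(read_id=r.read_id, library=library, contig=contig,
                          start=start0 + 1, strand=strand, seq=oriented, mismatches=mm)
            )
        return out


def test_align(reads: Sequence, reference: Mapping[str, str] | str, *,
               max_edit: int | None = None, library: str = "reads") -> list[Alignment]:
    """Align synthetic FASTQ reads with the built-in ungapped aligner.

    ``max_edit`` defaults to 4 for reads up to ~100 bp and 6 for longer reads.
    Only reads with exactly one best-scoring location are emitted.
    """
    reads = list(reads)
    if not reads:
        return []
    rl = len(reads[0].seq)
    return TestAligner(reference, rl, max_edit).align(reads, library)


def remove_duplicates(alignments: Iterable[Alignment]) -> list[Alignment]:
    """Remove potential PCR duplicates on mapping coordinates.

    Among records sharing (library, contig, start, strand) exactly one
    representative is kept — the lexicographically smallest read id, for
    determinism. Output is sorted by (library, contig, start, strand).
    Idempotent by construction.
    """
    best: dict[tuple[str, str, int, str], Alignment] = {}
    for aln in alignments:
        key = (aln.library, aln.contig, aln.start, aln.strand)
        cur = best.get(key)
        if cur is None or aln.read_id < cur.read_id:
            best[key] = aln
    return [best[k] for k in sorted(best)]


def pileup_counts(alignments: Iterable[Alignment],
                  reference: Mapping[str, str]) -> dict[tuple[str, str], np.ndarray]:
    """Dense per-position base counts: (library, contig) -> (contig length, 4).

    Row i holds counts of A, C, G, T observed at 1-based position i + 1.
    """
    arrays: dict[tuple[str, str], np.ndarray] = {}
    for aln in alignments:
        key = (aln.library, aln.contig)
        arr = arrays.get(key)
        if arr is None:
            arr = arrays[key] = np.zeros((len(reference[aln.contig]), 4), dtype=np.int32)
        codes = base_indices(aln.seq)
        valid = codes != 255
        pos = np.arange(aln.start - 1, aln.start - 1 + len(aln.seq))
        np.add.at(arr, (pos[valid], codes[valid]), 1)
    return arrays


def pileup(alignments: Iterable[Alignment],
           reference: Mapping[str, str]) -> Iterator[PileupColumn]:
    """Coverage of each position by base A, C, G and T, per library.

    Positions with zero coverage are omitted. Expects duplicates already
    removed and only unique-best alignments.
    """
    arrays = pileup_counts(alignments, reference)
    for (library, contig) in sorted(arrays):
        arr = arrays[(library, contig)]
        covered = np.nonzero(arr.sum(axis=1))[0]
        for i in covered.tolist():
            yield PileupColumn(
                contig=contig,
                position=i + 1,
                counts=tuple(int(c) for c in arr[i]),
                library=library,
            )
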