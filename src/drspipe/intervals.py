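"""Genomic intervals and the interval set arithmetic the pipeline is built on.

All internal coordinates are 0-based half-open ``[start, end)``; file formats
that use other conventions (GFF3, SAF, SJ.out.tab) convert at the I/O boundary.
Set operations work on plain ``(start, end)`` tuples per chromosome, which keeps
the stringent-interval derivations easy to check against a per-base oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

Span = Tuple[int, int]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval.

    ``strand`` is one of ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def merge_spans(spans: Iterable[Span]) -> List[Span]:
    """Union of spans as maximal disjoint sorted intervals."""
    out: List[Span] = []
    for start, end in sorted(spans):
        if out and start <= out[-1][1]:
            if end > out[-1][1]:
                out[-1] = (out[-1][0], end)
        else:
            out.append((start, end))
    return out


def subtract_spans(minuend: Sequence[Span], subtrahend: Sequence[Span]) -> List[Span]:
    """Set difference ``union(minuend) - union(subtrahend)``.

    Both arguments may be unsorted/overlapping; the result is maximal disjoint
    sorted spans.
    """
    a = merge_spans(minuend)
    b = merge_spans(subtrahend)
    out: List[Span] = []
    j = 0
    for start, end in a:
        cur = start
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < end:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= end:
                break
            k += 1
        if cur < end:
            out.append((cur, end))
    return out


def complement_spans(spans: Sequence[Span], lo: int, hi: int) -> List[Span]:
    """Complement of ``union(spans)`` within ``[lo, hi)``."""
    return subtract_spans([(lo, hi)], spans)


def intersect_size(blocks: Sequence[Span], span: Span) -> int:
    """Total overlap (in bases) between a block list and one span."""
    s, e = span
    total = 0
    for bs, be in blocks:
        total += max(0, min(be, e) - max(bs, s))
    return total


@dataclass
class TranscriptModel:
    """One transcript: ordered exons, optional CDS, strand and biotype.

    Exons are sorted in genome order (ascending start) and non-overlapping;
    for minus-strand transcripts the 5' end is therefore the *last* exon's end.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: List[GenomicInterval]
    cds: List[GenomicInterval] | None = None
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap "
                    f"({prev.start},{prev.end}) vs ({cur.start},{cur.end})"
                )
            if cur.start == prev.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: zero-length intron"
                )
        if self.cds:
            self.cds = sorted(self.cds, key=lambda iv: iv.start)
            exon_spans = [(e.start, e.end) for e in self.exons]
            for c in self.cds:
                if intersect_size(exon_spans, (c.start, c.end)) != len(c):
                    raise ValueError(
                        f"transcript {self.transcript_id}: CDS interval "
                        f"[{c.start},{c.end}) not contained in exons"
                    )

    @property
    def span(self) -> Span:
        return (self.exons[0].start, self.exons[-1].end)

    @property
    def introns(self) -> List[Span]:
        return [
            (prev.end, cur.start) for prev, cur in zip(self.exons, self.exons[1:])
        ]

    @property
    def intron_chain(self) -> Tuple[Span, ...]:
        return tuple(self.introns)

    @property
    def tss(self) -> int:
        """Genomic coordinate of the 5'-most transcribed base (strand-aware)."""
        if self.strand == "-":
            return self.exons[-1].end - 1
        return self.exons[0].start

    @property
    def three_prime_end(self) -> int:
        """3'-end coordinate: max end for '+', min start for '-'."""
        if self.strand == "-":
            return self.exons[0].start
        return self.exons[-1].end

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    biotype: str = "protein_coding"
    transcripts: List[TranscriptModel] = field(default_factory=list)

    @property
    def span(self) -> Span:
        starts = [t.span[0] for t in self.transcripts]
        ends = [t.span[1] for t in self.transcripts]
        return (min(starts), max(ends))

    @property
    def span_length(self) -> int:
        s, e = self.span
        return e - s
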