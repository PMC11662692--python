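"""Long-read filtering and feature assignment.

Nanopore direct RNA sequencing reads are frequently 5'-truncated; only reads
whose 5' end sits at an annotated transcription start site and which carry a
poly(A) tail call that passed QC are treated as full-length. Feature
assignment mirrors fractional-overlap read counting: a read is assigned to a
feature only when at least a given fraction of its aligned bases overlap it.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

from .annotation import AnnotationDB
from .intervals import GenomicInterval, Span, intersect_size


@dataclass
class ReadRecord:
    """One aligned long read as a list of aligned blocks."""

    read_id: str
    chrom: str
    strand: str
    blocks: List[Span]
    is_secondary: bool = False
    is_supplementary: bool = False
    polya_qc: str = "PASS"
    polya_length: float | None = None

    def __post_init__(self) -> None:
        self.blocks = sorted(tuple(b) for b in self.blocks)
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if s2 < e1:
                raise ValueError(f"read {self.read_id}: overlapping blocks")
        for s, e in self.blocks:
            if e <= s or s < 0:
                raise ValueError(f"read {self.read_id}: invalid block [{s},{e})")

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def five_prime_pos(self) -> int:
        """Genomic coordinate of the 5'-most aligned base (strand-aware)."""
        if self.strand == "-":
            return self.blocks[-1][1] - 1
        return self.blocks[0][0]


# -- TSV dialect -----------------------------------------------------------

_READ_COLUMNS = [
    "read_id", "chrom", "strand", "block_starts", "block_ends",
    "is_secondary", "is_supplementary", "polya_qc", "polya_length",
]


def read_reads_tsv(path: str | Path) -> List[ReadRecord]:
    reads: List[ReadRecord] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            starts = [int(x) for x in row["block_starts"].split(",") if x]
            ends = [int(x) for x in row["block_ends"].split(",") if x]
            length = row.get("polya_length", "")
            reads.append(
                ReadRecord(
                    read_id=row["read_id"],
                    chrom=row["chrom"],
                    strand=row["strand"],
                    blocks=list(zip(starts, ends)),
                    is_secondary=row["is_secondary"] == "1",
                    is_supplementary=row["is_supplementary"] == "1",
                    polya_qc=row["polya_qc"],
                    polya_length=float(length) if length else None,
                )
            )
    return reads


def write_reads_tsv(reads: Sequence[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_READ_COLUMNS) + "\n")
        for r in reads:
            fh.write(
                "\t".join(
                    [
                        r.read_id,
                        r.chrom,
                        r.strand,
                        ",".join(str(s) for s, _ in r.blocks),
                        ",".join(str(e) for _, e in r.blocks),
                        "1" if r.is_secondary else "0",
                        "1" if r.is_supplementary else "0",
                        r.polya_qc,
                        "" if r.polya_length is None else f"{r.polya_length:.2f}",
                    ]
                )
                + "\n"
            )


# -- full-length filter ----------------------------------------------------


def filter_full_length(
    reads: Sequence[ReadRecord],
    db: AnnotationDB,
    tss_window: int = 10,
) -> Tuple[List[ReadRecord], Dict[str, int]]:
    """Sequential full-length filter with per-stage removal counts.

    Stages: (0) reads on contigs absent from the annotation are dropped and
    counted separately; (1) secondary/supplementary alignments; (2) reads whose
    strand-aware 5' end lies farther than ``tss_window`` nt from every
    annotated TSS on the same chromosome and strand; (3) reads whose poly(A)
    tail call is not PASS.
    """
    tss_by_key: Dict[Tuple[str, str], np.ndarray] = {}
    for chrom, strand, pos in db.tss_set():
        tss_by_key.setdefault((chrom, strand), []).append(pos)  # type: ignore[arg-type]
    tss_by_key = {k: np.sort(np.asarray(v)) for k, v in tss_by_key.items()}

    counts = {
        "input": len(reads),
        "unknown_chrom": 0,
        "secondary_or_supplementary": 0,
        "tss_fail": 0,
        "polya_fail": 0,
        "kept": 0,
    }
    kept: List[ReadRecord] = []
    for r in reads:
        if r.chrom not in db.chrom_sizes:
            counts["unknown_chrom"] += 1
            continue
        if r.is_secondary or r.is_supplementary:
            counts["secondary_or_supplementary"] += 1
            continue
        positions = tss_by_key.get((r.chrom, r.strand))
        pos5 = r.five_prime_pos
        if positions is None or not _within(positions, pos5, tss_window):
            counts["tss_fail"] += 1
            continue
        if r.polya_qc != "PASS":
            counts["polya_fail"] += 1
            continue
        counts["kept"] += 1
        kept.append(r)
    return kept, counts


def _within(sorted_positions: np.ndarray, pos: int, window: int) -> bool:
    i = int(np.searchsorted(sorted_positions, pos))
    for j in (i - 1, i):
        if 0 <= j < len(sorted_positions) and abs(int(sorted_positions[j]) - pos) <= window:
            return True
    return False


# -- fractional-overlap assignment ----------------------------------------


@dataclass
class AssignmentResult:
    feature_counts: Counter = field(default_factory=Counter)
    n_assigned: int = 0
    n_ambiguous: int = 0
    n_unassigned: int = 0
    n_reads: int = 0

    @property
    def percent_assigned(self) -> float:
        if self.n_reads == 0:
            raise ValueError("no reads to assign")
        return 100.0 * self.n_assigned / self.n_reads


def assign_reads_to_features(
    reads: Sequence[ReadRecord],
    features: Sequence[Tuple[str, GenomicInterval]],
    frac_overlap: float = 0.5,
    strand_mode: str = "ignore",
) -> AssignmentResult:
    """Assign each read to the feature holding >= ``frac_overlap`` of its
    aligned bases.

    When several features qualify, the largest overlap wins; an exact tie is
    counted ambiguous (not double-counted). ``strand_mode`` is ``ignore``,
    ``same`` or ``opposite`` (the latter matching reverse-stranded short-read
    protocols).
    """
    if strand_mode not in ("ignore", "same", "opposite"):
        raise ValueError(f"invalid strand_mode {strand_mode!r}")
    trees: Dict[str, IntervalTree] = {}
    for fid, iv in features:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, (fid, iv))

    res = AssignmentResult(n_reads=len(reads))
    for r in reads:
        tree = trees.get(r.chrom)
        overlaps: Dict[str, int] = {}
        if tree is not None:
            hits = set()
            for s, e in r.blocks:
                hits |= tree.overlap(s, e)
            for hit in hits:
                fid, iv = hit.data
                if strand_mode == "same" and iv.strand != r.strand:
                    continue
                if strand_mode == "opposite" and (
                    iv.strand == r.strand or iv.strand == "." or r.strand == "."
                ):
                    continue
                ov = intersect_size(r.blocks, (iv.start, iv.end))
                if ov > 0:
                    overlaps[fid] = overlaps.get(fid, 0) + ov
        threshold = frac_overlap * r.aligned_length
        qualifying = {f: ov for f, ov in overlaps.items() if ov >= threshold and ov > 0}
        if not qualifying:
            res.n_unassigned += 1
            continue
        best = max(qualifying.values())
        winners = [f for f, ov in qualifying.items() if ov == best]
        if len(winners) > 1:
            res.n_ambiguous += 1
        else:
            res.feature_counts[winners[0]] += 1
            res.n_assigned += 1
    return res


# -- metagene profile ------------------------------------------------------


def metagene_profile(
    reads: Sequence[ReadRecord],
    db: AnnotationDB,
    n_bins: int = 100,
) -> np.ndarray:
    """Mean normalized read density across protein-coding gene bodies.

    Each gene span is cut into ``n_bins`` equal bins ordered 5' to 3'
    (strand-aware); per-gene bin coverages are normalized to the gene's mean
    bin coverage, then averaged over genes. Genes shorter than ``n_bins`` nt
    or with zero coverage from same-strand reads are excluded.
    """
    genes = [
        g for g in db.genes.values()
        if g.biotype == "protein_coding" and g.span_length >= n_bins
    ]
    if not genes:
        raise ValueError("no eligible protein-coding genes")

    trees: Dict[Tuple[str, str], IntervalTree] = {}
    for gi, g in enumerate(genes):
        s, e = g.span
        trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(s, e, gi)

    coverage = [np.zeros(g.span_length) for g in genes]
    for r in reads:
        if r.is_secondary or r.is_supplementary:
            continue
        tree = trees.get((r.chrom, r.strand))
        if tree is None:
            continue
        hits = set()
        for s, e in r.blocks:
            hits |= tree.overlap(s, e)
        for hit in hits:
            gi = hit.data
            gs, _ = genes[gi].span
            cov = coverage[gi]
            for s, e in r.blocks:
                lo = max(s, hit.begin) - gs
                hi = min(e, hit.end) - gs
                if hi > lo:
                    cov[lo:hi] += 1

    profiles = []
    for g, cov in zip(genes, coverage):
        if cov.sum() == 0:
            continue
        L = len(cov)
        edges = (np.arange(n_bins + 1) * L) // n_bins
        bins = np.array(
            [cov[edges[i]:edges[i + 1]].mean() for i in range(n_bins)]
        )
        if g.strand == "-":
            bins = bins[::-1]
        profiles.append(bins / bins.mean())
    if not profiles:
        raise ValueError("no gene has nonzero coverage")
    return np.mean(profiles, axis=0)
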