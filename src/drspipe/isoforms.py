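"""Isoform call-set filtering and novelty classification.

An isoform's identity is its exact intron chain; terminal exon ends are free.
After read-support filtering (>=20 total reads and >=10% of the gene's reads),
each surviving isoform is classified as:

* ``fusion``      — splice-novel, has an intron longer than the median gene
                    span and exons overlapping two or more annotated genes;
* ``novel``       — intron chain absent from the annotation;
* ``novel_utr3``  — annotated chain, but the 3'UTR end of the productive
                    transcript falls more than 10 bp from every annotated
                    3' end of its gene;
* ``known``       — everything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Set, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .annotation import AnnotationDB
from .intervals import GenomicInterval, Span, intersect_size

START_CODON = "ATG"
STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class IsoformCall:
    """One isoform model (BED12 structure) with per-sample read counts."""

    isoform_id: str
    chrom: str
    strand: str
    exons: List[Span]
    read_counts: Dict[str, int] = field(default_factory=dict)
    gene_id: str | None = None
    productivity: str = "unknown"

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"isoform {self.isoform_id}: invalid exon order")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> List[Span]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    @property
    def intron_chain(self) -> Tuple[Span, ...]:
        return tuple(self.introns)

    @property
    def total_reads(self) -> int:
        return sum(self.read_counts.values())

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    # transcript-coordinate helpers (0 at the 5' end, strand-aware)

    def tx_to_genomic_blocks(self, tx_start: int, tx_end: int) -> List[Span]:
        """Genomic spans covered by transcript coordinates [tx_start, tx_end)."""
        if not 0 <= tx_start < tx_end <= self.exonic_length:
            raise ValueError("transcript coordinates out of range")
        exons = self.exons if self.strand != "-" else self.exons[::-1]
        out: List[Span] = []
        offset = 0
        for s, e in exons:
            length = e - s
            lo = max(tx_start - offset, 0)
            hi = min(tx_end - offset, length)
            if hi > lo:
                if self.strand == "-":
                    out.append((e - hi, e - lo))
                else:
                    out.append((s + lo, s + hi))
            offset += length
        return sorted(out)

    def genomic_to_tx(self, gpos: int) -> int | None:
        """Transcript coordinate of a genomic position, or None if intronic."""
        offset = 0
        exons = self.exons if self.strand != "-" else self.exons[::-1]
        for s, e in exons:
            if s <= gpos < e:
                return offset + (gpos - s if self.strand != "-" else e - 1 - gpos)
            offset += e - s
        return None

    def spliced_sequence(self, db: AnnotationDB) -> str:
        parts = [db.get_seq(self.chrom, s, e) for s, e in self.exons]
        seq = "".join(parts)
        if self.strand == "-":
            from .genetic_code import revcomp

            seq = revcomp(seq)
        return seq


# -- BED12 / counts I/O ----------------------------------------------------


def read_bed12(path: str | Path) -> List[IsoformCall]:
    out: List[IsoformCall] = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            chrom, start = f[0], int(f[1])
            name, strand = f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)]
            out.append(IsoformCall(name, chrom, strand, exons))
    return out


def write_bed12(isoforms: Sequence[IsoformCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iso in isoforms:
            start, end = iso.start, iso.end
            sizes = ",".join(str(e - s) for s, e in iso.exons)
            starts = ",".join(str(s - start) for s, _ in iso.exons)
            fh.write(
                f"{iso.chrom}\t{start}\t{end}\t{iso.isoform_id}\t0\t{iso.strand}\t"
                f"{start}\t{end}\t0\t{len(iso.exons)}\t{sizes}\t{starts}\n"
            )


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def attach_counts(isoforms: Sequence[IsoformCall], counts: pd.DataFrame) -> None:
    for iso in isoforms:
        if iso.isoform_id in counts.index:
            iso.read_counts = {
                c: int(v) for c, v in counts.loc[iso.isoform_id].items()
            }


# -- gene assignment and filtering ----------------------------------------


def _exon_tree(db: AnnotationDB, stranded: bool) -> Dict[tuple, IntervalTree]:
    trees: Dict[tuple, IntervalTree] = {}
    for t in db.transcripts:
        key = (t.chrom, t.strand) if stranded else (t.chrom,)
        tree = trees.setdefault(key, IntervalTree())
        for e in t.exons:
            tree.addi(e.start, e.end, t.gene_id)
    return trees


def assign_genes(isoforms: Sequence[IsoformCall], db: AnnotationDB) -> None:
    """Assign each isoform to the same-strand gene sharing the most exonic
    overlap; exact ties leave the isoform unassigned."""
    trees = _exon_tree(db, stranded=True)
    for iso in isoforms:
        tree = trees.get((iso.chrom, iso.strand))
        overlap: Dict[str, int] = {}
        if tree is not None:
            hits = set()
            for s, e in iso.exons:
                hits |= tree.overlap(s, e)
            for hit in hits:
                ov = intersect_size(iso.exons, (hit.begin, hit.end))
                if ov > 0:
                    overlap[hit.data] = overlap.get(hit.data, 0) + ov
        if not overlap:
            iso.gene_id = None
            continue
        best = max(overlap.values())
        winners = [g for g, ov in overlap.items() if ov == best]
        iso.gene_id = winners[0] if len(winners) == 1 else None


def filter_isoforms(
    callset: Sequence[IsoformCall],
    min_total_reads: int = 20,
    min_gene_fraction: float = 0.10,
) -> List[IsoformCall]:
    """Keep isoforms with >= ``min_total_reads`` summed over all samples AND
    >= ``min_gene_fraction`` of the total reads of their gene's isoforms.

    Unassigned isoforms pass the fraction rule vacuously. Both thresholds are
    inclusive. Idempotent: gene totals only shrink after filtering, so every
    survivor survives a second pass.
    """
    gene_totals: Dict[str, int] = {}
    for iso in callset:
        if iso.gene_id is not None:
            gene_totals[iso.gene_id] = gene_totals.get(iso.gene_id, 0) + iso.total_reads
    kept = []
    for iso in callset:
        if iso.total_reads < min_total_reads:
            continue
        if iso.gene_id is not None and gene_totals[iso.gene_id] > 0:
            # ratio comparison keeps the inclusive boundary exact (10/100 == 0.10)
            if iso.total_reads / gene_totals[iso.gene_id] < min_gene_fraction:
                continue
        kept.append(iso)
    return kept


# -- novelty classification ------------------------------------------------


def classify_splice_novelty(
    isoform: IsoformCall,
    db: AnnotationDB,
    end_tolerance: int = 10,
) -> str:
    """``known`` iff some annotated transcript on the same chrom+strand has an
    identical intron chain; mono-exonic isoforms are known iff contained in a
    mono-exonic annotated transcript extended by ``end_tolerance`` both ends."""
    if len(isoform.exons) > 1:
        chains = db.intron_chain_index().get((isoform.chrom, isoform.strand), set())
        return "known" if isoform.intron_chain in chains else "novel"
    for t in db.transcripts:
        if (
            t.chrom == isoform.chrom
            and t.strand == isoform.strand
            and len(t.exons) == 1
            and t.span[0] - end_tolerance <= isoform.start
            and isoform.end <= t.span[1] + end_tolerance
        ):
            return "known"
    return "novel"


@dataclass
class ProductivityResult:
    productive: bool
    start_tx: int | None = None
    stop_tx: int | None = None  # transcript coordinate of the stop codon start
    reason: str = ""


def predict_productivity(
    isoform: IsoformCall,
    db: AnnotationDB,
) -> ProductivityResult:
    """ORF-based productivity call.

    The start codon is the assigned gene's annotated start codon when that
    genomic position maps into the isoform; otherwise the first AUG of the
    spliced sequence. The isoform is productive iff an in-frame stop codon
    occurs before the transcript end.
    """
    seq = isoform.spliced_sequence(db)
    start_tx: int | None = None
    if isoform.gene_id and isoform.gene_id in db.genes:
        gene = db.genes[isoform.gene_id]
        cds_starts = []
        for t in gene.transcripts:
            if t.cds:
                if t.strand == "-":
                    cds_starts.append(max(c.end for c in t.cds) - 1)
                else:
                    cds_starts.append(min(c.start for c in t.cds))
        # 5'-most annotated start codon position, strand-aware
        if cds_starts:
            gpos = max(cds_starts) if gene.strand == "-" else min(cds_starts)
            tx = isoform.genomic_to_tx(gpos)
            if tx is not None and seq[tx : tx + 3] == START_CODON:
                start_tx = tx
    if start_tx is None:
        start_tx = seq.find(START_CODON)
        if start_tx < 0:
            return ProductivityResult(False, reason="no start codon")
    for i in range(start_tx, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return ProductivityResult(True, start_tx=start_tx, stop_tx=i)
    return ProductivityResult(False, start_tx=start_tx, reason="no in-frame stop")


def extract_utr3(
    isoform: IsoformCall,
    stop_tx: int,
) -> Tuple[List[GenomicInterval], int]:
    """3'UTR of a productive isoform: from the base after the stop codon to the
    transcript 3' end, as the spliced genomic interval set plus the terminal
    genomic 3'-end coordinate."""
    utr_start = stop_tx + 3
    L = isoform.exonic_length
    end_coord = isoform.start if isoform.strand == "-" else isoform.end
    if utr_start >= L:
        return [], end_coord
    blocks = isoform.tx_to_genomic_blocks(utr_start, L)
    return (
        [GenomicInterval(isoform.chrom, s, e, isoform.strand) for s, e in blocks],
        end_coord,
    )


def classify_utr3_novelty(
    utr3_end: int,
    gene_id: str | None,
    utr3_end_index: Dict[str, Set[int]],
    window: int = 10,
    gene_scoped: bool = True,
) -> str:
    """``known`` iff the 3' end lies within ``window`` nt of an annotated
    3'UTR end (of the same gene by default); else ``novel``."""
    if gene_scoped:
        ends = utr3_end_index.get(gene_id, set()) if gene_id else set()
    else:
        ends = {e for s in utr3_end_index.values() for e in s}
    if any(abs(utr3_end - e) <= window for e in ends):
        return "known"
    return "novel"


def screen_fusion_isoforms(
    novel_isoforms: Sequence[IsoformCall],
    db: AnnotationDB,
    min_intron: int | None = None,
) -> List[IsoformCall]:
    """Fusion candidates among splice-novel isoforms: at least one intron
    strictly longer than ``min_intron`` (default: median annotated gene span)
    and exons overlapping exons of >= 2 distinct annotated genes (>= 1 nt,
    strand-blind)."""
    if min_intron is None:
        min_intron = db.median_gene_length()
    trees = _exon_tree(db, stranded=False)
    out: List[IsoformCall] = []
    for iso in novel_isoforms:
        if not any(e - s > min_intron for s, e in iso.introns):
            continue
        tree = trees.get((iso.chrom,))
        genes: Set[str] = set()
        if tree is not None:
            for s, e in iso.exons:
                for hit in tree.overlap(s, e):
                    genes.add(hit.data)
        if len(genes) >= 2:
            out.append(iso)
    return out


# -- orchestration ---------------------------------------------------------


def classify_callset(
    callset: Sequence[IsoformCall],
    db: AnnotationDB,
    end_tolerance: int = 10,
    utr_window: int = 10,
    min_intron: int | None = None,
) -> pd.DataFrame:
    """Four-way classification report for a (filtered) isoform call set.

    Returns one row per isoform: gene, read support, splice novelty,
    productivity, 3'UTR end and distance to the nearest annotated end, fusion
    evidence, and the final category (fusion > novel > novel_utr3 > known).
    """
    if min_intron is None:
        min_intron = db.median_gene_length()
    utr_index = db.utr3_ends()
    splice_labels = {
        iso.isoform_id: classify_splice_novelty(iso, db, end_tolerance)
        for iso in callset
    }
    novel = [iso for iso in callset if splice_labels[iso.isoform_id] == "novel"]
    fusion_ids = {
        iso.isoform_id for iso in screen_fusion_isoforms(novel, db, min_intron)
    }
    rows = []
    for iso in callset:
        splice = splice_labels[iso.isoform_id]
        prod = predict_productivity(iso, db)
        iso.productivity = "productive" if prod.productive else "unproductive"
        utr_end = None
        utr_dist = None
        utr_label = ""
        if prod.productive and prod.stop_tx is not None:
            _, utr_end = extract_utr3(iso, prod.stop_tx)
            utr_label = classify_utr3_novelty(
                utr_end, iso.gene_id, utr_index, window=utr_window
            )
            ends = utr_index.get(iso.gene_id, set()) if iso.gene_id else set()
            if ends:
                utr_dist = min(abs(utr_end - e) for e in ends)
        if iso.isoform_id in fusion_ids:
            category = "fusion"
        elif splice == "novel":
            category = "novel"
        elif utr_label == "novel":
            category = "novel_utr3"
        else:
            category = "known"
        rows.append(
            {
                "isoform_id": iso.isoform_id,
                "gene_id": iso.gene_id or "",
                "total_reads": iso.total_reads,
                "splice_novelty": splice,
                "productivity": iso.productivity,
                "utr3_end": utr_end if utr_end is not None else -1,
                "utr3_end_distance": utr_dist if utr_dist is not None else -1,
                "utr3_novelty": utr_label,
                "is_fusion": iso.isoform_id in fusion_ids,
                "category": category,
            }
        )
    return pd.DataFrame(rows).set_index("isoform_id")
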