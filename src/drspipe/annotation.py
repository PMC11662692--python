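"""Annotation database: GFF3 + genome ingest and every derived reference index.

The pipeline compares reads, junctions, isoforms and modification sites against
indexes derived once from the annotation:

* stringent introns — inter-exon regions overlapping no annotated exon of any
  gene (any biotype, either strand);
* stringent intergenic — the complement of transcript spans, minus exons;
* the junction database — every distinct annotated intron;
* the TSS set — strand-aware transcript 5' ends, used by the full-length filter;
* annotated 3'UTR ends per gene — used by the novel-3'UTR rule;
* the median gene span length — the fusion-screen intron threshold.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Set, Tuple

import gffutils
from pyfaidx import Fasta

from .genetic_code import revcomp
from .intervals import (
    GeneModel,
    GenomicInterval,
    Span,
    TranscriptModel,
    complement_spans,
    merge_spans,
    subtract_spans,
)

logger = logging.getLogger(__name__)

_TRANSCRIPT_TYPES = ("mRNA", "transcript")
_KNOWN_TYPES = {"gene", "exon", "CDS", *_TRANSCRIPT_TYPES}


@dataclass
class AnnotationDB:
    """Parsed gene models plus cached derived indexes."""

    genes: Dict[str, GeneModel]
    chrom_sizes: Dict[str, int]
    fasta_path: Path | None = None
    _fasta: Fasta | None = field(default=None, repr=False)
    _cache: dict = field(default_factory=dict, repr=False)

    # -- basic access ------------------------------------------------------

    @property
    def transcripts(self) -> List[TranscriptModel]:
        return [t for g in self.genes.values() for t in g.transcripts]

    def get_seq(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Genome sequence for [start, end); reverse-complemented for '-'."""
        if self._fasta is None:
            if self.fasta_path is None:
                raise ValueError("no genome FASTA attached to this AnnotationDB")
            self._fasta = Fasta(str(self.fasta_path))
        seq = str(self._fasta[chrom][start:end]).upper()
        return revcomp(seq) if strand == "-" else seq

    # -- derived indexes ---------------------------------------------------

    def exon_union(self) -> Dict[str, List[Span]]:
        """Union of ALL annotated exons per chromosome (any biotype/strand)."""
        if "exon_union" not in self._cache:
            per_chrom: Dict[str, List[Span]] = {}
            for t in self.transcripts:
                per_chrom.setdefault(t.chrom, []).extend(
                    (e.start, e.end) for e in t.exons
                )
            self._cache["exon_union"] = {
                c: merge_spans(sp) for c, sp in per_chrom.items()
            }
        return self._cache["exon_union"]

    def transcript_span_union(self) -> Dict[str, List[Span]]:
        if "span_union" not in self._cache:
            per_chrom: Dict[str, List[Span]] = {}
            for t in self.transcripts:
                per_chrom.setdefault(t.chrom, []).append(t.span)
            self._cache["span_union"] = {
                c: merge_spans(sp) for c, sp in per_chrom.items()
            }
        return self._cache["span_union"]

    def stringent_introns(self) -> List[GenomicInterval]:
        """Inter-exon regions minus every annotated exon, unstranded.

        Per chromosome: the union over all transcripts of their intron spans,
        minus the union of all exons of all genes (both strands, any biotype),
        returned as maximal disjoint intervals.
        """
        if "stringent_introns" not in self._cache:
            gaps: Dict[str, List[Span]] = {}
            for t in self.transcripts:
                gaps.setdefault(t.chrom, []).extend(t.introns)
            exons = self.exon_union()
            out: List[GenomicInterval] = []
            for chrom in sorted(gaps):
                for s, e in subtract_spans(gaps[chrom], exons.get(chrom, [])):
                    out.append(GenomicInterval(chrom, s, e, "."))
            self._cache["stringent_introns"] = out
        return self._cache["stringent_introns"]

    def stringent_intergenic(self, include_termini: bool = False) -> List[GenomicInterval]:
        """Complement of transcript spans, minus exons, per chromosome.

        With ``include_termini=False`` (default) the regions before the first
        and after the last transcript span on each chromosome are dropped, so
        only regions lying *between* annotated transcripts remain.
        """
        key = ("stringent_intergenic", include_termini)
        if key not in self._cache:
            spans = self.transcript_span_union()
            exons = self.exon_union()
            out: List[GenomicInterval] = []
            for chrom in sorted(self.chrom_sizes):
                size = self.chrom_sizes[chrom]
                chrom_spans = spans.get(chrom, [])
                comp = complement_spans(chrom_spans, 0, size)
                if not include_termini and chrom_spans:
                    first, last = chrom_spans[0][0], chrom_spans[-1][1]
                    comp = [(s, e) for s, e in comp if s >= first and e <= last]
                elif not include_termini:
                    comp = []
                for s, e in subtract_spans(comp, exons.get(chrom, [])):
                    out.append(GenomicInterval(chrom, s, e, "."))
            self._cache[key] = out
        return self._cache[key]

    def junction_db(self) -> Set[Tuple[str, int, int, str]]:
        """Every distinct annotated intron as (chrom, start, end, strand)."""
        if "junction_db" not in self._cache:
            self._cache["junction_db"] = {
                (t.chrom, s, e, t.strand)
                for t in self.transcripts
                for s, e in t.introns
            }
        return self._cache["junction_db"]

    def median_gene_length(self) -> int:
        """Median gene span length; even count -> midpoint rounded half away from zero."""
        if not self.genes:
            raise ValueError("annotation contains no genes")
        if "median_gene_length" not in self._cache:
            spans = sorted(g.span_length for g in self.genes.values())
            n = len(spans)
            if n % 2:
                med = spans[n // 2]
            else:
                mid = (spans[n // 2 - 1] + spans[n // 2]) / 2
                med = int(mid + 0.5) if mid >= 0 else -int(-mid + 0.5)
            self._cache["median_gene_length"] = int(med)
        return self._cache["median_gene_length"]

    def utr3_ends(self) -> Dict[str, Set[int]]:
        """Per gene, the set of annotated 3'-end coordinates of coding transcripts."""
        if "utr3_ends" not in self._cache:
            ends: Dict[str, Set[int]] = {}
            for t in self.transcripts:
                if t.cds:
                    ends.setdefault(t.gene_id, set()).add(t.three_prime_end)
            self._cache["utr3_ends"] = ends
        return self._cache["utr3_ends"]

    def tss_set(self) -> Set[Tuple[str, str, int]]:
        """Strand-aware transcript 5' ends as (chrom, strand, position)."""
        if "tss_set" not in self._cache:
            self._cache["tss_set"] = {
                (t.chrom, t.strand, t.tss) for t in self.transcripts
            }
        return self._cache["tss_set"]

    def intron_chain_index(self) -> Dict[Tuple[str, str], Set[Tuple[Span, ...]]]:
        """Annotated intron chains keyed by (chrom, strand), for isoform identity."""
        if "chain_index" not in self._cache:
            idx: Dict[Tuple[str, str], Set[Tuple[Span, ...]]] = {}
            for t in self.transcripts:
                if len(t.exons) > 1:
                    idx.setdefault((t.chrom, t.strand), set()).add(t.intron_chain)
            self._cache["chain_index"] = idx
        return self._cache["chain_index"]


# -- GFF3 / FASTA ingest ---------------------------------------------------


def _attr_first(feature, *names: str) -> str | None:
    for name in names:
        if name in feature.attributes:
            return feature.attributes[name][0]
    return None


def parse_gff(gff_path: str | Path, fasta_path: str | Path) -> AnnotationDB:
    """Parse a GFF3 annotation and its genome FASTA into an :class:`AnnotationDB`.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    Unknown feature types are skipped with a logged count; a transcript with no
    exons, or an exon outside its chromosome, is a hard error.
    """
    gff_path = Path(gff_path)
    fasta_path = Path(fasta_path)
    fasta = Fasta(str(fasta_path))
    chrom_sizes = {name: len(fasta[name]) for name in fasta.keys()}

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )

    skipped = Counter(
        ft for ft in db.featuretypes() if ft not in _KNOWN_TYPES
    )
    if skipped:
        for ft in skipped:
            n = db.count_features_of_type(ft)
            logger.info("skipping %d feature(s) of unknown type %r", n, ft)

    genes: Dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        gene_id = _attr_first(gene, "ID", "gene_id") or gene.id
        biotype = _attr_first(gene, "biotype", "gene_biotype") or "protein_coding"
        gmodel = GeneModel(gene_id=gene_id, chrom=gene.seqid, strand=gene.strand,
                           biotype=biotype)
        for tx in db.children(gene, featuretype=_TRANSCRIPT_TYPES, level=1):
            tx_id = _attr_first(tx, "ID", "transcript_id") or tx.id
            exons: List[GenomicInterval] = []
            cds: List[GenomicInterval] = []
            for child in db.children(tx, level=1):
                if child.featuretype not in ("exon", "CDS"):
                    continue
                chrom = child.seqid
                if chrom not in chrom_sizes:
                    raise ValueError(
                        f"{child.featuretype} of transcript {tx_id} on unknown "
                        f"contig {chrom!r}"
                    )
                start, end = child.start - 1, child.end
                if start < 0 or end > chrom_sizes[chrom]:
                    raise ValueError(
                        f"{child.featuretype} [{child.start},{child.end}] of "
                        f"transcript {tx_id} outside contig {chrom} "
                        f"(length {chrom_sizes[chrom]})"
                    )
                iv = GenomicInterval(chrom, start, end, tx.strand)
                (exons if child.featuretype == "exon" else cds).append(iv)
            if not exons:
                raise ValueError(f"transcript {tx_id} has no exons")
            gmodel.transcripts.append(
                TranscriptModel(
                    transcript_id=tx_id,
                    gene_id=gene_id,
                    chrom=tx.seqid,
                    strand=tx.strand,
                    exons=exons,
                    cds=cds or None,
                    biotype=_attr_first(tx, "biotype") or biotype,
                )
            )
        if not gmodel.transcripts:
            logger.info("gene %s has no transcripts; skipped", gene_id)
            continue
        genes[gene_id] = gmodel

    return AnnotationDB(genes=genes, chrom_sizes=chrom_sizes, fasta_path=fasta_path)


# -- exports ---------------------------------------------------------------


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path,
              name_prefix: str = "region") -> None:
    """Write intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            strand = iv.strand if iv.strand != "." else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name_prefix}_{i}\t0\t{strand}\n")


def write_saf(intervals: Sequence[GenomicInterval], path: str | Path,
              name_prefix: str = "region") -> None:
    """Write intervals in the SAF dialect (1-based inclusive) used by
    short-read feature counting."""
    with open(path, "w") as fh:
        fh.write("GeneID\tChr\tStart\tEnd\tStrand\n")
        for i, iv in enumerate(intervals):
            strand = iv.strand if iv.strand != "." else "+"
            fh.write(
                f"{name_prefix}_{i}\t{iv.chrom}\t{iv.start + 1}\t{iv.end}\t{strand}\n"
            )
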