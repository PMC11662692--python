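"""Seeded synthetic-data generator with a machine-readable truth manifest.

Emulates every input the pipeline consumes — genome FASTA, GFF3 annotation,
aligned-read TSV, per-sample splice-junction tables, an isoform call set
(BED12 + counts), per-read poly(A) tail tables, per-replicate modification
call tables, a repeat track and a tissue expression matrix — with planted
ground truth for every record, so each pipeline stage can be checked exactly.

Planted structure mirrors the study conditions the pipeline was built for:
~50% 5'-truncated (3'-biased) reads, per-sample unannotated-junction read
fractions, the four isoform categories with threshold-straddling read counts
(19/20 reads, 10/11 nt 3'UTR offsets, fusion introns one base either side of
the median gene span), abundance-anticorrelated poly(A) tail lengths with
planted old-young median shifts, and modification sites whose per-replicate
fractions/confidences straddle the consensus thresholds (0.049/0.05,
0.989/0.99, 0.89/0.90).

A single seed drives one root ``SeedSequence``; every sub-generator draws from
a deterministically spawned substream, so identical configs produce
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .intervals import GeneModel, GenomicInterval, Span, TranscriptModel
from .isoforms import IsoformCall, write_bed12
from .junctions import JunctionRecord, write_sj_tab
from .reads import ReadRecord, write_reads_tsv

BASES = np.array(list("ACGT"))
_CODE = {b: i for i, b in enumerate("ACGT")}  # complement: 3 - code
STOP_CODES = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA TAG TGA
ATG = (0, 3, 2)

YOUNG_SAMPLES = ("d1", "d2", "d3")
OLD_SAMPLES = ("d7", "d10", "d15")
ALL_SAMPLES = YOUNG_SAMPLES + OLD_SAMPLES
REPLICATES = ("rep1", "rep2", "rep3")
TISSUES = ("germline", "neuron", "muscle", "intestine", "hypodermis", "pharynx")


@dataclass
class SimConfig:
    """Generator parameters; the defaults are the desk-scale study conditions."""

    seed: int
    # genome / annotation
    n_chroms: int = 2
    chrom_length: int = 200_000
    n_genes: int = 60
    exons_per_gene: Tuple[int, int] = (2, 5)
    minus_fraction: float = 0.4
    target_median_gene_length: int = 1956
    n_multi_transcript_genes: int = 4
    n_mono_exon_genes: int = 2
    n_noncoding_genes: int = 3
    # reads
    n_reads: int = 20_000
    truncation_fraction: float = 0.5
    tss_jitter: int = 5
    polya_fail_fraction: float = 0.10
    secondary_fraction: float = 0.02
    n_unknown_chrom_reads: int = 3
    # splice-junction tables (per-sample unannotated read fractions)
    sj_total_reads: int = 2000
    sj_fractions: Dict[str, Tuple[float, ...]] = field(
        default_factory=lambda: {
            "young": (0.04, 0.05, 0.06),
            "old": (0.07, 0.08, 0.09),
        }
    )
    sj_n_annotated: int = 40
    sj_n_unannotated: int = 6
    # isoform call set
    n_known_isoforms: int = 18
    n_novel_isoforms: int = 6
    utr3_offsets: Tuple[int, ...] = (10, 11, 15, 25, 40, 60)
    fusion_intron_lengths: Tuple[int, ...] = (32_000, 1957)
    fusion_boundary_intron: int = 1956
    # poly(A) tails
    tail_reads_total: int = 20_000
    tail_sigma: float = 0.05
    tail_median_range: Tuple[float, float] = (35.0, 75.0)
    tail_fail_fraction: float = 0.05
    delta_shifts: Tuple[Tuple[str, float], ...] = (
        ("10-20", 15.0), ("10-20", -15.0), (">20", 25.0), (">20", -25.0),
        ("<10", 3.0), ("<10", -3.0),
    )
    # modification sites
    atoi_delta_counts: Dict[str, int] = field(
        default_factory=lambda: {"increase": 6, "decrease": 1, "stable": 4}
    )
    atoi_group_only: Dict[str, int] = field(
        default_factory=lambda: {"young": 3, "old": 5}
    )
    psi_gene_counts: Dict[str, int] = field(
        default_factory=lambda: {"young_only": 5, "shared": 6, "old_only": 8}
    )
    repeat_density: float = 0.3

    def __post_init__(self) -> None:
        for name in ("minus_fraction", "truncation_fraction", "polya_fail_fraction",
                     "secondary_fraction", "tail_fail_fraction", "repeat_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class SimState:
    """Everything the sub-generators share: gene models, sequence, truth."""

    config: SimConfig
    rng_streams: Dict[str, np.random.Generator]
    chrom_names: List[str]
    sequences: Dict[str, np.ndarray]  # base codes 0..3
    genes: List[GeneModel] = field(default_factory=list)
    roles: Dict[str, str] = field(default_factory=dict)  # gene_id -> role
    coding_arrays: Dict[str, np.ndarray] = field(default_factory=dict)
    gaps: List[Tuple[str, int, int]] = field(default_factory=list)
    truth: Dict = field(default_factory=dict)
    callset: List[IsoformCall] = field(default_factory=list)

    @property
    def transcripts(self) -> List[TranscriptModel]:
        return [t for g in self.genes for t in g.transcripts]

    def gene(self, gene_id: str) -> GeneModel:
        return next(g for g in self.genes if g.gene_id == gene_id)

    def genes_with_role(self, role: str) -> List[GeneModel]:
        return [g for g in self.genes if self.roles[g.gene_id] == role]

    def tx_seq_codes(self, t: TranscriptModel) -> np.ndarray:
        """Transcript-strand spliced exon sequence as base codes, 5'->3'."""
        parts = [self.sequences[t.chrom][e.start:e.end] for e in t.exons]
        seq = np.concatenate(parts)
        return (3 - seq)[::-1] if t.strand == "-" else seq


def _spawn_streams(seed: int) -> Dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    names = ["annotation", "reads", "junctions", "isoforms", "tails", "edits",
             "repeats", "tissue"]
    return {
        name: np.random.default_rng(child)
        for name, child in zip(names, root.spawn(len(names)))
    }


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def _plan_spans(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Gene span lengths whose median is exactly the configured target."""
    n = cfg.n_genes
    m = cfg.target_median_gene_length
    n_low = n // 2 - 1
    n_high = n - n_low - 2
    low = rng.integers(900, m - 50, n_low)
    high = rng.integers(m + 50, 4001, n_high)
    spans = np.concatenate([low, [m, m], high])
    rng.shuffle(spans)
    return spans


def _build_structure(
    span: int, k: int, rng: np.random.Generator
) -> Tuple[List[Span], List[Span]]:
    """Exon/intron layout (relative coordinates) matching the span exactly."""
    if k == 1:
        return [(0, span)], []
    for attempt in range(400):
        # narrower draws after 200 failures so short spans still resolve
        er, ir = ((100, 251), (60, 351)) if attempt < 200 else ((90, 131), (60, 101))
        exons = list(rng.integers(*er, k - 1))
        introns = list(rng.integers(*ir, k - 1))
        last = span - sum(exons) - sum(introns)
        if last >= 80:
            exons.append(int(last))
            break
    else:
        raise RuntimeError(f"cannot build structure for span {span}, k={k}")
    spans: List[Span] = []
    cursor = 0
    intron_spans: List[Span] = []
    for i, ex in enumerate(exons):
        spans.append((cursor, cursor + int(ex)))
        cursor += int(ex)
        if i < k - 1:
            intron_spans.append((cursor, cursor + int(introns[i])))
            cursor += int(introns[i])
    return spans, intron_spans


def _assign_roles(cfg: SimConfig) -> List[str]:
    """Role per placement slot (chromosome-major order)."""
    roles: List[str] = []
    for tag in ("fusion_a0", "fusion_b0", "fusion_a1", "fusion_b1",
                "fusion_a2", "fusion_b2"):
        roles.append(tag)
    roles += ["multi"] * cfg.n_multi_transcript_genes
    roles += ["mono"] * cfg.n_mono_exon_genes
    roles += ["noncoding"] * cfg.n_noncoding_genes
    roles += ["novelty"] * cfg.n_novel_isoforms
    roles += ["utr"] * len(cfg.utr3_offsets)
    roles += ["count19", "count20"]
    n_generic = cfg.n_genes - len(roles)
    if n_generic < cfg.n_known_isoforms:
        raise ValueError("n_genes too small for the configured plants")
    roles += ["generic"] * n_generic
    return roles


def generate_annotation(cfg: SimConfig, outdir: Path) -> SimState:
    """Build gene models + genome sequence; write FASTA and GFF3."""
    streams = _spawn_streams(cfg.seed)
    rng = streams["annotation"]
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    state = SimState(
        config=cfg,
        rng_streams=streams,
        chrom_names=chroms,
        sequences={
            c: rng.integers(0, 4, cfg.chrom_length).astype(np.int8) for c in chroms
        },
    )
    spans = _plan_spans(cfg, rng)
    roles = _assign_roles(cfg)
    per_chrom = cfg.n_genes // cfg.n_chroms
    fusion_gaps = {
        "fusion_a0": cfg.fusion_intron_lengths[0],
        "fusion_a1": cfg.fusion_intron_lengths[1],
        "fusion_a2": cfg.fusion_boundary_intron,
    }
    slot = 0
    gene_spans_truth: Dict[str, int] = {}
    for ci, chrom in enumerate(chroms):
        cursor = int(rng.integers(1000, 3001))
        n_here = per_chrom if ci < cfg.n_chroms - 1 else cfg.n_genes - slot
        prev_end = 0
        for _ in range(n_here):
            role = roles[slot]
            span = int(spans[slot])
            if role.startswith("fusion"):
                strand = "+"
            else:
                strand = "-" if rng.random() < cfg.minus_fraction else "+"
            if role == "mono":
                k = 1
            elif role == "multi":
                k = int(rng.integers(4, cfg.exons_per_gene[1] + 1))
            elif role == "novelty":
                k = int(rng.integers(3, cfg.exons_per_gene[1] + 1))
            elif role.startswith("fusion"):
                k = int(rng.integers(2, 4))
            else:
                k = int(rng.integers(*[cfg.exons_per_gene[0],
                                       cfg.exons_per_gene[1] + 1]))
            rel_exons, _ = _build_structure(span, k, rng)
            gene_id = f"gene{slot + 1:03d}"
            coding = role != "noncoding"
            biotype = "protein_coding" if coding else "ncRNA"
            exons = [
                GenomicInterval(chrom, cursor + s, cursor + e, strand)
                for s, e in rel_exons
            ]
            tx = TranscriptModel(
                transcript_id=f"{gene_id}.t1",
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=exons,
                biotype=biotype,
            )
            gene = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                             biotype=biotype, transcripts=[tx])
            if role == "multi":
                # second annotated transcript skipping exon 1, sharing introns
                t2_exons = [exons[0]] + exons[2:]
                gene.transcripts.append(
                    TranscriptModel(
                        transcript_id=f"{gene_id}.t2",
                        gene_id=gene_id,
                        chrom=chrom,
                        strand=strand,
                        exons=list(t2_exons),
                        biotype=biotype,
                    )
                )
            state.genes.append(gene)
            state.roles[gene_id] = role
            gene_spans_truth[gene_id] = span
            if prev_end:
                state.gaps.append((chrom, prev_end, cursor))
            prev_end = cursor + span
            gap = fusion_gaps.get(role, int(rng.integers(300, 801)))
            cursor = cursor + span + gap
            slot += 1
        if cursor >= cfg.chrom_length - 500:
            raise ValueError("chromosome too short for the configured genes")

    _write_coding_sequences(state)
    _write_fasta(state, outdir / "genome.fa")
    _write_gff3(state, outdir / "annotation.gff3")

    spans_sorted = sorted(gene_spans_truth.values())
    n = len(spans_sorted)
    state.truth["annotation"] = {
        "gene_spans": gene_spans_truth,
        "median_gene_length": cfg.target_median_gene_length,
        "n_genes": n,
        "n_transcripts": len(state.transcripts),
    }
    return state


def _write_coding_sequences(state: SimState) -> None:
    """Plant an ORF (AUG ... stop, no internal stop) in every coding gene."""
    rng = state.rng_streams["annotation"]
    sense = [c for c in np.ndindex(4, 4, 4) if c not in STOP_CODES]
    stop_by_role: Dict[str, Tuple[int, int, int]] = {}
    # reserve specific terminal stops on the first two generic genes so that
    # stop_retained (TAA) and stop_lost (TGA) edit contexts exist
    generic = [g for g in state.genes if state.roles[g.gene_id] == "generic"]
    if len(generic) >= 2:
        stop_by_role[generic[0].gene_id] = (3, 0, 0)  # TAA
        stop_by_role[generic[1].gene_id] = (3, 2, 0)  # TGA
    stops = list(STOP_CODES)
    for gene in state.genes:
        if gene.biotype != "protein_coding":
            continue
        t = gene.transcripts[0]
        exonic = t.exonic_length
        utr5 = 30
        cds_len = ((exonic - 110) // 3) * 3
        if cds_len < 60:
            raise ValueError(f"gene {gene.gene_id} too short for an ORF")
        n_codons = cds_len // 3
        codes = np.empty(cds_len, dtype=np.int8)
        codes[0:3] = ATG
        body = [sense[i] for i in rng.integers(0, len(sense), n_codons - 2)]
        codes[3 : cds_len - 3] = np.array(body, dtype=np.int8).ravel()
        stop = stop_by_role.get(gene.gene_id, stops[int(rng.integers(0, 3))])
        codes[cds_len - 3 :] = stop
        gpos = _tx_positions(t)[utr5 : utr5 + cds_len]
        seq = state.sequences[t.chrom]
        if t.strand == "-":
            seq[gpos] = 3 - codes
        else:
            seq[gpos] = codes
        state.coding_arrays[gene.gene_id] = gpos
        # CDS genomic intervals for every transcript of the gene
        cds_spans = _blocks_from_positions(np.sort(gpos))
        for tx in gene.transcripts:
            tx.cds = _clip_cds_to_exons(cds_spans, tx)


def _tx_positions(t: TranscriptModel) -> np.ndarray:
    """Genomic position of each transcript base, ordered 5'->3'."""
    if t.strand == "-":
        parts = [np.arange(e.end - 1, e.start - 1, -1) for e in reversed(t.exons)]
    else:
        parts = [np.arange(e.start, e.end) for e in t.exons]
    return np.concatenate(parts)


def _blocks_from_positions(sorted_positions: np.ndarray) -> List[Span]:
    breaks = np.where(np.diff(sorted_positions) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(sorted_positions) - 1]])
    return [
        (int(sorted_positions[s]), int(sorted_positions[e]) + 1)
        for s, e in zip(starts, ends)
    ]


def _clip_cds_to_exons(cds_spans: List[Span], tx: TranscriptModel) -> List[GenomicInterval]:
    out = []
    for cs, ce in cds_spans:
        for e in tx.exons:
            lo, hi = max(cs, e.start), min(ce, e.end)
            if hi > lo:
                out.append(GenomicInterval(tx.chrom, lo, hi, tx.strand))
    return out


def _write_fasta(state: SimState, path: Path) -> None:
    with open(path, "w") as fh:
        for chrom in state.chrom_names:
            fh.write(f">{chrom}\n")
            seq = "".join(BASES[state.sequences[chrom]])
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _write_gff3(state: SimState, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in state.genes:
            gs, ge = gene.span
            fh.write(
                f"{gene.chrom}\tsim\tgene\t{gs + 1}\t{ge}\t.\t{gene.strand}\t.\t"
                f"ID={gene.gene_id};biotype={gene.biotype}\n"
            )
            for t in gene.transcripts:
                ts, te = t.span
                fh.write(
                    f"{t.chrom}\tsim\tmRNA\t{ts + 1}\t{te}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={gene.gene_id}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{t.chrom}\tsim\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{t.strand}\t.\tParent={t.transcript_id}\n"
                    )
                for c in t.cds or []:
                    fh.write(
                        f"{t.chrom}\tsim\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                        f"{t.strand}\t0\tParent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# reads + splice junctions
# ---------------------------------------------------------------------------


def _trim_blocks_5p(t: TranscriptModel, tx_offset: int) -> List[Span]:
    """Exon blocks with the first ``tx_offset`` transcript bases removed."""
    pos = _tx_positions(t)[tx_offset:]
    return _blocks_from_positions(np.sort(pos))


def generate_reads(cfg: SimConfig, state: SimState, outdir: Path) -> None:
    """Aligned-read TSV plus per-sample SJ.out.tab tables, with truth."""
    rng = state.rng_streams["reads"]
    txs = [g.transcripts[0] for g in state.genes]
    weights = 1.0 / (np.arange(len(txs)) + 1.0)
    weights /= weights.sum()
    tx_index = rng.choice(len(txs), size=cfg.n_reads, p=weights)
    tss_by_key: Dict[Tuple[str, str], np.ndarray] = {}
    for t in state.transcripts:
        tss_by_key.setdefault((t.chrom, t.strand), []).append(t.tss)  # type: ignore
    tss_by_key = {k: np.sort(np.array(v)) for k, v in tss_by_key.items()}

    reads: List[ReadRecord] = []
    truth_reads: Dict[str, Dict] = {}
    n_truncated = 0
    for i, ti in enumerate(tx_index):
        t = txs[ti]
        rid = f"r{i:06d}"
        secondary = rng.random() < cfg.secondary_fraction
        truncated = rng.random() < cfg.truncation_fraction
        if truncated:
            L = t.exonic_length
            for _ in range(50):
                off = int(rng.integers(int(0.35 * L), int(0.9 * L)))
                blocks = _trim_blocks_5p(t, off)
                pos5 = blocks[-1][1] - 1 if t.strand == "-" else blocks[0][0]
                arr = tss_by_key[(t.chrom, t.strand)]
                j = int(np.searchsorted(arr, pos5))
                near = any(
                    0 <= k < len(arr) and abs(int(arr[k]) - pos5) <= 10
                    for k in (j - 1, j)
                )
                if not near:
                    break
            else:
                continue
            qc = "PASS"
            n_truncated += 1
        else:
            jit = int(rng.integers(-cfg.tss_jitter, cfg.tss_jitter + 1))
            blocks = [(e.start, e.end) for e in t.exons]
            if t.strand == "-":
                s, e = blocks[-1]
                blocks[-1] = (s, max(s + 1, e + jit))
            else:
                s, e = blocks[0]
                blocks[0] = (max(0, s + jit), e)
            qc = "FAIL" if rng.random() < cfg.polya_fail_fraction else "PASS"
        tail = float(np.round(rng.lognormal(np.log(50.0), 0.3), 2)) if qc == "PASS" else None
        reads.append(
            ReadRecord(
                read_id=rid, chrom=t.chrom, strand=t.strand, blocks=blocks,
                is_secondary=secondary, polya_qc=qc, polya_length=tail,
            )
        )
        truth_reads[rid] = {
            "full_length": (not secondary) and (not truncated) and qc == "PASS",
            "truncated": truncated,
        }
    for i in range(cfg.n_unknown_chrom_reads):
        rid = f"u{i:03d}"
        reads.append(
            ReadRecord(read_id=rid, chrom="chrUn", strand="+",
                       blocks=[(100, 400)], polya_qc="PASS", polya_length=50.0)
        )
        truth_reads[rid] = {"full_length": False, "truncated": False,
                            "unknown_chrom": True}
    write_reads_tsv(reads, outdir / "reads.tsv")

    state.truth["reads"] = {
        "per_read": truth_reads,
        "n_full_length": sum(1 for v in truth_reads.values() if v["full_length"]),
        "n_reads": len(reads),
    }
    _generate_sj_tables(cfg, state, outdir)


def _generate_sj_tables(cfg: SimConfig, state: SimState, outdir: Path) -> None:
    rng = state.rng_streams["junctions"]
    jdb = sorted(
        {
            (t.chrom, s, e, t.strand)
            for t in state.transcripts
            for s, e in t.introns
        }
    )
    starts = {(c, s) for c, s, _, _ in jdb}
    ends = {(c, e) for c, _, e, _ in jdb}
    samples = {"young": YOUNG_SAMPLES, "old": OLD_SAMPLES}
    truth: Dict[str, Dict] = {}
    for group, names in samples.items():
        for frac, sample in zip(cfg.sj_fractions[group], names):
            N = cfg.sj_total_reads
            k = round(frac * N)
            idx = rng.choice(len(jdb), size=cfg.sj_n_annotated, replace=False)
            annotated = [jdb[i] for i in idx]
            base, rem = divmod(N - k, cfg.sj_n_annotated)
            records = [
                JunctionRecord(c, s, e, st, unique_reads=base + (1 if i < rem else 0))
                for i, (c, s, e, st) in enumerate(annotated)
            ]
            kinds = ["donor", "acceptor", "both"]
            ub, urem = divmod(k, cfg.sj_n_unannotated)
            planted = []
            used = set()
            for j in range(cfg.sj_n_unannotated):
                kind = kinds[j % 3]
                for _ in range(100):
                    c, s, e, st = jdb[int(rng.integers(0, len(jdb)))]
                    d1 = int(rng.integers(3, 9)) * int(rng.choice([-1, 1]))
                    d2 = int(rng.integers(3, 9)) * int(rng.choice([-1, 1]))
                    # donor boundary is the start for '+', the end for '-'
                    shift_start = (kind in ("donor", "both")) == (st != "-")
                    shift_end = (kind in ("acceptor", "both")) == (st != "-")
                    if kind == "both":
                        shift_start = shift_end = True
                    ns = s + d1 if shift_start else s
                    ne = e + d2 if shift_end else e
                    if ne - ns < 30 or (c, ns, ne) in used:
                        continue
                    start_ok = shift_start == ((c, ns) not in starts)
                    end_ok = shift_end == ((c, ne) not in ends)
                    if start_ok and end_ok:
                        break
                else:
                    raise RuntimeError("could not plant a shifted junction")
                used.add((c, ns, ne))
                n_reads = ub + (1 if j < urem else 0)
                records.append(JunctionRecord(c, ns, ne, st, unique_reads=n_reads))
                if st == "-":
                    label = {"donor": "five_prime_only",
                             "acceptor": "three_prime_only",
                             "both": "both"}[kind]
                else:
                    label = {"donor": "five_prime_only",
                             "acceptor": "three_prime_only",
                             "both": "both"}[kind]
                planted.append(
                    {"chrom": c, "start": ns, "end": ne, "strand": st,
                     "kind": kind, "expected_label": label, "unique_reads": n_reads}
                )
            write_sj_tab(records, outdir / f"sj_{sample}.tab")
            truth[sample] = {
                "group": group,
                "total_reads": N,
                "unannotated_reads": k,
                "percent_unannotated": 100.0 * k / N,
                "planted_unannotated": planted,
            }
    state.truth["junctions"] = truth


# ---------------------------------------------------------------------------
# isoform call set
# ---------------------------------------------------------------------------


def _jitter_ends(exons: List[Span], rng: np.random.Generator, amt: int = 5) -> List[Span]:
    out = list(exons)
    s, e = out[0]
    out[0] = (max(0, s + int(rng.integers(-amt, amt + 1))), e)
    s, e = out[-1]
    out[-1] = (s, e + int(rng.integers(-amt, amt + 1)))
    if len(out) == 1 and out[0][1] - out[0][0] < 50:
        out[0] = exons[0]
    return out


def generate_isoform_callset(cfg: SimConfig, state: SimState, outdir: Path) -> None:
    """BED12 + per-sample counts planting the four categories and the
    threshold-straddling boundary cases."""
    rng = state.rng_streams["isoforms"]
    plan: List[Tuple[str, str, List[Span], TranscriptModel, int, Dict]] = []

    def tx_exons(t: TranscriptModel) -> List[Span]:
        return [(e.start, e.end) for e in t.exons]

    # known isoforms on generic genes (3' end jitter <= 5 keeps the UTR known)
    generic = state.genes_with_role("generic")
    for g in generic[: cfg.n_known_isoforms]:
        t = g.transcripts[0]
        plan.append(("known", g.gene_id, _jitter_ends(tx_exons(t), rng), t,
                     int(rng.integers(25, 301)), {}))
    # mono-exonic known, contained within the annotated span
    for g in state.genes_with_role("mono"):
        t = g.transcripts[0]
        (s, e) = tx_exons(t)[0]
        plan.append(("known", g.gene_id, [(s + 3, e - 3)], t,
                     int(rng.integers(25, 200)), {}))
    # read-count boundary: 19 dropped, 20 kept
    for role, count in (("count19", 19), ("count20", 20)):
        g = state.genes_with_role(role)[0]
        t = g.transcripts[0]
        plan.append(("known", g.gene_id, tx_exons(t), t, count, {}))
    # gene-fraction boundary on multi-transcript genes: (180,20) both kept
    # (20/200 = 10%, inclusive), (190,20) second dropped (20/210 < 10%)
    # while still clearing the 20-read minimum
    multi = state.genes_with_role("multi")
    for g, counts in zip(multi[:2], ((180, 20), (190, 20))):
        t1, t2 = g.transcripts[0], g.transcripts[1]
        plan.append(("known", g.gene_id, tx_exons(t1), t1, counts[0], {}))
        plan.append(("known", g.gene_id, tx_exons(t2), t2, counts[1], {}))
    # splice-novel: skip the second exon of a >=3-exon single-transcript gene
    for g in state.genes_with_role("novelty"):
        t = g.transcripts[0]
        exons = tx_exons(t)
        plan.append(("novel", g.gene_id, [exons[0]] + exons[2:], t,
                     int(rng.integers(25, 151)), {}))
    # 3'UTR plants: annotated chain, 3' end moved by the configured offset
    for g, offset in zip(state.genes_with_role("utr"), cfg.utr3_offsets):
        t = g.transcripts[0]
        exons = tx_exons(t)
        if t.strand == "-":
            s, e = exons[0]
            exons[0] = (s - offset, e)
        else:
            s, e = exons[-1]
            exons[-1] = (s, e + offset)
        cat = "known" if offset <= 10 else "novel_utr3"
        plan.append((cat, g.gene_id, exons, t, int(rng.integers(30, 151)),
                     {"utr_offset": offset}))
    # fusion isoforms joining adjacent gene pairs; the boundary pair's intron
    # equals the median gene span exactly, so it stays merely novel
    for i, cat in ((0, "fusion"), (1, "fusion"), (2, "novel")):
        a = state.genes_with_role(f"fusion_a{i}")[0]
        b = state.genes_with_role(f"fusion_b{i}")[0]
        exons = tx_exons(a.transcripts[0]) + tx_exons(b.transcripts[0])
        plan.append((cat, a.gene_id, exons, a.transcripts[0],
                     int(rng.integers(25, 61)),
                     {"fusion_genes": [a.gene_id, b.gene_id]}))

    callset: List[IsoformCall] = []
    truth: Dict[str, Dict] = {}
    gene_totals: Dict[str, int] = {}
    for cat, gene_id, exons, t, total, extra in plan:
        gene_totals[gene_id] = gene_totals.get(gene_id, 0) + total
    for idx, (cat, gene_id, exons, t, total, extra) in enumerate(plan):
        iso_id = f"iso{idx + 1:03d}"
        counts = rng.multinomial(total, np.full(6, 1 / 6))
        iso = IsoformCall(
            isoform_id=iso_id, chrom=t.chrom, strand=t.strand, exons=exons,
            read_counts={s: int(c) for s, c in zip(ALL_SAMPLES, counts)},
        )
        callset.append(iso)
        passes = total >= 20 and total / gene_totals[gene_id] >= 0.10
        truth[iso_id] = {
            "category": cat,
            "gene_id": gene_id,
            "total_reads": total,
            "passes_filter": bool(passes),
            **extra,
        }
    write_bed12(callset, outdir / "isoforms.bed")
    with open(outdir / "isoform_counts.tsv", "w") as fh:
        fh.write("isoform_id\t" + "\t".join(ALL_SAMPLES) + "\n")
        for iso in callset:
            fh.write(
                iso.isoform_id + "\t"
                + "\t".join(str(iso.read_counts[s]) for s in ALL_SAMPLES) + "\n"
            )
    state.callset = callset
    state.truth["isoforms"] = truth


# ---------------------------------------------------------------------------
# poly(A) tails
# ---------------------------------------------------------------------------


def generate_tails(cfg: SimConfig, state: SimState, outdir: Path) -> None:
    """Per-read tail table + read->isoform assignments.

    Tail medians decrease with isoform abundance rank (the planted
    anticorrelation); configured isoforms get old-young median shifts in each
    delta class; everything else shifts by 0 nt.
    """
    rng = state.rng_streams["tails"]
    iso_truth = state.truth["isoforms"]
    survivors = [
        iso for iso in state.callset if iso_truth[iso.isoform_id]["passes_filter"]
    ]
    n = len(survivors)
    expr = np.array([iso.total_reads for iso in survivors], dtype=float)
    order = np.argsort(expr, kind="stable")  # ascending abundance
    lo, hi = cfg.tail_median_range
    base = np.empty(n)
    for rank, idx in enumerate(order):
        base[idx] = hi - (hi - lo) * rank / max(n - 1, 1)

    shifts = np.zeros(n)
    shift_class = ["<10"] * n
    for i, (cls, shift) in enumerate(cfg.delta_shifts):
        if i >= n:
            break
        shifts[i] = shift
        shift_class[i] = cls

    per_iso_group = cfg.tail_reads_total // (2 * n)
    rows: List[str] = []
    assignments: List[str] = []
    truth: Dict[str, Dict] = {}
    rid = 0
    for i, iso in enumerate(survivors):
        for group, samples in (("young", YOUNG_SAMPLES), ("old", OLD_SAMPLES)):
            med = base[i] + (shifts[i] if group == "old" else 0.0)
            lengths = rng.lognormal(np.log(med), cfg.tail_sigma, per_iso_group)
            for j, L in enumerate(lengths):
                sample = samples[j % 3]
                name = f"t{rid:06d}"
                rid += 1
                rows.append(f"{name}\t{sample}\t{L:.2f}\tPASS")
                assignments.append(f"{name}\t{iso.isoform_id}")
        n_fail = int(cfg.tail_fail_fraction * per_iso_group)
        for _ in range(n_fail):
            name = f"t{rid:06d}"
            rid += 1
            rows.append(f"{name}\td1\t{rng.lognormal(np.log(40), 0.3):.2f}\tFAIL")
            assignments.append(f"{name}\t{iso.isoform_id}")
        truth[iso.isoform_id] = {
            "base_median": float(base[i]),
            "old_shift": float(shifts[i]),
            "delta_class": shift_class[i],
            "expression": float(expr[i]),
            "n_per_group": per_iso_group,
        }
    with open(outdir / "tails.tsv", "w") as fh:
        fh.write("readname\tsample_id\tpolya_length\tqc_tag\n")
        fh.write("\n".join(rows) + "\n")
    with open(outdir / "tail_assignments.tsv", "w") as fh:
        fh.write("readname\tisoform_id\n")
        fh.write("\n".join(assignments) + "\n")
    state.truth["tails"] = {
        "per_isoform": truth,
        "n_fail_records": sum(1 for r in rows if r.endswith("FAIL")),
    }


# ---------------------------------------------------------------------------
# modification calls, repeats, tissue matrix
# ---------------------------------------------------------------------------


def _codon_search(
    state: SimState, codon: str, offset: int, genes: Sequence[GeneModel], used: set
) -> Tuple[str, int, str] | None:
    """Find (chrom, genomic position of the codon base at ``offset``, strand)
    for an internal occurrence of ``codon`` in some gene's planted ORF."""
    target = tuple(_CODE[b] for b in codon)
    for g in genes:
        gpos = state.coding_arrays.get(g.gene_id)
        if gpos is None:
            continue
        t = g.transcripts[0]
        seq = state.sequences[t.chrom][gpos]
        if t.strand == "-":
            seq = 3 - seq
        n_codons = len(seq) // 3
        for ci in range(1, n_codons - 1):
            if tuple(seq[3 * ci : 3 * ci + 3]) == target:
                pos = int(gpos[3 * ci + offset])
                if (t.chrom, pos) not in used:
                    used.add((t.chrom, pos))
                    return (t.chrom, pos, t.strand)
    return None


def _region_base_positions(
    state: SimState, chrom: str, spans: Sequence[Span], strand: str, base: str
) -> np.ndarray:
    """Genomic positions within ``spans`` whose transcript-strand base is ``base``."""
    code = _CODE[base]
    want = 3 - code if strand == "-" else code
    hits = []
    for s, e in spans:
        local = np.where(state.sequences[chrom][s:e] == want)[0]
        hits.append(local + s)
    return np.concatenate(hits) if hits else np.array([], dtype=int)


def _utr_spans(g: GeneModel, which: str) -> List[Span]:
    t = g.transcripts[0]
    if not t.cds:
        return []
    cds_lo = min(c.start for c in t.cds)
    cds_hi = max(c.end for c in t.cds)
    out = []
    for e in t.exons:
        if which in ("utr5", "utr3"):
            before = (max(e.start, 0), min(e.end, cds_lo))
            after = (max(e.start, cds_hi), e.end)
            pick = before if (which == "utr5") == (t.strand != "-") else after
            if pick[1] > pick[0]:
                out.append(pick)
    return out


def generate_edit_calls(cfg: SimConfig, state: SimState, outdir: Path) -> None:
    """Per-replicate A-to-I BEDs and pseudouridine TSVs, a repeat track and a
    tissue expression matrix, with per-site truth."""
    rng = state.rng_streams["edits"]
    repeats = _generate_repeats(cfg, state, outdir)
    rep_starts = {c: np.array([s for s, _ in sp]) for c, sp in repeats.items()}
    rep_ends = {c: np.array([e for _, e in sp]) for c, sp in repeats.items()}

    def in_repeat(chrom: str, pos: int) -> bool:
        if chrom not in rep_starts:
            return False
        i = int(np.searchsorted(rep_starts[chrom], pos, side="right")) - 1
        return i >= 0 and pos < int(rep_ends[chrom][i])

    used: set = set()
    single_cov = [
        g for g in state.genes
        if g.biotype == "protein_coding" and len(g.transcripts) == 1
        and state.roles[g.gene_id] == "generic"
    ]

    # -- CDS consequence contexts (A-to-I: edited A read as G) --------------
    consequence_specs = [
        ("CCA", 2, "synonymous", False),
        ("ACA", 2, "synonymous", False),
        ("AGA", 0, "missense", True),   # Arg -> Gly
        ("AAC", 0, "missense", True),   # Asn -> Asp
        ("ATA", 2, "missense", False),  # Ile -> Met
        ("CAT", 1, "missense", False),  # His -> Arg
    ]
    sites: List[Dict] = []
    for codon, offset, category, prop in consequence_specs:
        assert codon[offset] == "A"
        found = _codon_search(state, codon, offset, single_cov, used)
        if found is None:
            continue
        chrom, pos, strand = found
        sites.append(
            {"chrom": chrom, "pos": pos, "strand": strand, "feature": "CDS",
             "consequence": category, "property_change": prop,
             "codon": codon, "codon_offset": offset}
        )
    # terminal-stop contexts: TAA offset1 -> TGA (stop_retained),
    # TGA offset2 -> TGG (stop_lost)
    for gene, offset, category in (
        (single_cov[0], 1, "stop_retained"),
        (single_cov[1], 2, "stop_lost"),
    ):
        gpos = state.coding_arrays[gene.gene_id]
        t = gene.transcripts[0]
        pos = int(gpos[len(gpos) - 3 + offset])
        if (t.chrom, pos) in used:
            continue
        used.add((t.chrom, pos))
        sites.append(
            {"chrom": t.chrom, "pos": pos, "strand": t.strand, "feature": "CDS",
             "consequence": category, "property_change": False}
        )

    # -- non-CDS features ---------------------------------------------------
    def pick_positions(feature: str, count: int) -> None:
        pool: List[Tuple[str, int, str]] = []
        if feature in ("utr3", "utr5"):
            for g in single_cov:
                spans = _utr_spans(g, feature)
                t = g.transcripts[0]
                for p in _region_base_positions(state, t.chrom, spans, t.strand, "A"):
                    pool.append((t.chrom, int(p), t.strand))
        elif feature == "noncoding_exon":
            for g in state.genes_with_role("noncoding"):
                t = g.transcripts[0]
                spans = [(e.start, e.end) for e in t.exons]
                for p in _region_base_positions(state, t.chrom, spans, t.strand, "A"):
                    pool.append((t.chrom, int(p), t.strand))
        elif feature == "intron":
            for g in single_cov:
                t = g.transcripts[0]
                for p in _region_base_positions(state, t.chrom, t.introns, t.strand, "A"):
                    pool.append((t.chrom, int(p), t.strand))
        elif feature == "intergenic":
            for chrom, s, e in state.gaps:
                if e - s < 200:
                    continue
                for p in _region_base_positions(
                    state, chrom, [(s + 70, e - 70)], "+", "A"
                ):
                    pool.append((chrom, int(p), "+"))
        taken = 0
        step = max(1, len(pool) // max(count * 3, 1))
        for chrom, p, strand in pool[:: step]:
            if taken >= count:
                break
            if (chrom, p) in used:
                continue
            used.add((chrom, p))
            sites.append({"chrom": chrom, "pos": p, "strand": strand,
                          "feature": feature})
            taken += 1

    pick_positions("utr3", 8)
    pick_positions("utr5", 2)
    pick_positions("noncoding_exon", 3)
    pick_positions("intron", 4)
    pick_positions("intergenic", 3)
    # one antisense site: inside a plus-strand gene, called on the minus strand
    for g in single_cov:
        if g.strand == "+":
            t = g.transcripts[0]
            pos = t.exons[0].start + 10
            if (t.chrom, pos) not in used:
                used.add((t.chrom, pos))
                sites.append({"chrom": t.chrom, "pos": pos, "strand": "-",
                              "feature": "antisense_intragenic"})
                break

    # -- group membership and per-replicate values -------------------------
    def frac_reps(f: float) -> Tuple[float, float, float]:
        return (round(f - 0.01, 3), round(f, 3), round(f + 0.01, 3))

    conf_pass = (0.995, 0.999, 0.992)
    delta_plan: List[Tuple[str, float, float]] = []
    for i in range(cfg.atoi_delta_counts["increase"]):
        delta_plan.append(("increase", 0.20 + 0.01 * i, 0.35 + 0.01 * i))
    for i in range(cfg.atoi_delta_counts["decrease"]):
        delta_plan.append(("decrease", 0.35, 0.20))
    for i in range(cfg.atoi_delta_counts["stable"]):
        delta_plan.append(("stable", 0.25 + 0.01 * i, 0.27 + 0.01 * i))
    # near-threshold deltas: 10.5 and 9.5 percentage points
    delta_plan.append(("increase", 0.20, 0.305))
    delta_plan.append(("stable", 0.20, 0.295))

    site_specs: List[Dict] = []
    si = 0

    def next_site() -> Dict | None:
        nonlocal si
        if si < len(sites):
            s = sites[si]
            si += 1
            return s
        return None

    for cls, fy, fo in delta_plan:
        s = next_site()
        if s is None:
            break
        site_specs.append(
            {**s, "groups": {"young": frac_reps(fy), "old": frac_reps(fo)},
             "conf": {"young": conf_pass, "old": conf_pass},
             "pass": {"young": True, "old": True}, "delta_class": cls}
        )
    for group, n_only in cfg.atoi_group_only.items():
        for _ in range(n_only):
            s = next_site()
            if s is None:
                break
            f = float(np.round(rng.uniform(0.15, 0.4), 2))
            site_specs.append(
                {**s, "groups": {group: frac_reps(f)},
                 "conf": {group: conf_pass},
                 "pass": {group: True,
                          ("old" if group == "young" else "young"): False}}
            )
    # threshold-straddling plants
    boundary_specs = [
        # exact thresholds pass (inclusive >=)
        {"groups": {"young": (0.05, 0.05, 0.05)}, "conf": {"young": (0.99, 0.99, 0.99)},
         "pass": {"young": True, "old": False}, "tag": "boundary_pass"},
        # one replicate fraction at 0.049 fails
        {"groups": {"young": (0.049, 0.20, 0.20)}, "conf": {"young": conf_pass},
         "pass": {"young": False, "old": False}, "tag": "fraction_fail"},
        {"groups": {"old": (0.049, 0.30, 0.30)}, "conf": {"old": conf_pass},
         "pass": {"young": False, "old": False}, "tag": "fraction_fail"},
        # one replicate confidence at 0.989 fails
        {"groups": {"young": (0.2, 0.2, 0.2)}, "conf": {"young": (0.989, 0.995, 0.995)},
         "pass": {"young": False, "old": False}, "tag": "confidence_fail"},
        # present in only two replicates fails
        {"groups": {"young": (0.2, 0.2)}, "conf": {"young": (0.995, 0.995)},
         "pass": {"young": False, "old": False}, "tag": "missing_replicate"},
    ]
    for spec in boundary_specs:
        s = next_site()
        if s is None:
            break
        site_specs.append({**s, **spec})
    # drain remaining planted positions as stable sites passing both groups,
    # so every planted feature (incl. the antisense site) is emitted
    while True:
        s = next_site()
        if s is None:
            break
        f = float(np.round(rng.uniform(0.15, 0.4), 2))
        site_specs.append(
            {**s, "groups": {"young": frac_reps(f), "old": frac_reps(f)},
             "conf": {"young": conf_pass, "old": conf_pass},
             "pass": {"young": True, "old": True}, "delta_class": "stable"}
        )

    # -- write A-to-I BEDs --------------------------------------------------
    atoi_truth: Dict[str, Dict] = {}
    for group in ("young", "old"):
        per_rep_rows: Dict[str, List[Tuple]] = {r: [] for r in REPLICATES}
        for spec in site_specs:
            fracs = spec["groups"].get(group)
            if fracs is None:
                continue
            confs = spec["conf"][group]
            for ri, rep in enumerate(REPLICATES[: len(fracs)]):
                cov = int(rng.integers(50, 201))
                per_rep_rows[rep].append(
                    (spec["chrom"], spec["pos"], f"{cov},{fracs[ri]:g}",
                     f"{confs[ri]:g}", spec["strand"])
                )
        for rep, rows in per_rep_rows.items():
            rows.sort()
            with open(outdir / f"atoi_{group}_{rep}.bed", "w") as fh:
                for chrom, pos, payload, conf, strand in rows:
                    fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{payload}\t{conf}\t{strand}\n")
    for spec in site_specs:
        key = f"{spec['chrom']}:{spec['pos']}:{spec['strand']}"
        entry = {
            "feature": spec["feature"],
            "pass_young": bool(spec["pass"].get("young", False)),
            "pass_old": bool(spec["pass"].get("old", False)),
            "repeat_overlap": in_repeat(spec["chrom"], spec["pos"]),
        }
        if "delta_class" in spec:
            entry["delta_class"] = spec["delta_class"]
            entry["mean_young"] = float(np.mean(spec["groups"]["young"]))
            entry["mean_old"] = float(np.mean(spec["groups"]["old"]))
        if "consequence" in spec:
            entry["consequence"] = spec["consequence"]
            entry["property_change"] = spec["property_change"]
        if "tag" in spec:
            entry["tag"] = spec["tag"]
        atoi_truth[key] = entry
    state.truth["atoi"] = atoi_truth

    _generate_psi(cfg, state, outdir, used)
    _generate_tissue_matrix(cfg, state, outdir)


def _generate_repeats(
    cfg: SimConfig, state: SimState, outdir: Path
) -> Dict[str, List[Span]]:
    rng = state.rng_streams["repeats"]
    from .intervals import merge_spans

    repeats: Dict[str, List[Span]] = {}
    for chrom in state.chrom_names:
        target = cfg.repeat_density * cfg.chrom_length
        spans: List[Span] = []
        covered = 0
        while covered < target:
            length = int(rng.integers(200, 801))
            start = int(rng.integers(0, cfg.chrom_length - length))
            spans.append((start, start + length))
            merged = merge_spans(spans)
            covered = sum(e - s for s, e in merged)
            spans = merged
        repeats[chrom] = spans
    with open(outdir / "repeats.bed", "w") as fh:
        for chrom in state.chrom_names:
            for s, e in repeats[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")
    state.truth["repeats"] = {
        "genome_fraction": sum(
            e - s for sp in repeats.values() for s, e in sp
        ) / (cfg.n_chroms * cfg.chrom_length)
    }
    return repeats


def _generate_psi(cfg: SimConfig, state: SimState, outdir: Path, used: set) -> None:
    rng = state.rng_streams["edits"]
    pool = [
        g for g in state.genes
        if g.biotype == "protein_coding" and len(g.transcripts) == 1
        and state.roles[g.gene_id] in ("generic", "utr", "novelty")
    ]
    need = sum(cfg.psi_gene_counts.values()) + 2  # + 2 failing-site genes
    if len(pool) < need:
        raise ValueError("not enough genes for the pseudouridine plants")
    assignments: List[Tuple[str, str]] = []  # (gene_id, set name)
    gi = 0
    for name in ("young_only", "shared", "old_only"):
        for _ in range(cfg.psi_gene_counts[name]):
            assignments.append((pool[gi].gene_id, name))
            gi += 1
    fail_genes = [pool[gi].gene_id, pool[gi + 1].gene_id]

    def site_for_gene(gene_id: str) -> Tuple[str, int, str] | None:
        g = state.gene(gene_id)
        t = g.transcripts[0]
        spans = [(e.start, e.end) for e in t.exons]
        for p in _region_base_positions(state, t.chrom, spans, t.strand, "T"):
            if (t.chrom, int(p)) not in used:
                used.add((t.chrom, int(p)))
                return (t.chrom, int(p), t.strand)
        return None

    specs = []
    for i, (gene_id, name) in enumerate(assignments):
        found = site_for_gene(gene_id)
        if found is None:
            continue
        chrom, pos, strand = found
        probs = (0.90, 0.90, 0.90) if (name == "shared" and i == cfg.psi_gene_counts["young_only"]) \
            else (0.93, 0.95, 0.97)
        groups = {"young_only": ("young",), "old_only": ("old",),
                  "shared": ("young", "old")}[name]
        specs.append({"chrom": chrom, "pos": pos, "strand": strand,
                      "gene_id": gene_id, "set": name, "groups": groups,
                      "probs": probs, "passes": True})
    for gene_id in fail_genes:
        found = site_for_gene(gene_id)
        if found is None:
            continue
        chrom, pos, strand = found
        specs.append({"chrom": chrom, "pos": pos, "strand": strand,
                      "gene_id": gene_id, "set": "fail", "groups": ("young", "old"),
                      "probs": (0.89, 0.95, 0.97), "passes": False})

    for group in ("young", "old"):
        for ri, rep in enumerate(REPLICATES):
            rows = []
            for spec in specs:
                if group not in spec["groups"]:
                    continue
                rows.append(
                    (spec["chrom"], spec["pos"], spec["strand"],
                     spec["probs"][ri])
                )
            rows.sort()
            with open(outdir / f"psi_{group}_{rep}.tsv", "w") as fh:
                fh.write("chrom\tpos\tstrand\tprobability\n")
                for chrom, pos, strand, prob in rows:
                    fh.write(f"{chrom}\t{pos}\t{strand}\t{prob:g}\n")

    genes_young = sorted(
        {s["gene_id"] for s in specs if s["passes"] and "young" in s["groups"]}
    )
    genes_old = sorted(
        {s["gene_id"] for s in specs if s["passes"] and "old" in s["groups"]}
    )
    state.truth["psi"] = {
        "genes_young": genes_young,
        "genes_old": genes_old,
        "overlap": (
            len(set(genes_young) - set(genes_old)),
            len(set(genes_young) & set(genes_old)),
            len(set(genes_old) - set(genes_young)),
        ),
        "sites": {
            f"{s['chrom']}:{s['pos']}:{s['strand']}": {
                "gene_id": s["gene_id"], "set": s["set"], "passes": s["passes"],
            }
            for s in specs
        },
    }


def _generate_tissue_matrix(cfg: SimConfig, state: SimState, outdir: Path) -> None:
    rng = state.rng_streams["tissue"]
    gene_ids = [g.gene_id for g in state.genes]
    expr = rng.lognormal(np.log(20.0), 0.6, (len(gene_ids), len(TISSUES)))
    boosted = set(state.truth.get("psi", {}).get("genes_young", [])) | set(
        state.truth.get("psi", {}).get("genes_old", [])
    )
    germline = TISSUES.index("germline")
    for i, gid in enumerate(gene_ids):
        if gid in boosted:
            expr[i, germline] *= 4.0
    with open(outdir / "tissue_expression.tsv", "w") as fh:
        fh.write("gene_id\t" + "\t".join(TISSUES) + "\n")
        for gid, row in zip(gene_ids, expr):
            fh.write(gid + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")
    state.truth["tissue"] = {"boosted_tissue": "germline",
                             "boosted_genes": sorted(boosted)}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def simulate_all(cfg: SimConfig, outdir: str | Path) -> SimState:
    """Generate every pipeline input plus ``truth.json`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state = generate_annotation(cfg, outdir)
    generate_reads(cfg, state, outdir)
    generate_isoform_callset(cfg, state, outdir)
    generate_tails(cfg, state, outdir)
    generate_edit_calls(cfg, state, outdir)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(state.truth, fh, indent=1)
        fh.write("\n")
    return state
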