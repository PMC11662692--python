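"""Shared fixtures: one synthetic data set + pipeline run per session, and
builders for small hand-made annotations."""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
import pytest

from drspipe.annotation import AnnotationDB
from drspipe.intervals import GeneModel, GenomicInterval, TranscriptModel
from drspipe.pipeline import run_pipeline
from drspipe.simulate import SimConfig, simulate_all

SESSION_SEED = 0


@pytest.fixture(scope="session")
def sim(tmp_path_factory):
    """(input dir, SimState) for the default desk-scale synthetic data set."""
    d = tmp_path_factory.mktemp("sim")
    state = simulate_all(SimConfig(seed=SESSION_SEED), d)
    return d, state


@pytest.fixture(scope="session")
def reports(sim):
    """(report dir, pipeline summary) for the session data set."""
    d, _ = sim
    out = d / "reports"
    summary = run_pipeline(d, out)
    return out, summary


def make_db(
    genes: List[Tuple[str, str, str, List[List[Tuple[int, int]]]]],
    chrom_sizes: Dict[str, int],
    cds: Dict[str, List[Tuple[int, int]]] | None = None,
    biotypes: Dict[str, str] | None = None,
) -> AnnotationDB:
    """Build an AnnotationDB from compact tuples.

    genes: list of (gene_id, chrom, strand, [exon list per transcript]);
    cds: optional map transcript_id (gene_id.tN) -> CDS span list.
    """
    cds = cds or {}
    biotypes = biotypes or {}
    out: Dict[str, GeneModel] = {}
    for gene_id, chrom, strand, tx_exons in genes:
        bt = biotypes.get(gene_id, "protein_coding")
        g = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, biotype=bt)
        for ti, exons in enumerate(tx_exons):
            tid = f"{gene_id}.t{ti + 1}"
            g.transcripts.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
                    cds=[GenomicInterval(chrom, s, e, strand) for s, e in cds[tid]]
                    if tid in cds else None,
                    biotype=bt,
                )
            )
        out[gene_id] = g
    return AnnotationDB(genes=out, chrom_sizes=chrom_sizes)


def random_toy_db(rng: np.random.Generator, chrom_len: int = 2000,
                  n_chroms: int = 2, n_genes: int = 8) -> AnnotationDB:
    """Random, possibly overlapping, toy annotation for oracle comparisons."""
    genes = []
    for i in range(n_genes):
        chrom = f"c{rng.integers(n_chroms)}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 5))
        start = int(rng.integers(0, chrom_len - 500))
        exons = []
        cursor = start
        for _ in range(n_exons):
            length = int(rng.integers(10, 61))
            exons.append((cursor, cursor + length))
            cursor += length + int(rng.integers(5, 41))
        if exons[-1][1] > chrom_len:
            exons = [(s, e) for s, e in exons if e <= chrom_len] or [(start, start + 10)]
        genes.append((f"g{i}", chrom, strand, [exons]))
    sizes = {f"c{i}": chrom_len for i in range(n_chroms)}
    return make_db(genes, sizes)


def per_base_stringent_oracle(
    db: AnnotationDB, include_termini: bool = False
) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Brute-force per-base membership for stringent introns and intergenic."""
    introns: Dict[str, np.ndarray] = {}
    intergenic: Dict[str, np.ndarray] = {}
    for chrom, size in db.chrom_sizes.items():
        exon = np.zeros(size, bool)
        gap = np.zeros(size, bool)
        span = np.zeros(size, bool)
        for t in db.transcripts:
            if t.chrom != chrom:
                continue
            for e in t.exons:
                exon[e.start:e.end] = True
            for s, e in t.introns:
                gap[s:e] = True
            span[t.span[0]:t.span[1]] = True
        introns[chrom] = gap & ~exon
        comp = ~span
        if not include_termini:
            if span.any():
                first = int(span.argmax())
                last = size - int(span[::-1].argmax())
                comp[:first] = False
                comp[last:] = False
            else:
                comp[:] = False
        intergenic[chrom] = comp & ~exon
    return introns, intergenic


def intervals_to_mask(intervals, chrom_sizes) -> Dict[str, np.ndarray]:
    masks = {c: np.zeros(n, bool) for c, n in chrom_sizes.items()}
    for iv in intervals:
        masks[iv.chrom][iv.start:iv.end] = True
    return masks
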