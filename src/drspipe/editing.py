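"""Replicate-consensus RNA-modification site calling and annotation.

A-to-I (read as A-to-G) sites pass in an age group only when every one of
``n_required`` biological replicates reports the site with edited-read
fraction >= 0.05 and confidence >= 0.99; pseudouridine sites require
probability >= 0.90 in each replicate (no fraction threshold — the caller
emits a probability only). Consensus sites are annotated with a gene feature
(fixed priority CDS > 3'UTR > 5'UTR > noncoding exon > intron), recoding
consequences for CDS sites, age-group delta-editing classes, repeat overlap,
and per-gene counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .annotation import AnnotationDB
from .genetic_code import CodonChange, codon_consequence
from .intervals import Span, merge_spans, subtract_spans

CALL_COLUMNS = [
    "chrom", "pos", "strand", "modality", "edited_fraction", "coverage",
    "confidence", "replicate_id", "age_group",
]

FEATURE_PRIORITY = ["CDS", "utr3", "utr5", "noncoding_exon", "intron"]


# -- ingest ----------------------------------------------------------------


def read_sailor_bed(
    path: str | Path, replicate_id: str, age_group: str
) -> pd.DataFrame:
    """SAILOR-style BED: chrom, start, end, 'coverage,fraction', confidence,
    strand. One A-to-I call per row."""
    rows = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            cov, frac = f[3].split(",")
            rows.append(
                {
                    "chrom": f[0],
                    "pos": int(f[1]),
                    "strand": f[5],
                    "modality": "AtoI",
                    "edited_fraction": float(frac),
                    "coverage": int(cov),
                    "confidence": float(f[4]),
                    "replicate_id": replicate_id,
                    "age_group": age_group,
                }
            )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def read_psi_tsv(path: str | Path, replicate_id: str, age_group: str) -> pd.DataFrame:
    """Pseudouridine caller TSV: chrom, pos (0-based), strand, probability."""
    df = pd.read_csv(path, sep="\t")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"].astype(int),
            "strand": df["strand"],
            "modality": "Psi",
            "edited_fraction": np.nan,
            "coverage": df.get("coverage", pd.Series(0, index=df.index)).astype(int),
            "confidence": df["probability"].astype(float),
            "replicate_id": replicate_id,
            "age_group": age_group,
        }
    )
    return out[CALL_COLUMNS]


def write_sailor_bed(calls: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for _, r in calls.iterrows():
            fh.write(
                f"{r.chrom}\t{int(r.pos)}\t{int(r.pos) + 1}\t"
                f"{int(r.coverage)},{r.edited_fraction:g}\t{r.confidence:g}\t{r.strand}\n"
            )


# -- consensus -------------------------------------------------------------


def consensus_sites(
    calls: pd.DataFrame,
    fraction_min: float = 0.05,
    confidence_min: float = 0.99,
    n_required: int = 3,
) -> pd.DataFrame:
    """Cross-replicate consensus per (site, age group).

    A site passes in a group iff >= ``n_required`` distinct replicates of that
    group report it with confidence >= ``confidence_min`` and (A-to-I only)
    edited fraction >= ``fraction_min``. ``mean_fraction`` is averaged over the
    passing replicates. A (chrom, pos, strand) key carrying both modalities is
    an error.
    """
    if calls.empty:
        return pd.DataFrame(
            columns=["chrom", "pos", "strand", "modality", "age_group",
                     "n_pass", "passes", "mean_fraction", "mean_confidence"]
        )
    mixed = calls.groupby(["chrom", "pos", "strand"])["modality"].nunique()
    if (mixed > 1).any():
        bad = mixed[mixed > 1].index[0]
        raise ValueError(f"site {bad} carries calls of mixed modality")

    df = calls.copy()
    conf_ok = df["confidence"] >= confidence_min
    frac_ok = np.where(
        df["modality"] == "AtoI", df["edited_fraction"] >= fraction_min, True
    )
    df["rep_pass"] = conf_ok & frac_ok

    key = ["chrom", "pos", "strand", "modality", "age_group"]
    passing = df[df["rep_pass"]]
    n_pass = passing.groupby(key)["replicate_id"].nunique().rename("n_pass")
    mean_frac = passing.groupby(key)["edited_fraction"].mean().rename("mean_fraction")
    mean_conf = passing.groupby(key)["confidence"].mean().rename("mean_confidence")
    out = pd.concat([n_pass, mean_frac, mean_conf], axis=1).reset_index()
    all_sites = df.groupby(key).size().rename("n_called").reset_index()
    out = all_sites.merge(out, on=key, how="left")
    out["n_pass"] = out["n_pass"].fillna(0).astype(int)
    out["passes"] = out["n_pass"] >= n_required
    return out.sort_values(["chrom", "pos", "strand", "age_group"]).reset_index(drop=True)


def passing_sites(consensus: pd.DataFrame) -> pd.DataFrame:
    return consensus[consensus["passes"]].reset_index(drop=True)


# -- feature assignment ----------------------------------------------------


class SiteAnnotator:
    """Indexes transcript sub-features for point queries.

    For every transcript, exonic intervals are split into CDS, 5'UTR, 3'UTR
    (coding transcripts) or noncoding exon; inter-exon gaps are introns. A
    query returns the highest-priority feature among same-strand transcripts
    containing the position; positions inside genes only on the opposite
    strand are ``antisense_intragenic``; otherwise ``intergenic``.
    """

    def __init__(self, db: AnnotationDB) -> None:
        self.db = db
        self._trees: Dict[Tuple[str, str], IntervalTree] = {}
        self._span_trees: Dict[str, IntervalTree] = {}
        for t in db.transcripts:
            tree = self._trees.setdefault((t.chrom, t.strand), IntervalTree())
            exon_spans = [(e.start, e.end) for e in t.exons]
            if t.cds:
                cds_spans = [(c.start, c.end) for c in t.cds]
                cds_lo = min(s for s, _ in cds_spans)
                cds_hi = max(e for _, e in cds_spans)
                before = subtract_spans(
                    [sp for sp in exon_spans], [(cds_lo, self.db.chrom_sizes[t.chrom])]
                )
                after = subtract_spans([sp for sp in exon_spans], [(0, cds_hi)])
                utr5, utr3 = (after, before) if t.strand == "-" else (before, after)
                for s, e in cds_spans:
                    tree.addi(s, e, ("CDS", t))
                for s, e in utr5:
                    tree.addi(s, e, ("utr5", t))
                for s, e in utr3:
                    tree.addi(s, e, ("utr3", t))
            else:
                for s, e in exon_spans:
                    tree.addi(s, e, ("noncoding_exon", t))
            for s, e in t.introns:
                tree.addi(s, e, ("intron", t))
            span_tree = self._span_trees.setdefault(t.chrom, IntervalTree())
            span_tree.addi(t.span[0], t.span[1], t.strand)

    def assign(self, chrom: str, pos: int, strand: str) -> Tuple[str, str | None, str | None]:
        """Feature label, gene_id and biotype for one site."""
        tree = self._trees.get((chrom, strand))
        hits = tree[pos] if tree is not None else set()
        best: Tuple[int, str, object] | None = None
        for hit in hits:
            feature, t = hit.data
            rank = FEATURE_PRIORITY.index(feature)
            if best is None or rank < best[0]:
                best = (rank, feature, t)
        if best is not None:
            t = best[2]
            return best[1], t.gene_id, t.biotype
        span_tree = self._span_trees.get(chrom)
        if span_tree is not None and any(
            hit.data != strand for hit in span_tree[pos]
        ):
            return "antisense_intragenic", None, None
        return "intergenic", None, None


def assign_site_features(
    sites: pd.DataFrame, db: AnnotationDB, annotator: SiteAnnotator | None = None
) -> pd.DataFrame:
    """Annotate a consensus table with feature / gene / biotype columns."""
    if annotator is None:
        annotator = SiteAnnotator(db)
    features, gene_ids, biotypes = [], [], []
    for _, r in sites.iterrows():
        f, g, b = annotator.assign(r["chrom"], int(r["pos"]), r["strand"])
        features.append(f)
        gene_ids.append(g or "")
        biotypes.append(b or "")
    out = sites.copy()
    out["feature"] = features
    out["gene_id"] = gene_ids
    out["biotype"] = biotypes
    return out


# -- recoding consequence --------------------------------------------------


@dataclass
class RecodingRecord:
    chrom: str
    pos: int
    strand: str
    gene_id: str
    transcript_id: str
    codon: str
    codon_offset: int
    change: CodonChange


def recoding_consequence(
    chrom: str,
    pos: int,
    strand: str,
    db: AnnotationDB,
    edited_base: str = "G",
) -> RecodingRecord:
    """Codon-level consequence of an edit at a CDS position.

    The representative transcript is the one with the longest total CDS among
    same-strand transcripts whose CDS contains the position. The
    transcript-strand reference base must be A (A-to-I mode); anything else
    signals a strand or reference inconsistency.
    """
    candidates = []
    for t in db.transcripts:
        if t.chrom != chrom or t.strand != strand or not t.cds:
            continue
        if any(c.start <= pos < c.end for c in t.cds):
            candidates.append(t)
    if not candidates:
        raise ValueError(f"position {chrom}:{pos}({strand}) is not in any CDS")
    t = max(candidates, key=lambda t: sum(len(c) for c in t.cds))

    cds_spans = [(c.start, c.end) for c in t.cds]
    if strand == "-":
        cds_spans = cds_spans[::-1]
    coding_pos = 0
    for s, e in cds_spans:
        if s <= pos < e:
            coding_pos += (e - 1 - pos) if strand == "-" else (pos - s)
            break
        coding_pos += e - s
    codon_index, offset = divmod(coding_pos, 3)

    # spliced CDS sequence on the coding strand
    parts = [db.get_seq(chrom, s, e) for s, e in sorted(cds_spans)]
    seq = "".join(parts)
    if strand == "-":
        from .genetic_code import revcomp

        seq = revcomp(seq)
    codon = seq[3 * codon_index : 3 * codon_index + 3]
    change = codon_consequence(codon, offset, edited_base, expected_ref="A")
    return RecodingRecord(
        chrom=chrom, pos=pos, strand=strand, gene_id=t.gene_id,
        transcript_id=t.transcript_id, codon=codon, codon_offset=offset,
        change=change,
    )


# -- delta editing, repeats, summaries ------------------------------------


def delta_editing(
    consensus: pd.DataFrame,
    threshold: float = 10.0,
    relative: bool = False,
) -> pd.DataFrame:
    """Per-site editing change class for sites passing consensus in BOTH groups.

    ``delta`` is in percentage points of the edited-read fraction:
    100 * (mean_old - mean_young). ``relative=True`` instead uses percent
    change relative to the young fraction.
    """
    passing = consensus[consensus["passes"]]
    key = ["chrom", "pos", "strand", "modality"]
    young = passing[passing["age_group"] == "young"].set_index(key)["mean_fraction"]
    old = passing[passing["age_group"] == "old"].set_index(key)["mean_fraction"]
    shared = young.index.intersection(old.index)
    df = pd.DataFrame(
        {"mean_young": young.loc[shared], "mean_old": old.loc[shared]}
    ).reset_index()
    if relative:
        df["delta"] = 100.0 * (df["mean_old"] - df["mean_young"]) / df["mean_young"]
    else:
        df["delta"] = 100.0 * (df["mean_old"] - df["mean_young"])
    df["delta_class"] = np.select(
        [df["delta"] > threshold, df["delta"] < -threshold],
        ["increase", "decrease"],
        default="stable",
    )
    return df


@dataclass
class EnrichmentResult:
    site_fraction: float
    genome_fraction: float
    statistic: float
    pvalue: float
    n_sites: int
    n_in_repeats: int


def repeat_enrichment(
    sites: pd.DataFrame,
    repeat_track: Sequence[Tuple[str, int, int]],
    chrom_sizes: Dict[str, int],
    exact: bool = False,
) -> EnrichmentResult:
    """Repeat overlap of sites vs the genome-wide repeat base fraction.

    Two-sided one-sample proportion test of the observed site repeat fraction
    against the repeat-covered fraction of the genome (normal approximation
    with null variance; exact binomial via ``exact=True``).
    """
    if len(sites) == 0:
        raise ValueError("no sites given; enrichment undefined")
    by_chrom: Dict[str, List[Span]] = {}
    for chrom, s, e in repeat_track:
        by_chrom.setdefault(chrom, []).append((s, e))
    merged = {c: merge_spans(sp) for c, sp in by_chrom.items()}
    repeat_bases = sum(e - s for sp in merged.values() for s, e in sp)
    genome_bases = sum(chrom_sizes.values())
    p0 = repeat_bases / genome_bases

    starts = {c: np.array([s for s, _ in sp]) for c, sp in merged.items()}
    ends = {c: np.array([e for _, e in sp]) for c, sp in merged.items()}
    n_in = 0
    for c, sub in sites.groupby("chrom"):
        if c not in starts:
            continue
        pos = sub["pos"].to_numpy(int)
        i = np.searchsorted(starts[c], pos, side="right") - 1
        valid = i >= 0
        n_in += int(np.count_nonzero(valid & (pos < ends[c][np.clip(i, 0, None)])))
    n = len(sites)
    phat = n_in / n
    if exact:
        test = stats.binomtest(n_in, n, p0, alternative="two-sided")
        return EnrichmentResult(phat, p0, float(n_in), float(test.pvalue), n, n_in)
    se = np.sqrt(p0 * (1 - p0) / n)
    z = (phat - p0) / se
    p = 2 * stats.norm.sf(abs(z))
    return EnrichmentResult(phat, p0, float(z), float(p), n, n_in)


def edits_per_gene(annotated_sites: pd.DataFrame) -> pd.Series:
    """Consensus sites per assigned gene; intergenic and antisense excluded."""
    genic = annotated_sites[
        ~annotated_sites["feature"].isin(["intergenic", "antisense_intragenic"])
    ]
    if genic.empty:
        return pd.Series(dtype=int, name="n_edits")
    return genic.groupby("gene_id").size().rename("n_edits").sort_index()


def group_overlap(genes_young: Set[str], genes_old: Set[str]) -> Tuple[int, int, int]:
    """(young-only, shared, old-only) gene counts."""
    shared = genes_young & genes_old
    return (len(genes_young - shared), len(shared), len(genes_old - shared))


def gene_set_tissue_zscore(
    expression: pd.DataFrame,
    gene_set: Sequence[str],
) -> pd.Series:
    """Mean per-tissue z-score over a gene set.

    Each gene's expression is standardized across tissues ((x - row mean) /
    row sd); genes with zero row sd are excluded with a warning, genes absent
    from the matrix are ignored.
    """
    present = [g for g in gene_set if g in expression.index]
    sub = expression.loc[present].astype(float)
    sd = sub.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} gene(s) with constant expression excluded "
            "from tissue z-score"
        )
        sub = sub[~constant]
        sd = sd[~constant]
    if sub.empty:
        raise ValueError("no informative genes in the gene set")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    return z.mean(axis=0).rename("mean_zscore")


def read_repeat_bed(path: str | Path) -> List[Tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out
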