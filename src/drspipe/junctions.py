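"""Splice-junction fidelity against the annotated intron database.

Collapsed splice-junction tables (STAR ``SJ.out.tab`` dialect) are classified
against the annotation's intron database; the fidelity statistic is the
percentage of junction-spanning unique reads falling on unannotated junctions.
Group comparisons (e.g. young vs old animals) use a two-sided t-test after
probit transformation of the percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from scipy import stats

_STRAND_CODE = {0: ".", 1: "+", 2: "-"}
_STRAND_TO_CODE = {".": 0, "+": 1, "-": 2}

JunctionKey = Tuple[str, int, int, str]


@dataclass(frozen=True)
class JunctionRecord:
    """One collapsed splice junction with unique-read support.

    Coordinates are 0-based half-open over the intron after ingest.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    unique_reads: int = 0
    multi_reads: int = 0
    motif: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"intron end must exceed start: [{self.start},{self.end})")
        if self.unique_reads < 0:
            raise ValueError("unique_reads must be >= 0")


def read_sj_tab(path: str | Path) -> List[JunctionRecord]:
    """Ingest a STAR-style SJ.out.tab (1-based inclusive intron coordinates)."""
    out: List[JunctionRecord] = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                JunctionRecord(
                    chrom=f[0],
                    start=int(f[1]) - 1,
                    end=int(f[2]),
                    strand=_STRAND_CODE[int(f[3])],
                    unique_reads=int(f[6]),
                    multi_reads=int(f[7]),
                    motif=int(f[4]),
                )
            )
    return out


def write_sj_tab(junctions: Sequence[JunctionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(
                f"{j.chrom}\t{j.start + 1}\t{j.end}\t{_STRAND_TO_CODE[j.strand]}\t"
                f"{j.motif}\t0\t{j.unique_reads}\t{j.multi_reads}\t30\n"
            )


def classify_junctions(
    junctions: Sequence[JunctionRecord],
    junction_db: Set[JunctionKey],
    use_strand: bool = False,
) -> List[Tuple[JunctionRecord, str]]:
    """Label each junction ``annotated`` or ``unannotated``.

    Annotated means an exact (chrom, start, end) match to a database intron;
    strand is ignored by default because SJ tables may carry undefined strand.
    """
    if use_strand:
        keys = set(junction_db)
        return [
            (j, "annotated" if (j.chrom, j.start, j.end, j.strand) in keys
             else "unannotated")
            for j in junctions
        ]
    keys3 = {(c, s, e) for c, s, e, _ in junction_db}
    return [
        (j, "annotated" if (j.chrom, j.start, j.end) in keys3 else "unannotated")
        for j in junctions
    ]


def fidelity_percentage(
    classified: Sequence[Tuple[JunctionRecord, str]],
) -> float:
    """Percent of junction-spanning unique reads on unannotated junctions."""
    total = sum(j.unique_reads for j, _ in classified)
    if total == 0:
        raise ValueError("no junction-spanning reads; fidelity undefined")
    unann = sum(j.unique_reads for j, label in classified if label == "unannotated")
    return 100.0 * unann / total


def attribute_mismatch_end(
    junction: JunctionRecord,
    junction_db: Set[JunctionKey],
) -> str:
    """Which end of an unannotated junction deviates from the annotation.

    The label names the deviating end: a junction sharing only its acceptor
    boundary with some annotated intron has a shifted donor, i.e. its 5' end
    deviates -> ``five_prime_only``; sharing only the donor -> the 3' end
    deviates -> ``three_prime_only``; sharing neither -> ``both``. A junction
    whose two boundaries each match *different* annotated introns is a novel
    pairing of known ends -> ``novel_combination``.
    """
    starts = {(c, s) for c, s, _, _ in junction_db}
    ends = {(c, e) for c, _, e, _ in junction_db}
    start_shared = (junction.chrom, junction.start) in starts
    end_shared = (junction.chrom, junction.end) in ends
    if junction.strand == "-":
        donor_shared, acceptor_shared = end_shared, start_shared
    else:
        donor_shared, acceptor_shared = start_shared, end_shared
    if donor_shared and acceptor_shared:
        return "novel_combination"
    if donor_shared:
        return "three_prime_only"
    if acceptor_shared:
        return "five_prime_only"
    return "both"


def probit_transform(
    percents: Sequence[float],
    read_totals: Sequence[int] | None = None,
) -> np.ndarray:
    """Inverse standard-normal CDF of percentages (as proportions).

    Proportions at 0 or 1 are clamped to [1/(2n), 1 - 1/(2n)] with n the
    sample's read total when available, else 1e-6, with a warning.
    """
    p = np.asarray(percents, dtype=float) / 100.0
    out = np.empty_like(p)
    for i, v in enumerate(p):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"percentage out of range: {v * 100}")
        if v in (0.0, 1.0):
            n = read_totals[i] if read_totals is not None else None
            lo = 1.0 / (2 * n) if n else 1e-6
            clamped = lo if v == 0.0 else 1.0 - lo
            warnings.warn(
                f"proportion {v} clamped to {clamped} before probit transform",
                stacklevel=2,
            )
            v = clamped
        out[i] = stats.norm.ppf(v)
    return out


def compare_groups_probit(
    values_young: Sequence[float],
    values_old: Sequence[float],
    read_totals_young: Sequence[int] | None = None,
    read_totals_old: Sequence[int] | None = None,
    welch: bool = False,
) -> Tuple[float, float]:
    """Two-sided two-sample t-test on probit-transformed percentages.

    A pooled-variance (Student) test by default; Welch via ``welch=True``.
    """
    if len(values_young) < 2 or len(values_old) < 2:
        raise ValueError("each group needs at least 2 values")
    a = probit_transform(values_young, read_totals_young)
    b = probit_transform(values_old, read_totals_old)
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def fidelity_report(
    sample_junctions: Dict[str, Sequence[JunctionRecord]],
    junction_db: Set[JunctionKey],
) -> Dict[str, dict]:
    """Per-sample fidelity summary: totals, unannotated reads, percentage and
    mismatch-end attribution counts."""
    report: Dict[str, dict] = {}
    for sample, junctions in sample_junctions.items():
        classified = classify_junctions(junctions, junction_db)
        total = sum(j.unique_reads for j, _ in classified)
        unann = [(j, lab) for j, lab in classified if lab == "unannotated"]
        ends = {"five_prime_only": 0, "three_prime_only": 0, "both": 0,
                "novel_combination": 0}
        for j, _ in unann:
            ends[attribute_mismatch_end(j, junction_db)] += 1
        report[sample] = {
            "total_reads": total,
            "unannotated_reads": sum(j.unique_reads for j, _ in unann),
            "percent_unannotated": fidelity_percentage(classified),
            "mismatch_ends": ends,
        }
    return report
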