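"""Poly(A) tail length analytics.

Per-read tail estimates (Nanopolish-style TSV) are QC-filtered to PASS reads,
grouped into young (days 1, 2, 3) and old (days 7, 10, 15) animals, and
summarized per isoform. Analytics: pooled distribution medians, two-sample KS
comparison, abundance-quartile bins (low = 1st quartile, medium = 2nd + 3rd,
high = 4th), and |delta median| classes <10 / 10-20 / >20 nt.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

YOUNG_DAYS = (1, 2, 3)
OLD_DAYS = (7, 10, 15)


def default_group_for_sample(sample_id: str) -> str | None:
    """Map a sample id carrying a day number (e.g. ``d7`` or ``day7_rep1``)
    to 'young'/'old'; None when the day is not in either set."""
    m = re.search(r"(\d+)", sample_id)
    if not m:
        return None
    day = int(m.group(1))
    if day in YOUNG_DAYS:
        return "young"
    if day in OLD_DAYS:
        return "old"
    return None


def read_tails_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"readname": str, "sample_id": str})
    required = {"readname", "sample_id", "polya_length", "qc_tag"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tail table missing columns: {sorted(missing)}")
    return df


def read_assignments_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def filter_pass(records: pd.DataFrame) -> Tuple[pd.DataFrame, int]:
    """Keep PASS-tagged tail calls; report the removed count."""
    kept = records[records["qc_tag"] == "PASS"].copy()
    return kept, len(records) - len(kept)


def add_age_group(
    records: pd.DataFrame,
    sample_to_group: Dict[str, str] | None = None,
) -> pd.DataFrame:
    df = records.copy()
    if sample_to_group is not None:
        df["age_group"] = df["sample_id"].map(sample_to_group)
    else:
        df["age_group"] = df["sample_id"].map(default_group_for_sample)
    return df[df["age_group"].notna()].copy()


def group_tail_distribution(
    records: pd.DataFrame, group: str
) -> Tuple[np.ndarray, float]:
    """Pooled per-read tail lengths of one age group: (sorted lengths, median)."""
    lengths = np.sort(
        records.loc[records["age_group"] == group, "polya_length"].to_numpy(float)
    )
    if lengths.size == 0:
        raise ValueError(f"no tail records in group {group!r}")
    return lengths, float(np.median(lengths))


def ks_compare(lengths_a: Sequence[float], lengths_b: Sequence[float]) -> Tuple[float, float]:
    """Classical two-sample Kolmogorov-Smirnov D and asymptotic two-sided p."""
    res = stats.ks_2samp(lengths_a, lengths_b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def abundance_bins(isoform_expression: pd.Series) -> pd.Series:
    """Quartile bins on normalized isoform expression.

    low = 1st quartile, medium = 2nd and 3rd quartiles, high = 4th quartile;
    values exactly at a cut point fall in the lower bin. A degenerate
    distribution (q1 == q3) puts everything in ``medium`` with a warning.
    """
    x = isoform_expression.astype(float)
    q1, q3 = np.quantile(x.to_numpy(), [0.25, 0.75])
    if q1 == q3:
        warnings.warn("degenerate expression distribution: all isoforms -> medium")
        return pd.Series("medium", index=x.index, name="abundance_bin")
    labels = np.where(x <= q1, "low", np.where(x > q3, "high", "medium"))
    return pd.Series(labels, index=x.index, name="abundance_bin")


def isoform_group_medians(
    tails: pd.DataFrame,
    assignments: pd.DataFrame,
    min_reads: int = 5,
) -> pd.DataFrame:
    """Per-isoform median tail length and read count in each age group.

    ``tails`` must carry ``age_group``; reads without an isoform assignment are
    dropped. Medians are computed on reads pooled within each group.
    """
    merged = tails.merge(assignments, on="readname", how="inner")
    g = merged.groupby(["isoform_id", "age_group"])["polya_length"]
    table = g.agg(["median", "count"]).unstack("age_group")
    out = pd.DataFrame(index=table.index)
    for grp in ("young", "old"):
        if ("median", grp) in table.columns:
            out[f"median_{grp}"] = table[("median", grp)]
            out[f"n_{grp}"] = table[("count", grp)].fillna(0).astype(int)
        else:
            out[f"median_{grp}"] = np.nan
            out[f"n_{grp}"] = 0
    out["eligible"] = (out["n_young"] >= min_reads) & (out["n_old"] >= min_reads)
    return out


def delta_median_class(delta: float) -> str:
    """|delta| class with the closed middle interval [10, 20]."""
    d = abs(delta)
    if d < 10:
        return "<10"
    if d <= 20:
        return "10-20"
    return ">20"


def delta_median_classes(
    medians: pd.DataFrame,
    min_reads: int = 5,
) -> pd.DataFrame:
    """Delta-median class per isoform with >= ``min_reads`` in BOTH groups."""
    eligible = medians[
        (medians["n_young"] >= min_reads) & (medians["n_old"] >= min_reads)
    ].copy()
    eligible["delta_median"] = eligible["median_old"] - eligible["median_young"]
    eligible["delta_class"] = eligible["delta_median"].map(delta_median_class)
    return eligible


def bin_tail_summary(
    medians: pd.DataFrame,
    bins: pd.Series,
) -> pd.DataFrame:
    """Median of per-isoform median tail lengths within each abundance bin,
    per age group."""
    df = medians.join(bins, how="inner")
    rows = []
    for b in ("low", "medium", "high"):
        sub = df[df["abundance_bin"] == b]
        rows.append(
            {
                "abundance_bin": b,
                "n_isoforms": len(sub),
                "median_tail_young": float(sub["median_young"].median()),
                "median_tail_old": float(sub["median_old"].median()),
            }
        )
    return pd.DataFrame(rows).set_index("abundance_bin")
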