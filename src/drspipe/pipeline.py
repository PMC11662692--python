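"""End-to-end pipeline: ingest a directory of inputs, write every report table.

Expected input layout (the synthetic generator's conventions; real data in the
same dialects works identically):

    genome.fa, annotation.gff3
    reads.tsv
    sj_d{1,2,3,7,10,15}.tab
    isoforms.bed, isoform_counts.tsv
    tails.tsv, tail_assignments.tsv
    atoi_{young,old}_rep{1,2,3}.bed, psi_{young,old}_rep{1,2,3}.tsv
    repeats.bed, tissue_expression.tsv

Outputs are plain TSV tables with deterministic ordering and formatting, so a
rerun on the same inputs is byte-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from . import annotation as ann
from . import editing, isoforms, junctions, polya, reads as readsmod

FLOAT_FMT = "%.6g"

SAMPLES = ("d1", "d2", "d3", "d7", "d10", "d15")
YOUNG = ("d1", "d2", "d3")
OLD = ("d7", "d10", "d15")
GROUPS = ("young", "old")
REPLICATES = ("rep1", "rep2", "rep3")


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


def run_pipeline(indir: str | Path, outdir: str | Path,
                 tss_window: int = 10) -> Dict[str, object]:
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: Dict[str, object] = {}

    db = ann.parse_gff(indir / "annotation.gff3", indir / "genome.fa")

    # reference interval sets
    introns = db.stringent_introns()
    intergenic = db.stringent_intergenic()
    ann.write_bed(introns, outdir / "stringent_introns.bed", "intron")
    ann.write_bed(intergenic, outdir / "stringent_intergenic.bed", "intergenic")
    ann.write_saf(introns, outdir / "stringent_introns.saf", "intron")
    ann.write_saf(intergenic, outdir / "stringent_intergenic.saf", "intergenic")
    summary["median_gene_length"] = db.median_gene_length()

    # full-length read filtering + metagene
    all_reads = readsmod.read_reads_tsv(indir / "reads.tsv")
    kept, counts = readsmod.filter_full_length(all_reads, db, tss_window)
    _write(
        pd.DataFrame([counts]).T.rename(columns={0: "reads"}),
        outdir / "filter_stats.tsv",
    )
    summary["filter_counts"] = counts

    pre = readsmod.metagene_profile(all_reads, db, n_bins=50)
    post = readsmod.metagene_profile(kept, db, n_bins=50)
    _write(
        pd.DataFrame({"bin": np.arange(50), "prefilter": pre, "postfilter": post}),
        outdir / "metagene.tsv", index=False,
    )
    summary["metagene"] = {"pre": pre, "post": post}

    # fractional-overlap assignment of filtered-out + kept reads to the
    # stringent sets (percent of reads in introns / intergenic regions)
    primary = [r for r in all_reads
               if not (r.is_secondary or r.is_supplementary)
               and r.chrom in db.chrom_sizes]
    feature_rows = []
    for label, ivs in (("intron", introns), ("intergenic", intergenic)):
        feats = [(f"{label}_{i}", iv) for i, iv in enumerate(ivs)]
        res = readsmod.assign_reads_to_features(primary, feats, frac_overlap=0.5)
        feature_rows.append(
            {"feature_set": label, "n_reads": res.n_reads,
             "n_assigned": res.n_assigned, "percent": res.percent_assigned}
        )
    _write(pd.DataFrame(feature_rows).set_index("feature_set"),
           outdir / "feature_assignment.tsv")

    # splice-junction fidelity
    jdb = db.junction_db()
    sample_junctions = {
        s: junctions.read_sj_tab(indir / f"sj_{s}.tab") for s in SAMPLES
    }
    report = junctions.fidelity_report(sample_junctions, jdb)
    rows = []
    for s in SAMPLES:
        r = report[s]
        rows.append(
            {"sample": s, "group": "young" if s in YOUNG else "old",
             "total_reads": r["total_reads"],
             "unannotated_reads": r["unannotated_reads"],
             "percent_unannotated": r["percent_unannotated"],
             **{f"end_{k}": v for k, v in r["mismatch_ends"].items()}}
        )
    fid = pd.DataFrame(rows).set_index("sample")
    _write(fid, outdir / "junction_fidelity.tsv")
    t, p = junctions.compare_groups_probit(
        [report[s]["percent_unannotated"] for s in YOUNG],
        [report[s]["percent_unannotated"] for s in OLD],
        read_totals_young=[report[s]["total_reads"] for s in YOUNG],
        read_totals_old=[report[s]["total_reads"] for s in OLD],
    )
    _write(pd.DataFrame([{"comparison": "young_vs_old_percent_unannotated",
                          "t_statistic": t, "p_value": p}]).set_index("comparison"),
           outdir / "fidelity_group_comparison.tsv")
    summary["fidelity"] = report
    summary["fidelity_test"] = (t, p)

    # isoform classification
    callset = isoforms.read_bed12(indir / "isoforms.bed")
    isoform_counts = isoforms.read_counts_tsv(indir / "isoform_counts.tsv")
    isoforms.attach_counts(callset, isoform_counts)
    isoforms.assign_genes(callset, db)
    filtered = isoforms.filter_isoforms(callset)
    classification = isoforms.classify_callset(filtered, db)
    _write(classification, outdir / "isoform_classification.tsv")
    summary["isoforms"] = {
        "n_input": len(callset),
        "n_filtered": len(filtered),
        "classification": classification,
    }

    # poly(A) tails
    tails = polya.read_tails_tsv(indir / "tails.tsv")
    assignments = polya.read_assignments_tsv(indir / "tail_assignments.tsv")
    tails_pass, n_removed = polya.filter_pass(tails)
    tails_grouped = polya.add_age_group(tails_pass)
    young_lengths, young_med = polya.group_tail_distribution(tails_grouped, "young")
    old_lengths, old_med = polya.group_tail_distribution(tails_grouped, "old")
    D, ks_p = polya.ks_compare(young_lengths, old_lengths)
    _write(
        pd.DataFrame([{"n_removed_qc": n_removed,
                       "median_young": young_med, "median_old": old_med,
                       "ks_D": D, "ks_p": ks_p}], index=["polya"]),
        outdir / "polya_summary.tsv",
    )
    medians = polya.isoform_group_medians(tails_grouped, assignments)
    expr = isoform_counts.sum(axis=1).reindex(medians.index).dropna()
    bins = polya.abundance_bins(expr)
    bin_summary = polya.bin_tail_summary(medians, bins)
    _write(bin_summary, outdir / "polya_abundance_bins.tsv")
    deltas = polya.delta_median_classes(medians)
    _write(deltas.sort_index(), outdir / "polya_delta_classes.tsv")
    summary["polya"] = {
        "median_young": young_med, "median_old": old_med, "ks": (D, ks_p),
        "bin_summary": bin_summary, "deltas": deltas,
    }

    # modification consensus
    annotator = editing.SiteAnnotator(db)
    atoi_calls = pd.concat(
        [
            editing.read_sailor_bed(indir / f"atoi_{g}_{r}.bed", r, g)
            for g in GROUPS for r in REPLICATES
        ],
        ignore_index=True,
    )
    psi_calls = pd.concat(
        [
            editing.read_psi_tsv(indir / f"psi_{g}_{r}.tsv", r, g)
            for g in GROUPS for r in REPLICATES
        ],
        ignore_index=True,
    )
    atoi_cons = editing.consensus_sites(atoi_calls, 0.05, 0.99, 3)
    psi_cons = editing.consensus_sites(psi_calls, confidence_min=0.90, n_required=3)
    atoi_pass = editing.assign_site_features(
        editing.passing_sites(atoi_cons), db, annotator
    )
    psi_pass = editing.assign_site_features(
        editing.passing_sites(psi_cons), db, annotator
    )

    consequences = []
    for _, r in atoi_pass[atoi_pass["feature"] == "CDS"].iterrows():
        rec = editing.recoding_consequence(r["chrom"], int(r["pos"]), r["strand"], db)
        consequences.append(
            {"chrom": r["chrom"], "pos": int(r["pos"]), "strand": r["strand"],
             "age_group": r["age_group"], "gene_id": rec.gene_id,
             "codon": rec.codon, "category": rec.change.category,
             "aa_before": rec.change.aa_before, "aa_after": rec.change.aa_after,
             "property_change": rec.change.property_change}
        )
    cons_df = pd.DataFrame(consequences)
    _write(cons_df, outdir / "atoi_recoding.tsv", index=False)

    deltas_edit = editing.delta_editing(atoi_cons)
    _write(deltas_edit.sort_values(["chrom", "pos"]),
           outdir / "atoi_delta_editing.tsv", index=False)

    repeat_track = editing.read_repeat_bed(indir / "repeats.bed")
    enrich_rows = []
    for g in GROUPS:
        sites_g = atoi_pass[atoi_pass["age_group"] == g][["chrom", "pos"]].drop_duplicates()
        enr = editing.repeat_enrichment(sites_g, repeat_track, db.chrom_sizes)
        enrich_rows.append(
            {"group": g, "site_fraction": enr.site_fraction,
             "genome_fraction": enr.genome_fraction, "statistic": enr.statistic,
             "p_value": enr.pvalue, "n_sites": enr.n_sites}
        )
    _write(pd.DataFrame(enrich_rows).set_index("group"),
           outdir / "atoi_repeat_enrichment.tsv")

    per_gene = editing.edits_per_gene(atoi_pass.drop_duplicates(["chrom", "pos", "gene_id"]))
    _write(per_gene.to_frame(), outdir / "atoi_edits_per_gene.tsv")

    for name, table in (("atoi", atoi_pass), ("psi", psi_pass)):
        out = table.sort_values(["chrom", "pos", "age_group"]).reset_index(drop=True)
        _write(out, outdir / f"{name}_consensus_sites.tsv", index=False)

    psi_young = set(psi_pass.loc[psi_pass["age_group"] == "young", "gene_id"]) - {""}
    psi_old = set(psi_pass.loc[psi_pass["age_group"] == "old", "gene_id"]) - {""}
    overlap = editing.group_overlap(psi_young, psi_old)
    _write(
        pd.DataFrame([{"young_only": overlap[0], "shared": overlap[1],
                       "old_only": overlap[2]}], index=["psi_genes"]),
        outdir / "psi_gene_overlap.tsv",
    )

    expr_matrix = pd.read_csv(indir / "tissue_expression.tsv", sep="\t", index_col=0)
    gene_set = sorted(psi_young | psi_old)
    z = editing.gene_set_tissue_zscore(expr_matrix, gene_set)
    _write(z.to_frame(), outdir / "psi_tissue_zscore.tsv")

    summary["editing"] = {
        "atoi_consensus": atoi_cons, "psi_consensus": psi_cons,
        "atoi_annotated": atoi_pass, "psi_annotated": psi_pass,
        "delta": deltas_edit, "consequences": cons_df,
        "psi_overlap": overlap, "tissue_z": z,
    }
    return summary


REPORT_FILES: List[str] = [
    "stringent_introns.bed", "stringent_intergenic.bed",
    "stringent_introns.saf", "stringent_intergenic.saf",
    "filter_stats.tsv", "metagene.tsv", "feature_assignment.tsv",
    "junction_fidelity.tsv", "fidelity_group_comparison.tsv",
    "isoform_classification.tsv",
    "polya_summary.tsv", "polya_abundance_bins.tsv", "polya_delta_classes.tsv",
    "atoi_recoding.tsv", "atoi_delta_editing.tsv", "atoi_repeat_enrichment.tsv",
    "atoi_edits_per_gene.tsv", "atoi_consensus_sites.tsv",
    "psi_consensus_sites.tsv", "psi_gene_overlap.tsv", "psi_tissue_zscore.tsv",
]
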