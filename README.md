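# drspipe

Downstream analytics for nanopore **direct RNA sequencing (DRS)** studies of
the aging transcriptome, built around the bespoke computations such studies
need after alignment and base-level calling are done:

* **Stringent interval sets** — introns that overlap no annotated exon of any
  gene, and intergenic regions lying strictly between annotated transcripts,
  derived from a GFF3 annotation and exportable as BED/SAF for
  fractional-overlap read counting.
* **Full-length read filtering** — DRS reads are frequently 5′-truncated
  (3′-biased); reads are kept only if they are primary alignments, start
  within a small window of an annotated transcription start site
  (strand-aware), and carry a PASS poly(A) tail call.
* **Splice-junction fidelity** — the percentage of junction-spanning unique
  reads whose intron coordinates do not exactly match the annotated intron
  database, with each mismatch attributed to its deviating (5′/3′) end, and
  group comparisons by two-sided *t*-test after probit transformation.
* **Isoform novelty** — isoform call sets (BED12 + per-sample counts) are
  filtered (≥ 20 total reads and ≥ 10 % of the gene's reads) and classified
  by exact intron-chain identity into known / novel / novel-3′UTR (3′ end
  > 10 bp from every annotated end of the gene) / fusion (an intron longer
  than the median gene span joining exons of ≥ 2 annotated genes).
* **Poly(A) tail analytics** — PASS-filtered per-read tail lengths, pooled
  young/old medians, Kolmogorov–Smirnov comparisons, abundance-quartile bins
  (low = 1st quartile, medium = 2nd + 3rd, high = 4th), and |Δ median|
  classes < 10 / 10–20 / > 20 nt per isoform.
* **RNA-modification consensus calling** — A-to-I sites pass in an age group
  only when all three biological replicates report edited-read fraction
  ≥ 0.05 **and** confidence ≥ 0.99 (pseudouridine: probability ≥ 0.90);
  consensus sites get a feature label (priority CDS > 3′UTR > 5′UTR >
  noncoding exon > intron), codon-level recoding consequences, Δ-editing
  classes (> 10 percentage points), repeat-overlap enrichment and per-gene
  summaries, plus tissue z-score context for gene sets.

A seeded synthetic-data generator (`drspipe.simulate`) emits every input the
pipeline consumes — genome FASTA, GFF3, read tables, SJ.out.tab junction
tables, BED12 call sets, Nanopolish-style tail tables, SAILOR-style edit BEDs,
pseudouridine TSVs, a repeat track and a tissue matrix — with a truth manifest
that plants threshold-straddling cases (19/20 reads, 10/11 nt UTR offsets,
fusion introns one base either side of the median gene span, fractions
0.049/0.05, confidences 0.989/0.99) so every stage can be validated exactly.

## Worked example

```python
from pathlib import Path
from drspipe import SimConfig, simulate_all, run_pipeline

work = Path("example")
state = simulate_all(SimConfig(seed=7), work / "inputs")
summary = run_pipeline(work / "inputs", work / "reports")

c = summary["filter_counts"]
print(f"full-length reads: {c['kept']}/{c['input']} "
      f"({100 * c['kept'] / c['input']:.1f}%)")
print(f"median gene span: {summary['median_gene_length']} nt")
fid = summary["fidelity"]
young = [fid[s]["percent_unannotated"] for s in ("d1", "d2", "d3")]
old = [fid[s]["percent_unannotated"] for s in ("d7", "d10", "d15")]
t, p = summary["fidelity_test"]
print(f"unannotated junction reads: young {young} vs old {old} "
      f"(t = {t:.2f}, p = {p:.3g})")
cl = summary["isoforms"]["classification"]
print("isoform categories:", cl["category"].value_counts().to_dict())
pa = summary["polya"]
print(f"poly(A) medians: young {pa['median_young']:.1f} nt, "
      f"old {pa['median_old']:.1f} nt "
      f"(KS D = {pa['ks'][0]:.3f}, p = {pa['ks'][1]:.2g})")
delta = summary["editing"]["delta"]
print("A-to-I delta-editing classes:",
      delta["delta_class"].value_counts().to_dict())
print("psi genes (young-only, shared, old-only):",
      summary["editing"]["psi_overlap"])
```

prints

```
full-length reads: 8837/20003 (44.2%)
median gene span: 1956 nt
unannotated junction reads: young [4.0, 5.0, 6.0] vs old [7.0, 8.0, 9.0] (t = -3.53, p = 0.0242)
isoform categories: {'known': 25, 'novel': 7, 'novel_utr3': 5, 'fusion': 2}
poly(A) medians: young 54.9 nt, old 55.2 nt (KS D = 0.028, p = 0.00085)
A-to-I delta-editing classes: {'stable': 8, 'increase': 7, 'decrease': 1}
psi genes (young-only, shared, old-only): (5, 6, 8)
```

About 44 % of simulated reads survive the full-length filter because half are
planted as 5′ truncations and further reads fail the poly(A) or primary-flag
stages; the planted per-sample unannotated-junction fractions (4–6 % young,
7–9 % old) are recovered exactly and differ significantly on the probit scale;
the four isoform categories match the planted truth; old tails are slightly
longer than young; and most A-to-I sites with > 10-point editing changes
increase with age, mirroring the structure such studies report.

The same stages run from the shell:

```bash
drspipe pipeline --seed 7 --outdir example       # simulate + analyze
drspipe simulate --seed 7 --outdir inputs        # inputs only
drspipe run --indir inputs --outdir reports      # analyze existing inputs
```

Every report is a deterministic TSV (`reports/` holds filter statistics,
metagene profiles, junction fidelity, isoform classification, poly(A)
summaries, consensus sites with consequences, enrichment and overlap tables);
rerunning with the same seed reproduces every file byte-for-byte.

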