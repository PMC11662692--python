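# Methods

This note documents the models and procedures `drspipe` implements, the
parameters that matter, the design choices made where the design was open,
what the synthetic-data generator does and does not emulate, and known
limitations. No empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` compute.

## Coordinates and interval arithmetic

All internal coordinates are 0-based half-open; GFF3 and SAF (1-based
inclusive) and SJ.out.tab intron coordinates convert at the I/O boundary.
Interval set operations (union, subtraction, complement) are implemented as
sorted sweeps over `(start, end)` tuples and are validated base-for-base
against a brute-force membership oracle on random toy annotations.

**Stringent introns** are the union over all transcripts of their inter-exon
gaps, minus the union of *all* annotated exons of *all* genes. "All exons"
means every biotype and both strands, and the subtraction is strand-blind: a
region is only called intronic if nothing annotated as exonic touches it.
**Stringent intergenic** regions are the complement of transcript spans,
minus exons. Chromosome termini (before the first and after the last
transcript span) are excluded by default — the sets are meant to capture
regions *between* annotated transcripts — with `include_termini=True`
available. By construction exons, stringent introns and the
termini-inclusive intergenic set tile each chromosome exactly once; this is
asserted per-base in the tests.

**Median gene span**: per gene, max transcript end − min transcript start;
with an even gene count, the mean of the two middle values rounded half away
from zero, so the statistic is always an integer number of bases.

## Full-length read filtering

Nanopore DRS reads truncate at the 5′ end, producing 3′-biased coverage. The
filter removes, in order: (0) reads on contigs absent from the annotation
(counted separately), (1) secondary/supplementary alignments, (2) reads whose
strand-aware 5′-most aligned position is farther than `tss_window` nt
(default 10, configurable) from every annotated transcript 5′ end on the same
chromosome and strand, (3) reads without a PASS poly(A) tail call. The 5′
end of a minus-strand read is its maximal genomic coordinate. Stage counts
always sum to the input count.

The default `tss_window` of 10 nt is a package choice: published pipelines
delegate this step to an external script whose tolerance is not stated, and
10 nt comfortably covers the start-position jitter of correctly mapped
full-length reads while rejecting internal starts.

**Fractional-overlap assignment** mirrors short-read feature counting: a read
is assigned to a feature only if at least `frac_overlap` of its aligned bases
overlap it (0.5 for stringent-set assignment, 0.8 for gene-level counting);
among qualifying features the largest overlap wins and exact ties are counted
ambiguous rather than double-counted, preserving read conservation.

**Metagene profiles** rescale per-gene span coverage onto equal bins ordered
5′→3′ (strand-aware), normalize each gene to its mean bin coverage, and
average over protein-coding genes with nonzero coverage; the profile of a
fully uniform gene is exactly 1.0 in every bin and profiles sum to the bin
count. Gene span (not spliced length) is used so that 5′-truncation bias is
visible as a monotone 3′ trend.

## Splice-junction fidelity

Junction tables are compared to the database of distinct annotated introns by
exact coordinate match. Strand is ignored by default because collapsed
junction tables may carry undefined strand; exact strand matching is a flag.
The fidelity statistic is 100 × (unique reads on unannotated junctions) /
(all junction-spanning unique reads); it is scale-invariant in the counts and
undefined (an explicit error) with zero reads.

Each unannotated junction is attributed to its deviating end: sharing only
its acceptor boundary with an annotated intron means the donor moved
(`five_prime_only`), sharing only the donor means the acceptor moved
(`three_prime_only`), sharing neither is `both`. A junction whose two
boundaries each match *different* annotated introns is a novel pairing of
known ends and is labelled `novel_combination`; the four labels partition
the unannotated set.

Group comparisons transform each percentage to a proportion, apply the
inverse standard-normal CDF (probit), and run a two-sample *t*-test,
two-sided. The pooled-variance (Student) form is the default — the source
analyses state only "t-test, two-sided" — with Welch behind a flag.
Proportions of exactly 0 or 1 are clamped to [1/(2n), 1 − 1/(2n)] with n the
sample's read total when known (else 10⁻⁶), with a warning, so the transform
stays finite.

## Isoform novelty

Isoform identity is the exact ordered intron chain; terminal exon ends are
free. This matches the collapse semantics of long-read isoform callers and
makes "novel isoform" well defined. Mono-exonic isoforms are known iff
contained in a mono-exonic annotated transcript extended by `end_tolerance`
(default 10 nt) at both ends.

Filtering keeps isoforms with ≥ 20 reads summed over all samples **and**
≥ 10 % of the summed reads of all isoforms of their gene. Both bounds are
inclusive; the fraction is compared as a ratio so that 20/200 = 10 % passes
exactly despite binary floating point. Gene assignment for unannotated
structures picks the same-strand gene with the largest exonic overlap (ties
→ unassigned, which passes the fraction rule vacuously). The filter is
idempotent because gene totals only shrink.

**Productivity** is a simplified ORF rule: the start codon is the gene's
annotated start codon when that genomic position maps into the isoform,
otherwise the first AUG of the spliced sequence; the isoform is productive
iff an in-frame stop precedes the transcript end. No NMD (50-nt) rule is
applied — a deliberate divergence from heavier isoform-annotation tools.
The 3′UTR of a productive isoform runs from the base after the stop codon to
the 3′ end, possibly across splice junctions; its terminal genomic
coordinate is compared against the annotated 3′ ends *of the same gene*
(window 10 bp, inclusive, symmetric). Restricting to the same gene is a
choice; a flag widens the comparison genome-wide.

**Fusion screening** applies to splice-novel isoforms only: a candidate needs
at least one intron strictly longer than the median annotated gene span and
exonic overlap (≥ 1 nt, strand-blind) with two or more annotated genes. The
final categories are assigned with priority fusion > novel > novel-3′UTR >
known, so the four labels are mutually exclusive.

## Poly(A) tails

Only PASS-tagged tail calls are analyzed; tail lengths are real-valued nt.
Samples map to age groups by collection day — young = days {1, 2, 3}, old =
days {7, 10, 15}, configurable. Per-isoform medians are computed on reads
pooled within each group (rather than per-day medians of medians), and an
isoform enters the Δ-median analysis only with ≥ 5 reads in *both* groups
(the source analyses state no minimum; 5 is the package default).
|median_old − median_young| classes use a closed middle interval: < 10,
[10, 20], > 20 nt.

Abundance bins cut normalized isoform expression at the empirical quartiles
(type-7 linear interpolation): low = 1st quartile, medium = 2nd + 3rd,
high = 4th, with boundary values falling to the lower bin and a degenerate
all-equal distribution collapsing to `medium` with a warning. Distribution
comparisons use the classical two-sample Kolmogorov–Smirnov test with the
asymptotic p-value.

## Modification consensus calling

A site passes in an age group only when at least `n_required` (default 3,
i.e. all) biological replicates report it above threshold: A-to-I needs
edited-read fraction ≥ 0.05 **and** confidence ≥ 0.99; pseudouridine needs
probability ≥ 0.90 only, because the Ψ caller emits no per-read fraction.
Both thresholds are inclusive. Group mean fractions are averaged over
passing replicates. Passing sets are monotone under threshold tightening.

Feature assignment considers transcripts on the site's strand containing the
position and applies the fixed priority CDS > 3′UTR > 5′UTR > noncoding
exon > intron; sites inside genes only on the opposite strand are
`antisense_intragenic` and excluded from feature counts (the source analyses
are silent on antisense calls); everything else is intergenic.

Recoding consequences locate the codon in the representative transcript —
the longest total CDS among same-strand transcripts containing the site
(transcript choice is unstated in the source analyses) — and substitute G at
the edited position: synonymous, missense, stop_lost or stop_retained, plus
a flag for changes that cross side-chain property classes (nonpolar
{A,V,L,I,P,M,F,W,G}; polar-uncharged {S,T,C,Y,N,Q}; positive {K,R,H};
negative {D,E}; the classification scheme is a package choice). A→G cannot
create a stop codon, so `stop_gained` is reachable only for other
substitutions; the exhaustive 64-codon oracle test covers it. A
transcript-strand reference base other than A is an error signalling an
inconsistent site call.

**Δ editing** is read in percentage points of the edited fraction:
Δ = 100 × (mean_old − mean_young), classed increase/decrease/stable at
|Δ| > 10 points; a relative-change mode is available behind a flag since the
wording "% change" is ambiguous. **Repeat enrichment** compares the fraction
of sites inside the repeat-track union against the repeat-covered fraction of
the genome with a two-sided one-sample proportion test using the null
variance (exact binomial via flag). **Tissue z-scores** standardize each
gene's expression across tissues ((x − row mean)/row sd, population sd),
excluding constant rows with a warning, and report the gene-set mean per
tissue.

## The synthetic-data generator

The generator's defaults are the desk-scale study conditions: 2 chromosomes
× 200 kb, 60 genes (including mono-exonic, multi-transcript and noncoding
genes), 20 000 aligned reads with a 50 % planted 5′-truncation fraction
(matching the roughly half of reads such filters remove), TSS jitter ±5 nt,
10 % poly(A)-QC failures, six junction tables planting unannotated-read
fractions of exactly 4/5/6 % (young) and 7/8/9 % (old), an isoform call set
planting all four categories with boundary cases (19 vs 20 reads; 10 % vs
<10 % gene fraction at ≥ 20 reads; 3′UTR offsets of exactly 10 and 11 nt;
fusion introns of 32 000, 1957 and exactly 1956 nt against a planted median
gene span of 1956 nt), 20 000 tail reads with per-isoform log-normal tails
(σ = 0.05) whose medians fall linearly from 75 to 35 nt with abundance rank
and with planted old−young shifts of ±3/±15/±25 nt, and modification call
tables straddling every consensus threshold (fractions 0.049/0.05,
confidences 0.989/0.99, probabilities 0.89/0.90, a missing replicate) with
planted codon contexts for each reachable consequence class and planted
young-only/shared/old-only pseudouridine gene sets.

A single seed drives one root `SeedSequence`; each file family draws from a
deterministically spawned substream, so identical configurations are
byte-identical. The truth manifest (`truth.json`) covers every emitted
record: per-read full-length flags, per-junction shift kinds and expected
end labels, per-isoform categories and filter outcomes, per-isoform tail
delta classes, and per-site pass flags, features, consequences, repeat
overlap and Δ classes.

What the generator does **not** emulate: sequencing error and basecalling
noise, signal-level artifacts, alignment ambiguity, overlapping or nested
genes, trans-splicing, expression-dependent coverage biases beyond the
planted rank anticorrelation, and biological replicate variability beyond
the planted per-replicate offsets. Passing tests therefore demonstrate that
the *computations* are correct on inputs with known truth, not that upstream
callers are accurate on real data.

## Numerical choices

Inclusive thresholds everywhere a boundary is stated (20 reads, 10 %, 10 bp,
0.05, 0.99, 0.90); strict inequalities for the fusion intron (> median) and
Δ-editing (> 10 points). Fraction-of-gene comparisons are done as ratios to
keep decimal boundaries exact in binary floating point. Ambiguous
assignment ties are never double-counted. KS uses the asymptotic p-value;
the probit clamp is 1/(2n). Degenerate inputs (zero junction reads, zero
sites, empty gene sets, all-equal expression) raise explicit errors or
warnings rather than returning silent defaults.

## Limitations

* Junction classification uses only the annotation-derived intron database,
  not any caller-provided "annotated" flag.
* Productivity ignores NMD and selenocysteine recoding; start-codon choice
  falls back to the first AUG.
* The Ψ consensus carries no edited-fraction information, so Δ-editing
  applies to A-to-I sites only.
* The repeat-enrichment normal approximation is calibrated (exact size
  ≈ 0.048 at 2000 sites, 30 % repeat genome) but still a ~5 %-level test:
  roughly one uniform-site simulation in twenty is expected to cross
  p = 0.05 by chance.
* Desk-scale problem sizes (60 genes, 20 000 reads, ~30 modification sites)
  are the package's chosen defaults for fast, exhaustive validation; they
  are not a claim about statistical power on genome-scale data.
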