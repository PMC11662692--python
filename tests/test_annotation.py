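"""Annotation parsing and the derived reference indexes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drspipe.annotation import parse_gff, write_bed, write_saf
from drspipe.intervals import (
    GenomicInterval,
    merge_spans,
    subtract_spans,
    complement_spans,
)

from conftest import (
    intervals_to_mask,
    make_db,
    per_base_stringent_oracle,
    random_toy_db,
)


# -- interval algebra -------------------------------------------------------


@pytest.mark.parametrize(
    "spans,expected",
    [
        ([(0, 10), (5, 15)], [(0, 15)]),
        ([(0, 10), (10, 20)], [(0, 20)]),
        ([(5, 8), (0, 2)], [(0, 2), (5, 8)]),
        ([], []),
    ],
)
def test_merge_spans(spans, expected):
    assert merge_spans(spans) == expected


def test_subtract_and_complement_match_per_base_oracle():
    rng = np.random.default_rng(11)
    for _ in range(50):
        a = [(int(s), int(s) + int(l)) for s, l in
             zip(rng.integers(0, 180, 6), rng.integers(1, 30, 6))]
        b = [(int(s), int(s) + int(l)) for s, l in
             zip(rng.integers(0, 180, 6), rng.integers(1, 30, 6))]
        mask_a = np.zeros(220, bool)
        mask_b = np.zeros(220, bool)
        for s, e in a:
            mask_a[s:e] = True
        for s, e in b:
            mask_b[s:e] = True
        got = np.zeros(220, bool)
        for s, e in subtract_spans(a, b):
            assert e > s
            got[s:e] = True
        assert np.array_equal(got, mask_a & ~mask_b)
        comp = np.zeros(220, bool)
        for s, e in complement_spans(a, 0, 220):
            comp[s:e] = True
        assert np.array_equal(comp, ~mask_a)


spans_strategy = st.lists(
    st.tuples(st.integers(0, 150), st.integers(1, 40)).map(
        lambda t: (t[0], t[0] + t[1])
    ),
    max_size=8,
)


@settings(derandomize=True, max_examples=60)
@given(a=spans_strategy, b=spans_strategy)
def test_interval_algebra_identities(a, b):
    """(A - B) and (A ∩ B-complement) agree per base; subtraction never
    returns empty or out-of-order spans."""
    size = 200
    mask_a = np.zeros(size, bool)
    mask_b = np.zeros(size, bool)
    for s, e in a:
        mask_a[s:e] = True
    for s, e in b:
        mask_b[s:e] = True
    out = subtract_spans(a, b)
    got = np.zeros(size, bool)
    prev_end = -1
    for s, e in out:
        assert e > s > prev_end or (prev_end == -1 and e > s)
        prev_end = e
        got[s:e] = True
    assert np.array_equal(got, mask_a & ~mask_b)
    # subtracting the complement of B equals intersecting with B
    comp_b = complement_spans(b, 0, size)
    inter = np.zeros(size, bool)
    for s, e in subtract_spans(a, comp_b):
        inter[s:e] = True
    assert np.array_equal(inter, mask_a & mask_b)


def test_genomic_interval_validation():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 10, 10)
    with pytest.raises(ValueError):
        GenomicInterval("", 0, 5)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -1, 5)


# -- GFF3 / FASTA ingest ----------------------------------------------------


GFF = """##gff-version 3
chrI\t.\tgene\t11\t100\t.\t+\t.\tID=gA;biotype=protein_coding
chrI\t.\tmRNA\t11\t100\t.\t+\t.\tID=gA.t1;Parent=gA
chrI\t.\texon\t11\t20\t.\t+\t.\tParent=gA.t1
chrI\t.\texon\t41\t100\t.\t+\t.\tParent=gA.t1
chrI\t.\tCDS\t45\t80\t.\t+\t0\tParent=gA.t1
chrI\t.\tmRNA\t11\t100\t.\t+\t.\tID=gA.t2;Parent=gA
chrI\t.\texon\t11\t100\t.\t+\t.\tParent=gA.t2
chrI\t.\tweird_feature\t5\t8\t.\t+\t.\tID=x1
"""


def _write_inputs(tmp_path, gff=GFF, seqlen=200):
    gff_path = tmp_path / "a.gff3"
    gff_path.write_text(gff)
    fa = tmp_path / "g.fa"
    fa.write_text(">chrI\n" + "ACGT" * (seqlen // 4) + "\n")
    return gff_path, fa


def test_parse_gff_converts_coordinates_and_groups_transcripts(tmp_path):
    db = parse_gff(*_write_inputs(tmp_path))
    assert list(db.genes) == ["gA"]
    gene = db.genes["gA"]
    assert len(gene.transcripts) == 2
    t1 = gene.transcripts[0]
    # 1-based inclusive 11..20 -> 0-based half-open [10, 20)
    assert (t1.exons[0].start, t1.exons[0].end) == (10, 20)
    assert t1.cds[0].start == 44 and t1.cds[0].end == 80
    assert db.chrom_sizes == {"chrI": 200}


def test_parse_gff_rejects_out_of_bounds_exon(tmp_path):
    bad = GFF.replace("exon\t41\t100", "exon\t41\t300")
    with pytest.raises(ValueError, match="gA.t1"):
        parse_gff(*_write_inputs(tmp_path, gff=bad))


def test_parse_gff_rejects_transcript_without_exons(tmp_path):
    gff = (
        "##gff-version 3\n"
        "chrI\t.\tgene\t11\t100\t.\t+\t.\tID=gB\n"
        "chrI\t.\tmRNA\t11\t100\t.\t+\t.\tID=gB.t1;Parent=gB\n"
    )
    with pytest.raises(ValueError, match="no exons"):
        parse_gff(*_write_inputs(tmp_path, gff=gff))


# -- stringent interval sets ------------------------------------------------


def test_stringent_introns_simple_gap():
    db = make_db([("g1", "c0", "+", [[(0, 10), (20, 30)]])], {"c0": 100})
    assert [(iv.start, iv.end) for iv in db.stringent_introns()] == [(10, 20)]


def test_stringent_introns_remove_overlapping_exon_of_other_gene():
    db = make_db(
        [
            ("g1", "c0", "+", [[(0, 10), (20, 30)]]),
            ("g2", "c0", "-", [[(12, 18)]]),
        ],
        {"c0": 100},
    )
    got = [(iv.start, iv.end) for iv in db.stringent_introns()]
    assert got == [(10, 12), (18, 20)]


def test_stringent_intergenic_termini_flag():
    db = make_db(
        [("g1", "c0", "+", [[(0, 30)]]), ("g2", "c0", "+", [[(50, 80)]])],
        {"c0": 100},
    )
    inner = [(iv.start, iv.end) for iv in db.stringent_intergenic()]
    assert inner == [(30, 50)]
    with_termini = [
        (iv.start, iv.end) for iv in db.stringent_intergenic(include_termini=True)
    ]
    assert with_termini == [(30, 50), (80, 100)]


def test_stringent_sets_match_per_base_oracle_on_random_annotations():
    rng = np.random.default_rng(5)
    for _ in range(30):
        db = random_toy_db(rng)
        for termini in (False, True):
            oracle_introns, oracle_interg = per_base_stringent_oracle(db, termini)
            got_i = intervals_to_mask(db.stringent_introns(), db.chrom_sizes)
            got_g = intervals_to_mask(
                db.stringent_intergenic(include_termini=termini), db.chrom_sizes
            )
            for c in db.chrom_sizes:
                assert np.array_equal(got_i[c], oracle_introns[c])
                assert np.array_equal(got_g[c], oracle_interg[c])


def test_intron_intergenic_exon_sets_are_disjoint_and_tile():
    """Exons, stringent introns, stringent intergenic (with termini) tile each
    chromosome exactly once."""
    rng = np.random.default_rng(17)
    for _ in range(10):
        db = random_toy_db(rng)
        exon = intervals_to_mask(
            [
                iv
                for t in db.transcripts
                for iv in t.exons
            ],
            db.chrom_sizes,
        )
        intr = intervals_to_mask(db.stringent_introns(), db.chrom_sizes)
        interg = intervals_to_mask(
            db.stringent_intergenic(include_termini=True), db.chrom_sizes
        )
        for c in db.chrom_sizes:
            total = exon[c].astype(int) + intr[c].astype(int) + interg[c].astype(int)
            # every base belongs to exactly one of the three sets
            assert np.all(total == 1)


# -- junction DB, median gene length, UTR ends ------------------------------


def test_junction_db_dedupes_shared_introns():
    db = make_db(
        [("g1", "c0", "+", [[(0, 10), (20, 30), (40, 50)],
                            [(0, 10), (20, 30)]])],
        {"c0": 100},
    )
    assert db.junction_db() == {("c0", 10, 20, "+"), ("c0", 30, 40, "+")}


def test_junction_db_matches_bruteforce_enumeration():
    rng = np.random.default_rng(23)
    for _ in range(20):
        db = random_toy_db(rng)
        expected = set()
        for t in db.transcripts:
            for s, e in t.introns:
                expected.add((t.chrom, s, e, t.strand))
        assert db.junction_db() == expected


@pytest.mark.parametrize(
    "spans,expected",
    [([100, 200, 300], 200), ([100, 200], 150), ([101, 102], 102)],
)
def test_median_gene_length(spans, expected):
    genes = [
        (f"g{i}", "c0", "+", [[(1000 * i, 1000 * i + s)]])
        for i, s in enumerate(spans)
    ]
    db = make_db(genes, {"c0": 10000})
    assert db.median_gene_length() == expected


def test_median_gene_length_invariant_under_reordering():
    rng = np.random.default_rng(3)
    spans = rng.integers(50, 900, 15)
    genes = [
        (f"g{i}", "c0", "+", [[(1000 * i, 1000 * i + int(s))]])
        for i, s in enumerate(spans)
    ]
    db1 = make_db(genes, {"c0": 20000})
    db2 = make_db(genes[::-1], {"c0": 20000})
    # independent sort-based oracle
    srt = np.sort(spans)
    expected = int(srt[len(srt) // 2])
    assert db1.median_gene_length() == db2.median_gene_length() == expected


def test_utr3_ends_strand_aware_and_cds_only():
    db = make_db(
        [
            ("gp", "c0", "+", [[(100, 200), (300, 500)]]),
            ("gm", "c0", "-", [[(40, 90), (120, 160)]]),
            ("gn", "c0", "+", [[(600, 700)]]),  # no CDS: excluded
        ],
        {"c0": 1000},
        cds={"gp.t1": [(150, 200), (300, 400)], "gm.t1": [(60, 90), (120, 140)]},
    )
    ends = db.utr3_ends()
    assert ends == {"gp": {500}, "gm": {40}}


def test_bed_and_saf_round_trip_coordinates(tmp_path):
    ivs = [GenomicInterval("c0", 10, 20, "+"), GenomicInterval("c1", 0, 5, ".")]
    bed = tmp_path / "x.bed"
    saf = tmp_path / "x.saf"
    write_bed(ivs, bed)
    write_saf(ivs, saf)
    bed_rows = [l.split("\t") for l in bed.read_text().splitlines()]
    assert bed_rows[0][1:3] == ["10", "20"]
    saf_rows = [l.split("\t") for l in saf.read_text().splitlines()]
    assert saf_rows[0] == ["GeneID", "Chr", "Start", "End", "Strand"]
    assert saf_rows[1][2:4] == ["11", "20"]  # 1-based inclusive
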