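"""Isoform filtering, novelty classification, productivity, 3'UTRs, fusions."""

import numpy as np
import pytest

from drspipe.isoforms import (
    IsoformCall,
    classify_splice_novelty,
    classify_utr3_novelty,
    extract_utr3,
    filter_isoforms,
    predict_productivity,
    read_bed12,
    screen_fusion_isoforms,
    write_bed12,
)

from conftest import make_db


def iso(iso_id="i1", exons=((0, 50), (100, 150)), gene="g1", total=30,
        chrom="c0", strand="+"):
    return IsoformCall(iso_id, chrom, strand, list(exons),
                       read_counts={"s1": total}, gene_id=gene)


class TestFilter:
    def test_19_reads_dropped_20_kept(self):
        kept = filter_isoforms([iso("a", total=19), iso("b", gene="g2", total=20)])
        assert [i.isoform_id for i in kept] == ["b"]

    def test_gene_fraction_boundary_inclusive(self):
        # (180, 20): 20/200 = 10% >= 10% -> both kept (inclusive boundary)
        kept = filter_isoforms([iso("a", total=180), iso("b", total=20)])
        assert len(kept) == 2
        # (190, 20): 20/210 < 10% -> second dropped by the fraction rule alone
        kept = filter_isoforms([iso("a", total=190), iso("b", total=20)])
        assert [i.isoform_id for i in kept] == ["a"]

    def test_unassigned_isoform_passes_fraction_vacuously(self):
        kept = filter_isoforms([iso("a", gene=None, total=25)])
        assert len(kept) == 1

    def test_idempotent(self):
        rng = np.random.default_rng(41)
        calls = [
            iso(f"i{k}", gene=f"g{int(rng.integers(0, 5))}",
                total=int(rng.integers(0, 120)))
            for k in range(40)
        ]
        once = filter_isoforms(calls)
        twice = filter_isoforms(once)
        assert [i.isoform_id for i in once] == [i.isoform_id for i in twice]

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(43)
        for _ in range(20):
            calls = [
                iso(f"i{k}", gene=f"g{int(rng.integers(0, 4))}",
                    total=int(rng.integers(0, 80)))
                for k in range(25)
            ]
            gene_tot = {}
            for c in calls:
                gene_tot[c.gene_id] = gene_tot.get(c.gene_id, 0) + c.total_reads
            expected = [
                c.isoform_id for c in calls
                if c.total_reads >= 20
                and c.total_reads >= 0.10 * gene_tot[c.gene_id]
            ]
            got = [c.isoform_id for c in filter_isoforms(calls)]
            assert got == expected


@pytest.fixture()
def novelty_db():
    return make_db(
        [
            ("g1", "c0", "+", [[(0, 50), (100, 150), (200, 260)]]),
            ("gm", "c0", "+", [[(400, 500)]]),  # mono-exonic
        ],
        {"c0": 1000},
    )


class TestSpliceNovelty:
    def test_identical_intron_chain_with_free_terminal_ends_is_known(self, novelty_db):
        i = iso(exons=((10, 50), (100, 150), (200, 240)))
        assert classify_splice_novelty(i, novelty_db) == "known"

    def test_skipped_exon_is_novel(self, novelty_db):
        i = iso(exons=((0, 50), (200, 260)))
        assert classify_splice_novelty(i, novelty_db) == "novel"

    def test_mono_exonic_containment_with_tolerance(self, novelty_db):
        inside = iso(exons=((405, 495),))
        at_tol = iso(exons=((390, 510),))
        beyond = iso(exons=((389, 500),))
        assert classify_splice_novelty(inside, novelty_db, end_tolerance=10) == "known"
        assert classify_splice_novelty(at_tol, novelty_db, end_tolerance=10) == "known"
        assert classify_splice_novelty(beyond, novelty_db, end_tolerance=10) == "novel"

    def test_strand_mismatch_is_novel(self, novelty_db):
        i = iso(exons=((10, 50), (100, 150), (200, 240)), strand="-")
        assert classify_splice_novelty(i, novelty_db) == "novel"


class TestProductivityAndUtr3:
    @pytest.fixture()
    def coding_db(self, tmp_path):
        # 300 nt chromosome; gene: exons [10,100) + [150,250), CDS starts at 40
        seq = ["T"] * 300
        # ORF: ATG + 20 sense codons + TAA; first exon part 40..100 (60 nt),
        # second part 150..156 (6 nt): CDS 40..100 + 150..156
        orf = "ATG" + "GCT" * 20 + "TAA"  # 66 nt
        positions = list(range(40, 100)) + list(range(150, 156))
        for p, b in zip(positions, orf):
            seq[p] = b
        fa = tmp_path / "g.fa"
        fa.write_text(">c0\n" + "".join(seq) + "\n")
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c0\t.\tgene\t11\t250\t.\t+\t.\tID=g1\n"
            "c0\t.\tmRNA\t11\t250\t.\t+\t.\tID=g1.t1;Parent=g1\n"
            "c0\t.\texon\t11\t100\t.\t+\t.\tParent=g1.t1\n"
            "c0\t.\texon\t151\t250\t.\t+\t.\tParent=g1.t1\n"
            "c0\t.\tCDS\t41\t100\t.\t+\t0\tParent=g1.t1\n"
            "c0\t.\tCDS\t151\t156\t.\t+\t0\tParent=g1.t1\n"
        )
        from drspipe.annotation import parse_gff

        return parse_gff(gff, fa)

    def test_isoform_containing_annotated_cds_is_productive(self, coding_db):
        i = iso(exons=((10, 100), (150, 250)))
        res = predict_productivity(i, coding_db)
        assert res.productive
        # stop codon begins at transcript coordinate 30 + 63 = 93
        assert res.start_tx == 30
        assert res.stop_tx == 93

    def test_no_start_codon_is_unproductive(self, coding_db):
        i = iso("i2", exons=((200, 250),), gene=None)
        res = predict_productivity(i, coding_db)
        assert not res.productive and "start" in res.reason

    def test_utr3_single_interval(self, coding_db):
        i = iso(exons=((10, 100), (150, 250)))
        res = predict_productivity(i, coding_db)
        utr, end = extract_utr3(i, res.stop_tx)
        # UTR runs from genomic 156 to 250 on the second exon
        assert [(u.start, u.end) for u in utr] == [(156, 250)]
        assert end == 250

    def test_utr3_spanning_two_exons(self, coding_db):
        # stop early in exon 1 -> UTR covers rest of exon1 + all of exon2
        i = iso(exons=((10, 100), (150, 250)))
        utr, end = extract_utr3(i, 60)  # pretend stop at tx coord 60
        assert [(u.start, u.end) for u in utr] == [(73, 100), (150, 250)]
        assert end == 250

    def test_minus_strand_utr3_end_is_min_start(self):
        i = iso(exons=((100, 160), (200, 260)), strand="-")
        utr, end = extract_utr3(i, 100)  # 120 tx bases, stop at 100
        assert end == 100
        assert utr[-1].end == 117  # 17 residual bases at the genomic start side


class TestUtr3Novelty:
    INDEX = {"g1": {500, 800}}

    @pytest.mark.parametrize(
        "end,expected",
        [(500, "known"), (510, "known"), (511, "novel"), (490, "known"),
         (489, "novel"), (800, "known")],
    )
    def test_window_boundary_inclusive_and_symmetric(self, end, expected):
        assert classify_utr3_novelty(end, "g1", self.INDEX, window=10) == expected

    def test_gene_scoping(self):
        assert classify_utr3_novelty(500, "g2", self.INDEX) == "novel"
        assert classify_utr3_novelty(
            500, "g2", self.INDEX, gene_scoped=False
        ) == "known"


class TestFusionScreen:
    @pytest.fixture()
    def fusion_db(self):
        return make_db(
            [
                ("gA", "c0", "+", [[(0, 100), (200, 300)]]),
                ("gB", "c0", "+", [[(2500, 2600), (2700, 2800)]]),
            ],
            {"c0": 10_000},
        )

    def test_long_intron_joining_two_genes_is_candidate(self, fusion_db):
        fusion = iso(exons=((0, 100), (200, 300), (2500, 2600)))
        out = screen_fusion_isoforms([fusion], fusion_db, min_intron=1956)
        assert out == [fusion]

    def test_intron_exactly_at_threshold_is_not_candidate(self, fusion_db):
        # connector intron of exactly 1956 nt: 300 -> 2256; second exon
        # overlaps gB only if it reaches 2500, so use a gB exon start
        fusion = iso(exons=((0, 300), (2256 + 0, 2600)))
        # intron length = 2256 - 300 = 1956 -> excluded (strict >)
        out = screen_fusion_isoforms([fusion], fusion_db, min_intron=1956)
        assert out == []
        # one base longer qualifies
        fusion2 = iso(exons=((0, 300), (2257, 2600)))
        assert screen_fusion_isoforms([fusion2], fusion_db, min_intron=1956)

    def test_long_intron_within_one_gene_is_not_candidate(self, fusion_db):
        i = iso(exons=((0, 100), (2500, 2600)))
        db1 = make_db([("gA", "c0", "+", [[(0, 100), (2500, 2600)]])],
                      {"c0": 10_000})
        assert screen_fusion_isoforms([i], db1, min_intron=1956) == []

    def test_default_threshold_is_median_gene_length(self, fusion_db):
        assert fusion_db.median_gene_length() == 300
        fusion = iso(exons=((0, 300), (2500, 2600)))
        assert screen_fusion_isoforms([fusion], fusion_db)


class TestSyntheticRecovery:
    def test_four_way_classification_matches_truth_with_zero_confusion(
        self, sim, reports
    ):
        _, state = sim
        _, summary = reports
        cl = summary["isoforms"]["classification"]
        truth = state.truth["isoforms"]
        for iso_id in cl.index:
            assert cl.loc[iso_id, "category"] == truth[iso_id]["category"]

    def test_filter_survivors_match_truth_including_boundaries(self, sim, reports):
        _, state = sim
        _, summary = reports
        truth = state.truth["isoforms"]
        survivors = set(summary["isoforms"]["classification"].index)
        assert survivors == {k for k, v in truth.items() if v["passes_filter"]}
        totals = {v["total_reads"] for v in truth.values()}
        assert 19 in totals and 20 in totals  # boundary cases planted

    def test_every_fusion_candidate_is_also_splice_novel(self, reports):
        _, summary = reports
        cl = summary["isoforms"]["classification"]
        fused = cl[cl["is_fusion"]]
        assert len(fused) > 0
        assert (fused["splice_novelty"] == "novel").all()


def test_bed12_round_trip(tmp_path):
    calls = [iso(exons=((5, 50), (80, 130), (150, 200)), strand="-")]
    path = tmp_path / "x.bed"
    write_bed12(calls, path)
    back = read_bed12(path)
    assert back[0].exons == [(5, 50), (80, 130), (150, 200)]
    assert back[0].strand == "-"
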