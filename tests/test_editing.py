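"""Consensus modification calling, feature assignment, recoding, enrichment."""

import numpy as np
import pandas as pd
import pytest

from drspipe.editing import (
    CALL_COLUMNS,
    SiteAnnotator,
    consensus_sites,
    delta_editing,
    edits_per_gene,
    gene_set_tissue_zscore,
    group_overlap,
    passing_sites,
    read_sailor_bed,
    recoding_consequence,
    repeat_enrichment,
)

from conftest import make_db


def call(chrom="c0", pos=100, strand="+", modality="AtoI", frac=0.2, cov=80,
         conf=0.995, rep="rep1", group="young"):
    return dict(zip(CALL_COLUMNS,
                    (chrom, pos, strand, modality, frac, cov, conf, rep, group)))


def calls_df(rows):
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


class TestConsensus:
    def test_three_passing_replicates_pass(self):
        df = calls_df([
            call(frac=0.06, conf=0.995, rep="rep1"),
            call(frac=0.05, conf=0.999, rep="rep2"),
            call(frac=0.07, conf=0.992, rep="rep3"),
        ])
        out = consensus_sites(df)
        assert out["passes"].tolist() == [True]
        assert out["mean_fraction"].iloc[0] == pytest.approx(0.06)

    def test_one_replicate_below_fraction_fails(self):
        df = calls_df([
            call(frac=0.04, rep="rep1"), call(frac=0.2, rep="rep2"),
            call(frac=0.2, rep="rep3"),
        ])
        assert not consensus_sites(df)["passes"].any()

    def test_boundary_values_inclusive(self):
        df = calls_df([
            call(frac=0.05, conf=0.99, rep=r) for r in ("rep1", "rep2", "rep3")
        ])
        assert consensus_sites(df)["passes"].all()
        df = calls_df([
            call(frac=0.049, rep="rep1"), call(frac=0.2, rep="rep2"),
            call(frac=0.2, rep="rep3"),
        ])
        assert not consensus_sites(df)["passes"].any()

    def test_psi_ignores_fraction_threshold(self):
        df = calls_df([
            call(modality="Psi", frac=np.nan, conf=0.93, rep=r)
            for r in ("rep1", "rep2", "rep3")
        ])
        out = consensus_sites(df, confidence_min=0.90)
        assert out["passes"].all()

    def test_missing_replicate_fails(self):
        df = calls_df([call(rep="rep1"), call(rep="rep2")])
        assert not consensus_sites(df)["passes"].any()

    def test_mixed_modalities_at_one_site_rejected(self):
        df = calls_df([call(), call(modality="Psi", rep="rep2")])
        with pytest.raises(ValueError, match="mixed modality"):
            consensus_sites(df)

    def test_matches_bruteforce_oracle_on_random_tables(self):
        rng = np.random.default_rng(83)
        rows = []
        for i in range(500):
            group = "young" if rng.random() < 0.5 else "old"
            for rep in ("rep1", "rep2", "rep3"):
                if rng.random() < 0.8:
                    rows.append(call(
                        pos=i,
                        frac=float(rng.choice([0.049, 0.05, 0.03, 0.2, 0.6])),
                        conf=float(rng.choice([0.989, 0.99, 0.95, 0.999])),
                        rep=rep, group=group,
                    ))
        df = calls_df(rows)
        out = consensus_sites(df, 0.05, 0.99, 3)
        # brute-force oracle
        expected = {}
        for r in rows:
            key = (r["chrom"], r["pos"], r["strand"], r["modality"],
                   r["age_group"])
            ok = r["edited_fraction"] >= 0.05 and r["confidence"] >= 0.99
            expected.setdefault(key, set())
            if ok:
                expected[key].add(r["replicate_id"])
        for _, row in out.iterrows():
            key = (row["chrom"], row["pos"], row["strand"], row["modality"],
                   row["age_group"])
            assert row["passes"] == (len(expected[key]) >= 3)

    def test_monotone_under_threshold_tightening(self):
        rng = np.random.default_rng(89)
        rows = [
            call(pos=i, frac=float(rng.uniform(0.0, 0.3)),
                 conf=float(rng.uniform(0.9, 1.0)), rep=rep)
            for i in range(200) for rep in ("rep1", "rep2", "rep3")
        ]
        df = calls_df(rows)
        loose = set(
            passing_sites(consensus_sites(df, 0.05, 0.95))["pos"]
        )
        tight_frac = set(passing_sites(consensus_sites(df, 0.10, 0.95))["pos"])
        tight_conf = set(passing_sites(consensus_sites(df, 0.05, 0.99))["pos"])
        assert tight_frac <= loose and tight_conf <= loose


@pytest.fixture()
def feature_db():
    # plus-strand coding gene, minus-strand noncoding gene, shared chromosome
    return make_db(
        [
            ("gc", "c0", "+", [[(100, 200), (300, 500)]]),
            ("gn", "c0", "-", [[(700, 760)]]),
        ],
        {"c0": 2000},
        cds={"gc.t1": [(150, 200), (300, 400)]},
        biotypes={"gn": "ncRNA"},
    )


class TestFeatureAssignment:
    @pytest.mark.parametrize(
        "pos,strand,expected",
        [
            (160, "+", "CDS"),
            (120, "+", "utr5"),
            (450, "+", "utr3"),
            (250, "+", "intron"),
            (720, "-", "noncoding_exon"),
            (600, "+", "intergenic"),
            (160, "-", "antisense_intragenic"),
        ],
    )
    def test_feature_priority_and_strand(self, feature_db, pos, strand, expected):
        annot = SiteAnnotator(feature_db)
        feature, gene, _ = annot.assign("c0", pos, strand)
        assert feature == expected

    def test_cds_beats_intron_of_other_transcript(self):
        db = make_db(
            [("g1", "c0", "+", [[(0, 100), (200, 300)], [(0, 300)]])],
            {"c0": 1000},
            cds={"g1.t2": [(140, 260)]},
        )
        annot = SiteAnnotator(db)
        # 150 is intron of t1 but CDS of t2
        assert annot.assign("c0", 150, "+")[0] == "CDS"

    def test_planted_site_features_fully_recovered(self, sim, reports):
        _, state = sim
        _, summary = reports
        atoi = summary["editing"]["atoi_annotated"]
        truth = state.truth["atoi"]
        assert len(atoi) > 0
        for _, r in atoi.iterrows():
            key = f"{r.chrom}:{r.pos}:{r.strand}"
            assert truth[key]["feature"] == r["feature"]


class TestRecoding:
    def test_minus_strand_reference_complemented(self, tmp_path):
        # minus-strand gene: genome TCA at [10,13) reads TGA on the transcript;
        # CDS 5'->3' = ATG AAA TGA, genome holds its reverse complement
        fa = tmp_path / "g.fa"
        fa.write_text(">c0\n" + "GGGGGGGGGG" + "TCATTTCAT" + "G" * 11 + "\n")
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c0\t.\tgene\t11\t19\t.\t-\t.\tID=g1\n"
            "c0\t.\tmRNA\t11\t19\t.\t-\t.\tID=g1.t1;Parent=g1\n"
            "c0\t.\texon\t11\t19\t.\t-\t.\tParent=g1.t1\n"
            "c0\t.\tCDS\t11\t19\t.\t-\t0\tParent=g1.t1\n"
        )
        from drspipe.annotation import parse_gff

        db = parse_gff(gff, fa)
        # transcript codon 2 is AAA; its middle A sits at genomic pos 14 (base T)
        rec = recoding_consequence("c0", 14, "-", db)
        assert rec.codon == "AAA"
        assert rec.change.category == "missense"  # AAA->AGA Lys->Arg

    def test_non_adenosine_reference_is_error(self, feature_db):
        # genome is random; find a CDS position whose base is not A
        with pytest.raises(ValueError):
            # position 160 in gc CDS; the test db has no FASTA -> error either way
            recoding_consequence("c0", 160, "+", feature_db)

    def test_planted_consequences_recovered(self, sim, reports):
        _, state = sim
        _, summary = reports
        cons = summary["editing"]["consequences"].drop_duplicates(["chrom", "pos"])
        truth = state.truth["atoi"]
        checked = 0
        for _, r in cons.iterrows():
            t = truth[f"{r.chrom}:{r.pos}:{r.strand}"]
            if "consequence" not in t:
                continue
            assert r["category"] == t["consequence"]
            assert r["property_change"] == t["property_change"]
            checked += 1
        assert checked >= 6  # all planted codon contexts observed


class TestDeltaEditing:
    def _consensus(self, rows):
        return pd.DataFrame(
            rows,
            columns=["chrom", "pos", "strand", "modality", "age_group",
                     "n_pass", "passes", "mean_fraction"],
        )

    def test_threshold_classes(self):
        rows = []
        for pos, fy, fo in ((1, 0.20, 0.35), (2, 0.20, 0.25), (3, 0.40, 0.20)):
            rows.append(("c0", pos, "+", "AtoI", "young", 3, True, fy))
            rows.append(("c0", pos, "+", "AtoI", "old", 3, True, fo))
        out = delta_editing(self._consensus(rows)).set_index("pos")
        assert out.loc[1, "delta_class"] == "increase"
        assert out.loc[2, "delta_class"] == "stable"
        assert out.loc[3, "delta_class"] == "decrease"

    def test_requires_pass_in_both_groups(self):
        rows = [
            ("c0", 1, "+", "AtoI", "young", 3, True, 0.2),
            ("c0", 1, "+", "AtoI", "old", 2, False, 0.5),
        ]
        assert delta_editing(self._consensus(rows)).empty

    def test_planted_delta_classes_recovered(self, sim, reports):
        _, state = sim
        _, summary = reports
        deltas = summary["editing"]["delta"]
        truth = state.truth["atoi"]
        n = 0
        for _, r in deltas.iterrows():
            t = truth[f"{r.chrom}:{r.pos}:{r.strand}"]
            if "delta_class" in t:
                assert r["delta_class"] == t["delta_class"]
                n += 1
        assert n == len(deltas) and n > 10


class TestRepeatEnrichment:
    CHROMS = {"c0": 10_000}
    REPEATS = [("c0", 0, 3000)]  # 30% of the genome

    def test_all_sites_in_repeats_strongly_enriched(self):
        sites = pd.DataFrame({"chrom": "c0", "pos": np.arange(100, 2900, 100)})
        res = repeat_enrichment(sites, self.REPEATS, self.CHROMS)
        assert res.site_fraction == 1.0
        assert res.genome_fraction == pytest.approx(0.3)
        assert res.pvalue < 1e-6

    def test_uniform_sites_not_significant(self):
        rng = np.random.default_rng(97)
        sites = pd.DataFrame(
            {"chrom": "c0", "pos": rng.integers(0, 10_000, 2000)}
        )
        res = repeat_enrichment(sites, self.REPEATS, self.CHROMS)
        assert abs(res.site_fraction - 0.3) < 0.05

    def test_zero_sites_is_an_error(self):
        with pytest.raises(ValueError):
            repeat_enrichment(pd.DataFrame({"chrom": [], "pos": []}),
                              self.REPEATS, self.CHROMS)

    def test_exact_binomial_flag(self):
        sites = pd.DataFrame({"chrom": "c0", "pos": [100, 200, 5000, 6000]})
        res = repeat_enrichment(sites, self.REPEATS, self.CHROMS, exact=True)
        assert 0 <= res.pvalue <= 1


class TestSummaries:
    def test_edits_per_gene_excludes_intergenic(self):
        df = pd.DataFrame(
            {"chrom": "c0", "pos": range(5), "gene_id": ["g1", "g1", "g1", "", ""],
             "feature": ["CDS", "utr3", "intron", "intergenic",
                         "antisense_intragenic"]}
        )
        counts = edits_per_gene(df)
        assert counts.to_dict() == {"g1": 3}

    def test_group_overlap_set_algebra(self):
        assert group_overlap({"a", "b"}, {"b", "c"}) == (1, 1, 1)
        assert group_overlap({"a", "b"}, {"a", "b"}) == (0, 2, 0)
        assert group_overlap(set(), {"x"}) == (0, 0, 1)

    def test_psi_group_overlap_matches_truth(self, sim, reports):
        _, state = sim
        _, summary = reports
        assert summary["editing"]["psi_overlap"] == tuple(
            state.truth["psi"]["overlap"]
        )


class TestTissueZscore:
    def test_matches_direct_formula(self):
        rng = np.random.default_rng(101)
        expr = pd.DataFrame(
            rng.lognormal(3, 1, (20, 5)),
            index=[f"g{k}" for k in range(20)],
            columns=list("ABCDE"),
        )
        genes = [f"g{k}" for k in range(0, 10)]
        z = gene_set_tissue_zscore(expr, genes)
        sub = expr.loc[genes]
        manual = ((sub.T - sub.mean(axis=1)) / sub.std(axis=1, ddof=0)).T.mean()
        assert np.allclose(z.to_numpy(), manual.to_numpy(), atol=1e-12)
        # each standardized row has mean ~0 and sd ~1
        zz = ((sub.T - sub.mean(axis=1)) / sub.std(axis=1, ddof=0)).T
        assert np.allclose(zz.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(zz.std(axis=1, ddof=0), 1, atol=1e-9)

    def test_constant_row_excluded_with_warning(self):
        expr = pd.DataFrame(
            {"A": [1.0, 5.0], "B": [1.0, 7.0], "C": [1.0, 9.0]},
            index=["flat", "ok"],
        )
        with pytest.warns(UserWarning, match="constant"):
            z = gene_set_tissue_zscore(expr, ["flat", "ok"])
        assert len(z) == 3

    def test_single_tissue_expression_peaks_there(self):
        expr = pd.DataFrame(
            {"A": [10.0], "B": [0.0], "C": [0.0]}, index=["g1"]
        )
        z = gene_set_tissue_zscore(expr, ["g1"])
        assert z.idxmax() == "A"

    def test_planted_germline_boost_recovered(self, sim, reports):
        _, state = sim
        _, summary = reports
        z = summary["editing"]["tissue_z"]
        assert z.idxmax() == state.truth["tissue"]["boosted_tissue"]


def test_sailor_bed_ingest(tmp_path):
    p = tmp_path / "x.bed"
    p.write_text("c0\t99\t100\t80,0.06\t0.995\t+\nc0\t200\t201\t55,0.3\t0.99\t-\n")
    df = read_sailor_bed(p, "rep1", "young")
    assert df["pos"].tolist() == [99, 200]
    assert df["edited_fraction"].tolist() == [0.06, 0.3]
    assert df["coverage"].tolist() == [80, 55]
    assert (df["modality"] == "AtoI").all()
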