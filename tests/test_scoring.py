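"""Scoring engine: file parsing, allele matching, PLINK-style score computation."""

import numpy as np
import pandas as pd
import pytest

from polymix import (
    DosageMatrix,
    ScoringModel,
    SimConfig,
    compute_scores,
    emit_genotype_layer,
    match_alleles,
    read_raw,
    read_scoring_file,
    read_vcf,
    simulate_cohort,
    write_raw,
    write_scoring_file,
)


def make_model(rows):
    return ScoringModel(pd.DataFrame(
        rows, columns=["variant_id", "effect_allele", "other_allele", "weight"]))


def make_matrix(dosages, variant_ids=None, counted=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return DosageMatrix(
        person_ids=[f"P{i}" for i in range(n)],
        variant_ids=variant_ids or [f"v{j}" for j in range(m)],
        counted_alleles=counted or ["A"] * m,
        dosages=dosages,
    )


class TestScoringFileIO:
    def _write(self, tmp_path, body, headers=("#pgs_id=TEST",)):
        p = tmp_path / "w.txt"
        p.write_text("\n".join(headers) + "\n" + body)
        return p

    def test_valid_three_rows(self, tmp_path):
        body = ("rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight\n"
                "rs1\t1\t100\tA\tG\t0.5\nrs2\t1\t200\tC\tT\t-0.2\nrs3\t2\t300\tG\tA\t0.1\n")
        model = read_scoring_file(self._write(tmp_path, body))
        assert len(model) == 3
        assert model.headers == ["#pgs_id=TEST"]
        assert model.records["weight"].tolist() == [0.5, -0.2, 0.1]

    def test_duplicate_id_names_offender(self, tmp_path):
        body = ("rsID\teffect_allele\teffect_weight\n"
                "rs1\tA\t0.5\nrs1\tC\t0.1\n")
        with pytest.raises(ValueError, match="rs1"):
            read_scoring_file(self._write(tmp_path, body))

    def test_headers_only_is_no_records(self, tmp_path):
        p = tmp_path / "w.txt"
        p.write_text("#pgs_id=TEST\n#build=38\n")
        with pytest.raises(ValueError, match="no records"):
            read_scoring_file(p)

    def test_missing_mandatory_column(self, tmp_path):
        body = "rsID\teffect_allele\n" "rs1\tA\n"
        with pytest.raises(ValueError, match="effect_weight"):
            read_scoring_file(self._write(tmp_path, body))

    def test_non_finite_weights_rejected_with_count(self, tmp_path):
        body = ("rsID\teffect_allele\teffect_weight\n"
                "rs1\tA\t0.5\nrs2\tC\tnan\nrs3\tG\tinf\n")
        with pytest.warns(UserWarning, match="rejected 2"):
            model = read_scoring_file(self._write(tmp_path, body))
        assert len(model) == 1 and model.n_rejected == 2

    def test_roundtrip(self, tmp_path):
        model = make_model([("rs1", "A", "G", 0.5), ("rs2", "C", "T", -0.25)])
        p = tmp_path / "out.txt"
        write_scoring_file(model, p)
        back = read_scoring_file(p)
        assert np.allclose(back.records["weight"], model.records["weight"])
        assert list(back.records["variant_id"]) == ["rs1", "rs2"]


class TestAlleleMatching:
    def test_direct(self):
        model = make_model([("v0", "A", "G", 0.5)])
        aln = match_alleles(model, make_matrix([[1.0]], counted=["A"]))
        assert aln.table["orientation"].tolist() == ["direct"]

    def test_flipped(self):
        model = make_model([("v0", "A", "G", 0.5)])
        aln = match_alleles(model, make_matrix([[1.0]], counted=["G"]))
        assert aln.table["orientation"].tolist() == ["flipped"]

    def test_strand_complement_resolved(self):
        # counted C, effect G (=comp C), other A: direct after complementing
        model = make_model([("v0", "G", "A", 0.5)])
        aln = match_alleles(model, make_matrix([[1.0]], counted=["C"]))
        row = aln.table.iloc[0]
        assert row["orientation"] == "direct" and row["strand_complemented"]

    def test_ambiguous_pair_dropped_or_kept(self):
        model = make_model([("v0", "A", "T", 0.5)])
        matrix = make_matrix([[1.0]], counted=["A"])
        dropped = match_alleles(model, matrix, drop_ambiguous=True)
        assert len(dropped.table) == 0
        assert dropped.counts["ambiguous_dropped"] == 1
        kept = match_alleles(model, matrix, drop_ambiguous=False)
        assert kept.table["orientation"].tolist() == ["direct"]

    def test_strand_flip_fully_resolves_single_bases(self):
        # comp(T)=A=effect -> direct; comp(C)=G=other -> flipped
        model = make_model([("v0", "A", "G", 0.5)])
        direct = match_alleles(model, make_matrix([[1.0]], counted=["T"]))
        flipped = match_alleles(model, make_matrix([[1.0]], counted=["C"]))
        assert direct.counts["direct"] == 1 and direct.counts["strand_complemented"] == 1
        assert flipped.counts["flipped"] == 1

    def test_unmatched_alleles_excluded(self):
        # an indel-style counted allele cannot be complement-resolved
        model = make_model([("v0", "A", "G", 0.5)])
        aln = match_alleles(model, make_matrix([[1.0]], counted=["AT"]))
        assert aln.counts["unmatched_alleles"] == 1 and len(aln.table) == 0

    def test_zero_overlap_errors(self):
        model = make_model([("absent", "A", "G", 0.5)])
        with pytest.raises(ValueError, match="no overlapping"):
            match_alleles(model, make_matrix([[1.0]], variant_ids=["v0"]))


class TestComputeScores:
    def test_sum_mode_arithmetic(self):
        model = make_model([("v0", "A", "G", 0.5), ("v1", "A", "G", -0.2)])
        res = compute_scores(model, make_matrix([[2.0, 0.0]]))
        assert res.scores["score"].tolist() == [1.0]
        assert res.scores["used_variants"].tolist() == [2]

    def test_all_zero_weights(self):
        model = make_model([("v0", "A", "G", 0.0), ("v1", "A", "G", 0.0)])
        res = compute_scores(model, make_matrix([[2.0, 1.0], [0.0, 2.0]]))
        assert np.allclose(res.scores["score"], 0.0)

    def test_average_equals_sum_over_2m(self):
        model = make_model([("v0", "A", "G", 0.4), ("v1", "A", "G", -0.1),
                            ("v2", "A", "G", 0.3)])
        matrix = make_matrix([[2.0, 1.0, 0.0], [1.0, 1.0, 2.0]])
        s = compute_scores(model, matrix, mode="sum").scores["score"]
        a = compute_scores(model, matrix, mode="average").scores["score"]
        assert np.allclose(a, s / (2 * 3))

    def test_mean_imputation_matches_brute_force(self):
        model = make_model([("v0", "A", "G", 0.5), ("v1", "A", "G", -0.2),
                            ("v2", "A", "G", 0.7)])
        d = np.array([[2.0, np.nan, 1.0],
                      [0.0, 1.0, np.nan],
                      [1.0, 2.0, 2.0],
                      [np.nan, 0.0, 0.0]])
        res = compute_scores(model, make_matrix(d))
        # brute-force oracle: impute each column mean over observed entries
        w = np.array([0.5, -0.2, 0.7])
        expected = []
        for i in range(4):
            tot = 0.0
            for j in range(3):
                x = d[i, j]
                if np.isnan(x):
                    x = np.nanmean(d[:, j])
                tot += w[j] * x
            expected.append(tot)
        assert np.allclose(res.scores["score"], expected, atol=1e-12)
        assert res.scores["used_variants"].tolist() == [2, 2, 3, 2]

    def test_flipped_dosage_complemented(self):
        model = make_model([("v0", "A", "G", 1.0)])
        res = compute_scores(model, make_matrix([[2.0], [0.5]], counted=["G"]))
        assert np.allclose(res.scores["score"], [0.0, 1.5])

    def test_all_missing_person_gets_nan(self):
        model = make_model([("v0", "A", "G", 0.5)])
        with pytest.warns(UserWarning, match="all dosages missing"):
            res = compute_scores(model, make_matrix([[np.nan], [1.0]]))
        assert np.isnan(res.scores["score"].iloc[0])
        assert res.scores["score"].iloc[1] == 0.5

    def test_flip_consistency(self):
        """Swapping alleles and negating weights shifts sum scores by exactly 2*sum(w)."""
        rng = np.random.default_rng(0)
        w = rng.normal(size=5)
        d = rng.integers(0, 3, size=(20, 5)).astype(float)
        ids = [f"v{j}" for j in range(5)]
        eff = ["A", "C", "G", "A", "C"]
        oth = ["G", "T", "A", "C", "A"]
        model = make_model(list(zip(ids, eff, oth, w)))
        flipped = make_model(list(zip(ids, oth, eff, -w)))
        matrix = make_matrix(d, variant_ids=ids, counted=eff)
        s1 = compute_scores(model, matrix).scores["score"].to_numpy()
        s2 = compute_scores(flipped, matrix).scores["score"].to_numpy()
        assert np.allclose(s2, s1 - 2 * w.sum(), atol=1e-12)


@pytest.fixture(scope="module")
def layer():
    cfg = SimConfig({"EUR": 400}, {"EUR": 0.1}, ["AF", "HF"],
                    n_pcs=3, n_variants=60, seed=17)
    cohort = simulate_cohort(cfg)
    matrix, models = emit_genotype_layer(cohort, cfg, seed=18)
    return cohort, matrix, models


class TestSyntheticTruthRoundTrip:
    def test_engine_matches_truth_exactly(self, layer):
        cohort, matrix, models = layer
        for t in ("AF", "HF"):
            res = compute_scores(models[t], matrix)
            assert np.array_equal(res.scores["score"].to_numpy(),
                                  cohort.df[f"score_{t}"].to_numpy())

    def test_raw_roundtrip_preserves_scores(self, layer, tmp_path):
        cohort, matrix, models = layer
        write_raw(matrix, tmp_path / "g.raw")
        back = read_raw(tmp_path / "g.raw")
        assert back.person_ids == matrix.person_ids
        assert back.counted_alleles == matrix.counted_alleles
        res = compute_scores(models["AF"], back)
        assert np.allclose(res.scores["score"], cohort.df["score_AF"], atol=1e-9)

    def test_mean_imputation_oracle_under_missingness(self):
        cfg = SimConfig({"EUR": 200}, {"EUR": 0.1}, ["AF"],
                        n_pcs=2, n_variants=40, seed=23)
        cohort = simulate_cohort(cfg)
        matrix, models = emit_genotype_layer(cohort, cfg, seed=29,
                                             missing_fraction=0.1)
        res = compute_scores(models["AF"], matrix)
        w = models["AF"].records["weight"].to_numpy()
        col_means = np.nanmean(matrix.dosages, axis=0)
        imputed = np.where(np.isnan(matrix.dosages), col_means, matrix.dosages)
        assert np.allclose(res.scores["score"], imputed @ w, atol=1e-10)


class TestRawParsing:
    def test_bad_header_rejected(self, tmp_path):
        p = tmp_path / "bad.raw"
        p.write_text("A\tB\n1\t2\n")
        with pytest.raises(ValueError, match="FID|IID"):
            read_raw(p)

    def test_na_becomes_missing(self, tmp_path):
        p = tmp_path / "g.raw"
        p.write_text("FID\tIID\tPAT\tMAT\tSEX\tPHENOTYPE\trs1_A\trs2_G\n"
                     "P0\tP0\t0\t0\t0\t-9\tNA\t2\n")
        m = read_raw(p)
        assert np.isnan(m.dosages[0, 0]) and m.dosages[0, 1] == 2.0
        assert m.variant_ids == ["rs1", "rs2"]
        assert m.counted_alleles == ["A", "G"]


class TestVcfReading:
    VCF = """##fileformat=VCFv4.2
##contig=<ID=1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
1\t100\trs1\tA\tG\t.\t.\t.\tGT:DS\t0/1:0.9\t1/1:2.0
1\t200\trs2\tC\tT\t.\t.\t.\tGT\t0/0\t./.
"""

    def test_ds_preferred_gt_fallback(self, tmp_path):
        p = tmp_path / "t.vcf"
        p.write_text(self.VCF)
        m = read_vcf(p)
        assert m.person_ids == ["S1", "S2"]
        assert m.variant_ids == ["rs1", "rs2"]
        assert m.counted_alleles == ["G", "T"]
        assert np.allclose(m.dosages[:, 0], [0.9, 2.0])
        assert m.dosages[0, 1] == 0.0 and np.isnan(m.dosages[1, 1])

    def test_scores_from_vcf(self, tmp_path):
        p = tmp_path / "t.vcf"
        p.write_text(self.VCF)
        m = read_vcf(p)
        model = make_model([("rs1", "G", "A", 1.0), ("rs2", "T", "C", 2.0)])
        res = compute_scores(model, m)
        # rs2 missing for S2 imputed with column mean (0.0)
        assert np.allclose(res.scores["score"], [0.9, 2.0])
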