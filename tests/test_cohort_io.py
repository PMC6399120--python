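"""Cohort data model and file round-trips."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cgas
from cgas.cohort import MISSING, GenotypeMatrix, PhenotypeTable, ResultsBundle, VariantInfo
from cgas.io import (
    read_genotype_table,
    read_phenotypes,
    read_vcf,
    write_phenotypes,
    write_results,
    write_vcf,
)


def _toy_matrix():
    variants = [
        VariantInfo("rs1", gene="G1", chromosome="1", allele_ref="A", allele_alt="G"),
        VariantInfo("rs2", gene="G2", chromosome="2", allele_ref="C", allele_alt="T"),
    ]
    calls = np.array([[0, 2], [1, MISSING], [2, 1]], dtype=np.int8)
    return GenotypeMatrix(["S1", "S2", "S3"], variants, calls)


class TestGenotypeMatrix:
    def test_validation(self):
        with pytest.raises(ValueError, match="duplicated rsID"):
            GenotypeMatrix(
                ["a"],
                [VariantInfo("rs1"), VariantInfo("rs1")],
                np.zeros((1, 2), dtype=np.int8),
            )
        with pytest.raises(ValueError, match="shape"):
            GenotypeMatrix(["a"], [VariantInfo("rs1")], np.zeros((2, 1), dtype=np.int8))
        with pytest.raises(ValueError, match="calls"):
            GenotypeMatrix(["a"], [VariantInfo("rs1")], np.array([[5]], dtype=np.int8))

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            VariantInfo("rs1", allele_ref="A", allele_alt="A")

    @given(st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_effect_allele_flip_complements_dosage(self, calls):
        gm = GenotypeMatrix(
            [f"s{i}" for i in range(len(calls))],
            [VariantInfo("rs1")],
            np.array(calls, dtype=np.int8).reshape(-1, 1),
        )
        flipped = gm.flip_effect_allele("rs1")
        orig, new = gm.dosages("rs1"), flipped.dosages("rs1")
        obs = orig != MISSING
        assert (new[obs] == 2 - orig[obs]).all()
        assert (new[~obs] == MISSING).all()
        # double flip is the identity
        assert (flipped.flip_effect_allele("rs1").calls == gm.calls).all()


class TestVcf:
    def test_round_trip_identity(self, tmp_path):
        gm = _toy_matrix()
        path = tmp_path / "toy.vcf"
        write_vcf(gm, path)
        back = read_vcf(path, effect_allele_rule="alt")
        assert back.subject_ids == gm.subject_ids
        assert back.snp_ids == gm.snp_ids
        assert (back.calls == gm.calls).all()
        assert [v.gene for v in back.variants] == ["G1", "G2"]

    def test_simulator_round_trip(self, small_cohort, tmp_path):
        gm, _, _ = small_cohort
        path = tmp_path / "sim.vcf"
        write_vcf(gm, path)
        back = read_vcf(path, effect_allele_rule="alt")
        assert (back.calls == gm.calls).all()

    def test_het_dosage_coding(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            "1\t1\trs1\tA\tG\t.\t.\t.\tGT\t0/1\t1/1\t./.\n"
        )
        gm = read_vcf(path, effect_allele_rule="alt")
        assert list(gm.dosages("rs1")) == [1, 2, MISSING]
        # complementary coding: effect allele = ref
        gm_ref = read_vcf(path, effect_allele_rule="ref")
        assert list(gm_ref.dosages("rs1")) == [1, 0, MISSING]

    def test_multiallelic_rejected(self, tmp_path):
        path = tmp_path / "m.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t1\trs9\tA\tG,T\t.\t.\t.\tGT\t0/1\n"
        )
        with pytest.raises(ValueError, match="rs9"):
            read_vcf(path)

    def test_minor_allele_rule(self, tmp_path):
        # alt allele is the major allele -> coding flips to count ref
        path = tmp_path / "f.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            "1\t1\trs1\tA\tG\t.\t.\t.\tGT\t1/1\t1/1\t0/1\n"
        )
        gm = read_vcf(path, effect_allele_rule="minor")
        assert gm.variant("rs1").effect_allele == "ref"
        assert list(gm.dosages("rs1")) == [0, 0, 1]


class TestGenotypeTable:
    def test_allele_pair_dialect(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("subject_id,rs1,rs2\nS1,AA,TA\nS2,AT,AT\nS3,TT,NN\n")
        gm = read_genotype_table(p, dialect="allele-pair", effect_allele_rule="alt")
        # alt = T (lexicographically later observed allele)
        assert list(gm.dosages("rs1")) == [0, 1, 2]
        # unordered pairs: "TA" == "AT"
        assert gm.dosages("rs2")[0] == gm.dosages("rs2")[1]
        assert gm.dosages("rs2")[2] == MISSING

    def test_dosage_dialect(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("subject_id,rs1\nS1,2\nS2,0\nS3,\n")
        gm = read_genotype_table(p, dialect="dosage", effect_allele_rule="alt")
        assert list(gm.dosages("rs1")) == [2, 0, MISSING]

    def test_vcf_and_table_agree(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            "1\t1\trs1\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
        )
        tab = tmp_path / "x.csv"
        tab.write_text("subject_id,rs1\nS1,AA\nS2,AT\nS3,TT\n")
        gm_v = read_vcf(vcf)
        gm_t = read_genotype_table(tab)
        assert gm_v.subject_ids == gm_t.subject_ids
        assert (gm_v.calls == gm_t.calls).all()

    @pytest.mark.parametrize(
        "content,dialect,msg",
        [
            ("subject_id,rs1\nS1,AX\n", "allele-pair", "invalid genotype"),
            ("subject_id,rs1\nS1,AC\nS2,AG\nS3,CG\n", "allele-pair", "alleles observed"),
            ("subject_id,rs1\nS1,3\n", "dosage", "invalid dosage"),
        ],
    )
    def test_bad_tables_rejected(self, tmp_path, content, dialect, msg):
        p = tmp_path / "bad.csv"
        p.write_text(content)
        with pytest.raises(ValueError, match=msg):
            read_genotype_table(p, dialect=dialect)


class TestPhenotypes:
    def test_normalised_row(self, tmp_path):
        p = tmp_path / "p.csv"
        p.write_text(
            "subject_id,outcome,sex,age,caucasian,diabetes,hypertension,smoking\n"
            "S1,1,male,60,1,0,1,former\n"
        )
        ph = read_phenotypes(p)
        row = ph.data.loc["S1"]
        assert row["outcome"] == 1 and row["sex"] == "male" and row["age"] == 60
        assert row["caucasian"] == 1 and row["diabetes"] == 0
        assert row["hypertension"] == 1 and row["smoking"] == "former"

    def test_missing_outcome_column(self, tmp_path):
        p = tmp_path / "p.csv"
        p.write_text("subject_id,sex,age\nS1,male,60\n")
        with pytest.raises(ValueError, match="outcome"):
            read_phenotypes(p)

    def test_negative_age(self, tmp_path):
        p = tmp_path / "p.csv"
        p.write_text(
            "subject_id,outcome,sex,age,caucasian,diabetes,hypertension,smoking\n"
            "S1,1,male,-5,1,0,1,former\n"
        )
        with pytest.raises(ValueError, match="age"):
            read_phenotypes(p)

    def test_unknown_level_names_row(self, tmp_path):
        p = tmp_path / "p.csv"
        p.write_text(
            "subject_id,outcome,sex,age,caucasian,diabetes,hypertension,smoking\n"
            "S7,maybe,male,60,1,0,1,former\n"
        )
        with pytest.raises(ValueError, match="S7"):
            read_phenotypes(p)

    def test_round_trip(self, small_cohort, tmp_path):
        _, pheno, _ = small_cohort
        path = tmp_path / "pheno.tsv"
        write_phenotypes(pheno, path)
        back = read_phenotypes(path)
        pd.testing.assert_frame_equal(
            back.data, pheno.data, check_dtype=False, check_exact=False
        )


class TestResults:
    def _bundle(self):
        assoc = pd.DataFrame(
            {
                "snp_id": ["rs1", "rs2"],
                "gene": ["G1", "G2"],
                "model": ["dominant", "recessive"],
                "adjusted_p": [0.005, 0.2],
                "or_point": [1.31, 1.1],
                "or_low": [1.08, 0.9],
                "or_high": [1.58, 1.3],
                "aic": [2777.0, 2800.0],
                "permutation_p": [0.005, np.nan],
                "n_used": [2804, 2800],
                "status": ["ok", "ok"],
            }
        )
        empty_ld = pd.DataFrame(columns=["snp1", "snp2", "r2", "p"])
        return ResultsBundle(
            association_table=assoc, ld_table=empty_ld, provenance={"seed": 1}
        )

    def test_write_layout_and_empty_table(self, tmp_path):
        files = write_results(self._bundle(), tmp_path)
        assoc = pd.read_csv(tmp_path / "association.tsv", sep="\t")
        assert len(assoc) == 2
        for col in ("snp_id", "gene", "model", "adjusted_p", "aic", "permutation_p"):
            assert col in assoc.columns
        assert assoc["or_ci"][0].startswith("1.31 (")
        ld = (tmp_path / "ld.tsv").read_text().strip().splitlines()
        assert len(ld) == 1  # header only
        assert (tmp_path / "summary.json") in files

    def test_numeric_round_trip(self, tmp_path):
        bundle = self._bundle()
        write_results(bundle, tmp_path)
        back = pd.read_csv(tmp_path / "association.tsv", sep="\t")
        np.testing.assert_allclose(
            back["adjusted_p"], bundle.association_table["adjusted_p"], rtol=1e-9
        )
        np.testing.assert_allclose(
            back["or_point"], bundle.association_table["or_point"], rtol=1e-9
        )

    def test_rerun_byte_identical(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        write_results(self._bundle(), a)
        write_results(self._bundle(), b)
        for name in ("association.tsv", "ld.tsv", "summary.json"):
            assert (a / name).read_bytes() == (b / name).read_bytes()


def test_align_cohort_drops_unmatched():
    gm = _toy_matrix()
    df = pd.DataFrame(
        {
            "outcome": [1, 0],
            "sex": ["male", "female"],
            "age": [60.0, 50.0],
            "caucasian": [1, 1],
            "diabetes": [0, 0],
            "hypertension": [1, 0],
            "smoking": ["never", "former"],
        },
        index=pd.Index(["S1", "S3"], name="subject_id"),
    )
    gm2, ph2 = cgas.align_cohort(gm, PhenotypeTable(df))
    assert gm2.subject_ids == ["S1", "S3"] == ph2.subject_ids
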