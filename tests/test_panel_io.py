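import json
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiogrs.panel_io import (
    GenotypeMatrix,
    PanelConfigError,
    SNPDef,
    SNPPanel,
    assemble_cohort,
    default_panel,
    load_panel,
    read_phenotypes,
    risk_allele_dosage,
)

ALLELES = "ACGT"


class TestPanel:
    def test_default_panel_is_the_18_snp_set(self):
        panel = default_panel()
        assert panel.K == 18
        assert panel.max_raw_score == 36
        assert "rs9939609" in panel.rsids
        assert len(set(panel.rsids)) == 18

    def test_single_snp_panel(self):
        panel = SNPPanel((SNPDef("rs1", "A"),))
        assert panel.K == 1
        assert panel.max_raw_score == 2

    def test_duplicate_rsid_rejected(self):
        with pytest.raises(PanelConfigError, match="duplicate"):
            SNPPanel((SNPDef("rs9939609", "A"), SNPDef("rs9939609", "T")))

    def test_invalid_risk_allele_rejected(self):
        with pytest.raises(PanelConfigError, match="risk allele"):
            SNPDef("rs1", "X")

    def test_load_panel_tsv_and_json_preserve_order(self, tmp_path):
        tsv = tmp_path / "p.tsv"
        tsv.write_text("rsid\tgene\trisk_allele\nrs2\tG2\tC\nrs1\tG1\tA\n")
        p1 = load_panel(tsv)
        assert p1.rsids == ["rs2", "rs1"]
        js = tmp_path / "p.json"
        js.write_text(json.dumps([
            {"rsid": "rs2", "gene": "G2", "risk_allele": "C"},
            {"rsid": "rs1", "gene": "G1", "risk_allele": "A"},
        ]))
        p2 = load_panel(js)
        assert p2.rsids == p1.rsids
        assert [s.risk_allele for s in p2.snps] == ["C", "A"]


class TestDosage:
    @pytest.mark.parametrize(
        "genotype,risk,expected",
        [("AA", "A", 2), ("AT", "A", 1), ("TT", "A", 0), ("GC", "C", 1),
         ("A/T", "A", 1), ("C|C", "C", 2)],
    )
    def test_risk_allele_counting(self, genotype, risk, expected):
        assert risk_allele_dosage(genotype, risk) == expected

    @pytest.mark.parametrize("genotype", [None, "", "./.", "NN"])
    def test_uncalled_genotypes_are_missing(self, genotype):
        assert np.isnan(risk_allele_dosage(genotype, "A"))

    @given(
        g=st.tuples(st.sampled_from(ALLELES), st.sampled_from(ALLELES)),
        risk=st.sampled_from(ALLELES),
    )
    def test_dosages_over_all_alleles_sum_to_ploidy(self, g, risk):
        genotype = "".join(g)
        total = sum(risk_allele_dosage(genotype, r) for r in ALLELES)
        assert total == 2


class TestGenotypeMatrix:
    def test_tsv_round_trip_preserves_dosages_and_missing(self, tmp_path, panel3):
        df = pd.DataFrame(
            [[0.0, 1.0, 2.0], [2.0, np.nan, 0.0]],
            index=pd.Index(["s1", "s2"], name="sample_id"),
            columns=panel3.rsids,
        )
        gm = GenotypeMatrix(df)
        path = tmp_path / "g.tsv"
        gm.to_tsv(path)
        assert "NA" in path.read_text()
        back = GenotypeMatrix.from_tsv(path, panel3)
        pd.testing.assert_frame_equal(back.dosages, gm.dosages)

    def test_invalid_dosage_value_rejected(self, panel3):
        df = pd.DataFrame([[3.0, 0.0, 0.0]], index=["s1"], columns=panel3.rsids)
        with pytest.raises(ValueError, match="0/1/2"):
            GenotypeMatrix(df)

    def test_absent_panel_snp_becomes_missing_column_with_warning(
        self, tmp_path, panel3
    ):
        path = tmp_path / "g.tsv"
        path.write_text("sample_id\trs9939609\trs7903146\ns1\t1\t2\n")
        with pytest.warns(UserWarning, match="rs17782313"):
            gm = GenotypeMatrix.from_tsv(path, panel3)
        assert gm.dosages["rs17782313"].isna().all()


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
"""


class TestVCF:
    def _write(self, tmp_path, body):
        path = tmp_path / "test.vcf"
        path.write_text(VCF_HEADER + body)
        return path

    def test_dosage_counts_risk_allele_and_missing_calls(self, tmp_path, panel3):
        body = (
            "1\t100\trs9939609\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\n"
            "1\t200\trs7903146\tC\tT\t.\t.\t.\tGT\t1/1\t./.\n"
            "1\t300\trs17782313\tT\tC\t.\t.\t.\tGT\t0/1\t1/1\n"
        )
        gm = GenotypeMatrix.from_vcf(self._write(tmp_path, body), panel3)
        # rs9939609 risk A = REF: 0/0 -> 2, 0/1 -> 1
        assert gm.dosages.loc["s1", "rs9939609"] == 2
        assert gm.dosages.loc["s2", "rs9939609"] == 1
        # rs7903146 risk T = ALT: 1/1 -> 2, ./. -> missing
        assert gm.dosages.loc["s1", "rs7903146"] == 2
        assert np.isnan(gm.dosages.loc["s2", "rs7903146"])
        assert gm.dosages.loc["s2", "rs17782313"] == 2

    def test_risk_allele_absent_from_record_raises_naming_rsid(self, tmp_path, panel3):
        body = "1\t100\trs9939609\tG\tC\t.\t.\t.\tGT\t0/0\t0/1\n"
        with pytest.raises(ValueError, match="rs9939609"):
            GenotypeMatrix.from_vcf(self._write(tmp_path, body), panel3)

    def test_multiallelic_record_rejected(self, tmp_path, panel3):
        body = "1\t100\trs9939609\tA\tT,C\t.\t.\t.\tGT\t0/1\t0/2\n"
        with pytest.raises(ValueError, match="multi-allelic"):
            GenotypeMatrix.from_vcf(self._write(tmp_path, body), panel3)


def _pheno_csv(tmp_path, rows):
    path = tmp_path / "pheno.csv"
    header = "sample_id,age,sex,weight_kg,height_m,smoking,history,medications\n"
    path.write_text(header + "".join(rows))
    return path


class TestPhenotypeIO:
    def test_read_phenotypes_parses_label_sets(self, tmp_path):
        path = _pheno_csv(
            tmp_path,
            ["s1,41,F,75.0,1.65,yes,hypertension;t2dm,metformin\n",
             "s2,30,M,80.0,1.80,no,,\n"],
        )
        df = read_phenotypes(path)
        assert df.loc["s1", "history"] == frozenset({"hypertension", "t2dm"})
        assert df.loc["s2", "medications"] == frozenset()
        assert bool(df.loc["s1", "smoking"]) and not bool(df.loc["s2", "smoking"])
        assert df.loc["s1", "weight"] == 75.0

    def test_non_positive_anthropometrics_rejected(self, tmp_path):
        path = _pheno_csv(tmp_path, ["s1,41,F,0,1.65,no,,\n"])
        with pytest.raises(ValueError, match="weight"):
            read_phenotypes(path)


def _gm(ids, panel):
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        rng.integers(0, 3, (len(ids), panel.K)).astype(float),
        index=pd.Index(ids, name="sample_id"),
        columns=panel.rsids,
    )
    return GenotypeMatrix(df)


def _pheno(ids):
    return pd.DataFrame(
        {
            "age": 40.0, "sex": "F", "weight": 70.0, "height": 1.7,
            "smoking": False,
            "history": [frozenset()] * len(ids),
            "medications": [frozenset()] * len(ids),
        },
        index=pd.Index(ids, name="sample_id"),
    )


class TestAssembly:
    def test_partial_overlap_bookkeeping(self, panel3):
        asm = assemble_cohort(
            _gm(["a", "b", "c", "d", "e"], panel3), _pheno(["c", "d", "e"])
        )
        assert asm.included_ids == ["c", "d", "e"]
        assert asm.exclusion_counts()["missing_questionnaire"] == 2

    def test_disjoint_ids_error(self, panel3):
        with pytest.raises(ValueError, match="both genotype and questionnaire"):
            assemble_cohort(_gm(["a", "b"], panel3), _pheno(["c", "d"]))

    def test_bmi_outlier_exclusion_keeps_conservation(self, panel3):
        ids = [f"s{i}" for i in range(10)]
        asm = assemble_cohort(_gm(ids, panel3), _pheno(ids))
        asm2 = asm.exclude(["s3"], "bmi_outlier")
        counts = asm2.exclusion_counts()
        assert len(asm2.included_ids) == 9
        assert counts == {
            "missing_questionnaire": 0, "missing_genotype": 0, "bmi_outlier": 1,
        }
        assert len(asm2.included_ids) + sum(counts.values()) == asm2.n_input == 10

    def test_conservation_through_both_exclusion_stages(self, panel3):
        asm = assemble_cohort(
            _gm(["a", "b", "c", "d"], panel3), _pheno(["b", "c", "d", "x"])
        )
        asm = asm.exclude(["b"], "bmi_outlier")
        assert len(asm.included_ids) + len(asm.excluded) == asm.n_input == 5
        assert (asm.excluded["reason"].value_counts()["missing_genotype"]) == 1
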