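"""VCF parsing, table readers, and the results-table writer."""

import numpy as np
import pandas as pd
import pytest

import fasdvar as fv
from conftest import TINY_SHEET, make_genotypes


class TestReadVcf:
    def test_dosages_match_hand_count(self, tiny_files):
        geno, sheet = fv.read_vcf(tiny_files["cohort"], tiny_files["samples"])
        # site chr1:100 A>G: GTs 0/1, 1/1, ./. -> 1, 2, missing
        d = geno.dosage["chr1:100:A:G"]
        assert d["NA1"] == 1 and d["NA2"] == 2 and np.isnan(d["NA3"])
        assert list(sheet["sample_id"]) == ["NA1", "NA2", "NA3"]

    def test_multiallelic_split(self, tiny_files):
        geno, _ = fv.read_vcf(tiny_files["cohort"], tiny_files["samples"])
        # A>C,T with GT 1/2 -> one copy of each alternate after splitting
        assert geno.dosage.loc["NA1", "chr1:200:A:C"] == 1
        assert geno.dosage.loc["NA1", "chr1:200:A:T"] == 1
        # splitting conserves total alt-allele count per sample per site
        assert geno.dosage.loc["NA3", "chr1:200:A:C"] + geno.dosage.loc["NA3", "chr1:200:A:T"] == 1

    def test_empty_vcf(self, tmp_path, tiny_files):
        vcf = tmp_path / "empty.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNA1\tNA2\tNA3\n"
        )
        geno, _ = fv.read_vcf(vcf, tiny_files["samples"])
        assert geno.n_variants == 0
        assert geno.n_samples == 3

    def test_sample_mismatch_names_samples(self, tmp_path, tiny_files):
        sheet = tmp_path / "bad_sheet.tsv"
        sheet.write_text(TINY_SHEET.replace("NA3", "NAX"))
        with pytest.raises(ValueError, match="NAX") as exc:
            fv.read_vcf(tiny_files["cohort"], sheet)
        assert "NA3" in str(exc.value)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_write_read_round_trip(self, tmp_path, seed, tiny_files):
        rng = np.random.default_rng(seed)
        arr = rng.choice([0.0, 1.0, 2.0, np.nan], size=(3, 8), p=[0.4, 0.3, 0.2, 0.1])
        geno = make_genotypes(arr, samples=["NA1", "NA2", "NA3"])
        path = tmp_path / "rt.vcf"
        fv.write_vcf(geno, path)
        back, _ = fv.read_vcf(path, tiny_files["samples"])
        pd.testing.assert_frame_equal(back.dosage, geno.dosage)


class TestVariantKey:
    def test_invariants(self):
        with pytest.raises(ValueError):
            fv.VariantKey("chr1", 0, "A", "G")
        with pytest.raises(ValueError):
            fv.VariantKey("chr1", 5, "A", "A")
        with pytest.raises(ValueError):
            fv.VariantKey("chr1", 5, "A", "G", rsid="snp1")
        assert fv.VariantKey("chr1", 5, "A", "G", "rs42").key == "chr1:5:A:G"


class TestReadPanel:
    def test_multi_pathway_gene_with_ndd_tag(self, tiny_files):
        panel = fv.read_panel(tiny_files["panel"])
        assert panel.pathways_by_gene["SOX9"] == frozenset({"RA", "SHH"})
        row = panel.table[panel.table["gene"] == "SOX9"].iloc[0]
        assert row["ndd_syndrome"] == "Campomelic Dysplasia"
        assert panel.pathways_by_gene["ORPHAN"] == frozenset()

    def test_empty_panel(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("gene\tpanel_id\tpathways\tndd_syndrome\n")
        assert len(fv.read_panel(p).genes) == 0

    def test_unknown_pathway_rejected(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("gene\tpanel_id\tpathways\tndd_syndrome\nGLI1\t2\tHEDGEHOG\t\n")
        with pytest.raises(ValueError, match="HEDGEHOG"):
            fv.read_panel(p)

    def test_duplicate_gene_panel_rejected(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("gene\tpanel_id\tpathways\tndd_syndrome\nGLI1\t2\tSHH\t\nGLI1\t2\tSHH\t\n")
        with pytest.raises(ValueError, match="GLI1"):
            fv.read_panel(p)

    def test_same_gene_two_panels_allowed(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("gene\tpanel_id\tpathways\tndd_syndrome\nGLI1\t2\tSHH\t\nGLI1\t3\tWNT\t\n")
        panel = fv.read_panel(p)
        assert panel.pathways_by_gene["GLI1"] == frozenset({"SHH", "WNT"})


class TestReadReference:
    def test_values_stored_exactly(self, tiny_files):
        ref = fv.read_reference_frequencies(tiny_files["reference"])
        assert ref.table.loc["chr1:100:A:G", "ref_freq"] == 0.82
        assert ref.table.loc["chr1:100:A:G", "ref_an"] == 5008

    def test_out_of_bounds_frequency_rejected(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text(
            "rsid\tchrom\tpos\tref\talt\ttested_allele\tref_freq\tref_an\n"
            "rs1\tchr1\t100\tA\tG\tG\t1.2\t5008\n"
        )
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            fv.read_reference_frequencies(p)

    def test_duplicate_key_rejected(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text(
            "rsid\tchrom\tpos\tref\talt\ttested_allele\tref_freq\tref_an\n"
            "rs1\tchr1\t100\tA\tG\tG\t0.5\t5008\n"
            "rs1\tchr1\t100\tA\tG\tG\t0.4\t5008\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            fv.read_reference_frequencies(p)

    def test_small_ref_an_rejected(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text(
            "rsid\tchrom\tpos\tref\talt\ttested_allele\tref_freq\tref_an\n"
            "rs1\tchr1\t100\tA\tG\tG\t0.5\t1\n"
        )
        with pytest.raises(ValueError, match="ref_an"):
            fv.read_reference_frequencies(p)


class TestResultsTable:
    @staticmethod
    def _frame():
        return pd.DataFrame(
            {
                "rsid": ["rs2066836", "rs1229984"],
                "gene": ["PTCH1", "ADH1B"],
                "consequence": ["silent", "missense"],
                "tested_allele": ["A", "C"],
                "cohort_freq": [0.326086956, 0.130434782],
                "ref_freq": [0.09, 0.05],
                "p_value": [4.80e-08, 1.70e-02],
                "call": ["risk", "resilience"],
            }
        )

    def test_formatting(self, tmp_path):
        path = tmp_path / "results.tsv"
        fv.write_results_table(self._frame(), path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == fv.variants.RESULTS_COLUMNS
        # sorted by gene: ADH1B before PTCH1
        first, second = lines[1].split("\t"), lines[2].split("\t")
        assert first[0] == "rs1229984"
        assert second[6] == "4.80e-08"  # 3 significant digits, scientific
        assert second[4] == "0.33" and first[4] == "0.13"  # 2 dp rounding

    def test_empty_results(self, tmp_path):
        path = tmp_path / "empty.tsv"
        fv.write_results_table(pd.DataFrame(), path)
        assert path.read_text().splitlines() == ["\t".join(fv.variants.RESULTS_COLUMNS)]

    def test_round_trip_to_printed_precision(self, tmp_path):
        path = tmp_path / "rt.tsv"
        frame = self._frame()
        fv.write_results_table(frame, path)
        back = fv.read_results_table(path).sort_values("rsid").reset_index(drop=True)
        orig = frame.sort_values("rsid").reset_index(drop=True)
        assert np.allclose(back["cohort_freq"], np.round(orig["cohort_freq"], 2))
        assert np.allclose(back["p_value"], orig["p_value"], rtol=5e-3)
        assert list(back["call"]) == list(orig["call"])


class TestAnnotations:
    def test_read_and_vocabulary(self, tiny_files):
        ann = fv.read_annotations(tiny_files["annotations"])
        assert ann.loc["chr1:100:A:G", "cadd_phred"] == 12.75
        assert np.isnan(ann.loc["chr1:200:A:T", "cadd_phred"])
        assert ann.loc["chr1:100:A:G", "allele_role"] == "protective_allele"

    def test_bad_sift_rejected(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(
            "rsid\tchrom\tpos\tref\talt\tgene\tconsequence\tsift\tpolyphen\tcadd_phred\tliterature_flag\n"
            "rs1\tchr1\t100\tA\tG\tADH1B\tmissense\tDAMAGING\tbenign\tNA\tnone\n"
        )
        with pytest.raises(ValueError, match="sift"):
            fv.read_annotations(p)
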