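"""Shared fixtures: a tiny hand-checkable cohort written as real input files."""

import textwrap

import numpy as np
import pandas as pd
import pytest

from fasdvar import CohortGenotypes

TINY_VCF = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##contig=<ID=chr1>
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNA1\tNA2\tNA3
    chr1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/1\t1/1\t./.
    chr1\t200\trs2\tA\tC,T\t.\t.\t.\tGT\t1/2\t0/0\t0/1
    chr1\t300\t.\tG\tA\t.\t.\t.\tGT\t0/0\t0/0\t0/0
    """
)

TINY_SHEET = textwrap.dedent(
    """\
    sample_id\tdiagnosis\tsex\tancestry_label
    NA1\tFAS\tM\tEuropean
    NA2\tpFAS\tF\tIndigenous
    NA3\tARND\tM\tEuropean
    """
)

TINY_PANEL = textwrap.dedent(
    """\
    gene\tpanel_id\tpathways\tndd_syndrome
    SOX9\t3\tRA;SHH\tCampomelic Dysplasia
    ADH1B\t1\tRA\t
    GLI2\t2\tSHH\t
    ORPHAN\t4\t\t
    """
)

TINY_REFERENCE = textwrap.dedent(
    """\
    rsid\tchrom\tpos\tref\talt\ttested_allele\tref_freq\tref_an
    rs1\tchr1\t100\tA\tG\tG\t0.82\t5008
    rs2\tchr1\t200\tA\tC\tC\t0.05\t5008
    rs2\tchr1\t200\tA\tT\tT\t0.30\t5008
    """
)

TINY_ANNOTATIONS = textwrap.dedent(
    """\
    rsid\tchrom\tpos\tref\talt\tgene\tconsequence\tsift\tpolyphen\tcadd_phred\tliterature_flag\tallele_role
    rs1\tchr1\t100\tA\tG\tADH1B\tmissense\tdeleterious\tbenign\t12.75\talcohol_protective\tprotective_allele
    rs2\tchr1\t200\tA\tC\tSOX9\tsilent\ttolerated\tbenign\t11.83\tnone\trisk_allele
    rs2\tchr1\t200\tA\tT\tGLI2\tmissense\ttolerated\tprobably_damaging\tNA\tnone\trisk_allele
    """
)


@pytest.fixture
def tiny_files(tmp_path):
    paths = {}
    for name, content in (
        ("cohort.vcf", TINY_VCF),
        ("samples.tsv", TINY_SHEET),
        ("panel.tsv", TINY_PANEL),
        ("reference.tsv", TINY_REFERENCE),
        ("annotations.tsv", TINY_ANNOTATIONS),
    ):
        p = tmp_path / name
        p.write_text(content)
        paths[name.split(".")[0]] = p
    return paths


def make_genotypes(dosage_rows, samples=None, chrom="chr1", ref="A", alt="G"):
    """Build CohortGenotypes from a samples x variants nested list (NaN ok)."""
    arr = np.asarray(dosage_rows, dtype=float)
    n_samples, n_variants = arr.shape
    samples = samples or [f"S{i + 1:02d}" for i in range(n_samples)]
    keys = [f"{chrom}:{100 + 10 * j}:{ref}:{alt}" for j in range(n_variants)]
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": [100 + 10 * j for j in range(n_variants)],
            "ref": ref,
            "alt": alt,
            "rsid": [f"rs{j + 1}" for j in range(n_variants)],
        },
        index=pd.Index(keys, name="key"),
    )
    dosage = pd.DataFrame(arr, index=samples, columns=variants.index)
    return CohortGenotypes(samples, variants, dosage)
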