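"""Domain types and file I/O for cohort variant data.

All inputs are standard text formats: a VCF v4.x with GT genotypes for the
cohort, and UTF-8 TSV tables for the sample sheet, candidate-gene panel,
reference allele frequencies, and per-variant annotations.  Results tables
are written as fixed-layout TSVs mirroring the conventional
risk-allele-frequency report (rsID, gene, mutation type, risk allele, cohort
and reference frequencies, p-value, risk-or-resilience call).

Conventions
-----------
* Coordinates are 1-based VCF coordinates; no liftover.
* Variants are keyed by the string ``chrom:pos:ref:alt``.
* Dosage counts the VCF ALT allele per sample (0/1/2, NaN = missing).
  Orientation onto a tested ("risk") allele happens downstream, driven by the
  reference table's ``tested_allele`` column, never inferred from ref/alt.
* Missing genotypes reduce the per-variant allele number (AN = 2 x
  non-missing samples); nothing is imputed.
* All input files are assumed to share strand/allele encoding; an allele in
  one table that is neither ref nor alt of the keyed variant is a hard error,
  never silently complemented.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PATHWAYS",
    "DIAGNOSES",
    "VariantKey",
    "CohortGenotypes",
    "GenePanel",
    "ReferenceFrequencyTable",
    "read_vcf",
    "write_vcf",
    "read_sample_sheet",
    "read_panel",
    "read_reference_frequencies",
    "read_annotations",
    "write_results_table",
    "read_results_table",
    "RESULTS_COLUMNS",
]

#: The eight developmental signaling pathways used for pathway-level risk
#: scores, in fixed reporting order: retinoic acid, sonic hedgehog, WNT,
#: fibroblast growth factor, TGF-beta, RAS-MAPK, RHO-RAC, and mTOR.
PATHWAYS: tuple[str, ...] = (
    "RA",
    "SHH",
    "WNT",
    "FGF",
    "TGF-β",
    "RAS-MAPK",
    "RHO-RAC",
    "mTOR",
)

#: FASD diagnostic categories: full fetal alcohol syndrome, partial FAS, and
#: alcohol-related neurodevelopmental disorder.
DIAGNOSES: tuple[str, ...] = ("FAS", "pFAS", "ARND")

SIFT_VALUES = frozenset({"deleterious", "tolerated", "NA"})
POLYPHEN_VALUES = frozenset({"benign", "possibly_damaging", "probably_damaging", "NA"})
LITERATURE_FLAGS = frozenset(
    {"alcohol_protective", "alcohol_sensitizing", "syndrome_associated", "none"}
)
CONSEQUENCES = frozenset({"missense", "silent", "intron", "3'UTR", "5'UTR", "upstream"})
ALLELE_ROLES = frozenset({"risk_allele", "protective_allele", "unknown"})

_RSID_RE = re.compile(r"^rs\d+$")


@dataclass(frozen=True)
class VariantKey:
    """A single (chrom, pos, ref, alt) allele pair with optional dbSNP id."""

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")
        if self.rsid != "." and not _RSID_RE.match(self.rsid):
            raise ValueError(f"rsid must be '.' or rs<digits>, got {self.rsid!r}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def _variant_frame(keys: Iterable[VariantKey]) -> pd.DataFrame:
    rows = [(k.key, k.chrom, k.pos, k.ref, k.alt, k.rsid) for k in keys]
    df = pd.DataFrame(rows, columns=["key", "chrom", "pos", "ref", "alt", "rsid"])
    return df.set_index("key")


@dataclass
class CohortGenotypes:
    """Sample x variant ALT-allele dosage matrix with variant metadata.

    ``dosage`` is a float DataFrame (rows = samples in sample-sheet order,
    columns = variant keys) holding 0/1/2 counts of the ALT allele, with NaN
    for missing genotypes.  ``variants`` is indexed by variant key and has
    columns chrom, pos, ref, alt, rsid.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.dosage.index) != list(self.samples):
            raise ValueError("dosage rows must match samples")
        if list(self.dosage.columns) != list(self.variants.index):
            raise ValueError("dosage columns must match variants")
        vals = self.dosage.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"dosage must be 0/1/2/missing; got {vals[i, j]} at "
                f"sample {self.samples[i]}, variant {self.variants.index[j]}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def oriented_dosage(self, tested_allele: Mapping[str, str] | pd.Series) -> pd.DataFrame:
        """Dosage of the tested allele per variant.

        ``tested_allele`` maps variant key -> allele; for variants whose
        tested allele is the VCF REF allele the dosage is recoded 2 - d
        (missing stays missing).  Variants absent from the mapping keep ALT
        orientation.  A tested allele matching neither ref nor alt is an
        error.
        """
        out = self.dosage.copy()
        for key, allele in dict(tested_allele).items():
            if key not in self.variants.index:
                continue
            row = self.variants.loc[key]
            if allele == row["alt"]:
                continue
            if allele == row["ref"]:
                out[key] = 2.0 - out[key]
            else:
                raise ValueError(
                    f"tested allele {allele!r} is neither ref nor alt of {key}"
                )
        return out


@dataclass
class GenePanel:
    """Candidate-gene panel: gene -> panel membership and pathway tags.

    ``table`` has one row per (gene, panel_id) with a frozenset ``pathways``
    column and optional ``ndd_syndrome``.  ``pathways_by_gene`` is the union
    of pathway memberships across panels for each gene.
    """

    table: pd.DataFrame
    pathways_by_gene: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pathways_by_gene:
            merged: dict[str, frozenset[str]] = {}
            for _, row in self.table.iterrows():
                g = row["gene"]
                merged[g] = merged.get(g, frozenset()) | row["pathways"]
            self.pathways_by_gene = merged

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.pathways_by_gene)


@dataclass
class ReferenceFrequencyTable:
    """Reference (control) allele frequencies keyed by variant.

    One row per variant key with columns rsid, chrom, pos, ref, alt,
    tested_allele, ref_freq (in [0, 1]) and ref_an (total reference allele
    number, e.g. 5008 for 1000 Genomes phase 3).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise ValueError(f"duplicate reference key {dup}")
        if ((t["ref_freq"] < 0) | (t["ref_freq"] > 1)).any():
            bad = t.index[(t["ref_freq"] < 0) | (t["ref_freq"] > 1)][0]
            raise ValueError(f"ref_freq outside [0, 1] at {bad}")
        if (t["ref_an"] < 2).any():
            bad = t.index[t["ref_an"] < 2][0]
            raise ValueError(f"ref_an < 2 at {bad}")
        mismatch = (t["tested_allele"] != t["ref"]) & (t["tested_allele"] != t["alt"])
        if mismatch.any():
            bad = t.index[mismatch][0]
            raise ValueError(f"tested_allele is neither ref nor alt at {bad}")

    def __contains__(self, key: str) -> bool:
        return key in self.table.index

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# readers


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the sample sheet TSV (sample_id, diagnosis, sex, ancestry_label)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "diagnosis", "sex", "ancestry_label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r}")
    bad = set(df["diagnosis"]) - set(DIAGNOSES)
    if bad:
        raise ValueError(f"unknown diagnosis categories {sorted(bad)}; expected {DIAGNOSES}")
    return df[required]


def read_vcf(vcf_path: str | Path, sample_sheet_path: str | Path) -> tuple[CohortGenotypes, pd.DataFrame]:
    """Read cohort genotypes from a VCF plus its sample sheet.

    Biallelic records yield one variant; multiallelic records are split into
    one (ref, alt) pair per alternate allele, each carrying that sample's
    count of that specific alternate.  ``./.`` (or any half-call) maps to
    missing.  Sample order follows the sample sheet.
    """
    from cyvcf2 import VCF

    sheet = read_sample_sheet(sample_sheet_path)
    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    sheet_samples = list(sheet["sample_id"])
    extra = sorted(set(vcf_samples) - set(sheet_samples))
    absent = sorted(set(sheet_samples) - set(vcf_samples))
    if extra or absent:
        raise ValueError(
            "sample sheet / VCF mismatch: "
            f"VCF samples missing from sheet: {extra}; "
            f"sheet samples missing from VCF: {absent}"
        )
    order = [vcf_samples.index(s) for s in sheet_samples]

    keys: list[VariantKey] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        try:
            gts = rec.genotypes  # [[a0, a1, phased], ...]
        except Exception as exc:  # malformed GT
            raise ValueError(
                f"malformed genotypes at {rec.CHROM}:{rec.POS}"
            ) from exc
        rsid = rec.ID if rec.ID else "."
        for alt_idx, alt in enumerate(rec.ALT, start=1):
            key = VariantKey(str(rec.CHROM), int(rec.POS), rec.REF, alt, rsid)
            dose = np.full(len(sheet_samples), np.nan)
            for out_i, vcf_i in enumerate(order):
                alleles = gts[vcf_i][:-1]
                if len(alleles) != 2 or any(a is None or a < 0 for a in alleles):
                    continue  # missing / half call
                dose[out_i] = sum(1 for a in alleles if a == alt_idx)
            keys.append(key)
            cols.append(dose)

    variants = _variant_frame(keys) if keys else _variant_frame([])
    dosage = pd.DataFrame(
        np.column_stack(cols) if cols else np.empty((len(sheet_samples), 0)),
        index=sheet_samples,
        columns=variants.index,
    )
    return CohortGenotypes(sheet_samples, variants, dosage), sheet


def write_vcf(genotypes: CohortGenotypes, path: str | Path) -> None:
    """Write genotypes as a minimal VCF v4.2 (GT only, biallelic records)."""
    lines = ["##fileformat=VCFv4.2", '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    for chrom in dict.fromkeys(genotypes.variants["chrom"]):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(genotypes.samples)
    )
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for key, row in genotypes.variants.iterrows():
        dose = genotypes.dosage[key]
        gts = "\t".join(gt_map.get(d, "./.") if not np.isnan(d) else "./." for d in dose)
        lines.append(
            f"{row['chrom']}\t{row['pos']}\t{row['rsid']}\t{row['ref']}\t"
            f"{row['alt']}\t.\t.\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_panel(path: str | Path) -> GenePanel:
    """Read the candidate-gene panel TSV.

    Columns: gene, panel_id (1-4), pathways (semicolon-separated subset of
    the eight pathway names, may be empty), ndd_syndrome (optional free
    text).  The same gene may appear in several panels; duplicate
    (gene, panel_id) rows and unknown pathway tokens are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["gene", "panel_id", "pathways"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"panel missing columns: {missing}")
    if "ndd_syndrome" not in df.columns:
        df["ndd_syndrome"] = ""
    df["panel_id"] = df["panel_id"].astype(int)
    bad_panel = ~df["panel_id"].isin([1, 2, 3, 4])
    if bad_panel.any():
        raise ValueError(f"panel_id must be 1-4, got {df.loc[bad_panel, 'panel_id'].iloc[0]}")
    if df.duplicated(subset=["gene", "panel_id"]).any():
        dup = df.loc[df.duplicated(subset=["gene", "panel_id"]), "gene"].iloc[0]
        raise ValueError(f"duplicate (gene, panel_id) row for {dup}")

    def parse_pathways(cell: str) -> frozenset[str]:
        tokens = [t.strip() for t in cell.split(";") if t.strip()]
        unknown = [t for t in tokens if t not in PATHWAYS]
        if unknown:
            raise ValueError(f"unknown pathway name(s) {unknown}; expected {PATHWAYS}")
        return frozenset(tokens)

    df["pathways"] = df["pathways"].map(parse_pathways)
    df["ndd_syndrome"] = df["ndd_syndrome"].replace("", None)
    return GenePanel(df[["gene", "panel_id", "pathways", "ndd_syndrome"]])


def read_reference_frequencies(path: str | Path) -> ReferenceFrequencyTable:
    """Read the reference allele-frequency TSV.

    Columns: rsid, chrom, pos, ref, alt, tested_allele, ref_freq, ref_an.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["rsid", "chrom", "pos", "ref", "alt", "tested_allele", "ref_freq", "ref_an"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"reference table missing columns: {missing}")
    df["pos"] = df["pos"].astype(int)
    df["ref_freq"] = df["ref_freq"].astype(float)
    df["ref_an"] = df["ref_an"].astype(int)
    df["key"] = (
        df["chrom"] + ":" + df["pos"].astype(str) + ":" + df["ref"] + ":" + df["alt"]
    )
    return ReferenceFrequencyTable(df.set_index("key"))


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the per-variant annotation TSV.

    Columns: rsid, chrom, pos, ref, alt, gene, consequence, sift, polyphen,
    cadd_phred ('NA' or nonnegative real), literature_flag, and optionally
    allele_role (risk_allele / protective_allele / unknown; defaults to
    risk_allele, matching reports that orient every row around a named risk
    allele).  Returns a DataFrame indexed by variant key.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [
        "rsid", "chrom", "pos", "ref", "alt", "gene",
        "consequence", "sift", "polyphen", "cadd_phred", "literature_flag",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    if "allele_role" not in df.columns:
        df["allele_role"] = "risk_allele"
    df.loc[df["allele_role"] == "", "allele_role"] = "risk_allele"
    for col, allowed in (
        ("sift", SIFT_VALUES),
        ("polyphen", POLYPHEN_VALUES),
        ("literature_flag", LITERATURE_FLAGS),
        ("consequence", CONSEQUENCES),
        ("allele_role", ALLELE_ROLES),
    ):
        bad = set(df[col]) - allowed
        if bad:
            raise ValueError(f"unknown {col} value(s) {sorted(bad)}")
    df["pos"] = df["pos"].astype(int)
    df["cadd_phred"] = df["cadd_phred"].replace("NA", "nan").astype(float)
    if (df["cadd_phred"].dropna() < 0).any():
        raise ValueError("cadd_phred must be nonnegative when present")
    df["key"] = (
        df["chrom"] + ":" + df["pos"].astype(str) + ":" + df["ref"] + ":" + df["alt"]
    )
    if df["key"].duplicated().any():
        dup = df.loc[df["key"].duplicated(), "key"].iloc[0]
        raise ValueError(f"duplicate annotation for {dup}")
    return df.set_index("key")


# ---------------------------------------------------------------------------
# results tables

RESULTS_COLUMNS = [
    "rsID",
    "Gene",
    "Type_of_Mutation",
    "Risk_Allele",
    "FASD_Risk_Allele_Frequency",
    "Ref_Risk_Allele_Frequency",
    "p_Value",
    "Risk_or_Resilience",
]

_CALL_LABEL = {"risk": "Risk", "resilience": "Resilience", "candidate_only": "Candidate"}
_LABEL_CALL = {v: k for k, v in _CALL_LABEL.items()}


def write_results_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write an enrichment-results table in the fixed report layout.

    ``results`` needs columns rsid, gene, consequence, tested_allele,
    cohort_freq, ref_freq, p_value, call.  Frequencies print at 2 decimal
    places, p-values in scientific notation with 3 significant digits; rows
    sort by gene then rsID.
    """
    if len(results) == 0:
        Path(path).write_text("\t".join(RESULTS_COLUMNS) + "\n", encoding="utf-8")
        return
    out = pd.DataFrame(
        {
            "rsID": results["rsid"].values,
            "Gene": results["gene"].values,
            "Type_of_Mutation": results["consequence"].values,
            "Risk_Allele": results["tested_allele"].values,
            "FASD_Risk_Allele_Frequency": [f"{x:.2f}" for x in results["cohort_freq"]],
            "Ref_Risk_Allele_Frequency": [f"{x:.2f}" for x in results["ref_freq"]],
            "p_Value": [f"{x:.2e}" for x in results["p_value"]],
            "Risk_or_Resilience": [_CALL_LABEL.get(c, c) for c in results["call"]],
        }
    )
    out = out.sort_values(["Gene", "rsID"], kind="stable")
    out.to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read a results table back into internal column names (round trip)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in RESULTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"results table missing columns: {missing}")
    return pd.DataFrame(
        {
            "rsid": df["rsID"],
            "gene": df["Gene"],
            "consequence": df["Type_of_Mutation"],
            "tested_allele": df["Risk_Allele"],
            "cohort_freq": df["FASD_Risk_Allele_Frequency"].astype(float),
            "ref_freq": df["Ref_Risk_Allele_Frequency"].astype(float),
            "p_value": df["p_Value"].astype(float),
            "call": [_LABEL_CALL.get(c, c) for c in df["Risk_or_Resilience"]],
        }
    )
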