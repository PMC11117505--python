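"""Synthetic cohorts with known ground truth.

Generates every input the pipeline consumes — cohort VCF, sample sheet,
candidate-gene panel, reference frequency table, annotations — with the
statistical structure the analysis assumes, plus ground truth for recovery
tests:

* reference allele frequencies drawn uniformly from configurable bounds and
  reported with a fixed reference allele number (default 5008 chromosomes);
* cohort genotypes drawn per individual as Binomial(2, p') under
  Hardy-Weinberg, where the cohort frequency p' solves
  logit(p') = logit(p_ref) + ln(OR) for a planted per-variant odds ratio
  (OR = 1 gives the null);
* optional per-(diagnosis, pathway) burden planting that adds Bernoulli risk
  alleles in pathway-tagged genes for individuals of that diagnosis, so the
  diagnosis-partition and pathway-score stages see a real group difference;
* annotations that mark planted variants as damaging (deleterious SIFT,
  CADD > 10) and everything else benign.

No linkage disequilibrium is simulated: the statistics exercised are
per-variant, so LD would not change them, but this is a documented gap
between the generator and real exome data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .variants import (
    PATHWAYS,
    CohortGenotypes,
    GenePanel,
    ReferenceFrequencyTable,
    VariantKey,
    write_vcf,
)
from .enrichment import ContingencyTable2x2, chi_square_allele_test, benjamini_hochberg, reconstruct_counts

__all__ = ["SimulationConfig", "SimulatedCohort", "simulate_reference", "simulate_cohort", "power_experiment"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the emulated study: 23 diploid individuals split
    6 FAS / 12 pFAS / 5 ARND, controls reported over 5008 chromosomes.
    ``planted_or`` maps variant index -> odds ratio (unlisted variants get
    OR = 1); ``planted_pathway_burden`` maps (diagnosis, pathway) -> the
    expected number of extra risk alleles per person of that diagnosis,
    spread across that pathway's variants.  A seed is mandatory: every
    stochastic draw flows from it.
    """

    seed: int
    n_variants: int = 100
    n_cohort: int = 23
    diagnosis_split: tuple[int, int, int] = (6, 12, 5)
    ref_af_bounds: tuple[float, float] = (0.05, 0.95)
    ref_af_override: Mapping[int, float] = field(default_factory=dict)
    planted_or: Mapping[int, float] = field(default_factory=dict)
    planted_pathway_burden: Mapping[tuple[str, str], float] = field(default_factory=dict)
    ref_an: int = 5008
    variants_per_gene: int = 2

    def __post_init__(self) -> None:
        if sum(self.diagnosis_split) != self.n_cohort:
            raise ValueError("diagnosis_split must sum to n_cohort")
        lo, hi = self.ref_af_bounds
        if not (0 <= lo <= hi <= 1):
            raise ValueError(f"invalid ref_af_bounds {self.ref_af_bounds}")
        if any(not 0 <= f <= 1 for f in self.ref_af_override.values()):
            raise ValueError("ref_af_override frequencies must lie in [0, 1]")
        if any(or_ <= 0 for or_ in self.planted_or.values()):
            raise ValueError("odds ratios must be > 0")
        if self.ref_an < 2:
            raise ValueError("ref_an must be >= 2")

    @property
    def n_genes(self) -> int:
        return math.ceil(self.n_variants / self.variants_per_gene)


def _gene_of(config: SimulationConfig, variant_index: int) -> int:
    return variant_index // config.variants_per_gene


def _gene_pathways(config: SimulationConfig, gene_index: int) -> frozenset[str]:
    """Deterministic pathway assignment: gene i carries pathway i mod 8,
    except every tenth gene, which is pathway-less (exercises rule 3)."""
    if gene_index % 10 == 9:
        return frozenset()
    return frozenset({PATHWAYS[gene_index % len(PATHWAYS)]})


def _variant_keys(config: SimulationConfig) -> list[VariantKey]:
    keys = []
    for i in range(config.n_variants):
        gene = _gene_of(config, i)
        chrom = f"chr{1 + gene % 22}"
        keys.append(VariantKey(chrom, 1000 + 10 * i, "A", "G", f"rs{900000 + i}"))
    return keys


def simulate_reference(config: SimulationConfig) -> ReferenceFrequencyTable:
    """Draw the reference (control) frequency table.

    The tested allele is always ALT; frequencies come from U(ref_af_bounds),
    except variants listed in ``ref_af_override`` (e.g. rare literature-known
    alleles), which take their frequency verbatim.  Deterministic under the
    config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    lo, hi = config.ref_af_bounds
    freqs = rng.uniform(lo, hi, size=config.n_variants)
    for i, f in config.ref_af_override.items():
        freqs[i] = f
    keys = _variant_keys(config)
    df = pd.DataFrame(
        {
            "rsid": [k.rsid for k in keys],
            "chrom": [k.chrom for k in keys],
            "pos": [k.pos for k in keys],
            "ref": [k.ref for k in keys],
            "alt": [k.alt for k in keys],
            "tested_allele": [k.alt for k in keys],
            "ref_freq": freqs,
            "ref_an": config.ref_an,
        },
        index=pd.Index([k.key for k in keys], name="key"),
    )
    return ReferenceFrequencyTable(df)


@dataclass
class SimulatedCohort:
    """Bundle of generated inputs plus ground truth."""

    genotypes: CohortGenotypes
    sample_sheet: pd.DataFrame
    panel: GenePanel
    reference: ReferenceFrequencyTable
    annotations: pd.DataFrame
    ground_truth: pd.DataFrame  # per variant: gene, true_or, cohort_p, planted
    burden_truth: dict[tuple[str, str], float]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the five pipeline input files (plus ground truth) as text."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "cohort.vcf",
            "samples": outdir / "samples.tsv",
            "panel": outdir / "panel.tsv",
            "reference": outdir / "reference.tsv",
            "annotations": outdir / "annotations.tsv",
            "ground_truth": outdir / "ground_truth.tsv",
        }
        write_vcf(self.genotypes, paths["vcf"])
        self.sample_sheet.to_csv(paths["samples"], sep="\t", index=False)
        panel_out = self.panel.table.copy()
        panel_out["pathways"] = panel_out["pathways"].map(lambda s: ";".join(sorted(s)))
        panel_out["ndd_syndrome"] = panel_out["ndd_syndrome"].fillna("")
        panel_out.to_csv(paths["panel"], sep="\t", index=False)
        self.reference.table.to_csv(paths["reference"], sep="\t", index=False)
        ann = self.annotations.copy()
        ann["cadd_phred"] = ann["cadd_phred"].map(lambda v: "NA" if np.isnan(v) else f"{v:.2f}")
        ann.to_csv(paths["annotations"], sep="\t", index=False)
        self.ground_truth.to_csv(paths["ground_truth"], sep="\t")
        return paths


def _shift_freq(p_ref: float, odds_ratio: float) -> float:
    """Cohort frequency after a log-odds shift, clamped into (0, 1)."""
    eps = 1e-9
    p = min(max(p_ref, eps), 1 - eps)
    odds = p / (1 - p) * odds_ratio
    return odds / (1 + odds)


def simulate_cohort(config: SimulationConfig, reference: ReferenceFrequencyTable) -> SimulatedCohort:
    """Draw a full synthetic cohort against a simulated reference."""
    import warnings

    if len(reference) != config.n_variants:
        raise ValueError("reference was generated with a different variant set")
    ss = np.random.SeedSequence(config.seed).spawn(4)
    rng = np.random.default_rng(ss[1])

    keys = _variant_keys(config)
    key_strs = [k.key for k in keys]
    ref_freqs = reference.table.loc[key_strs, "ref_freq"].to_numpy()

    ors = np.array([config.planted_or.get(i, 1.0) for i in range(config.n_variants)])
    cohort_p = np.array([_shift_freq(f, o) for f, o in zip(ref_freqs, ors)])
    if np.any((cohort_p <= 0) | (cohort_p >= 1)):
        warnings.warn("planted odds ratio pushed a cohort frequency to the (0,1) boundary; clamped")

    dosage = rng.binomial(2, cohort_p, size=(config.n_cohort, config.n_variants)).astype(float)

    # sample sheet
    n_fas, n_pfas, n_arnd = config.diagnosis_split
    sample_ids = [f"S{i + 1:02d}" for i in range(config.n_cohort)]
    diagnosis = ["FAS"] * n_fas + ["pFAS"] * n_pfas + ["ARND"] * n_arnd
    sexes = [("M" if i % 2 == 0 else "F") for i in range(config.n_cohort)]
    ancestry = list(rng.choice(["European", "Indigenous"], size=config.n_cohort, p=[10 / 23, 13 / 23]))
    sheet = pd.DataFrame(
        {"sample_id": sample_ids, "diagnosis": diagnosis, "sex": sexes, "ancestry_label": ancestry}
    )

    # burden planting: for each (diagnosis, pathway) delta, add a Bernoulli
    # risk allele per pathway variant with probability delta / n_variants in
    # that pathway (expected extra alleles per person ~ delta, capped at 2
    # per genotype)
    burden_rng = np.random.default_rng(ss[2])
    pathway_variants = {
        pw: [i for i in range(config.n_variants) if pw in _gene_pathways(config, _gene_of(config, i))]
        for pw in PATHWAYS
    }
    burden_variants: set[int] = set()
    for (diag, pw), delta in config.planted_pathway_burden.items():
        if diag not in ("FAS", "pFAS", "ARND"):
            raise ValueError(f"unknown diagnosis {diag!r} in planted_pathway_burden")
        variants = pathway_variants.get(pw, [])
        if not variants:
            raise ValueError(f"no variants in pathway {pw!r} to plant burden on")
        q = min(1.0, delta / len(variants))
        members = [i for i, d in enumerate(diagnosis) if d == diag]
        for v in variants:
            burden_variants.add(v)
            extra = burden_rng.binomial(1, q, size=len(members))
            for m, e in zip(members, extra):
                dosage[m, v] = min(2.0, dosage[m, v] + e)

    variants = pd.DataFrame(
        {
            "chrom": [k.chrom for k in keys],
            "pos": [k.pos for k in keys],
            "ref": [k.ref for k in keys],
            "alt": [k.alt for k in keys],
            "rsid": [k.rsid for k in keys],
        },
        index=pd.Index(key_strs, name="key"),
    )
    genotypes = CohortGenotypes(
        sample_ids,
        variants,
        pd.DataFrame(dosage, index=sample_ids, columns=variants.index),
    )

    # panel
    panel_rows = []
    for g in range(config.n_genes):
        panel_rows.append(
            {
                "gene": f"GENE{g + 1:03d}",
                "panel_id": 1 + g % 4,
                "pathways": _gene_pathways(config, g),
                "ndd_syndrome": None,
            }
        )
    panel = GenePanel(pd.DataFrame(panel_rows))

    # annotations: planted (enrichment or burden) variants look damaging
    ann_rng = np.random.default_rng(ss[3])
    planted = np.array(
        [ors[i] != 1.0 or i in burden_variants for i in range(config.n_variants)]
    )
    consequences = ann_rng.choice(
        ["missense", "silent", "intron", "3'UTR", "5'UTR", "upstream"],
        size=config.n_variants,
        p=[0.35, 0.25, 0.2, 0.08, 0.07, 0.05],
    )
    sift = np.where(planted, "deleterious", "tolerated")
    polyphen = np.where(planted & (consequences == "missense"), "probably_damaging", "benign")
    cadd = np.where(planted, ann_rng.uniform(10.5, 35.0, config.n_variants), ann_rng.uniform(0.0, 9.9, config.n_variants))
    protective = ors < 1.0
    annotations = pd.DataFrame(
        {
            "rsid": [k.rsid for k in keys],
            "chrom": [k.chrom for k in keys],
            "pos": [k.pos for k in keys],
            "ref": [k.ref for k in keys],
            "alt": [k.alt for k in keys],
            "gene": [f"GENE{_gene_of(config, i) + 1:03d}" for i in range(config.n_variants)],
            "consequence": consequences,
            "sift": sift,
            "polyphen": polyphen,
            "cadd_phred": cadd,
            "literature_flag": np.where(protective, "alcohol_protective", "none"),
            "allele_role": np.where(protective, "protective_allele", "risk_allele"),
        },
        index=pd.Index(key_strs, name="key"),
    )

    ground_truth = pd.DataFrame(
        {
            "gene": annotations["gene"],
            "true_or": ors,
            "ref_freq": ref_freqs,
            "cohort_p": cohort_p,
            "planted": planted,
        },
        index=pd.Index(key_strs, name="key"),
    )
    return SimulatedCohort(
        genotypes, sheet, panel, reference, annotations, ground_truth,
        dict(config.planted_pathway_burden),
    )


def power_experiment(
    or_grid,
    p_ref_grid,
    n_replicates: int,
    seed: int,
    n_cohort: int = 23,
    ref_an: int = 5008,
    alpha: float = 0.05,
    n_null_background: int = 50,
    use_yates: bool = False,
) -> pd.DataFrame:
    """Monte-Carlo power / type-I-error table for the enrichment test.

    For each (odds ratio, reference frequency) cell, each replicate draws
    the target variant's cohort allele count as Binomial(2 n, p') plus a
    background of null variants (reference frequencies U(0.05, 0.95)), runs
    the chi-squared test against reconstructed reference counts, and applies
    BH across the replicate's variants.  Reports the fraction of replicates
    where the target is flagged before (raw p <= alpha) and after BH.
    OR = 1 cells report type-I error.
    """
    rng = np.random.default_rng(seed)
    an = 2 * n_cohort
    rows = []
    for or_ in or_grid:
        for p_ref in p_ref_grid:
            p_cohort = _shift_freq(p_ref, or_)
            raw_hits = 0
            bh_hits = 0
            for _ in range(n_replicates):
                bg_freqs = rng.uniform(0.05, 0.95, size=n_null_background)
                freqs = np.concatenate([[p_ref], bg_freqs])
                true_p = np.concatenate([[p_cohort], bg_freqs])
                counts = rng.binomial(an, true_p)
                pvals = np.empty(len(freqs))
                for i, (cnt, f) in enumerate(zip(counts, freqs)):
                    c = reconstruct_counts(float(f), ref_an)
                    _, pvals[i] = chi_square_allele_test(
                        ContingencyTable2x2(int(cnt), an - int(cnt), c, ref_an - c),
                        use_yates,
                    )
                raw_hits += pvals[0] <= alpha
                reject, _ = benjamini_hochberg(pvals, alpha)
                bh_hits += bool(reject[0])
            rows.append(
                {
                    "odds_ratio": or_,
                    "p_ref": p_ref,
                    "power_raw": raw_hits / n_replicates,
                    "power_bh": bh_hits / n_replicates,
                    "n_replicates": n_replicates,
                }
            )
    return pd.DataFrame(rows)
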