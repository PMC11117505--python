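"""Built-in simulation experiments validating the pipeline end to end.

Three standard experiments, each driven entirely by a seed:

* :func:`null_calibration` — cohorts simulated with odds ratio 1 everywhere;
  measures the pre-correction rejection rate at alpha (which should sit
  near alpha) and the post-BH empirical false discovery rate.  Note that
  chi-squared p-values on a 46-chromosome cohort are only approximate in
  the far tail, so BH's FDR control is itself approximate at this cohort
  size (see the methods documentation).
* :func:`enrichment_recovery` — replicate cohorts with one strongly
  enriched, damaging-annotated variant planted among null background
  variants; measures how often the full pipeline flags it BH-significant
  and classifies it a risk allele.
* :func:`burden_separation` — a cohort with rare pathway variants whose
  risk-allele burden differs between FAS and pFAS (retinoic-acid-heavy in
  FAS, WNT-heavy in pFAS), run through enrichment, diagnosis partition,
  inclusion rules, pathway scoring and PCA; measures the FAS/pFAS
  silhouette and its permutation p-value.  The matched null arm scores the
  same pathway variants without any planted group difference.

Problem sizes default to what each measurement needs at desk scale
(hundreds of replicates, thousands of null variants) while keeping each
experiment in the seconds-to-a-minute range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import pca, separation
from .enrichment import enrichment_scan
from .model import EnrichmentModel, PathwayBurdenModel
from .pathways import pathway_score_matrix
from .simulate import SimulationConfig, simulate_cohort, simulate_reference

__all__ = [
    "null_calibration",
    "enrichment_recovery",
    "burden_separation",
    "NullCalibration",
    "RecoveryRate",
    "BurdenSeparation",
]


@dataclass(frozen=True)
class NullCalibration:
    raw_rejection_rate: float  # single large null cohort, p <= alpha
    fdr: float                 # mean V/max(R,1) over replicate null cohorts
    n_variants: int
    n_replicates: int


def null_calibration(
    seed: int,
    n_variants: int = 2000,
    alpha: float = 0.05,
    n_fdr_replicates: int = 60,
    n_fdr_variants: int = 2000,
) -> NullCalibration:
    """Type-I calibration on all-null cohorts (odds ratio 1 everywhere).

    The rejection rate comes from one cohort of ``n_variants`` null
    variants; the empirical FDR averages V/max(R, 1) over
    ``n_fdr_replicates`` smaller null cohorts (every BH rejection under the
    null is a false discovery).
    """
    rng_seeds = np.random.SeedSequence(seed).generate_state(1 + n_fdr_replicates) % (2**31)
    cfg = SimulationConfig(seed=int(rng_seeds[0]), n_variants=n_variants)
    cohort = simulate_cohort(cfg, simulate_reference(cfg))
    res, _ = enrichment_scan(cohort.genotypes, cohort.reference)
    raw_rate = float(res["raw_significant"].mean())

    fdrs = []
    for s in rng_seeds[1:]:
        cfg = SimulationConfig(seed=int(s), n_variants=n_fdr_variants)
        cohort = simulate_cohort(cfg, simulate_reference(cfg))
        res, _ = enrichment_scan(cohort.genotypes, cohort.reference)
        rejected = int(res["bh_significant"].sum())
        fdrs.append(rejected / max(rejected, 1))
    return NullCalibration(raw_rate, float(np.mean(fdrs)), n_variants, n_fdr_replicates)


@dataclass(frozen=True)
class RecoveryRate:
    flagged_and_risk: float   # BH-significant AND classified risk
    flagged: float            # BH-significant
    n_replicates: int
    odds_ratio: float
    ref_freq: float


def enrichment_recovery(
    seed: int,
    n_replicates: int = 500,
    odds_ratio: float = 5.0,
    ref_freq: float = 0.25,
    n_background: int = 29,
) -> RecoveryRate:
    """Recovery of a planted enriched damaging variant by the full pipeline.

    Each replicate cohort carries one variant at reference frequency
    ``ref_freq`` with the planted odds ratio (annotated damaging by the
    generator) among ``n_background`` null variants; recovery means the
    variant is BH-significant and classified a risk allele.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    flagged = 0
    recovered = 0
    for s in seeds:
        cfg = SimulationConfig(
            seed=int(s),
            n_variants=1 + n_background,
            ref_af_override={0: ref_freq},
            planted_or={0: odds_ratio},
        )
        cohort = simulate_cohort(cfg, simulate_reference(cfg))
        res = EnrichmentModel(
            cohort.genotypes, cohort.reference, cohort.sample_sheet,
            cohort.panel, cohort.annotations,
        ).fit()
        key = cohort.genotypes.variants.index[0]
        if key in res.table.index and res.table.loc[key, "bh_significant"]:
            flagged += 1
            if res.table.loc[key, "call"] == "risk":
                recovered += 1
    return RecoveryRate(
        recovered / n_replicates, flagged / n_replicates, n_replicates, odds_ratio, ref_freq
    )


@dataclass(frozen=True)
class BurdenSeparation:
    silhouette: float
    permutation_p: float
    null_silhouette: float
    null_permutation_p: float


def _burden_config(seed: int, planted: bool) -> SimulationConfig:
    """Study design of the burden-separation experiment.

    64 variants in 32 genes; the retinoic-acid and WNT pathway variants are
    rare in the reference (2.5%), emulating low-frequency alleles shared
    within the FAS/pFAS groups; the planted arm gives FAS individuals about
    six extra risk alleles in RA (one in WNT) and pFAS individuals the
    mirror image, so both groups carry the variants (keeping them common to
    FAS and pFAS) while their pathway profiles differ.
    """
    n_variants = 64
    # RA = genes 0,8,16,24 -> variants 0,1,16,17,32,33,48,49; WNT = genes 2,10,18,26
    rare = [i for g in (0, 8, 16, 24, 2, 10, 18, 26) for i in (2 * g, 2 * g + 1)]
    burden = (
        {
            ("FAS", "RA"): 6.0,
            ("pFAS", "RA"): 1.0,
            ("FAS", "WNT"): 1.0,
            ("pFAS", "WNT"): 6.0,
        }
        if planted
        else {}
    )
    return SimulationConfig(
        seed=seed,
        n_variants=n_variants,
        ref_af_override={i: 0.025 for i in rare},
        planted_pathway_burden=burden,
    )


def burden_separation(seed: int, n_permutations: int = 999) -> BurdenSeparation:
    """FAS-vs-pFAS separation with and without a planted burden difference.

    The planted arm runs the complete flow: enrichment, BH, classification,
    diagnosis partition, inclusion rules, pathway matrix, PCA, silhouette +
    permutation test on PC1-2 of the FAS and pFAS individuals.  The null
    arm scores the same candidate pathway variants (all treated as risk
    alleles, bypassing the significance gate a null cohort cannot pass) on
    an unplanted cohort, so the clustering statistic is calibrated on data
    with no group signal.
    """
    s_planted, s_null = (int(x) for x in np.random.SeedSequence(seed).generate_state(2) % (2**31))

    cfg = _burden_config(s_planted, planted=True)
    cohort = simulate_cohort(cfg, simulate_reference(cfg))
    res = EnrichmentModel(
        cohort.genotypes, cohort.reference, cohort.sample_sheet, cohort.panel, cohort.annotations
    ).fit()
    burden = PathwayBurdenModel(res).fit()
    rep = burden.separation(n_permutations=n_permutations, seed=s_planted)

    null_cfg = _burden_config(s_null, planted=False)
    null_cohort = simulate_cohort(null_cfg, simulate_reference(null_cfg))
    gene_map = dict(null_cohort.annotations["gene"])
    keep = [
        k for k in null_cohort.genotypes.variants.index
        if null_cohort.panel.pathways_by_gene.get(gene_map[k])
    ]
    matrix = pathway_score_matrix(
        keep, {k: "risk" for k in keep}, null_cohort.genotypes, gene_map,
        null_cohort.panel, null_cohort.sample_sheet,
    )
    fit = pca(matrix.scores)
    mask = null_cohort.sample_sheet["diagnosis"].isin(["FAS", "pFAS"]).to_numpy()
    null_rep = separation(
        fit.scores[mask],
        null_cohort.sample_sheet.loc[mask, "diagnosis"].to_numpy(),
        n_permutations=n_permutations,
        seed=s_null,
    )
    return BurdenSeparation(rep.silhouette, rep.permutation_p, null_rep.silhouette, null_rep.permutation_p)
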