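"""Pathway-level polygenic risk-allele burden.

Significant variants are first partitioned by which diagnostic groups carry
them (FAS, pFAS, ARND), then filtered by three inclusion rules oriented
around the FAS/pFAS axis (the two categories sharing sentinel facial
features):

1. if a gene has a variant common to FAS and pFAS, all significant variants
   in that gene are included;
2. variants common to all three diagnostic groups are dropped;
3. variants in genes with no developmental-pathway membership are dropped.

The included risk-called variants are then aggregated into a per-person,
per-pathway risk-allele count matrix over the eight developmental signaling
pathways.  "Risk alleles per person" is read as allele dosage (het = 1,
hom = 2), not carrier status; a gene belonging to several pathways
contributes its dosage to each of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .variants import PATHWAYS, DIAGNOSES, CohortGenotypes, GenePanel

__all__ = [
    "DiagnosisGroupSets",
    "PathwayScoreMatrix",
    "partition_by_diagnosis",
    "apply_inclusion_rules",
    "pathway_score_matrix",
]


@dataclass(frozen=True)
class DiagnosisGroupSets:
    """Disjoint occurrence-pattern sets of significant variants.

    Patterns the three named categories do not cover (FAS+ARND only,
    pFAS+ARND only) are reported under unique_fas / unique_pfas
    respectively but never seed the common-gene expansion, which only
    operationalizes the FAS-pFAS axis.
    """

    unique_fas: frozenset[str]
    unique_pfas: frozenset[str]
    unique_arnd: frozenset[str]
    common_fas_pfas: frozenset[str]
    common_all: frozenset[str]

    def __post_init__(self) -> None:
        sets = [self.unique_fas, self.unique_pfas, self.unique_arnd, self.common_fas_pfas, self.common_all]
        total = sum(len(s) for s in sets)
        if total != len(frozenset().union(*sets)):
            raise ValueError("diagnosis group sets must be pairwise disjoint")

    @property
    def all_observed(self) -> frozenset[str]:
        return (
            self.unique_fas | self.unique_pfas | self.unique_arnd
            | self.common_fas_pfas | self.common_all
        )

    def gene_sets(self, gene_map: Mapping[str, str]) -> dict[str, frozenset[str]]:
        """Gene-level view of each set via a variant -> gene map."""
        return {
            name: frozenset(gene_map[v] for v in getattr(self, name) if v in gene_map)
            for name in ("unique_fas", "unique_pfas", "unique_arnd", "common_fas_pfas", "common_all")
        }


def partition_by_diagnosis(
    significant_variants: Iterable[str],
    genotypes: CohortGenotypes,
    sample_sheet: pd.DataFrame,
    tested_allele: Mapping[str, str] | pd.Series | None = None,
) -> DiagnosisGroupSets:
    """Assign each significant variant to one occurrence-pattern set.

    A variant "occurs in" a diagnostic group iff at least one individual of
    that group carries at least one tested allele (dosage > 0; missing
    genotypes do not count).  Variants carried by nobody are omitted.
    """
    dosage = (
        genotypes.oriented_dosage(tested_allele) if tested_allele is not None else genotypes.dosage
    )
    groups = {d: sample_sheet.loc[sample_sheet["diagnosis"] == d, "sample_id"] for d in DIAGNOSES}
    for d, members in groups.items():
        if len(members) == 0:
            warnings.warn(f"diagnosis group {d} is empty", stacklevel=2)

    sets: dict[str, set[str]] = {
        "unique_fas": set(), "unique_pfas": set(), "unique_arnd": set(),
        "common_fas_pfas": set(), "common_all": set(),
    }
    for key in significant_variants:
        occ = {
            d: bool((dosage.loc[members, key].fillna(0) > 0).any())
            for d, members in groups.items()
        }
        fas, pfas, arnd = occ["FAS"], occ["pFAS"], occ["ARND"]
        if fas and pfas and arnd:
            sets["common_all"].add(key)
        elif fas and pfas:
            sets["common_fas_pfas"].add(key)
        elif fas:
            sets["unique_fas"].add(key)  # includes FAS+ARND pattern
        elif pfas:
            sets["unique_pfas"].add(key)  # includes pFAS+ARND pattern
        elif arnd:
            sets["unique_arnd"].add(key)
    return DiagnosisGroupSets(**{k: frozenset(v) for k, v in sets.items()})


def apply_inclusion_rules(
    sets: DiagnosisGroupSets,
    all_significant_variants: Iterable[str],
    gene_map: Mapping[str, str],
    panel: GenePanel,
) -> frozenset[str]:
    """Apply the three inclusion rules, in order, to pick burden variants.

    Starts from the FAS/pFAS-common set, expands per rule 1 to every
    significant variant in a common gene, removes per rule 2 any variant
    common to all three groups, and removes per rule 3 variants whose gene
    has no pathway membership.
    """
    common_genes = {gene_map[v] for v in sets.common_fas_pfas if v in gene_map}
    # rule 1: expand to all significant variants in FAS/pFAS-common genes
    included = {v for v in all_significant_variants if gene_map.get(v) in common_genes}
    # rule 2: drop variants present in all three diagnostic groups
    included -= sets.common_all
    # rule 3: drop variants in genes without any developmental-pathway tag
    included = {
        v for v in included if panel.pathways_by_gene.get(gene_map[v], frozenset())
    }
    return frozenset(included)


@dataclass
class PathwayScoreMatrix:
    """Individual x pathway risk-allele counts with full provenance.

    ``scores`` rows follow the sample sheet, columns are the eight pathways
    in fixed order.  ``provenance`` is a long-format frame of every
    (sample, variant, gene, pathway, dosage, weight) contribution; each
    matrix entry equals the sum of its weighted provenance dosages.
    """

    scores: pd.DataFrame
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.scores.columns) != list(PATHWAYS):
            raise ValueError(f"score columns must be exactly {PATHWAYS}")


def pathway_score_matrix(
    included_variants: Iterable[str],
    risk_calls: Mapping[str, str] | pd.Series,
    genotypes: CohortGenotypes,
    gene_map: Mapping[str, str],
    panel: GenePanel,
    sample_sheet: pd.DataFrame,
    tested_allele: Mapping[str, str] | pd.Series | None = None,
    include_resilience: bool = False,
) -> PathwayScoreMatrix:
    """Build the per-person per-pathway risk-allele count matrix.

    Each entry is the sum over included risk-called variants, in genes
    belonging to that pathway, of the person's tested-allele dosage
    (missing counts 0).  Resilience-called variants are excluded by default
    (it is a risk-allele score); ``include_resilience`` adds them with
    weight -1 for exploration.  Candidate-only variants never contribute.
    A variant with no gene mapping is a hard error (rule 3 should have
    removed it).
    """
    dosage = (
        genotypes.oriented_dosage(tested_allele) if tested_allele is not None else genotypes.dosage
    )
    samples = list(sample_sheet["sample_id"])
    scores = pd.DataFrame(0.0, index=samples, columns=list(PATHWAYS))
    prov_rows = []
    calls = dict(risk_calls)
    for key in sorted(included_variants):
        gene = gene_map.get(key)
        if gene is None:
            raise ValueError(f"variant {key} has no gene mapping (rule 3 should have removed it)")
        call = calls.get(key, "candidate_only")
        if call == "risk":
            weight = 1.0
        elif call == "resilience" and include_resilience:
            weight = -1.0
        else:
            continue
        pathways = panel.pathways_by_gene.get(gene, frozenset())
        dose = dosage.loc[samples, key].fillna(0.0)
        for pw in PATHWAYS:
            if pw not in pathways:
                continue
            scores[pw] += weight * dose
            for s in samples:
                if dose[s] != 0:
                    prov_rows.append((s, key, gene, pw, dose[s], weight))
    provenance = pd.DataFrame(
        prov_rows, columns=["sample_id", "key", "gene", "pathway", "dosage", "weight"]
    )
    if not include_resilience:
        assert (scores.to_numpy() >= 0).all()
    return PathwayScoreMatrix(scores, provenance)
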