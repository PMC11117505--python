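"""Model / Results objects tying the pipeline stages together.

:class:`EnrichmentModel` holds the data (cohort genotypes, reference
frequencies, panel, annotations) and testing configuration; ``fit()``
subsets to candidate genes, computes cohort frequencies, applies the MAF
filter + whitelist, chi-squared tests each variant, corrects with BH, and
classifies risk/resilience.  The returned :class:`EnrichmentResults` carries
the per-variant table, the BH threshold, tallies, and a ``summary()``.

:class:`PathwayBurdenModel` consumes an :class:`EnrichmentResults` (or an
explicit variant set) and builds the diagnosis partition, inclusion rules,
and pathway score matrix; its :class:`PathwayBurdenResults` exposes PCA and
the silhouette/permutation separation statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import variants as vio
from .variants import CohortGenotypes, GenePanel, ReferenceFrequencyTable, PATHWAYS
from .enrichment import TestingConfig, enrichment_scan
from .classify import classify_results, CADD_DAMAGING_CUTOFF
from .pathways import (
    DiagnosisGroupSets,
    PathwayScoreMatrix,
    apply_inclusion_rules,
    partition_by_diagnosis,
    pathway_score_matrix,
)
from .clustering import PCAResult, SeparationReport, pca, separation, plot_scores

__all__ = ["EnrichmentModel", "EnrichmentResults", "PathwayBurdenModel", "PathwayBurdenResults"]


class EnrichmentModel:
    """Cohort-vs-reference allele-frequency enrichment model.

    Parameters
    ----------
    genotypes, reference
        The two sides of every test.
    sample_sheet
        Cohort metadata (required downstream for diagnosis grouping).
    panel, annotations
        Candidate-gene panel and per-variant annotations.  When both are
        given, testing is restricted to variants whose annotated gene is in
        the panel; annotations also drive classification.
    config
        :class:`fasdvar.enrichment.TestingConfig`.
    cadd_cutoff
        CADD phred cutoff for the damaging-evidence flag (default 10).
    """

    def __init__(
        self,
        genotypes: CohortGenotypes,
        reference: ReferenceFrequencyTable,
        sample_sheet: pd.DataFrame | None = None,
        panel: GenePanel | None = None,
        annotations: pd.DataFrame | None = None,
        config: TestingConfig = TestingConfig(),
        cadd_cutoff: float = CADD_DAMAGING_CUTOFF,
    ) -> None:
        self.genotypes = genotypes
        self.reference = reference
        self.sample_sheet = sample_sheet
        self.panel = panel
        self.annotations = annotations
        self.config = config
        self.cadd_cutoff = cadd_cutoff

    @classmethod
    def from_files(
        cls,
        vcf_path,
        sample_sheet_path,
        reference_path,
        panel_path=None,
        annotations_path=None,
        config: TestingConfig = TestingConfig(),
        cadd_cutoff: float = CADD_DAMAGING_CUTOFF,
    ) -> "EnrichmentModel":
        genotypes, sheet = vio.read_vcf(vcf_path, sample_sheet_path)
        reference = vio.read_reference_frequencies(reference_path)
        panel = vio.read_panel(panel_path) if panel_path else None
        annotations = vio.read_annotations(annotations_path) if annotations_path else None
        return cls(genotypes, reference, sheet, panel, annotations, config, cadd_cutoff)

    def _candidate_genotypes(self) -> CohortGenotypes:
        """Restrict to variants in candidate-panel genes (if panel given)."""
        if self.panel is None or self.annotations is None:
            return self.genotypes
        genes = self.panel.genes
        keep = [
            k
            for k in self.genotypes.variants.index
            if k in self.annotations.index and self.annotations.loc[k, "gene"] in genes
        ]
        return CohortGenotypes(
            self.genotypes.samples,
            self.genotypes.variants.loc[keep],
            self.genotypes.dosage[keep],
        )

    def fit(self) -> "EnrichmentResults":
        candidates = self._candidate_genotypes()
        table, bh_threshold = enrichment_scan(candidates, self.reference, self.config)
        if self.annotations is not None:
            table = classify_results(table, self.annotations, self.cadd_cutoff)
            table["gene"] = [
                self.annotations.loc[k, "gene"] if k in self.annotations.index else ""
                for k in table.index
            ]
            table["consequence"] = [
                self.annotations.loc[k, "consequence"] if k in self.annotations.index else ""
                for k in table.index
            ]
        else:
            table["call"] = "candidate_only"
            table["rationale"] = "no annotations supplied"
            table["gene"] = ""
            table["consequence"] = ""
        return EnrichmentResults(
            model=self,
            table=table,
            bh_threshold=bh_threshold,
            n_candidates=candidates.n_variants,
        )


@dataclass
class EnrichmentResults:
    """Fitted per-variant enrichment results."""

    model: EnrichmentModel
    table: pd.DataFrame
    bh_threshold: float
    n_candidates: int

    @property
    def significant(self) -> pd.DataFrame:
        """BH-significant rows."""
        return self.table[self.table["bh_significant"]]

    @property
    def stage_counts(self) -> dict[str, int]:
        t = self.table
        sig = self.significant
        return {
            "cohort_variants": self.model.genotypes.n_variants,
            "candidate_variants": self.n_candidates,
            "tested_variants": len(t),
            "whitelisted": int(t["whitelisted"].sum()),
            "raw_significant": int(t["raw_significant"].sum()),
            "bh_significant": len(sig),
            "risk_calls": int((sig["call"] == "risk").sum()),
            "resilience_calls": int((sig["call"] == "resilience").sum()),
            "candidate_only_calls": int((sig["call"] == "candidate_only").sum()),
        }

    def summary(self) -> str:
        c = self.stage_counts
        cfg = self.model.config
        lines = [
            "Candidate-gene allele-frequency enrichment",
            "=" * 46,
            f"Samples:                 {self.model.genotypes.n_samples}",
            f"Cohort variants:         {c['cohort_variants']}",
            f"Candidate-gene variants: {c['candidate_variants']}",
            f"Tested (MAF/whitelist):  {c['tested_variants']} ({c['whitelisted']} whitelisted)",
            f"alpha:                   {cfg.alpha}",
            f"Effective n tests:       {cfg.n_tests_override or c['tested_variants']}",
            f"BH p-value threshold:    {self.bh_threshold:.3g}",
            f"Raw significant:         {c['raw_significant']}",
            f"BH significant:          {c['bh_significant']}",
            f"  risk calls:            {c['risk_calls']}",
            f"  resilience calls:      {c['resilience_calls']}",
            f"  candidate-only:        {c['candidate_only_calls']}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path, which: str = "bh") -> None:
        """Write the results table (``which``: 'bh', 'raw', or 'all')."""
        if which == "bh":
            rows = self.significant
        elif which == "raw":
            rows = self.table[self.table["raw_significant"]]
        elif which == "all":
            rows = self.table
        else:
            raise ValueError(f"which must be bh/raw/all, got {which!r}")
        vio.write_results_table(rows.reset_index(), path)


class PathwayBurdenModel:
    """Pathway-aggregated polygenic risk-allele burden model.

    Takes fitted enrichment results (the source of significance and
    risk/resilience calls), partitions significant variants by diagnosis
    occurrence, applies the three inclusion rules, and counts risk alleles
    per person per pathway.
    """

    def __init__(
        self,
        results: EnrichmentResults,
        significance: str = "bh",
        include_resilience: bool = False,
    ) -> None:
        if significance not in ("bh", "raw"):
            raise ValueError("significance must be 'bh' or 'raw'")
        if results.model.sample_sheet is None:
            raise ValueError("a sample sheet is required for diagnosis grouping")
        if results.model.panel is None or results.model.annotations is None:
            raise ValueError("a gene panel and annotations are required")
        self.results = results
        self.significance = significance
        self.include_resilience = include_resilience

    def fit(self) -> "PathwayBurdenResults":
        res = self.results
        model = res.model
        col = "bh_significant" if self.significance == "bh" else "raw_significant"
        sig = res.table[res.table[col]]
        sig_keys = list(sig.index)
        tested_allele = sig["tested_allele"]
        gene_map = {k: model.annotations.loc[k, "gene"] for k in sig_keys if k in model.annotations.index}

        groups = partition_by_diagnosis(
            sig_keys, model.genotypes, model.sample_sheet, tested_allele
        )
        included = apply_inclusion_rules(groups, sig_keys, gene_map, model.panel)
        matrix = pathway_score_matrix(
            included,
            sig["call"],
            model.genotypes,
            gene_map,
            model.panel,
            model.sample_sheet,
            tested_allele,
            self.include_resilience,
        )
        return PathwayBurdenResults(
            model=self, groups=groups, included=included, matrix=matrix,
            sample_sheet=model.sample_sheet,
        )


@dataclass
class PathwayBurdenResults:
    """Diagnosis partition, included variants, and the score matrix."""

    model: PathwayBurdenModel
    groups: DiagnosisGroupSets
    included: frozenset[str]
    matrix: PathwayScoreMatrix
    sample_sheet: pd.DataFrame
    _pca: PCAResult | None = field(default=None, repr=False)

    @property
    def scores(self) -> pd.DataFrame:
        return self.matrix.scores

    def pca(self, center: bool = True, scale: bool = True) -> PCAResult:
        self._pca = pca(self.matrix.scores, center=center, scale=scale)
        return self._pca

    def separation(
        self,
        groups: tuple[str, ...] = ("FAS", "pFAS"),
        labels_column: str = "diagnosis",
        n_permutations: int = 999,
        seed: int = 0,
        center: bool = True,
        scale: bool = True,
    ) -> SeparationReport:
        """Silhouette + permutation separation of the given diagnostic
        groups on PC1-2 of the burden matrix."""
        fit = self._pca if self._pca is not None else self.pca(center, scale)
        if fit.degenerate:
            raise ValueError("burden matrix is degenerate (no variance); cannot separate groups")
        mask = self.sample_sheet[labels_column].isin(groups).to_numpy()
        labels = self.sample_sheet.loc[mask, labels_column].to_numpy()
        return separation(fit.scores[mask], labels, n_permutations, seed)

    def plot(self, path=None, center: bool = True, scale: bool = True):
        fit = self._pca if self._pca is not None else self.pca(center, scale)
        ancestry = self.sample_sheet["ancestry_label"].to_numpy()
        return plot_scores(fit, self.sample_sheet["diagnosis"].to_numpy(), ancestry, path)

    def summary(self) -> str:
        g = self.groups
        lines = [
            "Pathway polygenic risk-allele burden",
            "=" * 42,
            f"Significant variants observed:  {len(g.all_observed)}",
            f"  unique to FAS:                {len(g.unique_fas)}",
            f"  unique to pFAS:               {len(g.unique_pfas)}",
            f"  unique to ARND:               {len(g.unique_arnd)}",
            f"  common FAS+pFAS:              {len(g.common_fas_pfas)}",
            f"  common to all three:          {len(g.common_all)}",
            f"Included after rules 1-3:       {len(self.included)}",
            f"Matrix total risk alleles:      {self.matrix.scores.to_numpy().sum():g}",
            "Per-pathway totals:",
        ]
        totals = self.matrix.scores.sum(axis=0)
        for pw in PATHWAYS:
            lines.append(f"  {pw:<9} {totals[pw]:g}")
        return "\n".join(lines)
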