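"""Cohort allele frequencies.

The cohort side of every enrichment test: per-variant counts of the tested
allele over genotyped chromosomes.  Missing genotypes reduce the allele
number (AN = 2 x non-missing samples).  Frequencies are held as exact
rationals and rounded only at output.

All samples are treated as diploid, including X-linked sites in males; no
hemizygosity adjustment is applied (documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .variants import CohortGenotypes, ReferenceFrequencyTable

__all__ = ["CohortFrequency", "allele_frequency", "cohort_frequency_table", "min_detectable_frequency"]


@dataclass(frozen=True)
class CohortFrequency:
    """Tested-allele count and frequency at one variant."""

    key: str
    tested_allele: str
    count: int
    an: int

    def __post_init__(self) -> None:
        if not 0 <= self.count <= self.an:
            raise ValueError(f"count {self.count} outside [0, an={self.an}] at {self.key}")

    @property
    def freq(self) -> Fraction:
        return Fraction(self.count, self.an)


def allele_frequency(
    genotypes: CohortGenotypes, key: str, tested_allele: str | None = None
) -> CohortFrequency:
    """Frequency of ``tested_allele`` (default: ALT) at one variant.

    Raises if every genotype at the variant is missing.
    """
    if key not in genotypes.variants.index:
        raise KeyError(f"variant {key} not in cohort")
    row = genotypes.variants.loc[key]
    allele = row["alt"] if tested_allele is None else tested_allele
    if allele not in (row["ref"], row["alt"]):
        raise ValueError(f"tested allele {allele!r} is neither ref nor alt of {key}")
    dose = genotypes.dosage[key].to_numpy(dtype=float)
    nonmiss = ~np.isnan(dose)
    if not nonmiss.any():
        raise ValueError(f"all genotypes missing at {key}")
    an = 2 * int(nonmiss.sum())
    alt_count = int(dose[nonmiss].sum())
    count = alt_count if allele == row["alt"] else an - alt_count
    return CohortFrequency(key, allele, count, an)


def cohort_frequency_table(
    genotypes: CohortGenotypes, reference: ReferenceFrequencyTable | None = None
) -> pd.DataFrame:
    """Per-variant tested-allele frequencies for the whole cohort.

    When a reference table is given, the tested allele for each variant is
    taken from its ``tested_allele`` column and variants absent from the
    reference are dropped (they cannot be tested).  Variants where every
    genotype is missing are dropped with a warning.  Returns a DataFrame
    indexed by variant key with columns rsid, tested_allele, cohort_count,
    cohort_an, cohort_freq.
    """
    import warnings

    rows = []
    for key in genotypes.variants.index:
        tested = None
        if reference is not None:
            if key not in reference:
                continue
            tested = reference.table.loc[key, "tested_allele"]
        try:
            cf = allele_frequency(genotypes, key, tested)
        except ValueError:
            warnings.warn(f"dropping variant {key}: all genotypes missing", stacklevel=2)
            continue
        rows.append(
            (
                key,
                genotypes.variants.loc[key, "rsid"],
                cf.tested_allele,
                cf.count,
                cf.an,
                cf.count / cf.an,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["key", "rsid", "tested_allele", "cohort_count", "cohort_an", "cohort_freq"],
    ).set_index("key")


def min_detectable_frequency(n_individuals: int) -> Fraction:
    """Smallest nonzero allele frequency observable in ``n_individuals``
    diploid samples: 1 / (2 n).  For the 23-person cohort this is 1/46,
    about 2.17%, which doubles as the default minor-allele-frequency filter
    floor."""
    if n_individuals < 1:
        raise ValueError(f"n_individuals must be >= 1, got {n_individuals}")
    return Fraction(1, 2 * n_individuals)
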