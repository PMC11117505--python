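"""Cohort-vs-reference allele-frequency enrichment testing.

Each variant is compared between the cohort and a reference population by a
Pearson chi-squared test on the 2x2 allele-count table (cohort vs reference,
tested allele vs other allele), followed by Benjamini-Hochberg step-up
correction.  The BH procedure supports a fixed total-test-count override,
the convention where rare literature-known ("whitelisted") variants that
fail the minor-allele-frequency filter are still tested and counted in the
total number of tests.

Reference counts are reconstructed from published frequencies (round half
away from zero), since controls are typically distributed as frequencies
plus a total allele number (e.g. 5008 chromosomes for 1000 Genomes phase 3),
not raw counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .variants import CohortGenotypes, ReferenceFrequencyTable
from .frequencies import cohort_frequency_table, min_detectable_frequency

__all__ = [
    "TestingConfig",
    "ContingencyTable2x2",
    "reconstruct_counts",
    "chi_square_allele_test",
    "maf_filter",
    "benjamini_hochberg",
    "enrichment_scan",
]


@dataclass(frozen=True)
class TestingConfig:
    """Knobs of the enrichment stage.

    alpha : float
        BH significance level (default 0.05).
    n_tests_override : int or None
        Fixed total number of tests for BH; must be >= the number of
        p-values actually supplied.  None uses the per-run count.
    use_yates : bool
        Yates continuity correction (default off; the uncorrected Pearson
        statistic matches published cohort-vs-reference p-values better).
    ref_an_default : int
        Reference allele number to assume when a reference row lacks one.
    maf_threshold : float or None
        Reference minor-allele-frequency floor; None = auto, the smallest
        frequency detectable in the cohort, 1/(2N).
    whitelist : frozenset of variant keys
        Literature-known variants retained (and counted) regardless of the
        MAF filter.
    """

    alpha: float = 0.05
    n_tests_override: int | None = None
    use_yates: bool = False
    ref_an_default: int = 5008
    maf_threshold: float | None = None
    whitelist: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_tests_override is not None and self.n_tests_override < 1:
            raise ValueError("n_tests_override must be positive")
        if self.maf_threshold is not None and not 0 < self.maf_threshold < 1:
            raise ValueError("maf_threshold must be in (0, 1)")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Allele counts: cohort (a tested, b other) vs reference (c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative count in {self}")


def reconstruct_counts(freq: float, an: int) -> int:
    """Nearest-integer allele count for a published frequency.

    Rounds half away from zero and clamps to [0, an].
    """
    if not 0 <= freq <= 1:
        raise ValueError(f"freq must be in [0, 1], got {freq}")
    if an < 1:
        raise ValueError(f"an must be >= 1, got {an}")
    return min(an, max(0, int(math.floor(freq * an + 0.5))))


def chi_square_allele_test(
    table: ContingencyTable2x2, use_yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-squared (1 df) on a 2x2 allele-count table.

    Returns (statistic, p).  A zero column margin (tested allele absent, or
    fixed, in both groups) has every observed cell equal to its expectation,
    so the statistic is 0 and p = 1.  Both row margins (the two allele
    numbers) must be positive.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, row2 = a + b, c + d
    if row1 == 0 or row2 == 0:
        raise ValueError("both margins (cohort and reference AN) must be positive")
    col1, col2 = a + c, b + d
    if col1 == 0 or col2 == 0:
        return 0.0, 1.0
    n = row1 + row2
    delta = abs(a * d - b * c)
    if use_yates:
        delta = max(delta - n / 2.0, 0.0)
    stat = n * delta * delta / (row1 * row2 * col1 * col2)
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), max(p, np.nextafter(0.0, 1.0))


def maf_filter(
    reference: ReferenceFrequencyTable,
    threshold: float,
    whitelist: frozenset[str] | set[str] = frozenset(),
) -> pd.DataFrame:
    """Flag variants passing the reference minor-allele-frequency floor.

    ``passed`` = reference MAF (min of the tested-allele frequency and its
    complement) >= threshold; whitelisted variants are flagged separately
    and retained for testing regardless.  A variant enters results iff
    passed or whitelisted.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    t = reference.table
    maf = np.minimum(t["ref_freq"], 1.0 - t["ref_freq"])
    return pd.DataFrame(
        {
            "passed": maf >= threshold,
            "whitelisted": t.index.isin(list(whitelist)),
        },
        index=t.index,
    )


def benjamini_hochberg(
    p_values, alpha: float = 0.05, n_tests_override: int | None = None
) -> tuple[np.ndarray, float]:
    """BH step-up decisions with an optional fixed total test count.

    The effective test count n is max(n_tests_override, len(p_values)); the
    step-up rule finds the largest rank k with p_(k) <= k*alpha/n, rejects
    every p <= p_(k), and reports the threshold k*alpha/n (0.0 when nothing
    is rejected).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p <= 0) or np.any(p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    n = m if n_tests_override is None else n_tests_override
    if n < m:
        raise ValueError(f"n_tests_override {n} is smaller than the {m} p-values supplied")
    if m == 0:
        return np.zeros(0, dtype=bool), 0.0
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    crit = (np.arange(1, m + 1) * alpha) / n
    below = np.nonzero(sorted_p <= crit)[0]
    if below.size == 0:
        return np.zeros(m, dtype=bool), 0.0
    k = below[-1] + 1
    threshold = k * alpha / n
    return p <= sorted_p[k - 1], float(threshold)


def enrichment_scan(
    genotypes: CohortGenotypes,
    reference: ReferenceFrequencyTable,
    config: TestingConfig = TestingConfig(),
) -> tuple[pd.DataFrame, float]:
    """Run the full per-variant enrichment stage.

    Computes cohort tested-allele frequencies (orientation from the
    reference table), applies the MAF filter with whitelist, chi-squared
    tests every retained variant against reconstructed reference counts, and
    applies BH.  Returns (results, bh_threshold); results is indexed by
    variant key with columns rsid, tested_allele, cohort_count, cohort_an,
    cohort_freq, ref_freq, ref_an, chi2_stat, p_value, direction,
    raw_significant, bh_significant, passed_maf_filter, whitelisted.
    """
    cohort = cohort_frequency_table(genotypes, reference)
    dropped = set(genotypes.variants.index) - set(cohort.index)
    if dropped:
        warnings.warn(
            f"{len(dropped)} variant(s) absent from the reference table or fully "
            "missing were excluded from testing",
            stacklevel=2,
        )
    threshold = (
        float(min_detectable_frequency(genotypes.n_samples))
        if config.maf_threshold is None
        else config.maf_threshold
    )
    flags = maf_filter(reference, threshold, config.whitelist)
    joined = cohort.join(reference.table[["ref_freq", "ref_an"]]).join(flags)
    keep = joined["passed"] | joined["whitelisted"]
    res = joined.loc[keep].copy()

    stats_out = np.empty(len(res))
    p_out = np.empty(len(res))
    for i, (_, row) in enumerate(res.iterrows()):
        ref_an = int(row["ref_an"]) if row["ref_an"] > 0 else config.ref_an_default
        c = reconstruct_counts(float(row["ref_freq"]), ref_an)
        table = ContingencyTable2x2(
            int(row["cohort_count"]),
            int(row["cohort_an"]) - int(row["cohort_count"]),
            c,
            ref_an - c,
        )
        stats_out[i], p_out[i] = chi_square_allele_test(table, config.use_yates)
    res["chi2_stat"] = stats_out
    res["p_value"] = p_out
    diff = res["cohort_freq"] - res["ref_freq"]
    res["direction"] = np.select([diff > 0, diff < 0], ["enriched", "depleted"], "equal")
    res["raw_significant"] = res["p_value"] <= config.alpha
    reject, bh_threshold = benjamini_hochberg(
        res["p_value"].to_numpy(), config.alpha, config.n_tests_override
    )
    res["bh_significant"] = reject
    res = res.rename(columns={"passed": "passed_maf_filter"})
    return res, bh_threshold
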