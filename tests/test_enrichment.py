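"""Chi-squared allele test, count reconstruction, MAF filter, and BH."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import fasdvar as fv
from fasdvar.enrichment import ContingencyTable2x2


def brute_force_chi2(a, b, c, d):
    """Independent Pearson oracle: sum of (O - E)^2 / E over the four cells."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    return float(((obs - exp) ** 2 / exp).sum())


def brute_force_bh(p, alpha, n):
    """Independent step-up oracle: check every rank k explicitly."""
    p = np.asarray(p, float)
    order = np.argsort(p, kind="stable")
    best_k = 0
    for k in range(1, len(p) + 1):
        if p[order[k - 1]] <= k * alpha / n:
            best_k = k
    if best_k == 0:
        return np.zeros(len(p), dtype=bool), 0.0
    return p <= p[order[best_k - 1]], best_k * alpha / n


def random_tables(n, seed, low=1, high=300):
    rng = np.random.default_rng(seed)
    while n:
        a, b, c, d = rng.integers(low, high, size=4)
        if (a + c) and (b + d):
            n -= 1
            yield int(a), int(b), int(c), int(d)


class TestReconstructCounts:
    @pytest.mark.parametrize(
        "freq,an,expected",
        [(0.96, 46, 44), (0.0, 46, 0), (0.82, 5008, 4107), (0.5, 1, 1), (1.0, 46, 46)],
    )
    def test_values(self, freq, an, expected):
        assert fv.reconstruct_counts(freq, an) == expected

    def test_bounds(self):
        with pytest.raises(ValueError):
            fv.reconstruct_counts(1.2, 46)


class TestChiSquare:
    def test_identical_proportions(self):
        assert fv.chi_square_allele_test(ContingencyTable2x2(10, 10, 100, 100)) == (0.0, 1.0)

    def test_zero_column_margin(self):
        stat, p = fv.chi_square_allele_test(ContingencyTable2x2(0, 20, 0, 200))
        assert (stat, p) == (0.0, 1.0)

    def test_cohort_44_of_46_vs_reference_082(self):
        # counts reconstructed from cohort frequency 0.96 and reference 0.82
        table = ContingencyTable2x2(44, 2, 4107, 901)
        stat, p = fv.chi_square_allele_test(table)
        assert stat == pytest.approx(brute_force_chi2(44, 2, 4107, 901), abs=1e-10)
        assert stat == pytest.approx(5.78, abs=0.01)
        assert p == pytest.approx(0.0162, abs=5e-4)

    def test_yates_matches_scipy(self):
        for a, b, c, d in random_tables(50, seed=3):
            stat, p = fv.chi_square_allele_test(ContingencyTable2x2(a, b, c, d), use_yates=True)
            ref_stat, ref_p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=True)
            assert stat == pytest.approx(ref_stat, abs=1e-10)
            assert p == pytest.approx(ref_p, abs=1e-12)

    def test_oracle_equivalence_and_symmetry(self):
        for a, b, c, d in random_tables(500, seed=4):
            stat, p = fv.chi_square_allele_test(ContingencyTable2x2(a, b, c, d))
            assert stat == pytest.approx(brute_force_chi2(a, b, c, d), abs=1e-10)
            # swapping cohort and reference rows changes nothing
            swapped, _ = fv.chi_square_allele_test(ContingencyTable2x2(c, d, a, b))
            assert stat == pytest.approx(swapped, abs=1e-10)

    def test_matches_two_proportion_z_squared(self):
        for a, b, c, d in random_tables(200, seed=5):
            n1, n2 = a + b, c + d
            p1, p2 = a / n1, c / n2
            pool = (a + c) / (n1 + n2)
            if pool in (0.0, 1.0):
                continue
            z2 = (p1 - p2) ** 2 / (pool * (1 - pool) * (1 / n1 + 1 / n2))
            stat, _ = fv.chi_square_allele_test(ContingencyTable2x2(a, b, c, d))
            assert stat == pytest.approx(z2, rel=1e-10)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestMafFilter:
    def _reference(self, freqs):
        import pandas as pd

        rows = {
            f"chr1:{100 + i}:A:G": f for i, f in enumerate(freqs)
        }
        df = pd.DataFrame(
            {
                "rsid": [f"rs{i}" for i in range(len(freqs))],
                "chrom": "chr1",
                "pos": [100 + i for i in range(len(freqs))],
                "ref": "A",
                "alt": "G",
                "tested_allele": "G",
                "ref_freq": list(rows.values()),
                "ref_an": 5008,
            },
            index=list(rows),
        )
        return fv.ReferenceFrequencyTable(df)

    def test_threshold_and_whitelist(self):
        ref = self._reference([0.05, 0.01, 0.01, 0.99])
        flags = fv.maf_filter(ref, threshold=0.0217, whitelist={"chr1:102:A:G"})
        assert flags["passed"].tolist() == [True, False, False, False]
        assert flags["whitelisted"].tolist() == [False, False, True, False]
        # high-frequency tested allele has a rare *minor* allele: filtered out
        assert not flags.loc["chr1:103:A:G", "passed"]

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            fv.maf_filter(self._reference([0.5]), threshold=0.0)


class TestBenjaminiHochberg:
    def test_all_ones(self):
        reject, threshold = fv.benjamini_hochberg([1.0, 1.0, 1.0], alpha=0.05)
        assert not reject.any() and threshold == 0.0

    def test_paper_convention_threshold(self):
        # with alpha 0.05 and a fixed n of 1100, k rejections put the
        # threshold at k * 0.05 / 1100; k = 528 gives 0.024
        rng = np.random.default_rng(0)
        p = np.concatenate([rng.uniform(1e-6, 0.02, 528), rng.uniform(0.5, 1.0, 100)])
        reject, threshold = fv.benjamini_hochberg(p, alpha=0.05, n_tests_override=1100)
        assert reject.sum() == 528
        assert threshold == pytest.approx(528 * 0.05 / 1100)
        assert threshold == pytest.approx(0.024)

    def test_override_smaller_than_count_rejected(self):
        with pytest.raises(ValueError):
            fv.benjamini_hochberg([0.1, 0.2], alpha=0.05, n_tests_override=1)

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(1, 100)
        p = rng.uniform(1e-8, 1.0, m)
        override = None if seed % 2 else int(m + rng.integers(0, 1000))
        n = m if override is None else override
        reject, threshold = fv.benjamini_hochberg(p, 0.05, override)
        exp_reject, exp_threshold = brute_force_bh(p, 0.05, n)
        assert (reject == exp_reject).all()
        assert threshold == pytest.approx(exp_threshold)

    def test_matches_statsmodels_without_override(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.uniform(1e-8, 1.0, rng.integers(2, 200))
            reject, _ = fv.benjamini_hochberg(p, 0.05)
            sm_reject = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert (reject == sm_reject).all()

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40),
        st.floats(0.01, 0.2),
        st.floats(0.2, 0.5),
    )
    def test_monotone_in_alpha_and_bounded(self, p, alpha_lo, alpha_hi):
        """Rejections grow with alpha; every rejected p <= threshold <= alpha."""
        r_lo, t_lo = fv.benjamini_hochberg(p, alpha_lo)
        r_hi, t_hi = fv.benjamini_hochberg(p, alpha_hi)
        assert r_lo.sum() <= r_hi.sum()
        assert (~r_lo | r_hi).all()  # rejected at low alpha => rejected at high
        for reject, threshold, alpha in ((r_lo, t_lo, alpha_lo), (r_hi, t_hi, alpha_hi)):
            assert threshold <= alpha + 1e-12
            assert all(pv <= threshold + 1e-12 for pv, r in zip(p, reject) if r)


class TestEnrichmentScan:
    def test_scan_on_tiny_cohort(self, tiny_files):
        geno, _ = fv.read_vcf(tiny_files["cohort"], tiny_files["samples"])
        ref = fv.read_reference_frequencies(tiny_files["reference"])
        res, threshold = fv.enrichment_scan(geno, ref, fv.TestingConfig(maf_threshold=0.0217))
        # chr1:300:G:A is absent from the reference: excluded
        assert "chr1:300:G:A" not in res.index
        # rs1: cohort 3/4 = 0.75 vs ref 0.82 -> depleted
        row = res.loc["chr1:100:A:G"]
        assert row["cohort_count"] == 3 and row["cohort_an"] == 4
        assert row["direction"] == "depleted"
        exp = brute_force_chi2_cell(3, 1, fv.reconstruct_counts(0.82, 5008), 5008)
        assert row["chi2_stat"] == pytest.approx(exp, abs=1e-10)

    def test_direction_labels(self, tiny_files):
        geno, _ = fv.read_vcf(tiny_files["cohort"], tiny_files["samples"])
        ref = fv.read_reference_frequencies(tiny_files["reference"])
        res, _ = fv.enrichment_scan(geno, ref, fv.TestingConfig(maf_threshold=0.0217))
        # rs2 C allele: cohort 1/6 ~ 0.167 vs 0.05 -> enriched
        assert res.loc["chr1:200:A:C", "direction"] == "enriched"


def brute_force_chi2_cell(a, b, c_count, ref_an):
    return brute_force_chi2(a, b, c_count, ref_an - c_count)
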