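import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2

from icld.composite_ld import (
    GenotypeCrossTab,
    LDScanConfig,
    combine_pvalues,
    cross_tab,
    exact_pvalue_positive,
    carrier_table,
    pair_stats,
    scan_pairs,
    sigma_ab,
    t2_pvalue,
    t2_stat,
)
from icld.genotype_io import MISSING
from icld.synthetic_data import BatchSimConfig, simulate_genotypes


def oracle_sigma_ab(tab: GenotypeCrossTab) -> float:
    """Independent gamete-count oracle: per-genotype expected AB gametes.

    A sample with gA copies of the minor allele at locus A and gB at locus B
    contributes: gB if gA == 2, 0 if gA == 0, and for gA == 1 either gB == 2
    -> 1, gB == 0 -> 0, or the phase-ambiguous double heterozygote, which
    contributes 1/2 under equal weighting of the two phasings.
    """
    total = 0.0
    for i in range(3):  # row 0 = 2 minor alleles at A
        for j in range(3):
            ga, gb = 2 - i, 2 - j
            if ga == 2:
                w = gb
            elif ga == 0:
                w = 0.0
            elif gb == 2:
                w = 1.0
            elif gb == 0:
                w = 0.0
            else:
                w = 0.5
            total += w * tab.counts[i, j]
    return total


def random_tables(n_tables, n_max=30, seed=0):
    rng = np.random.default_rng(seed)
    for _ in range(n_tables):
        counts = rng.multinomial(rng.integers(1, n_max), np.full(9, 1 / 9)).reshape(3, 3)
        yield GenotypeCrossTab(counts)


class TestCrossTab:
    def test_double_homozygote(self):
        tab = cross_tab(np.array([2, 2]), np.array([2, 2]))
        assert tab.counts[0, 0] == 2 and tab.n == 2

    def test_double_het(self):
        tab = cross_tab(np.array([1]), np.array([1]))
        assert tab.counts[1, 1] == 1

    def test_pairwise_deletion(self):
        tab = cross_tab(np.array([2, MISSING]), np.array([2, 2]))
        assert tab.counts[0, 0] == 1 and tab.n == 1

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cross_tab(np.array([1, 2]), np.array([1]))


class TestSigmaAB:
    def test_eq1_arithmetic(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 0], counts[0, 1], counts[1, 0], counts[1, 1] = 1, 2, 0, 4
        assert sigma_ab(GenotypeCrossTab(counts)) == 6.0

    def test_all_double_het(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[1, 1] = 10
        assert sigma_ab(GenotypeCrossTab(counts)) == 5.0

    def test_repulsion_only(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 2] = 4
        assert sigma_ab(GenotypeCrossTab(counts)) == 0.0

    def test_matches_oracle_on_random_tables(self):
        for tab in random_tables(300, seed=1):
            assert sigma_ab(tab) == oracle_sigma_ab(tab)


class TestPairStats:
    def test_independence(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[1, 1] = 10
        st_ = pair_stats(GenotypeCrossTab(counts))
        assert st_.sigma_ab == 5.0
        assert st_.p_a == st_.p_b == 0.5
        assert st_.d_ab == pytest.approx(0.0)

    def test_maximal_coupling(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 0] = counts[2, 2] = 5
        st_ = pair_stats(GenotypeCrossTab(counts))
        assert st_.sigma_ab == 10.0
        assert st_.d_ab == pytest.approx(0.5)

    def test_maximal_repulsion(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 2] = counts[2, 0] = 5
        st_ = pair_stats(GenotypeCrossTab(counts))
        assert st_.sigma_ab == 0.0
        assert st_.d_ab == pytest.approx(-0.5)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            pair_stats(GenotypeCrossTab(np.zeros((3, 3), dtype=int)))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_antisymmetry_under_one_locus_swap(self, seed):
        rng = np.random.default_rng(seed)
        ga = rng.integers(0, 3, size=25)
        gb = rng.integers(0, 3, size=25)
        d = pair_stats(cross_tab(ga, gb)).d_ab
        d_swapped = pair_stats(cross_tab(ga, 2 - gb)).d_ab
        assert d_swapped == pytest.approx(-d, abs=1e-12)


class TestT2:
    def test_zero_d_gives_p_one(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[1, 1] = 10
        assert t2_pvalue(GenotypeCrossTab(counts)) == pytest.approx(1.0)

    def test_maximal_coupling_value(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 0] = counts[2, 2] = 5
        tab = GenotypeCrossTab(counts)
        assert t2_stat(tab) == pytest.approx(10.0)
        assert t2_pvalue(tab) == pytest.approx(float(chi2.sf(10.0, 1)), rel=1e-12)

    def test_n_scaling(self):
        counts = np.array([[3, 2, 1], [2, 4, 1], [1, 1, 3]])
        t_single = t2_stat(GenotypeCrossTab(counts))
        t_double = t2_stat(GenotypeCrossTab(2 * counts))
        assert t_double == pytest.approx(2 * t_single)

    def test_degenerate_table(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 0] = 5  # monomorphic at both loci
        assert t2_pvalue(GenotypeCrossTab(counts)) == 1.0


def oracle_exact_positive(k, n_a, n_b, n):
    """Full hypergeometric enumeration of the positive tail."""
    total = math.comb(n, n_b)  # all ways to place the n_b B-carriers
    acc = 0
    for kk in range(k, min(n_a, n_b) + 1):
        if n - n_a >= n_b - kk >= 0:
            acc += math.comb(n_a, kk) * math.comb(n - n_a, n_b - kk)
    return acc / total


class TestExactPositive:
    def test_diagonal_table(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 0] = counts[2, 2] = 5
        p = exact_pvalue_positive(GenotypeCrossTab(counts))
        assert p == pytest.approx(1 / math.comb(10, 5), rel=1e-12)

    def test_independent_margins(self):
        counts = np.array([[2, 3, 5], [3, 2, 5], [5, 5, 10]])
        tab = GenotypeCrossTab(counts)
        k, n_a, n_b, n = carrier_table(tab)
        assert exact_pvalue_positive(tab) >= 0.5

    def test_zero_double_carriers(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 2] = counts[2, 0] = 5
        assert exact_pvalue_positive(GenotypeCrossTab(counts)) == pytest.approx(1.0)

    def test_degenerate_margin(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 0] = 4  # every sample carries both
        assert exact_pvalue_positive(GenotypeCrossTab(counts)) == 1.0

    def test_matches_enumeration_oracle(self):
        for tab in random_tables(200, seed=2):
            if tab.n == 0:
                continue
            k, n_a, n_b, n = carrier_table(tab)
            expected = 1.0 if n_a in (0, n) or n_b in (0, n) else oracle_exact_positive(k, n_a, n_b, n)
            assert exact_pvalue_positive(tab) == pytest.approx(expected, abs=1e-12)

    def test_calibration_on_independent_genotypes(self):
        rng = np.random.default_rng(3)
        hits = 0
        n_pairs = 2000
        for _ in range(n_pairs):
            ga = rng.binomial(2, 0.2, size=80)
            gb = rng.binomial(2, 0.2, size=80)
            if exact_pvalue_positive(cross_tab(ga, gb)) < 0.05:
                hits += 1
        assert hits / n_pairs <= 0.05 + 0.01


class TestCombinePvalues:
    def test_all_ones(self):
        assert combine_pvalues([1.0, 1.0]) == pytest.approx(1.0)

    def test_halves(self):
        # -2*(ln .5 + ln .5) = 2.7726, chi2 sf with 4 df
        assert combine_pvalues([0.5, 0.5]) == pytest.approx(0.5966, abs=2e-4)

    def test_single_identity(self):
        for p in (0.01, 0.2, 0.73, 1.0):
            assert combine_pvalues([p]) == pytest.approx(p, rel=1e-9)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            combine_pvalues([])


class TestScanPairs:
    def test_single_chromosome_error(self, clean_small):
        single = clean_small.subset_variants(
            clean_small.variants["chrom"].to_numpy() == "chr1"
        )
        with pytest.raises(ValueError):
            scan_pairs(single)

    def test_pair_count(self):
        cfg = BatchSimConfig(n_individuals=30, n_variants=20, n_chromosomes=2, seed=2)
        m = simulate_genotypes(cfg)
        res = scan_pairs(m)
        assert len(res.table) == 100

    def test_exact_only_below_threshold(self, clean_small):
        res = scan_pairs(clean_small)
        t = res.table
        has_exact = ~t["p_exact"].isna()
        assert (t.loc[has_exact, "p_approx"] < res.exact_threshold).all()
        assert (t.loc[~has_exact, "p_combined"] == t.loc[~has_exact, "p_approx"]).all()

    def test_vectorized_matches_per_table_stats(self, two_pop_matrix):
        res = scan_pairs(two_pop_matrix, LDScanConfig(min_samples=2))
        t = res.table
        pops = two_pop_matrix.pop_indices()
        for _, row in t.iloc[:20].iterrows():
            stats = []
            for pop, rows in pops.items():
                tab = cross_tab(
                    two_pop_matrix.genotypes[rows, int(row.a_idx)],
                    two_pop_matrix.genotypes[rows, int(row.b_idx)],
                )
                if tab.n < 2:
                    continue
                ps = pair_stats(tab)
                d_a = tab.counts[0, :].sum() / tab.n - ps.p_a**2
                d_b = tab.counts[:, 0].sum() / tab.n - ps.p_b**2
                denom = (ps.p_a * (1 - ps.p_a) + d_a) * (ps.p_b * (1 - ps.p_b) + d_b)
                if denom <= 1e-12:
                    continue  # scan treats the pair as untestable in this pop
                stats.append(t2_pvalue(tab))
            expected = combine_pvalues(stats)
            assert row.p_approx == pytest.approx(expected, rel=1e-6, abs=1e-12)

    def test_max_pairs_subsampling_deterministic(self, clean_small):
        cfg = LDScanConfig(max_pairs=50, seed=9)
        r1 = scan_pairs(clean_small, cfg)
        r2 = scan_pairs(clean_small, cfg)
        assert len(r1.table) <= 50
        assert r1.table.equals(r2.table)
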