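import numpy as np
import pandas as pd
import pytest

from poolscan.snp_parallelism import (
    bootstrap_mean_r_test,
    chisq_bin_test,
    contig_correlations,
    correlation_test,
    ecotype_allele_diff,
)

from conftest import make_snp_table


class TestEcotypeAlleleDiff:
    def test_replicate_averaged_difference(self, design):
        freqs = np.full((1, 12), 0.5)
        freqs[0, 0:2] = 0.9   # SP crab replicates
        freqs[0, 2:4] = 0.1   # SP wave replicates
        table = make_snp_table(freqs, contigs=["c"])
        d = ecotype_allele_diff(table, design, "SP")
        assert d[0] == pytest.approx(0.8)
        assert ecotype_allele_diff(table, design, "SW")[0] == pytest.approx(0.0)

    def test_polarisation_flip_negates_difference(self, design, rng):
        freqs = rng.integers(0, 21, size=(10, 12)) / 20
        table = make_snp_table(freqs, contigs=[f"c{i}" for i in range(10)])
        flipped = make_snp_table(1 - freqs, contigs=[f"c{i}" for i in range(10)])
        d = ecotype_allele_diff(table, design, "UK")
        assert np.allclose(ecotype_allele_diff(flipped, design, "UK"), -d)


def _table_with_contig_sizes(sizes):
    total = sum(sizes)
    contigs = [f"c{i}" for i, k in enumerate(sizes) for _ in range(k)]
    return make_snp_table(np.full((total, 2), 0.5), contigs=contigs)


class TestContigCorrelations:
    def test_proportional_vectors_give_unit_correlation(self):
        table = _table_with_contig_sizes([3])
        frame, _ = contig_correlations(table, np.array([0.1, 0.2, 0.3]), np.array([0.05, 0.1, 0.15]))
        assert frame["r"].iloc[0] == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self):
        table = _table_with_contig_sizes([3])
        d = np.array([0.1, 0.2, 0.3])
        frame, _ = contig_correlations(table, d, -d)
        assert frame["r"].iloc[0] == pytest.approx(-1.0)

    def test_constant_vector_is_excluded_and_counted(self):
        table = _table_with_contig_sizes([3])
        frame, excluded = contig_correlations(
            table, np.array([0.2, 0.2, 0.2]), np.array([0.1, 0.2, 0.3])
        )
        assert len(frame) == 0
        assert excluded["zero_variance"] == 1

    def test_contigs_with_two_snps_are_excluded(self):
        table = _table_with_contig_sizes([2, 3])
        d = np.array([0.1, 0.3, 0.1, 0.2, 0.35])
        frame, excluded = contig_correlations(table, d, d + 0.01 * np.arange(5))
        assert list(frame["contig"]) == ["c1"]
        assert excluded["too_few_snps"] == 1

    def test_joint_polarisation_flip_is_invariant_single_flip_negates(self, rng):
        sizes = [3, 5, 4, 8]
        table = _table_with_contig_sizes(sizes)
        d_a = rng.normal(size=sum(sizes))
        d_b = rng.normal(size=sum(sizes))
        base, _ = contig_correlations(table, d_a, d_b)
        joint, _ = contig_correlations(table, -d_a, -d_b)
        single, _ = contig_correlations(table, -d_a, d_b)
        assert np.allclose(joint["r"], base["r"])
        assert np.allclose(single["r"], -base["r"])

    def test_three_snp_noise_contigs_produce_extreme_r_often(self, rng):
        # with only 3 SNPs, |r| near 1 arises by chance at a high rate;
        # permutation oracle: same pairs, many more SNPs -> rare
        n = 2000
        small = _table_with_contig_sizes([3] * n)
        big = _table_with_contig_sizes([12] * (n // 4))
        r_small, _ = contig_correlations(small, rng.normal(size=3 * n), rng.normal(size=3 * n))
        r_big, _ = contig_correlations(big, rng.normal(size=3 * n), rng.normal(size=3 * n))
        rate_small = np.mean(np.abs(r_small["r"]) > 0.9)
        rate_big = np.mean(np.abs(r_big["r"]) > 0.9)
        assert rate_small > 5 * max(rate_big, 1e-3)


class TestBootstrapMeanRTest:
    def test_self_comparison_is_not_significant(self, rng):
        rs = rng.normal(size=200)
        p = bootstrap_mean_r_test(rs, rs, B=2000, rng=rng)
        assert p > 0.5

    def test_extreme_shift_is_significant(self, rng):
        all_rs = rng.normal(0, 0.5, size=2000).clip(-1, 1)
        outliers = np.ones(30)
        assert bootstrap_mean_r_test(outliers, all_rs, B=10_000, rng=rng) <= 0.01

    def test_null_pvalues_roughly_uniform(self):
        from scipy import stats as sps
        rng = np.random.default_rng(5)
        all_rs = rng.normal(0, 0.5, size=3000).clip(-1, 1)
        ps = [
            bootstrap_mean_r_test(rng.choice(all_rs, 25, replace=False), all_rs, B=500, rng=rng)
            for _ in range(400)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_small_b_warns(self, rng):
        with pytest.warns(UserWarning, match="B=50"):
            bootstrap_mean_r_test(np.array([0.5]), rng.normal(size=100), B=50, rng=rng)

    def test_empty_outlier_set_is_an_error(self, rng):
        with pytest.raises(ValueError, match="empty outlier set"):
            bootstrap_mean_r_test(np.array([]), rng.normal(size=100), rng=rng)


class TestChisqBinTest:
    def test_identical_distributions_give_zero_statistic(self, rng):
        all_rs = np.concatenate([np.full(40, v) for v in (-0.75, -0.25, 0.25, 0.75)])
        stat, df, p = chisq_bin_test(all_rs, all_rs)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_oracle_all_outliers_in_one_bin(self):
        # uniform all-contig proportions over 4 bins, n outliers all in bin 1:
        # chi2 = sum over bins of (obs - n/4)^2 / (n/4) = n * 3
        n = 40
        all_rs = np.concatenate([np.full(100, v) for v in (-0.75, -0.25, 0.25, 0.75)])
        outliers = np.full(n, -0.75)
        stat, df, p = chisq_bin_test(outliers, all_rs)
        assert stat == pytest.approx(n * 3)
        assert df == 3

    def test_small_expected_bins_are_merged(self):
        # tails hold 2% of mass -> expected < 5 with 100 outliers -> merged
        rng = np.random.default_rng(0)
        all_rs = rng.normal(0, 0.25, size=5000).clip(-1, 1)
        outliers = rng.choice(all_rs, 100, replace=False)
        stat, df, p = chisq_bin_test(outliers, all_rs)
        assert df < 3

    def test_degenerate_binning_reports_missing(self):
        all_rs = np.full(50, 0.25)  # everything in one bin
        assert chisq_bin_test(np.full(3, 0.25), all_rs) is None

    def test_bad_edges_rejected(self, rng):
        with pytest.raises(ValueError, match="edges"):
            chisq_bin_test(rng.normal(size=10), rng.normal(size=10), bin_edges=(-1, 0.5, 0.2, 1))


class TestCorrelationTest:
    def test_summary_fields_are_consistent(self, rng):
        frame = pd.DataFrame(
            {
                "contig": [f"c{i}" for i in range(100)],
                "n_snps": 4,
                "r": rng.uniform(-1, 1, size=100),
            }
        )
        outliers = frozenset(f"c{i}" for i in range(10))
        result = correlation_test(frame, outliers, "SP-SW", 0.94, B=500, rng=rng)
        assert result.n_outlier_contigs == 10
        assert result.n_all_contigs == 100
        assert sum(result.bin_counts_all) == 100
        assert sum(result.bin_counts_outliers) == 10
        assert 0 <= result.bootstrap_p <= 1

    def test_empty_outlier_set_reports_missing_tests(self, rng):
        frame = pd.DataFrame({"contig": ["c1"], "n_snps": 3, "r": [0.5]})
        result = correlation_test(frame, frozenset(), "SP-SW", 0.94, rng=rng)
        assert result.bootstrap_p is None and result.chi2_p is None
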