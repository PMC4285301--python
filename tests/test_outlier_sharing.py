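import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from poolscan.outlier_sharing import (
    OutlierSet,
    control_sharing,
    detect_outliers,
    hypergeometric_null,
    replicate_sharing,
    restrict_to_universe,
    shared_outliers,
    sharing_proportions,
    three_way_shared,
)


def _series(values, prefix="c"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


class TestDetectOutliers:
    def test_identical_replicates_give_exact_top_tail(self):
        fst = _series(np.linspace(0, 1, 100))
        out = detect_outliers(fst, fst.copy(), q=0.94)
        assert out.contigs == {f"c{i}" for i in range(94, 100)}

    def test_anti_ranked_replicates_share_nothing(self):
        fst = _series(np.linspace(0, 1, 100))
        out = detect_outliers(fst, fst.iloc[::-1].set_axis(fst.index), q=0.94)
        assert out.contigs == frozenset()

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.1, 1.5])
    def test_quantile_outside_unit_interval_rejected(self, q):
        fst = _series(np.linspace(0, 1, 10))
        with pytest.raises(ValueError, match="quantile"):
            detect_outliers(fst, fst, q)

    def test_raising_quantile_never_adds_contigs(self, rng):
        rep1 = _series(rng.random(500))
        rep2 = _series(rng.random(500))
        previous = None
        for q in (0.94, 0.95, 0.96, 0.97, 0.98):
            out = detect_outliers(rep1, rep2, q)
            if previous is not None:
                assert out.contigs <= previous
            previous = out.contigs

    def test_replicate_consistency_shrinks_below_marginal_tail(self, rng):
        # independent replicates: P(both in top 6%) ~ 0.06^2 per contig
        n, q = 2000, 0.94
        hits = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            out = detect_outliers(_series(r.random(n)), _series(r.random(n)), q)
            hits.append(out.n)
        assert np.mean(hits) < (1 - q) * n / 2
        assert abs(np.mean(hits) - n * (1 - q) ** 2) < 3 * np.std(hits)

    def test_only_common_contigs_form_the_universe(self):
        rep1 = _series(np.linspace(0, 1, 50))
        rep2 = rep1.iloc[:40]
        out = detect_outliers(rep1, rep2, 0.9)
        assert len(out.universe) == 40


class TestHypergeometricNull:
    def test_full_set_overlap_is_deterministic(self):
        expected, lo, hi = hypergeometric_null(100, 100, 20)
        assert (expected, lo, hi) == (20.0, 20, 20)

    def test_empty_set_has_degenerate_interval(self):
        assert hypergeometric_null(100, 0, 20) == (0.0, 0, 0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_null(10, 11, 5)

    def test_matches_enumeration_oracle_on_grid(self):
        # brute-force the discrete CI definition from the pmf
        for N in (1, 2, 5, 20, 100, 200):
            sizes = sorted({0, 1, N // 3, N // 2, N})
            for n_a, n_b in itertools.product(sizes, sizes):
                expected, lo, hi = hypergeometric_null(N, n_a, n_b)
                ks = np.arange(0, min(n_a, n_b) + 1)
                pmf = sps.hypergeom.pmf(ks, N, n_a, n_b)
                cdf = np.cumsum(pmf)
                support = ks[pmf > 0]
                lo_oracle = max(k for k in support if (cdf[k - 1] if k > 0 else 0.0) <= 0.025)
                hi_oracle = min(k for k in support if cdf[k] >= 0.975 - 1e-12)
                assert expected == pytest.approx(n_a * n_b / N if N else 0)
                assert (lo, hi) == (lo_oracle, hi_oracle), (N, n_a, n_b)

    def test_expectation_matches_random_set_overlap(self, rng):
        # permutation oracle for E[overlap] = n_a * n_b / N
        N, n_a, n_b, draws = 100, 10, 20, 10_000
        overlaps = np.empty(draws)
        for i in range(draws):
            a = rng.choice(N, n_a, replace=False)
            b = rng.choice(N, n_b, replace=False)
            overlaps[i] = np.intersect1d(a, b).size
        expected, lo, hi = hypergeometric_null(N, n_a, n_b)
        assert expected == pytest.approx(2.0)
        assert abs(overlaps.mean() - expected) < 3 * overlaps.std() / np.sqrt(draws)
        # CI bounds agree with the empirical distribution
        assert np.mean((overlaps >= lo) & (overlaps <= hi)) > 0.94


def _outlier_set(contigs, universe, country="X", q=0.94):
    return OutlierSet(country, q, (0.0, 0.0), frozenset(contigs), frozenset(universe))


class TestSharedOutliers:
    def test_identical_sets_share_everything(self):
        universe = {f"c{i}" for i in range(50)}
        s = _outlier_set(["c1", "c2", "c3"], universe)
        shared, result = shared_outliers(s, s)
        assert shared == s.contigs
        assert result.observed_shared == 3

    def test_disjoint_sets_share_nothing(self):
        universe = {f"c{i}" for i in range(50)}
        a = _outlier_set(["c1", "c2"], universe, "A")
        b = _outlier_set(["c3", "c4"], universe, "B")
        shared, result = shared_outliers(a, b)
        assert shared == frozenset()
        assert result.observed_shared == 0
        assert result.expected_shared == pytest.approx(4 / 50)

    def test_different_universes_rejected(self):
        a = _outlier_set(["c1"], {"c1", "c2"})
        b = _outlier_set(["c1"], {"c1", "c2", "c3"})
        with pytest.raises(ValueError, match="universe"):
            shared_outliers(a, b)

    def test_restrict_to_universe_projects_members(self):
        a = _outlier_set(["c1", "c9"], {f"c{i}" for i in range(10)})
        small = frozenset({f"c{i}" for i in range(5)})
        restricted = restrict_to_universe(a, small)
        assert restricted.contigs == {"c1"}
        assert restricted.universe == small

    def test_sharing_proportions_recounted_by_hand(self):
        universe = {f"c{i}" for i in range(10)}
        a = _outlier_set(["c0", "c1", "c2", "c3"], universe, "A")
        b = _outlier_set(["c2", "c3", "c4"], universe, "B")
        shared, result = shared_outliers(a, b)
        props = sharing_proportions(result, shared)
        assert props["prop_of_a"] == pytest.approx(2 / 4)
        assert props["prop_of_b"] == pytest.approx(2 / 3)
        assert props["jaccard"] == pytest.approx(2 / 5)


class TestControlAndThreeWay:
    def test_identical_within_ecotype_tables_share_fully(self):
        fst = _series(np.linspace(0, 1, 100))
        result = control_sharing(fst, fst.copy(), q=0.94)
        assert result.observed_shared == result.n_a == result.n_b == 6

    def test_three_identical_sets_intersect_to_full_set(self):
        universe = {f"c{i}" for i in range(20)}
        s = _outlier_set(["c1", "c2"], universe)
        assert three_way_shared({"A": s, "B": s, "C": s}) == s.contigs

    def test_any_empty_set_gives_empty_intersection(self):
        universe = {f"c{i}" for i in range(20)}
        full = _outlier_set(["c1", "c2"], universe)
        empty = _outlier_set([], universe)
        assert three_way_shared({"A": full, "B": empty, "C": full}) == frozenset()

    def test_random_triple_overlap_matches_expectation(self, rng):
        # three independent 5% sets of N=7000: E[triple] = N * 0.05^3 ~ 0.875
        N, k, runs = 7000, 350, 300
        triples = []
        for _ in range(runs):
            sets = [frozenset(rng.choice(N, k, replace=False)) for _ in range(3)]
            triples.append(len(sets[0] & sets[1] & sets[2]))
        expected = N * (k / N) ** 3
        assert abs(np.mean(triples) - expected) < 4 * np.std(triples) / np.sqrt(runs)

    def test_replicate_sharing_uses_marginal_sets(self):
        universe = frozenset(f"c{i}" for i in range(100))
        s = OutlierSet(
            "SP", 0.94, (0.0, 0.0),
            frozenset({"c1"}), universe,
            marginal=(frozenset({"c1", "c2"}), frozenset({"c1", "c3"})),
        )
        result = replicate_sharing(s)
        assert result.observed_shared == 1
        assert result.n_a == result.n_b == 2
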