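import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolscan.preprocess import (
    FilterStats,
    SnpTable,
    call_snps,
    remove_deletion_sites,
    subsample_counts,
    subsample_matrix,
)
from poolscan.sync_io import SiteCounts, SyncMatrix


def _matrix(counts, contigs=None):
    counts = np.asarray(counts, dtype=np.int64)
    n = counts.shape[0]
    contigs = contigs or [f"c{i}" for i in range(n)]
    return SyncMatrix(contigs, np.arange(1, n + 1), ["A"] * n, counts)


class TestRemoveDeletionSites:
    def test_any_deletion_read_drops_the_site(self):
        counts = np.zeros((2, 12, 6), dtype=int)
        counts[:, :, 0] = 20
        counts[0, 7, 5] = 1  # one deletion-supporting read in one sample
        kept, n_dropped = remove_deletion_sites(_matrix(counts))
        assert n_dropped == 1
        assert list(kept.contig) == ["c1"]

    def test_deletion_free_sites_pass_unchanged(self):
        counts = np.zeros((3, 12, 6), dtype=int)
        counts[:, :, :4] = 5
        kept, n_dropped = remove_deletion_sites(_matrix(counts))
        assert n_dropped == 0
        assert kept.n_sites == 3

    def test_empty_stream_stays_empty(self):
        kept, n_dropped = remove_deletion_sites(_matrix(np.zeros((0, 12, 6), dtype=int)))
        assert kept.n_sites == 0 and n_dropped == 0


class TestSubsampleCounts:
    def test_single_allele_is_deterministic(self, rng):
        site = SiteCounts(a=40)
        for _ in range(5):
            out = subsample_counts(site, target=20, rng=rng)
            assert out == SiteCounts(a=20)

    def test_multinomial_mean_matches_input_frequency(self, rng):
        # E[a] = 20 * 30/40 = 15; binomial SE over 10,000 draws
        draws = np.array(
            [subsample_counts(SiteCounts(a=30, t=10), 20, rng).a for _ in range(10_000)]
        )
        se = np.sqrt(20 * 0.75 * 0.25 / 10_000)
        assert abs(draws.mean() / 20 - 0.75) < 3 * se

    def test_below_min_coverage_is_excluded_not_an_error(self, rng):
        assert subsample_counts(SiteCounts(a=5, t=5), 20, rng, min_coverage=20) is None

    def test_absent_alleles_stay_absent(self, rng):
        out = subsample_counts(SiteCounts(a=13, g=29), 20, rng)
        assert out.t == 0 and out.c == 0 and out.coverage == 20

    def test_matrix_version_drops_site_if_any_sample_low(self, rng):
        counts = np.zeros((2, 3, 6), dtype=int)
        counts[:, :, 0] = 40
        counts[1, 2, 0] = 5  # one shallow sample kills the whole site
        out, n_dropped = subsample_matrix(_matrix(counts), target=20, min_coverage=10, rng=rng)
        assert n_dropped == 1
        assert out.n_sites == 1
        assert (out.nucleotide_counts.sum(axis=2) == 20).all()

    @given(
        st.lists(st.integers(min_value=0, max_value=200), min_size=4, max_size=4).filter(
            lambda c: sum(c) >= 10
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_output_coverage_always_equals_target(self, counts):
        rng = np.random.default_rng(0)
        out = subsample_counts(SiteCounts(*counts), target=20, rng=rng)
        assert out.coverage == 20

    def test_frequency_unbiasedness_over_many_draws(self):
        # law-of-large-numbers check at a grid of input frequencies
        rng = np.random.default_rng(7)
        for a in (10, 25, 70, 199):
            site = SiteCounts(a=a, t=200 - a)
            freq = a / 200
            mean = np.mean([subsample_counts(site, 20, rng).a for _ in range(4000)]) / 20
            se = np.sqrt(freq * (1 - freq) / (20 * 4000))
            assert abs(mean - freq) < 4 * se


def _even_matrix(per_sample_counts, contigs=None):
    """Sites x samples x 4 nucleotide counts with even coverage, as post-subsampling."""
    arr = np.asarray(per_sample_counts, dtype=np.int64)
    counts = np.zeros(arr.shape[:2] + (6,), dtype=np.int64)
    counts[:, :, :4] = arr
    return _matrix(counts, contigs)


class TestCallSnps:
    def test_minor_count_at_threshold_is_retained(self, rng):
        # 12 samples x 20 coverage; totals A=216, T=24 -> exactly 10% of 240
        site = np.tile([18, 2, 0, 0], (1, 12, 1))
        table = call_snps(_even_matrix(site), min_minor_count=24, target=20, rng=rng)
        assert table.n_snps == 1
        assert table.major[0] == "A" and table.minor[0] == "T"

    def test_minor_count_below_threshold_is_dropped(self, rng):
        site = np.tile([18, 2, 0, 0], (1, 12, 1))
        site[0, 0] = [19, 1, 0, 0]  # totals 217 / 23
        table = call_snps(_even_matrix(site), min_minor_count=24, target=20, rng=rng)
        assert table.n_snps == 0

    def test_monomorphic_site_is_dropped_even_without_threshold(self, rng):
        site = np.tile([20, 0, 0, 0], (1, 12, 1))
        stats = FilterStats()
        table = call_snps(_even_matrix(site), min_minor_count=1, target=20, rng=rng, stats=stats)
        assert table.n_snps == 0
        assert stats.n_monomorphic_dropped == 1

    def test_every_polymorphic_site_emitted_at_threshold_one(self, rng):
        sites = np.zeros((10, 12, 4), dtype=int)
        sites[:, :, 0] = 20
        sites[:5, 0, 0] = 19
        sites[:5, 0, 2] = 1  # five sites carry a single C read
        table = call_snps(_even_matrix(sites), min_minor_count=1, target=20, rng=rng)
        assert table.n_snps == 5

    def test_tie_broken_in_fixed_nucleotide_order(self, rng):
        # C and G tie for minor; fixed order A<T<C<G selects C
        site = np.tile([16, 0, 2, 2], (1, 12, 1))
        table = call_snps(_even_matrix(site), min_minor_count=24, target=20, rng=rng)
        assert table.minor[0] == "C"

    def test_third_allele_reads_are_redrawn_to_target(self, rng):
        site = np.tile([14, 4, 2, 0], (1, 12, 1))  # 2 C reads per sample are third-allele
        table = call_snps(_even_matrix(site), min_minor_count=24, target=20, rng=rng)
        assert (table.counts.sum(axis=2) == 20).all()

    def test_major_minor_counts_sum_to_target_always(self, rng):
        sites = rng.multinomial(20, [0.5, 0.3, 0.15, 0.05], size=(30, 12))
        table = call_snps(_even_matrix(sites), min_minor_count=1, target=20, rng=rng)
        assert (table.counts.sum(axis=2) == 20).all()

    def test_uneven_coverage_is_rejected(self, rng):
        counts = np.zeros((1, 2, 6), dtype=int)
        counts[0, 0, 0] = 20
        counts[0, 1, 0] = 19
        with pytest.raises(ValueError, match="even coverage"):
            call_snps(_matrix(counts), rng=rng)


class TestSnpTable:
    def test_rows_are_grouped_by_contig(self):
        counts = np.full((4, 2, 2), 10, dtype=np.int64)
        table = SnpTable(
            contig=np.array(["b", "a", "b", "a"], dtype=object),
            position=np.array([1, 2, 3, 4]),
            major=np.array(list("AAAA"), dtype=object),
            minor=np.array(list("TTTT"), dtype=object),
            counts=counts,
            target=20,
        )
        assert list(table.contigs) == ["b", "a"]
        assert list(table.snps_per_contig) == [2, 2]
        assert list(table.position) == [1, 3, 2, 4]

    def test_tsv_round_trip(self, tmp_path, design, rng):
        sites = rng.multinomial(20, [0.6, 0.4, 0, 0], size=(8, 12))
        table = call_snps(_even_matrix(sites, contigs=["x"] * 4 + ["y"] * 4),
                          min_minor_count=1, target=20, rng=rng)
        path = tmp_path / "snps.tsv"
        table.write(path, design)
        back = SnpTable.read(path, target=20)
        assert np.array_equal(back.counts, table.counts)
        assert list(back.contig) == list(table.contig)
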