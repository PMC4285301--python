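"""Site filtering, coverage subsampling and SNP calling for pooled counts.

RNA-seq pools have wildly variable depth, so allele counts are normalised by
subsampling every sample at every retained site to one even target coverage
(drawing reads with replacement, i.e. a multinomial over the observed base
counts). SNPs are then called with a single minor-allele-count threshold
applied to the subsampled counts summed over all samples, which removes both
sequencing errors and uninformative near-monomorphic sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sync_io import NUCLEOTIDES, PoolDesign, SiteCounts, SyncMatrix

#: defaults: even target coverage per pool, observed-coverage floor before
#: subsampling, and minimum total minor-allele count over all samples
TARGET_COVERAGE = 20
MIN_COVERAGE = 10
MIN_MINOR_COUNT = 24


@dataclass
class FilterStats:
    """Site accounting along the filter chain (monotonically non-increasing)."""

    n_input: int = 0
    n_deletion_dropped: int = 0
    n_low_coverage_dropped: int = 0
    n_degenerate_dropped: int = 0
    n_monomorphic_dropped: int = 0
    n_below_minor_threshold: int = 0
    n_snps: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def remove_deletion_sites(matrix: SyncMatrix) -> tuple[SyncMatrix, int]:
    """Drop every site where any sample has deletion-supporting reads."""
    has_deletion = (matrix.counts[:, :, 5] > 0).any(axis=1)
    return matrix.select(~has_deletion), int(has_deletion.sum())


def subsample_counts(
    site: SiteCounts,
    target: int = TARGET_COVERAGE,
    rng: np.random.Generator | None = None,
    min_coverage: int = MIN_COVERAGE,
) -> SiteCounts | None:
    """Resample one sample's base counts to exactly ``target`` coverage.

    Draws ``target`` reads with replacement, with probabilities proportional
    to the observed A/T/C/G counts. Returns ``None`` when the observed
    coverage is below ``min_coverage`` (site excluded, not an error). N and
    deletion counts are zeroed: they never carry allele information.
    """
    if target < 1:
        raise ValueError(f"target coverage must be >= 1, got {target}")
    if rng is None:
        rng = np.random.default_rng()
    observed = np.array(site.nucleotide_counts, dtype=float)
    coverage = observed.sum()
    if coverage < min_coverage:
        return None
    drawn = rng.multinomial(target, observed / coverage)
    return SiteCounts(int(drawn[0]), int(drawn[1]), int(drawn[2]), int(drawn[3]), 0, 0)


def subsample_matrix(
    matrix: SyncMatrix,
    target: int = TARGET_COVERAGE,
    min_coverage: int = MIN_COVERAGE,
    rng: np.random.Generator | None = None,
) -> tuple[SyncMatrix, int]:
    """Vectorised :func:`subsample_counts` over all sites and samples.

    Sites where *any* sample is below ``min_coverage`` are dropped entirely,
    so every downstream stage sees one shared site set with even coverage.
    Returns the subsampled matrix and the number of sites dropped.
    """
    if rng is None:
        rng = np.random.default_rng()
    observed = matrix.nucleotide_counts
    coverage = observed.sum(axis=2)
    keep = (coverage >= min_coverage).all(axis=1)
    n_dropped = int((~keep).sum())
    kept = matrix.select(keep)
    observed = kept.nucleotide_counts.astype(float)
    totals = observed.sum(axis=2, keepdims=True)
    if kept.n_sites:
        drawn = rng.multinomial(target, observed / totals)
    else:
        drawn = np.empty((0, matrix.n_samples, 4), dtype=np.int64)
    counts = np.zeros((kept.n_sites, kept.n_samples, 6), dtype=np.int64)
    counts[:, :, :4] = drawn
    return SyncMatrix(kept.contig, kept.position, kept.ref_base, counts), n_dropped


@dataclass
class SnpTable:
    """Biallelic SNPs after subsampling, with per-sample major/minor counts.

    ``counts[s, m, 0]`` and ``counts[s, m, 1]`` are the major- and
    minor-allele counts for SNP ``s`` in sample ``m``; they sum to ``target``
    for every sample. Major/minor are defined by the grand total over all
    samples, which also fixes the reference allele used when allele-frequency
    differences are polarised across countries. SNPs are stored grouped by
    contig in input order.
    """

    contig: np.ndarray
    position: np.ndarray
    major: np.ndarray
    minor: np.ndarray
    counts: np.ndarray
    target: int

    def __post_init__(self) -> None:
        self.contig = np.asarray(self.contig, dtype=object)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        # group rows by contig (stable, first-appearance order) so per-contig
        # reductions can use contiguous slices
        codes, order = _group_order(self.contig)
        if not np.array_equal(order, np.arange(len(order))):
            self.contig = self.contig[order]
            self.position = np.asarray(self.position)[order]
            self.major = np.asarray(self.major)[order]
            self.minor = np.asarray(self.minor)[order]
            self.counts = self.counts[order]
            codes = codes[order]
        self._codes = codes
        if len(codes) == 0:
            self.group_starts = np.empty(0, dtype=np.int64)
            self.snps_per_contig = np.empty(0, dtype=np.int64)
            self.contigs = np.empty(0, dtype=object)
            return
        boundaries = np.flatnonzero(np.diff(codes)) + 1
        self.group_starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(codes)]))
        self.snps_per_contig = ends - self.group_starts
        self.contigs = self.contig[self.group_starts]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    @property
    def major_freq(self) -> np.ndarray:
        """Per-sample frequency of the (grand-total) major allele, shape (snps, samples)."""
        return self.counts[:, :, 0] / self.target

    def to_frame(self, design: PoolDesign | None = None) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "contig": self.contig,
                "position": self.position,
                "major": self.major,
                "minor": self.minor,
            }
        )
        ids = (
            [s.sample_id for s in design.samples]
            if design is not None
            else [f"sample{i + 1}" for i in range(self.n_samples)]
        )
        for m, sample_id in enumerate(ids):
            frame[f"{sample_id}_major"] = self.counts[:, m, 0]
            frame[f"{sample_id}_minor"] = self.counts[:, m, 1]
        return frame

    def write(self, path: str | Path, design: PoolDesign | None = None) -> None:
        self.to_frame(design).to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, target: int = TARGET_COVERAGE) -> "SnpTable":
        frame = pd.read_csv(path, sep="\t")
        major_cols = [c for c in frame.columns if c.endswith("_major")]
        minor_cols = [c.replace("_major", "_minor") for c in major_cols]
        counts = np.stack(
            [frame[major_cols].to_numpy(), frame[minor_cols].to_numpy()], axis=2
        )
        return cls(
            frame["contig"].to_numpy(dtype=object),
            frame["position"].to_numpy(),
            frame["major"].to_numpy(dtype=object),
            frame["minor"].to_numpy(dtype=object),
            counts,
            target,
        )


def _group_order(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First-appearance integer codes and a stable grouping permutation."""
    codes, _ = pd.factorize(values)
    codes = codes.astype(np.int64)
    return codes, np.argsort(codes, kind="stable")


def call_snps(
    matrix: SyncMatrix,
    min_minor_count: int = MIN_MINOR_COUNT,
    target: int = TARGET_COVERAGE,
    rng: np.random.Generator | None = None,
    stats: FilterStats | None = None,
) -> SnpTable:
    """Identify biallelic SNPs from evenly subsampled counts.

    The two nucleotides with the highest grand totals over all samples become
    major and minor (ties broken in fixed A<T<C<G order). A site is a SNP iff
    the minor grand total is at least ``min_minor_count``; monomorphic sites
    are dropped. Residual third-allele reads in individual samples are
    removed by redrawing that sample's counts to ``target`` from a binomial
    over the two retained alleles, so every sample's major+minor counts sum
    to the target coverage exactly.
    """
    if rng is None:
        rng = np.random.default_rng()
    nuc = matrix.nucleotide_counts
    if matrix.n_sites and not (nuc.sum(axis=2) == nuc.sum(axis=2)[:, :1]).all():
        raise ValueError("call_snps expects even coverage across samples (subsample first)")
    totals = nuc.sum(axis=1)  # (sites, 4)
    order = np.argsort(-totals, axis=1, kind="stable")  # stable => A<T<C<G on ties
    major_idx = order[:, 0]
    minor_idx = order[:, 1]
    rows = np.arange(matrix.n_sites)
    total_minor = totals[rows, minor_idx]
    polymorphic = total_minor > 0
    passing = total_minor >= min_minor_count

    if stats is not None:
        stats.n_monomorphic_dropped = int((~polymorphic).sum())
        stats.n_below_minor_threshold = int((polymorphic & ~passing).sum())

    keep = passing & polymorphic
    kept = matrix.select(keep)
    major_idx, minor_idx = major_idx[keep], minor_idx[keep]
    nuc = kept.nucleotide_counts
    rows = np.arange(kept.n_sites)
    major_counts = nuc[rows[:, None], np.arange(kept.n_samples)[None, :], major_idx[:, None]]
    minor_counts = nuc[rows[:, None], np.arange(kept.n_samples)[None, :], minor_idx[:, None]]

    # third-allele reads: redraw the affected samples over the two retained alleles
    two_allele_total = major_counts + minor_counts
    degenerate = (two_allele_total == 0).any(axis=1)
    if degenerate.any():
        keep2 = ~degenerate
        kept = kept.select(keep2)
        major_idx, minor_idx = major_idx[keep2], minor_idx[keep2]
        major_counts, minor_counts = major_counts[keep2], minor_counts[keep2]
        two_allele_total = two_allele_total[keep2]
    if stats is not None:
        stats.n_degenerate_dropped = int(degenerate.sum())
    needs_redraw = two_allele_total < target
    if needs_redraw.any():
        p_major = major_counts[needs_redraw] / two_allele_total[needs_redraw]
        redrawn = rng.binomial(target, p_major)
        major_counts = major_counts.copy()
        minor_counts = minor_counts.copy()
        major_counts[needs_redraw] = redrawn
        minor_counts[needs_redraw] = target - redrawn

    counts = np.stack([major_counts, minor_counts], axis=2)
    nuc_arr = np.array(NUCLEOTIDES, dtype=object)
    table = SnpTable(
        kept.contig,
        kept.position,
        nuc_arr[major_idx],
        nuc_arr[minor_idx],
        counts,
        target,
    )
    if stats is not None:
        stats.n_snps = table.n_snps
    return table


def preprocess_matrix(
    matrix: SyncMatrix,
    target: int = TARGET_COVERAGE,
    min_coverage: int = MIN_COVERAGE,
    min_minor_count: int = MIN_MINOR_COUNT,
    rng: np.random.Generator | None = None,
) -> tuple[SnpTable, FilterStats]:
    """Full chain: deletion removal -> even-coverage subsampling -> SNP calling."""
    if rng is None:
        rng = np.random.default_rng()
    stats = FilterStats(n_input=matrix.n_sites)
    matrix, stats.n_deletion_dropped = remove_deletion_sites(matrix)
    matrix, stats.n_low_coverage_dropped = subsample_matrix(matrix, target, min_coverage, rng)
    table = call_snps(matrix, min_minor_count, target, rng, stats)
    return table, stats
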