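"""SNP-level parallelism: are shared outlier contigs driven by the same SNPs?

For each contig, the per-SNP allele-frequency difference between ecotypes
(crab minus wave, for one globally fixed reference allele) is computed in
each location and the two difference vectors are correlated. A positive
Pearson r means the same alleles track the crab ecotype in both locations;
negative r means the alleles are associated with opposite ecotypes; r near
zero means different SNPs carry the divergence. Only the overall shift of
the r distribution in shared outlier contigs, relative to all contigs, is
interpreted — individual three-SNP contigs give near-+/-1 correlations by
chance, so per-contig values are noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import SnpTable
from .sync_io import PoolDesign

MIN_SNPS_PER_CONTIG = 3
DEFAULT_BOOTSTRAP_B = 10_000
DEFAULT_BIN_EDGES = (-1.0, -0.5, 0.0, 0.5, 1.0)
_MIN_EXPECTED_PER_BIN = 5.0


def ecotype_allele_diff(table: SnpTable, design: PoolDesign, country: str) -> np.ndarray:
    """Per-SNP crab-minus-wave frequency difference in one country.

    Frequencies are of the grand-total major allele (the fixed reference
    polarisation), differenced per replicate pair and averaged over
    replicates; values lie in [-1, 1].
    """
    freq = table.major_freq
    diffs = [freq[:, i] - freq[:, j] for i, j in design.replicate_pairs(country)]
    return np.mean(diffs, axis=0)


def contig_correlations(
    table: SnpTable,
    diff_a: np.ndarray,
    diff_b: np.ndarray,
    min_snps: int = MIN_SNPS_PER_CONTIG,
) -> tuple[pd.DataFrame, dict]:
    """Per-contig Pearson r between two per-SNP difference vectors.

    Contigs with fewer than ``min_snps`` SNPs, or with zero variance in
    either vector, are excluded; the returned accounting dict reports both
    exclusions so reported n always matches the included contig count.
    """
    diff_a = np.asarray(diff_a, dtype=float)
    diff_b = np.asarray(diff_b, dtype=float)
    starts = table.group_starts
    n = table.snps_per_contig.astype(float)
    sum_a = np.add.reduceat(diff_a, starts)
    sum_b = np.add.reduceat(diff_b, starts)
    sum_aa = np.add.reduceat(diff_a * diff_a, starts)
    sum_bb = np.add.reduceat(diff_b * diff_b, starts)
    sum_ab = np.add.reduceat(diff_a * diff_b, starts)
    var_a = n * sum_aa - sum_a**2
    var_b = n * sum_bb - sum_b**2
    cov = n * sum_ab - sum_a * sum_b
    enough = table.snps_per_contig >= min_snps
    # guard tiny negative variances from cancellation
    varying = (var_a > 1e-12) & (var_b > 1e-12)
    keep = enough & varying
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(var_a * var_b)
    frame = pd.DataFrame(
        {
            "contig": table.contigs[keep],
            "n_snps": table.snps_per_contig[keep],
            "r": np.clip(r[keep], -1.0, 1.0),
        }
    )
    excluded = {
        "too_few_snps": int((~enough).sum()),
        "zero_variance": int((enough & ~varying).sum()),
    }
    return frame, excluded


def bootstrap_mean_r_test(
    outlier_rs: np.ndarray,
    all_rs: np.ndarray,
    B: int = DEFAULT_BOOTSTRAP_B,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-tailed bootstrap test of mean(outlier r) against all contigs.

    Draws B with-replacement samples of the outlier-set size from the
    all-contig r values and compares |mean - mean_all| of the observed set
    with the bootstrap distribution, with +1 continuity correction:
    p = (1 + #{|mean_b - mean_all| >= |mean_obs - mean_all|}) / (B + 1).
    """
    outlier_rs = np.asarray(outlier_rs, dtype=float)
    all_rs = np.asarray(all_rs, dtype=float)
    if outlier_rs.size == 0:
        raise ValueError("empty outlier set: bootstrap test undefined")
    if B < 100:
        warnings.warn(f"bootstrap with B={B} < 100 replicates is unreliable", stacklevel=2)
    if rng is None:
        rng = np.random.default_rng()
    mean_obs = outlier_rs.mean()
    mean_all = all_rs.mean()
    idx = rng.integers(0, all_rs.size, size=(B, outlier_rs.size))
    boot_means = all_rs[idx].mean(axis=1)
    extreme = np.abs(boot_means - mean_all) >= np.abs(mean_obs - mean_all)
    return float((1 + extreme.sum()) / (B + 1))


def _merge_small_bins(observed: np.ndarray, expected: np.ndarray, edges: list) -> tuple:
    """Merge bins with expected < 5 into their smaller adjacent neighbour."""
    observed = list(observed)
    expected = list(expected)
    edges = list(edges)
    while len(expected) > 1 and min(expected) < _MIN_EXPECTED_PER_BIN:
        i = int(np.argmin(expected))
        if i == 0:
            j = 1
        elif i == len(expected) - 1:
            j = i - 1
        else:
            j = i - 1 if expected[i - 1] <= expected[i + 1] else i + 1
        lo, hi = min(i, j), max(i, j)
        observed[lo] += observed[hi]
        expected[lo] += expected[hi]
        del observed[hi], expected[hi], edges[hi]
    return np.array(observed), np.array(expected), edges


def chisq_bin_test(
    outlier_rs: np.ndarray,
    all_rs: np.ndarray,
    bin_edges: tuple = DEFAULT_BIN_EDGES,
) -> tuple[float, int, float] | None:
    """Chi-square test of the binned outlier r distribution vs all contigs.

    Expected outlier counts per bin are the all-contig bin proportions times
    the outlier-set size; bins with expected < 5 are merged with their
    smaller adjacent neighbour before computing the statistic
    (df = #bins - 1). Returns None if fewer than 2 bins survive merging.
    """
    outlier_rs = np.asarray(outlier_rs, dtype=float)
    all_rs = np.asarray(all_rs, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    if edges[0] != -1.0 or edges[-1] != 1.0 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must increase from -1 to 1")
    observed, _ = np.histogram(outlier_rs, bins=edges)
    all_counts, _ = np.histogram(all_rs, bins=edges)
    proportions = all_counts / all_counts.sum()
    expected = outlier_rs.size * proportions
    observed, expected, _ = _merge_small_bins(observed, expected, list(edges))
    if len(observed) < 2:
        return None
    stat = float(((observed - expected) ** 2 / expected).sum())
    df = len(observed) - 1
    return stat, df, float(sps.chi2.sf(stat, df))


@dataclass
class CorrelationTestResult:
    """Summary of the SNP-parallelism tests for one country pair x quantile."""

    country_pair: str
    q: float
    n_outlier_contigs: int
    n_all_contigs: int
    mean_r_outliers: float
    mean_r_all: float
    bootstrap_p: float | None
    chi2_stat: float | None
    chi2_df: int | None
    chi2_p: float | None
    bin_edges: tuple
    bin_counts_outliers: tuple
    bin_counts_all: tuple
    excluded: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def correlation_test(
    correlations: pd.DataFrame,
    outlier_contigs: frozenset,
    country_pair: str,
    q: float,
    B: int = DEFAULT_BOOTSTRAP_B,
    bin_edges: tuple = DEFAULT_BIN_EDGES,
    rng: np.random.Generator | None = None,
    excluded: dict | None = None,
) -> CorrelationTestResult:
    """Run bootstrap and chi-square tests of shared-outlier r values vs all."""
    all_rs = correlations["r"].to_numpy()
    mask = correlations["contig"].isin(outlier_contigs).to_numpy()
    outlier_rs = all_rs[mask]
    bootstrap_p = None
    chi2 = None
    if outlier_rs.size:
        bootstrap_p = bootstrap_mean_r_test(outlier_rs, all_rs, B=B, rng=rng)
        chi2 = chisq_bin_test(outlier_rs, all_rs, bin_edges)
    edges = np.asarray(bin_edges, dtype=float)
    return CorrelationTestResult(
        country_pair=country_pair,
        q=q,
        n_outlier_contigs=int(outlier_rs.size),
        n_all_contigs=int(all_rs.size),
        mean_r_outliers=float(outlier_rs.mean()) if outlier_rs.size else np.nan,
        mean_r_all=float(all_rs.mean()) if all_rs.size else np.nan,
        bootstrap_p=bootstrap_p,
        chi2_stat=chi2[0] if chi2 else None,
        chi2_df=chi2[1] if chi2 else None,
        chi2_p=chi2[2] if chi2 else None,
        bin_edges=tuple(edges),
        bin_counts_outliers=tuple(int(x) for x in np.histogram(outlier_rs, bins=edges)[0]),
        bin_counts_all=tuple(int(x) for x in np.histogram(all_rs, bins=edges)[0]),
        excluded=excluded or {},
    )
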