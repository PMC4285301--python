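"""Quantile-threshold outlier contigs and cross-location sharing.

A contig is an outlier within one location only when *both* replicate
between-ecotype FST estimates fall strictly above the empirical quantile
threshold of their respective distributions — replicate consistency guards
against pool-construction and expression noise. Sharing of outliers between
locations is compared with the chance expectation for the overlap of two
fixed-size random subsets of a common contig universe, which follows a
hypergeometric distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_QUANTILES = (0.94, 0.95, 0.96, 0.97, 0.98)


@dataclass
class OutlierSet:
    """Replicate-consistent outlier contigs for one location at one quantile."""

    country: str
    q: float
    thresholds: tuple[float, ...]
    contigs: frozenset
    universe: frozenset
    #: marginal (single-replicate) outlier sets, for replicate-sharing reporting
    marginal: tuple[frozenset, ...] = field(default_factory=tuple)

    @property
    def n(self) -> int:
        return len(self.contigs)


def detect_outliers(
    fst_rep1: pd.Series,
    fst_rep2: pd.Series,
    q: float,
    country: str = "",
) -> OutlierSet:
    """Contigs strictly above the q-quantile in both replicate FST estimates.

    The two series are aligned on their contig index; only contigs with a
    defined estimate in both replicates form the universe. Each replicate's
    threshold is the empirical quantile (linear interpolation) of its own
    distribution over that universe.
    """
    if not 0 < q < 1:
        raise ValueError(f"quantile must be in (0, 1), got {q}")
    joined = pd.concat({"rep1": fst_rep1, "rep2": fst_rep2}, axis=1, join="inner").dropna()
    thresholds = tuple(float(np.quantile(joined[c].to_numpy(), q)) for c in ("rep1", "rep2"))
    above = [joined.index[joined[c] > t] for c, t in zip(("rep1", "rep2"), thresholds)]
    marginal = tuple(frozenset(a) for a in above)
    return OutlierSet(
        country=country,
        q=q,
        thresholds=thresholds,
        contigs=frozenset(marginal[0] & marginal[1]),
        universe=frozenset(joined.index),
        marginal=marginal,
    )


@dataclass
class SharingResult:
    """Observed vs chance-expected overlap of two outlier sets."""

    set_a: str
    set_b: str
    N: int
    n_a: int
    n_b: int
    observed_shared: int
    expected_shared: float
    ci_low: int
    ci_high: int

    @property
    def exceeds_chance(self) -> bool:
        return self.observed_shared > self.ci_high

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["exceeds_chance"] = self.exceeds_chance
        return d


def hypergeometric_null(N: int, n_a: int, n_b: int, alpha: float = 0.05) -> tuple[float, int, int]:
    """Chance expectation and discrete central CI for the overlap of two sets.

    The overlap K of random subsets of sizes n_a and n_b from a universe of
    N follows Hypergeometric(N, n_a, n_b): expectation n_a*n_b/N. The CI is
    [largest k with CDF(k-1) <= alpha/2, smallest k with CDF(k) >= 1-alpha/2],
    so it covers at least 1-alpha of the mass (conservative, as discrete
    intervals are).
    """
    if not (0 <= n_a <= N and 0 <= n_b <= N):
        raise ValueError(f"need 0 <= n_a, n_b <= N, got N={N}, n_a={n_a}, n_b={n_b}")
    if N == 0:
        return 0.0, 0, 0
    expected = n_a * n_b / N
    dist = sps.hypergeom(M=N, n=n_a, N=n_b)
    lo_support = max(0, n_a + n_b - N)
    hi_support = min(n_a, n_b)
    ks = np.arange(lo_support, hi_support + 1)
    cdf = dist.cdf(ks)
    # largest k with CDF(k-1) <= alpha/2; CDF(lo_support - 1) = 0 always qualifies
    cdf_below = np.concatenate(([0.0], cdf[:-1]))
    ci_low = int(ks[cdf_below <= alpha / 2][-1])
    ci_high = int(ks[cdf >= 1 - alpha / 2][0])
    return expected, ci_low, ci_high


def shared_outliers(set_a: OutlierSet, set_b: OutlierSet) -> tuple[frozenset, SharingResult]:
    """Intersection of two outlier sets plus its hypergeometric chance null.

    Both sets must come from the same contig universe; the null conditions
    on the realised set sizes.
    """
    if set_a.universe != set_b.universe:
        raise ValueError("outlier sets come from different contig universes")
    shared = set_a.contigs & set_b.contigs
    N = len(set_a.universe)
    expected, ci_low, ci_high = hypergeometric_null(N, set_a.n, set_b.n)
    result = SharingResult(
        set_a=set_a.country or "a",
        set_b=set_b.country or "b",
        N=N,
        n_a=set_a.n,
        n_b=set_b.n,
        observed_shared=len(shared),
        expected_shared=expected,
        ci_low=ci_low,
        ci_high=ci_high,
    )
    return frozenset(shared), result


def restrict_to_universe(outlier_set: OutlierSet, universe: frozenset) -> OutlierSet:
    """Project an outlier set onto a common (smaller) contig universe."""
    return OutlierSet(
        country=outlier_set.country,
        q=outlier_set.q,
        thresholds=outlier_set.thresholds,
        contigs=frozenset(outlier_set.contigs & universe),
        universe=frozenset(universe),
        marginal=tuple(frozenset(m & universe) for m in outlier_set.marginal),
    )


def replicate_sharing(outlier_set: OutlierSet) -> SharingResult:
    """Sharing between the two marginal (single-replicate) outlier sets.

    Under pure chance the two replicates' top tails would overlap like
    random subsets; strong overlap is the signature of a real, repeatable
    FST signal within the location.
    """
    m1, m2 = outlier_set.marginal
    N = len(outlier_set.universe)
    expected, ci_low, ci_high = hypergeometric_null(N, len(m1), len(m2))
    return SharingResult(
        set_a=f"{outlier_set.country}_rep1",
        set_b=f"{outlier_set.country}_rep2",
        N=N,
        n_a=len(m1),
        n_b=len(m2),
        observed_shared=len(m1 & m2),
        expected_shared=expected,
        ci_low=ci_low,
        ci_high=ci_high,
    )


def control_sharing(
    crab_fst: pd.Series,
    wave_fst: pd.Series,
    q: float,
    country: str = "",
) -> SharingResult:
    """Negative control: top-tail overlap of the two within-ecotype FST tables.

    crab1-crab2 and wave1-wave2 pairs contain no ecotype contrast, so their
    'outliers' are noise and should overlap only at chance level.
    """
    if not 0 < q < 1:
        raise ValueError(f"quantile must be in (0, 1), got {q}")
    joined = pd.concat({"crab": crab_fst, "wave": wave_fst}, axis=1, join="inner").dropna()
    sets = {}
    for col in ("crab", "wave"):
        threshold = float(np.quantile(joined[col].to_numpy(), q))
        sets[col] = frozenset(joined.index[joined[col] > threshold])
    N = len(joined)
    expected, ci_low, ci_high = hypergeometric_null(N, len(sets["crab"]), len(sets["wave"]))
    return SharingResult(
        set_a=f"{country}_crab1_crab2",
        set_b=f"{country}_wave1_wave2",
        N=N,
        n_a=len(sets["crab"]),
        n_b=len(sets["wave"]),
        observed_shared=len(sets["crab"] & sets["wave"]),
        expected_shared=expected,
        ci_low=ci_low,
        ci_high=ci_high,
    )


def three_way_shared(outlier_sets: dict) -> frozenset:
    """Contigs that are outliers in every location (triple intersection)."""
    sets = list(outlier_sets.values())
    if not sets:
        return frozenset()
    shared = sets[0].contigs
    for s in sets[1:]:
        shared = shared & s.contigs
    return frozenset(shared)


def sharing_proportions(result: SharingResult, shared: frozenset) -> dict:
    """Shared outliers as a fraction of each focal set, plus the Jaccard index."""
    union = result.n_a + result.n_b - result.observed_shared
    return {
        "prop_of_a": result.observed_shared / result.n_a if result.n_a else np.nan,
        "prop_of_b": result.observed_shared / result.n_b if result.n_b else np.nan,
        "jaccard": result.observed_shared / union if union else np.nan,
    }
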