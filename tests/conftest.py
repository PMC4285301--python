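import numpy as np
import pytest

from poolscan.preprocess import SnpTable
from poolscan.sync_io import PoolDesign, PoolSample


COUNTRIES = ("SP", "SW", "UK")


@pytest.fixture
def design() -> PoolDesign:
    """The emulated layout: three countries x two ecotypes x two replicates."""
    return PoolDesign(
        [
            PoolSample(f"{c}_{e}{r}", c, e, r)
            for c in COUNTRIES
            for e in ("crab", "wave")
            for r in (1, 2)
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_snp_table(freqs, contigs=None, target=20) -> SnpTable:
    """Build a SnpTable from per-SNP per-sample major-allele frequencies.

    ``freqs`` is (n_snps, n_samples); counts are freq*target (must be whole).
    """
    freqs = np.asarray(freqs, dtype=float)
    major = np.rint(freqs * target).astype(np.int64)
    assert np.allclose(major, freqs * target), "frequencies must be multiples of 1/target"
    counts = np.stack([major, target - major], axis=2)
    n = freqs.shape[0]
    if contigs is None:
        contigs = [f"c{i}" for i in range(n)]
    return SnpTable(
        contig=np.asarray(contigs, dtype=object),
        position=np.arange(1, n + 1),
        major=np.array(["A"] * n, dtype=object),
        minor=np.array(["T"] * n, dtype=object),
        counts=counts,
        target=target,
    )
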