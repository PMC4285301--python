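"""Synthetic pool-seq transcriptome data with a known selection truth table.

Emulates the replicated two-ecotype study design: three locations, each with
two crab and two wave pools of ~40 females, short (~660 bp) transcript
contigs carrying a handful of SNPs, RNA-seq-like overdispersed coverage, and
ecotype allele-frequency divergence at a minority of contigs. The generative
chain per SNP:

1. ancestral frequency pi ~ Beta(a, b), clamped away from fixation;
2. per-location frequency = logistic(logit(pi) + eps), eps jointly normal
   across locations (drift, optionally correlated for one location pair);
3. ecotype frequencies = location frequency +/- delta/2 according to the
   contig's selection label (complete linkage: all SNPs of a selected contig
   shift together);
4. each replicate pool draws 2 * pool_individuals allele copies binomially
   (pool composition noise);
5. site coverage ~ negative binomial per sample; reads ~ binomial(coverage,
   pool frequency), with sequencing errors redistributed uniformly over the
   other three nucleotides.

Selection labels: ``shared_selected`` shifts every location in the same
direction; ``country_specific:<loc>`` shifts one location only;
``sign_flipped:<a>-<b>`` shifts two designated locations in opposite
directions (the third is untouched). The truth table records the per-contig
label and signed per-location deltas — the key for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .sync_io import NUCLEOTIDES, PoolDesign, PoolSample, SyncMatrix

TRUTH_LABELS = ("neutral", "shared_selected", "country_specific", "sign_flipped")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults mirror the emulated study design."""

    n_contigs: int = 2000
    #: truncated geometric SNP count per contig: mean ~3, range 1..20
    snps_per_contig_mean: float = 3.0
    snps_per_contig_max: int = 20
    #: selected contigs carry at least this many SNPs (SNP-level tests need >2)
    min_snps_selected: int = 3
    countries: tuple = ("SP", "SW", "UK")
    replicates: tuple = (1, 2)
    pool_individuals: int = 40
    contig_length: int = 660
    ancestral_beta: tuple = (0.8, 0.8)
    #: SD of the logit-scale per-location drift perturbation
    drift_sd: float = 0.5
    #: drift correlation between ``corr_pair`` locations (shared history knob)
    country_corr: float = 0.0
    corr_pair: tuple = ("SW", "UK")
    frac_shared_selected: float = 0.05
    frac_country_specific: float = 0.05
    frac_sign_flipped: float = 0.02
    #: the opposite-direction pair (crab allele in one = wave allele in the other)
    flip_pair: tuple = ("SP", "UK")
    #: ecotype frequency shift at selected SNPs
    effect_delta: float = 0.3
    coverage_mean: float = 50.0
    #: within-contig negative-binomial shape k; variance = mean + mean^2 / k
    coverage_dispersion: float = 10.0
    #: gamma shape of the per-contig expression multiplier (mean 1) shared by
    #: all samples; None disables it. Low shape = strong between-contig
    #: depth variation, the RNA-seq signature that removes whole
    #: low-expression contigs at the coverage filter.
    expression_shape: float | None = 2.0
    error_rate: float = 0.001
    freq_clamp: tuple = (0.02, 0.98)
    seed: int | None = None

    def validate(self) -> None:
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")
        if not 1 <= self.snps_per_contig_mean <= self.snps_per_contig_max:
            raise ValueError("snps_per_contig_mean must lie in [1, snps_per_contig_max]")
        fracs = (self.frac_shared_selected, self.frac_country_specific, self.frac_sign_flipped)
        if any(f < 0 for f in fracs) or sum(fracs) > 1:
            raise ValueError("selection fractions must be >= 0 and sum to <= 1")
        if not 0 < self.effect_delta <= 0.5:
            raise ValueError("effect_delta must be in (0, 0.5]")
        if not -1 < self.country_corr < 1:
            raise ValueError("country_corr must be in (-1, 1)")
        if self.error_rate < 0 or self.error_rate >= 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage parameters must be positive")
        if self.expression_shape is not None and self.expression_shape <= 0:
            raise ValueError("expression_shape must be positive (or None)")
        for c in self.corr_pair + self.flip_pair:
            if c not in self.countries:
                raise ValueError(f"unknown country {c!r} in corr_pair/flip_pair")

    def design(self) -> PoolDesign:
        samples = [
            PoolSample(f"{country}_{ecotype}{replicate}", country, ecotype, replicate)
            for country in self.countries
            for ecotype in ("crab", "wave")
            for replicate in self.replicates
        ]
        return PoolDesign(samples)


@dataclass
class SimulatedDataset:
    matrix: SyncMatrix
    design: PoolDesign
    truth: pd.DataFrame
    #: latent per-SNP state (contig index, country/crab/wave frequencies of
    #: allele 1) — inspection and testing only, never used by the analysis
    latent: dict = field(default_factory=dict)


def _truncated_geometric(rng, p: float, size: int, low: int, high: int) -> np.ndarray:
    """Geometric draws conditioned on low <= k <= high (resampling the tail)."""
    draws = low - 1 + rng.geometric(p, size=size)
    bad = draws > high
    while bad.any():
        draws[bad] = low - 1 + rng.geometric(p, size=int(bad.sum()))
        bad = draws > high
    return draws


def _assign_labels(config: SimulationConfig, rng) -> pd.DataFrame:
    n = config.n_contigs
    n_shared = int(round(config.frac_shared_selected * n))
    n_specific = int(round(config.frac_country_specific * n))
    n_flipped = int(round(config.frac_sign_flipped * n))
    labels = np.array(["neutral"] * n, dtype=object)
    order = rng.permutation(n)
    selected = order[: n_shared + n_specific + n_flipped]
    labels[selected[:n_shared]] = "shared_selected"
    specific = selected[n_shared : n_shared + n_specific]
    for i, contig in enumerate(specific):
        country = config.countries[i % len(config.countries)]
        labels[contig] = f"country_specific:{country}"
    flip_a, flip_b = config.flip_pair
    labels[selected[n_shared + n_specific :]] = f"sign_flipped:{flip_a}-{flip_b}"
    deltas = np.zeros((n, len(config.countries)))
    for c_idx, country in enumerate(config.countries):
        is_shared = labels == "shared_selected"
        is_specific = labels == f"country_specific:{country}"
        deltas[is_shared | is_specific, c_idx] = config.effect_delta
        flipped = labels == f"sign_flipped:{flip_a}-{flip_b}"
        if country == flip_a:
            deltas[flipped, c_idx] = config.effect_delta
        elif country == flip_b:
            deltas[flipped, c_idx] = -config.effect_delta
    truth = pd.DataFrame({"contig": [f"contig{i:05d}" for i in range(n)], "label": labels})
    for c_idx, country in enumerate(config.countries):
        truth[f"delta_{country}"] = deltas[:, c_idx]
    return truth


def _drift_cholesky(config: SimulationConfig) -> np.ndarray:
    n_c = len(config.countries)
    corr = np.eye(n_c)
    if config.country_corr != 0.0:
        i = config.countries.index(config.corr_pair[0])
        j = config.countries.index(config.corr_pair[1])
        corr[i, j] = corr[j, i] = config.country_corr
    return np.linalg.cholesky(corr)


def simulate_dataset(config: SimulationConfig, rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Generate sync counts, the matching design and the truth table."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    design = config.design()
    n_countries = len(config.countries)
    lo, hi = config.freq_clamp

    truth = _assign_labels(config, rng)
    selected = (truth["label"] != "neutral").to_numpy()
    p_geom = 1.0 / config.snps_per_contig_mean
    n_snps = _truncated_geometric(rng, p_geom, config.n_contigs, 1, config.snps_per_contig_max)
    if config.min_snps_selected > 1:
        n_snps[selected] = _truncated_geometric(
            rng, p_geom, int(selected.sum()), config.min_snps_selected, config.snps_per_contig_max
        )
    truth["n_snps"] = n_snps

    S = int(n_snps.sum())
    contig_of_snp = np.repeat(np.arange(config.n_contigs), n_snps)
    # evenly spaced positions within the contig (spacing >= 31 bp at 20 SNPs)
    snp_rank = np.concatenate([np.arange(k) for k in n_snps])
    spacing = config.contig_length / (n_snps[contig_of_snp] + 1)
    positions = np.floor((snp_rank + 1) * spacing).astype(np.int64)
    positions = np.maximum(positions, 1)

    a, b = config.ancestral_beta
    pi = np.clip(rng.beta(a, b, size=S), lo, hi)
    chol = _drift_cholesky(config)
    eps = rng.standard_normal((S, n_countries)) @ chol.T * config.drift_sd
    country_freq = np.clip(expit(logit(pi)[:, None] + eps), lo, hi)

    # selected SNPs realise the full +/-delta: the ecotype pair is centred
    # inside the clamp bounds rather than truncated at them
    deltas = truth[[f"delta_{c}" for c in config.countries]].to_numpy()[contig_of_snp]
    half = np.abs(deltas) / 2.0
    centre = np.clip(country_freq, lo + half, hi - half)
    crab_freq = centre + deltas / 2.0
    wave_freq = centre - deltas / 2.0

    # per-pool population frequency after sampling 2N allele copies
    copies = 2 * config.pool_individuals
    pool_freq = np.empty((S, len(design)))
    for m, sample in enumerate(design.samples):
        c_idx = config.countries.index(sample.country)
        freq = crab_freq[:, c_idx] if sample.ecotype == "crab" else wave_freq[:, c_idx]
        pool_freq[:, m] = rng.binomial(copies, freq) / copies

    k = config.coverage_dispersion
    site_mean = np.full(S, config.coverage_mean)
    if config.expression_shape is not None:
        g = config.expression_shape
        expression = rng.gamma(g, 1.0 / g, size=config.n_contigs)
        site_mean = site_mean * expression[contig_of_snp]
    coverage = rng.negative_binomial(
        k, k / (k + site_mean[:, None]), size=(S, len(design))
    )

    # two distinct allele nucleotides per SNP; allele 1 carries pool_freq
    allele1 = rng.integers(0, 4, size=S)
    allele2 = (allele1 + rng.integers(1, 4, size=S)) % 4

    reads1 = rng.binomial(coverage, pool_freq)
    reads2 = coverage - reads1
    counts = np.zeros((S, len(design), 6), dtype=np.int64)
    rows = np.arange(S)[:, None]
    cols = np.arange(len(design))[None, :]
    if config.error_rate > 0:
        err1 = rng.binomial(reads1, config.error_rate)
        err2 = rng.binomial(reads2, config.error_rate)
        reads1 = reads1 - err1
        reads2 = reads2 - err2
        # errors land uniformly on the other three nucleotides
        others = np.array([[j for j in range(4) if j != i] for i in range(4)])
        spread1 = rng.multinomial(err1, np.full(3, 1 / 3))
        spread2 = rng.multinomial(err2, np.full(3, 1 / 3))
        for slot in range(3):
            counts[rows, cols, others[allele1][:, slot][:, None]] += spread1[:, :, slot]
            counts[rows, cols, others[allele2][:, slot][:, None]] += spread2[:, :, slot]
    counts[rows, cols, allele1[:, None]] += reads1
    counts[rows, cols, allele2[:, None]] += reads2

    contigs = truth["contig"].to_numpy(dtype=object)[contig_of_snp]
    nuc = np.array(NUCLEOTIDES, dtype=object)
    matrix = SyncMatrix(contigs, positions, nuc[allele1], counts)
    latent = {
        "contig_of_snp": contig_of_snp,
        "country_freq": country_freq,
        "crab_freq": crab_freq,
        "wave_freq": wave_freq,
    }
    return SimulatedDataset(matrix=matrix, design=design, truth=truth, latent=latent)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t")
    required = {"contig", "label"}
    missing = required - set(truth.columns)
    if missing:
        raise ValueError(f"truth table {path}: missing columns {sorted(missing)}")
    base_labels = truth["label"].str.split(":").str[0]
    unknown = set(base_labels) - set(TRUTH_LABELS)
    if unknown:
        raise ValueError(f"truth table {path}: unknown labels {sorted(unknown)}")
    return truth
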