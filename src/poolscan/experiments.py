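"""Repeated-simulation experiments: null calibration, power and direction recovery.

These drivers run the generator plus the minimal slice of the analysis chain
many times and aggregate rates: how often observed cross-location sharing
falls inside the hypergeometric CI on neutral data (calibration), how often
selection-driven sharing exceeds chance and how many truth-labelled shared
contigs are recovered (power), and whether same-direction vs opposite-
direction selection separates in the SNP-correlation sign (direction).
They are what the acceptance checks and the analysis scripts call.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import diversity, outlier_sharing, preprocess, snp_parallelism
from .synthetic_data import SimulationConfig, simulate_dataset

def calibration_subset_size(n_all: int) -> int:
    """Pseudo-outlier subset size for p-value uniformity checks.

    Capped at 5% of the all-contig pool: the subset is drawn without
    replacement from the same finite pool that defines the reference
    distribution, which deflates the test statistics by roughly a factor
    (1 - n/N); keeping n/N small makes that bias negligible. The floor of
    25 keeps expected chi-square bin counts near the validity threshold.
    """
    return max(25, min(100, n_all // 20))


def _country_fst_frames(table, design):
    """Between-ecotype replicate FST frames per country, indexed by contig."""
    frames = {}
    for country in design.countries:
        reps = []
        for replicate, pair in zip(design.replicates, design.replicate_pairs(country)):
            frame = diversity.contig_fst(table, pair)
            reps.append(frame.set_index("contig")["fst"].rename(f"rep{replicate}"))
        frames[country] = pd.concat(reps, axis=1).dropna()
    return frames


def run_sharing_once(
    config: SimulationConfig,
    seed: int,
    q: float = 0.94,
    with_control: bool = False,
    target_coverage: int = preprocess.TARGET_COVERAGE,
    min_minor_count: int = preprocess.MIN_MINOR_COUNT,
):
    """One simulate -> preprocess -> FST -> outliers -> sharing pass.

    Returns (sharing rows, outlier sets, snp table, truth, design).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sim = simulate_dataset(replace(config, seed=None), rng)
    table, _ = preprocess.preprocess_matrix(
        sim.matrix, target=target_coverage, min_minor_count=min_minor_count, rng=rng
    )
    frames = _country_fst_frames(table, sim.design)
    sets = {
        country: outlier_sharing.detect_outliers(
            frames[country]["rep1"], frames[country]["rep2"], q, country
        )
        for country in sim.design.countries
    }
    rows = []
    for country_a, country_b in sim.design.country_pairs():
        universe = sets[country_a].universe & sets[country_b].universe
        set_a = outlier_sharing.restrict_to_universe(sets[country_a], universe)
        set_b = outlier_sharing.restrict_to_universe(sets[country_b], universe)
        shared, result = outlier_sharing.shared_outliers(set_a, set_b)
        rows.append({"kind": "between_country", "pair": (country_a, country_b),
                     "shared": shared, "result": result})
    if with_control:
        for country in sim.design.countries:
            crab_pair, wave_pair = sim.design.within_ecotype_pairs(country)
            crab = diversity.contig_fst(table, crab_pair).set_index("contig")["fst"]
            wave = diversity.contig_fst(table, wave_pair).set_index("contig")["fst"]
            rows.append({"kind": "control", "pair": country,
                         "result": outlier_sharing.control_sharing(crab, wave, q, country)})
    return rows, sets, table, sim.truth, sim.design


@dataclass
class CalibrationResult:
    n_runs: int
    inside_ci: float          # fraction of (run, pair) sharing inside the 95% CI
    control_inside_ci: float
    bootstrap_pvalues: np.ndarray
    chi2_pvalues: np.ndarray


def null_calibration(
    n_runs: int,
    config: SimulationConfig | None = None,
    seed: int = 0,
    q: float = 0.94,
    bootstrap_B: int = snp_parallelism.DEFAULT_BOOTSTRAP_B,
    subset_size: int | None = None,
) -> CalibrationResult:
    """Neutral-data calibration of the sharing null and the SNP-level tests.

    Every run simulates a fully neutral dataset, measures whether the
    observed cross-location sharing (and the within-ecotype control
    sharing) falls inside the hypergeometric 95% CI, and computes bootstrap
    and chi-square p-values for a random pseudo-outlier subset of the
    all-contig r distribution (the tests' own null).
    """
    if config is None:
        config = SimulationConfig()
    config = replace(
        config, frac_shared_selected=0.0, frac_country_specific=0.0, frac_sign_flipped=0.0
    )
    seeds = np.random.SeedSequence(seed).generate_state(n_runs, dtype=np.uint32)
    inside, control_inside, boot_ps, chi_ps = [], [], [], []
    for run_seed in seeds:
        rows, sets, table, _, design = run_sharing_once(
            config, int(run_seed), q=q, with_control=True
        )
        rng = np.random.default_rng(int(run_seed) + 1)
        for row in rows:
            result = row["result"]
            ok = result.ci_low <= result.observed_shared <= result.ci_high
            (inside if row["kind"] == "between_country" else control_inside).append(ok)
        country_a, country_b = design.country_pairs()[0]
        diff_a = snp_parallelism.ecotype_allele_diff(table, design, country_a)
        diff_b = snp_parallelism.ecotype_allele_diff(table, design, country_b)
        frame, _ = snp_parallelism.contig_correlations(table, diff_a, diff_b)
        all_rs = frame["r"].to_numpy()
        size = calibration_subset_size(all_rs.size) if subset_size is None else subset_size
        if all_rs.size > size:
            pseudo = rng.choice(all_rs, size=size, replace=False)
            boot_ps.append(
                snp_parallelism.bootstrap_mean_r_test(pseudo, all_rs, B=bootstrap_B, rng=rng)
            )
            chi = snp_parallelism.chisq_bin_test(pseudo, all_rs)
            if chi is not None:
                chi_ps.append(chi[2])
    return CalibrationResult(
        n_runs=n_runs,
        inside_ci=float(np.mean(inside)),
        control_inside_ci=float(np.mean(control_inside)),
        bootstrap_pvalues=np.asarray(boot_ps),
        chi2_pvalues=np.asarray(chi_ps),
    )


@dataclass
class PowerResult:
    n_runs: int
    exceeds_chance_rate: float       # fraction of (run, pair) with sharing above CI
    recovery_rate: float             # truth shared-selected contigs found in shared sets
    replicate_sharing: float         # |rep1 & rep2| / |rep1 outliers|, averaged
    replicate_sharing_chance: float  # same proportion expected under the null
    replicate_exceeds_rate: float    # replicate overlap above hypergeometric CI


def power_recovery(
    n_runs: int,
    config: SimulationConfig | None = None,
    seed: int = 0,
    q: float = 0.94,
) -> PowerResult:
    """Selection-data power: chance-exceeding sharing and truth recovery."""
    if config is None:
        config = SimulationConfig(
            frac_shared_selected=0.05, frac_country_specific=0.0, frac_sign_flipped=0.0
        )
    seeds = np.random.SeedSequence(seed).generate_state(n_runs, dtype=np.uint32)
    exceeds, recovered, rep_share, rep_chance, rep_exceeds = [], [], [], [], []
    for run_seed in seeds:
        rows, sets, _, truth, design = run_sharing_once(config, int(run_seed), q=q)
        truth_shared = set(truth.loc[truth["label"] == "shared_selected", "contig"])
        for row in rows:
            if row["kind"] != "between_country":
                continue
            result = row["result"]
            exceeds.append(result.observed_shared > result.ci_high)
            country_a, country_b = row["pair"]
            universe = sets[country_a].universe & sets[country_b].universe
            in_universe = truth_shared & universe
            if in_universe:
                recovered.append(len(row["shared"] & in_universe) / len(in_universe))
        for country in design.countries:
            outlier_set = sets[country]
            rep = outlier_sharing.replicate_sharing(outlier_set)
            if rep.n_a:
                rep_share.append(rep.observed_shared / rep.n_a)
                rep_chance.append(rep.expected_shared / rep.n_a)
            rep_exceeds.append(rep.exceeds_chance)
    return PowerResult(
        n_runs=n_runs,
        exceeds_chance_rate=float(np.mean(exceeds)),
        recovery_rate=float(np.mean(recovered)),
        replicate_sharing=float(np.mean(rep_share)),
        replicate_sharing_chance=float(np.mean(rep_chance)),
        replicate_exceeds_rate=float(np.mean(rep_exceeds)),
    )


@dataclass
class DirectionResult:
    n_runs: int
    mean_r_same_direction: float
    mean_r_flipped: float
    same_positive_significant: float  # rate of mean r > 0 with bootstrap p < 0.05
    flipped_negative_significant: float


def direction_recovery(
    n_runs: int,
    config: SimulationConfig | None = None,
    seed: int = 0,
    q: float = 0.92,
    bootstrap_B: int = 2000,
) -> DirectionResult:
    """Same-direction vs opposite-direction selection in the SNP correlation sign.

    Uses the opposite-direction country pair: shared outliers there contain
    both same-direction (shared_selected) and sign-flipped contigs, whose r
    distributions should separate to positive and negative. The default
    threshold is the least stringent quantile of the published range (92%),
    where shared sets are large enough for the mean-r bootstrap to have
    power; the default scan size is 4000 contigs for the same reason.
    """
    if config is None:
        config = SimulationConfig(
            n_contigs=4000,
            frac_shared_selected=0.05,
            frac_country_specific=0.0,
            frac_sign_flipped=0.05,
        )
    seeds = np.random.SeedSequence(seed).generate_state(n_runs, dtype=np.uint32)
    mean_same, mean_flip, sig_same, sig_flip = [], [], [], []
    flip_a, flip_b = config.flip_pair
    flip_label = f"sign_flipped:{flip_a}-{flip_b}"
    for run_seed in seeds:
        rows, sets, table, truth, design = run_sharing_once(config, int(run_seed), q=q)
        rng = np.random.default_rng(int(run_seed) + 1)
        shared = next(
            row["shared"] for row in rows
            if row["kind"] == "between_country" and set(row["pair"]) == {flip_a, flip_b}
        )
        diff_a = snp_parallelism.ecotype_allele_diff(table, design, flip_a)
        diff_b = snp_parallelism.ecotype_allele_diff(table, design, flip_b)
        frame, _ = snp_parallelism.contig_correlations(table, diff_a, diff_b)
        all_rs = frame["r"].to_numpy()
        by_label = truth.set_index("contig")["label"]
        for label, means, sigs, sign in (
            ("shared_selected", mean_same, sig_same, 1),
            (flip_label, mean_flip, sig_flip, -1),
        ):
            contigs = {c for c in shared if by_label.get(c) == label}
            rs = frame.loc[frame["contig"].isin(contigs), "r"].to_numpy()
            if rs.size == 0:
                continue
            means.append(rs.mean())
            p = snp_parallelism.bootstrap_mean_r_test(rs, all_rs, B=bootstrap_B, rng=rng)
            sigs.append(sign * rs.mean() > sign * all_rs.mean() and p < 0.05)
    return DirectionResult(
        n_runs=n_runs,
        mean_r_same_direction=float(np.mean(mean_same)) if mean_same else np.nan,
        mean_r_flipped=float(np.mean(mean_flip)) if mean_flip else np.nan,
        same_positive_significant=float(np.mean(sig_same)) if sig_same else np.nan,
        flipped_negative_significant=float(np.mean(sig_flip)) if sig_flip else np.nan,
    )


def fst_ordering(config: SimulationConfig | None = None, seed: int = 0) -> dict:
    """Mean FST of within-ecotype, between-ecotype and between-country pairs.

    Under location drift > ecotype effect > 0 these should reproduce the
    rank order within-ecotype < between-ecotype < between-country.
    """
    if config is None:
        config = SimulationConfig(
            frac_shared_selected=0.10, frac_country_specific=0.0, frac_sign_flipped=0.0
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sim = simulate_dataset(replace(config, seed=None), rng)
    table, _ = preprocess.preprocess_matrix(sim.matrix, rng=rng)
    summary = diversity.all_pair_fst(table, sim.design).summary()
    return {
        kind: float(summary.loc[summary["kind"] == kind, "mean_fst"].mean())
        for kind in ("within_ecotype", "between_ecotype", "between_country")
    }
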