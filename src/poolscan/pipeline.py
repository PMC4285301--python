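"""End-to-end orchestration: simulate/load -> SNPs -> FST -> outliers -> SNP tests.

Each stage is a pure function of (inputs, config, seed); one top-level seed
deterministically spawns independent per-stage streams (simulation,
subsampling, bootstrap) so stages can be re-run in isolation. Outputs are
grep-able TSVs plus a JSON summary and a run manifest with the filter-chain
counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, outlier_sharing, preprocess, snp_parallelism
from .outlier_sharing import DEFAULT_QUANTILES
from .preprocess import MIN_COVERAGE, MIN_MINOR_COUNT, TARGET_COVERAGE
from .snp_parallelism import DEFAULT_BIN_EDGES, DEFAULT_BOOTSTRAP_B, MIN_SNPS_PER_CONTIG
from .sync_io import PoolDesign, SyncMatrix, read_design
from .synthetic_data import SimulationConfig, simulate_dataset, write_truth

logger = logging.getLogger("poolscan")

_STAGES = ("simulate", "subsample", "snp_call", "bootstrap")


def stage_rngs(seed: int | None) -> dict:
    """Independent, reproducible per-stage generators from one top-level seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(s) for name, s in zip(_STAGES, children)}


@dataclass
class PipelineConfig:
    """Configuration for one full analysis run."""

    sync_path: str | None = None
    design_path: str | None = None
    simulate: SimulationConfig | None = None
    target_coverage: int = TARGET_COVERAGE
    min_coverage: int = MIN_COVERAGE
    min_minor_count: int = MIN_MINOR_COUNT
    quantiles: tuple = DEFAULT_QUANTILES
    bootstrap_B: int = DEFAULT_BOOTSTRAP_B
    bin_edges: tuple = DEFAULT_BIN_EDGES
    min_snps_per_contig: int = MIN_SNPS_PER_CONTIG
    seed: int | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        if isinstance(sim, dict):
            sim = SimulationConfig(**sim)
        config = cls(simulate=sim, **raw)
        if config.simulate is None and config.sync_path is None:
            raise ValueError("config needs either simulate parameters or a sync_path")
        return config


@dataclass
class ReportBundle:
    """In-memory results of a full run (also what gets written to disk)."""

    design: PoolDesign
    snp_table: preprocess.SnpTable
    fst_tables: diversity.PairFstTables
    fst_summary: pd.DataFrame
    correlations: pd.DataFrame
    outliers: dict            # {(q, country): OutlierSet}
    sharing: pd.DataFrame
    shared_contigs: dict      # {(q, country_a, country_b): frozenset}
    three_way: dict           # {q: frozenset}
    snp_tests: list           # [CorrelationTestResult]
    snp_correlations: dict    # {(country_a, country_b): DataFrame}
    truth: pd.DataFrame | None
    manifest: dict


def run_all(config: PipelineConfig, outdir: str | Path | None = None) -> ReportBundle:
    """Run every stage in order; optionally write the report bundle to ``outdir``."""
    rngs = stage_rngs(config.seed)
    truth = None
    if config.simulate is not None:
        logger.info("simulate: %d contigs", config.simulate.n_contigs)
        sim = simulate_dataset(config.simulate, rngs["simulate"])
        matrix, design, truth = sim.matrix, sim.design, sim.truth
    else:
        if config.design_path is None:
            raise FileNotFoundError("no design file given")
        design = read_design(config.design_path)
        matrix = SyncMatrix.read(config.sync_path, design)
        logger.info("load: %d sites, %d samples", matrix.n_sites, matrix.n_samples)

    stats = preprocess.FilterStats(n_input=matrix.n_sites)
    matrix2, stats.n_deletion_dropped = preprocess.remove_deletion_sites(matrix)
    matrix2, stats.n_low_coverage_dropped = preprocess.subsample_matrix(
        matrix2, config.target_coverage, config.min_coverage, rngs["subsample"]
    )
    snp_table = preprocess.call_snps(
        matrix2, config.min_minor_count, config.target_coverage, rngs["snp_call"], stats
    )
    logger.info("preprocess: %d sites -> %d SNPs on %d contigs",
                stats.n_input, snp_table.n_snps, snp_table.n_contigs)

    fst_tables = diversity.all_pair_fst(snp_table, design)
    fst_summary = fst_tables.summary()
    correlations = diversity.replicate_correlation(fst_tables, design)

    country_tables = {c: diversity.country_fst(fst_tables, c) for c in design.countries}
    outliers: dict = {}
    sharing_rows = []
    shared_contigs: dict = {}
    three_way: dict = {}
    snp_tests = []
    snp_correlations: dict = {}

    # per-SNP ecotype differences and per-contig correlations, once per country pair
    diffs = {c: snp_parallelism.ecotype_allele_diff(snp_table, design, c) for c in design.countries}
    for country_a, country_b in design.country_pairs():
        frame, excluded = snp_parallelism.contig_correlations(
            snp_table, diffs[country_a], diffs[country_b], config.min_snps_per_contig
        )
        snp_correlations[(country_a, country_b)] = frame
        snp_correlations[("excluded", country_a, country_b)] = excluded

    for q in config.quantiles:
        sets = {}
        for country in design.countries:
            frame = country_tables[country]
            sets[country] = outlier_sharing.detect_outliers(
                frame.set_index("contig")["fst_rep1"],
                frame.set_index("contig")["fst_rep2"],
                q,
                country,
            )
            outliers[(q, country)] = sets[country]
            rep = outlier_sharing.replicate_sharing(sets[country])
            sharing_rows.append({"q": q, "kind": "replicate", **rep.as_dict()})
            crab = fst_tables.within_ecotype[(country, "crab")].set_index("contig")["fst"]
            wave = fst_tables.within_ecotype[(country, "wave")].set_index("contig")["fst"]
            control = outlier_sharing.control_sharing(crab, wave, q, country)
            sharing_rows.append({"q": q, "kind": "control", **control.as_dict()})
        for country_a, country_b in design.country_pairs():
            universe = sets[country_a].universe & sets[country_b].universe
            set_a = outlier_sharing.restrict_to_universe(sets[country_a], universe)
            set_b = outlier_sharing.restrict_to_universe(sets[country_b], universe)
            shared, result = outlier_sharing.shared_outliers(set_a, set_b)
            shared_contigs[(q, country_a, country_b)] = shared
            props = outlier_sharing.sharing_proportions(result, shared)
            sharing_rows.append({"q": q, "kind": "between_country", **result.as_dict(), **props})
            snp_tests.append(
                snp_parallelism.correlation_test(
                    snp_correlations[(country_a, country_b)],
                    shared,
                    f"{country_a}-{country_b}",
                    q,
                    B=config.bootstrap_B,
                    bin_edges=config.bin_edges,
                    rng=rngs["bootstrap"],
                    excluded=snp_correlations[("excluded", country_a, country_b)],
                )
            )
        three_way[q] = outlier_sharing.three_way_shared(sets)
    sharing = pd.DataFrame(sharing_rows)

    manifest = {
        "seed": config.seed,
        "filter_chain": stats.as_dict(),
        "n_samples": len(design),
        "n_contigs_with_fst": int(snp_table.n_contigs),
        "quantiles": list(config.quantiles),
        "target_coverage": config.target_coverage,
        "min_minor_count": config.min_minor_count,
    }
    bundle = ReportBundle(
        design=design,
        snp_table=snp_table,
        fst_tables=fst_tables,
        fst_summary=fst_summary,
        correlations=correlations,
        outliers=outliers,
        sharing=sharing,
        shared_contigs=shared_contigs,
        three_way=three_way,
        snp_tests=snp_tests,
        snp_correlations=snp_correlations,
        truth=truth,
        manifest=manifest,
    )
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: ReportBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.snp_table.write(outdir / "snp_table.tsv", bundle.design)
    for (country, rep), frame in bundle.fst_tables.between_ecotype.items():
        frame.to_csv(outdir / f"fst_between_ecotype_{country}_rep{rep}.tsv", sep="\t", index=False)
    for (country, ecotype), frame in bundle.fst_tables.within_ecotype.items():
        frame.to_csv(outdir / f"fst_within_ecotype_{country}_{ecotype}.tsv", sep="\t", index=False)
    for (ca, cb), frame in bundle.fst_tables.between_country.items():
        frame.to_csv(outdir / f"fst_between_country_{ca}_{cb}.tsv", sep="\t", index=False)
    bundle.fst_summary.to_csv(outdir / "fst_summary.tsv", sep="\t", index=False)
    bundle.correlations.to_csv(outdir / "fst_correlations.tsv", sep="\t", index=False)
    bundle.sharing.to_csv(outdir / "sharing.tsv", sep="\t", index=False)
    membership_rows = []
    for (q, country), outlier_set in bundle.outliers.items():
        for contig in sorted(outlier_set.contigs):
            membership_rows.append({"q": q, "country": country, "contig": contig})
    pd.DataFrame(membership_rows, columns=["q", "country", "contig"]).to_csv(
        outdir / "outlier_membership.tsv", sep="\t", index=False
    )
    for (key, frame) in bundle.snp_correlations.items():
        if key[0] == "excluded":
            continue
        ca, cb = key
        frame.to_csv(outdir / f"snp_correlations_{ca}_{cb}.tsv", sep="\t", index=False)
    with open(outdir / "snp_tests.json", "w") as handle:
        json.dump([t.as_dict() for t in bundle.snp_tests], handle, indent=2, default=_jsonable)
    if bundle.truth is not None:
        write_truth(bundle.truth, outdir / "truth.tsv")
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(bundle.manifest, handle, indent=2, default=_jsonable)
    with open(outdir / "summary.json", "w") as handle:
        json.dump(summarize(bundle), handle, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def summarize(bundle: ReportBundle) -> dict:
    """Headline numbers of a run as one JSON-able dict."""
    fst = {
        row["pair_id"]: {"mean": row["mean_fst"], "se": row["se_fst"], "n": row["n_contigs"]}
        for _, row in bundle.fst_summary.iterrows()
    }
    correlations = {
        row["comparison"]: {"r": row["r"], "n": row["n"]}
        for _, row in bundle.correlations.iterrows()
    }
    sharing = {}
    for _, row in bundle.sharing.iterrows():
        key = f"q{row['q']}_{row['kind']}_{row['set_a']}_{row['set_b']}"
        sharing[key] = {
            "observed": int(row["observed_shared"]),
            "expected": float(row["expected_shared"]),
            "ci": [int(row["ci_low"]), int(row["ci_high"])],
            "exceeds_chance": bool(row["exceeds_chance"]),
            "n_a": int(row["n_a"]),
            "n_b": int(row["n_b"]),
        }
        if row["kind"] == "between_country":
            sharing[key]["prop_of_a"] = float(row["prop_of_a"])
            sharing[key]["prop_of_b"] = float(row["prop_of_b"])
    snp_tests = {
        f"q{t.q}_{t.country_pair}": {
            "n_outlier_contigs": t.n_outlier_contigs,
            "mean_r_outliers": t.mean_r_outliers,
            "mean_r_all": t.mean_r_all,
            "bootstrap_p": t.bootstrap_p,
            "chi2_p": t.chi2_p,
        }
        for t in bundle.snp_tests
    }
    return {
        "manifest": bundle.manifest,
        "fst_summary": fst,
        "fst_correlations": correlations,
        "sharing": sharing,
        "three_way_shared": {f"q{q}": sorted(v) for q, v in bundle.three_way.items()},
        "snp_tests": snp_tests,
    }
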