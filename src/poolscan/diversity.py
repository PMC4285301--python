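"""Expected heterozygosity and per-contig FST between pool pairs.

FST is computed per contig, not per SNP: expected heterozygosity within
pools (Hw) and in the pooled total (Ht) is averaged over the contig's
retained SNPs first, and FST = (Ht_mean - Hw_mean) / Ht_mean. Contigs are
short transcript fragments, so they act as the locus unit, integrating
signal over linked SNPs and avoiding pseudoreplication of single SNPs.

No pool-size bias correction is applied to the heterozygosities; this is a
plain Nei-style estimator on subsampled counts (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import SnpTable
from .sync_io import PoolDesign

MIN_CONTIGS_FOR_CORRELATION = 3


def snp_heterozygosities(p1, p2) -> tuple[np.ndarray, np.ndarray]:
    """Within-pool and total expected heterozygosity for a biallelic SNP.

    hw = (2 p1 (1-p1) + 2 p2 (1-p2)) / 2, ht = 2 pbar (1-pbar) with
    pbar = (p1+p2)/2. Accepts scalars or arrays.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    hw = p1 * (1.0 - p1) + p2 * (1.0 - p2)
    pbar = 0.5 * (p1 + p2)
    ht = 2.0 * pbar * (1.0 - pbar)
    return hw, ht


def _contig_means(table: SnpTable, values: np.ndarray) -> np.ndarray:
    sums = np.add.reduceat(values, table.group_starts)
    return sums / table.snps_per_contig


def contig_fst(table: SnpTable, sample_pair: tuple[int, int], pair_id: str = "") -> pd.DataFrame:
    """Per-contig FST between two pools (columns of the design).

    Returns one row per contig with hw_mean, ht_mean, fst and n_snps; fst is
    NaN where ht_mean == 0 (no variation in the pair: excluded downstream).
    """
    i, j = sample_pair
    freq = table.major_freq
    hw, ht = snp_heterozygosities(freq[:, i], freq[:, j])
    hw_mean = _contig_means(table, hw)
    ht_mean = _contig_means(table, ht)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(ht_mean > 0, (ht_mean - hw_mean) / ht_mean, np.nan)
    return pd.DataFrame(
        {
            "contig": table.contigs,
            "pair_id": pair_id,
            "hw_mean": hw_mean,
            "ht_mean": ht_mean,
            "fst": fst,
            "n_snps": table.snps_per_contig,
        }
    )


@dataclass
class PairFstTables:
    """All per-contig FST tables for one design, keyed by comparison."""

    #: {(country, replicate): frame} for crab_r vs wave_r
    between_ecotype: dict
    #: {(country, ecotype): frame} for replicate 1 vs replicate 2 of one ecotype
    within_ecotype: dict
    #: {(country_a, country_b): frame} averaged over the 4 matched cross pairs
    between_country: dict

    def summary(self) -> pd.DataFrame:
        """Mean +/- SE of FST across contigs for every comparison."""
        rows = []
        for kind, tables in (
            ("between_ecotype", self.between_ecotype),
            ("within_ecotype", self.within_ecotype),
            ("between_country", self.between_country),
        ):
            for key, frame in tables.items():
                fst = frame["fst"].dropna().to_numpy()
                rows.append(
                    {
                        "kind": kind,
                        "pair_id": frame["pair_id"].iloc[0] if len(frame) else "_".join(map(str, key)),
                        "mean_fst": fst.mean() if fst.size else np.nan,
                        "se_fst": fst.std(ddof=1) / np.sqrt(fst.size) if fst.size > 1 else np.nan,
                        "n_contigs": int(fst.size),
                    }
                )
        return pd.DataFrame(rows)


def all_pair_fst(table: SnpTable, design: PoolDesign) -> PairFstTables:
    """Per-contig FST for between-ecotype, within-ecotype and between-country pairs.

    Between-country FST per contig is the mean over the four ecotype- and
    replicate-matched cross-country pool pairs, keeping ecotype composition
    balanced; pairs with undefined FST (ht_mean = 0) are skipped in that mean.
    """
    between_ecotype: dict = {}
    within_ecotype: dict = {}
    between_country: dict = {}
    for country in design.countries:
        for replicate, pair in zip(design.replicates, design.replicate_pairs(country)):
            pair_id = f"{country}_crab{replicate}_wave{replicate}"
            between_ecotype[(country, replicate)] = contig_fst(table, pair, pair_id)
        for (ecotype, _), pair in zip(
            [("crab", None), ("wave", None)], design.within_ecotype_pairs(country)
        ):
            pair_id = f"{country}_{ecotype}1_{ecotype}2"
            within_ecotype[(country, ecotype)] = contig_fst(table, pair, pair_id)
    for country_a, country_b in design.country_pairs():
        frames = [
            contig_fst(table, pair)["fst"].to_numpy()
            for pair in design.between_country_pairs(country_a, country_b)
        ]
        stacked = np.vstack(frames)
        n_defined = (~np.isnan(stacked)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean_fst = np.where(
                n_defined > 0, np.nansum(stacked, axis=0) / np.maximum(n_defined, 1), np.nan
            )
        between_country[(country_a, country_b)] = pd.DataFrame(
            {
                "contig": table.contigs,
                "pair_id": f"{country_a}-{country_b}",
                "fst": mean_fst,
                "n_pairs": n_defined,
            }
        )
    return PairFstTables(between_ecotype, within_ecotype, between_country)


def country_fst(tables: PairFstTables, country: str) -> pd.DataFrame:
    """Replicate between-ecotype estimates and their mean, for contigs with both."""
    rep_frames = {
        r: tables.between_ecotype[(country, r)] for r in sorted(
            rep for (c, rep) in tables.between_ecotype if c == country
        )
    }
    replicates = sorted(rep_frames)
    merged = None
    for r in replicates:
        frame = rep_frames[r][["contig", "fst"]].rename(columns={"fst": f"fst_rep{r}"})
        merged = frame if merged is None else merged.merge(frame, on="contig")
    merged = merged.dropna()
    merged["fst_mean"] = merged[[f"fst_rep{r}" for r in replicates]].mean(axis=1)
    merged.insert(1, "country", country)
    return merged.reset_index(drop=True)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < MIN_CONTIGS_FOR_CORRELATION:
        return np.nan
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def replicate_correlation(tables: PairFstTables, design: PoolDesign) -> pd.DataFrame:
    """Pearson correlations of per-contig FST between replicate estimates.

    One row per country (replicate 1 vs replicate 2 of the between-ecotype
    FST) and one per country pair (replicate-averaged FST of one country vs
    the other). Undefined correlations (n < 3 or zero variance) are NaN.
    """
    rows = []
    per_country = {}
    for country in design.countries:
        frame = country_fst(tables, country)
        per_country[country] = frame
        cols = [c for c in frame.columns if c.startswith("fst_rep")]
        x, y = frame[cols[0]].to_numpy(), frame[cols[1]].to_numpy()
        rows.append(
            {
                "comparison": f"{country}_rep1_rep2",
                "kind": "replicate",
                "r": _pearson(x, y),
                "n": len(frame),
            }
        )
    for country_a, country_b in design.country_pairs():
        merged = per_country[country_a][["contig", "fst_mean"]].merge(
            per_country[country_b][["contig", "fst_mean"]], on="contig", suffixes=("_a", "_b")
        )
        rows.append(
            {
                "comparison": f"{country_a}-{country_b}",
                "kind": "between_country",
                "r": _pearson(merged["fst_mean_a"].to_numpy(), merged["fst_mean_b"].to_numpy()),
                "n": len(merged),
            }
        )
    return pd.DataFrame(rows)
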