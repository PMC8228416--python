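"""Spatial clustering of DMS and cross-comparison analyses.

Covers the question of whether significant sites cluster along the
genome more than chance: nearest-neighbour distance distributions
against a resampling null (repeated uniform draws of the same number of
sites from the background CpG set), the fraction of close DMS pairs
changing in the same direction, DMS density differences in 1-Mb genomic
bins, nested correlations of methylation changes between two
comparisons, and the screen for sites whose methylation response differs
by at least 20 percentage points between two treatments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BIN_SIZE = 1_000_000  # bp; bins anchored at coordinate 0, half-open

# distance histogram: logarithmic bins, 1 bp .. 10 Mb
DEFAULT_DISTANCE_EDGES = np.geomspace(1.0, 1e7, 31)


@dataclass
class DistanceDistribution:
    distances: np.ndarray           # pooled neighbour distances, all chromosomes
    bin_edges: np.ndarray
    observed_counts: np.ndarray
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None
    n_resamples: int | None = None
    seed: int | None = None


def _check_unique(sites: pd.DataFrame) -> None:
    if sites.duplicated(subset=["chrom", "pos"]).any():
        dup = sites.loc[sites.duplicated(subset=["chrom", "pos"])].iloc[0]
        raise ValueError(f"duplicated site {dup['chrom']}:{dup['pos']}")


def neighbor_distances(
    sites: pd.DataFrame, bin_edges: np.ndarray | None = None
) -> DistanceDistribution:
    """Successive-position differences within each chromosome.

    A chromosome with a single site contributes no distance; the total
    number of distances is n_sites minus the number of chromosomes that
    carry sites.
    """
    _check_unique(sites)
    if bin_edges is None:
        bin_edges = DEFAULT_DISTANCE_EDGES
    parts = []
    for _, sub in sites.groupby("chrom", sort=False):
        pos = np.sort(sub["pos"].to_numpy(dtype=np.int64))
        if len(pos) > 1:
            parts.append(np.diff(pos))
    distances = np.concatenate(parts) if parts else np.array([], dtype=np.int64)
    counts, _ = np.histogram(distances, bins=bin_edges)
    return DistanceDistribution(
        distances=distances, bin_edges=np.asarray(bin_edges), observed_counts=counts
    )


def resample_null(
    dms_count: int,
    background_sites: pd.DataFrame,
    n_resamples: int = 100,
    seed: int = 0,
    bin_edges: np.ndarray | None = None,
) -> DistanceDistribution:
    """Null distance histogram from uniform draws out of the background.

    Each draw samples ``dms_count`` sites without replacement from the
    genome-wide background CpG set, recomputes neighbour distances and
    histograms them; the null is the per-bin mean (and SD) over exactly
    ``n_resamples`` draws. Deterministic under the seed.
    """
    if dms_count > len(background_sites):
        raise ValueError(
            f"cannot draw {dms_count} sites from a background of "
            f"{len(background_sites)}"
        )
    if bin_edges is None:
        bin_edges = DEFAULT_DISTANCE_EDGES
    rng = np.random.default_rng(seed)
    bg = background_sites[["chrom", "pos"]].reset_index(drop=True)
    hists = np.zeros((n_resamples, len(bin_edges) - 1))
    for r in range(n_resamples):
        idx = rng.choice(len(bg), size=dms_count, replace=False)
        draw = bg.iloc[np.sort(idx)]
        hists[r] = neighbor_distances(draw, bin_edges).observed_counts
    return DistanceDistribution(
        distances=np.array([]),
        bin_edges=np.asarray(bin_edges),
        observed_counts=hists.mean(axis=0),
        null_mean=hists.mean(axis=0),
        null_sd=hists.std(axis=0, ddof=0),
        n_resamples=n_resamples,
        seed=seed,
    )


def same_direction_fraction(
    dms: pd.DataFrame, radius: int = 100
) -> dict:
    """Co-direction of close DMS pairs.

    Over all DMS pairs on the same chromosome within ``radius`` bp:
    the fraction whose meth_diff signs agree, plus the median absolute
    difference of meth_diff among same-sign pairs (amplitude agreement).
    With no qualifying pairs the fraction is reported as None.
    """
    _check_unique(dms)
    same = 0
    total = 0
    amp: list[float] = []
    for _, sub in dms.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="stable")
        pos = sub["pos"].to_numpy(dtype=np.int64)
        diff = sub["meth_diff"].to_numpy(dtype=float)
        n = len(pos)
        for i in range(n):
            j = i + 1
            while j < n and pos[j] - pos[i] <= radius:
                total += 1
                if np.sign(diff[i]) == np.sign(diff[j]):
                    same += 1
                    amp.append(abs(diff[i] - diff[j]))
                j += 1
    return {
        "n_pairs": total,
        "fraction_same_direction": (same / total) if total else None,
        "median_amplitude_gap": float(np.median(amp)) if amp else None,
    }


def bin_difference(
    dms_1: pd.DataFrame,
    dms_2: pd.DataFrame,
    chrom_sizes: dict[str, int] | None = None,
    bin_size: int = BIN_SIZE,
) -> pd.DataFrame:
    """Per-bin DMS count difference (comparison 2 minus comparison 1).

    Bins are [k*bin_size, (k+1)*bin_size) anchored at coordinate 0 on
    each chromosome. When chromosome sizes are given every bin is
    reported, otherwise bins up to the last occupied one. The result is
    sorted by (chrom, bin) and carries an ``abs_rank`` column ranking
    bins by absolute difference for reporting.
    """
    def bin_counts(df: pd.DataFrame) -> dict[tuple[str, int], int]:
        out: dict[tuple[str, int], int] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            bins = (sub["pos"].to_numpy(dtype=np.int64) // bin_size).astype(int)
            for b, c in zip(*np.unique(bins, return_counts=True)):
                out[(chrom, int(b))] = int(c)
        return out

    c1, c2 = bin_counts(dms_1), bin_counts(dms_2)
    if chrom_sizes:
        keys = [
            (chrom, b)
            for chrom, size in chrom_sizes.items()
            for b in range(int(np.ceil(size / bin_size)) or 1)
        ]
    else:
        keys = sorted(set(c1) | set(c2))
    rows = [
        {
            "chrom": chrom,
            "bin_start": b * bin_size,
            "bin_end": (b + 1) * bin_size,
            "count_1": c1.get((chrom, b), 0),
            "count_2": c2.get((chrom, b), 0),
        }
        for chrom, b in keys
    ]
    track = pd.DataFrame(
        rows, columns=["chrom", "bin_start", "bin_end", "count_1", "count_2"]
    )
    track["difference"] = track["count_2"] - track["count_1"]
    track = track.sort_values(["chrom", "bin_start"], kind="stable").reset_index(
        drop=True
    )
    track["abs_rank"] = (
        track["difference"].abs().rank(method="first", ascending=False).astype(int)
    )
    return track


def nested_correlations(
    shared: pd.DataFrame,
) -> dict[str, float]:
    """Pearson correlations of per-CpG changes on three nested site sets.

    ``shared`` needs columns diff_1, diff_2, dms_1, dms_2 on CpGs present
    in both comparisons. Correlations are computed on (i) all shared
    CpGs, (ii) CpGs that are DMS in at least one comparison, (iii) CpGs
    that are DMS in both. Subsets with fewer than 3 points give NaN.
    """
    def pearson(sub: pd.DataFrame) -> float:
        if len(sub) < 3:
            return float("nan")
        x = sub["diff_1"].to_numpy(dtype=float)
        y = sub["diff_2"].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])

    any_dms = shared.loc[shared["dms_1"] | shared["dms_2"]]
    both_dms = shared.loc[shared["dms_1"] & shared["dms_2"]]
    return {
        "r_all": pearson(shared),
        "r_any_dms": pearson(any_dms),
        "r_both_dms": pearson(both_dms),
        "n_all": len(shared),
        "n_any_dms": len(any_dms),
        "n_both_dms": len(both_dms),
    }


def delta_screen(
    shared: pd.DataFrame, threshold: float = 20.0
) -> pd.DataFrame:
    """Sites responding differently to the two treatments.

    Keeps CpGs that are DMS in at least one comparison AND whose
    absolute methylation-change difference |diff_1 - diff_2| is greater
    than or equal to the threshold (the boundary value is included).
    """
    shared = shared.copy()
    shared["abs_delta"] = (shared["diff_1"] - shared["diff_2"]).abs()
    keep = (shared["dms_1"] | shared["dms_2"]) & (shared["abs_delta"] >= threshold)
    return shared.loc[keep].reset_index(drop=True)


def shared_comparison_table(
    records_1: pd.DataFrame, records_2: pd.DataFrame
) -> pd.DataFrame:
    """Inner-join two adjusted comparison tables on (chrom, pos, strand).

    Produces the diff_1/diff_2/dms_1/dms_2 layout consumed by
    :func:`nested_correlations` and :func:`delta_screen`.
    """
    a = records_1[["chrom", "pos", "strand", "meth_diff", "is_dms"]].rename(
        columns={"meth_diff": "diff_1", "is_dms": "dms_1"}
    )
    b = records_2[["chrom", "pos", "strand", "meth_diff", "is_dms"]].rename(
        columns={"meth_diff": "diff_2", "is_dms": "dms_2"}
    )
    return a.merge(b, on=["chrom", "pos", "strand"], how="inner")
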