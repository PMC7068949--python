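"""Distance-decay binomial background model for intra-chromosomal pairs.

A single contact is a priori equally likely to join any of the M possible
locus pairs in the distance range (``p = 1/M``); the refined model replaces
this constant with a distance-dependent contact probability ``f(d)``
estimated by a smoothing spline over equal-occupancy distance bins, with a
second fitting phase that excludes likely-real contacts from the null
estimate.  P-values are binomial upper tails over the N mid-range reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .core_data import ContactMap, chrom_sort_key
from .multitest import bh_adjust, binom_sf, pvalue_ranks
from .result import RESULT_COLUMNS, SignificanceResult

__all__ = [
    "DistanceFunction",
    "FithicModel",
    "enumerate_possible_pairs",
    "naive_pvalue",
    "equal_occupancy_binning",
    "bin_statistics",
    "fit_distance_function",
    "spline_pvalues",
    "refine",
    "run_fithic",
]

_EPS = 1e-15


class DistanceFunction:
    """Monotone non-increasing map from genomic distance to contact probability.

    Piecewise-linear between calibration points, constant beyond them, and
    clamped to ``[1e-15, 1]``.
    """

    def __init__(self, grid_d: np.ndarray, grid_p: np.ndarray):
        grid_d = np.asarray(grid_d, dtype=float)
        grid_p = np.asarray(grid_p, dtype=float)
        if grid_d.size == 0 or grid_d.size != grid_p.size:
            raise ValueError("need matching non-empty grids")
        if not np.all(np.isfinite(grid_d)) or not np.all(np.isfinite(grid_p)):
            raise ValueError("non-finite calibration points")
        order = np.argsort(grid_d)
        self.grid_d = grid_d[order]
        self.grid_p = np.clip(grid_p[order], _EPS, 1.0)

    @classmethod
    def constant(cls, p: float) -> "DistanceFunction":
        return cls(np.array([0.0]), np.array([p]))

    def __call__(self, d):
        out = np.interp(np.asarray(d, dtype=float), self.grid_d, self.grid_p)
        if np.ndim(d) == 0:
            return float(out)
        return out


@dataclass
class FithicModel:
    """Fitted null for one phase: bin table, prior function, and totals."""

    bins: pd.DataFrame  # s, e, c, prior, d, n_pairs, total per occupancy bin
    f: DistanceFunction
    M: int
    N: int
    b: int
    dist_low: int
    dist_high: int | None
    phase: int = 1
    extra: dict = field(default_factory=dict)


def enumerate_possible_pairs(
    cmap: ContactMap, dist_low: int, dist_high: int | None = None
) -> pd.DataFrame:
    """All intra-chromosomal bin pairs within the distance window.

    Zero-count pairs are included; the pair universe (and hence M = its
    size) depends only on the bins, never on the observed counts.  Returns
    columns chrom, start1, end1, start2, end2, distance, count.
    """
    if dist_high is not None and dist_low > dist_high:
        raise ValueError("dist_low exceeds dist_high")
    bins = cmap.bins()
    counts = cmap.table.set_index(["chrom1", "start1", "chrom2", "start2"])["count"]
    frames = []
    for chrom in sorted(bins["chrom"].unique(), key=chrom_sort_key):
        grp = bins[bins["chrom"] == chrom].sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        mids = (starts + ends) // 2
        i, j = np.triu_indices(len(grp), k=1)
        dist = np.abs(mids[j] - mids[i])
        keep = dist >= dist_low
        if dist_high is not None:
            keep &= dist <= dist_high
        i, j, dist = i[keep], j[keep], dist[keep]
        frame = pd.DataFrame(
            {
                "chrom": chrom,
                "start1": starts[i],
                "end1": ends[i],
                "start2": starts[j],
                "end2": ends[j],
                "distance": dist,
            }
        )
        idx = pd.MultiIndex.from_arrays(
            [frame["chrom"], frame["start1"], frame["chrom"], frame["start2"]]
        )
        frame["count"] = counts.reindex(idx).fillna(0).to_numpy()
        frames.append(frame)
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "start1", "end1", "start2", "end2", "distance", "count"]
        )
    return pd.concat(frames, ignore_index=True)


def naive_pvalue(k, N: int, M: int):
    """Binomial upper tail under the uniform null ``p = 1/M``."""
    if M < 1:
        raise ValueError("M must be >= 1")
    return binom_sf(k, N, 1.0 / M)


def equal_occupancy_binning(
    universe: pd.DataFrame, b: int, occupancy: str = "count"
) -> np.ndarray:
    """Assign each pair to one of ~b distance bins of near-equal total count.

    Pairs are sorted by genomic distance and accumulated greedily until each
    bin holds roughly ``N/b`` contacts.  All pairs at one distance are
    indivisible, so per-bin totals can overshoot by at most the largest
    single-distance total.  ``b`` larger than the number of distinct
    distances is reduced with a warning.  Returns the bin index (0-based)
    per row of ``universe``.

    ``occupancy='pairs'`` balances the number of pairs per bin instead of
    the total contact count.
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    if occupancy not in ("count", "pairs"):
        raise ValueError(f"unknown occupancy mode {occupancy!r}")
    N = universe["count"].sum()
    if N <= 0:
        raise ValueError("total count must be positive")
    if occupancy == "pairs":
        groups = universe.groupby("distance")["count"].size().sort_index()
        N = len(universe)
    else:
        groups = (
            universe.groupby("distance")["count"].sum().sort_index()
        )  # distance -> total
    n_distinct = len(groups)
    if b > n_distinct:
        warnings.warn(
            f"b={b} exceeds {n_distinct} distinct distances; reduced", stacklevel=2
        )
        b = n_distinct
    target = N / b
    bin_of_distance: dict = {}
    bin_id = 0
    running = 0.0
    for distance, total in groups.items():
        if bin_id >= b:
            bin_id = b - 1
        bin_of_distance[distance] = bin_id
        running += total
        if running >= target and bin_id < b - 1:
            bin_id += 1
            running = 0.0
    return universe["distance"].map(bin_of_distance).to_numpy()


def bin_statistics(universe: pd.DataFrame, assignment: np.ndarray) -> pd.DataFrame:
    """Per-occupancy-bin averages over the full pair universe.

    ``c`` is the mean contact count per pair (zero-count pairs included),
    ``prior = c/N`` the per-pair contact probability, and ``d`` the mean
    pair distance.  ``s``/``e`` are the smallest distances in this bin and
    the next (the next bin's lower edge closes this one).
    """
    N = universe["count"].sum()
    df = universe.assign(_bin=assignment)
    agg = df.groupby("_bin").agg(
        c=("count", "mean"),
        d=("distance", "mean"),
        n_pairs=("count", "size"),
        total=("count", "sum"),
        s=("distance", "min"),
        _max=("distance", "max"),
    )
    if (agg["n_pairs"] == 0).any():
        raise ValueError("empty occupancy bin")
    agg = agg.sort_index()
    agg["e"] = agg["s"].shift(-1)
    agg.loc[agg.index[-1], "e"] = agg["_max"].iloc[-1]
    agg["prior"] = agg["c"] / N
    return agg[["s", "e", "c", "prior", "d", "n_pairs", "total"]].reset_index(drop=True)


def _pav_decreasing(y: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
    """Weighted least-squares projection onto non-increasing sequences."""
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if w is None else np.asarray(w, dtype=float)
    # pool adjacent violators on the negated sequence (increasing fit)
    vals = list(-y)
    wts = list(w)
    sizes = [1] * len(y)
    i = 0
    merged_vals: list[float] = []
    merged_wts: list[float] = []
    merged_sizes: list[int] = []
    for v, wt, sz in zip(vals, wts, sizes):
        merged_vals.append(v)
        merged_wts.append(wt)
        merged_sizes.append(sz)
        while len(merged_vals) > 1 and merged_vals[-2] > merged_vals[-1]:
            v2, w2, s2 = merged_vals.pop(), merged_wts.pop(), merged_sizes.pop()
            v1, w1, s1 = merged_vals.pop(), merged_wts.pop(), merged_sizes.pop()
            merged_vals.append((v1 * w1 + v2 * w2) / (w1 + w2))
            merged_wts.append(w1 + w2)
            merged_sizes.append(s1 + s2)
    out = np.empty_like(y)
    pos = 0
    for v, sz in zip(merged_vals, merged_sizes):
        out[pos : pos + sz] = -v
        pos += sz
    return out


def fit_distance_function(
    d_points: np.ndarray, priors: np.ndarray
) -> DistanceFunction:
    """Smoothing spline through the (distance, prior) calibration points.

    Cubic with GCV-chosen smoothing when enough points are available,
    linear interpolation otherwise; the fitted curve is projected onto
    non-increasing sequences (a contact prior rising with distance is
    non-physical) and clamped to ``[1e-15, 1]`` with constant extrapolation
    beyond the calibrated range.
    """
    d = np.asarray(d_points, dtype=float)
    pr = np.asarray(priors, dtype=float)
    if not (np.all(np.isfinite(d)) and np.all(np.isfinite(pr))):
        raise ValueError("non-finite calibration points")
    if d.size != pr.size or d.size == 0:
        raise ValueError("need matching non-empty point arrays")
    order = np.argsort(d)
    d, pr = d[order], pr[order]
    if d.size == 1 or np.allclose(pr, pr[0]):
        return DistanceFunction(d, pr)
    if d.size >= 5:
        spline = make_smoothing_spline(d, pr)
        fitted = spline(d)
    else:
        fitted = pr
    fitted = _pav_decreasing(fitted)
    return DistanceFunction(d, fitted)


def spline_pvalues(universe: pd.DataFrame, f: DistanceFunction, N: int) -> np.ndarray:
    """Per-pair binomial upper-tail p-values with ``p = f(distance)``."""
    p = f(universe["distance"].to_numpy())
    return binom_sf(universe["count"].to_numpy().astype(np.int64), N, p)


def _fit_phase(
    universe: pd.DataFrame, b: int, N: int, include: np.ndarray | None = None
) -> tuple[pd.DataFrame, DistanceFunction]:
    """One binning + spline pass, optionally on a subset of the universe."""
    sub = universe if include is None else universe[include]
    if sub.empty or sub["count"].sum() <= 0:
        raise ValueError("no pairs (or no counts) left for null estimation")
    assignment = equal_occupancy_binning(sub, b)
    stats = bin_statistics(sub, assignment)
    # priors are per-read probabilities relative to the phase's own N so the
    # function stays a probability under the full-N binomial
    stats["prior"] = stats["c"] / N
    f = fit_distance_function(stats["d"].to_numpy(), stats["prior"].to_numpy())
    return stats, f


def refine(
    universe: pd.DataFrame,
    phase1_qvalues: np.ndarray,
    b: int,
    N: int,
    refinement_q: float = 0.05,
) -> tuple[pd.DataFrame, DistanceFunction, np.ndarray]:
    """Second-phase null estimate excluding likely-real contacts.

    Pairs whose phase-1 q-value is below ``refinement_q`` are dropped from
    the binning and spline fit; the refit prior function is then used to
    recompute p-values for *all* pairs, excluded ones included.
    """
    exclude = phase1_qvalues < refinement_q
    if exclude.all():
        raise ValueError("refinement excluded every pair")
    stats, f = _fit_phase(universe, b, N, include=~exclude)
    pvals = spline_pvalues(universe, f, N)
    return stats, f, pvals


def run_fithic(
    cmap: ContactMap,
    b: int = 200,
    dist_low: int | None = None,
    dist_high: int | None = None,
    fdr_threshold: float = 0.05,
    refinement_q: float = 0.05,
    two_phase: bool = True,
) -> SignificanceResult:
    """Full two-phase pipeline on a cis, fixed-resolution map.

    Defaults: ``dist_low = 2 * binsize`` (drops adjacent-bin pairs),
    no upper bound.  Only pairs with an observed contact are reported;
    zero-count pairs still shape the null (binning, averages, M).
    """
    df = cmap.table
    if (df["chrom1"] != df["chrom2"]).any():
        raise ValueError("this model works on intra-chromosomal maps only")
    if dist_low is None:
        if cmap.resolution is None:
            raise ValueError("dist_low required for fragment-level maps")
        dist_low = 2 * cmap.resolution

    universe = enumerate_possible_pairs(cmap, dist_low, dist_high)
    M = len(universe)
    if M == 0:
        raise ValueError("no possible pairs in the distance range")
    N = int(universe["count"].sum())
    if N == 0:
        raise ValueError("no reads in the distance range")

    stats1, f1 = _fit_phase(universe, b, N)
    pvals = spline_pvalues(universe, f1, N)
    tested = universe["count"].to_numpy() > 0
    qvals = np.full(M, np.nan)
    qvals[tested] = bh_adjust(pvals[tested])

    phase = 1
    stats, f = stats1, f1
    if two_phase and refinement_q > 0:
        q_for_refine = np.where(tested, qvals, 1.0)
        stats, f, pvals = refine(universe, q_for_refine, b, N, refinement_q)
        qvals = np.full(M, np.nan)
        qvals[tested] = bh_adjust(pvals[tested])
        phase = 2

    out = universe[tested].reset_index(drop=True)
    result = pd.DataFrame(
        {
            "chrom1": out["chrom"],
            "start1": out["start1"],
            "end1": out["end1"],
            "chrom2": out["chrom"],
            "start2": out["start2"],
            "end2": out["end2"],
            "count": out["count"],
            "null_p": f(out["distance"].to_numpy()),
            "pvalue": pvals[tested],
            "rank": pvalue_ranks(pvals[tested]),
            "qvalue": qvals[tested],
            "significant": qvals[tested] < fdr_threshold,
        }
    )
    model = FithicModel(
        bins=stats, f=f, M=M, N=N, b=b, dist_low=dist_low, dist_high=dist_high,
        phase=phase,
    )
    return SignificanceResult(
        table=result[RESULT_COLUMNS],
        model="fithic",
        N=N,
        m=int(tested.sum()),
        fdr=fdr_threshold,
        metadata={"M": M, "phase": phase, "fithic_model": model},
    )
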