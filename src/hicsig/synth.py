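"""Synthetic Hi-C data drawn from each background model's own assumptions.

Every generator takes a single integer seed and uses one private
``numpy.random.Generator`` stream; there is no global random state.
Writers emit fixture files in each supported input dialect so the readers
can be exercised without external downloads.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .core_data import ContactMap, FragmentTable, GenomicBin, canonicalize
from .io_formats import FeatureTable, write_hicpro, write_interactions

__all__ = [
    "make_bins",
    "make_features",
    "simulate_gothic_null",
    "simulate_hicnorm",
    "simulate_decay",
    "emit_fixture_files",
]


def make_bins(
    chrom_lengths: dict[str, int], binsize: int, seed: int | None = None
) -> FragmentTable:
    """Contiguous fixed-size bins tiling each chromosome.

    The last bin of a chromosome is truncated at the chromosome end.  The
    seed is accepted for interface uniformity; the tiling is deterministic.
    """
    rows = []
    frag_id = 1
    for chrom, length in chrom_lengths.items():
        if length < binsize:
            raise ValueError(f"{chrom}: length {length} < binsize {binsize}")
        for start in range(0, length, binsize):
            rows.append((chrom, start, min(start + binsize, length), frag_id))
            frag_id += 1
    return FragmentTable(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "frag_id"])
    )


def make_features(
    bins: FragmentTable,
    seed: int,
    length_range: tuple[float, float] = (0.2, 1.0),
    gc_range: tuple[float, float] = (0.3, 0.6),
    mappability_range: tuple[float, float] = (0.5, 1.0),
    length_scale: str = "bin",
) -> FeatureTable:
    """Random strictly-positive covariates for every bin.

    Effective length is uniform on ``length_range`` times the bin width when
    ``length_scale='bin'`` (the default, plausible for real data) or on the
    raw range when ``length_scale='unit'`` (convenient for regression
    benchmarks where the covariate magnitude must stay moderate).
    """
    rng = np.random.default_rng(seed)
    df = bins.table.copy()
    width = (df["end"] - df["start"]).to_numpy()
    lo, hi = length_range
    eff = rng.uniform(lo, hi, len(df))
    if length_scale == "bin":
        eff = eff * width
    elif length_scale != "unit":
        raise ValueError(f"unknown length_scale {length_scale!r}")
    return FeatureTable(
        pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"],
                "end": df["end"],
                "effective_length": eff,
                "gc": rng.uniform(*gc_range, len(df)),
                "mappability": rng.uniform(*mappability_range, len(df)),
            }
        )
    )


def _bin_frame(bins: FragmentTable) -> pd.DataFrame:
    return bins.table.reset_index(drop=True)


def simulate_gothic_null(
    bins: FragmentTable,
    coverage_weights: np.ndarray,
    N: int,
    seed: int,
) -> ContactMap:
    """N read pairs over off-diagonal bin pairs with probability ~ w_j * w_h.

    This is the spurious-ligation null read generatively: both ends land
    independently according to the coverage weights, conditioned on the two
    ends being distinct bins.  The total count is exactly N.
    """
    w = np.asarray(coverage_weights, dtype=float)
    df = _bin_frame(bins)
    if len(w) != len(df):
        raise ValueError("one weight per bin required")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative and not all zero")
    i, j = np.triu_indices(len(df), k=1)
    probs = w[i] * w[j]
    total = probs.sum()
    if total <= 0:
        raise ValueError("no positive-probability pair")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(N, probs / total)
    keep = counts > 0
    records = [
        (
            GenomicBin(df.iloc[a]["chrom"], int(df.iloc[a]["start"]), int(df.iloc[a]["end"])),
            GenomicBin(df.iloc[b]["chrom"], int(df.iloc[b]["start"]), int(df.iloc[b]["end"])),
            int(c),
        )
        for a, b, c in zip(i[keep], j[keep], counts[keep])
    ]
    widths = df["end"] - df["start"]
    res = int(widths.iloc[0]) if widths.nunique() == 1 else None
    return canonicalize(records, resolution=res)


def simulate_hicnorm(
    bins: FragmentTable,
    features: FeatureTable,
    beta0: float,
    beta_len: float,
    beta_gc: float,
    seed: int,
) -> ContactMap:
    """Independent Poisson counts per off-diagonal pair with mean

    ``t = exp[beta0 + beta_len*log(x_j*x_h) + beta_gc*log(y_j*y_h)
    + log(z_j*z_h)]``.
    """
    df = _bin_frame(bins)
    feat = features.table
    keys = list(zip(df["chrom"], df["start"]))
    x = feat["effective_length"].loc[keys].to_numpy()
    y = feat["gc"].loc[keys].to_numpy()
    z = feat["mappability"].loc[keys].to_numpy()
    if np.any(x <= 0) or np.any(y <= 0) or np.any(z <= 0):
        raise ValueError("all features must be strictly positive")
    i, j = np.triu_indices(len(df), k=1)
    t = np.exp(
        beta0
        + beta_len * np.log(x[i] * x[j])
        + beta_gc * np.log(y[i] * y[j])
        + np.log(z[i] * z[j])
    )
    rng = np.random.default_rng(seed)
    counts = rng.poisson(t)
    keep = counts > 0
    records = [
        (
            GenomicBin(df.iloc[a]["chrom"], int(df.iloc[a]["start"]), int(df.iloc[a]["end"])),
            GenomicBin(df.iloc[b]["chrom"], int(df.iloc[b]["start"]), int(df.iloc[b]["end"])),
            int(c),
        )
        for a, b, c in zip(i[keep], j[keep], counts[keep])
    ]
    widths = df["end"] - df["start"]
    res = int(widths.iloc[0]) if widths.nunique() == 1 else None
    return canonicalize(records, resolution=res)


def simulate_decay(
    bins: FragmentTable,
    N: int,
    decay_exponent: float = 1.0,
    loops: list[tuple[tuple[str, int, str, int], float]] | None = None,
    seed: int = 0,
    dist_low: int = 0,
) -> ContactMap:
    """N reads multinomial over cis pairs with weight ``distance**-exponent``.

    ``loops`` plants extra signal: each entry is ``((chrom1, start1, chrom2,
    start2), fold)`` and multiplies that pair's weight by ``fold``.  Pairs
    closer than ``dist_low`` get zero weight.
    """
    if decay_exponent <= 0:
        raise ValueError("decay exponent must be positive")
    df = _bin_frame(bins)
    frames = []
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start").reset_index(drop=True)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        mids = (starts + ends) // 2
        i, j = np.triu_indices(len(grp), k=1)
        dist = np.abs(mids[j] - mids[i])
        keep = dist >= max(dist_low, 1)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start1": starts[i[keep]],
                    "end1": ends[i[keep]],
                    "start2": starts[j[keep]],
                    "end2": ends[j[keep]],
                    "distance": dist[keep],
                }
            )
        )
    pairs = pd.concat(frames, ignore_index=True)
    weights = pairs["distance"].to_numpy().astype(float) ** (-decay_exponent)
    if loops:
        index = {
            (r.chrom, r.start1, r.chrom, r.start2): k
            for k, r in enumerate(pairs.itertuples())
        }
        for (c1, s1, c2, s2), fold in loops:
            if fold < 1:
                raise ValueError("loop fold must be >= 1")
            key = (c1, s1, c2, s2) if (c1, s1) <= (c2, s2) else (c2, s2, c1, s1)
            if key not in index:
                raise ValueError(f"loop pair {key} outside the bin universe")
            weights[index[key]] *= fold
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(N, weights / weights.sum())
    keep = counts > 0
    sub = pairs[keep]
    records = [
        (
            GenomicBin(r.chrom, int(r.start1), int(r.end1)),
            GenomicBin(r.chrom, int(r.start2), int(r.end2)),
            int(c),
        )
        for r, c in zip(sub.itertuples(), counts[keep])
    ]
    widths = df["end"] - df["start"]
    res = int(widths.iloc[0]) if widths.nunique() == 1 else None
    return canonicalize(records, resolution=res)


def emit_fixture_files(
    cmap: ContactMap,
    fragments: FragmentTable,
    dialect: str,
    outdir: str,
    prefix: str = "synthetic",
) -> dict[str, str]:
    """Write a map in one input dialect; returns the paths written.

    Dialects: ``hicup`` (4-column pairs + digest; a count-c pair becomes c
    read-pair id groups), ``hicpro`` (.matrix + .bed), ``homer`` (CSV with
    header), ``interactions`` (5-column output layout).
    """
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    if dialect == "hicup":
        pairs_path = os.path.join(outdir, f"{prefix}.pairs.txt")
        digest_path = os.path.join(outdir, f"{prefix}.digest.txt")
        read_id = 1
        with open(pairs_path, "w") as fh:
            for a, b, count in cmap.records():
                for _ in range(int(count)):
                    fh.write(f"{read_id}\t0\t{a.chrom}\t{a.mid}\n")
                    fh.write(f"{read_id}\t0\t{b.chrom}\t{b.mid}\n")
                    read_id += 1
        fragments.table[["chrom", "start", "end"]].to_csv(
            digest_path, sep="\t", header=False, index=False
        )
        paths = {"pairs": pairs_path, "digest": digest_path}
    elif dialect == "hicpro":
        matrix_path = os.path.join(outdir, f"{prefix}.matrix")
        bed_path = os.path.join(outdir, f"{prefix}.bed")
        write_hicpro(cmap, matrix_path, bed_path)
        paths = {"matrix": matrix_path, "bed": bed_path}
    elif dialect == "homer":
        path = os.path.join(outdir, f"{prefix}.homer.csv")
        df = cmap.table
        out = pd.DataFrame(
            {
                "chr1": df["chrom1"],
                "start1": df["start1"],
                "chr2": df["chrom2"],
                "start2": df["start2"],
                "count": df["count"],
            }
        )
        out.to_csv(path, index=False)
        paths = {"homer": path}
    elif dialect == "interactions":
        path = os.path.join(outdir, f"{prefix}.interactions.tsv")
        write_interactions(cmap, path)
        paths = {"interactions": path}
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return paths
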