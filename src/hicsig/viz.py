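"""Static arc-diagram and heatmap rendering.

Arc diagrams show cis interactions only: one arc per pair between bin
midpoints, with line width increasing linearly in read count and
significant pairs (when available) drawn in a highlight color.  Heatmaps
assemble a symmetric matrix over one, several, or all chromosomes, colored
by read count or by -log10 p-value between two user-chosen endpoint
colors.
"""

from __future__ import annotations

import logging

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap
from matplotlib.patches import Arc, Rectangle

from .core_data import ContactMap, chrom_sort_key, split_cis_trans
from .io_formats import AnnotationTrack
from .result import SignificanceResult

__all__ = ["arc_plot", "heatmap_plot", "assemble_matrix", "filter_arc_pairs"]

log = logging.getLogger(__name__)

DEFAULT_COLOR_LOW = "yellow"
DEFAULT_COLOR_HIGH = "black"


def _as_table(data) -> tuple[pd.DataFrame, bool]:
    """Normalize input to a pair table; second value marks test results."""
    if isinstance(data, SignificanceResult):
        return data.table, True
    if isinstance(data, ContactMap):
        return data.table, False
    raise TypeError(f"cannot plot {type(data).__name__}")


def filter_arc_pairs(
    data,
    region: tuple[str, int, int] | None = None,
    min_count: float = 0,
    only_significant: bool = False,
) -> pd.DataFrame:
    """The pairs an arc plot will draw: cis, in-region, above threshold."""
    df, has_test = _as_table(data)
    cis = df[df["chrom1"] == df["chrom2"]]
    n_trans = len(df) - len(cis)
    if n_trans:
        log.info("dropping %d trans pair(s) from arc diagram", n_trans)
    if region is not None:
        chrom, start, end = region
        cis = cis[
            (cis["chrom1"] == chrom)
            & (cis["start1"] >= start)
            & (cis["end2"] <= end)
        ]
    cis = cis[cis["count"] >= min_count]
    if only_significant:
        if not has_test:
            raise ValueError("no significance flags on this input")
        cis = cis[cis["significant"]]
    return cis.reset_index(drop=True)


def _arc_widths(counts: np.ndarray, w_min: float = 0.5, w_max: float = 4.0):
    c_min, c_max = counts.min(), counts.max()
    if c_max == c_min:
        return np.full(len(counts), (w_min + w_max) / 2)
    frac = (counts - c_min) / (c_max - c_min)
    return np.clip(w_min + (w_max - w_min) * frac, w_min, w_max)


def arc_plot(
    data,
    region: tuple[str, int, int] | None = None,
    min_count: float = 0,
    annotations: AnnotationTrack | None = None,
    out_path: str | None = None,
    highlight_significant: bool = True,
    only_significant: bool = False,
    color: str = "steelblue",
    significant_color: str = "crimson",
):
    """Render an arc diagram; returns the matplotlib figure.

    Arcs are ``matplotlib.patches.Arc`` instances, so tests (and callers)
    can count rendered interactions directly from the axes.  Annotation
    intervals, when given, appear as rectangles on a top track (promoter
    strand shown in blue, other intervals in yellow).
    """
    df, has_test = _as_table(data)
    if region is not None:
        chroms = set(df["chrom1"]) | set(df["chrom2"])
        if region[0] not in chroms:
            raise ValueError(f"chromosome {region[0]!r} not present in the data")
    pairs = filter_arc_pairs(
        data, region=region, min_count=min_count, only_significant=only_significant
    )

    fig, ax = plt.subplots(figsize=(10, 4))
    if len(pairs):
        mid1 = ((pairs["start1"] + pairs["end1"]) // 2).to_numpy()
        mid2 = ((pairs["start2"] + pairs["end2"]) // 2).to_numpy()
        counts = pairs["count"].to_numpy().astype(float)
        widths = _arc_widths(counts)
        sig = (
            pairs["significant"].to_numpy()
            if has_test and highlight_significant
            else np.zeros(len(pairs), dtype=bool)
        )
        for x1, x2, lw, is_sig in zip(mid1, mid2, widths, sig):
            span = abs(x2 - x1)
            arc = Arc(
                ((x1 + x2) / 2, 0),
                width=span,
                height=span / 2,
                theta1=0,
                theta2=180,
                lw=lw,
                color=significant_color if is_sig else color,
            )
            ax.add_patch(arc)
        lo = min(mid1.min(), mid2.min())
        hi = max(mid1.max(), mid2.max())
        pad = max((hi - lo) * 0.05, 1)
        ax.set_xlim(lo - pad, hi + pad)
        ax.set_ylim(0, (hi - lo) / 3 + pad)
    else:
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)

    if annotations is not None and len(annotations):
        y_top = ax.get_ylim()[1]
        band = y_top * 0.06 if y_top > 0 else 0.06
        ann = annotations.intervals
        if region is not None:
            ann = annotations.in_region(*region)
        for r in ann.itertuples():
            is_promoter = r.strand in ("+", "-")
            ax.add_patch(
                Rectangle(
                    (r.start, y_top),
                    r.end - r.start,
                    band,
                    clip_on=False,
                    facecolor="blue" if is_promoter else "yellow",
                    edgecolor="none",
                )
            )
    ax.set_yticks([])
    ax.set_xlabel("position (bp)")
    if out_path:
        fig.savefig(out_path, bbox_inches="tight")
    return fig


def assemble_matrix(
    data,
    chroms: list[str] | None = None,
    value: str = "count",
    min_count: float = 0,
) -> tuple[np.ndarray, pd.DataFrame, list[int]]:
    """Symmetric matrix over the selected chromosomes.

    Returns ``(matrix, bin_table, boundaries)`` where ``boundaries`` are the
    row indices at which a new chromosome starts (useful as separators).
    ``value='pvalue'`` fills cells with -log10 p (requires test results);
    cells below ``min_count`` are NaN (blank).
    """
    df, has_test = _as_table(data)
    if value not in ("count", "pvalue"):
        raise ValueError(f"unknown value mode {value!r}")
    if value == "pvalue" and not has_test:
        raise ValueError("p-value coloring requires a significance result")

    a = df[["chrom1", "start1", "end1"]].rename(
        columns={"chrom1": "chrom", "start1": "start", "end1": "end"}
    )
    b = df[["chrom2", "start2", "end2"]].rename(
        columns={"chrom2": "chrom", "start2": "start", "end2": "end"}
    )
    bins = pd.concat([a, b]).drop_duplicates()
    if chroms is not None:
        missing = set(chroms) - set(bins["chrom"])
        if missing:
            raise ValueError(f"chromosome(s) not present: {sorted(missing)}")
        bins = bins[bins["chrom"].isin(chroms)]
        df = df[df["chrom1"].isin(chroms) & df["chrom2"].isin(chroms)]
    bins = bins.sort_values(
        ["chrom", "start"],
        key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s,
        kind="stable",
    ).reset_index(drop=True)

    index = {(r.chrom, r.start): i for i, r in enumerate(bins.itertuples())}
    n = len(bins)
    mat = np.full((n, n), np.nan)
    for r in df.itertuples():
        i = index.get((r.chrom1, r.start1))
        j = index.get((r.chrom2, r.start2))
        if i is None or j is None:
            continue
        if r.count < min_count:
            continue
        v = r.count if value == "count" else -np.log10(max(r.pvalue, 1e-300))
        mat[i, j] = v
        mat[j, i] = v

    boundaries = []
    prev = None
    for i, r in enumerate(bins.itertuples()):
        if prev is not None and r.chrom != prev:
            boundaries.append(i)
        prev = r.chrom
    return mat, bins, boundaries


def heatmap_plot(
    data,
    chroms: list[str] | None = None,
    value: str = "count",
    color_low: str = DEFAULT_COLOR_LOW,
    color_high: str = DEFAULT_COLOR_HIGH,
    min_count: float = 0,
    out_path: str | None = None,
):
    """Render the contact-map heatmap; returns the matplotlib figure.

    The assembled matrix and chromosome boundaries are attached to the
    figure as ``fig.hic_matrix`` and ``fig.hic_boundaries``.
    """
    mat, bins, boundaries = assemble_matrix(
        data, chroms=chroms, value=value, min_count=min_count
    )
    cmap = LinearSegmentedColormap.from_list("hic", [color_low, color_high])
    fig, ax = plt.subplots(figsize=(6, 6))
    if mat.size:
        im = ax.imshow(mat, cmap=cmap, interpolation="nearest")
        fig.colorbar(
            im, ax=ax, label="read count" if value == "count" else "-log10 p"
        )
    for boundary in boundaries:
        ax.axhline(boundary - 0.5, color="grey", lw=0.8)
        ax.axvline(boundary - 0.5, color="grey", lw=0.8)
    ax.set_xlabel("bin")
    ax.set_ylabel("bin")
    fig.hic_matrix = mat
    fig.hic_boundaries = boundaries
    if out_path:
        fig.savefig(out_path, bbox_inches="tight")
    return fig
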