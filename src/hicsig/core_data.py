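"""Contact-map data model and preprocessing.

Coordinates are 0-based, half-open throughout. A :class:`ContactMap` is a
canonical table of locus-pair counts: every record is ordered so that
``(chrom1, start1) <= (chrom2, start2)`` under a natural chromosome sort,
duplicates are aggregated, and ``N`` always equals the sum of counts.
Counts are integers for raw maps and reals after normalization (tracked by
the ``normalized`` flag).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicBin",
    "FragmentTable",
    "ContactMap",
    "chrom_sort_key",
    "canonicalize",
    "rebin",
    "remove_diagonal",
    "split_cis_trans",
    "pair_distance",
]

PAIR_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "count"]

_CHUNK_RE = re.compile(r"(\d+)")


def chrom_sort_key(chrom: str) -> tuple:
    """Natural-sort key so that chr2 < chr10 and chrX > chr22."""
    parts = _CHUNK_RE.split(str(chrom))
    return tuple((0, int(p)) if p.isdigit() else (1, p) for p in parts if p != "")


@dataclass(frozen=True, order=False)
class GenomicBin:
    """A half-open genomic interval ``[start, end)``.

    The midpoint is ``floor((start + end) / 2)``; it is the position used
    for distance computations and fixed-size re-binning.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def mid(self) -> int:
        return (self.start + self.end) // 2

    def sort_key(self) -> tuple:
        return (chrom_sort_key(self.chrom), self.start)


class FragmentTable:
    """Ordered, non-overlapping genomic fragments with unique identifiers.

    Backed by a DataFrame with columns ``chrom, start, end, frag_id``,
    sorted by (chrom, start).  Used both for restriction digests
    (fragment-level data) and for fixed-size bin tilings.
    """

    COLUMNS = ["chrom", "start", "end", "frag_id"]

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"fragment table missing columns: {missing}")
        df = table[self.COLUMNS].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
            raise ValueError("fragments must satisfy 0 <= start < end")
        if df["frag_id"].duplicated().any():
            dup = df.loc[df["frag_id"].duplicated(), "frag_id"].iloc[0]
            raise ValueError(f"duplicate fragment identifier: {dup!r}")
        df = df.sort_values(
            ["chrom", "start"],
            key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s,
            kind="stable",
        ).reset_index(drop=True)
        for chrom, grp in df.groupby("chrom", sort=False):
            if (grp["start"].values[1:] < grp["end"].values[:-1]).any():
                raise ValueError(f"overlapping fragments on {chrom}")
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other) -> bool:
        return isinstance(other, FragmentTable) and self.table.equals(other.table)

    def bins(self) -> list[GenomicBin]:
        return [
            GenomicBin(r.chrom, int(r.start), int(r.end))
            for r in self.table.itertuples()
        ]

    def locate(self, chrom: str, pos: int) -> GenomicBin | None:
        """Return the fragment containing ``pos`` on ``chrom`` or None."""
        grp = self.table[self.table["chrom"] == chrom]
        if grp.empty:
            return None
        starts = grp["start"].values
        idx = np.searchsorted(starts, pos, side="right") - 1
        if idx < 0:
            return None
        row = grp.iloc[idx]
        if pos >= row["end"]:
            return None
        return GenomicBin(chrom, int(row["start"]), int(row["end"]))


class ContactMap:
    """Canonical sparse table of locus-pair interaction counts.

    Parameters
    ----------
    table : DataFrame with columns ``chrom1, start1, end1, chrom2, start2,
        end2, count``, already canonical (use :func:`canonicalize` to build
        one from raw records).
    resolution : fixed bin size in bp, or ``None`` for fragment-level maps.
    normalized : whether counts are real-valued model residuals rather than
        raw integer read counts.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        resolution: int | None = None,
        normalized: bool = False,
    ):
        missing = [c for c in PAIR_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"contact table missing columns: {missing}")
        df = table[PAIR_COLUMNS].reset_index(drop=True).copy()
        for c in ("start1", "end1", "start2", "end2"):
            df[c] = df[c].astype(np.int64)
        df["count"] = df["count"].astype(float)
        if (df["count"] < 0).any():
            idx = int(df.index[df["count"] < 0][0])
            raise ValueError(f"negative count at record {idx}")
        if not normalized:
            counts = df["count"].to_numpy()
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("raw contact maps require integer counts")
            df["count"] = np.round(counts).astype(np.int64)
        self.table = df
        self.resolution = resolution
        self.normalized = normalized

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ContactMap):
            return NotImplemented
        return (
            self.resolution == other.resolution
            and self.normalized == other.normalized
            and self.table.equals(other.table)
        )

    @property
    def N(self) -> float:
        total = self.table["count"].sum()
        return float(total) if self.normalized else int(total)

    @property
    def is_empty(self) -> bool:
        return len(self.table) == 0

    def bins(self) -> pd.DataFrame:
        """Unique bins appearing as either endpoint, in canonical order."""
        a = self.table[["chrom1", "start1", "end1"]].rename(
            columns={"chrom1": "chrom", "start1": "start", "end1": "end"}
        )
        b = self.table[["chrom2", "start2", "end2"]].rename(
            columns={"chrom2": "chrom", "start2": "start", "end2": "end"}
        )
        bins = pd.concat([a, b]).drop_duplicates()
        bins = bins.sort_values(
            ["chrom", "start"],
            key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s,
            kind="stable",
        ).reset_index(drop=True)
        return bins

    def records(self) -> Iterable[tuple[GenomicBin, GenomicBin, float]]:
        for r in self.table.itertuples():
            yield (
                GenomicBin(r.chrom1, r.start1, r.end1),
                GenomicBin(r.chrom2, r.start2, r.end2),
                r.count,
            )


def _canonical_sort(df: pd.DataFrame) -> pd.DataFrame:
    key1 = df["chrom1"].map(chrom_sort_key)
    key2 = df["chrom2"].map(chrom_sort_key)
    order = pd.DataFrame(
        {"k1": key1, "s1": df["start1"], "k2": key2, "s2": df["start2"]}
    )
    idx = order.sort_values(["k1", "s1", "k2", "s2"], kind="stable").index
    return df.loc[idx].reset_index(drop=True)


def canonicalize(
    records: Sequence[tuple[GenomicBin, GenomicBin, float]] | pd.DataFrame,
    resolution: int | None = None,
    normalized: bool = False,
) -> ContactMap:
    """Build a canonical :class:`ContactMap` from raw pair records.

    Pairs are ordered so the lesser locus comes first, duplicates are merged
    by summing counts, and rows are sorted deterministically.  Negative
    counts are rejected with the offending record index.
    """
    if isinstance(records, pd.DataFrame):
        df = records[PAIR_COLUMNS].copy()
    else:
        rows = []
        for i, (a, b, count) in enumerate(records):
            if count < 0:
                raise ValueError(f"negative count at record {i}")
            rows.append(
                (a.chrom, a.start, a.end, b.chrom, b.start, b.end, count)
            )
        df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    if df.empty:
        return ContactMap(
            pd.DataFrame(columns=PAIR_COLUMNS), resolution, normalized
        )
    if (df["count"] < 0).any():
        idx = int(df.index[df["count"] < 0][0])
        raise ValueError(f"negative count at record {idx}")

    key1 = df["chrom1"].map(chrom_sort_key)
    key2 = df["chrom2"].map(chrom_sort_key)
    swap = (key2 < key1) | ((key2 == key1) & (df["start2"] < df["start1"]))
    if swap.any():
        left = df.loc[swap, ["chrom1", "start1", "end1"]].values
        right = df.loc[swap, ["chrom2", "start2", "end2"]].values
        df.loc[swap, ["chrom1", "start1", "end1"]] = right
        df.loc[swap, ["chrom2", "start2", "end2"]] = left

    grouped = (
        df.groupby(
            ["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
            as_index=False,
            sort=False,
        )["count"].sum()
    )
    grouped = _canonical_sort(grouped)
    return ContactMap(grouped, resolution, normalized)


def rebin(
    cmap: ContactMap,
    binsize: int,
    fragments: FragmentTable | None = None,
) -> ContactMap:
    """Aggregate a map to fixed-size bins of ``binsize`` bp.

    Each locus is assigned to the bin ``floor(mid / binsize)``; the total
    count is preserved exactly.  Refinement (a binsize smaller than the
    current resolution) is rejected.  ``fragments`` may supply chromosome
    extents to truncate the last bin of each chromosome; otherwise bins are
    full-width.
    """
    if binsize <= 0:
        raise ValueError("binsize must be positive")
    if cmap.resolution is not None and binsize < cmap.resolution:
        raise ValueError(
            f"cannot refine resolution {cmap.resolution} to {binsize}"
        )
    chrom_ends: dict[str, int] = {}
    if fragments is not None:
        chrom_ends = fragments.table.groupby("chrom")["end"].max().to_dict()

    df = cmap.table.copy()
    if df.empty:
        return ContactMap(df, binsize, cmap.normalized)

    for side in ("1", "2"):
        mid = (df[f"start{side}"] + df[f"end{side}"]) // 2
        bstart = (mid // binsize) * binsize
        bend = bstart + binsize
        if chrom_ends:
            cap = df[f"chrom{side}"].map(chrom_ends)
            bend = np.minimum(bend, cap.fillna(bend).astype(np.int64))
        df[f"start{side}"] = bstart
        df[f"end{side}"] = bend
    return canonicalize(df, resolution=binsize, normalized=cmap.normalized)


def remove_diagonal(cmap: ContactMap) -> ContactMap:
    """Drop self-pair records (both endpoints the same bin)."""
    df = cmap.table
    keep = ~((df["chrom1"] == df["chrom2"]) & (df["start1"] == df["start2"]))
    return ContactMap(
        df[keep].reset_index(drop=True), cmap.resolution, cmap.normalized
    )


def split_cis_trans(cmap: ContactMap) -> tuple[ContactMap, ContactMap]:
    """Partition records into intra- and inter-chromosomal maps."""
    df = cmap.table
    is_cis = df["chrom1"] == df["chrom2"]
    cis = ContactMap(
        df[is_cis].reset_index(drop=True), cmap.resolution, cmap.normalized
    )
    trans = ContactMap(
        df[~is_cis].reset_index(drop=True), cmap.resolution, cmap.normalized
    )
    return cis, trans


def pair_distance(a: GenomicBin, b: GenomicBin) -> int:
    """Genomic distance between two same-chromosome bins (midpoint based)."""
    if a.chrom != b.chrom:
        raise ValueError(
            f"pair distance undefined across chromosomes {a.chrom}/{b.chrom}"
        )
    return abs(a.mid - b.mid)
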