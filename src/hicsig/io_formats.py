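"""Readers and writers for the supported text dialects.

Supported inputs: HiCUP-style 4-column paired-read file plus restriction
digest table; HiC-Pro sparse ``.matrix`` plus bin ``.bed``; a minimal
header-driven HOMER-like interaction table; a per-bin covariate table for
normalization; BED annotation tracks.  Output: the tab-separated
interaction file (5 columns for raw maps, 8 when a significance test has
been run).

All readers return canonical :class:`~hicsig.core_data.ContactMap` objects.
The HiCUP "flag" column is read and ignored.  HiC-Pro bed starts are
treated as 0-based.  Interaction-file locus columns are bin starts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import (
    ContactMap,
    FragmentTable,
    GenomicBin,
    canonicalize,
    chrom_sort_key,
)

__all__ = [
    "AnnotationTrack",
    "FeatureTable",
    "read_hicup",
    "read_hicpro",
    "write_hicpro",
    "read_homer",
    "read_features",
    "read_annotations",
    "read_interactions",
    "write_interactions",
]

log = logging.getLogger(__name__)

FEATURE_COLUMNS = ["chrom", "start", "end", "effective_length", "gc", "mappability"]


class FeatureTable:
    """Per-bin covariates: effective length, GC fraction and mappability.

    Indexed by ``(chrom, start)``.  Bins with any feature equal to zero are
    loaded but flagged unusable (``usable`` column) because the model takes
    logs of the features.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        df = table[FEATURE_COLUMNS].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if ((df["gc"] < 0) | (df["gc"] > 1)).any():
            raise ValueError("gc content must lie in [0, 1]")
        if ((df["mappability"] < 0) | (df["mappability"] > 1)).any():
            raise ValueError("mappability must lie in [0, 1]")
        if (df["effective_length"] < 0).any():
            raise ValueError("effective length must be >= 0")
        if df.duplicated(["chrom", "start"]).any():
            dup = df[df.duplicated(["chrom", "start"])].iloc[0]
            raise ValueError(f"duplicate feature row for {dup.chrom}:{dup.start}")
        df["usable"] = (
            (df["effective_length"] > 0)
            & (df["gc"] > 0)
            & (df["mappability"] > 0)
        )
        self.table = df.set_index(["chrom", "start"], drop=False)

    def __len__(self) -> int:
        return len(self.table)

    def lookup(self, chrom: str, start: int) -> pd.Series:
        try:
            return self.table.loc[(chrom, start)]
        except KeyError:
            raise KeyError(f"no features for bin {chrom}:{start}") from None

    def require_covering(self, bins: pd.DataFrame) -> None:
        """Raise if any bin (chrom/start rows) lacks a feature row."""
        have = set(zip(self.table["chrom"], self.table["start"]))
        for r in bins.itertuples():
            if (r.chrom, r.start) not in have:
                raise ValueError(f"bin {r.chrom}:{r.start} absent from feature table")


@dataclass
class AnnotationTrack:
    """BED-derived interval annotations for plotting."""

    intervals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "start", "end", "name", "strand"]
        )
    )

    def __len__(self) -> int:
        return len(self.intervals)

    def in_region(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        df = self.intervals
        sel = (df["chrom"] == chrom) & (df["end"] > start) & (df["start"] < end)
        return df[sel]


# ---------------------------------------------------------------------------
# readers


def read_hicup(pairs_path, digest_path) -> ContactMap:
    """Read a HiCUP-style paired-read file against a restriction digest.

    The pairs file has 4 whitespace-delimited columns: id, flag, chromosome,
    position.  Two rows sharing an id form one read pair; each such pair
    contributes a count of 1 between the digest fragments containing the two
    positions.  Ids with other than two rows, and positions outside every
    fragment, are skipped with a warning.  The flag column is ignored.
    """
    digest = pd.read_csv(
        digest_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "start", "end"],
        usecols=[0, 1, 2],
        comment="#",
        dtype={0: str},
    )
    digest["frag_id"] = np.arange(1, len(digest) + 1)
    fragments = FragmentTable(digest)

    try:
        reads = pd.read_csv(
            pairs_path,
            sep=r"\s+",
            header=None,
            names=["read_id", "flag", "chrom", "pos"],
            usecols=[0, 1, 2, 3],
            dtype={0: str, 2: str},
        )
    except pd.errors.EmptyDataError:
        return canonicalize([])

    sizes = reads.groupby("read_id", sort=False).size()
    bad_ids = sizes[sizes != 2]
    if len(bad_ids):
        warnings.warn(
            f"skipping {len(bad_ids)} read id(s) without exactly two rows",
            stacklevel=2,
        )
        reads = reads[~reads["read_id"].isin(bad_ids.index)]

    records = []
    n_unmapped = 0
    for _, grp in reads.groupby("read_id", sort=False):
        (c1, p1), (c2, p2) = zip(grp["chrom"], grp["pos"])
        a = fragments.locate(c1, int(p1))
        b = fragments.locate(c2, int(p2))
        if a is None or b is None:
            n_unmapped += 1
            continue
        records.append((a, b, 1))
    if n_unmapped:
        warnings.warn(
            f"skipping {n_unmapped} read pair(s) outside the digest", stacklevel=2
        )
    return canonicalize(records)


def read_hicpro(matrix_path, bed_path) -> ContactMap:
    """Read a HiC-Pro sparse matrix (id1, id2, count) plus its bin bed file."""
    try:
        bed = pd.read_csv(
            bed_path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "frag_id"],
            dtype={0: str},
        )
    except pd.errors.EmptyDataError:
        bed = pd.DataFrame(columns=["chrom", "start", "end", "frag_id"])
    fragments = FragmentTable(bed)
    by_id = {
        r.frag_id: GenomicBin(r.chrom, int(r.start), int(r.end))
        for r in fragments.table.itertuples()
    }
    try:
        mat = pd.read_csv(
            matrix_path, sep="\t", header=None, names=["id1", "id2", "count"]
        )
    except pd.errors.EmptyDataError:
        mat = pd.DataFrame(columns=["id1", "id2", "count"])

    counts = mat["count"].to_numpy()
    integral = len(counts) == 0 or np.allclose(
        counts.astype(float), np.round(counts.astype(float))
    )
    records = []
    for r in mat.itertuples():
        for locus_id in (r.id1, r.id2):
            if locus_id not in by_id:
                raise ValueError(f"matrix locus id {locus_id} missing from bed file")
        records.append((by_id[r.id1], by_id[r.id2], float(r.count)))
    widths = fragments.table["end"] - fragments.table["start"]
    resolution = int(widths.iloc[0]) if len(widths) and widths.nunique() == 1 else None
    return canonicalize(records, resolution=resolution, normalized=not integral)


def write_hicpro(cmap: ContactMap, matrix_path, bed_path) -> None:
    """Write a map as a HiC-Pro sparse matrix + bed pair (round-trippable)."""
    bins = cmap.bins().reset_index(drop=True)
    bins["frag_id"] = np.arange(1, len(bins) + 1)
    ids = {(r.chrom, r.start): r.frag_id for r in bins.itertuples()}
    bins[["chrom", "start", "end", "frag_id"]].to_csv(
        bed_path, sep="\t", header=False, index=False
    )
    df = cmap.table
    out = pd.DataFrame(
        {
            "id1": [ids[(c, s)] for c, s in zip(df["chrom1"], df["start1"])],
            "id2": [ids[(c, s)] for c, s in zip(df["chrom2"], df["start2"])],
            "count": df["count"].values,
        }
    )
    out.to_csv(matrix_path, sep="\t", header=False, index=False)


_HOMER_REQUIRED = ["chr1", "start1", "chr2", "start2", "count"]


def read_homer(path, binsize: int | None = None) -> ContactMap:
    """Read the minimal HOMER-like interaction table.

    Delimited text (comma or tab, sniffed) with a header containing at least
    ``chr1, start1, chr2, start2, count``.  ``binsize`` gives bin widths; when
    omitted it is inferred from the smallest positive start difference.
    """
    with open(path) as fh:
        header_line = fh.readline()
    sep = "," if header_line.count(",") >= header_line.count("\t") else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"chr1": str, "chr2": str})
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _HOMER_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(
            f"missing required column(s) {missing}; header was {list(df.columns)}"
        )
    if df.empty:
        return canonicalize([], resolution=binsize)
    if binsize is None:
        starts = np.unique(
            np.concatenate([df["start1"].values, df["start2"].values])
        )
        diffs = np.diff(np.sort(starts))
        diffs = diffs[diffs > 0]
        if len(diffs) == 0:
            raise ValueError("cannot infer binsize; pass it explicitly")
        binsize = int(diffs.min())
    records = [
        (
            GenomicBin(r.chr1, int(r.start1), int(r.start1) + binsize),
            GenomicBin(r.chr2, int(r.start2), int(r.start2) + binsize),
            float(r.count),
        )
        for r in df.itertuples()
    ]
    return canonicalize(records, resolution=binsize)


def read_features(path, bins: pd.DataFrame | None = None) -> FeatureTable:
    """Read the per-bin covariate table.

    Whitespace/tab-delimited columns: chrom, start, end, effective_length,
    gc, mappability.  When ``bins`` (a chrom/start/end frame, e.g.
    ``ContactMap.bins()``) is given, every bin must be covered.
    """
    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=FEATURE_COLUMNS, comment="#",
        dtype={0: str},
    )
    # tolerate a header row
    if len(df) and not str(df.iloc[0]["start"]).lstrip("-").isdigit():
        df = df.iloc[1:].reset_index(drop=True)
    for c in ("start", "end"):
        df[c] = df[c].astype(np.int64)
    for c in ("effective_length", "gc", "mappability"):
        df[c] = df[c].astype(float)
    features = FeatureTable(df)
    if bins is not None:
        features.require_covering(bins)
    return features


def write_features(features: FeatureTable, path) -> None:
    features.table[FEATURE_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_annotations(bed_path) -> AnnotationTrack:
    """Read a BED3+ annotation track; malformed lines are skipped with a warning."""
    rows = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                if start >= end:
                    raise ValueError
            except (IndexError, ValueError):
                warnings.warn(f"skipping malformed BED line {lineno}", stacklevel=2)
                continue
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else ""
            rows.append((chrom, start, end, name, strand))
    return AnnotationTrack(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    )


# ---------------------------------------------------------------------------
# interaction files

_RAW_HEADER = ["chr1", "locus1", "chr2", "locus2", "readCount"]
_TESTED_HEADER = _RAW_HEADER + ["pvalue", "qvalue", "significant"]


def write_interactions(data, path) -> None:
    """Write a contact map or significance result as a tab-separated table.

    Raw maps produce the 5-column layout (chr1, locus1, chr2, locus2,
    readCount); significance results append pvalue, qvalue and significant.
    The locus columns are bin starts and rows follow canonical pair order.
    """
    from .result import SignificanceResult  # local import avoids a cycle

    if isinstance(data, SignificanceResult):
        df = data.table
        out = pd.DataFrame(
            {
                "chr1": df["chrom1"],
                "locus1": df["start1"],
                "chr2": df["chrom2"],
                "locus2": df["start2"],
                "readCount": df["count"],
                "pvalue": df["pvalue"],
                "qvalue": df["qvalue"],
                "significant": df["significant"].astype(int),
            }
        )
    elif isinstance(data, ContactMap):
        df = data.table
        out = pd.DataFrame(
            {
                "chr1": df["chrom1"],
                "locus1": df["start1"],
                "chr2": df["chrom2"],
                "locus2": df["start2"],
                "readCount": df["count"],
            }
        )
    else:
        raise TypeError(f"cannot write {type(data).__name__}")
    out.to_csv(path, sep="\t", index=False)


def read_interactions(path, binsize: int | None = None) -> ContactMap:
    """Read a 5- or 8-column interaction file back into a ContactMap.

    Bin ends are ``locus + binsize``; when ``binsize`` is omitted it is
    inferred as in :func:`read_homer`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chr1": str, "chr2": str})
    missing = [c for c in _RAW_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"interaction file missing column(s) {missing}")
    if df.empty:
        return canonicalize([], resolution=binsize)
    if binsize is None:
        starts = np.unique(
            np.concatenate([df["locus1"].values, df["locus2"].values])
        )
        diffs = np.diff(np.sort(starts))
        diffs = diffs[diffs > 0]
        if len(diffs) == 0:
            raise ValueError("cannot infer binsize; pass it explicitly")
        binsize = int(diffs.min())
    counts = df["readCount"].to_numpy().astype(float)
    normalized = not np.allclose(counts, np.round(counts))
    records = [
        (
            GenomicBin(r.chr1, int(r.locus1), int(r.locus1) + binsize),
            GenomicBin(r.chr2, int(r.locus2), int(r.locus2) + binsize),
            float(r.readCount),
        )
        for r in df.itertuples()
    ]
    return canonicalize(records, resolution=binsize, normalized=normalized)
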