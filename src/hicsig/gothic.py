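"""Coverage-product binomial background model.

The null says a read pair joins loci j and h through spurious ligation with
probability ``p = 2 * rc_j * rc_h`` where ``rc_j = reads_j / (2N)`` is the
locus's relative coverage (its share of all mapped read ends).  The p-value
of an observed count is the binomial upper tail over all N read pairs, and
q-values come from the BH adjustment.  Cis and trans pairs are modeled
jointly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import ContactMap, remove_diagonal as _remove_diagonal
from .multitest import bh_adjust, binom_sf, pvalue_ranks
from .result import RESULT_COLUMNS, SignificanceResult

__all__ = ["GothicModel", "compute_relative_coverage", "pair_null_probability", "run_gothic"]


@dataclass
class GothicModel:
    """Relative coverage per bin plus the totals behind it."""

    relative_coverage: pd.Series  # indexed by (chrom, start)
    N: int
    m: int


def compute_relative_coverage(cmap: ContactMap) -> GothicModel:
    """Per-bin relative coverage ``reads_j / (2N)``.

    ``reads_j`` sums the counts of every pair incident to bin j; a self-pair
    contributes both of its read ends, i.e. twice its count.  On a
    self-pair-free map the coverages sum to exactly 1.
    """
    if cmap.is_empty or cmap.N == 0:
        raise ValueError("cannot compute coverage of an empty map")
    df = cmap.table
    ends = pd.concat(
        [
            df[["chrom1", "start1", "count"]].rename(
                columns={"chrom1": "chrom", "start1": "start"}
            ),
            df[["chrom2", "start2", "count"]].rename(
                columns={"chrom2": "chrom", "start2": "start"}
            ),
        ]
    )
    reads = ends.groupby(["chrom", "start"])["count"].sum()
    rc = reads / (2.0 * cmap.N)
    return GothicModel(relative_coverage=rc, N=int(cmap.N), m=len(df))


def pair_null_probability(rc_j, rc_h):
    """Spurious-ligation probability ``min(1, 2 * rc_j * rc_h)``.

    The raw product can exceed 1 for very high-coverage pairs; it is clamped
    to remain a valid probability.
    """
    return np.minimum(1.0, 2.0 * np.asarray(rc_j) * np.asarray(rc_h))


def run_gothic(
    cmap: ContactMap,
    fdr_threshold: float = 0.05,
    remove_diagonal: bool = True,
    m_mode: str = "tested",
) -> SignificanceResult:
    """Test every observed pair against the coverage-product binomial null.

    Only pairs with an observed count are tested (zero-count pairs would
    contribute p-values of 1 and inflate ``m``); set ``m_mode='possible'``
    to adjust against the count of all unordered off-diagonal bin pairs
    instead of the tested count.
    """
    if cmap.N == 0:
        raise ValueError("contact map has no reads")
    if m_mode not in ("tested", "possible"):
        raise ValueError(f"unknown m_mode {m_mode!r}")
    if remove_diagonal:
        cmap = _remove_diagonal(cmap)
    if cmap.N == 0:
        raise ValueError("contact map has no off-diagonal reads")

    model = compute_relative_coverage(cmap)
    rc = model.relative_coverage
    df = cmap.table.copy()
    rc1 = rc.loc[list(zip(df["chrom1"], df["start1"]))].to_numpy()
    rc2 = rc.loc[list(zip(df["chrom2"], df["start2"]))].to_numpy()
    null_p = pair_null_probability(rc1, rc2)
    pvals = binom_sf(df["count"].to_numpy(), model.N, null_p)

    if m_mode == "possible":
        n_bins = len(rc)
        m = n_bins * (n_bins - 1) // 2
        m = max(m, len(df))
    else:
        m = len(df)
    qvals = bh_adjust(pvals, m=m)

    df["null_p"] = null_p
    df["pvalue"] = pvals
    df["rank"] = pvalue_ranks(pvals)
    df["qvalue"] = qvals
    df["significant"] = qvals < fdr_threshold
    return SignificanceResult(
        table=df[RESULT_COLUMNS],
        model="gothic",
        N=model.N,
        m=m,
        fdr=fdr_threshold,
    )
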