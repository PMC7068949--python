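"""Shared result container for the background models."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

RESULT_COLUMNS = [
    "chrom1",
    "start1",
    "end1",
    "chrom2",
    "start2",
    "end2",
    "count",
    "null_p",
    "pvalue",
    "rank",
    "qvalue",
    "significant",
]


@dataclass
class SignificanceResult:
    """Per-pair test outcome from one background model.

    ``table`` has one row per tested pair with the observed count, the null
    probability used, the p-value, its ascending rank, the BH q-value and
    the significance flag at ``fdr``.  ``m`` is the number of comparisons
    used in the adjustment.
    """

    table: pd.DataFrame
    model: str
    N: int
    m: int
    fdr: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in RESULT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"result table missing columns: {missing}")
        self.table = self.table[RESULT_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())
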