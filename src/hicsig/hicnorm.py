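"""Covariate-driven Poisson normalization of contact counts.

Counts ``u`` are regressed on the log products of per-bin effective length
and GC content, with the log mappability product entering as an offset
(coefficient fixed at 1):

    t = exp[b0 + b_len*log(x_j*x_h) + b_gc*log(y_j*y_h) + log(z_j*z_h)]

Fits are per chromosome for cis pairs and per chromosome pair for trans
pairs; the normalized map is ``e = u / t``.  Logs are natural logs, which
makes the offset coefficient exactly 1.

Significance calling from this model is an extension of the normalization
itself: the observed count is compared against Poisson(t) via the upper
tail, then BH-adjusted.  Results are labeled ``hicnorm+poisson-tail`` to
make the extension explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core_data import ContactMap, chrom_sort_key
from .io_formats import FeatureTable
from .multitest import bh_adjust, pvalue_ranks
from .result import RESULT_COLUMNS, SignificanceResult

__all__ = [
    "HicnormFit",
    "build_design",
    "fit_poisson",
    "normalize",
    "poisson_tail_pvalue",
    "run_hicnorm",
]

Scope = str | tuple[str, str]

_PAIR_KEY = ["chrom1", "start1", "chrom2", "start2"]


@dataclass
class HicnormFit:
    """One per-scope Poisson regression fit."""

    scope: Scope
    beta0: float
    beta_len: float
    beta_gc: float
    pairs: pd.DataFrame  # design plus fitted t and normalized e
    converged: bool = True
    extra: dict = field(default_factory=dict)

    def t_lookup(self) -> pd.Series:
        return self.pairs.set_index(_PAIR_KEY)["t"]


def _scope_bins(cmap: ContactMap, features: FeatureTable, scope: Scope):
    """Usable bins for a scope, split into the two endpoint sets."""
    bins = cmap.bins()
    features.require_covering(bins)
    usable = features.table["usable"]

    def side(chrom: str) -> pd.DataFrame:
        sel = bins[bins["chrom"] == chrom].copy()
        keys = list(zip(sel["chrom"], sel["start"]))
        sel["usable"] = usable.loc[keys].to_numpy()
        return sel

    if isinstance(scope, str):
        a = b = side(scope)
    else:
        a, b = side(scope[0]), side(scope[1])
    return a, b


def _pair_frame(a: pd.DataFrame, b: pd.DataFrame, cis: bool) -> pd.DataFrame:
    """All unordered off-diagonal pairs between the two bin sets."""
    if cis:
        i, j = np.triu_indices(len(a), k=1)
        left, right = a.iloc[i].reset_index(drop=True), a.iloc[j].reset_index(drop=True)
    else:
        i, j = np.meshgrid(np.arange(len(a)), np.arange(len(b)), indexing="ij")
        left = a.iloc[i.ravel()].reset_index(drop=True)
        right = b.iloc[j.ravel()].reset_index(drop=True)
    return pd.DataFrame(
        {
            "chrom1": left["chrom"].values,
            "start1": left["start"].values,
            "end1": left["end"].values,
            "chrom2": right["chrom"].values,
            "start2": right["start"].values,
            "end2": right["end"].values,
        }
    )


def build_design(
    cmap: ContactMap, features: FeatureTable, scope: Scope
) -> pd.DataFrame:
    """Per-pair covariates for one scope.

    Returns one row per unordered off-diagonal bin pair in scope with the
    observed count ``u`` (0 when absent from the map) and columns
    ``cov_len = log(x_j*x_h)``, ``cov_gc = log(y_j*y_h)`` and
    ``offset = log(z_j*z_h)``.  All bins in scope must be usable
    (strictly positive features).
    """
    a, b = _scope_bins(cmap, features, scope)
    for sel in (a, b):
        bad = sel[~sel["usable"]]
        if len(bad):
            r = bad.iloc[0]
            raise ValueError(
                f"bin {r.chrom}:{r.start} has a zero feature; exclude it first"
            )
    cis = isinstance(scope, str)
    pairs = _pair_frame(a, b, cis)

    feat = features.table
    def col(side: str, name: str) -> np.ndarray:
        keys = list(zip(pairs[f"chrom{side}"], pairs[f"start{side}"]))
        return feat[name].loc[keys].to_numpy()

    pairs["cov_len"] = np.log(col("1", "effective_length") * col("2", "effective_length"))
    pairs["cov_gc"] = np.log(col("1", "gc") * col("2", "gc"))
    pairs["offset"] = np.log(col("1", "mappability") * col("2", "mappability"))

    counts = cmap.table.set_index(_PAIR_KEY)["count"]
    idx = pd.MultiIndex.from_frame(pairs[_PAIR_KEY])
    pairs["u"] = counts.reindex(idx).fillna(0).to_numpy()
    return pairs


def fit_poisson(
    cmap: ContactMap,
    features: FeatureTable,
    scope: Scope,
    positive_only: bool = False,
) -> HicnormFit:
    """Maximum-likelihood Poisson regression for one scope.

    Zero-count pairs are part of the likelihood by default; set
    ``positive_only`` to fit on observed pairs only.  Counts must be
    integers (raw reads, not an already-normalized map).
    """
    if cmap.normalized:
        raise ValueError("Poisson fitting requires raw integer counts")
    design = build_design(cmap, features, scope)
    fit_rows = design[design["u"] > 0] if positive_only else design
    if len(fit_rows) < 3:
        raise ValueError(
            f"scope {scope!r}: {len(fit_rows)} pairs is fewer than the 3 parameters"
        )
    X = sm.add_constant(
        fit_rows[["cov_len", "cov_gc"]].to_numpy(), has_constant="add"
    )
    model = sm.GLM(
        fit_rows["u"].to_numpy(),
        X,
        family=sm.families.Poisson(),
        offset=fit_rows["offset"].to_numpy(),
    )
    res = model.fit()
    if not getattr(res, "converged", True):
        raise RuntimeError(
            f"scope {scope!r}: Poisson fit did not converge "
            f"after {res.fit_history.get('iteration', '?')} iterations"
        )
    beta0, beta_len, beta_gc = (float(v) for v in res.params)
    design = design.copy()
    design["t"] = np.exp(
        beta0
        + beta_len * design["cov_len"]
        + beta_gc * design["cov_gc"]
        + design["offset"]
    )
    design["e"] = design["u"] / design["t"]
    return HicnormFit(
        scope=scope,
        beta0=beta0,
        beta_len=beta_len,
        beta_gc=beta_gc,
        pairs=design,
        converged=bool(getattr(res, "converged", True)),
    )


def _scopes_of(cmap: ContactMap) -> list[Scope]:
    df = cmap.table
    scopes: set[Scope] = set()
    for c1, c2 in zip(df["chrom1"], df["chrom2"]):
        scopes.add(c1 if c1 == c2 else (c1, c2))
    return sorted(
        scopes,
        key=lambda s: (chrom_sort_key(s),) if isinstance(s, str)
        else tuple(chrom_sort_key(c) for c in s),
    )


def fit_all(
    cmap: ContactMap, features: FeatureTable, positive_only: bool = False
) -> dict[Scope, HicnormFit]:
    """Fit every cis chromosome and trans chromosome pair present in the map."""
    return {
        scope: fit_poisson(cmap, features, scope, positive_only=positive_only)
        for scope in _scopes_of(cmap)
    }


def normalize(cmap: ContactMap, fits: dict[Scope, HicnormFit]) -> ContactMap:
    """Normalized map ``e = u / t`` for every pair in the input map."""
    t_by_scope = {scope: fit.t_lookup() for scope, fit in fits.items()}
    df = cmap.table.copy()
    t = np.empty(len(df))
    for i, r in enumerate(df.itertuples()):
        scope: Scope = r.chrom1 if r.chrom1 == r.chrom2 else (r.chrom1, r.chrom2)
        lookup = t_by_scope.get(scope)
        key = (r.chrom1, r.start1, r.chrom2, r.start2)
        if lookup is None or key not in lookup.index:
            raise ValueError(f"no fitted expectation for pair {key}")
        t[i] = lookup.loc[key]
    df["count"] = df["count"].to_numpy() / t
    return ContactMap(df, cmap.resolution, normalized=True)


def poisson_tail_pvalue(u, t):
    """Upper tail P(U >= u) for U ~ Poisson(t)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("Poisson mean must be positive")
    out = stats.poisson.sf(np.asarray(u) - 1, t)
    if np.ndim(out) == 0:
        return float(out)
    return out


def run_hicnorm(
    cmap: ContactMap,
    features: FeatureTable,
    fdr_threshold: float = 0.05,
    positive_only: bool = False,
) -> SignificanceResult:
    """Normalize and call significance via the Poisson-tail extension.

    Pairs touching an unusable bin (a zero feature) cannot be normalized;
    they are dropped from testing and counted in the result metadata.
    """
    usable = features.table["usable"]
    df = cmap.table
    keys1 = list(zip(df["chrom1"], df["start1"]))
    keys2 = list(zip(df["chrom2"], df["start2"]))
    features.require_covering(cmap.bins())
    ok = usable.loc[keys1].to_numpy() & usable.loc[keys2].to_numpy()
    ok &= ~(
        (df["chrom1"] == df["chrom2"]).to_numpy()
        & (df["start1"] == df["start2"]).to_numpy()
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} pair(s) unnormalizable (zero feature or diagonal); dropped",
            stacklevel=2,
        )
    usable_map = ContactMap(
        df[ok].reset_index(drop=True), cmap.resolution, cmap.normalized
    )
    if usable_map.is_empty:
        raise ValueError("no normalizable pairs")

    fits = fit_all(usable_map, features, positive_only=positive_only)
    out = usable_map.table.copy()
    t = np.empty(len(out))
    for i, r in enumerate(out.itertuples()):
        scope: Scope = r.chrom1 if r.chrom1 == r.chrom2 else (r.chrom1, r.chrom2)
        t[i] = fits[scope].t_lookup().loc[(r.chrom1, r.start1, r.chrom2, r.start2)]
    pvals = poisson_tail_pvalue(out["count"].to_numpy(), t)
    qvals = bh_adjust(pvals)
    out["null_p"] = t  # fitted Poisson mean, not a probability
    out["pvalue"] = pvals
    out["rank"] = pvalue_ranks(pvals)
    out["qvalue"] = qvals
    out["significant"] = qvals < fdr_threshold
    return SignificanceResult(
        table=out[RESULT_COLUMNS],
        model="hicnorm+poisson-tail",
        N=int(usable_map.N),
        m=len(out),
        fdr=fdr_threshold,
        metadata={
            "extension": "poisson upper-tail test against fitted t (not part of "
            "the original normalization model)",
            "n_unnormalizable": n_dropped,
            "coefficients": {
                str(scope): (fit.beta0, fit.beta_len, fit.beta_gc)
                for scope, fit in fits.items()
            },
        },
    )
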