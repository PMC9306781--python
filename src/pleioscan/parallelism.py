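"""Outlier calling and parallelism classification across replicate pairs.

A window is an outlier within one population pair when its window F_ST lies
strictly above that pair's empirical 95% quantile (computed over windows with
data only). A window is *parallel* when it is an outlier in at least
``min_pairs`` independent pairs (default 2), and *nonparallel* when it is an
outlier in one pair or none. Windows missing in a pair contribute neither to
that pair's quantile nor to its outlier count, which lets windows with data
in only two pairs still be called parallel.

The continuous companion metric ranks each pair's window F_ST values
(average ties), then averages ranks across pairs per window, so it is
invariant to any monotone per-pair rescaling of F_ST.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "call_outliers",
    "classify_parallel",
    "rank_normalize",
    "mean_rank",
]

STATUS_PARALLEL = "parallel"
STATUS_NONPARALLEL = "nonparallel"


def call_outliers(fst: pd.DataFrame, quantile: float = 0.95) -> pd.DataFrame:
    """Flag per-pair outlier windows above the empirical F_ST quantile.

    Parameters
    ----------
    fst : pandas.DataFrame
        Windows x pairs matrix of window F_ST; NaN marks windows without
        data in a pair.
    quantile : float
        Genome-wide quantile defining outliers (default 0.95, the top 5%).
        The threshold uses the linear-interpolation (type-7) empirical
        quantile; windows strictly above it are outliers — ties at the
        threshold are excluded.

    Returns
    -------
    pandas.DataFrame of pandas "boolean" dtype
        True/False per (window, pair); NA where F_ST is missing.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    out = {}
    for pair in fst.columns:
        col = fst[pair].to_numpy(dtype=float)
        defined = np.isfinite(col)
        if not defined.any():
            raise ValueError(f"all window F_ST missing for pair {pair!r}")
        thr = np.quantile(col[defined], quantile)  # type-7 / linear
        flags = pd.array(col > thr, dtype="boolean")
        flags[~defined] = pd.NA
        out[pair] = flags
    return pd.DataFrame(out, index=fst.index)


def classify_parallel(flags: pd.DataFrame, min_pairs: int = 2) -> pd.DataFrame:
    """Assign parallel / nonparallel status from per-pair outlier flags.

    Returns a DataFrame with ``n_pairs_with_data``, ``n_pairs_outlier`` and
    ``status`` per window. Windows with no data in any pair keep a missing
    status.
    """
    if min_pairs < 1:
        raise ValueError("min_pairs must be >= 1")
    notna = flags.notna().to_numpy()
    outlier = flags.fillna(False).to_numpy(dtype=bool)
    n_data = notna.sum(axis=1)
    n_out = outlier.sum(axis=1)
    status = np.where(n_out >= min_pairs, STATUS_PARALLEL, STATUS_NONPARALLEL)
    status = pd.array(status, dtype="string")
    status[n_data == 0] = pd.NA
    return pd.DataFrame(
        {
            "n_pairs_with_data": n_data,
            "n_pairs_outlier": n_out,
            "status": status,
        },
        index=flags.index,
    )


def rank_normalize(fst: pd.Series) -> pd.Series:
    """Rank one pair's window F_ST values, averaging ties.

    Largest F_ST receives the largest rank; missing values stay missing and
    do not occupy rank positions, so the ranks of the W defined windows sum
    to W(W+1)/2.
    """
    if fst.notna().sum() < 1:
        raise ValueError("no defined F_ST values to rank")
    return fst.rank(method="average", na_option="keep")


def mean_rank(fst: pd.DataFrame) -> pd.Series:
    """Mean F_ST rank per window across pairs (pairs without data skipped).

    Windows with no data in any pair come back missing.
    """
    ranks = fst.apply(rank_normalize, axis=0)
    return ranks.mean(axis=1, skipna=True)
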