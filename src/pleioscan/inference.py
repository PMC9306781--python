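"""Class contrasts with a permutation null, and rank associations.

The headline statistic is the difference in class means of a per-window
metric between parallel and nonparallel windows. Because the pleiotropy
metrics are far from normal, significance comes from a label-shuffling
permutation null: parallel/nonparallel labels are reassigned uniformly at
random among the windows that actually carry a metric value (missing
windows keep their missingness and never enter either class), the observed
number of parallel labels is preserved, and the difference is recomputed
each iteration. The reported p-value uses the add-one estimator
``(1 + #{|null| >= |observed|}) / (1 + n_iter)``, two-sided by default.

For small problems every label arrangement can be enumerated instead, which
gives the exact permutation p-value.

The continuous companion analysis is the Pearson correlation between a
metric and mean F_ST rank, with the usual t-test on n - 2 degrees of
freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .parallelism import STATUS_PARALLEL

__all__ = [
    "PermutationResult",
    "AssociationResult",
    "empirical_difference",
    "permutation_test",
    "linear_association",
    "run_contrasts",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationResult:
    metric_name: str
    diff_observed: float
    null_diffs: np.ndarray = field(repr=False)
    p_value: float
    n_iter: int
    n_parallel: int
    n_nonparallel: int
    mean_parallel: float
    mean_nonparallel: float
    se_parallel: float
    se_nonparallel: float
    sided: str
    seed: int | None


@dataclass(frozen=True)
class AssociationResult:
    metric_name: str
    r: float
    p_value: float
    n: int


def _clean(metric, is_parallel):
    values = np.asarray(metric, dtype=float)
    labels = np.asarray(is_parallel, dtype=bool)
    if values.shape != labels.shape:
        raise ValueError("metric and labels must align")
    ok = np.isfinite(values)
    return values[ok], labels[ok]


def empirical_difference(metric, is_parallel) -> float:
    """mean(parallel) - mean(nonparallel), missing metric values excluded.

    Equivalent to the slope of a linear model of the metric on a
    parallel-status indicator.
    """
    values, labels = _clean(metric, is_parallel)
    if not labels.any() or labels.all():
        raise ValueError("need at least one non-missing value in each class")
    return float(values[labels].mean() - values[~labels].mean())


def _null_diffs_sampled(values, k, n_iter, rng, chunk=500):
    """Class-mean differences under uniformly random label reassignment."""
    n = values.size
    total = values.sum()
    out = np.empty(n_iter)
    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        # each row: an independent uniform shuffle of the values; the first k
        # entries act as the parallel class
        mat = rng.permuted(np.broadcast_to(values, (m, n)), axis=1)
        s = mat[:, :k].sum(axis=1)
        out[done:done + m] = s / k - (total - s) / (n - k)
        done += m
    return out


def _null_diffs_exhaustive(values, k):
    n = values.size
    total = values.sum()
    diffs = np.empty(comb(n, k))
    for i, idx in enumerate(combinations(range(n), k)):
        s = values[list(idx)].sum()
        diffs[i] = s / k - (total - s) / (n - k)
    return diffs


def permutation_test(
    metric,
    is_parallel,
    n_iter: int = 10_000,
    seed: int | None = None,
    sided: str = "two",
    method: str = "sampled",
    metric_name: str = "metric",
) -> PermutationResult:
    """Permutation test of the parallel-vs-nonparallel class difference.

    Parameters
    ----------
    metric : array-like
        Per-window metric; NaN marks missing windows, which are held in
        place (never relabelled).
    is_parallel : array-like of bool
        Parallel status per window.
    n_iter : int
        Number of random label shuffles (ignored for exhaustive runs).
    seed : int or None
        Seed for the shuffle stream.
    sided : {"two", "greater"}
        Two-sided compares |null| with |observed|; "greater" counts
        null >= observed.
    method : {"sampled", "exhaustive"}
        Exhaustive enumerates all C(n, k) arrangements and returns the exact
        p-value (no add-one correction needed: the observed labelling is one
        of the arrangements).
    """
    if n_iter < 100:
        warnings.warn("fewer than 100 permutation iterations", stacklevel=2)
    values, labels = _clean(metric, is_parallel)
    k = int(labels.sum())
    n = values.size
    if k < 2 or n - k < 2:
        raise ValueError(
            f"class sizes too small for permutation ({k} vs {n - k})"
        )
    observed = float(values[labels].mean() - values[~labels].mean())

    if method == "exhaustive":
        null = _null_diffs_exhaustive(values, k)
        if sided == "two":
            p = float(np.mean(np.abs(null) >= abs(observed) - 1e-12))
        else:
            p = float(np.mean(null >= observed - 1e-12))
        n_iter = null.size
    elif method == "sampled":
        rng = np.random.default_rng(seed)
        null = _null_diffs_sampled(values, k, n_iter, rng)
        if sided == "two":
            exceed = int(np.count_nonzero(np.abs(null) >= abs(observed)))
        else:
            exceed = int(np.count_nonzero(null >= observed))
        p = (1 + exceed) / (1 + n_iter)
    else:
        raise ValueError(f"unknown method {method!r}")

    par, non = values[labels], values[~labels]
    return PermutationResult(
        metric_name=metric_name,
        diff_observed=observed,
        null_diffs=null,
        p_value=float(p),
        n_iter=int(n_iter),
        n_parallel=k,
        n_nonparallel=n - k,
        mean_parallel=float(par.mean()),
        mean_nonparallel=float(non.mean()),
        se_parallel=float(par.std(ddof=1) / np.sqrt(k)),
        se_nonparallel=float(non.std(ddof=1) / np.sqrt(n - k)),
        sided=sided,
        seed=seed,
    )


def linear_association(
    metric, mean_fst_rank, metric_name: str = "metric"
) -> AssociationResult:
    """Pearson correlation between a metric and mean F_ST rank.

    Only windows with both quantities present are used; the p-value is the
    simple-linear-model slope test on n - 2 degrees of freedom.
    """
    x = np.asarray(metric, dtype=float)
    y = np.asarray(mean_fst_rank, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete (metric, rank) pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant metric or constant rank")
    res = stats.pearsonr(x, y)
    return AssociationResult(
        metric_name=metric_name,
        r=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


METRIC_COLUMNS = (
    "trait_count",
    "mean_pve",
    "mean_connectivity",
    "gene_count",
    "recomb_cm_per_mbp",
    "ds",
)


def run_contrasts(
    annotation: pd.DataFrame,
    calls: pd.DataFrame,
    mean_fst_rank: pd.Series | None = None,
    n_iter: int = 10_000,
    seed: int | None = None,
    sided: str = "two",
    restrict: str | None = None,
    metrics=METRIC_COLUMNS,
) -> dict:
    """All per-metric class contrasts and rank associations in one report.

    Parameters
    ----------
    annotation : pandas.DataFrame
        Per-window metric columns (any subset of ``METRIC_COLUMNS``),
        aligned with ``calls``.
    calls : pandas.DataFrame
        Output of :func:`pleioscan.parallelism.classify_parallel`.
    mean_fst_rank : pandas.Series or None
        Continuous differentiation metric; associations are skipped if None.
    restrict : {None, "outliers_only", "outlier_vs_nonoutlier"}
        * None — parallel vs nonparallel over all windows with status.
        * "outliers_only" — parallel-outlier vs single-pair-outlier windows.
        * "outlier_vs_nonoutlier" — any-outlier vs never-outlier windows.

    Returns
    -------
    dict with one entry per metric: the PermutationResult and
    AssociationResult, or an ``error`` string when a metric was not
    computable (other metrics are unaffected).
    """
    if not annotation.index.equals(calls.index):
        raise ValueError("annotation and calls are on different window grids")
    has_status = calls["status"].notna().to_numpy()
    if restrict is None:
        in_scope = has_status
        is_parallel = (calls["status"] == STATUS_PARALLEL).to_numpy()
    elif restrict == "outliers_only":
        in_scope = has_status & (calls["n_pairs_outlier"].to_numpy() >= 1)
        is_parallel = (calls["status"] == STATUS_PARALLEL).to_numpy()
    elif restrict == "outlier_vs_nonoutlier":
        in_scope = has_status
        is_parallel = calls["n_pairs_outlier"].to_numpy() >= 1
    else:
        raise ValueError(f"unknown restriction {restrict!r}")

    ss = np.random.SeedSequence(seed) if seed is not None else None
    report: dict = {}
    for i, metric in enumerate(metrics):
        if metric not in annotation.columns:
            continue
        values = annotation[metric].to_numpy(dtype=float).copy()
        values[~in_scope] = np.nan
        entry: dict = {}
        sub_seed = (
            int(ss.spawn(1)[0].generate_state(1)[0] % (2**31)) if ss else None
        )
        try:
            entry["permutation"] = permutation_test(
                values, is_parallel, n_iter=n_iter, seed=sub_seed,
                sided=sided, metric_name=metric,
            )
        except (ValueError, ZeroDivisionError) as exc:
            entry["error"] = f"not computable: {exc}"
            log.warning("contrast for %s skipped: %s", metric, exc)
        if mean_fst_rank is not None and "error" not in entry:
            try:
                entry["association"] = linear_association(
                    values, mean_fst_rank.to_numpy(dtype=float),
                    metric_name=metric,
                )
            except ValueError as exc:
                entry["association_error"] = str(exc)
        report[metric] = entry
    return report


def report_to_frame(report: dict) -> pd.DataFrame:
    """Flatten a run_contrasts report into a tidy per-metric table."""
    rows = []
    for metric, entry in report.items():
        row = {"metric": metric}
        perm = entry.get("permutation")
        if perm is not None:
            row.update(
                mean_parallel=perm.mean_parallel,
                se_parallel=perm.se_parallel,
                mean_nonparallel=perm.mean_nonparallel,
                se_nonparallel=perm.se_nonparallel,
                diff=perm.diff_observed,
                perm_p=perm.p_value,
                n_parallel=perm.n_parallel,
                n_nonparallel=perm.n_nonparallel,
            )
        assoc = entry.get("association")
        if assoc is not None:
            row.update(r=assoc.r, assoc_p=assoc.p_value, n_assoc=assoc.n)
        if "error" in entry:
            row["error"] = entry["error"]
        rows.append(row)
    return pd.DataFrame(rows)
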