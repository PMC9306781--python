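"""Weighted coexpression connectivity (kTotal) and window-level averaging.

An unsigned weighted network is built from a genes x samples expression
matrix: adjacency ``a_ij = |cor(x_i, x_j)| ** beta`` with Pearson
correlation across samples, and a gene's total connectivity is
``kTotal_i = sum_{j != i} a_ij`` — the connectivity within and between
modules together, so no module detection is required. The soft-thresholding
power beta is chosen where the scale-free topology fit saturates, mirroring
the usual weighted-correlation-network workflow; a fixed power can be forced
instead.

Expression preprocessing is FPKM -> log2(x + 1) followed by removal of the
lowest-variance quartile of genes (lowly expressed / non-varying genes are
mostly noise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import WindowGrid

__all__ = [
    "preprocess_expression",
    "total_connectivity",
    "scale_free_fit",
    "select_soft_power",
    "window_connectivity",
]

log = logging.getLogger(__name__)


def preprocess_expression(
    matrix: pd.DataFrame, variance_quantile: float = 0.25
) -> pd.DataFrame:
    """log2(x+1)-transform FPKM and drop the low-variance gene tail.

    Genes whose log-scale variance falls strictly below the
    ``variance_quantile`` quantile of all gene variances are removed
    (default: first quartile). Gene order is preserved.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("FPKM values must be non-negative")
    logm = np.log2(matrix + 1.0)
    variances = logm.var(axis=1, ddof=1)
    cutoff = variances.quantile(variance_quantile)
    kept = logm.loc[variances >= cutoff]
    if kept.empty:
        raise ValueError("variance filter removed every gene")
    return kept


def _abs_cor_pow(values: np.ndarray, beta: int) -> np.ndarray:
    """|Pearson correlation|**beta across rows, by squaring for integer beta."""
    cor = np.corrcoef(values)
    np.abs(cor, out=cor)
    beta = int(beta)
    # exponentiation by squaring: much faster than np.power for the large
    # gene x gene matrices this sees
    result = np.ones_like(cor)
    base = cor
    e = beta
    while e:
        if e & 1:
            result = result * base
        e >>= 1
        if e:
            base = base * base
    return result


def total_connectivity(log_matrix: pd.DataFrame, beta: int) -> pd.Series:
    """Per-gene total connectivity kTotal under an unsigned network.

    ``kTotal_i = sum_{j != i} |cor(x_i, x_j)|**beta``; self-adjacency is
    excluded, so values lie in [0, G - 1] for G genes.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    values = log_matrix.to_numpy(dtype=np.float64)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    if np.any(values.std(axis=1) == 0):
        raise ValueError("zero-variance gene present; run preprocessing first")
    adj = _abs_cor_pow(values, beta)
    k = adj.sum(axis=1) - np.diag(adj)
    return pd.Series(k, index=log_matrix.index, name="kTotal")


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R² of the log-log degree-distribution regression.

    Genes are binned by connectivity into ``n_bins`` equal-width bins;
    log10(bin frequency) is regressed on log10(mean connectivity per bin)
    over non-empty bins. The squared correlation is returned with a negative
    sign when the slope is positive (the usual signed scale-free-fit index:
    a genuine power law has a negative slope). Fewer than 3 usable bins ->
    NaN.
    """
    k = np.asarray(k, dtype=float)
    k = k[np.isfinite(k) & (k > 0)]
    if k.size < n_bins:
        raise ValueError("need at least n_bins genes with positive connectivity")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=k, minlength=n_bins)
    ok = counts > 0
    if ok.sum() < 3:
        log.info("scale-free fit undefined: %d non-empty bins", int(ok.sum()))
        return float("nan")
    mean_k = sums[ok] / counts[ok]
    freq = counts[ok] / counts.sum()
    x = np.log10(mean_k)
    y = np.log10(freq)
    if np.allclose(x, x[0]):
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    r2 = r * r
    slope_sign = np.sign(r)  # slope of y on x shares the sign of r
    return float(-r2 if slope_sign > 0 else r2)


@dataclass(frozen=True)
class SoftPowerDiagnostics:
    beta: int
    table: pd.DataFrame  # power, signed_r2, mean_connectivity


def select_soft_power(
    log_matrix: pd.DataFrame,
    powers=tuple(range(1, 21)),
    r2_threshold: float = 0.85,
    n_bins: int = 10,
    fixed_power: int | None = None,
) -> SoftPowerDiagnostics:
    """Pick the soft-thresholding power from scale-free-fit diagnostics.

    Returns the smallest candidate whose signed R² reaches ``r2_threshold``;
    if none does, the power maximizing R². A ``fixed_power`` override skips
    selection but the diagnostic table is still computed for reporting.
    """
    if not len(powers):
        raise ValueError("candidate power list is empty")
    rows = []
    for p in powers:
        k = total_connectivity(log_matrix, p).to_numpy()
        rows.append((int(p), scale_free_fit(k, n_bins=n_bins), float(k.mean())))
    table = pd.DataFrame(rows, columns=["power", "signed_r2", "mean_connectivity"])
    if fixed_power is not None:
        return SoftPowerDiagnostics(beta=int(fixed_power), table=table)
    reaching = table[table["signed_r2"] >= r2_threshold]
    if len(reaching):
        beta = int(reaching["power"].iloc[0])
    else:
        beta = int(table.loc[table["signed_r2"].idxmax(), "power"])
    return SoftPowerDiagnostics(beta=beta, table=table)


def window_connectivity(
    ktotal: pd.Series, genes: pd.DataFrame, grid: WindowGrid
) -> pd.Series:
    """Mean kTotal per window, mapping genes by coding-region midpoint.

    ``genes`` needs columns ``chrom, start, end`` indexed by gene id;
    midpoints use floor((start + end) / 2) and the half-open window rule.
    Windows with no genes come back missing.
    """
    common = ktotal.index.intersection(genes.index)
    if len(common) < len(ktotal):
        missing = ktotal.index.difference(genes.index)
        raise ValueError(f"genes without coordinates: {list(missing[:5])}")
    g = genes.loc[ktotal.index]
    mid = ((g["start"] + g["end"]) // 2).to_numpy(np.int64)
    widx = grid.locate(g["chrom"].to_numpy(), mid)
    sums = np.bincount(widx, weights=ktotal.to_numpy(), minlength=grid.n_windows)
    counts = np.bincount(widx, minlength=grid.n_windows)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    means[counts == 0] = np.nan
    return pd.Series(means, index=grid.windows.index, name="mean_connectivity")
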