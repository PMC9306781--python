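"""Weir–Cockerham F_ST genome scan.

Per-SNP variance components of the Weir & Cockerham (1984) theta estimator
for two populations, aggregated into fixed windows by the ratio-of-sums rule:
the window estimate is sum(a) / sum(a + b + c) over the window's variable
sites, not the mean of per-site ratios. Negative per-site components are kept
unclipped, and sites whose denominator is zero (monomorphic across both
populations) carry no information — they are flagged non-variable and do not
count toward the minimum-sites filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import WindowGrid

__all__ = [
    "SiteFstComponents",
    "wc_components",
    "window_fst",
    "read_genotype_counts_tsv",
    "read_vcf_counts",
    "scan_pair",
]

log = logging.getLogger(__name__)

COUNTS_COLUMNS = ["chrom", "pos", "pair", "pop", "nAA", "nAa", "naa"]


@dataclass(frozen=True)
class SiteFstComponents:
    """Variance components of theta-hat at one biallelic site.

    ``a`` is the among-population component (the numerator); ``bc`` is the
    summed within-population components b + c, so the denominator of
    theta-hat is ``a + bc``. ``variable`` is False when the denominator is
    zero and the site carries no information.
    """

    chrom: str
    pos: int
    a: float
    bc: float
    variable: bool

    @property
    def numerator(self) -> float:
        return self.a

    @property
    def denominator(self) -> float:
        return self.a + self.bc

    @property
    def theta(self) -> float:
        return self.a / (self.a + self.bc) if self.variable else float("nan")


def wc_components(counts1, counts2):
    """Weir–Cockerham variance components for two populations.

    Parameters
    ----------
    counts1, counts2 : array-like, shape (..., 3)
        Genotype counts ``(nAA, nAa, naa)`` per site for each population,
        where A is the reference allele. Any leading shape is broadcast, so a
        whole chromosome can be processed in one call.

    Returns
    -------
    a, bc, variable : numpy.ndarray
        Among-population component, summed within components ``b + c``, and a
        boolean mask of informative sites (denominator non-zero). Theta-hat is
        ``a / (a + bc)`` where ``variable`` holds; negative values are
        legitimate and are not clipped.

    Notes
    -----
    This is the r = 2 case of the general estimator: with sample sizes
    ``n_i`` (diploids), allele frequencies ``p_i`` and observed heterozygote
    frequencies ``h_i``,

    .. math::

        a &= \\frac{\\bar n}{n_c}\\Big[s^2 - \\frac{1}{\\bar n - 1}
             \\big(\\bar p(1-\\bar p) - \\tfrac{r-1}{r}s^2 -
             \\tfrac{\\bar h}{4}\\big)\\Big] \\\\
        b &= \\frac{\\bar n}{\\bar n - 1}\\Big[\\bar p(1-\\bar p) -
             \\tfrac{r-1}{r}s^2 - \\tfrac{2\\bar n - 1}{4\\bar n}\\bar h\\Big]
             \\qquad c = \\bar h / 2
    """
    c1 = np.asarray(counts1, dtype=np.float64)
    c2 = np.asarray(counts2, dtype=np.float64)
    if c1.shape[-1] != 3 or c2.shape[-1] != 3:
        raise ValueError("genotype counts must have a trailing axis of length 3")
    n1 = c1.sum(axis=-1)
    n2 = c2.sum(axis=-1)
    if np.any(n1 < 1) or np.any(n2 < 1):
        raise ValueError("each population needs at least one genotyped diploid")

    r = 2.0
    p1 = (2 * c1[..., 0] + c1[..., 1]) / (2 * n1)
    p2 = (2 * c2[..., 0] + c2[..., 1]) / (2 * n2)
    h1 = c1[..., 1] / n1
    h2 = c2[..., 1] / n2

    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    with np.errstate(divide="ignore", invalid="ignore"):
        inner = pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4
        a = (nbar / nc) * (s2 - inner / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
    c = hbar / 2
    bc = b + c
    # n̄ = 1 (one diploid per pop) leaves a, b undefined; such sites carry no
    # usable within-population information — flag non-variable.
    denom = a + bc
    variable = np.isfinite(denom) & (denom != 0)
    a = np.where(np.isfinite(a), a, 0.0)
    bc = np.where(np.isfinite(bc), bc, 0.0)
    return a, bc, variable


def site_components(chrom, pos, counts1, counts2) -> SiteFstComponents:
    """Scalar convenience wrapper around :func:`wc_components` for one site."""
    a, bc, variable = wc_components(np.asarray(counts1), np.asarray(counts2))
    return SiteFstComponents(
        chrom=str(chrom), pos=int(pos), a=float(a), bc=float(bc),
        variable=bool(variable),
    )


def window_fst(
    sites: pd.DataFrame, grid: WindowGrid, min_sites: int = 3
) -> pd.DataFrame:
    """Aggregate per-site components into window F_ST by ratio of sums.

    Parameters
    ----------
    sites : pandas.DataFrame
        Columns ``chrom``, ``pos``, ``a``, ``bc``, ``variable`` (as produced
        by :func:`wc_components`).
    grid : WindowGrid
    min_sites : int
        Minimum number of variable sites for a window to receive an F_ST
        value; windows below the cutoff are reported with ``fst`` missing.

    Returns
    -------
    pandas.DataFrame
        One row per grid window: ``chrom, start, end, fst, n_variable_sites``.
    """
    widx = grid.locate(sites["chrom"].to_numpy(), sites["pos"].to_numpy())
    var = sites["variable"].to_numpy(dtype=bool)
    num = np.bincount(widx[var], weights=sites["a"].to_numpy()[var],
                      minlength=grid.n_windows)
    den = np.bincount(
        widx[var],
        weights=(sites["a"].to_numpy() + sites["bc"].to_numpy())[var],
        minlength=grid.n_windows,
    )
    nvar = np.bincount(widx[var], minlength=grid.n_windows)

    out = grid.windows.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = num / den
    fst[nvar < min_sites] = np.nan
    out["fst"] = fst
    out["n_variable_sites"] = nvar
    return out


def _counts_from_gt(gt_types: np.ndarray, pop_mask: np.ndarray) -> tuple:
    g = gt_types[pop_mask]
    return (
        int(np.count_nonzero(g == 0)),   # hom ref
        int(np.count_nonzero(g == 1)),   # het
        int(np.count_nonzero(g == 3)),   # hom alt (cyvcf2 code)
    )


def read_vcf_counts(path, pop_of_sample=None, pair: str = "pair") -> pd.DataFrame:
    """Read a two-population VCF into per-site genotype counts.

    Only biallelic SNPs are loaded; multiallelic and indel records are
    skipped with a logged count. Missing genotypes are excluded from the
    counts.

    Parameters
    ----------
    path : str
        VCF path (gzip allowed).
    pop_of_sample : mapping or None
        Sample name -> population label. When None, the prefix before the
        first ``_`` of each sample name is used.
    pair : str
        Pair identifier stored in the output.

    Returns
    -------
    pandas.DataFrame in counts-TSV layout
        (``chrom, pos, pair, pop, nAA, nAa, naa``); positions are converted
        to the package's 0-based convention.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if pop_of_sample is None:
        pop_of_sample = {s: s.split("_")[0] for s in samples}
    unknown = [s for s in samples if s not in pop_of_sample]
    if unknown:
        raise ValueError(f"samples without population assignment: {unknown[:5]}")
    pops = sorted(set(pop_of_sample[s] for s in samples))
    if len(pops) != 2:
        raise ValueError(f"expected exactly 2 populations, got {pops}")
    masks = {
        p: np.array([pop_of_sample[s] == p for s in samples]) for p in pops
    }

    rows = []
    n_skipped = 0
    for rec in vcf:
        if not rec.is_snp or len(rec.ALT) != 1:
            n_skipped += 1
            continue
        gt = rec.gt_types  # 0 hom ref, 1 het, 2 unknown, 3 hom alt
        for p in pops:
            naa, nAa, nalt = _counts_from_gt(gt, masks[p])
            rows.append((rec.CHROM, rec.POS - 1, pair, p, naa, nAa, nalt))
    if n_skipped:
        log.info("skipped %d non-biallelic-SNP records in %s", n_skipped, path)
    if not rows:
        raise ValueError(f"no biallelic SNPs in {path}")
    return pd.DataFrame(rows, columns=COUNTS_COLUMNS)


def read_genotype_counts_tsv(path) -> pd.DataFrame:
    """Load a genotype-count table (``chrom pos pair pop nAA nAa naa``)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pair": str, "pop": str})
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns {sorted(missing)}")
    return df[COUNTS_COLUMNS]


def scan_pair(
    counts: pd.DataFrame, grid: WindowGrid, min_sites: int = 3
) -> pd.DataFrame:
    """Window F_ST for one population pair from a genotype-count table.

    ``counts`` must contain exactly two population labels; sites present in
    only one population are dropped.
    """
    pops = sorted(counts["pop"].unique())
    if len(pops) != 2:
        raise ValueError(f"expected 2 populations in counts, got {pops}")
    wide = counts.pivot_table(
        index=["chrom", "pos"], columns="pop",
        values=["nAA", "nAa", "naa"], aggfunc="first",
    )
    wide = wide.dropna()
    c1 = wide[[("nAA", pops[0]), ("nAa", pops[0]), ("naa", pops[0])]].to_numpy()
    c2 = wide[[("nAA", pops[1]), ("nAa", pops[1]), ("naa", pops[1])]].to_numpy()
    a, bc, variable = wc_components(c1, c2)
    sites = pd.DataFrame(
        {
            "chrom": wide.index.get_level_values("chrom"),
            "pos": wide.index.get_level_values("pos"),
            "a": a,
            "bc": bc,
            "variable": variable,
        }
    )
    return window_fst(sites, grid, min_sites=min_sites)
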