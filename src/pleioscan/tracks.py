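"""Per-window covariate tracks: gene density, recombination rate, dS.

Gene density counts each gene toward the single window containing its
midpoint (the same rule used to map connectivity), so a count of zero is a
real observation, not missing. Recombination rates come from a genetic map
by linear interpolation of cM positions at window boundaries
(rate = delta-cM / window length in Mbp); windows not fully covered by the
marker span are missing. The mutation-rate proxy is a precomputed per-window
synonymous-substitution-rate (dS) track joined onto the grid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import WindowGrid

__all__ = [
    "gene_density",
    "recombination_rate",
    "load_ds_track",
    "read_gene_bed",
    "read_gene_gff",
    "build_tracks",
]


def read_gene_bed(path) -> pd.DataFrame:
    """Gene intervals from a BED file (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "name"],
        dtype={0: str},
    )
    return df.set_index("name")


def read_gene_gff(path, feature: str = "gene") -> pd.DataFrame:
    """Gene intervals from a GFF3 file, converted to 0-based half-open."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "source", "type", "start", "end", "score", "strand",
               "frame", "attributes"],
        dtype={"chrom": str},
    )
    df = df[df["type"] == feature].copy()
    ids = df["attributes"].str.extract(r"ID=([^;]+)")[0]
    df["name"] = ids.fillna(pd.Series(
        [f"gene{i}" for i in range(len(df))], index=df.index))
    df["start"] = df["start"].astype(np.int64) - 1  # GFF is 1-based inclusive
    df["end"] = df["end"].astype(np.int64)
    return df[["chrom", "start", "end", "name"]].set_index("name")


def gene_density(genes: pd.DataFrame, grid: WindowGrid) -> pd.Series:
    """Number of gene midpoints per window (0 is a valid value)."""
    counts = np.zeros(grid.n_windows, dtype=float)
    if len(genes):
        if (genes["start"] > genes["end"]).any():
            bad = genes[genes["start"] > genes["end"]].index[0]
            raise ValueError(f"malformed gene interval (start > end): {bad!r}")
        mid = ((genes["start"] + genes["end"]) // 2).to_numpy(np.int64)
        widx = grid.locate(genes["chrom"].to_numpy(), mid)
        counts = np.bincount(widx, minlength=grid.n_windows).astype(float)
    return pd.Series(counts, index=grid.windows.index, name="gene_count")


def recombination_rate(gmap: pd.DataFrame, grid: WindowGrid) -> pd.Series:
    """Per-window recombination rate (cM/Mbp) from a genetic map.

    ``gmap`` columns: ``chrom, bp, cM``; the map must be non-decreasing in
    cM with bp within each chromosome and have at least 2 markers per
    chromosome. Window rate = interpolated cM at window end minus at window
    start, divided by window length in Mbp; windows outside the marker span
    of their chromosome (or on unmapped chromosomes) are missing.
    """
    rates = np.full(grid.n_windows, np.nan)
    win = grid.windows
    for chrom, markers in gmap.groupby("chrom", sort=False):
        m = markers.sort_values("bp")
        bp = m["bp"].to_numpy(dtype=float)
        cm = m["cM"].to_numpy(dtype=float)
        if len(bp) < 2:
            raise ValueError(f"chromosome {chrom}: need >= 2 map markers")
        if np.any(np.diff(cm) < 0):
            bad = m.iloc[np.where(np.diff(cm) < 0)[0] + 1]
            raise ValueError(
                f"non-monotone genetic map on {chrom}: "
                f"{bad[['bp', 'cM']].to_dict('records')}"
            )
        sel = win["chrom"] == str(chrom)
        if not sel.any():
            continue
        starts = win.loc[sel, "start"].to_numpy(dtype=float)
        ends = win.loc[sel, "end"].to_numpy(dtype=float)
        covered = (starts >= bp[0]) & (ends <= bp[-1])
        cm_start = np.interp(starts, bp, cm)
        cm_end = np.interp(ends, bp, cm)
        r = (cm_end - cm_start) / ((ends - starts) / 1e6)
        r[~covered] = np.nan
        rates[np.where(sel)[0]] = r
    return pd.Series(rates, index=win.index, name="recomb_cm_per_mbp")


def load_ds_track(path, grid: WindowGrid) -> pd.Series:
    """Join a per-window dS TSV (``chrom, window_start, ds``) onto the grid.

    Windows absent from the file are missing; duplicate (chrom, start) keys
    or negative dS values are data errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "window_start", "ds"}
    if not required <= set(df.columns):
        raise ValueError(f"dS track needs columns {sorted(required)}")
    dup = df.duplicated(subset=["chrom", "window_start"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate dS entry for ({row['chrom']}, {row['window_start']})"
        )
    if (df["ds"] < 0).any():
        raise ValueError("negative dS value in track")
    key = grid.windows.set_index(["chrom", "start"]).index
    series = df.set_index(["chrom", "window_start"])["ds"].reindex(key)
    series.index = grid.windows.index
    return series.rename("ds")


def build_tracks(
    grid: WindowGrid,
    genes: pd.DataFrame | None = None,
    gmap: pd.DataFrame | None = None,
    ds_path=None,
) -> pd.DataFrame:
    """Assemble the merged per-window track table from available inputs."""
    out = grid.windows.copy()
    out["gene_count"] = gene_density(genes, grid) if genes is not None else np.nan
    out["recomb_cm_per_mbp"] = (
        recombination_rate(gmap, grid) if gmap is not None else np.nan
    )
    out["ds"] = load_ds_track(ds_path, grid) if ds_path is not None else np.nan
    return out
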