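"""QTL curation and per-window pleiotropy annotation (mapped-trait proxy).

Each QTL record is placed at the midpoint of its marker confidence interval
(falling back to the midpoint of the flanking markers when no CI was
reported) and assigned to the 50-kb window containing that midpoint. Within
a window, the same trait is counted once regardless of how many studies
mapped it there, and percent-variance-explained (PVE) is averaged in two
stages: within trait first, then across traits.

Windows carrying no QTL are reported with a *missing* trait count by default
rather than zero: the QTL database covers only mapped traits, so absence of
a record is absence of information, and the permutation machinery downstream
holds missing data in place. Set ``zero_as_missing=False`` to treat such
windows as zero instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import WindowGrid

__all__ = [
    "TRAIT_CATEGORIES",
    "position_qtl",
    "curate_and_assign",
    "read_qtl_table",
    "read_qtl_database_export",
]

TRAIT_CATEGORIES = (
    "behaviour/sensory",
    "body shape",
    "body size",
    "defensive armour",
    "feeding morphology",
    "pigmentation",
    "respiration",
    "swimming",
)

QTL_COLUMNS = [
    "trait", "category", "chrom", "ci_start", "ci_end",
    "flank_start", "flank_end", "pve", "study", "cross",
]


def _normalize_trait(name: str) -> str:
    return " ".join(str(name).split()).casefold()


def position_qtl(records: pd.DataFrame) -> pd.DataFrame:
    """Compute the placement midpoint of each QTL record.

    Uses floor((ci_start + ci_end) / 2); records without a confidence
    interval fall back to the midpoint of their flanking markers. Records
    with neither interval raise, naming the offender.

    Returns a copy with ``midpoint`` added.
    """
    df = records.copy()
    ci_ok = df["ci_start"].notna() & df["ci_end"].notna()
    fl_ok = df.get("flank_start", pd.Series(np.nan, index=df.index)).notna() & df.get(
        "flank_end", pd.Series(np.nan, index=df.index)
    ).notna()
    bad = ~(ci_ok | fl_ok)
    if bad.any():
        i = df.index[bad][0]
        raise ValueError(
            f"QTL record {i} (trait {df.loc[i, 'trait']!r}) has neither a "
            "confidence interval nor flanking markers"
        )
    if (df.loc[ci_ok, "ci_start"] > df.loc[ci_ok, "ci_end"]).any():
        raise ValueError("confidence interval with ci_start > ci_end")
    start = df["ci_start"].where(ci_ok, df.get("flank_start"))
    end = df["ci_end"].where(ci_ok, df.get("flank_end"))
    df["midpoint"] = ((start + end) // 2).astype(np.int64)
    return df


def curate_and_assign(
    records: pd.DataFrame, grid: WindowGrid, zero_as_missing: bool = True
) -> pd.DataFrame:
    """Per-window distinct-trait counts and two-stage mean PVE.

    Parameters
    ----------
    records : pandas.DataFrame
        QTL table with at least ``trait, chrom, ci_start, ci_end`` (optional
        ``flank_start, flank_end, pve``).
    grid : WindowGrid
    zero_as_missing : bool
        When True (default) windows without any assigned QTL report missing
        ``trait_count`` and are excluded from class contrasts.

    Returns
    -------
    pandas.DataFrame indexed like ``grid.windows`` with columns
    ``trait_count`` and ``mean_pve``.
    """
    out = pd.DataFrame(
        {"trait_count": np.nan, "mean_pve": np.nan}, index=grid.windows.index
    )
    if len(records):
        df = position_qtl(records)
        df["window"] = grid.locate(df["chrom"].to_numpy(), df["midpoint"].to_numpy())
        df["trait_key"] = df["trait"].map(_normalize_trait)

        counts = df.groupby("window")["trait_key"].nunique()
        out.loc[counts.index, "trait_count"] = counts.to_numpy(dtype=float)

        if "pve" in df.columns:
            with_pve = df[df["pve"].notna()]
            if len(with_pve):
                per_trait = with_pve.groupby(["window", "trait_key"])["pve"].mean()
                per_window = per_trait.groupby("window").mean()
                out.loc[per_window.index, "mean_pve"] = per_window.to_numpy()
    if not zero_as_missing:
        out["trait_count"] = out["trait_count"].fillna(0.0)
    return out


def read_qtl_table(path) -> pd.DataFrame:
    """Load a QTL TSV with the package's documented header."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"trait", "chrom"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"QTL table missing columns {sorted(missing)}")
    for col in QTL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[QTL_COLUMNS]


def read_qtl_database_export(
    path,
    column_map: dict | None = None,
    species_column: str = "species",
    species_keep: str = "G. aculeatus",
) -> pd.DataFrame:
    """Loader profile for a curated stickleback QTL-database export.

    Maps the export's column names onto the package schema and keeps only
    threespine stickleback (*G. aculeatus*) records when a species column is
    present. ``column_map`` overrides the default export-name -> schema-name
    mapping for deviating exports.
    """
    default_map = {
        "Trait": "trait",
        "Trait category": "category",
        "Chromosome": "chrom",
        "CI start": "ci_start",
        "CI end": "ci_end",
        "Flanking marker start": "flank_start",
        "Flanking marker end": "flank_end",
        "PVE": "pve",
        "Study": "study",
        "Cross": "cross",
    }
    if column_map:
        default_map.update(column_map)
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns=default_map)
    if species_column in df.columns:
        df = df[df[species_column].astype(str).str.contains(species_keep, regex=False)]
        df = df.drop(columns=[species_column])
    df["chrom"] = df["chrom"].astype(str)
    return read_qtl_table_frame(df)


def read_qtl_table_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate/complete an in-memory QTL frame against the package schema."""
    missing = {"trait", "chrom"} - set(df.columns)
    if missing:
        raise ValueError(f"QTL table missing columns {sorted(missing)}")
    df = df.copy()
    for col in QTL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[QTL_COLUMNS].reset_index(drop=True)
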