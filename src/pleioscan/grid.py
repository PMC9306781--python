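"""Fixed-width genomic window grid shared by every per-window annotation.

All coordinates are 0-based half-open (BED convention). A position ``p`` on
chromosome ``c`` belongs to the window ``[start, end)`` with
``start <= p < end``; interval features are assigned by midpoint under the
same rule, so every module in the package places data on identical windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["WindowGrid"]


@dataclass(frozen=True)
class WindowGrid:
    """Non-overlapping tiling of a genome into fixed-size windows.

    Parameters
    ----------
    windows : pandas.DataFrame
        Columns ``chrom`` (str), ``start`` (int), ``end`` (int); one row per
        window, ordered by chromosome then start. The trailing window of a
        chromosome may be shorter than ``window_size``.
    window_size : int
        Nominal window width in bp.
    """

    windows: pd.DataFrame
    window_size: int
    _chrom_info: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        w = self.windows
        info: dict[str, tuple[int, int]] = {}
        for chrom, grp in w.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if not np.array_equal(starts[1:], ends[:-1]) or starts[0] != 0:
                raise ValueError(f"windows on {chrom} do not tile from 0")
            if np.any((ends[:-1] - starts[:-1]) != self.window_size):
                raise ValueError(f"non-terminal window on {chrom} has wrong size")
            # (index of first window on chrom, chromosome length)
            info[str(chrom)] = (int(grp.index[0]), int(ends[-1]))
        object.__setattr__(self, "_chrom_info", info)

    @classmethod
    def from_chrom_sizes(
        cls, sizes: Mapping[str, int], window_size: int = 50_000
    ) -> "WindowGrid":
        """Tile each chromosome from 0 to its length with ``window_size`` bins."""
        if window_size <= 0:
            raise ValueError("window_size must be positive")
        rows = []
        for chrom, length in sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
            for start in range(0, length, window_size):
                rows.append((str(chrom), start, min(start + window_size, length)))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        return cls(windows=df, window_size=window_size)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def chroms(self) -> list[str]:
        return list(self._chrom_info)

    def chrom_length(self, chrom: str) -> int:
        return self._chrom_info[str(chrom)][1]

    def locate(self, chrom, pos) -> np.ndarray:
        """Map positions to window row indices.

        Parameters
        ----------
        chrom : array-like of str
        pos : array-like of int
            0-based positions.

        Returns
        -------
        numpy.ndarray of int
            Row index into :attr:`windows` for each position.

        Raises
        ------
        ValueError
            If a chromosome is unknown or a position lies outside it.
        """
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        out = np.empty(pos.shape, dtype=np.int64)
        for c in np.unique(chrom):
            if c not in self._chrom_info:
                raise ValueError(f"position on unknown chromosome {c!r}")
            first, length = self._chrom_info[c]
            m = chrom == c
            p = pos[m]
            bad = (p < 0) | (p >= length)
            if bad.any():
                raise ValueError(
                    f"position {int(p[bad][0])} outside chromosome {c} "
                    f"(length {length})"
                )
            out[m] = first + p // self.window_size
        return out

    def equals(self, other: "WindowGrid") -> bool:
        return self.window_size == other.window_size and self.windows[
            ["chrom", "start", "end"]
        ].equals(other.windows[["chrom", "start", "end"]])
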