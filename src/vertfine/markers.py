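"""Ordered marker maps.

A :class:`MarkerMap` holds the SNP panel the pipeline works on: marker
names, chromosome labels, physical positions (bp, 1-based) and genetic
positions (cM).  Physical positions must be strictly increasing within a
chromosome and genetic positions non-decreasing with them; when only
physical positions are available the genetic map defaults to 1 cM per Mb,
the usual sex-averaged approximation for the pig autosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MarkerMap"]

_COLS = ["name", "chrom", "bp", "cm"]


@dataclass
class MarkerMap:
    """An ordered list of markers over one or more chromosomes."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _COLS if c not in t.columns]
        if missing:
            raise ValueError(f"marker table lacks columns {missing}")
        if len(t) == 0:
            raise ValueError("empty marker map")
        t = t.loc[:, _COLS].reset_index(drop=True)
        t["bp"] = t["bp"].astype(np.int64)
        t["cm"] = t["cm"].astype(float)
        if t["name"].duplicated().any():
            dup = t.loc[t["name"].duplicated(), "name"].iloc[0]
            raise ValueError(f"duplicated marker name {dup!r}")
        if (t["bp"] < 1).any():
            raise ValueError("bp positions must be >= 1")
        if (t["cm"] < 0).any():
            raise ValueError("cM positions must be non-negative")
        for chrom, sub in t.groupby("chrom", sort=False):
            if not np.all(np.diff(sub["bp"].to_numpy()) > 0):
                raise ValueError(f"bp positions not strictly increasing on {chrom}")
            if not np.all(np.diff(sub["cm"].to_numpy()) >= 0):
                raise ValueError(f"cM positions decrease with bp on {chrom}")
        object.__setattr__(self, "table", t)

    # -- constructors -------------------------------------------------

    @classmethod
    def from_positions(
        cls,
        names: list[str],
        chroms: list[str],
        bp: list[int],
        cm: list[float] | None = None,
    ) -> "MarkerMap":
        """Build a map; ``cm`` defaults to bp / 1e6 (1 cM per Mb)."""
        bp_arr = np.asarray(bp, dtype=np.int64)
        cm_arr = np.asarray(cm, dtype=float) if cm is not None else bp_arr / 1e6
        return cls(
            pd.DataFrame(
                {"name": list(names), "chrom": list(chroms), "bp": bp_arr, "cm": cm_arr}
            )
        )

    @classmethod
    def regular_grid(
        cls, chrom_sizes_mb: dict[str, float], n_per_chrom: int, prefix: str = "M"
    ) -> "MarkerMap":
        """Evenly spaced panel, ``n_per_chrom`` markers per chromosome."""
        names: list[str] = []
        chroms: list[str] = []
        bp: list[int] = []
        for chrom, size_mb in chrom_sizes_mb.items():
            pos = np.linspace(1e6, size_mb * 1e6, n_per_chrom).astype(np.int64)
            # keep strictly increasing even for tiny chromosomes
            pos = np.maximum.accumulate(pos + np.arange(n_per_chrom))
            for i, p in enumerate(pos):
                names.append(f"{prefix}{chrom}_{i}")
                chroms.append(chrom)
                bp.append(int(p))
        return cls.from_positions(names, chroms, bp)

    # -- accessors ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    @property
    def names(self) -> np.ndarray:
        return self.table["name"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def bp(self) -> np.ndarray:
        return self.table["bp"].to_numpy()

    @property
    def cm(self) -> np.ndarray:
        return self.table["cm"].to_numpy()

    def index_of(self, name: str) -> int:
        idx = np.flatnonzero(self.names == name)
        if idx.size == 0:
            raise KeyError(f"marker {name!r} not in map")
        return int(idx[0])

    def chrom_indices(self, chrom: str) -> np.ndarray:
        """Row indices (contiguous) of the markers on ``chrom``."""
        return np.flatnonzero(self.chroms == np.asarray(chrom))

    def subset(self, rows: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.table.iloc[np.asarray(rows)].reset_index(drop=True))

    def region_indices(self, chrom: str, start_bp: int, end_bp: int) -> np.ndarray:
        """Indices of markers inside the closed interval [start_bp, end_bp]."""
        m = (self.chroms == np.asarray(chrom)) & (self.bp >= start_bp) & (self.bp <= end_bp)
        return np.flatnonzero(m)

    def nearest_index(self, chrom: str, bp: int) -> int:
        idx = self.chrom_indices(chrom)
        if idx.size == 0:
            raise KeyError(f"no markers on chromosome {chrom!r}")
        return int(idx[np.argmin(np.abs(self.bp[idx] - bp))])

    def insert(self, name: str, chrom: str, bp: int, cm: float | None = None) -> "MarkerMap":
        """Return a new map with one extra marker placed in physical order."""
        if cm is None:
            cm = self._interp_cm(chrom, bp)
        row = pd.DataFrame({"name": [name], "chrom": [chrom], "bp": [bp], "cm": [cm]})
        idx = self.chrom_indices(chrom)
        if idx.size == 0:
            t = pd.concat([self.table, row], ignore_index=True)
        else:
            after = idx[self.bp[idx] < bp]
            pos = int(after[-1]) + 1 if after.size else int(idx[0])
            t = pd.concat(
                [self.table.iloc[:pos], row, self.table.iloc[pos:]], ignore_index=True
            )
        return MarkerMap(t)

    def _interp_cm(self, chrom: str, bp: int) -> float:
        idx = self.chrom_indices(chrom)
        if idx.size == 0:
            return bp / 1e6
        return float(np.interp(bp, self.bp[idx], self.cm[idx]))
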