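"""Pedigree container with referential-integrity checks.

Individuals carry sire/dam links, a sex, a generation label (F0/F1/F2 for
intercross designs, "outbred" otherwise) and a population label.  Both
parents must be present or both absent; parents must exist; no individual
may be its own ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["Pedigree", "PedigreeError"]

_COLS = ["id", "sire", "dam", "sex", "generation", "population"]


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table.copy()
        missing = [c for c in _COLS if c not in t.columns]
        if missing:
            raise PedigreeError(f"pedigree lacks columns {missing}")
        t = t.loc[:, _COLS].reset_index(drop=True)
        for c in ("sire", "dam"):
            t[c] = t[c].where(pd.notna(t[c]), None)
            t[c] = t[c].replace({"0": None, "": None})
        if t["id"].duplicated().any():
            dup = t.loc[t["id"].duplicated(), "id"].iloc[0]
            raise PedigreeError(f"duplicated id {dup!r}")
        ids = set(t["id"])
        for _, row in t.iterrows():
            s, d = row["sire"], row["dam"]
            if (s is None) != (d is None):
                raise PedigreeError(f"{row['id']!r}: one parent given, one absent")
            for p in (s, d):
                if p is not None and p not in ids:
                    raise PedigreeError(f"{row['id']!r}: unknown parent {p!r}")
            if s == row["id"] or d == row["id"]:
                raise PedigreeError(f"{row['id']!r} is its own parent")
        object.__setattr__(self, "table", t)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        order = self.topological_order()
        if len(order) != len(self.table):
            raise PedigreeError("pedigree contains a cycle")

    # -- accessors ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        row = self.table.loc[self.table["id"] == iid]
        if row.empty:
            raise KeyError(iid)
        return row["sire"].iloc[0], row["dam"].iloc[0]

    @property
    def founder_ids(self) -> list[str]:
        return [r["id"] for _, r in self.table.iterrows() if r["sire"] is None]

    def is_founder(self, iid: str) -> bool:
        s, _ = self.parents(iid)
        return s is None

    def offspring_of(self, parent_id: str) -> list[str]:
        t = self.table
        return list(t.loc[(t["sire"] == parent_id) | (t["dam"] == parent_id), "id"])

    def topological_order(self) -> list[str]:
        """Kahn's algorithm: parents before offspring."""
        t = self.table
        children: dict[str, list[str]] = {i: [] for i in t["id"]}
        indeg = {i: 0 for i in t["id"]}
        for _, row in t.iterrows():
            for p in (row["sire"], row["dam"]):
                if p is not None:
                    children[p].append(row["id"])
                    indeg[row["id"]] += 1
        queue = [i for i, k in indeg.items() if k == 0]
        order: list[str] = []
        while queue:
            i = queue.pop()
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        return order

    def generation_ids(self, generation: str) -> list[str]:
        t = self.table
        return list(t.loc[t["generation"] == generation, "id"])

    def population_ids(self, population: str) -> list[str]:
        t = self.table
        return list(t.loc[t["population"] == population, "id"])

    def subset(self, ids: list[str]) -> pd.DataFrame:
        """Rows for ``ids`` (no integrity re-check; parents may be absent)."""
        t = self.table
        return t.loc[t["id"].isin(ids)].reset_index(drop=True)

    @classmethod
    def from_records(cls, records: list[tuple]) -> "Pedigree":
        """Records of (id, sire, dam, sex, generation, population)."""
        return cls(pd.DataFrame(records, columns=_COLS))
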