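"""Phased genotype matrices.

Alleles are coded 1 for the major and 2 for the minor allele (the coding
conventional for haplotype-sharing figures in livestock genetics), with 0
as the missing sentinel.  Each individual carries two haplotypes over an
ordered :class:`~vertfine.markers.MarkerMap`; haplotype 0 is paternal and
haplotype 1 maternal whenever parental origin is known.

``hap_source`` optionally records, per transmitted allele, which of the
parent's own two haplotypes it was copied from (simulator truth used to
validate phasing and progeny splitting).  ``phase_known`` marks sites
whose paternal/maternal assignment is resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import MarkerMap

__all__ = ["PhasedGenotypeMatrix", "MISSING", "MAJOR", "MINOR"]

MISSING = 0
MAJOR = 1
MINOR = 2


@dataclass
class PhasedGenotypeMatrix:
    """``alleles[i, m, h]`` = allele of individual ``i`` at marker ``m`` on
    haplotype ``h`` (0 paternal, 1 maternal where origin is known)."""

    ids: list[str]
    markers: MarkerMap
    alleles: np.ndarray = field(repr=False)  # (n, m, 2) int8 in {0,1,2}
    origin: pd.DataFrame | None = field(default=None, repr=False)  # cols sire,dam per id
    hap_source: np.ndarray | None = field(default=None, repr=False)  # (n, m, 2) int8
    phase_known: np.ndarray | None = field(default=None, repr=False)  # (n, m) bool

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        a = np.asarray(self.alleles, dtype=np.int8)
        if a.shape != (len(self.ids), len(self.markers), 2):
            raise ValueError(
                f"alleles shape {a.shape} != ({len(self.ids)}, {len(self.markers)}, 2)"
            )
        bad = ~np.isin(a, (MISSING, MAJOR, MINOR))
        if bad.any():
            raise ValueError("allele codes must be in {0,1,2}")
        object.__setattr__(self, "alleles", a)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicated individual ids")

    # -- basic accessors ----------------------------------------------

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def m(self) -> int:
        return len(self.markers)

    def row(self, iid: str) -> int:
        try:
            return self.ids.index(iid)
        except ValueError:
            raise KeyError(f"individual {iid!r} not genotyped") from None

    def haplotype(self, iid: str, hap: int) -> np.ndarray:
        return self.alleles[self.row(iid), :, hap]

    def dosage(self) -> np.ndarray:
        """Minor-allele dosage per (individual, marker); -1 where either
        allele is missing."""
        a = self.alleles
        dos = (a == MINOR).sum(axis=2).astype(np.int8)
        dos[(a == MISSING).any(axis=2)] = -1
        return dos

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage(), index=self.ids, columns=self.markers.names)

    # -- subsetting ---------------------------------------------------

    def take_individuals(self, ids: list[str]) -> "PhasedGenotypeMatrix":
        rows = [self.row(i) for i in ids]
        return PhasedGenotypeMatrix(
            ids=list(ids),
            markers=self.markers,
            alleles=self.alleles[rows],
            origin=self.origin.loc[list(ids)] if self.origin is not None else None,
            hap_source=self.hap_source[rows] if self.hap_source is not None else None,
            phase_known=self.phase_known[rows] if self.phase_known is not None else None,
        )

    def take_markers(self, marker_rows: np.ndarray) -> "PhasedGenotypeMatrix":
        r = np.asarray(marker_rows)
        return PhasedGenotypeMatrix(
            ids=self.ids,
            markers=self.markers.subset(r),
            alleles=self.alleles[:, r, :],
            origin=self.origin,
            hap_source=self.hap_source[:, r, :] if self.hap_source is not None else None,
            phase_known=self.phase_known[:, r] if self.phase_known is not None else None,
        )

    # -- summaries ----------------------------------------------------

    def call_rate_per_individual(self) -> pd.Series:
        ok = (self.alleles != MISSING).all(axis=2)
        return pd.Series(ok.mean(axis=1), index=self.ids)

    def call_rate_per_marker(self) -> pd.Series:
        ok = (self.alleles != MISSING).all(axis=2)
        return pd.Series(ok.mean(axis=0), index=self.markers.names)

    def minor_allele_frequency(self) -> pd.Series:
        """Frequency of allele code 2 among non-missing alleles, per marker."""
        a = self.alleles
        nonmiss = (a != MISSING).sum(axis=(0, 2))
        minor = (a == MINOR).sum(axis=(0, 2))
        with np.errstate(invalid="ignore"):
            f = np.where(nonmiss > 0, minor / np.maximum(nonmiss, 1), np.nan)
        return pd.Series(f, index=self.markers.names)

    def normalize_major_minor(self) -> "PhasedGenotypeMatrix":
        """Flip codes at markers where allele 2 is the commoner one, so that
        1 is always the cohort-major allele."""
        f = self.minor_allele_frequency().to_numpy()
        flip = f > 0.5
        a = self.alleles.copy()
        sub = a[:, flip, :]
        sub[sub == MAJOR] = 3
        sub[sub == MINOR] = MAJOR
        sub[sub == 3] = MINOR
        a[:, flip, :] = sub
        return PhasedGenotypeMatrix(
            ids=self.ids,
            markers=self.markers,
            alleles=a,
            origin=self.origin,
            hap_source=self.hap_source,
            phase_known=self.phase_known,
        )
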