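"""SNP-chip quality control.

Mirrors the standard chip-data cleaning for pedigreed association
studies: animals failing call-rate or familial Mendelian-error bounds are
dropped first, then markers failing call rate, minor-allele frequency or
Hardy-Weinberg equilibrium.  HWE is tested on the unrelated (founder)
subset only — testing F2 litters would count family structure as
disequilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import PhasedGenotypeMatrix
from .pedigree import Pedigree

__all__ = [
    "QCThresholds",
    "QCReport",
    "QCError",
    "hwe_exact_midp",
    "mendelian_error_rates",
    "qc_filter",
]


class QCError(ValueError):
    pass


@dataclass
class QCThresholds:
    snp_call_rate_min: float = 0.95
    maf_min: float = 0.10
    hwe_p_min: float = 1e-6
    animal_call_rate_min: float = 0.95
    mendel_error_rate_max: float = 0.1

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class QCReport:
    n_animals_in: int
    n_markers_in: int
    animals_removed: dict[str, int] = field(default_factory=dict)
    markers_removed: dict[str, int] = field(default_factory=dict)
    animal_pass: pd.Series | None = field(default=None, repr=False)

    @property
    def n_informative(self) -> int:
        return self.n_markers_in - sum(self.markers_removed.values())

    @property
    def n_animals_out(self) -> int:
        return self.n_animals_in - sum(self.animals_removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("animals_in", self.n_animals_in), ("markers_in", self.n_markers_in)]
        rows += [(f"animals_removed_{k}", v) for k, v in self.animals_removed.items()]
        rows += [(f"markers_removed_{k}", v) for k, v in self.markers_removed.items()]
        rows += [("animals_out", self.n_animals_out), ("n_informative", self.n_informative)]
        return pd.DataFrame(rows, columns=["item", "count"])


# ---------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------


def _log_het_prob(n_het: int, n_a: int, n: int) -> float:
    """log P(n_het heterozygotes | n diploids, n_a copies of the rarer
    allele) under the exact conditional HWE distribution."""
    n_hom_a = (n_a - n_het) // 2
    n_hom_b = n - n_het - n_hom_a
    return (
        gammaln(n + 1)
        - gammaln(n_hom_a + 1)
        - gammaln(n_het + 1)
        - gammaln(n_hom_b + 1)
        + n_het * math.log(2)
        + gammaln(n_a + 1)
        + gammaln(2 * n - n_a + 1)
        - gammaln(2 * n + 1)
    )


def hwe_exact_midp(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact (mid-p) Hardy-Weinberg test from genotype counts.

    Enumerates the conditional distribution of the heterozygote count
    given the allele counts; the mid-p variant sums configurations less
    probable than the observed one plus half the probability of ties.
    Monomorphic markers return 1.0 by convention.
    """
    for c in (n_hom1, n_het, n_hom2):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("no genotypes observed")
    n_a = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    if n_a == 0:
        return 1.0
    obs = n_het
    hets = np.arange(n_a % 2, n_a + 1, 2)
    logp = np.array([_log_het_prob(int(h), n_a, n) for h in hets])
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[hets == obs][0]
    eps = 1e-12
    midp = p[p < p_obs - eps].sum() + 0.5 * p[np.abs(p - p_obs) <= eps].sum()
    return float(min(1.0, midp))


# ---------------------------------------------------------------------
# Mendelian errors
# ---------------------------------------------------------------------


def mendelian_error_rates(
    genotypes: PhasedGenotypeMatrix, pedigree: Pedigree
) -> pd.Series:
    """Per-animal familial Mendelian-error rate: among markers where the
    animal and its genotyped parents have calls, the fraction showing an
    impossible transmission (opposing homozygotes, or a heterozygous
    child of two identical homozygotes)."""
    dos = genotypes.dosage_frame()
    rates = {}
    for iid in genotypes.ids:
        try:
            sire, dam = pedigree.parents(iid)
        except KeyError:
            rates[iid] = 0.0
            continue
        if sire is None:
            rates[iid] = 0.0
            continue
        c = dos.loc[iid].to_numpy()
        s = dos.loc[sire].to_numpy() if sire in dos.index else np.full_like(c, -1)
        d = dos.loc[dam].to_numpy() if dam in dos.index else np.full_like(c, -1)
        err = np.zeros(len(c), dtype=bool)
        tested = c >= 0
        for p in (s, d):
            known = tested & (p >= 0)
            err |= known & (((c == 0) & (p == 2)) | ((c == 2) & (p == 0)))
        both = tested & (s >= 0) & (d >= 0)
        err |= both & (c == 1) & (((s == 0) & (d == 0)) | ((s == 2) & (d == 2)))
        n_tested = int((tested & ((s >= 0) | (d >= 0))).sum())
        rates[iid] = float(err.sum() / n_tested) if n_tested else 0.0
    return pd.Series(rates, name="mendel_error_rate")


# ---------------------------------------------------------------------
# the filter
# ---------------------------------------------------------------------


def qc_filter(
    genotypes: PhasedGenotypeMatrix,
    pedigree: Pedigree | None = None,
    thresholds: QCThresholds | None = None,
) -> tuple[PhasedGenotypeMatrix, QCReport]:
    """Two-pass filter: animals first (call rate, Mendelian errors), then
    markers (call rate, MAF, HWE on unrelated animals)."""
    th = thresholds or QCThresholds()
    report = QCReport(n_animals_in=genotypes.n, n_markers_in=genotypes.m)

    # ---- animals
    cr = genotypes.call_rate_per_individual()
    fail_cr = cr < th.animal_call_rate_min
    if pedigree is not None:
        mer = mendelian_error_rates(genotypes, pedigree)
        fail_me = mer > th.mendel_error_rate_max
    else:
        fail_me = pd.Series(False, index=genotypes.ids)
    report.animals_removed["call_rate"] = int(fail_cr.sum())
    report.animals_removed["mendel_error"] = int((fail_me & ~fail_cr).sum())
    keep_ids = [i for i in genotypes.ids if not (fail_cr[i] or fail_me[i])]
    report.animal_pass = ~(fail_cr | fail_me)
    if not keep_ids:
        raise QCError("all animals removed by QC")
    g = genotypes.take_individuals(keep_ids)

    # ---- markers
    cr_m = g.call_rate_per_marker().to_numpy()
    maf = g.minor_allele_frequency()
    maf = np.minimum(maf.to_numpy(), 1 - maf.to_numpy())
    fail_cr_m = cr_m < th.snp_call_rate_min
    fail_maf = ~fail_cr_m & (np.nan_to_num(maf) < th.maf_min)
    fail_hwe = np.zeros(g.m, dtype=bool)
    unrelated = (
        [i for i in pedigree.founder_ids if i in g.ids] if pedigree is not None else g.ids
    )
    if unrelated:
        dos = g.take_individuals(unrelated).dosage()
        for j in np.flatnonzero(~fail_cr_m & ~fail_maf):
            col = dos[:, j]
            col = col[col >= 0]
            if col.size == 0:
                continue
            counts = [(col == k).sum() for k in (0, 1, 2)]
            if hwe_exact_midp(*counts) < th.hwe_p_min:
                fail_hwe[j] = True
    report.markers_removed["call_rate"] = int(fail_cr_m.sum())
    report.markers_removed["maf"] = int(fail_maf.sum())
    report.markers_removed["hwe"] = int(fail_hwe.sum())
    keep = ~(fail_cr_m | fail_maf | fail_hwe)
    if not keep.any():
        raise QCError("all markers removed by QC")
    return g.take_markers(np.flatnonzero(keep)), report
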