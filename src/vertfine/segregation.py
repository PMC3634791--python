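"""Marker-assisted segregation analysis (progeny testing).

A sire's QTL genotype is deduced from its offspring's phenotypes grouped
by which of the sire's two chromosomes ("Left"/"Right", labels arbitrary
but fixed) each offspring inherited across the QTL region.  The evidence
is a log10 likelihood ratio Z comparing a heterozygous-sire model (two
group means) to a homozygous-sire model (one common mean), both with
Gaussian errors and maximum-likelihood variance:

    Z = (N / 2) * log10(SS0 / SS1)

with SS0/SS1 the total squared deviations under the one-mean and
two-mean models.  Z > 2 calls the sire Qq (Q on the higher-mean
chromosome), Z < -2 calls it homozygous, and intermediate values are
left undetermined.  Founder chromosomes are classified afterwards by
t-tests against the pooled Q- and q-group phenotypes of the deduced
sires, subject to Mendelian consistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, PhasedGenotypeMatrix
from .pedigree import Pedigree

__all__ = [
    "QTLState",
    "SireProgenyGroups",
    "ZScoreResult",
    "QTLGenotypeCall",
    "split_progeny",
    "zscore_segregation",
    "zscore_fixed_effect",
    "classify_sire",
    "resolve_homozygote",
    "founder_call",
    "MendelianInconsistencyError",
]


class QTLState(str, Enum):
    HET = "Qq"
    HOM = "QQ_or_qq"
    UNKNOWN = "unknown"


class MendelianInconsistencyError(ValueError):
    pass


@dataclass
class SireProgenyGroups:
    sire_id: str
    left: np.ndarray  # phenotypes of offspring inheriting haplotype 0
    right: np.ndarray  # likewise haplotype 1
    left_ids: list[str] = field(default_factory=list)
    right_ids: list[str] = field(default_factory=list)
    n_unassigned: int = 0


@dataclass
class ZScoreResult:
    z: float
    mean_left: float
    mean_right: float
    n_left: int
    n_right: int


@dataclass
class QTLGenotypeCall:
    animal_id: str
    state: QTLState
    hap_orientation: tuple[str, str] = ("unknown", "unknown")  # per haplotype: Q/q/unknown
    evidence: float | None = None  # Z score or t-test p, per caller
    note: str = ""


# ---------------------------------------------------------------------
# progeny splitting
# ---------------------------------------------------------------------


def _paternal_allele(child: np.ndarray, dam: np.ndarray | None) -> np.ndarray:
    """Deduce the paternally transmitted allele per marker from unphased
    child (and dam) genotypes; 0 where ambiguous.  Arrays are (m, 2)."""
    m = child.shape[0]
    out = np.zeros(m, dtype=np.int8)
    child_ok = (child != MISSING).all(axis=1)
    hom = child_ok & (child[:, 0] == child[:, 1])
    out[hom] = child[hom, 0]
    het = child_ok & ~hom
    if dam is not None:
        dam_hom = (dam != MISSING).all(axis=1) & (dam[:, 0] == dam[:, 1])
        resolvable = het & dam_hom
        # dam transmits her homozygous allele, so the paternal allele is
        # the child's other one
        dam_allele = dam[:, 0]
        other = np.where(child[:, 0] == dam_allele, child[:, 1], child[:, 0])
        valid = resolvable & ((child[:, 0] == dam_allele) | (child[:, 1] == dam_allele))
        out[valid] = other[valid]
    return out


def split_progeny(
    genotypes: PhasedGenotypeMatrix,
    pedigree: Pedigree,
    phenotypes: pd.Series,
    sire_id: str,
    region: tuple[str, int, int],
    trait: str | None = None,
) -> SireProgenyGroups:
    """Assign each phenotyped offspring of ``sire_id`` to the sire
    chromosome it inherited across ``region`` (chrom, start_bp, end_bp),
    by majority vote over markers where the sire is heterozygous and the
    offspring's paternal allele is deducible.  Offspring with no
    informative marker or a tied vote are excluded and counted."""
    chrom, start, end = region
    idx = genotypes.markers.region_indices(chrom, start, end)
    if idx.size == 0:
        raise ValueError(f"no markers in region {chrom}:{start}-{end}")
    sire_h = genotypes.alleles[genotypes.row(sire_id)][idx]  # (m, 2)
    informative = (
        (sire_h[:, 0] != sire_h[:, 1])
        & (sire_h[:, 0] != MISSING)
        & (sire_h[:, 1] != MISSING)
    )
    if not informative.any():
        raise ValueError(f"sire {sire_id!r} homozygous throughout region; untestable")
    offspring = [
        o for o in pedigree.offspring_of(sire_id) if o in phenotypes.index and o in genotypes.ids
    ]
    left_ids: list[str] = []
    right_ids: list[str] = []
    n_unassigned = 0
    info_idx = np.flatnonzero(informative)
    for o in offspring:
        child = genotypes.alleles[genotypes.row(o)][idx]
        _, dam_id = pedigree.parents(o)
        dam = (
            genotypes.alleles[genotypes.row(dam_id)][idx]
            if dam_id is not None and dam_id in genotypes.ids
            else None
        )
        pat = _paternal_allele(child, dam)
        votes_left = 0
        votes_right = 0
        for j in info_idx:
            if pat[j] == MISSING:
                continue
            if pat[j] == sire_h[j, 0]:
                votes_left += 1
            elif pat[j] == sire_h[j, 1]:
                votes_right += 1
        if votes_left > votes_right:
            left_ids.append(o)
        elif votes_right > votes_left:
            right_ids.append(o)
        else:
            n_unassigned += 1
    return SireProgenyGroups(
        sire_id=sire_id,
        left=phenotypes.loc[left_ids].to_numpy(dtype=float),
        right=phenotypes.loc[right_ids].to_numpy(dtype=float),
        left_ids=left_ids,
        right_ids=right_ids,
        n_unassigned=n_unassigned,
    )


# ---------------------------------------------------------------------
# the Z statistic
# ---------------------------------------------------------------------


def zscore_segregation(groups: SireProgenyGroups) -> ZScoreResult:
    """Closed-form log10 likelihood ratio of the two-mean (heterozygous)
    versus one-mean (homozygous) Gaussian model with ML variance."""
    left = np.asarray(groups.left, dtype=float)
    right = np.asarray(groups.right, dtype=float)
    if left.size < 2 or right.size < 2:
        raise ValueError("each progeny group needs at least 2 offspring")
    n = left.size + right.size
    pooled = np.concatenate([left, right])
    ss0 = float(np.sum((pooled - pooled.mean()) ** 2))
    ss1 = float(np.sum((left - left.mean()) ** 2) + np.sum((right - right.mean()) ** 2))
    if ss1 <= 0:
        raise ValueError("zero pooled variance; degenerate progeny groups")
    z = (n / 2.0) * math.log10(ss0 / ss1)
    return ZScoreResult(
        z=z,
        mean_left=float(left.mean()),
        mean_right=float(right.mean()),
        n_left=left.size,
        n_right=right.size,
    )


def zscore_fixed_effect(groups: SireProgenyGroups, delta: float = 0.5) -> ZScoreResult:
    """Log10 likelihood ratio with the gene-substitution effect fixed
    under the heterozygote hypothesis.

    The heterozygote model places the group means a known substitution
    effect ``delta`` apart (sign chosen by the data); the homozygote
    model gives both groups one mean.  Because the heterozygote model is
    not nested over the homozygote one, the ratio is informative in both
    directions: strongly negative values are positive evidence for
    homozygosity, which the purely data-fitted form of
    :func:`zscore_segregation` cannot provide.

    Closed form: with within-group SS1, observed mean difference D and
    w = nL*nR/N,  Z = (N/2) * log10[(SS1 + w D^2) / (SS1 + w (|D|-delta)^2)].
    """
    if delta <= 0:
        raise ValueError("substitution effect must be positive")
    left = np.asarray(groups.left, dtype=float)
    right = np.asarray(groups.right, dtype=float)
    if left.size < 2 or right.size < 2:
        raise ValueError("each progeny group needs at least 2 offspring")
    n = left.size + right.size
    ss1 = float(np.sum((left - left.mean()) ** 2) + np.sum((right - right.mean()) ** 2))
    if ss1 <= 0:
        raise ValueError("zero pooled variance; degenerate progeny groups")
    diff = float(left.mean() - right.mean())
    w = left.size * right.size / n
    ss_hom = ss1 + w * diff**2
    ss_het = ss1 + w * (abs(diff) - delta) ** 2
    z = (n / 2.0) * math.log10(ss_hom / ss_het)
    return ZScoreResult(
        z=z,
        mean_left=float(left.mean()),
        mean_right=float(right.mean()),
        n_left=left.size,
        n_right=right.size,
    )


def classify_sire(
    sire_id: str,
    z: ZScoreResult,
    thresholds: tuple[float, float] = (2.0, -2.0),
) -> QTLGenotypeCall:
    """Z above the upper threshold calls a heterozygous sire, with Q on
    the higher-mean chromosome; Z below the lower threshold calls a
    homozygote; anything between stays undetermined."""
    upper, lower = thresholds
    if not math.isfinite(z.z):
        raise ValueError("non-finite Z score")
    if z.z > upper:
        orient = ("Q", "q") if z.mean_left >= z.mean_right else ("q", "Q")
        return QTLGenotypeCall(sire_id, QTLState.HET, orient, evidence=z.z)
    if z.z < lower:
        return QTLGenotypeCall(sire_id, QTLState.HOM, ("unknown", "unknown"), evidence=z.z)
    return QTLGenotypeCall(sire_id, QTLState.UNKNOWN, ("unknown", "unknown"), evidence=z.z)


def resolve_homozygote(
    call: QTLGenotypeCall,
    progeny_phenotypes: np.ndarray,
    q_reference: np.ndarray,
    qq_reference: np.ndarray,
    alpha: float = 0.01,
) -> QTLGenotypeCall:
    """Resolve a homozygous sire call to QQ versus qq by comparing its
    pooled progeny with the reference Q- and q-chromosome progeny groups
    of the deduced heterozygous sires."""
    if call.state != QTLState.HOM:
        return call
    y = np.asarray(progeny_phenotypes, dtype=float)
    if y.size < 2 or q_reference.size < 2 or qq_reference.size < 2:
        return call
    t_q, p_q = _pooled_t(y, q_reference)
    t_qq, p_qq = _pooled_t(y, qq_reference)
    if p_q < alpha and t_q < 0 and p_qq >= alpha:
        return QTLGenotypeCall(call.animal_id, QTLState.HOM, ("q", "q"), call.evidence)
    if p_qq < alpha and t_qq > 0 and p_q >= alpha:
        return QTLGenotypeCall(call.animal_id, QTLState.HOM, ("Q", "Q"), call.evidence)
    return call


# ---------------------------------------------------------------------
# founder propagation
# ---------------------------------------------------------------------


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def founder_call(
    animal_id: str,
    carrier_phenotypes: np.ndarray,
    q_reference: np.ndarray,
    qq_reference: np.ndarray,
    alpha: float = 0.01,
    haplotype: int = 0,
    mendelian_label: str | None = None,
) -> QTLGenotypeCall:
    """Classify one founder chromosome from the phenotypes of the
    offspring that inherited it.

    ``q_reference`` / ``qq_reference`` are the pooled phenotypes of
    progeny known (from deduced heterozygous sires) to carry a Q,
    respectively q, chromosome.  The carrier group is compared with both
    by pooled-variance t-tests; a chromosome significantly below the Q
    reference and compatible with the q reference is called q, and
    symmetrically for Q.  A Mendelian label implied by an offspring's
    own call may resolve an undetermined chromosome but must never
    contradict a significant one.
    """
    carriers = np.asarray(carrier_phenotypes, dtype=float)
    orient = ["unknown", "unknown"]

    def finish(label: str, evidence: float | None, note: str = "") -> QTLGenotypeCall:
        if mendelian_label is not None and label != "unknown" and mendelian_label != label:
            raise MendelianInconsistencyError(
                f"{animal_id}: t-test call {label!r} contradicts Mendelian "
                f"transmission {mendelian_label!r}"
            )
        if label == "unknown" and mendelian_label is not None:
            label = mendelian_label
            note = (note + "; " if note else "") + "resolved by Mendelian transmission"
        orient[haplotype] = label
        state = QTLState.UNKNOWN
        return QTLGenotypeCall(animal_id, state, tuple(orient), evidence, note)

    if carriers.size < 2:
        return finish("unknown", None, "insufficient data")
    if q_reference.size == 0 or qq_reference.size == 0:
        raise ValueError("empty reference group")
    t_q, p_q = _pooled_t(carriers, q_reference)
    t_qq, p_qq = _pooled_t(carriers, qq_reference)
    below_q = p_q < alpha and t_q < 0
    above_qq = p_qq < alpha and t_qq > 0
    like_q = p_qq >= alpha
    like_big_q = p_q >= alpha
    if below_q and like_q:
        return finish("q", p_q)
    if above_qq and like_big_q:
        return finish("Q", p_qq)
    return finish("unknown", min(p_q, p_qq))
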