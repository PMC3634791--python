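"""Identity-by-descent haplotype sharing around the mapped locus.

If every chromosome carrying the count-increasing Q allele descends from
one ancestral mutation, all Q-bearing haplotypes must be identical over
a segment surrounding the causal site.  This module reconstructs
parental origin of alleles from pedigree information (rule-based
phasing), collects the Q-bearing haplotypes named by the segregation
calls, and extends outward from an anchor marker while all Q haplotypes
agree — the maximal shared segment is the refined QTL localization.
Sharing is identity-by-state over the collected haplotypes, used as the
IBD proxy; unknown alleles count as compatible wildcards and are
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, PhasedGenotypeMatrix
from .pedigree import Pedigree
from .segregation import QTLGenotypeCall

__all__ = [
    "QBearingSet",
    "SharedSegment",
    "pedigree_phase",
    "collect_q_haplotypes",
    "shared_region",
    "annotate_region",
]


@dataclass
class QBearingSet:
    """Chromosomes (animal, haplotype index) carrying the Q allele."""

    entries: list[tuple[str, int]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty Q-bearing set")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class SharedSegment:
    chrom: str
    start_bp: int
    end_bp: int
    flank_left: str | None  # discordant marker bounding the segment, None at chrom end
    flank_right: str | None
    n_markers: int
    n_haplotypes: int
    n_wildcard: int = 0  # allele comparisons skipped as unknown
    marker_names: list[str] = field(default_factory=list, repr=False)

    def contains(self, bp: int) -> bool:
        return self.start_bp <= bp <= self.end_bp


# ---------------------------------------------------------------------
# rule-based pedigree phasing
# ---------------------------------------------------------------------


def pedigree_phase(
    genotypes: PhasedGenotypeMatrix, pedigree: Pedigree
) -> tuple[PhasedGenotypeMatrix, int]:
    """Assign parental origin of alleles wherever parent genotypes force
    it; haplotype 0 becomes paternal and haplotype 1 maternal at resolved
    sites.  Homozygous sites are trivially resolved.  Heterozygous sites
    resolve when either parent is homozygous; sites contradicting
    Mendelian transmission are set missing.  Returns the phased matrix
    and the count of Mendelian-inconsistent sites blanked."""
    a = genotypes.alleles.copy()
    n, m, _ = a.shape
    known = np.zeros((n, m), dtype=bool)
    n_errors = 0
    row = {iid: k for k, iid in enumerate(genotypes.ids)}
    for iid in genotypes.ids:
        k = row[iid]
        try:
            sire, dam = pedigree.parents(iid)
        except KeyError:
            sire = dam = None
        child = a[k]
        hom = (child[:, 0] == child[:, 1]) & (child[:, 0] != MISSING)
        known[k, hom] = True
        het = (child[:, 0] != child[:, 1]) & (child != MISSING).all(axis=1)
        if sire is None or sire not in row:
            continue
        parent_g = []
        for pid in (sire, dam):
            if pid is not None and pid in row:
                parent_g.append(genotypes.alleles[row[pid]])
            else:
                parent_g.append(None)
        # homozygous child of an opposing homozygous parent is impossible
        for pg in parent_g:
            if pg is None:
                continue
            p_hom = (pg[:, 0] == pg[:, 1]) & (pg[:, 0] != MISSING)
            clash = hom & p_hom & (child[:, 0] != pg[:, 0])
            if clash.any():
                a[k, clash] = MISSING
                known[k, clash] = False
                n_errors += int(clash.sum())
                hom &= ~clash
        for j in np.flatnonzero(het):
            al = set(child[j])
            pat = mat = None
            bad = False
            for h, pg in enumerate(parent_g):
                if pg is None:
                    continue
                p0, p1 = pg[j]
                if p0 == MISSING or p1 == MISSING:
                    continue
                if p0 == p1:  # homozygous parent transmits its allele
                    if p0 not in al:
                        bad = True
                        break
                    if h == 0:
                        pat = p0
                    else:
                        mat = p0
            if not bad and pat is not None and mat is not None and pat == mat:
                bad = True  # two identical homozygous parents, heterozygous child
            if bad:
                a[k, j] = MISSING
                known[k, j] = False
                n_errors += 1
                continue
            if pat is None and mat is not None:
                pat = (al - {mat}).pop() if len(al) == 2 else mat
            if mat is None and pat is not None:
                mat = (al - {pat}).pop() if len(al) == 2 else pat
            if pat is not None and mat is not None and {pat, mat} == al:
                a[k, j, 0] = pat
                a[k, j, 1] = mat
                known[k, j] = True
    phased = PhasedGenotypeMatrix(
        ids=genotypes.ids,
        markers=genotypes.markers,
        alleles=a,
        origin=genotypes.origin,
        phase_known=known,
    )
    return phased, n_errors


# ---------------------------------------------------------------------
# Q-haplotype collection
# ---------------------------------------------------------------------


def collect_q_haplotypes(calls: list[QTLGenotypeCall]) -> QBearingSet:
    """One entry per chromosome whose orientation is Q.  Heterozygous
    calls contribute their Q haplotype, resolved QQ homozygotes both;
    undetermined chromosomes are skipped."""
    entries = [
        (c.animal_id, h)
        for c in calls
        for h in (0, 1)
        if c.hap_orientation[h] == "Q"
    ]
    return QBearingSet(entries)


# ---------------------------------------------------------------------
# the sharing scan
# ---------------------------------------------------------------------


def _hap_matrix(
    qset: QBearingSet, genotypes: PhasedGenotypeMatrix, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Alleles (k, m) of the Q haplotypes over marker rows ``idx``, and a
    wildcard mask for missing or phase-unresolved heterozygous sites."""
    k = len(qset)
    haps = np.empty((k, idx.size), dtype=np.int8)
    wild = np.zeros((k, idx.size), dtype=bool)
    for r, (iid, h) in enumerate(qset.entries):
        i = genotypes.row(iid)
        haps[r] = genotypes.alleles[i, idx, h]
        wild[r] = haps[r] == MISSING
        if genotypes.phase_known is not None:
            het = genotypes.alleles[i, idx, 0] != genotypes.alleles[i, idx, 1]
            wild[r] |= het & ~genotypes.phase_known[i, idx]
    return haps, wild


def _concordant(col: np.ndarray, wild: np.ndarray) -> bool:
    vals = col[~wild]
    return vals.size == 0 or bool((vals == vals[0]).all())


def shared_region(
    qset: QBearingSet,
    genotypes: PhasedGenotypeMatrix,
    chrom: str,
    anchor_bp: int,
) -> SharedSegment:
    """Maximal run of markers around the anchor at which all Q haplotypes
    carry the same allele (unknowns compatible with anything)."""
    mm = genotypes.markers
    idx = mm.chrom_indices(chrom)
    if idx.size == 0:
        raise ValueError(f"no markers on chromosome {chrom!r}")
    sub_bp = mm.bp[idx]
    if not (sub_bp.min() <= anchor_bp <= sub_bp.max()):
        raise ValueError("anchor outside the chromosome's marker range")
    haps, wild = _hap_matrix(qset, genotypes, idx)
    a = int(np.argmin(np.abs(sub_bp - anchor_bp)))
    if not _concordant(haps[:, a], wild[:, a]):
        raise ValueError(
            f"Q haplotypes discordant at the anchor marker {mm.names[idx[a]]}; "
            "no shared region"
        )
    left = a
    while left > 0 and _concordant(haps[:, left - 1], wild[:, left - 1]):
        left -= 1
    right = a
    while right < idx.size - 1 and _concordant(haps[:, right + 1], wild[:, right + 1]):
        right += 1
    inner = idx[left : right + 1]
    n_wild = int(wild[:, left : right + 1].sum())
    return SharedSegment(
        chrom=str(chrom),
        start_bp=int(mm.bp[inner[0]]),
        end_bp=int(mm.bp[inner[-1]]),
        flank_left=None if left == 0 else str(mm.names[idx[left - 1]]),
        flank_right=None if right == idx.size - 1 else str(mm.names[idx[right + 1]]),
        n_markers=int(inner.size),
        n_haplotypes=len(qset),
        n_wildcard=n_wild,
        marker_names=[str(s) for s in mm.names[inner]],
    )


# ---------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------


def annotate_region(segment: SharedSegment, genes: pd.DataFrame) -> list[str]:
    """Names of genes whose span overlaps the closed inner interval by at
    least 1 bp.  ``genes`` is a BED-derived frame with 1-based closed
    columns chrom/start/end/name (see :func:`vertfine.io.read_bed`)."""
    need = {"chrom", "start", "end", "name"}
    if not need.issubset(genes.columns):
        raise ValueError(f"gene table lacks columns {need - set(genes.columns)}")
    hit = (
        (genes["chrom"].astype(str) == segment.chrom)
        & (genes["start"] <= segment.end_bp)
        & (genes["end"] >= segment.start_bp)
    )
    return list(genes.loc[hit, "name"])
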