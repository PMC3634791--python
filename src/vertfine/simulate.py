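"""Synthetic pig-cross simulator.

Generates the material every downstream stage of the fine-mapping
pipeline consumes: founder haplotypes in linkage equilibrium, gamete
dropping through an arbitrary pedigree under the Haldane map function, a
biallelic QTL planted on chosen founder chromosomes, integer vertebral
counts from a latent Gaussian trait model, and genotyping artifacts
(missingness, allele errors) for exercising quality control.

The QTL is carried as a hidden pseudo-marker so that its alleles
recombine with flanking markers exactly as a genotyped SNP would; its
per-animal dosage is read back with :func:`plant_qtl`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MAJOR, MINOR, MISSING, PhasedGenotypeMatrix
from .markers import MarkerMap
from .pedigree import Pedigree

__all__ = [
    "TraitModel",
    "QTLSpec",
    "haldane_recomb_fraction",
    "simulate_founders",
    "drop_gametes",
    "insert_qtl",
    "plant_qtl",
    "simulate_phenotypes",
    "corrupt",
    "simulate_progeny_groups",
    "simulate_q_descendants",
]


# ---------------------------------------------------------------------
# trait / QTL parameterization
# ---------------------------------------------------------------------


@dataclass
class TraitModel:
    """Latent-Gaussian model for an integer vertebral count.

    thoracic latent = mu + a*dosage + d*[dosage==1] + polygenic + residual,
    rounded to the nearest integer when ``rounding`` is on.  The polygenic
    term carries a fraction ``h2_poly`` of the non-QTL variance and is
    structured by the pedigree.  The lumbar count is an independent
    integer trait with its own mean and spread and no QTL effect.
    """

    mu: float = 14.5
    a: float = 0.5  # additive effect per Q allele, in vertebrae
    d: float = 0.0  # dominance deviation
    h2_poly: float = 0.0
    sigma_e: float = 0.6
    rounding: bool = True
    lumbar_mu: float = 5.4
    lumbar_sigma: float = 0.45

    def __post_init__(self) -> None:
        if self.sigma_e <= 0:
            raise ValueError("sigma_e must be > 0")
        if not (0 <= self.h2_poly < 1):
            raise ValueError("h2_poly must be in [0, 1)")
        if self.lumbar_sigma <= 0:
            raise ValueError("lumbar_sigma must be > 0")

    @property
    def sigma_g(self) -> float:
        """Polygenic SD implied by h2_poly relative to sigma_e."""
        if self.h2_poly == 0:
            return 0.0
        return self.sigma_e * math.sqrt(self.h2_poly / (1 - self.h2_poly))


@dataclass
class QTLSpec:
    """A biallelic QTL: position plus the founder chromosomes carrying
    the count-increasing Q allele, named as (founder_id, haplotype)."""

    chrom: str
    position_bp: int
    founder_carriers: frozenset[tuple[str, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.founder_carriers = frozenset(self.founder_carriers)
        for iid, hap in self.founder_carriers:
            if hap not in (0, 1):
                raise ValueError(f"haplotype index must be 0/1, got {hap} for {iid}")

    @property
    def marker_name(self) -> str:
        return f"QTL@{self.chrom}:{self.position_bp}"


# ---------------------------------------------------------------------
# map function
# ---------------------------------------------------------------------


def haldane_recomb_fraction(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Haldane recombination fraction r = (1 - exp(-2d/100)) / 2 for a
    genetic distance in cM; no crossover interference."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(d_cm) else r


# ---------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------


def simulate_founders(
    marker_map: MarkerMap,
    n_per_population: dict[str, int],
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int | np.random.Generator = 0,
    ids_per_population: dict[str, list[str]] | None = None,
    freqs_per_population: dict[str, np.ndarray] | None = None,
) -> PhasedGenotypeMatrix:
    """Draw founder haplotypes marker-independently (linkage equilibrium)
    within each population.

    Per marker and population the minor-allele (code 2) frequency is
    uniform on ``maf_range`` unless fixed via ``freqs_per_population``;
    populations can thus be given divergent frequencies at chosen sites.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if len(marker_map) == 0:
        raise ValueError("empty marker map")
    rng = np.random.default_rng(seed)
    ids: list[str] = []
    pops: list[str] = []
    blocks: list[np.ndarray] = []
    m = len(marker_map)
    for pop, n in n_per_population.items():
        if n <= 0:
            raise ValueError(f"non-positive founder count for population {pop!r}")
        if freqs_per_population is not None and pop in freqs_per_population:
            f = np.asarray(freqs_per_population[pop], dtype=float)
            if f.shape != (m,):
                raise ValueError(f"frequency vector for {pop!r} has wrong length")
        else:
            f = rng.uniform(lo, hi, size=m)
        hap = rng.random((n, m, 2)) < f[None, :, None]
        blocks.append(np.where(hap, MINOR, MAJOR).astype(np.int8))
        if ids_per_population is not None and pop in ids_per_population:
            pid = list(ids_per_population[pop])
            if len(pid) != n:
                raise ValueError(f"{pop!r}: {len(pid)} ids for {n} founders")
        else:
            pid = [f"{pop}_F0_{k}" for k in range(n)]
        ids.extend(pid)
        pops.extend([pop] * n)
    return PhasedGenotypeMatrix(ids=ids, markers=marker_map, alleles=np.concatenate(blocks))


# ---------------------------------------------------------------------
# gamete dropping
# ---------------------------------------------------------------------


def _chrom_blocks(marker_map: MarkerMap) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per chromosome: (marker indices, recombination fractions between
    adjacent markers)."""
    blocks = []
    seen = []
    for chrom in marker_map.chroms:
        if chrom not in seen:
            seen.append(chrom)
    for chrom in seen:
        idx = marker_map.chrom_indices(chrom)
        d = np.diff(marker_map.cm[idx])
        blocks.append((idx, haldane_recomb_fraction(d) if d.size else np.empty(0)))
    return blocks


def _meiosis(
    parent_alleles: np.ndarray,
    blocks: list[tuple[np.ndarray, np.ndarray]],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete from a parent's (m, 2) haplotype pair.  Returns the
    gamete and the source haplotype index per marker."""
    m = parent_alleles.shape[0]
    source = np.empty(m, dtype=np.int8)
    for idx, r in blocks:
        start = rng.integers(2)
        if r.size:
            cross = rng.random(r.size) < r
            hapidx = (start + np.concatenate(([0], np.cumsum(cross)))) % 2
        else:
            hapidx = np.array([start])
        source[idx] = hapidx
    gamete = parent_alleles[np.arange(m), source]
    return gamete, source


def drop_gametes(
    founders: PhasedGenotypeMatrix,
    pedigree: Pedigree,
    seed: int | np.random.Generator = 0,
) -> PhasedGenotypeMatrix:
    """Propagate founder haplotypes through the pedigree.

    Each non-founder receives one recombinant gamete per parent; crossover
    counts between adjacent markers follow the Haldane fraction of the
    map's cM distances.  Haplotype 0 is the paternal gamete, haplotype 1
    the maternal one; ``hap_source`` records which parental haplotype each
    allele was copied from.
    """
    rng = np.random.default_rng(seed)
    marker_map = founders.markers
    blocks = _chrom_blocks(marker_map)
    order = pedigree.topological_order()
    m = len(marker_map)
    n = len(order)
    alleles = np.zeros((n, m, 2), dtype=np.int8)
    hap_source = np.full((n, m, 2), -1, dtype=np.int8)
    row_of = {iid: k for k, iid in enumerate(order)}
    origin_rows = []
    for iid in order:
        sire, dam = pedigree.parents(iid)
        k = row_of[iid]
        if sire is None:
            try:
                alleles[k] = founders.alleles[founders.row(iid)]
            except KeyError:
                raise KeyError(f"pedigree founder {iid!r} missing from founder genotypes")
            origin_rows.append((iid, None, None))
        else:
            for h, parent in enumerate((sire, dam)):
                gamete, source = _meiosis(alleles[row_of[parent]], blocks, rng)
                alleles[k, :, h] = gamete
                hap_source[k, :, h] = source
            origin_rows.append((iid, sire, dam))
    origin = pd.DataFrame(origin_rows, columns=["id", "sire", "dam"]).set_index("id")
    return PhasedGenotypeMatrix(
        ids=order,
        markers=marker_map,
        alleles=alleles,
        origin=origin,
        hap_source=hap_source,
    )


# ---------------------------------------------------------------------
# QTL planting
# ---------------------------------------------------------------------


def insert_qtl(founders: PhasedGenotypeMatrix, qtl: QTLSpec) -> PhasedGenotypeMatrix:
    """Insert the QTL as a hidden pseudo-marker in the founder matrix:
    allele 2 (Q) on every carrier chromosome, allele 1 (q) elsewhere."""
    mm = founders.markers
    idx = mm.chrom_indices(qtl.chrom)
    if idx.size == 0:
        raise ValueError(f"QTL chromosome {qtl.chrom!r} not in map")
    if not (mm.bp[idx].min() <= qtl.position_bp <= mm.bp[idx].max()):
        raise ValueError("QTL position outside the map range of its chromosome")
    for iid, _ in qtl.founder_carriers:
        if iid not in founders.ids:
            raise ValueError(f"QTL carrier {iid!r} is not a founder in this matrix")
    new_map = mm.insert(qtl.marker_name, qtl.chrom, qtl.position_bp)
    pos = new_map.index_of(qtl.marker_name)
    col = np.full((founders.n, 1, 2), MAJOR, dtype=np.int8)
    for iid, hap in qtl.founder_carriers:
        col[founders.row(iid), 0, hap] = MINOR
    alleles = np.concatenate(
        [founders.alleles[:, :pos, :], col, founders.alleles[:, pos:, :]], axis=1
    )
    return PhasedGenotypeMatrix(ids=founders.ids, markers=new_map, alleles=alleles)


def plant_qtl(
    genotypes: PhasedGenotypeMatrix,
    qtl: QTLSpec,
    pedigree: Pedigree | None = None,
) -> pd.Series:
    """Per-individual Q dosage in {0, 1, 2} read off the hidden QTL
    pseudo-marker (which recombined like any genotyped SNP during gamete
    dropping)."""
    if pedigree is not None:
        founder_set = set(pedigree.founder_ids)
        for iid, _ in qtl.founder_carriers:
            if iid not in founder_set:
                raise ValueError(f"QTL carrier {iid!r} is not a pedigree founder")
    try:
        pos = genotypes.markers.index_of(qtl.marker_name)
    except KeyError:
        raise KeyError(
            f"{qtl.marker_name} not present; insert_qtl() must run before gamete dropping"
        ) from None
    dos = (genotypes.alleles[:, pos, :] == MINOR).sum(axis=1)
    return pd.Series(dos, index=genotypes.ids, name="q_dosage")


# ---------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------


def _polygenic_values(
    pedigree: Pedigree, sigma_g: float, rng: np.random.Generator
) -> pd.Series:
    """Breeding values dropped down the pedigree: founders ~ N(0, sg^2),
    offspring = parent average + Mendelian-sampling N(0, sg^2 / 2)."""
    g: dict[str, float] = {}
    for iid in pedigree.topological_order():
        sire, dam = pedigree.parents(iid)
        if sire is None:
            g[iid] = rng.normal(0.0, sigma_g)
        else:
            g[iid] = 0.5 * (g[sire] + g[dam]) + rng.normal(0.0, sigma_g / math.sqrt(2))
    return pd.Series(g)


def simulate_phenotypes(
    dosages: pd.Series,
    trait: TraitModel,
    pedigree: Pedigree | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Thoracic and lumbar vertebral counts for the individuals indexed by
    ``dosages``.  The QTL acts on the thoracic count only."""
    rng = np.random.default_rng(seed)
    ids = list(dosages.index)
    dos = dosages.to_numpy(dtype=float)
    if trait.h2_poly > 0:
        if pedigree is not None:
            poly = _polygenic_values(pedigree, trait.sigma_g, rng).reindex(ids).to_numpy()
            if np.isnan(poly).any():
                raise ValueError("phenotyped individual missing from pedigree")
        else:
            poly = rng.normal(0.0, trait.sigma_g, size=len(ids))
    else:
        poly = np.zeros(len(ids))
    latent = (
        trait.mu
        + trait.a * dos
        + trait.d * (dos == 1)
        + poly
        + rng.normal(0.0, trait.sigma_e, size=len(ids))
    )
    lumbar = trait.lumbar_mu + rng.normal(0.0, trait.lumbar_sigma, size=len(ids))
    if trait.rounding:
        thoracic = np.rint(latent).astype(int)
        lumbar_out = np.rint(lumbar).astype(int)
    else:
        thoracic, lumbar_out = latent, lumbar
    return pd.DataFrame({"id": ids, "thoracic": thoracic, "lumbar": lumbar_out})


# ---------------------------------------------------------------------
# genotyping artifacts
# ---------------------------------------------------------------------


def corrupt(
    genotypes: PhasedGenotypeMatrix,
    missing_rate: float = 0.0,
    error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> PhasedGenotypeMatrix:
    """Set a fraction of allele entries missing and flip a fraction of the
    retained ones, emulating chip no-calls and genotyping errors."""
    for name, rate in (("missing_rate", missing_rate), ("error_rate", error_rate)):
        if not (0 <= rate < 1):
            raise ValueError(f"{name} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    a = genotypes.alleles.copy()
    if missing_rate > 0:
        a[rng.random(a.shape) < missing_rate] = MISSING
    if error_rate > 0:
        flip = (rng.random(a.shape) < error_rate) & (a != MISSING)
        a[flip] = np.where(a[flip] == MAJOR, MINOR, MAJOR)
    return PhasedGenotypeMatrix(
        ids=genotypes.ids,
        markers=genotypes.markers,
        alleles=a,
        origin=genotypes.origin,
        hap_source=genotypes.hap_source,
        phase_known=genotypes.phase_known,
    )


# ---------------------------------------------------------------------
# focused helpers for progeny testing and IBD studies
# ---------------------------------------------------------------------


def simulate_progeny_groups(
    sire_is_het: bool,
    n_left: int,
    n_right: int,
    trait: TraitModel,
    seed: int | np.random.Generator = 0,
    dam_q_freq: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Phenotypes of a sire's progeny split by transmitted chromosome.

    For a heterozygous (Qq) sire the "left" chromosome carries Q; for a
    homozygous sire both chromosomes are q.  Dams contribute a Q allele
    with frequency ``dam_q_freq``.  Returns (left, right) count arrays.
    """
    rng = np.random.default_rng(seed)

    def group(n: int, sire_allele_q: bool) -> np.ndarray:
        dam_q = rng.random(n) < dam_q_freq
        dos = dam_q.astype(float) + (1.0 if sire_allele_q else 0.0)
        lat = (
            trait.mu
            + trait.a * dos
            + trait.d * (dos == 1)
            + rng.normal(0.0, trait.sigma_e, size=n)
        )
        return np.rint(lat).astype(int) if trait.rounding else lat

    return group(n_left, sire_is_het), group(n_right, False)


def simulate_q_descendants(
    marker_map: MarkerMap,
    chrom: str,
    anchor_bp: int,
    n_haplotypes: int = 22,
    n_meioses: int = 8,
    background_maf: tuple[float, float] = (0.1, 0.5),
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Haplotypes descending from one ancestral chromosome, each eroded by
    successive meioses against random backgrounds but conditioned to keep
    the ancestral allele at the anchor (all remain Q-bearing).

    Returns (haplotypes (k, m) over the chromosome's markers, ancestral
    haplotype (m,)).
    """
    rng = np.random.default_rng(seed)
    idx = marker_map.chrom_indices(chrom)
    sub = marker_map.subset(idx)
    m = len(sub)
    anchor = int(np.argmin(np.abs(sub.bp - anchor_bp)))
    lo, hi = background_maf
    f = rng.uniform(lo, hi, size=m)
    ancestral = np.where(rng.random(m) < f, MINOR, MAJOR).astype(np.int8)
    r = haldane_recomb_fraction(np.diff(sub.cm))
    haps = np.empty((n_haplotypes, m), dtype=np.int8)
    for k in range(n_haplotypes):
        hap = ancestral.copy()
        ancestral_mask = np.ones(m, dtype=bool)
        for _ in range(n_meioses):
            background = np.where(rng.random(m) < f, MINOR, MAJOR).astype(np.int8)
            start = rng.integers(2)
            cross = rng.random(m - 1) < r
            hapidx = (start + np.concatenate(([0], np.cumsum(cross)))) % 2
            # keep the gamete that retains the ancestral anchor allele
            if hapidx[anchor] != 0:
                hapidx = 1 - hapidx
            hap = np.where(hapidx == 0, hap, background)
            ancestral_mask &= hapidx == 0
        haps[k] = hap
    return haps, ancestral
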