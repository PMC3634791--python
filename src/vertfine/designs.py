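"""Study designs: pedigree builders and the three-population fixture.

The demo fixture emulates the mapping material of the vertebral-number
study: a Western x Chinese F2 intercross (2 F0 sires x 17 F0 dams ->
9 F1 boars x 59 F1 sows -> phenotyped F2), a synthetic-breed half-sib
family set (4 sires x 55 dams), a small Chinese x Chinese F2 cross, and
an outbred three-way-hybrid sample.  A biallelic QTL of ~0.5 vertebrae
per Q allele sits on chromosome 7; every founder chromosome carrying Q
also carries a copy of one ancestral haplotype over a random window
around the causal site, so that all Q-bearing chromosomes are identical
by descent there — the premise the haplotype-sharing stage exploits.

A resequencing-style panel of dense variants surrounds the QTL: one
variant (the planted causal mutation) and a same-position twin ride the
ancestral haplotype exclusively and are therefore in complete LD with Q;
the remaining variants also segregate on non-carrier chromosomes and
have only partial LD with the QTL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MINOR, PhasedGenotypeMatrix
from .markers import MarkerMap
from .pedigree import Pedigree
from .simulate import (
    QTLSpec,
    TraitModel,
    drop_gametes,
    insert_qtl,
    plant_qtl,
    simulate_founders,
    simulate_phenotypes,
)

__all__ = [
    "f2_pedigree",
    "halfsib_pedigree",
    "outbred_pedigree",
    "FixtureParams",
    "PopulationData",
    "StudyFixture",
    "build_fixture",
]


# ---------------------------------------------------------------------
# pedigree builders
# ---------------------------------------------------------------------


def f2_pedigree(
    sire_ids: list[str],
    dam_ids: list[str],
    n_f1_boars: int,
    n_f1_sows: int,
    n_f2: int,
    prefix: str,
    population: str,
) -> Pedigree:
    """Two-generation intercross: F0 sires x F0 dams -> F1, then F1 boars
    x F1 sows -> F2, avoiding full-sib F1 matings where possible."""
    rows = [(i, None, None, "M", "F0", population) for i in sire_ids]
    rows += [(i, None, None, "F", "F0", population) for i in dam_ids]
    boars, sows = [], []
    for k in range(n_f1_boars + n_f1_sows):
        iid = f"{prefix}_F1_{k}"
        sire = sire_ids[k % len(sire_ids)]
        dam = dam_ids[k % len(dam_ids)]
        sex = "M" if k < n_f1_boars else "F"
        rows.append((iid, sire, dam, sex, "F1", population))
        (boars if sex == "M" else sows).append((iid, sire, dam))
    parents_of = {iid: (s, d) for iid, s, d in boars + sows}
    f2_parents = []
    for j, (sow, *_py) in enumerate(sows):
        boar = boars[j % len(boars)][0]
        if parents_of[boar] == parents_of[sow] and len(boars) > 1:
            boar = boars[(j + 1) % len(boars)][0]
        f2_parents.append((boar, sow))
    for k in range(n_f2):
        boar, sow = f2_parents[k % len(f2_parents)]
        rows.append((f"{prefix}_F2_{k}", boar, sow, "M" if k % 2 else "F", "F2", population))
    return Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "generation", "population"]))


def halfsib_pedigree(
    sire_ids: list[str], dam_ids: list[str], n_offspring: int, prefix: str, population: str
) -> Pedigree:
    """Half-sib families: each dam mated to one sire, offspring spread
    round-robin over dams."""
    rows = [(i, None, None, "M", "F0", population) for i in sire_ids]
    rows += [(i, None, None, "F", "F0", population) for i in dam_ids]
    for k in range(n_offspring):
        dam = dam_ids[k % len(dam_ids)]
        sire = sire_ids[(k % len(dam_ids)) % len(sire_ids)]
        rows.append((f"{prefix}_O_{k}", sire, dam, "M" if k % 2 else "F", "F2", population))
    return Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "generation", "population"]))


def outbred_pedigree(ids: list[str], population: str) -> Pedigree:
    rows = [(i, None, None, "M" if k % 2 else "F", "outbred", population) for k, i in enumerate(ids)]
    return Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "generation", "population"]))


# ---------------------------------------------------------------------
# fixture parameters
# ---------------------------------------------------------------------


@dataclass
class FixtureParams:
    """Defaults give the scaled-down emulation of the three experimental
    populations plus the outbred validation sample."""

    chrom_sizes_mb: dict[str, float] = field(
        default_factory=lambda: {"1": 120.0, "7": 135.0, "14": 120.0}
    )
    chip_per_chrom: int = 600
    qtl_chrom: str = "7"
    qtl_bp: int = 103_950_000
    n_seq_decoys: int = 13
    seq_span_bp: int = 450_000
    # White Duroc x Erhualian style intercross
    we_n_f1_boars: int = 9
    we_n_f1_sows: int = 59
    we_n_f2: int = 900
    we_n_carrier_dams: int = 3
    # synthetic-breed half-sib families
    su_n_sires: int = 4
    su_n_dams: int = 55
    su_n_offspring: int = 400
    su_dam_carrier_p: float = 0.35
    # small Chinese x Chinese intercross
    et_n_f1_boars: int = 2
    et_n_f1_sows: int = 7
    et_n_f2: int = 61
    # outbred three-way-hybrid sample
    dll_n: int = 400
    dll_carrier_p: float = 0.55
    # trait model (additive effect shared; baselines differ per population)
    trait_a: float = 0.5
    trait_sigma_e: float = 0.45
    trait_h2_poly: float = 0.1
    trait_mu: dict[str, float] = field(
        default_factory=lambda: {"WE": 14.5, "SU": 13.9, "ET": 14.2, "DLL": 14.7}
    )
    # ancestral-segment extent on each side of the QTL (Mb)
    segment_halfwidth_mb: tuple[float, float] = (0.6, 1.6)

    def trait_for(self, population: str) -> TraitModel:
        return TraitModel(
            mu=self.trait_mu[population],
            a=self.trait_a,
            h2_poly=self.trait_h2_poly,
            sigma_e=self.trait_sigma_e,
        )


@dataclass
class PopulationData:
    name: str
    pedigree: Pedigree
    genotypes: PhasedGenotypeMatrix  # includes the hidden QTL pseudo-marker
    phenotypes: pd.DataFrame
    dosages: pd.Series  # truth Q dosage per animal
    phenotyped_ids: list[str]


@dataclass
class StudyFixture:
    params: FixtureParams
    marker_map: MarkerMap  # chip + sequencing panel (no hidden marker)
    chip_markers: list[str]
    seq_variants: list[str]
    populations: dict[str, PopulationData]
    genes: pd.DataFrame  # 1-based closed chrom/start/end/name
    species_table: pd.DataFrame
    qtl: QTLSpec
    causal_variant: str
    twin_variant: str


# ---------------------------------------------------------------------
# fixture construction
# ---------------------------------------------------------------------


def _panel_map(p: FixtureParams) -> tuple[MarkerMap, list[str], list[str], str, str]:
    chip = MarkerMap.regular_grid(p.chrom_sizes_mb, p.chip_per_chrom, prefix="M")
    rows = [chip.table]
    offsets = np.linspace(-p.seq_span_bp, p.seq_span_bp, p.n_seq_decoys)
    offsets[np.abs(offsets) < 1500] += 4000  # keep clear of the causal site
    decoy_pos = (p.qtl_bp + offsets).astype(int)
    seq_names = [f"sv{k:02d}" for k in range(p.n_seq_decoys + 2)]
    positions = sorted(
        [(int(b), n) for b, n in zip(decoy_pos, seq_names[:-2])]
        + [(p.qtl_bp - 1, seq_names[-2]), (p.qtl_bp + 1, seq_names[-1])]
    )
    twin, causal = seq_names[-2], seq_names[-1]
    seq_tab = pd.DataFrame(
        {
            "name": [n for _, n in positions],
            "chrom": p.qtl_chrom,
            "bp": [b for b, _ in positions],
            "cm": [b / 1e6 for b, _ in positions],
        }
    )
    full = pd.concat(rows + [seq_tab], ignore_index=True)
    full = full.sort_values(["chrom", "bp"], kind="stable").reset_index(drop=True)
    # keep chromosome blocks in the chip's original chromosome order
    order = {c: k for k, c in enumerate(dict.fromkeys(chip.chroms))}
    full["__c"] = full["chrom"].map(order)
    full = full.sort_values(["__c", "bp"], kind="stable").drop(columns="__c")
    mm = MarkerMap(full.reset_index(drop=True))
    return mm, list(chip.names), [n for _, n in positions], causal, twin


def _carve_ancestral(
    founders: PhasedGenotypeMatrix,
    carriers: list[tuple[str, int]],
    ancestral: np.ndarray,
    window_idx: np.ndarray,
    p: FixtureParams,
    rng: np.random.Generator,
) -> None:
    """Copy the ancestral haplotype onto each carrier chromosome over a
    random window that always covers the causal site (in place)."""
    lo, hi = p.segment_halfwidth_mb
    bp = founders.markers.bp[window_idx]
    for iid, hap in carriers:
        left = p.qtl_bp - rng.uniform(lo, hi) * 1e6
        right = p.qtl_bp + rng.uniform(lo, hi) * 1e6
        sel = window_idx[(bp >= left) & (bp <= right)]
        founders.alleles[founders.row(iid), sel, hap] = ancestral[
            np.isin(window_idx, sel)
        ]


def build_fixture(params: FixtureParams | None = None, seed: int = 0) -> StudyFixture:
    """Simulate the full three-population study plus the outbred sample."""
    p = params or FixtureParams()
    rng = np.random.default_rng(seed)
    mm, chip_names, seq_names, causal, twin = _panel_map(p)
    m = len(mm)
    is_seq = np.isin(mm.names, seq_names)
    special = {causal, twin}

    # chip SNPs are ascertained once; breed frequencies are correlated
    # perturbations of the shared panel frequencies
    base_freq = rng.uniform(0.1, 0.5, size=m)
    base_freq[is_seq] = rng.uniform(0.15, 0.4, size=int(is_seq.sum()))

    def pop_freqs() -> np.ndarray:
        f = np.clip(base_freq + rng.normal(0.0, 0.05, size=m), 0.02, 0.98)
        f[np.isin(mm.names, list(special))] = 0.0  # exist only on the ancestral haplotype
        return f

    # one ancestral chromosome segment shared by every Q founder chromosome
    qtl_idx7 = mm.chrom_indices(p.qtl_chrom)
    window_idx = qtl_idx7[
        (mm.bp[qtl_idx7] >= p.qtl_bp - p.segment_halfwidth_mb[1] * 1e6)
        & (mm.bp[qtl_idx7] <= p.qtl_bp + p.segment_halfwidth_mb[1] * 1e6)
    ]
    # the ancestral Q chromosome is a rare derived haplotype: against the
    # cohort background it is strongly enriched for minor alleles, which is
    # what gives chip markers on it mapping information
    ancestral = np.where(rng.random(window_idx.size) < 0.85, MINOR, 1).astype(np.int8)
    ancestral[np.isin(mm.names[window_idx], list(special))] = MINOR

    populations: dict[str, PopulationData] = {}

    def make_population(
        name: str,
        founder_pops: dict[str, int],
        founder_ids: dict[str, list[str]],
        carriers: list[tuple[str, int]],
        pedigree: Pedigree,
        phenotyped: list[str],
    ) -> None:
        founders = simulate_founders(
            mm,
            founder_pops,
            seed=rng,
            ids_per_population=founder_ids,
            freqs_per_population={k: pop_freqs() for k in founder_pops},
        )
        _carve_ancestral(founders, carriers, ancestral, window_idx, p, rng)
        qtl = QTLSpec(p.qtl_chrom, p.qtl_bp, frozenset(carriers))
        founders_q = insert_qtl(founders, qtl)
        dropped = drop_gametes(founders_q, pedigree, seed=rng)
        dos = plant_qtl(dropped, qtl, pedigree)
        pheno = simulate_phenotypes(
            dos.loc[phenotyped], p.trait_for(name), pedigree, seed=rng
        )
        populations[name] = PopulationData(
            name=name,
            pedigree=pedigree,
            genotypes=dropped,
            phenotypes=pheno,
            dosages=dos,
            phenotyped_ids=phenotyped,
        )

    # ---- Western x Chinese F2 intercross
    wd = [f"WD_{k}" for k in range(1, 3)]
    eh = [f"EH_{k}" for k in range(1, 18)]
    we_ped = f2_pedigree(wd, eh, p.we_n_f1_boars, p.we_n_f1_sows, p.we_n_f2, "WE", "WE")
    carrier_dams = list(rng.choice(eh, size=p.we_n_carrier_dams, replace=False))
    we_carriers = [(s, 0) for s in wd] + [(d, 0) for d in carrier_dams]
    make_population(
        "WE",
        {"WD": len(wd), "EH": len(eh)},
        {"WD": wd, "EH": eh},
        we_carriers,
        we_ped,
        we_ped.generation_ids("F2"),
    )

    # ---- half-sib synthetic breed
    su_sires = [f"SU_B{k}" for k in range(1, p.su_n_sires + 1)]
    su_dams = [f"SU_D{k}" for k in range(1, p.su_n_dams + 1)]
    su_ped = halfsib_pedigree(su_sires, su_dams, p.su_n_offspring, "SU", "SU")
    su_carriers = [(su_sires[0], 0)]
    for d in su_dams:
        for hap in (0, 1):
            if rng.random() < p.su_dam_carrier_p:
                su_carriers.append((d, hap))
    make_population(
        "SU",
        {"SU": len(su_sires) + len(su_dams)},
        {"SU": su_sires + su_dams},
        su_carriers,
        su_ped,
        su_ped.generation_ids("F2"),
    )

    # ---- small Chinese x Chinese intercross
    et_ped = f2_pedigree(
        ["ET_BOAR"], ["ET_SOW"], p.et_n_f1_boars, p.et_n_f1_sows, p.et_n_f2, "ET", "ET"
    )
    make_population(
        "ET",
        {"ET": 2},
        {"ET": ["ET_BOAR", "ET_SOW"]},
        [("ET_SOW", 0)],
        et_ped,
        et_ped.generation_ids("F2"),
    )

    # ---- outbred hybrid sample
    dll_ids = [f"DLL_{k}" for k in range(p.dll_n)]
    dll_ped = outbred_pedigree(dll_ids, "DLL")
    dll_carriers = [
        (iid, hap) for iid in dll_ids for hap in (0, 1) if rng.random() < p.dll_carrier_p
    ]
    make_population("DLL", {"DLL": p.dll_n}, {"DLL": dll_ids}, dll_carriers, dll_ped, dll_ids)

    # ---- annotation and cross-species material
    genes = pd.DataFrame(
        [
            ("7", 103_945_000, 103_965_000, "VRTN"),
            ("7", 103_985_000, 104_010_000, "SYNDIG1L"),
            ("7", 102_400_000, 102_500_000, "NUMB"),
            ("7", 106_600_000, 106_700_000, "PROX2"),
            ("7", 115_300_000, 115_420_000, "FLRT2"),
            ("1", 60_000_000, 60_080_000, "NR6A1"),
        ],
        columns=["chrom", "start", "end", "name"],
    )
    others = ["human", "mouse", "cattle", "dog", "horse"]
    sp_rows = {}
    for v in seq_names:
        if v == causal:
            states = ["ref", "ref", "ref", "ref", "missing"]
        elif v == twin:
            states = ["ref", "derived", "derived", "ref", "ref"]
        else:
            # decoys are old standing variation, so the derived state is
            # observable in at least one outgroup species
            states = [str(rng.choice(["ref", "derived", "missing"], p=[0.5, 0.3, 0.2]))
                      for _ in others]
            if "derived" not in states:
                states[int(rng.integers(len(states)))] = "derived"
        sp_rows[v] = dict(zip(others, states), pig="derived")
    species_table = pd.DataFrame.from_dict(sp_rows, orient="index")[["pig"] + others]

    qtl_all = QTLSpec(p.qtl_chrom, p.qtl_bp, frozenset())
    return StudyFixture(
        params=p,
        marker_map=mm,
        chip_markers=chip_names,
        seq_variants=seq_names,
        populations=populations,
        genes=genes,
        species_table=species_table,
        qtl=qtl_all,
        causal_variant=causal,
        twin_variant=twin,
    )
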