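"""Candidate causal-variant filtering.

A variant can only be the causal mutation if its genotypes co-segregate
perfectly with the QTL genotypes deduced by progeny testing: every
QTL-heterozygous animal must be heterozygous at the variant, every QTL
homozygote must carry the matching homozygous genotype, under one
consistent assignment of variant alleles to Q/q.  Survivors are screened
against orthologous sequence in other mammals: a derived allele present
in another species long predates the trait and is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segregation import QTLGenotypeCall, QTLState

__all__ = [
    "VariantGenotypeTable",
    "ConcordanceReport",
    "diplotype_class",
    "concordance_test",
    "constraint_filter",
    "complete_ld_check",
]

HOM_REF, HET, HOM_ALT, MISSING_GT = 0, 1, 2, -1


@dataclass
class VariantGenotypeTable:
    """Genotype classes per (animal, variant): 0 hom-ref, 1 het, 2
    hom-alt, -1 missing.  ``positions`` is optional bp per variant."""

    genotypes: pd.DataFrame = field(repr=False)  # index: animals, columns: variants
    positions: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        g = self.genotypes
        bad = ~g.isin([HOM_REF, HET, HOM_ALT, MISSING_GT]).all().all()
        if bad:
            raise ValueError("variant genotypes must be coded 0/1/2/-1")

    @property
    def variants(self) -> list[str]:
        return list(self.genotypes.columns)

    @property
    def animals(self) -> list[str]:
        return list(self.genotypes.index)


def diplotype_class(call: QTLGenotypeCall) -> str:
    """Reduce a call to its QTL diplotype: Qq, QQ, qq, hom (homozygous
    with unresolved direction), Q_, q_ (one chromosome known) or
    unknown."""
    o = sorted(call.hap_orientation)
    if call.state == QTLState.HET or o == ["Q", "q"]:
        return "Qq"
    if o == ["Q", "Q"]:
        return "QQ"
    if o == ["q", "q"]:
        return "qq"
    if call.state == QTLState.HOM:
        return "hom"
    if o == ["Q", "unknown"]:
        return "Q_"
    if o == ["q", "unknown"]:
        return "q_"
    return "unknown"


_HOM_CLASSES = {HOM_REF, HOM_ALT}


def _allowed(cls: str, q_hom: int) -> set[int]:
    q_other = HOM_ALT if q_hom == HOM_REF else HOM_REF
    return {
        "Qq": {HET},
        "QQ": {q_hom},
        "qq": {q_other},
        "hom": set(_HOM_CLASSES),
        "Q_": {HET, q_hom},
        "q_": {HET, q_other},
    }[cls]


@dataclass
class ConcordanceReport:
    summary: pd.DataFrame = field(repr=False)
    mismatches: pd.DataFrame = field(repr=False)  # animal, variant, expected, observed

    @property
    def passing(self) -> list[str]:
        return list(self.summary.loc[self.summary["passed"], "variant"])


def concordance_test(
    table: VariantGenotypeTable, calls: list[QTLGenotypeCall]
) -> ConcordanceReport:
    """Test every variant for perfect co-segregation with the QTL calls.

    The mapping of the variant's alleles onto Q/q is not supplied: both
    orientations are evaluated and the variant passes if either yields
    zero mismatches among animals with (partly) known QTL state, making
    the result independent of animal order.  Missing genotypes are
    skipped and counted; a variant monomorphic across the tested animals
    fails as uninformative.
    """
    classes = {c.animal_id: diplotype_class(c) for c in calls}
    tested = [a for a in table.animals if classes.get(a, "unknown") != "unknown"]
    if not tested:
        raise ValueError("no animal with a known QTL state")
    rows = []
    detail = []
    for v in table.variants:
        g = table.genotypes.loc[tested, v]
        known = g[g != MISSING_GT]
        n_missing = int((g == MISSING_GT).sum())
        if known.nunique() <= 1:
            rows.append((v, False, len(known), n_missing, np.nan, "uninformative"))
            continue
        best = None
        for q_hom in (HOM_ALT, HOM_REF):
            mism = [
                a for a, gt in known.items() if gt not in _allowed(classes[a], q_hom)
            ]
            if best is None or len(mism) < len(best[1]):
                best = (q_hom, mism)
        q_hom, mism = best
        passed = len(mism) == 0
        rows.append(
            (
                v,
                passed,
                len(known),
                n_missing,
                "alt" if q_hom == HOM_ALT else "ref",
                "",
            )
        )
        for a in mism:
            detail.append((a, v, classes[a], int(known[a])))
    summary = pd.DataFrame(
        rows, columns=["variant", "passed", "n_checked", "n_missing", "q_allele", "flag"]
    )
    mismatches = pd.DataFrame(
        detail, columns=["animal", "variant", "qtl_class", "observed_genotype"]
    )
    return ConcordanceReport(summary=summary, mismatches=mismatches)


# ---------------------------------------------------------------------
# evolutionary-constraint screen
# ---------------------------------------------------------------------


def constraint_filter(
    candidates: list[str],
    species_table: pd.DataFrame,
    focal_species: str = "pig",
) -> pd.DataFrame:
    """Retain candidates whose derived allele is absent (or unassessed)
    at the orthologous position in every non-focal species.

    ``species_table``: index = variants, columns = species, values in
    {"ref", "derived", "missing"}.  All-missing comparison rows are
    retained but flagged as low-evidence.
    """
    if focal_species not in species_table.columns:
        raise ValueError(f"focal species {focal_species!r} not in table")
    others = [c for c in species_table.columns if c != focal_species]
    if not others:
        raise ValueError("species table has no comparison species")
    rows = []
    for v in candidates:
        if v not in species_table.index:
            raise KeyError(f"candidate {v!r} absent from species table")
        states = species_table.loc[v, others]
        bad = ~states.isin(["ref", "derived", "missing"])
        if bad.any():
            raise ValueError(f"{v}: invalid allele state {states[bad].iloc[0]!r}")
        derived_in = list(states[states == "derived"].index)
        retained = len(derived_in) == 0
        low_evidence = retained and (states == "missing").all()
        rows.append((v, retained, ",".join(derived_in), low_evidence))
    return pd.DataFrame(
        rows, columns=["variant", "retained", "derived_in_species", "low_evidence"]
    )


# ---------------------------------------------------------------------
# linkage-disequilibrium check
# ---------------------------------------------------------------------


def complete_ld_check(g1: pd.Series, g2: pd.Series) -> tuple[bool, int]:
    """True iff the two variants have identical genotype classes on every
    animal non-missing for both, allowing a fixed relabeling of the
    homozygote classes.  Returns (complete LD, mismatch count)."""
    common = g1.index.intersection(g2.index)
    a = g1.loc[common]
    b = g2.loc[common]
    ok = (a != MISSING_GT) & (b != MISSING_GT)
    if not ok.any():
        raise ValueError("no overlapping non-missing animals")
    a, b = a[ok], b[ok]
    direct = int((a != b).sum())
    swapped = int((a != (2 - b)).sum())
    mismatches = min(direct, swapped)
    return mismatches == 0, mismatches
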