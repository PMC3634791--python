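"""Validation statistics for a genotyped candidate variant.

Genotype-group summaries of vertebral counts, classical pooled-variance
t-tests and one-way ANOVA across the three genotype classes, the
additive effect per allele (half the homozygote-mean difference, plus
the dominance deviation of the heterozygote from the midpoint), and
allele-frequency tables per population.
"""

from __future__ import annotations


from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "group_stats",
    "association_test",
    "additive_effect",
    "allele_frequencies",
    "GENOTYPE_CLASSES",
]

GENOTYPE_CLASSES = {2: "ins/ins", 1: "ins/-", 0: "-/-"}


def group_stats(phenotypes: pd.Series, genotypes: pd.Series) -> pd.DataFrame:
    """Per genotype class (dosage 2/1/0): n, mean, SD of the phenotype.
    Missing genotypes (coded -1 or NaN) are excluded and counted."""
    df = pd.DataFrame({"y": phenotypes, "g": genotypes}).dropna(subset=["y"])
    missing = int(((df["g"] < 0) | df["g"].isna()).sum())
    df = df.loc[(df["g"] >= 0) & df["g"].notna()]
    if df.empty:
        raise ValueError("no non-missing phenotype/genotype pair")
    rows = []
    for dos in (2, 1, 0):
        y = df.loc[df["g"] == dos, "y"]
        rows.append(
            (
                GENOTYPE_CLASSES[dos],
                dos,
                len(y),
                float(y.mean()) if len(y) else np.nan,
                float(y.std(ddof=1)) if len(y) > 1 else np.nan,
            )
        )
    out = pd.DataFrame(rows, columns=["genotype", "dosage", "n", "mean", "sd"])
    out.attrs["n_missing"] = missing
    return out


def association_test(
    phenotypes: pd.Series, genotypes: pd.Series
) -> pd.DataFrame:
    """Pairwise pooled-variance t-tests between genotype classes and a
    one-way ANOVA F across them."""
    df = pd.DataFrame({"y": phenotypes, "g": genotypes}).dropna()
    df = df.loc[df["g"] >= 0]
    groups = {int(k): v["y"].to_numpy() for k, v in df.groupby("g") if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need at least two genotype classes with n >= 2")
    if all(np.var(y) == 0 for y in groups.values()):
        raise ValueError("zero within-class variance in every group")
    rows = []
    for a, b in combinations(sorted(groups, reverse=True), 2):
        t, p = stats.ttest_ind(groups[a], groups[b], equal_var=True)
        rows.append(
            (f"{GENOTYPE_CLASSES[a]} vs {GENOTYPE_CLASSES[b]}", "t", float(t), float(p))
        )
    f, p = stats.f_oneway(*groups.values())
    rows.append(("one-way", "F", float(f), float(p)))
    return pd.DataFrame(rows, columns=["comparison", "statistic", "value", "p"])


def additive_effect(summary: pd.DataFrame) -> tuple[float, float]:
    """(additive effect per allele, dominance deviation) from a
    :func:`group_stats` summary: a = (mean_hom_derived - mean_hom_wt)/2,
    d = mean_het - homozygote midpoint."""
    by_dos = summary.set_index("dosage")
    for dos in (0, 2):
        if dos not in by_dos.index or by_dos.loc[dos, "n"] == 0:
            raise ValueError(f"homozygote class with dosage {dos} is empty")
    m2, m0 = by_dos.loc[2, "mean"], by_dos.loc[0, "mean"]
    a = (m2 - m0) / 2.0
    if 1 in by_dos.index and by_dos.loc[1, "n"] > 0:
        d = by_dos.loc[1, "mean"] - (m2 + m0) / 2.0
    else:
        d = np.nan
    return float(a), float(d)


def allele_frequencies(
    genotypes: pd.Series, populations: pd.Series, origins: dict[str, str] | None = None
) -> pd.DataFrame:
    """Derived-allele frequency per population by allele counting:
    (2 * n_hom_derived + n_het) / (2 * n_genotyped)."""
    df = pd.DataFrame({"g": genotypes, "pop": populations})
    if df["pop"].isna().any():
        raise ValueError("every animal must carry a population label")
    rows = []
    for pop, sub in df.groupby("pop", sort=False):
        g = sub.loc[sub["g"] >= 0, "g"]
        if len(g) == 0:
            raise ValueError(f"population {pop!r} has no genotyped animal")
        freq = float((2 * (g == 2).sum() + (g == 1).sum()) / (2 * len(g)))
        rows.append((pop, (origins or {}).get(pop, ""), len(g), freq))
    return pd.DataFrame(rows, columns=["population", "origin", "n", "q_frequency"])
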