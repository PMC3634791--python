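"""Readers and writers for the formats the pipeline touches.

Genotypes travel as VCF (phased entries use ``|``) or as PED/MAP text;
pedigrees, phenotypes and stage outputs are tab-separated tables with
headers; gene annotation comes in as BED.  Parsers validate and reject
malformed input with line numbers rather than silently coercing it, and
every writer's output is re-readable by the matching reader.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotypes import MAJOR, MINOR, MISSING, PhasedGenotypeMatrix
from .markers import MarkerMap
from .pedigree import Pedigree

__all__ = [
    "FormatError",
    "write_vcf",
    "validate_vcf",
    "read_vcf",
    "write_pedmap",
    "read_pedmap",
    "read_pedigree",
    "write_pedigree",
    "read_phenotypes",
    "write_phenotypes",
    "read_bed",
    "write_bed",
    "write_table",
    "read_table",
    "check_id_overlap",
]

_REF, _ALT = "A", "C"  # symbolic bases for the numeric 1/2 coding


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------


def write_vcf(
    genotypes: PhasedGenotypeMatrix, path: str | Path, seed: int | None = None
) -> None:
    """Minimal VCF 4.2 with GT only.  Allele 1 (major) maps to REF and
    allele 2 (minor) to ALT; phased sites are written ``a|b`` and
    phase-unknown heterozygotes ``a/b``."""
    path = Path(path)
    a = genotypes.alleles
    known = genotypes.phase_known
    code = {MISSING: ".", MAJOR: "0", MINOR: "1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=vertfine\n")
        if seed is not None:
            fh.write(f"##vertfine_seed={seed}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(genotypes.markers.chroms):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.ids)
            + "\n"
        )
        mm = genotypes.markers
        for j in range(len(mm)):
            cells = []
            for i in range(genotypes.n):
                sep = "|"
                if known is not None and not known[i, j] and a[i, j, 0] != a[i, j, 1]:
                    sep = "/"
                cells.append(code[a[i, j, 0]] + sep + code[a[i, j, 1]])
            fh.write(
                f"{mm.chroms[j]}\t{mm.bp[j]}\t{mm.names[j]}\t{_REF}\t{_ALT}\t.\t.\t.\tGT\t"
                + "\t".join(cells)
                + "\n"
            )


def validate_vcf(path: str | Path) -> list[tuple[int, str]]:
    """Structural scan; returns (line number, message) per malformed
    data line."""
    errors = []
    n_samples = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line.strip():
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                if len(fields) < 10:
                    errors.append((lineno, "header has no sample columns"))
                else:
                    n_samples = len(fields) - 9
                continue
            if len(fields) < 9 + (n_samples or 0):
                errors.append((lineno, f"expected {9 + (n_samples or 0)} columns"))
                continue
            if not fields[1].isdigit():
                errors.append((lineno, f"non-integer POS {fields[1]!r}"))
                continue
            for cell in fields[9:]:
                gt = cell.split(":")[0]
                sep = "|" if "|" in gt else "/"
                parts = gt.split(sep)
                if len(parts) != 2:
                    errors.append((lineno, f"non-diploid genotype {gt!r}"))
                    break
                if any(p not in (".", "0", "1") for p in parts):
                    errors.append((lineno, f"bad allele in {gt!r}"))
                    break
    return errors


def read_vcf(path: str | Path, normalize: str = "none") -> PhasedGenotypeMatrix:
    """Read a GT-only biallelic VCF into a phased matrix.

    REF maps to allele 1 and ALT to allele 2; ``normalize="major"``
    re-codes so allele 1 is the cohort-major allele.  Phase-unknown
    heterozygotes (``/``) are flagged in ``phase_known``.
    """
    errors = validate_vcf(path)
    if errors:
        msgs = "; ".join(f"line {ln}: {m}" for ln, m in errors[:10])
        raise FormatError(f"{len(errors)} malformed VCF line(s): {msgs}")
    vcf = VCF(str(path))
    ids = list(vcf.samples)
    names, chroms, bps = [], [], []
    allele_rows, phased_rows = [], []
    for v in vcf:
        names.append(v.ID or f"{v.CHROM}:{v.POS}")
        chroms.append(v.CHROM)
        bps.append(v.POS)
        row = np.empty((len(ids), 2), dtype=np.int8)
        ph = np.empty(len(ids), dtype=bool)
        for i, g in enumerate(v.genotypes):
            a0, a1, is_phased = g[0], g[1], bool(g[2])
            row[i, 0] = MISSING if a0 < 0 else (MAJOR if a0 == 0 else MINOR)
            row[i, 1] = MISSING if a1 < 0 else (MAJOR if a1 == 0 else MINOR)
            ph[i] = is_phased or row[i, 0] == row[i, 1]
        allele_rows.append(row)
        phased_rows.append(ph)
    if not names:
        raise FormatError(f"{path}: no variant records")
    mm = MarkerMap.from_positions(names, chroms, bps)
    alleles = np.stack(allele_rows, axis=1)
    phase_known = np.stack(phased_rows, axis=1)
    g = PhasedGenotypeMatrix(
        ids=ids, markers=mm, alleles=alleles, phase_known=phase_known
    )
    if normalize == "major":
        g = g.normalize_major_minor()
    elif normalize != "none":
        raise ValueError(f"unknown normalize mode {normalize!r}")
    return g


# ---------------------------------------------------------------------
# PED/MAP text
# ---------------------------------------------------------------------


def write_pedmap(
    genotypes: PhasedGenotypeMatrix,
    prefix: str | Path,
    pedigree: Pedigree | None = None,
) -> None:
    """PED/MAP-style text: ``<prefix>.map`` (chrom, name, cM, bp) and
    ``<prefix>.ped`` with numeric 1/2 alleles, 0 for missing.  PED allele
    order within a genotype does not encode phase."""
    prefix = Path(prefix)
    mm = genotypes.markers
    with open(prefix.with_suffix(".map"), "w") as fh:
        for j in range(len(mm)):
            fh.write(f"{mm.chroms[j]}\t{mm.names[j]}\t{mm.cm[j]:.6f}\t{mm.bp[j]}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, iid in enumerate(genotypes.ids):
            sire = dam = "0"
            if pedigree is not None and iid in pedigree.ids:
                s, d = pedigree.parents(iid)
                sire, dam = s or "0", d or "0"
            cells = [
                f"{genotypes.alleles[i, j, 0]} {genotypes.alleles[i, j, 1]}"
                for j in range(len(mm))
            ]
            fh.write(f"FAM\t{iid}\t{sire}\t{dam}\t0\t-9\t" + "\t".join(cells) + "\n")


def read_pedmap(prefix: str | Path) -> PhasedGenotypeMatrix:
    prefix = Path(prefix)
    map_rows = []
    with open(prefix.with_suffix(".map")) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{prefix}.map line {lineno}: expected 4 columns")
            chrom, name, cm, bp = parts
            try:
                map_rows.append((name, chrom, int(bp), float(cm)))
            except ValueError as e:
                raise FormatError(f"{prefix}.map line {lineno}: {e}") from None
    mm = MarkerMap.from_positions(
        [r[0] for r in map_rows],
        [r[1] for r in map_rows],
        [r[2] for r in map_rows],
        [r[3] for r in map_rows],
    )
    ids, rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6 + 2 * len(mm):
                raise FormatError(
                    f"{prefix}.ped line {lineno}: expected {6 + 2 * len(mm)} fields"
                )
            ids.append(parts[1])
            alleles = np.array(parts[6:], dtype=np.int8).reshape(len(mm), 2)
            if not np.isin(alleles, (0, 1, 2)).all():
                raise FormatError(f"{prefix}.ped line {lineno}: allele codes not 0/1/2")
            rows.append(alleles)
    a = np.stack(rows)
    hom = a[:, :, 0] == a[:, :, 1]
    return PhasedGenotypeMatrix(ids=ids, markers=mm, alleles=a, phase_known=hom)


# ---------------------------------------------------------------------
# pedigree / phenotype / BED tables
# ---------------------------------------------------------------------


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    t = pedigree.table.copy()
    t["sire"] = t["sire"].fillna("0")
    t["dam"] = t["dam"].fillna("0")
    t.to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    t = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "id" not in t.columns:
        raise FormatError(f"{path}: pedigree file lacks an 'id' header")
    for c in ("sex", "generation", "population"):
        if c not in t.columns:
            t[c] = "unknown"
    return Pedigree(t)


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", comment="#")
    need = {"id", "thoracic", "lumbar"}
    if not need.issubset(t.columns):
        raise FormatError(f"{path}: phenotype file lacks columns {need - set(t.columns)}")
    t["id"] = t["id"].astype(str)
    if t["id"].duplicated().any():
        dup = t.loc[t["id"].duplicated(), "id"].iloc[0]
        raise FormatError(f"{path}: duplicated id {dup!r}")
    return t


def check_id_overlap(ids_a: list[str], ids_b: list[str]) -> list[str]:
    """Ids present in the first set but not the second (orphan report)."""
    return sorted(set(ids_a) - set(ids_b))


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED (0-based half-open) to a 1-based closed gene table."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path} line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(
                    f"{path} line {lineno}: non-integer coordinates"
                ) from None
            if end <= start:
                raise FormatError(f"{path} line {lineno}: end <= start")
            name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
            rows.append((parts[0], start + 1, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """Inverse of :func:`read_bed`: 1-based closed back to BED."""
    with open(path, "w") as fh:
        for _, r in genes.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['start']) - 1}\t{int(r['end'])}\t{r['name']}\n")


# ---------------------------------------------------------------------
# generic provenance-carrying tables
# ---------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> None:
    buf = _io.StringIO()
    for k, v in (provenance or {}).items():
        buf.write(f"# {k}: {v}\n")
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
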