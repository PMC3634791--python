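"""Mixed-model genome-wide association scan and interval logic.

The scan follows the two-stage strategy common for pedigreed livestock
GWAS: (1) fit a polygenic model y = mu + g + e with g ~ N(0, sg^2 K) for
a genomic kinship K, estimating the heritability by REML on the
eigen-rotated likelihood; (2) test each SNP's additive dosage by
generalized least squares in the rotated coordinates, which accounts for
family structure at the estimated variance ratio.  The per-marker 1-df
Wald statistic is referred to chi-square(1) and summarized as
LOD = log10(1/p).

Evidence from several populations is combined by summing the per-marker
chi-square statistics (df = number of contributing populations), and
support intervals are taken as the contiguous LOD-drop region around the
peak; intersecting the per-population intervals gives the consensus
localization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .genotypes import PhasedGenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "PolygenicModel",
    "ScanResult",
    "ConfidenceInterval",
    "genomic_kinship",
    "polygenic_fit",
    "single_locus_scan",
    "bonferroni_threshold",
    "meta_combine",
    "lod_drop_interval",
    "intersect_intervals",
    "genomic_control_lambda",
]

_LN10 = np.log(10.0)


# ---------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------


@dataclass
class KinshipMatrix:
    ids: list[str]
    values: np.ndarray = field(repr=False)  # (n, n) symmetric

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("kinship shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("kinship matrix not symmetric")
        object.__setattr__(self, "values", v)

    def align(self, ids: list[str]) -> "KinshipMatrix":
        pos = {iid: k for k, iid in enumerate(self.ids)}
        rows = np.array([pos[i] for i in ids])
        return KinshipMatrix(ids=list(ids), values=self.values[np.ix_(rows, rows)])


def _imputed_dosage(genotypes: PhasedGenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Dosage matrix with per-marker mean imputation of missing calls;
    also returns the allele-frequency vector p (of allele 2)."""
    dos = genotypes.dosage().astype(float)
    dos[dos < 0] = np.nan
    p = np.nanmean(dos, axis=0) / 2.0
    idx = np.where(np.isnan(dos))
    if idx[0].size:
        dos[idx] = 2.0 * p[idx[1]]
    return dos, p


def genomic_kinship(genotypes: PhasedGenotypeMatrix) -> KinshipMatrix:
    """Allele-frequency-standardized genomic relationship matrix:
    G_ij = mean_k (x_ik - 2p_k)(x_jk - 2p_k) / (2 p_k (1 - p_k)).

    Diagonal entries are ~1 + F; monomorphic markers carry no information
    and are excluded with a warning.
    """
    dos, p = _imputed_dosage(genotypes)
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(
            f"{int((~poly).sum())} monomorphic markers excluded from kinship",
            stacklevel=2,
        )
    dos, p = dos[:, poly], p[poly]
    if dos.shape[1] == 0:
        raise ValueError("no polymorphic markers for kinship")
    z = (dos - 2 * p) / np.sqrt(2 * p * (1 - p))
    g = (z @ z.T) / z.shape[1]
    g = (g + g.T) / 2.0
    return KinshipMatrix(ids=genotypes.ids, values=g)


# ---------------------------------------------------------------------
# polygenic model
# ---------------------------------------------------------------------


@dataclass
class PolygenicModel:
    """Eigen-rotated polygenic fit; carries everything the scan needs."""

    ids: list[str]
    h2: float
    sigma2: float  # total variance sg^2 + se^2
    mu: float
    eigvals: np.ndarray = field(repr=False)
    rot_y: np.ndarray = field(repr=False)  # U' y
    rot_one: np.ndarray = field(repr=False)  # U' 1
    eigvecs: np.ndarray = field(repr=False)
    residuals: pd.Series = field(repr=False, default=None)

    @property
    def weights(self) -> np.ndarray:
        """1 / Var of each rotated observation (up to sigma2)."""
        return 1.0 / (self.h2 * self.eigvals + (1.0 - self.h2))


def _reml_neg_loglik(h2: float, lam: np.ndarray, uy: np.ndarray, ux: np.ndarray) -> float:
    d = h2 * lam + (1.0 - h2)
    w = 1.0 / d
    xwx = np.sum(w * ux * ux)
    xwy = np.sum(w * ux * uy)
    mu = xwy / xwx
    r = uy - mu * ux
    rss = np.sum(w * r * r)
    n = lam.size
    sigma2 = rss / (n - 1)
    return 0.5 * (np.sum(np.log(d)) + (n - 1) * np.log(sigma2) + np.log(xwx))


def polygenic_fit(
    phenotypes: pd.Series, kinship: KinshipMatrix
) -> PolygenicModel:
    """REML estimate of the variance fraction attributable to genomic
    kinship, by one eigendecomposition plus 1-D likelihood optimization.
    Returns the fitted model with polygenic-adjusted residuals."""
    ids = list(phenotypes.index)
    k = kinship.align(ids)
    lam, u = np.linalg.eigh(k.values)
    if lam.min() < -1e-6:
        raise ValueError("kinship matrix has substantially negative eigenvalues")
    lam = np.clip(lam, 0.0, None)
    y = phenotypes.to_numpy(dtype=float)
    uy = u.T @ y
    ux = u.T @ np.ones_like(y)
    res = minimize_scalar(
        _reml_neg_loglik,
        bounds=(0.0, 1.0 - 1e-6),
        args=(lam, uy, ux),
        method="bounded",
        options={"xatol": 1e-8},
    )
    h2 = float(res.x)
    # edge refinement: the bounded optimizer never evaluates the exact ends
    for cand in (0.0,):
        if _reml_neg_loglik(cand, lam, uy, ux) < res.fun:
            h2 = cand
    d = h2 * lam + (1.0 - h2)
    w = 1.0 / d
    mu = np.sum(w * ux * uy) / np.sum(w * ux * ux)
    r = uy - mu * ux
    sigma2 = float(np.sum(w * r * r) / (len(y) - 1))
    # BLUP of the polygenic values, back-rotated
    g = u @ ((h2 * lam / d) * r)
    residuals = pd.Series(y - mu - g, index=ids, name="residual")
    return PolygenicModel(
        ids=ids,
        h2=h2,
        sigma2=sigma2,
        mu=float(mu),
        eigvals=lam,
        rot_y=uy,
        rot_one=ux,
        eigvecs=u,
        residuals=residuals,
    )


# ---------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------


@dataclass
class ScanResult:
    table: pd.DataFrame = field(repr=False)  # marker, chrom, bp, chi2, p, lod
    threshold_p: float | None = None

    def __post_init__(self) -> None:
        need = {"marker", "chrom", "bp", "chi2", "p", "lod"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"scan table lacks columns {need - set(self.table.columns)}")

    @property
    def top_marker(self) -> str:
        return str(self.table.loc[self.table["lod"].idxmax(), "marker"])

    def restrict_chrom(self, chrom: str) -> "ScanResult":
        return ScanResult(
            self.table.loc[self.table["chrom"] == chrom].reset_index(drop=True),
            threshold_p=self.threshold_p,
        )


def _chi2_p_lod(chi2: np.ndarray, df: int | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """p and LOD = log10(1/p) computed through the log survival function
    so that LOD survives p-value underflow."""
    logsf = stats.chi2.logsf(chi2, df)
    p = np.exp(logsf)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    lod = np.maximum(-logsf / _LN10, 0.0)
    return p, lod


def single_locus_scan(
    genotypes: PhasedGenotypeMatrix,
    phenotypes: pd.Series,
    kinship: KinshipMatrix | None = None,
    model: PolygenicModel | None = None,
) -> ScanResult:
    """Per-marker 1-df mixed-model association test of the additively
    coded dosage.  With ``model`` (or ``kinship``) given, the test is GLS
    in the polygenic eigenbasis; with neither, ordinary least squares.
    """
    ids = list(phenotypes.index)
    g = genotypes.take_individuals(ids)
    dos, _ = _imputed_dosage(g)
    n, m = dos.shape
    if model is None:
        if kinship is None:
            lam = np.ones(n)
            u = np.eye(n)
            y = phenotypes.to_numpy(dtype=float)
            model = PolygenicModel(
                ids=ids, h2=0.0, sigma2=float(np.var(y)), mu=float(np.mean(y)),
                eigvals=lam, rot_y=y.copy(), rot_one=np.ones(n), eigvecs=u,
                residuals=phenotypes - np.mean(y),
            )
            ux_all = dos
        else:
            model = polygenic_fit(phenotypes, kinship)
            ux_all = model.eigvecs.T @ dos
    else:
        if model.ids != ids:
            raise ValueError("polygenic model fitted on different individuals")
        ux_all = model.eigvecs.T @ dos
    w = model.weights
    uy = model.rot_y
    u1 = model.rot_one
    s11 = np.sum(w * u1 * u1)
    s1y = np.sum(w * uy * u1)
    syy = np.sum(w * uy * uy)
    s1x = (w * u1) @ ux_all
    sxy = (w * uy) @ ux_all
    sxx = np.einsum("i,ij,ij->j", w, ux_all, ux_all)
    sxx_c = sxx - s1x**2 / s11
    sxy_c = sxy - s1x * s1y / s11
    syy_c = syy - s1y**2 / s11
    chi2 = np.zeros(m)
    ok = sxx_c > 1e-12
    beta = np.where(ok, sxy_c / np.where(ok, sxx_c, 1.0), 0.0)
    rss = np.maximum(syy_c - beta**2 * sxx_c, 1e-300)
    sigma2 = rss / (n - 2)
    chi2[ok] = (beta[ok] ** 2) * sxx_c[ok] / sigma2[ok]
    p, lod = _chi2_p_lod(chi2, 1)
    p[~ok] = 1.0
    lod[~ok] = 0.0
    mm = g.markers
    table = pd.DataFrame(
        {
            "marker": mm.names,
            "chrom": mm.chroms,
            "bp": mm.bp,
            "chi2": chi2,
            "p": p,
            "lod": lod,
        }
    )
    return ScanResult(table)


def genomic_control_lambda(scan: ScanResult) -> float:
    """Median chi-square over its null expectation 0.4549."""
    return float(np.median(scan.table["chi2"]) / stats.chi2.ppf(0.5, 1))


def bonferroni_threshold(alpha: float, n_informative: int) -> float:
    """Genome-wide significance threshold alpha / N for N informative SNPs."""
    if n_informative < 1:
        raise ValueError("need at least one informative SNP")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_informative


# ---------------------------------------------------------------------
# meta-analysis
# ---------------------------------------------------------------------


def meta_combine(scans: list[ScanResult]) -> ScanResult:
    """Sum per-marker chi-square statistics across population scans; the
    meta statistic for a marker present in k scans is referred to
    chi-square(k).  Markers are matched by name."""
    if len(scans) < 1:
        raise ValueError("need at least one scan")
    if len(scans) == 1:
        return scans[0]
    frames = [s.table.set_index("marker") for s in scans]
    shared = set(frames[0].index)
    for f in frames[1:]:
        shared |= set(f.index)
    if not set.intersection(*[set(f.index) for f in frames]):
        raise ValueError("scans share no markers")
    all_markers = sorted(shared)
    chi2 = pd.Series(0.0, index=all_markers)
    df = pd.Series(0, index=all_markers)
    pos = {}
    for f in frames:
        chi2 = chi2.add(f["chi2"], fill_value=0.0)
        df = df.add(pd.Series(1, index=f.index), fill_value=0)
        for mk, row in f.iterrows():
            pos[mk] = (row["chrom"], row["bp"])
    p, lod = _chi2_p_lod(chi2.to_numpy(), df.to_numpy().astype(int))
    table = pd.DataFrame(
        {
            "marker": all_markers,
            "chrom": [pos[mk][0] for mk in all_markers],
            "bp": [int(pos[mk][1]) for mk in all_markers],
            "chi2": chi2.to_numpy(),
            "df": df.to_numpy().astype(int),
            "p": p,
            "lod": lod,
        }
    ).sort_values(["chrom", "bp"], kind="stable").reset_index(drop=True)
    return ScanResult(table)


# ---------------------------------------------------------------------
# support intervals
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class ConfidenceInterval:
    chrom: str
    start_bp: int
    end_bp: int
    top_marker: str | None = None
    lod_drop: float | None = None

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("interval start exceeds end")

    @property
    def width_bp(self) -> int:
        return self.end_bp - self.start_bp

    def contains(self, bp: int) -> bool:
        return self.start_bp <= bp <= self.end_bp


def lod_drop_interval(scan: ScanResult, drop: float = 2.0) -> ConfidenceInterval:
    """Support interval: the span of every marker whose LOD is within
    ``drop`` of the peak.  The scan must be restricted to a single
    chromosome.

    Using the full set rather than only the run contiguous with the peak
    keeps the interval meaningful on panels where marker informativeness
    varies sharply (an uninformative marker right beside the peak would
    otherwise truncate the interval to a point).
    """
    t = scan.table
    if len(t) == 0:
        raise ValueError("empty scan")
    chroms = t["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("scan spans several chromosomes; restrict first")
    t = t.sort_values("bp", kind="stable").reset_index(drop=True)
    lod = t["lod"].to_numpy()
    peak = int(np.argmax(lod))
    cut = lod[peak] - drop
    inside = np.flatnonzero(lod >= cut)
    left, right = int(inside[0]), int(inside[-1])
    return ConfidenceInterval(
        chrom=str(chroms[0]),
        start_bp=int(t.loc[left, "bp"]),
        end_bp=int(t.loc[right, "bp"]),
        top_marker=str(t.loc[peak, "marker"]),
        lod_drop=drop,
    )


def intersect_intervals(intervals: list[ConfidenceInterval]) -> ConfidenceInterval:
    """Closed-interval intersection [max start, min end]; raises naming
    the first disjoint pair encountered."""
    if not intervals:
        raise ValueError("no intervals to intersect")
    chrom = intervals[0].chrom
    for iv in intervals[1:]:
        if iv.chrom != chrom:
            raise ValueError(f"intervals on different chromosomes: {chrom} vs {iv.chrom}")
    cur = intervals[0]
    for iv in intervals[1:]:
        start = max(cur.start_bp, iv.start_bp)
        end = min(cur.end_bp, iv.end_bp)
        if start > end:
            raise ValueError(
                f"disjoint intervals: [{cur.start_bp}, {cur.end_bp}] and "
                f"[{iv.start_bp}, {iv.end_bp}]"
            )
        cur = ConfidenceInterval(chrom=chrom, start_bp=start, end_bp=end)
    return cur
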