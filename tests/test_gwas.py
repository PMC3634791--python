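"""Mixed-model scan machinery: kinship, REML, per-marker tests,
meta-analysis and interval logic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.integrate import quad

from vertfine.gwas import (
    ConfidenceInterval,
    ScanResult,
    bonferroni_threshold,
    genomic_control_lambda,
    genomic_kinship,
    intersect_intervals,
    lod_drop_interval,
    meta_combine,
    polygenic_fit,
    single_locus_scan,
)
from vertfine.gwas import _reml_neg_loglik
from vertfine.markers import MarkerMap
from vertfine.pedigree import Pedigree
from vertfine.simulate import drop_gametes, simulate_founders


def _random_map(m, chrom="1"):
    return MarkerMap.from_positions(
        [f"m{i}" for i in range(m)], [chrom] * m, list(range(1, m + 1))
    )


def _unrelated(n, m, seed=0):
    return simulate_founders(_random_map(m), {"P": n}, maf_range=(0.1, 0.5), seed=seed)


class TestKinship:
    def test_duplicated_individual_matches_self_entry(self):
        g = _unrelated(30, 500, seed=0)
        g.alleles[1] = g.alleles[0]  # animal 1 is a copy of animal 0
        k = genomic_kinship(g).values
        assert k[0, 1] == pytest.approx(max(k[0, 0], k[1, 1]), abs=1e-9)

    def test_unrelated_mean_off_diagonal_near_zero(self):
        n, m = 100, 2000
        k = genomic_kinship(_unrelated(n, m, seed=1)).values
        off = k[np.triu_indices(n, 1)]
        # a single pair has sampling SE ~ 1/sqrt(m); the grand mean is tighter
        assert abs(off.mean()) < 3 / math.sqrt(m)

    def test_full_sibs_near_half(self):
        # 100 couples, two offspring each: 200 sib pairs around 0.5
        mm = _random_map(1500)
        records = []
        for c in range(100):
            records += [
                (f"s{c}", None, None, "M", "F0", "P"),
                (f"d{c}", None, None, "F", "F0", "P"),
                (f"a{c}", f"s{c}", f"d{c}", "M", "F1", "P"),
                (f"b{c}", f"s{c}", f"d{c}", "F", "F1", "P"),
            ]
        ped = Pedigree(pd.DataFrame(records, columns=["id", "sire", "dam", "sex", "generation", "population"]))
        founders = simulate_founders(
            mm, {"P": 200}, seed=2,
            ids_per_population={"P": [f"{x}{c}" for c in range(100) for x in "sd"]},
        )
        g = drop_gametes(founders, ped, seed=2)
        k = genomic_kinship(g)
        pos = {iid: i for i, iid in enumerate(k.ids)}
        rel = [k.values[pos[f"a{c}"], pos[f"b{c}"]] for c in range(100)]
        assert abs(np.mean(rel) - 0.5) < 0.05

    def test_marker_order_invariance(self):
        from vertfine.genotypes import PhasedGenotypeMatrix

        g = _unrelated(20, 100, seed=3)
        k1 = genomic_kinship(g).values
        perm = np.random.default_rng(0).permutation(100)
        shuffled = PhasedGenotypeMatrix(
            ids=g.ids, markers=_random_map(100), alleles=g.alleles[:, perm, :]
        )
        k2 = genomic_kinship(shuffled).values
        assert np.allclose(k1, k2, atol=1e-12)


def _structured_kinship(n=300, seed=0):
    """GRM of a half-sib population (genuine family structure)."""
    from vertfine.designs import halfsib_pedigree

    mm = _random_map(800)
    sires = [f"S{i}" for i in range(6)]
    dams = [f"D{i}" for i in range(60)]
    ped = halfsib_pedigree(sires, dams, n, "H", "P")
    founders = simulate_founders(
        mm, {"P": 66}, seed=seed, ids_per_population={"P": sires + dams}
    )
    g = drop_gametes(founders, ped, seed=seed)
    off = [i for i in g.ids if i.startswith("H_O_")]
    return genomic_kinship(g.take_individuals(off))


@pytest.fixture(scope="module")
def kin():
    return _structured_kinship()


class TestPolygenicFit:
    def _draw(self, kin, h2, sigma2, rng):
        lam, u = np.linalg.eigh(kin.values)
        lam = np.clip(lam, 0, None)
        z = rng.standard_normal(len(lam))
        y = u @ (np.sqrt(sigma2 * (h2 * lam + 1 - h2)) * z)
        return pd.Series(y + 14.0, index=kin.ids)

    def test_null_heritability_recovered(self, kin):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(50):
            fit = polygenic_fit(self._draw(kin, 0.0, 1.0, rng), kin)
            hits += fit.h2 < 0.1
        assert hits >= 45

    def test_moderate_heritability_recovered(self, kin):
        rng = np.random.default_rng(1)
        est = [polygenic_fit(self._draw(kin, 0.6, 1.0, rng), kin).h2 for _ in range(50)]
        assert abs(np.mean(est) - 0.6) < 0.1

    def test_reml_beats_grid(self, kin):
        rng = np.random.default_rng(2)
        y = self._draw(kin, 0.4, 1.0, rng)
        fit = polygenic_fit(y, kin)
        lam, u = np.linalg.eigh(kin.values)
        lam = np.clip(lam, 0, None)
        uy, ux = u.T @ y.to_numpy(), u.T @ np.ones(len(y))
        best = _reml_neg_loglik(fit.h2, lam, uy, ux)
        for h2 in np.linspace(0, 0.99, 101):
            assert best <= _reml_neg_loglik(h2, lam, uy, ux) + 1e-6


class TestScan:
    def test_h2_zero_equals_ols(self):
        import statsmodels.api as sm

        g = _unrelated(80, 60, seed=4)
        rng = np.random.default_rng(4)
        y = pd.Series(rng.normal(14, 1, 80), index=g.ids)
        scan = single_locus_scan(g, y)  # no kinship: OLS path
        dos = g.dosage().astype(float)
        for j in [0, 17, 59]:
            x = sm.add_constant(dos[:, j])
            t = sm.OLS(y.to_numpy(), x).fit().tvalues[1]
            assert scan.table.loc[j, "chi2"] == pytest.approx(t**2, abs=1e-6)

    def test_monomorphic_marker_null_result(self):
        g = _unrelated(50, 20, seed=5)
        g.alleles[:, 7, :] = 1
        rng = np.random.default_rng(5)
        y = pd.Series(rng.normal(14, 1, 50), index=g.ids)
        scan = single_locus_scan(g, y)
        assert scan.table.loc[7, "chi2"] == 0.0
        assert scan.table.loc[7, "p"] == 1.0

    def test_null_type_one_error_calibrated(self):
        g = _unrelated(300, 1500, seed=6)
        rng = np.random.default_rng(6)
        y = pd.Series(rng.normal(14, 1, 300), index=g.ids)
        scan = single_locus_scan(g, y, kinship=genomic_kinship(g))
        frac = (scan.table["p"] < 0.05).mean()
        se = math.sqrt(0.05 * 0.95 / 1500)
        assert abs(frac - 0.05) < 4 * se

    def test_lod_matches_p(self):
        g = _unrelated(60, 30, seed=7)
        rng = np.random.default_rng(7)
        y = pd.Series(rng.normal(0, 1, 60), index=g.ids)
        t = single_locus_scan(g, y).table
        assert np.allclose(t["lod"], -np.log10(t["p"]), atol=1e-9)
        assert (t["p"] > 0).all() and (t["p"] <= 1).all()


class TestBonferroni:
    def test_printed_informative_counts_clear_plot_threshold(self):
        # each published informative-SNP count puts -log10(0.05/N) above 5
        for n in (39448, 43760, 20509):
            assert -math.log10(bonferroni_threshold(0.05, n)) > 5

    def test_division(self):
        assert bonferroni_threshold(0.05, 39448) == pytest.approx(0.05 / 39448, rel=1e-12)

    def test_single_test(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


def _scan_from(chi2s, chrom="1"):
    chi2s = np.asarray(chi2s, dtype=float)
    logsf = stats.chi2.logsf(chi2s, 1)
    return ScanResult(
        pd.DataFrame(
            {
                "marker": [f"m{i}" for i in range(len(chi2s))],
                "chrom": chrom,
                "bp": np.arange(1, len(chi2s) + 1) * 1000000,
                "chi2": chi2s,
                "p": np.exp(logsf),
                "lod": -logsf / math.log(10),
            }
        )
    )


class TestMeta:
    def test_sum_of_three(self):
        scans = [_scan_from([4.0]), _scan_from([5.0]), _scan_from([6.0])]
        meta = meta_combine(scans)
        assert meta.table.loc[0, "chi2"] == 15.0
        assert meta.table.loc[0, "df"] == 3

    def test_single_scan_identity(self):
        s = _scan_from([1.0, 2.0, 3.0])
        assert meta_combine([s]) is s

    def test_p_value_matches_quadrature(self):
        meta = meta_combine([_scan_from([10.0])] * 3)
        # numerically integrate the chi-square(3) density above 30
        integral, _ = quad(lambda x: stats.chi2.pdf(x, 3), 30, np.inf)
        assert meta.table.loc[0, "p"] == pytest.approx(integral, rel=1e-8)

    def test_meta_statistic_dominates_components(self):
        rng = np.random.default_rng(8)
        scans = [_scan_from(rng.chisquare(1, 50)) for _ in range(3)]
        meta = meta_combine(scans).table.set_index("marker")
        for s in scans:
            for _, row in s.table.iterrows():
                assert meta.loc[row["marker"], "chi2"] >= row["chi2"] - 1e-12

    def test_no_shared_markers_rejected(self):
        a = _scan_from([1.0])
        b = _scan_from([1.0])
        b.table["marker"] = ["other"]
        with pytest.raises(ValueError):
            meta_combine([a, b])


class TestLodDrop:
    def test_hand_checked_example(self):
        scan = _scan_from([0] * 6)
        scan.table["lod"] = [1, 3, 6, 5, 3, 1]
        iv = lod_drop_interval(scan, drop=2)
        assert (iv.start_bp, iv.end_bp) == (3000000, 4000000)
        assert iv.top_marker == "m2"

    def test_single_marker(self):
        iv = lod_drop_interval(_scan_from([9.0]), drop=2)
        assert iv.start_bp == iv.end_bp == 1000000

    def test_flat_scan_spans_chromosome(self):
        scan = _scan_from([5.0] * 8)
        iv = lod_drop_interval(scan, drop=2)
        assert (iv.start_bp, iv.end_bp) == (1000000, 8000000)

    def test_multi_chromosome_rejected(self):
        scan = _scan_from([1.0, 2.0])
        scan.table.loc[1, "chrom"] = "2"
        with pytest.raises(ValueError):
            lod_drop_interval(scan)


class TestIntersect:
    def test_published_three_interval_overlap(self):
        ivs = [
            ConfidenceInterval("7", 101_860_000, 105_750_000),
            ConfidenceInterval("7", 102_460_000, 104_310_000),
            ConfidenceInterval("7", 103_370_000, 117_040_000),
        ]
        out = intersect_intervals(ivs)
        assert (out.start_bp, out.end_bp) == (103_370_000, 104_310_000)

    def test_single_interval_identity(self):
        iv = ConfidenceInterval("7", 5, 9)
        out = intersect_intervals([iv])
        assert (out.start_bp, out.end_bp) == (5, 9)

    def test_disjoint_pair_named(self):
        with pytest.raises(ValueError, match="disjoint"):
            intersect_intervals(
                [ConfidenceInterval("7", 1, 2), ConfidenceInterval("7", 5, 6)]
            )

    @given(
        st.lists(
            st.tuples(st.integers(0, 1000), st.integers(0, 1000)).map(
                lambda t: ConfidenceInterval("7", min(t), max(t))
            ),
            min_size=1,
            max_size=5,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_intersection_algebra(self, intervals):
        try:
            out = intersect_intervals(intervals)
        except ValueError:
            # disjointness must be confirmed by the grid oracle
            grid = set(range(0, 1001))
            for iv in intervals:
                grid &= set(range(iv.start_bp, iv.end_bp + 1))
            assert not grid
            return
        # commutativity
        rev = intersect_intervals(intervals[::-1])
        assert (out.start_bp, out.end_bp) == (rev.start_bp, rev.end_bp)
        # containment in every input, verified against a grid oracle
        for iv in intervals:
            assert iv.start_bp <= out.start_bp and out.end_bp <= iv.end_bp
        grid = set(range(0, 1001))
        for iv in intervals:
            grid &= set(range(iv.start_bp, iv.end_bp + 1))
        assert grid == set(range(out.start_bp, out.end_bp + 1))


class TestCalibrationLambda:
    def test_null_lambda_near_one(self):
        g = _unrelated(500, 2000, seed=9)
        rng = np.random.default_rng(9)
        y = pd.Series(rng.normal(14.5, 0.8, 500), index=g.ids)
        scan = single_locus_scan(g, y, kinship=genomic_kinship(g))
        assert abs(genomic_control_lambda(scan) - 1.0) <= 0.1
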