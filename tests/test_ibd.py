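"""Pedigree phasing and Q-haplotype sharing."""

import numpy as np
import pandas as pd
import pytest

from vertfine.genotypes import MISSING, PhasedGenotypeMatrix
from vertfine.ibd import (
    QBearingSet,
    annotate_region,
    collect_q_haplotypes,
    pedigree_phase,
    shared_region,
)
from vertfine.markers import MarkerMap
from vertfine.pedigree import Pedigree
from vertfine.segregation import QTLGenotypeCall, QTLState
from vertfine.simulate import drop_gametes, simulate_founders, simulate_q_descendants

from conftest import matrix_from_haplotypes


class TestPedigreePhase:
    def test_forced_trio_assignment(self, trio_pedigree):
        mm = MarkerMap.from_positions(["m0"], ["1"], [100])
        g = matrix_from_haplotypes(
            {"sire": ([1], [1]), "dam": ([2], [2]), "kid": ([2], [1])}, mm
        )
        phased, n_err = pedigree_phase(g, trio_pedigree)
        k = phased.row("kid")
        assert n_err == 0
        assert phased.alleles[k, 0, 0] == 1  # paternal = sire's homozygous allele
        assert phased.alleles[k, 0, 1] == 2
        assert phased.phase_known[k, 0]

    def test_all_heterozygous_unresolved(self, trio_pedigree):
        mm = MarkerMap.from_positions(["m0"], ["1"], [100])
        g = matrix_from_haplotypes(
            {"sire": ([1], [2]), "dam": ([1], [2]), "kid": ([1], [2])}, mm
        )
        phased, _ = pedigree_phase(g, trio_pedigree)
        assert not phased.phase_known[phased.row("kid"), 0]

    def test_mendelian_clash_blanked(self, trio_pedigree):
        mm = MarkerMap.from_positions(["m0"], ["1"], [100])
        g = matrix_from_haplotypes(
            {"sire": ([1], [1]), "dam": ([1], [1]), "kid": ([2], [2])}, mm
        )
        phased, n_err = pedigree_phase(g, trio_pedigree)
        assert n_err == 1
        assert (phased.alleles[phased.row("kid"), 0] == MISSING).all()

    def test_simulated_truth_recovery(self):
        mm = MarkerMap.from_positions(
            [f"m{i}" for i in range(300)], ["1"] * 300, [int(1e5 * (i + 1)) for i in range(300)]
        )
        records = [
            ("s", None, None, "M", "F0", "P"),
            ("d", None, None, "F", "F0", "P"),
        ] + [(f"k{i}", "s", "d", "M", "F1", "P") for i in range(40)]
        ped = Pedigree.from_records(records)
        founders = simulate_founders(
            mm, {"P": 2}, seed=0, ids_per_population={"P": ["s", "d"]}
        )
        truth = drop_gametes(founders, ped, seed=0)
        phased, _ = pedigree_phase(truth, ped)
        checked = 0
        agree = 0
        for i, iid in enumerate(truth.ids):
            if iid in ("s", "d"):
                continue
            het = truth.alleles[i, :, 0] != truth.alleles[i, :, 1]
            resolved = phased.phase_known[i] & het
            checked += int(resolved.sum())
            agree += int(
                (phased.alleles[i, resolved, 0] == truth.alleles[i, resolved, 0]).sum()
            )
        assert checked > 1000
        assert agree / checked >= 0.99


class TestCollect:
    def test_het_call_contributes_one(self):
        calls = [QTLGenotypeCall("a", QTLState.HET, ("Q", "q"))]
        assert collect_q_haplotypes(calls).entries == [("a", 0)]

    def test_resolved_homozygote_contributes_both(self):
        calls = [QTLGenotypeCall("a", QTLState.HOM, ("Q", "Q"))]
        assert collect_q_haplotypes(calls).entries == [("a", 0), ("a", 1)]

    def test_unknowns_excluded_and_empty_rejected(self):
        calls = [QTLGenotypeCall("a", QTLState.UNKNOWN, ("unknown", "unknown"))]
        with pytest.raises(ValueError):
            collect_q_haplotypes(calls)


def brute_force_shared(haps: np.ndarray, anchor: int) -> tuple[int, int]:
    """Exhaustive-interval oracle: widest [l, r] containing the anchor
    with all haplotypes identical at every inside marker."""
    k, m = haps.shape
    best = (anchor, anchor)
    for l in range(m):
        for r in range(l, m):
            if not (l <= anchor <= r):
                continue
            ok = all(
                len({h[j] for h in haps if h[j] != 0}) <= 1 for j in range(l, r + 1)
            )
            if ok and (r - l) > (best[1] - best[0]):
                best = (l, r)
    return best


def _mm(m):
    return MarkerMap.from_positions(
        [f"m{i}" for i in range(m)], ["7"] * m, [int(1e6 * (i + 1)) for i in range(m)]
    )


def _matrix_from_rows(rows: np.ndarray, mm: MarkerMap) -> PhasedGenotypeMatrix:
    """One individual per haplotype row; haplotype 0 carries the row."""
    n, m = rows.shape
    a = np.stack([rows, rows], axis=2).astype(np.int8)
    return PhasedGenotypeMatrix(ids=[f"h{i}" for i in range(n)], markers=mm, alleles=a)


class TestSharedRegion:
    def test_single_haplotype_spans_chromosome(self):
        mm = _mm(10)
        rows = np.ones((1, 10), dtype=np.int8)
        g = _matrix_from_rows(rows, mm)
        seg = shared_region(QBearingSet([("h0", 0)]), g, "7", int(5e6))
        assert (seg.start_bp, seg.end_bp) == (int(1e6), int(10e6))
        assert seg.flank_left is None and seg.flank_right is None

    def test_constructed_discordances(self):
        mm = _mm(10)
        rows = np.ones((3, 10), dtype=np.int8)
        rows[0, 3] = 2  # discordance at marker index 3
        rows[1, 8] = 2  # and at marker index 8
        g = _matrix_from_rows(rows, mm)
        seg = shared_region(QBearingSet([(f"h{i}", 0) for i in range(3)]), g, "7", int(6e6))
        assert (seg.start_bp, seg.end_bp) == (int(5e6), int(8e6))
        assert seg.flank_left == "m3" and seg.flank_right == "m8"
        l, r = brute_force_shared(rows, 5)
        assert (mm.bp[l], mm.bp[r]) == (seg.start_bp, seg.end_bp)

    def test_random_instances_match_exhaustive_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(150):
            m = int(rng.integers(3, 13))
            k = int(rng.integers(2, 6))
            rows = rng.integers(1, 3, size=(k, m)).astype(np.int8)
            anchor = int(rng.integers(m))
            rows[:, anchor] = 1  # keep the anchor concordant
            g = _matrix_from_rows(rows, _mm(m))
            seg = shared_region(
                QBearingSet([(f"h{i}", 0) for i in range(k)]), g, "7",
                int(1e6 * (anchor + 1)),
            )
            l, r = brute_force_shared(rows, anchor)
            assert (seg.start_bp, seg.end_bp) == (int(1e6 * (l + 1)), int(1e6 * (r + 1)))

    def test_soundness_and_maximality(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            m = 20
            rows = rng.integers(1, 3, size=(4, m)).astype(np.int8)
            rows[:, 10] = 2
            g = _matrix_from_rows(rows, _mm(m))
            seg = shared_region(QBearingSet([(f"h{i}", 0) for i in range(4)]), g, "7", int(11e6))
            idx = [g.markers.index_of(n) for n in seg.marker_names]
            for j in idx:
                assert len(set(rows[:, j])) == 1
            if seg.flank_left is not None:
                jl = g.markers.index_of(seg.flank_left)
                assert len(set(rows[:, jl])) > 1
            if seg.flank_right is not None:
                jr = g.markers.index_of(seg.flank_right)
                assert len(set(rows[:, jr])) > 1

    def test_adding_haplotype_never_widens(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            m = 15
            rows = rng.integers(1, 3, size=(5, m)).astype(np.int8)
            rows[:, 7] = 1
            g = _matrix_from_rows(rows, _mm(m))
            seg4 = shared_region(QBearingSet([(f"h{i}", 0) for i in range(4)]), g, "7", int(8e6))
            seg5 = shared_region(QBearingSet([(f"h{i}", 0) for i in range(5)]), g, "7", int(8e6))
            assert seg5.start_bp >= seg4.start_bp
            assert seg5.end_bp <= seg4.end_bp

    def test_discordant_anchor_is_explicit(self):
        mm = _mm(5)
        rows = np.ones((2, 5), dtype=np.int8)
        rows[0, 2] = 2
        g = _matrix_from_rows(rows, mm)
        with pytest.raises(ValueError, match="anchor"):
            shared_region(QBearingSet([("h0", 0), ("h1", 0)]), g, "7", int(3e6))

    def test_missing_alleles_are_wildcards(self):
        mm = _mm(5)
        rows = np.ones((2, 5), dtype=np.int8)
        rows[0, 1] = 0  # missing, not discordant
        g = _matrix_from_rows(rows, mm)
        seg = shared_region(QBearingSet([("h0", 0), ("h1", 0)]), g, "7", int(3e6))
        assert (seg.start_bp, seg.end_bp) == (int(1e6), int(5e6))
        assert seg.n_wildcard == 1

    def test_true_qtl_covered_in_descendant_simulations(self):
        mm = MarkerMap.from_positions(
            [f"m{i}" for i in range(400)], ["7"] * 400,
            [int(2.5e5 * (i + 1)) for i in range(400)],
        )
        anchor_bp = int(5e7)
        hits = 0
        runs = 100
        for seed in range(runs):
            haps, _ = simulate_q_descendants(
                mm, "7", anchor_bp, n_haplotypes=22, n_meioses=8, seed=seed
            )
            g = _matrix_from_rows(haps, mm)
            seg = shared_region(
                QBearingSet([(f"h{i}", 0) for i in range(22)]), g, "7", anchor_bp
            )
            hits += seg.contains(anchor_bp)
        assert hits / runs >= 0.95

    def test_densified_map_never_widens(self):
        # adding the hidden dense variants can only keep or shrink the region
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = 30
            rows = rng.integers(1, 3, size=(6, m)).astype(np.int8)
            rows[:, 15] = 1
            g = _matrix_from_rows(rows, _mm(m))
            coarse_idx = np.arange(0, m, 2)
            if 15 not in coarse_idx:
                coarse_idx = np.sort(np.append(coarse_idx, 15))
            g_coarse = g.take_markers(coarse_idx)
            qset_c = QBearingSet([(f"h{i}", 0) for i in range(6)])
            seg_c = shared_region(qset_c, g_coarse, "7", int(16e6))
            seg_f = shared_region(qset_c, g, "7", int(16e6))
            assert seg_f.start_bp >= seg_c.start_bp
            assert seg_f.end_bp <= seg_c.end_bp


class TestAnnotate:
    def _segment(self):
        from vertfine.ibd import SharedSegment

        return SharedSegment("7", 100, 200, None, None, 3, 5)

    def test_gene_inside_included(self):
        genes = pd.DataFrame(
            [("7", 120, 180, "G1")], columns=["chrom", "start", "end", "name"]
        )
        assert annotate_region(self._segment(), genes) == ["G1"]

    def test_abutting_gene_excluded(self):
        genes = pd.DataFrame(
            [("7", 30, 99, "G1"), ("7", 201, 300, "G2")],
            columns=["chrom", "start", "end", "name"],
        )
        assert annotate_region(self._segment(), genes) == []

    def test_six_gene_fixture_linear_scan_oracle(self):
        rows = [
            ("7", 10, 50, "A"),
            ("7", 90, 110, "B"),   # overlaps on the left edge
            ("7", 150, 160, "C"),  # inside
            ("7", 250, 260, "D"),
            ("1", 100, 200, "E"),  # wrong chromosome
            ("7", 200, 240, "F"),  # overlaps on the right edge
        ]
        genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        seg = self._segment()
        got = set(annotate_region(seg, genes))
        oracle = {
            n for c, s, e, n in rows if c == "7" and s <= seg.end_bp and e >= seg.start_bp
        }
        assert got == oracle == {"B", "C", "F"}
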