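"""Progeny testing: haplotype grouping, the Z likelihood ratio, the
classification rule and founder propagation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from vertfine.markers import MarkerMap
from vertfine.pedigree import Pedigree
from vertfine.segregation import (
    MendelianInconsistencyError,
    QTLState,
    SireProgenyGroups,
    classify_sire,
    founder_call,
    resolve_homozygote,
    split_progeny,
    zscore_fixed_effect,
    zscore_segregation,
)
from vertfine.simulate import (
    QTLSpec,
    TraitModel,
    drop_gametes,
    insert_qtl,
    plant_qtl,
    simulate_founders,
    simulate_phenotypes,
    simulate_progeny_groups,
)


def numerical_mle_oracle(left, right):
    """Maximize both Gaussian likelihoods numerically and return the
    log10 ratio (independent of the closed form)."""
    left = np.asarray(left, float)
    right = np.asarray(right, float)
    y = np.concatenate([left, right])

    def negll_het(params):
        m1, m2, logs = params
        s2 = math.exp(2 * logs)
        ss = np.sum((left - m1) ** 2) + np.sum((right - m2) ** 2)
        return 0.5 * len(y) * math.log(2 * math.pi * s2) + ss / (2 * s2)

    def negll_hom(params):
        m, logs = params
        s2 = math.exp(2 * logs)
        return 0.5 * len(y) * math.log(2 * math.pi * s2) + np.sum((y - m) ** 2) / (2 * s2)

    r1 = minimize(
        negll_het, [left.mean(), right.mean(), math.log(y.std() + 0.1)], method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000},
    )
    r0 = minimize(
        negll_hom, [y.mean(), math.log(y.std() + 0.1)], method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000},
    )
    return (r0.fun - r1.fun) / math.log(10)


def groups_of(left, right):
    return SireProgenyGroups("s", np.asarray(left, float), np.asarray(right, float))


class TestZScore:
    def test_identical_group_means_zero(self):
        z = zscore_segregation(groups_of([15, 14, 15, 14], [14, 15, 14, 15]))
        assert z.z == pytest.approx(0.0, abs=1e-12)

    def test_matches_numerical_mle(self):
        got = zscore_segregation(groups_of([16, 16, 15, 15], [14, 14, 15, 15])).z
        want = numerical_mle_oracle([16, 16, 15, 15], [14, 14, 15, 15])
        assert got == pytest.approx(want, abs=1e-9)

    def test_label_exchange_symmetry(self):
        a, b = [16.0, 15, 15, 16], [14.0, 15, 14, 14]
        assert zscore_segregation(groups_of(a, b)).z == pytest.approx(
            zscore_segregation(groups_of(b, a)).z, abs=1e-12
        )

    def test_monotone_in_mean_difference(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 30)
        zs = []
        for shift in (0.0, 0.3, 0.6, 1.0, 1.5):
            zs.append(zscore_segregation(groups_of(base + shift, base)).z)
        assert all(b > a for a, b in zip(zs, zs[1:]))

    def test_oracle_equivalence_many_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            nl, nr = rng.integers(3, 25, size=2)
            left = rng.normal(15, 0.7, nl)
            right = rng.normal(15 - rng.uniform(0, 1), 0.7, nr)
            got = zscore_segregation(groups_of(left, right)).z
            want = numerical_mle_oracle(left, right)
            assert got == pytest.approx(want, abs=1e-7)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            zscore_segregation(groups_of([15, 15], [15, 15]))

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            zscore_segregation(groups_of([15], [14, 15]))


class TestZScoreFixedEffect:
    def test_sign_discriminates_het_from_hom(self):
        rng = np.random.default_rng(2)
        het = groups_of(rng.normal(15.0, 0.5, 80), rng.normal(14.5, 0.5, 80))
        hom = groups_of(rng.normal(14.5, 0.5, 80), rng.normal(14.5, 0.5, 80))
        assert zscore_fixed_effect(het, 0.5).z > 2
        assert zscore_fixed_effect(hom, 0.5).z < -2

    def test_symmetry(self):
        a, b = [16.0, 15, 15, 16], [14.0, 15, 14, 14]
        assert zscore_fixed_effect(groups_of(a, b)).z == pytest.approx(
            zscore_fixed_effect(groups_of(b, a)).z, abs=1e-12
        )

    def test_table_scale_magnitudes(self):
        # progeny summaries like the study's strongest sire give Z >> 2
        rng = np.random.default_rng(3)
        g = groups_of(rng.normal(15.33, 0.5, 79), rng.normal(14.50, 0.6, 78))
        assert zscore_fixed_effect(g, 0.5).z > 8


class TestClassification:
    @pytest.mark.parametrize(
        "z,expected",
        [
            (13.46, QTLState.HET),   # strongest printed heterozygote
            (-4.04, QTLState.HOM),   # clearest printed homozygote
            (2.05, QTLState.HET),    # boundary heterozygote in the tables
            (-2.08, QTLState.HOM),
            (1.99, QTLState.UNKNOWN),
            (-2.0, QTLState.UNKNOWN),
        ],
    )
    def test_threshold_rule(self, z, expected):
        from vertfine.segregation import ZScoreResult

        res = ZScoreResult(z=z, mean_left=15.0, mean_right=14.5, n_left=50, n_right=50)
        assert classify_sire("s", res).state == expected

    def test_q_assigned_to_higher_mean_group(self):
        from vertfine.segregation import ZScoreResult

        res = ZScoreResult(z=5.0, mean_left=14.4, mean_right=15.2, n_left=40, n_right=40)
        call = classify_sire("s", res)
        assert call.hap_orientation == ("q", "Q")

    def test_power_and_size_of_rule(self):
        # heterozygous sires with ample progeny are nearly always caught;
        # homozygous sires essentially never miscalled heterozygous
        trait = TraitModel(mu=14.5, a=0.5, h2_poly=0.0, sigma_e=0.6)
        rng = np.random.default_rng(4)
        n_runs = 500
        het_correct = 0
        hom_miscalled = 0
        for k in range(n_runs):
            left, right = simulate_progeny_groups(
                True, 100, 100, trait, seed=int(rng.integers(2**31))
            )
            z = zscore_segregation(groups_of(left, right))
            het_correct += classify_sire("s", z).state == QTLState.HET
            left, right = simulate_progeny_groups(
                False, 100, 100, trait, seed=int(rng.integers(2**31))
            )
            z = zscore_segregation(groups_of(left, right))
            hom_miscalled += classify_sire("s", z).state == QTLState.HET
        assert het_correct / n_runs >= 0.95
        assert hom_miscalled / n_runs <= 0.05


# ---------------------------------------------------------------------
# progeny splitting
# ---------------------------------------------------------------------


def _cross_with_qtl(n_off=60, seed=0, m=10):
    mm = MarkerMap.from_positions(
        [f"m{i}" for i in range(m)], ["7"] * m, [int(1e6 * (i + 1)) for i in range(m)]
    )
    ped = Pedigree.from_records(
        [("sire", None, None, "M", "F0", "P"), ("dam", None, None, "F", "F0", "P")]
        + [(f"k{i}", "sire", "dam", "M", "F1", "P") for i in range(n_off)]
    )
    founders = simulate_founders(
        mm, {"P": 2}, seed=seed, ids_per_population={"P": ["sire", "dam"]}
    )
    # make the sire fully heterozygous with known phase
    founders.alleles[0, :, 0] = 1
    founders.alleles[0, :, 1] = 2
    g = drop_gametes(founders, ped, seed=seed)
    return mm, ped, g


class TestSplitProgeny:
    def test_fully_informative_single_marker(self):
        mm, ped, g = _cross_with_qtl(n_off=40, seed=1, m=1)
        pheno = pd.Series(14.0, index=[f"k{i}" for i in range(40)])
        groups = split_progeny(g, ped, pheno, "sire", ("7", 1, int(2e6)))
        # direct allele match oracle: paternal allele at the marker
        for i in range(40):
            k = g.ids.index(f"k{i}")
            expected = "left" if g.alleles[k, 0, 0] == 1 else "right"
            member = f"k{i}" in groups.left_ids
            assert member == (expected == "left")
        assert groups.n_unassigned == 0

    def test_no_recombination_full_truth_recovery(self):
        mm, ped, g = _cross_with_qtl(n_off=80, seed=2)
        # narrow region (no recombination expected within 2 Mb for most)
        pheno = pd.Series(14.0, index=[f"k{i}" for i in range(80)])
        groups = split_progeny(g, ped, pheno, "sire", ("7", 1, int(10e6)))
        correct = 0
        total = 0
        for i in range(80):
            k = g.ids.index(f"k{i}")
            src = g.hap_source[k, :, 0]
            if (src == src[0]).all():  # offspring with a non-recombinant gamete
                total += 1
                got_left = f"k{i}" in groups.left_ids
                correct += got_left == (src[0] == 0)
        assert total > 0 and correct == total

    def test_majority_vote_matches_counting_oracle(self):
        mm, ped, g = _cross_with_qtl(n_off=100, seed=3)
        pheno = pd.Series(14.0, index=[f"k{i}" for i in range(100)])
        groups = split_progeny(g, ped, pheno, "sire", ("7", 1, int(10e6)))
        # oracle: count marker-wise agreement of the true paternal gamete
        # with each sire haplotype (sire is het everywhere by construction)
        sire_row = g.ids.index("sire")
        for i in range(100):
            k = g.ids.index(f"k{i}")
            pat = g.alleles[k, :, 0]
            left_votes = int((pat == g.alleles[sire_row, :, 0]).sum())
            right_votes = int((pat == g.alleles[sire_row, :, 1]).sum())
            if left_votes > right_votes:
                assert f"k{i}" in groups.left_ids
            elif right_votes > left_votes:
                assert f"k{i}" in groups.right_ids

    def test_homozygous_sire_untestable(self):
        mm, ped, g = _cross_with_qtl(n_off=10, seed=4)
        sire_row = g.ids.index("sire")
        g.alleles[sire_row, :, 1] = g.alleles[sire_row, :, 0]
        pheno = pd.Series(14.0, index=[f"k{i}" for i in range(10)])
        with pytest.raises(ValueError, match="homozygous"):
            split_progeny(g, ped, pheno, "sire", ("7", 1, int(10e6)))


class TestFounderCall:
    def _refs(self, rng, n=200, mu=14.5, a=0.5, sigma=0.6):
        q = np.rint(rng.normal(mu + a, sigma, n))
        qq = np.rint(rng.normal(mu, sigma, n))
        return q, qq

    def test_simulated_q_chromosome_called(self):
        rng = np.random.default_rng(5)
        hits = 0
        runs = 200
        for _ in range(runs):
            q_ref, qq_ref = self._refs(rng)
            carriers = np.rint(rng.normal(14.5, 0.6, 40))  # behaves like the q group
            call = founder_call("f", carriers, q_ref, qq_ref, alpha=0.01)
            hits += call.hap_orientation[0] == "q"
        assert hits / runs >= 0.95

    def test_carriers_identical_to_q_reference_never_q(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            q_ref, qq_ref = self._refs(rng)
            carriers = rng.choice(q_ref, size=40, replace=False)
            call = founder_call("f", carriers, q_ref, qq_ref, alpha=0.01)
            assert call.hap_orientation[0] in ("Q", "unknown")

    def test_single_carrier_insufficient(self):
        call = founder_call("f", np.array([14.0]), np.zeros(10) + 15, np.zeros(10) + 14)
        assert call.hap_orientation[0] == "unknown"
        assert "insufficient" in call.note

    def test_mendelian_label_resolves_unknown(self):
        call = founder_call(
            "f", np.array([14.0]), np.ones(10) * 15, np.ones(10) * 14,
            mendelian_label="Q",
        )
        assert call.hap_orientation[0] == "Q"

    def test_mendelian_contradiction_flagged(self):
        rng = np.random.default_rng(7)
        q_ref, qq_ref = self._refs(rng, n=400)
        carriers = np.rint(rng.normal(14.5, 0.6, 100))  # clearly a q chromosome
        with pytest.raises(MendelianInconsistencyError):
            founder_call("f", carriers, q_ref, qq_ref, mendelian_label="Q")


class TestResolveHomozygote:
    def test_qq_direction_assigned(self):
        from vertfine.segregation import QTLGenotypeCall

        rng = np.random.default_rng(8)
        call = QTLGenotypeCall("s", QTLState.HOM, ("unknown", "unknown"), -3.0)
        q_ref = rng.normal(15.0, 0.5, 150)
        qq_ref = rng.normal(14.5, 0.5, 150)
        own = rng.normal(14.5, 0.5, 100)
        out = resolve_homozygote(call, own, q_ref, qq_ref)
        assert out.hap_orientation == ("q", "q")
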