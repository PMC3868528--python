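"""Perkins mapping, interference statistics, assurance and E0 purging."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tetracross as tc
from tetracross.model import IntervalTally

from conftest import make_tetrad

IV = ("A", "B")


def tally(pd, npd, tt):
    return IntervalTally(IV, PD=pd, NPD=npd, TT=tt)


class TestPerkins:
    @pytest.mark.parametrize(
        "pd, npd, tt, expected",
        [
            (100, 0, 0, 0.0),     # no recombinants
            (0, 0, 100, 50.0),    # all tetratype
            (70, 2, 28, 20.0),    # 100*(6*2+28)/(2*100)
        ],
    )
    def test_values(self, pd, npd, tt, expected):
        assert tc.perkins_cM(tally(pd, npd, tt)).cM == pytest.approx(expected)

    def test_zero_iff_no_recombinants(self):
        assert tc.perkins_cM(tally(10, 0, 0)).cM == 0.0
        assert tc.perkins_cM(tally(10, 0, 1)).cM > 0.0
        assert tc.perkins_cM(tally(10, 1, 0)).cM > 0.0

    def test_empty_tally_errors(self):
        with pytest.raises(tc.TetradError):
            tc.perkins_cM(tally(0, 0, 0))

    @given(
        pd=st.integers(0, 500), npd=st.integers(0, 50), tt=st.integers(0, 500),
        k=st.integers(2, 7),
    )
    def test_scaling_invariance(self, pd, npd, tt, k):
        if pd + npd + tt == 0:
            return
        a = tc.perkins_cM(tally(pd, npd, tt))
        b = tc.perkins_cM(tally(k * pd, k * npd, k * tt))
        assert a.cM == pytest.approx(b.cM)

    @given(pd=st.integers(0, 500), npd=st.integers(0, 50), tt=st.integers(0, 500))
    def test_caption_form_identity(self, pd, npd, tt):
        """(TT + 3·NPD)/total × 100 equals 100(6·NPD+TT)/(2·total)."""
        n = pd + npd + tt
        if n == 0:
            return
        est = tc.perkins_cM(tally(pd, npd, tt))
        assert est.cM == pytest.approx(100.0 * (tt / 2 + 3 * npd) / n)

    def test_se_matches_bootstrap(self):
        """Delta-method SE agrees with a 10,000-rep multinomial bootstrap."""
        t = tally(700, 20, 280)
        est = tc.perkins_cM(t)
        rng = np.random.default_rng(42)
        draws = rng.multinomial(t.n, [700 / 1000, 20 / 1000, 280 / 1000], size=10_000)
        boots = 50.0 * (6.0 * draws[:, 1] + draws[:, 2]) / t.n
        assert est.se_cM == pytest.approx(boots.std(), rel=0.05)


class TestPapazian:
    @pytest.mark.parametrize(
        "fT, expected",
        [
            (0.0, 0.0),
            (2.0 / 3.0, 1.0 / 6.0),          # second bracket vanishes
            (0.4, 0.5 * (0.6 - 0.4 ** (2.0 / 3.0))),
        ],
    )
    def test_values(self, fT, expected):
        assert tc.papazian_expected_npd(fT) == pytest.approx(expected, abs=1e-12)

    def test_out_of_domain_flags_not_clamps(self):
        with pytest.warns(UserWarning, match="Papazian domain"):
            assert np.isnan(tc.papazian_expected_npd(0.8))

    def test_negative_errors(self):
        with pytest.raises(tc.TetradError):
            tc.papazian_expected_npd(-0.1)

    @given(fT=st.floats(0.0, 2.0 / 3.0))
    def test_non_negative_and_bounded(self, fT):
        v = tc.papazian_expected_npd(fT)
        assert 0.0 <= v <= 1.0 / 6.0 + 1e-12


class TestNPDRatio:
    def test_no_npd_gives_zero(self):
        r = tc.npd_ratio(tally(80, 0, 20))
        assert r.npd_ratio == 0.0
        assert not r.undefined

    def test_hand_example(self):
        # fT=0.28, expected ~0.012225, observed 0.02 -> ~1.64 (negative interference)
        r = tc.npd_ratio(tally(70, 2, 28))
        assert r.npd_ratio == pytest.approx(1.636, abs=0.01)
        assert 0.0 <= r.p_value <= 1.0

    def test_ratio_one_when_observed_equals_expected(self):
        exp = tc.papazian_expected_npd(0.4)
        n = 100_000
        npd = round(exp * n)
        r = tc.npd_ratio(tally(n - npd - 40_000, npd, 40_000))
        assert r.npd_ratio == pytest.approx(1.0, abs=0.01)

    def test_zero_expected_with_observed_npd_flagged_infinite(self):
        r = tc.npd_ratio(tally(90, 10, 0))
        assert np.isinf(r.npd_ratio)
        assert r.undefined


class TestAdjacentInterference:
    @staticmethod
    def _hand_set():
        """12 tetrads over three markers with known (X,Y)/(Y,Z) classes.

        ref-CO group: 1×TT/TT + 5×TT/PD; ref-PD group: 3×PD/TT + 3×PD/PD.
        Hand tally: forward (50·1/6)/(50·3/6) = 1/3; reverse
        (50·1/4)/(50·5/8) = 0.4; mean 11/30.
        """
        tt_pd = ["PPP", "PMM", "MPP", "MMM"]
        pd_tt = ["PPP", "PPM", "MMP", "MMM"]
        pd_pd = ["PPP", "PPP", "MMM", "MMM"]
        tt_tt = ["PPM", "PMM", "MPP", "MMP"]
        sets = [tt_tt] + [tt_pd] * 5 + [pd_tt] * 3 + [pd_pd] * 3
        return [make_tetrad(str(i), s) for i, s in enumerate(sets)]

    def test_hand_tally_oracle(self, map3):
        res = tc.adjacent_interference(
            self._hand_set(), map3, ("X", "Y"), ("Y", "Z"), n_permutations=500
        )
        assert res.adj_ratio == pytest.approx(11.0 / 30.0)
        assert res.adj_ratio_forward == pytest.approx(1.0 / 3.0)
        assert res.adj_ratio_reverse == pytest.approx(0.4)
        assert 0.0 <= res.p_value <= 1.0

    def test_complete_interference_gives_zero(self, map3):
        tt_pd = ["PPP", "PMM", "MPP", "MMM"]
        pd_tt = ["PPP", "PPM", "MMP", "MMM"]
        pd_pd = ["PPP", "PPP", "MMM", "MMM"]
        tetrads = [
            make_tetrad(str(i), s)
            for i, s in enumerate([tt_pd] * 4 + [pd_tt] * 4 + [pd_pd] * 4)
        ]
        res = tc.adjacent_interference(
            tetrads, map3, ("X", "Y"), ("Y", "Z"), n_permutations=200
        )
        assert res.adj_ratio == 0.0

    def test_empty_subset_flagged_undefined(self, map3):
        tetrads = [
            make_tetrad(str(i), ["PPP", "PPP", "MMM", "MMM"]) for i in range(5)
        ]
        res = tc.adjacent_interference(
            tetrads, map3, ("X", "Y"), ("Y", "Z"), n_permutations=0
        )
        assert res.undefined

    def test_independence_limit(self, sim_nointf, chr3):
        """Without interference the averaged ratio approaches 1."""
        res = tc.adjacent_interference(
            sim_nointf.tetrads, chr3, chr3.intervals[4], chr3.intervals[5],
            n_permutations=500,
        )
        assert res.adj_ratio == pytest.approx(1.0, abs=0.1)
        assert res.p_value > 0.01

    def test_interference_detected(self, sim_counting, chr3):
        res = tc.adjacent_interference(
            sim_counting.tetrads, chr3, chr3.intervals[4], chr3.intervals[5],
            n_permutations=500,
        )
        assert res.adj_ratio < 1.0
        assert res.p_value < 0.01


class TestCrossoverClasses:
    def test_minimal_counts(self, map3):
        e0 = make_tetrad("e0", ["PPP", "PPP", "MMM", "MMM"])
        e1 = make_tetrad("e1", ["PPP", "PMM", "MPP", "MMM"])
        e2 = make_tetrad("e2", ["PMM", "PMM", "MPP", "MPP"])  # NPD in (X,Y)
        dist = tc.crossover_classes([e0, e1, e2], map3)
        assert dist.counts.tolist() == [1, 1, 1]
        assert dist.mean_CO == pytest.approx(1.0)

    def test_unscorable_dropped_and_reported(self, map3):
        ok = make_tetrad("ok", ["PPP", "PPP", "MMM", "MMM"])
        dead = make_tetrad("x", ["PPP", "PPP", "MMM", "---"],
                           viable=(True, True, True, False))
        dist = tc.crossover_classes([ok, dead], map3)
        assert dist.n == 1
        assert dist.n_dropped == 1


class TestAssurance:
    def test_zero_mean_expects_all_e0(self):
        dist = tc.CrossoverClassDistribution(counts=np.array([5, 0]))
        assert tc.assurance_test(dist, 0.0).expected_fraction == 1.0

    def test_poisson_null_expectations(self):
        dist = tc.CrossoverClassDistribution(counts=np.array([100, 400, 300]))
        assert tc.assurance_test(dist, 116.8 / 50).expected_fraction == pytest.approx(
            np.exp(-2.336)
        )
        assert tc.assurance_test(dist, 131.6 / 50).expected_fraction == pytest.approx(
            0.072, abs=0.0005
        )

    def test_matches_simulator_zero_class(self, sim_nointf, chr3):
        """Under Poisson crossovers the realized E0 fraction sits within 3 SE
        of exp(−λ)."""
        lam = sim_nointf.config.lam
        p = np.exp(-lam)
        n = len(sim_nointf.tetrads)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(sim_nointf.realized_e0_fraction - p) < 3 * se
        # Genotype-level reconstruction is a *minimal* crossover count, so it
        # can only overcount E0 (invisible two-strand doubles), and only
        # slightly without interference.
        dist = tc.crossover_classes(sim_nointf.tetrads, chr3)
        res = tc.assurance_test(dist, lam)
        assert res.observed_fraction >= p - 3 * se
        assert res.observed_fraction - p < 0.02


class TestMeanCO:
    @pytest.mark.parametrize("cm, expected", [(131.6, 2.632), (116.8, 2.336), (0.0, 0.0)])
    def test_values(self, cm, expected):
        assert tc.cM_to_mean_CO(cm) == pytest.approx(expected)

    def test_negative_errors(self):
        with pytest.raises(tc.TetradError):
            tc.cM_to_mean_CO(-1.0)


class TestPurge:
    def test_identity_without_e0(self, map3):
        tetrads = [
            make_tetrad(str(i), ["PPP", "PMM", "MPP", "MMM"]) for i in range(5)
        ]
        res = tc.purge_nonexchange(tetrads, map3)
        assert res.exchange == tetrads
        assert res.e0 == []

    def test_all_e0_flags_empty_exchange(self, map3):
        tetrads = [
            make_tetrad(str(i), ["PPP", "PPP", "MMM", "MMM"]) for i in range(5)
        ]
        with pytest.warns(UserWarning, match="exchange subset is empty"):
            res = tc.purge_nonexchange(tetrads, map3)
        assert res.exchange == []
        assert len(res.e0) == 5

    def test_mixture_purge_recovers_forced_fraction(self, sim_mixture, chr3):
        """q=0.15 forced achiasmate + obligate CO otherwise: purging removes
        the E0 subset, whose size tracks q·n."""
        n = len(sim_mixture.tetrads)
        res = tc.purge_nonexchange(sim_mixture.tetrads, chr3)
        q = 0.15
        se = np.sqrt(q * (1 - q) / n)
        assert abs(len(res.e0) / n - q) < 3 * se
        dist = tc.crossover_classes(res.exchange, chr3)
        assert dist.e0 == 0


class TestSimulationRoundTrip:
    """Estimators applied to large clean simulations recover the generative
    truth; these are the core calibration checks for the whole toolkit."""

    def test_npd_ratio_near_one_without_interference(self, tallies_nointf):
        for iv, t in tallies_nointf.items():
            r = tc.npd_ratio(t)
            se = np.sqrt(r.expected_npd_freq * (1 - r.expected_npd_freq) / t.n)
            assert abs(r.npd_ratio - 1.0) <= 3 * se / r.expected_npd_freq, iv

    def test_npd_ratio_below_one_with_interference(self, tallies_counting):
        for iv, t in tallies_counting.items():
            r = tc.npd_ratio(t)
            assert r.npd_ratio < 1.0, iv
            assert r.p_value < 1e-6, iv

    def test_perkins_matches_analytic_expectation_no_interference(
        self, sim_nointf, tallies_nointf, chr3
    ):
        """Perkins is exact only through double crossovers; under a Poisson
        model its expectation is 50[5/3 + (4/3)e^(−1.5μ) − 3e^(−μ)] with
        μ = d/50. Estimates agree with that expectation for every interval,
        and with the nominal length itself for the short intervals where
        triple crossovers are negligible."""
        lengths = dict(zip(chr3.intervals, chr3.interval_lengths_cM))
        for iv, t in tallies_nointf.items():
            est = tc.perkins_cM(t)
            mu = lengths[iv] / 50.0
            analytic = 50.0 * (
                5.0 / 3.0 + (4.0 / 3.0) * np.exp(-1.5 * mu) - 3.0 * np.exp(-mu)
            )
            assert abs(est.cM - analytic) <= 3 * est.se_cM, iv
            if lengths[iv] <= 13.0:
                assert abs(est.cM - lengths[iv]) <= 3 * est.se_cM, iv

    def test_perkins_recovers_lengths_under_interference(
        self, sim_counting, tallies_counting, chr3
    ):
        """With interference suppressing multiple crossovers per interval,
        Perkins recovers every nominal interval length within 3 SE."""
        lengths = dict(zip(chr3.intervals, chr3.interval_lengths_cM))
        for iv, t in tallies_counting.items():
            est = tc.perkins_cM(t)
            assert abs(est.cM - lengths[iv]) <= 3 * est.se_cM, iv

    def test_purging_strengthens_interference_in_mixture(self, sim_mixture, chr3):
        """The achiasmate subpopulation dilutes the interference signal;
        purging E0 tetrads restores it (smaller adjacent-interval ratio)."""
        purged = tc.purge_nonexchange(sim_mixture.tetrads, chr3)
        stronger = 0
        for k in range(len(chr3.intervals) - 1):
            full = tc.adjacent_interference(
                sim_mixture.tetrads, chr3, chr3.intervals[k], chr3.intervals[k + 1],
                n_permutations=0,
            )
            sub = tc.adjacent_interference(
                purged.exchange, chr3, chr3.intervals[k], chr3.intervals[k + 1],
                n_permutations=0,
            )
            assert sub.adj_ratio < full.adj_ratio, k
            stronger += 1
        assert stronger == len(chr3.intervals) - 1
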