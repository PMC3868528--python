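"""Generative-model correctness of the meiosis simulator."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

import tetracross as tc
from tetracross.io import tetrad_table_string
from tetracross.model import calls_matrix, segregation_pattern_table
from tetracross.sim import TetradTruth

from conftest import clean_config


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(co_model="gamma"),
            dict(n_tetrads=0),
            dict(interference_m=-1),
            dict(assurance_fail_q=1.5),
            dict(conversion_prob=-0.1),
            dict(spore_death_rate=2.0),
            dict(mean_CO=-1.0),
            dict(mean_CO=0.0, obligate_CO=True),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(tc.TetradError):
            clean_config(**{"n_tetrads": 10, **kwargs})

    def test_default_mean_is_map_length_over_fifty(self, chr3):
        cfg = clean_config(n_tetrads=10)
        assert cfg.lam == pytest.approx(chr3.total_cM / 50.0)


class TestDeterminism:
    def test_same_config_bit_identical_tsv(self):
        cfg = tc.dmc1_hed1_like(n_tetrads=400, seed=21)
        a = tc.simulate_tetrads(cfg)
        b = tc.simulate_tetrads(cfg)
        assert tetrad_table_string(a.tetrads, cfg.map) == tetrad_table_string(
            b.tetrads, cfg.map
        )

    def test_different_seed_differs(self):
        from dataclasses import replace

        cfg = tc.wild_type_like(n_tetrads=200, seed=0)
        a = tc.simulate_tetrads(cfg)
        b = tc.simulate_tetrads(replace(cfg, seed=1))
        assert tetrad_table_string(a.tetrads, cfg.map) != tetrad_table_string(
            b.tetrads, cfg.map
        )


class TestConservation:
    def test_everything_two_to_two_without_noise(self):
        """No conversion, death or nondisjunction: every marker segregates
        exactly 2:2 in every tetrad."""
        cfg = clean_config(n_tetrads=2000, co_model="counting", interference_m=3,
                           obligate_CO=True, seed=13)
        res = tc.simulate_tetrads(cfg)
        C, V = calls_matrix(res.tetrads)
        assert V.all()
        assert (segregation_pattern_table(C, V) == 0).all()

    def test_obligate_co_eliminates_e0(self):
        cfg = clean_config(n_tetrads=10_000, obligate_CO=True, seed=14)
        res = tc.simulate_tetrads(cfg)
        assert (res.crossover_counts() >= 1).all()

    def test_forced_fraction_is_achiasmate(self):
        cfg = clean_config(
            n_tetrads=10_000, obligate_CO=True, assurance_fail_q=0.2, seed=15
        )
        res = tc.simulate_tetrads(cfg)
        frac = res.realized_e0_fraction
        se = np.sqrt(0.2 * 0.8 / 10_000)
        assert abs(frac - 0.2) < 3 * se
        assert all(
            rec.n_crossovers == 0 for rec in res.truth if rec.forced_e0
        )


class TestCrossoverNumberModels:
    def test_poisson_zero_class(self, sim_nointf):
        lam = sim_nointf.config.lam
        p = np.exp(-lam)
        se = np.sqrt(p * (1 - p) / len(sim_nointf.truth))
        assert abs(sim_nointf.realized_e0_fraction - p) < 3 * se

    def test_counting_m0_indistinguishable_from_poisson(self, sim_nointf):
        """m = 0 reduces the renewal model to the Poisson model (two-sample
        KS on crossover numbers over 50k meioses, α = 0.01)."""
        other = tc.simulate_tetrads(
            clean_config(co_model="counting", interference_m=0, seed=4)
        )
        ks = stats.ks_2samp(sim_nointf.crossover_counts(), other.crossover_counts())
        assert ks.pvalue > 0.01

    def test_interference_strength_monotone_in_m(self):
        """The variance/mean ratio of crossover numbers strictly decreases
        as the counting parameter m grows at fixed λ."""
        ratios = []
        for m, seed in ((0, 16), (2, 17), (4, 18)):
            res = tc.simulate_tetrads(
                clean_config(co_model="counting", interference_m=m, seed=seed)
            )
            counts = res.crossover_counts()
            ratios.append(counts.var() / counts.mean())
        assert ratios[0] > ratios[1] > ratios[2]

    def test_counting_preserves_mean(self, sim_counting):
        counts = sim_counting.crossover_counts()
        lam = sim_counting.config.lam
        se = counts.std() / np.sqrt(counts.size)
        assert abs(counts.mean() - lam) < 3 * se


class TestTruthConsistency:
    def test_replay_reproduces_emitted_genotypes(self):
        """Re-deriving genotypes from truth reproduces the emitted table
        bit-exactly, across all noise processes at once."""
        cfg = tc.SimConfig(
            n_tetrads=500, co_model="counting", interference_m=2,
            obligate_CO=True, assurance_fail_q=0.2, conversion_prob=0.05,
            backup_efficiency=0.5, spore_death_rate=0.2, seed=19,
        )
        res = tc.simulate_tetrads(cfg)
        for tet, rec in zip(res.tetrads, res.truth):
            G, viable = tc.replay_genotypes(rec, cfg.map)
            for s_i, spore in enumerate(tet.spores):
                assert spore.viable == viable[s_i]
                assert np.array_equal(spore.calls, G[s_i])

    def test_genotype_classes_match_truth_classes_when_clean(self, map3):
        cfg = clean_config(n_tetrads=2000, seed=20)
        cfg = replace(cfg, map=map3)
        res = tc.simulate_tetrads(cfg)
        tal = tc.tally_intervals(res.tetrads, map3, "none")
        for iv in map3.intervals:
            fr = tc.interval_recombinant_fraction(res, iv)
            n = len(res.tetrads)
            assert tal[iv].TT == round(fr["TT"] * n)
            assert tal[iv].NPD == round(fr["NPD"] * n)


class TestTruthOracles:
    @staticmethod
    def _result_with(positions, chromatids, mmap):
        rec = TetradTruth(
            tetrad_id="t", n_crossovers=len(positions), positions=positions,
            chromatids=chromatids, conversions=(), forced_e0=False,
            nondisjoined=False, spore_chromatids=(0, 1, 2, 3),
            disomic_slots=(), dead_slots=(False,) * 4,
        )
        cfg = clean_config(n_tetrads=1)
        cfg = replace(cfg, map=mmap)
        return tc.SimResult(config=cfg, tetrads=[], truth=[rec])

    def test_no_crossovers_all_pd(self, map3):
        res = self._result_with((), (), map3)
        assert tc.interval_recombinant_fraction(res, ("X", "Y"))["PD"] == 1.0

    def test_single_crossover_in_interval_is_tetratype(self, map3):
        res = self._result_with((5.0,), ((0, 2),), map3)
        assert tc.interval_recombinant_fraction(res, ("X", "Y"))["TT"] == 1.0
        assert tc.interval_recombinant_fraction(res, ("Y", "Z"))["PD"] == 1.0

    def test_four_strand_double_is_npd(self, map3):
        res = self._result_with((4.0, 6.0), ((0, 2), (1, 3)), map3)
        assert tc.interval_recombinant_fraction(res, ("X", "Y"))["NPD"] == 1.0

    def test_two_strand_double_is_pd(self, map3):
        res = self._result_with((4.0, 6.0), ((0, 2), (0, 2)), map3)
        assert tc.interval_recombinant_fraction(res, ("X", "Y"))["PD"] == 1.0

    def test_papazian_consistency_no_interference(self, sim_nointf, chr3):
        """Truth-level TT and NPD frequencies match the closed-form
        no-interference tetrad probabilities within 3 SE: fT = ⅔(1−e^(−1.5μ))
        and NPD = ½[(1−fT) − e^(−μ)] with μ = d/50."""
        n = len(sim_nointf.truth)
        for iv, d in zip(chr3.intervals, chr3.interval_lengths_cM):
            mu = d / 50.0
            ft = 2.0 / 3.0 * (1 - np.exp(-1.5 * mu))
            fnpd = 0.5 * ((1 - ft) - np.exp(-mu))
            fr = tc.interval_recombinant_fraction(sim_nointf, iv)
            assert abs(fr["TT"] - ft) < 3 * np.sqrt(ft * (1 - ft) / n), iv
            assert abs(fr["NPD"] - fnpd) < 3 * np.sqrt(fnpd * (1 - fnpd) / n), iv

    def test_true_cM_matches_map_under_stationarity(self, sim_nointf, chr3):
        n = len(sim_nointf.truth)
        for iv, d in zip(chr3.intervals, chr3.interval_lengths_cM):
            mu = d / 50.0
            se_cM = 50.0 * np.sqrt(mu / n)  # Poisson count SE
            assert abs(tc.interval_true_cM(sim_nointf, iv) - d) < 3 * se_cM, iv
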