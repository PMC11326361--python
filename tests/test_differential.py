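"""BIC model selection, downsampling, the G-test and the three-criterion call."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from rhyqtl import differential as dif
from rhyqtl import synthetic_data as sd
from rhyqtl.rhythm import cosinor_signal, fit_harmonic
from rhyqtl.differential import RhythmModel


def _two_groups(rng, nA=100, nB=100, ampA=0.0, ampB=0.0, phaseA=6.0,
                phaseB=6.0, mesorA=5.0, mesorB=5.0, sd_noise=1.0):
    tA = rng.uniform(0, 24, nA)
    tB = rng.uniform(0, 24, nB)
    yA = cosinor_signal(tA, mesorA, ampA, phaseA) + rng.normal(0, sd_noise, nA)
    yB = cosinor_signal(tB, mesorB, ampB, phaseB) + rng.normal(0, sd_noise, nB)
    return tA, yA, tB, yB


class TestFitModelSet:
    def test_flat_noise_selects_no_rhythm(self, rng):
        fits = dif.fit_model_set(*_two_groups(rng))
        assert dif.select_model(fits) is RhythmModel.M_NONE

    def test_single_group_rhythm_selects_one_sided_model(self, rng):
        fits = dif.fit_model_set(*_two_groups(rng, ampA=2.0, sd_noise=0.1))
        assert dif.select_model(fits) is RhythmModel.M_A_ONLY
        fits = dif.fit_model_set(*_two_groups(rng, ampB=2.0, sd_noise=0.1))
        assert dif.select_model(fits) is RhythmModel.M_B_ONLY

    def test_identical_strong_rhythm_selects_shared(self, rng):
        fits = dif.fit_model_set(
            *_two_groups(rng, ampA=2.0, ampB=2.0, sd_noise=0.1))
        assert dif.select_model(fits) is RhythmModel.M_SHARED

    def test_opposite_phases_select_distinct(self, rng):
        fits = dif.fit_model_set(
            *_two_groups(rng, ampA=2.0, ampB=2.0, phaseB=18.0, sd_noise=0.1))
        assert dif.select_model(fits) is RhythmModel.M_DISTINCT

    def test_mesor_difference_alone_is_not_differential(self, rng):
        """Group-specific mesors in every model: eQTLs cannot drive the call."""
        fits = dif.fit_model_set(
            *_two_groups(rng, mesorA=4.0, mesorB=7.0, sd_noise=0.5))
        assert dif.select_model(fits) is RhythmModel.M_NONE

    def test_bic_matches_independent_refit_oracle(self):
        """Argmin-BIC equals an exhaustive per-model refit built from separate
        per-group OLS fits (statsmodels for the shared model)."""
        import statsmodels.api as sm

        gen = np.random.default_rng(77)
        agree = 0
        for trial in range(100):
            amp = (gen.uniform(0, 1.5), gen.uniform(0, 1.5))
            tA, yA, tB, yB = _two_groups(
                gen, nA=int(gen.integers(20, 60)), nB=int(gen.integers(20, 60)),
                ampA=amp[0], ampB=amp[1], phaseB=gen.uniform(0, 24),
                sd_noise=gen.uniform(0.3, 1.0))
            n = len(tA) + len(tB)
            w = 2 * np.pi / 24

            def group_rss(t, y, harmonic):
                X = np.column_stack([np.ones_like(t)] +
                                    ([np.cos(w * t), np.sin(w * t)] if harmonic else []))
                res = sm.OLS(y, X).fit()
                return float(res.ssr)

            def shared_rss():
                t = np.concatenate([tA, tB])
                iA = np.concatenate([np.ones_like(tA), np.zeros_like(tB)])
                X = np.column_stack([iA, 1 - iA, np.cos(w * t), np.sin(w * t)])
                return float(sm.OLS(np.concatenate([yA, yB]), X).fit().ssr)

            oracle_rss = {
                RhythmModel.M_NONE: group_rss(tA, yA, 0) + group_rss(tB, yB, 0),
                RhythmModel.M_A_ONLY: group_rss(tA, yA, 1) + group_rss(tB, yB, 0),
                RhythmModel.M_B_ONLY: group_rss(tA, yA, 0) + group_rss(tB, yB, 1),
                RhythmModel.M_SHARED: shared_rss(),
                RhythmModel.M_DISTINCT: group_rss(tA, yA, 1) + group_rss(tB, yB, 1),
            }
            oracle_bic = {m: n * math.log(r / n) + m.k * math.log(n)
                          for m, r in oracle_rss.items()}
            oracle_pick = min(oracle_bic, key=lambda m: (oracle_bic[m], int(m)))
            fits = dif.fit_model_set(tA, yA, tB, yB)
            for m in RhythmModel:
                assert fits[m].rss == pytest.approx(oracle_rss[m], rel=1e-8)
                assert fits[m].bic == pytest.approx(oracle_bic[m], rel=1e-8)
            agree += dif.select_model(fits) is oracle_pick
        assert agree == 100


class TestDownsample:
    def test_sizes_matched_to_smaller_group(self, rng):
        a, b = dif.downsample_equal(np.arange(100), np.arange(100, 160), rng)
        assert len(a) == len(b) == 60
        assert set(b) == set(range(100, 160))
        assert set(a) <= set(range(100))

    def test_equal_sizes_unchanged(self, rng):
        a, b = dif.downsample_equal(np.arange(50), np.arange(50, 100), rng)
        np.testing.assert_array_equal(a, np.arange(50))
        np.testing.assert_array_equal(b, np.arange(50, 100))

    def test_seeded_determinism(self):
        r1 = np.random.default_rng(4)
        r2 = np.random.default_rng(4)
        r3 = np.random.default_rng(5)
        a1, _ = dif.downsample_equal(np.arange(100), np.arange(10), r1)
        a2, _ = dif.downsample_equal(np.arange(100), np.arange(10), r2)
        a3, _ = dif.downsample_equal(np.arange(100), np.arange(10), r3)
        np.testing.assert_array_equal(a1, a2)
        assert not np.array_equal(a1, a3)


class TestGTest:
    def test_null_identity(self):
        g, df, p = dif.g_test([4, 4, 4, 4, 4], [4, 4, 4, 4, 4])
        assert g == 0.0 and df == 4 and p == 1.0

    @pytest.mark.parametrize("obs, expected_g", [
        ((20, 0, 0, 0, 0), 2 * 20 * math.log(5)),        # 64.3775...
        ((10, 10, 0, 0, 0), 40 * math.log(2.5)),         # 36.6516...
    ])
    def test_hand_computed_values(self, obs, expected_g):
        g, df, p = dif.g_test(obs, [4] * 5)
        assert g == pytest.approx(expected_g, rel=1e-12)
        assert df == 4
        assert p == pytest.approx(stats.chi2.sf(expected_g, 4), rel=1e-12)

    def test_concentrated_frequency_is_highly_significant(self):
        g, df, p = dif.g_test([20, 0, 0, 0, 0], [4] * 5)
        assert g == pytest.approx(64.38, abs=0.01)
        assert p < 1e-12

    def test_all_compositions_against_enumerated_oracle(self):
        """Every composition of 20 into 5 parts from {0,4,5,10,20} matches the
        directly-summed formula and scipy's log-likelihood-ratio statistic."""
        parts = (0, 4, 5, 10, 20)
        seen = 0
        for obs in itertools.product(parts, repeat=5):
            if sum(obs) != 20:
                continue
            seen += 1
            g, df, p = dif.g_test(obs, [4] * 5)
            manual = 2 * sum(o * math.log(o / 4) for o in obs if o)
            assert g == pytest.approx(manual, rel=1e-12)
            g_sp, p_sp = stats.power_divergence(obs, [4] * 5,
                                                lambda_="log-likelihood")
            assert g == pytest.approx(float(g_sp), rel=1e-10)
            assert p == pytest.approx(float(p_sp), rel=1e-10)
        assert seen > 5

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            dif.g_test([10, 10], [20, 0])
        with pytest.raises(ValueError):
            dif.g_test([10, 10], [5, 5])


class TestRepeatModelSelection:
    def test_planted_effect_concentrates_on_one_model(self):
        pair, ds, _ = sd.simulate_pair_cohort(seed=21)
        msr = dif.repeat_model_selection(pair, ds, seed=1)
        one_sided = (msr.freq[int(RhythmModel.M_A_ONLY)]
                     + msr.freq[int(RhythmModel.M_B_ONLY)])
        assert one_sided >= 15
        assert msr.modal_is_differential
        assert msr.p_g < 1e-6

    def test_null_pairs_mostly_select_no_rhythm(self):
        modal_none = 0
        n_pairs = 50
        for i in range(n_pairs):
            pair, ds, _ = sd.simulate_pair_cohort(
                n_per_group=75, amplitude=(0.0, 0.0), seed=1000 + i)
            msr = dif.repeat_model_selection(pair, ds, seed=1)
            modal_none += msr.modal_model is RhythmModel.M_NONE
        assert modal_none / n_pairs >= 0.9

    def test_equal_groups_single_repeat_equals_full_fit(self):
        pair, ds, _ = sd.simulate_pair_cohort(seed=33)
        msr = dif.repeat_model_selection(pair, ds, n_repeats=1, seed=7)
        times = ds.times
        y = ds.values.loc[pair.gene_id].to_numpy()
        gA, gB = pair.groups[0], pair.groups[2]
        full = dif.fit_model_set(times[gA], y[gA], times[gB], y[gB])
        assert msr.selected == [dif.select_model(full)]

    def test_result_independent_of_seed_path(self):
        pair, ds, _ = sd.simulate_pair_cohort(seed=33)
        m1 = dif.repeat_model_selection(pair, ds, seed=7)
        m2 = dif.repeat_model_selection(pair, ds, seed=7)
        np.testing.assert_array_equal(m1.freq, m2.freq)
        assert m1.selected == m2.selected


class TestModalTieBreak:
    def test_prefers_differential_then_lowest_id(self):
        freq = np.array([10.0, 10.0, 0.0, 0.0, 0.0])
        assert dif._modal_model(freq) is RhythmModel.M_A_ONLY
        freq = np.array([0.0, 10.0, 10.0, 0.0, 0.0])
        assert dif._modal_model(freq) is RhythmModel.M_A_ONLY
        freq = np.array([10.0, 0.0, 0.0, 10.0, 0.0])
        assert dif._modal_model(freq) is RhythmModel.M_NONE


class TestCallRhyqtl:
    def _call(self, pair, ds, seed=1):
        times = ds.times
        y = ds.values.loc[pair.gene_id].to_numpy()
        fits = {g: fit_harmonic(times[m], y[m]) for g, m in pair.groups.items()}
        msr = dif.repeat_model_selection(pair, ds, seed=seed)
        return dif.call_rhyqtl(pair, fits, msr)

    def test_planted_rhyqtl_called(self):
        pair, ds, truth = sd.simulate_pair_cohort(seed=5)
        call = self._call(pair, ds)
        assert truth.is_rhyqtl
        assert call.crit1_rhythmic_any_genotype
        assert call.is_rhyqtl

    def test_shared_rhythm_not_called(self):
        pair, ds, truth = sd.simulate_pair_cohort(
            amplitude=(1.0, 1.0), phase=(6.0, 6.0), seed=6)
        assert not truth.is_rhyqtl
        call = self._call(pair, ds)
        assert call.crit1_rhythmic_any_genotype
        assert not call.crit2_differential_modal
        assert not call.is_rhyqtl

    def test_flat_pair_fails_first_criterion(self):
        pair, ds, _ = sd.simulate_pair_cohort(amplitude=(0.0, 0.0), seed=7)
        call = self._call(pair, ds)
        assert not call.crit1_rhythmic_any_genotype
        assert not call.is_rhyqtl


class TestReplication:
    def _fit(self, p, amp, phase=0.0):
        from rhyqtl.rhythm import HarmonicFit
        return HarmonicFit(n=10, mesor=5, coef_cos=amp, coef_sin=0,
                           amplitude=amp, phase=phase, p_value=p, rss=1.0)

    def test_phase_shift_is_differential(self):
        a = self._fit(1e-3, 0.5, phase=2.0)
        b = self._fit(1e-3, 0.5, phase=6.5)
        assert dif.replication_differential(a, b)

    def test_identical_fits_not_differential(self):
        a = self._fit(1e-3, 0.5, phase=2.0)
        assert not dif.replication_differential(a, a)

    def test_amplitude_ratio_rule(self):
        # fold changes 3.2 vs 1.6: ratio 2 > 1.5 -> differential
        a = self._fit(1e-3, np.log2(3.2) / 2)
        b = self._fit(1e-3, np.log2(1.6) / 2)
        assert dif.replication_differential(a, b)
        # ratio 1.4 < 1.5, same phase, both rhythmic -> not differential
        c = self._fit(1e-3, np.log2(2.8) / 2)
        d = self._fit(1e-3, np.log2(2.0) / 2)
        assert not dif.replication_differential(c, d)

    def test_one_sided_rhythmicity_rule(self):
        a = self._fit(1e-3, 0.5)
        b = self._fit(0.5, 0.5)
        assert dif.replication_differential(a, b)
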