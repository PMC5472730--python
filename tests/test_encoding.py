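"""Rate binning, normalization, windows, tuning fits, and the census."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import crossreact as cr
from crossreact.config import EpochWindow
from crossreact import encoding as enc
from crossreact.errors import AnalysisError

from conftest import flat_trials, make_tensor


class TestBinAndZscore:
    def test_single_spike_placement(self):
        trials = flat_trials(2, span_ms=2000.0)
        spikes = pd.DataFrame({"neuron_id": [0, 0, 0], "trial_id": [0, 0, 1],
                               "spike_time_ms": [105.0, 106.0, 500.0]})
        rt = enc.bin_and_zscore(spikes, trials)
        raw = rt.rate * rt.raw_sd[:, None, None] + rt.raw_mean[:, None, None]
        b = int((105.0 - rt.t_start) / rt.bin_ms)
        assert raw[0, 0, b] == pytest.approx(200.0)  # 2 spikes / 10 ms
        assert np.nansum(raw[0, 0]) == pytest.approx(200.0)

    def test_zscore_moments(self, small_tensor):
        flat = small_tensor.rate.reshape(small_tensor.rate.shape[0], -1)
        mu = np.nanmean(flat, axis=1)
        sd = np.nanstd(flat, axis=1)
        assert np.allclose(mu, 0.0, atol=1e-5)
        assert np.allclose(sd, 1.0, atol=1e-4)

    def test_homogeneous_poisson_rate_recovered(self):
        task = cr.TaskConfig()
        params = cr.SynthParams(n_neurons=5, baseline_median_hz=10.0,
                                baseline_log_sd=0.0, sigma_assoc_described=0.0,
                                sigma_assoc_experienced=0.0, sigma_general=0.0,
                                sigma_choice=0.0)
        rng = np.random.default_rng(31)
        trials = cr.generate_trials(task, params, 80, rng)
        spikes, _ = cr.generate_spikes(trials, params, rng)
        rt = enc.bin_and_zscore(spikes, trials)
        # pooled pre-normalization mean across ~4s x 80 trials per neuron
        se = np.sqrt(10.0 / (0.01 * rt.rate.shape[2] * 80))
        assert np.all(np.abs(rt.raw_mean - 10.0) < 4 * se)

    def test_silent_neuron_rejected(self):
        trials = flat_trials(2)
        spikes = pd.DataFrame({"neuron_id": [0, 1], "trial_id": [0, 0],
                               "spike_time_ms": [100.0, np.nan]}).dropna()
        spikes = pd.concat([spikes, pd.DataFrame(
            {"neuron_id": [1], "trial_id": [0], "spike_time_ms": [-1e9]})])
        with pytest.raises(AnalysisError, match="zero rate variance"):
            enc.bin_and_zscore(spikes, trials)


class TestPsth:
    def test_width_one_is_identity(self):
        x = np.random.default_rng(0).normal(size=(3, 40))
        assert np.allclose(enc._boxcar(x, 1), x)

    def test_constant_input(self):
        x = np.full((2, 50), 3.3)
        assert np.allclose(enc._boxcar(x, 20), 3.3)

    def test_step_becomes_ramp(self):
        # step 0->1 at bin 50 smoothed by 20 bins: linear ramp of length 20
        x = np.zeros((1, 100))
        x[0, 50:] = 1.0
        sm = enc._boxcar(x, 20)
        expected = np.convolve(x[0], np.ones(20) / 20, mode="same")
        # away from the edges (where _boxcar truncates instead of zero-pads)
        assert np.allclose(sm[0, 10:90], expected[10:90])
        ramp = sm[0, 41:60]
        assert np.all(np.diff(ramp) > 0)
        assert sm[0, 0] == 0.0 and sm[0, -1] == 1.0  # truncated-edge means

    def test_group_means(self, small_tensor, small_session):
        trials, _, _ = small_session
        out = enc.psth(small_tensor, trials, boxcar_ms=200.0,
                       group_by="trial_type")
        assert set(out) == {"described", "experienced"}
        assert out["described"].shape == (small_tensor.rate.shape[0],
                                          small_tensor.n_bins)


class TestEpochMean:
    def test_single_bin_window(self):
        trials = flat_trials(3)
        rate = np.arange(3 * 3 * 200, dtype=float).reshape(3, 3, 200)
        rt = make_tensor(rate, trials)
        win = EpochWindow("w", "offer1_cue_on", 0, 10)  # event at 100 -> bin 10
        em = enc.epoch_mean(rt, trials, win)
        assert em.shape == (3, 3)
        assert np.allclose(em, rate[:, :, 10].T)

    def test_all_zero_tensor(self):
        trials = flat_trials(4)
        rt = make_tensor(np.zeros((2, 4, 200)), trials)
        em = enc.epoch_mean(rt, trials, EpochWindow("w", "offer2_on", 0, 100))
        assert np.all(em == 0)

    def test_window_beyond_span_raises(self):
        trials = flat_trials(2)
        rt = make_tensor(np.zeros((1, 2, 50)), trials)
        with pytest.raises(AnalysisError, match="outside recorded span"):
            enc.epoch_mean(rt, trials, EpochWindow("w", "outcome_on", 0, 1000))


class TestFitTuning:
    def test_noiseless_linear_slope(self):
        trials = flat_trials(30)
        x = trials["offer1_size"].to_numpy()
        em = np.column_stack([2.0 * x, -0.5 * x + 7])
        cs = enc.fit_tuning(em, trials, "offer1_size")
        assert cs.slope == pytest.approx([2.0, -0.5], abs=1e-9)
        assert cs.r_squared == pytest.approx([1.0, 1.0], abs=1e-9)
        assert np.all(cs.p_value < 1e-20)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(41)
        trials = flat_trials(60)
        em = rng.normal(size=(60, 4))
        cs = enc.fit_tuning(em, trials, "offer1_size", include_choice=False)
        X = sm.add_constant(trials["offer1_size"].to_numpy(dtype=float))
        for j in range(4):
            fit = sm.OLS(em[:, j], X).fit()
            assert cs.slope[j] == pytest.approx(fit.params[1], rel=1e-9)
            assert cs.p_value[j] == pytest.approx(fit.pvalues[1], rel=1e-6)
            assert cs.r_squared[j] == pytest.approx(fit.rsquared, rel=1e-9)

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(42)
        trials = flat_trials(200)
        em = rng.normal(size=(200, 125))
        cs = enc.fit_tuning(em, trials, "offer1_size")
        assert abs((cs.p_value < 0.05).mean() - 0.05) < 0.05

    def test_constant_predictor_rejected(self):
        trials = flat_trials(20)
        trials["offer1_size"] = 100.0
        with pytest.raises(AnalysisError, match="constant predictor"):
            enc.fit_tuning(np.zeros((20, 2)), trials, "offer1_size")

    def test_census_invariant_to_neuron_order(self):
        rng = np.random.default_rng(43)
        trials = flat_trials(100)
        em = rng.normal(size=(100, 30))
        em[:, :10] += 0.01 * trials["offer1_size"].to_numpy()[:, None]
        cs = enc.fit_tuning(em, trials, "offer1_size")
        perm = rng.permutation(30)
        cs2 = enc.fit_tuning(em[:, perm], trials, "offer1_size")
        c1, c2 = enc.census(cs), enc.census(cs2)
        assert c1.n_tuned == c2.n_tuned
        assert c1.fraction == c2.fraction


class TestSliding:
    def test_partition_consistency_with_epoch_fit(self, small_tensor,
                                                  small_session):
        trials, _, _ = small_session
        sl = enc.sliding_tuning(small_tensor, trials, "offer1_size",
                                "offer1_value_on", (200.0, 500.0),
                                window_ms=300.0, step_ms=300.0)
        assert len(sl) == 1
        win = cr.default_windows()["offer1"]
        em = enc.epoch_mean(small_tensor, trials, win)
        cs = enc.fit_tuning(em, trials, "offer1_size")
        assert sl["fraction_tuned"].iloc[0] == pytest.approx(
            (cs.p_value < 0.05).mean())

    def test_peak_window_centering(self):
        centers = np.arange(50.0, 750.0, 50.0)
        strength = np.exp(-0.5 * ((centers - 300) / 80) ** 2)
        win = enc.find_peak_window(centers, strength, (0.0, 750.0), 400.0,
                                   "outcome_on")
        assert win.start_ms == pytest.approx(100.0)
        assert win.end_ms == pytest.approx(500.0)

    def test_peak_at_edge_is_clipped(self):
        centers = np.arange(50.0, 750.0, 50.0)
        strength = -centers  # peak at the first sample
        win = enc.find_peak_window(centers, strength, (0.0, 750.0), 400.0,
                                   "outcome_on")
        assert win.start_ms == 0.0
        assert win.width_ms == 400.0

    def test_planted_outcome_peak_detected(self, task):
        params = cr.SynthParams(n_neurons=40, sigma_assoc_described=0.02,
                                sigma_assoc_experienced=0.02, sigma_general=0.02)
        rng = np.random.default_rng(44)
        trials = cr.generate_trials(task, params, 300, rng)
        spikes, _ = cr.generate_spikes(trials, params, rng)
        rt = enc.bin_and_zscore(spikes, trials)
        sub = trials[trials["chosen_option"] == 1]
        sl = enc.sliding_tuning(rt, sub, "chosen_size", "outcome_on",
                                (0.0, 750.0), window_ms=300.0, step_ms=50.0)
        # tuning spans the whole outcome epoch, so encoding should be strong
        # throughout and the peak window must stay inside the epoch
        win = enc.find_peak_window(sl["center_ms"].to_numpy(),
                                   sl["mean_abs_t"].to_numpy(), (0.0, 750.0),
                                   400.0, "outcome_on")
        assert 0.0 <= win.start_ms and win.end_ms <= 750.0
        assert sl["fraction_tuned"].mean() > 0.3


class TestCensus:
    def test_reference_effect_sizes(self):
        cs = enc.CoefficientSet(
            slope=np.r_[np.ones(14), -np.ones(7), np.zeros(104)],
            p_value=np.r_[np.zeros(21), np.ones(104)],
            r_squared=np.zeros(125), t_stat=np.zeros(125),
            neuron_ids=np.arange(125), epoch="offer1",
            trial_type="experienced", predictor="offer1_size",
            model="size-only", selection="all", n_trials=200)
        c = enc.census(cs)
        assert c.n_tuned == 21 and c.n_positive == 14
        assert c.sign_split_effect == pytest.approx(4.00)
        assert c.binomial.effect_size == pytest.approx((21 / 125) / 0.05)

    def test_none_tuned(self):
        cs = enc.CoefficientSet(
            slope=np.zeros(125), p_value=np.ones(125), r_squared=np.zeros(125),
            t_stat=np.zeros(125), neuron_ids=np.arange(125), epoch="offer1",
            trial_type="described", predictor="offer1_size",
            model="size-only", selection="all", n_trials=200)
        c = enc.census(cs)
        assert c.n_tuned == 0
        assert c.binomial.p_value == pytest.approx(1.0)
        assert c.sign_test is None
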