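import numpy as np
import pandas as pd
import pytest

from circuitsync import GroundTruth, gen_auditory_session
from circuitsync.auditory import (
    ErpResult,
    component_metrics,
    detect_aep,
    epoch_trials,
    mmn_analysis,
)
from circuitsync.synthetic import erp_template


class TestEpochTrials:
    fs = 1000.0

    def test_all_clean_trials_kept(self, rng):
        x = rng.standard_normal(100000)
        onsets = np.arange(5.0, 95.0, 1.0)
        trials, t_ms = epoch_trials(x, self.fs, onsets, 500, 400)
        assert trials.shape == (90, 900)
        assert t_ms[0] == -500.0

    def test_constant_offset_removed_by_baseline_correction(self):
        x = np.full(20000, 42.0)
        trials, _ = epoch_trials(x, self.fs, np.array([5.0, 10.0]), 500, 400)
        assert np.allclose(trials, 0.0)

    def test_edge_trials_dropped_with_warning(self, rng):
        x = rng.standard_normal(5000)
        with pytest.warns(UserWarning, match="dropped"):
            trials, _ = epoch_trials(x, self.fs, np.array([0.1, 2.5, 4.9]), 500, 400)
        assert trials.shape[0] == 1

    def test_mean_erp_matches_template_at_low_noise(self):
        gt = GroundTruth(seed=1, aep_response_prob=1.0)
        rec, _ = gen_auditory_session(gt, "click_train", noise_sd_uv=1e-6)
        trials, t_ms = epoch_trials(rec.signals[0], rec.fs, rec.events["onset_s"].to_numpy())
        mean_erp = trials.mean(axis=0)
        tpl = erp_template(rec.fs)
        post = mean_erp[t_ms >= 0][: tpl.size]
        r = np.corrcoef(post, tpl)[0, 1]
        assert r > 0.95


class TestDetectAep:
    def test_high_snr_template_every_trial_gives_ratio_one(self, rng):
        tpl = erp_template(1000.0)
        trials = np.tile(tpl, (50, 1)) + rng.standard_normal((50, tpl.size)) * 0.3
        pre = rng.standard_normal((50, 500)) * 0.3
        full = np.hstack([pre, trials])
        t_ms = np.arange(-500, tpl.size) * 1.0
        _, ratio = detect_aep(full, t_ms)
        assert ratio == 1.0

    def test_pure_noise_rarely_detected(self, rng):
        trials = rng.standard_normal((500, 900)) * 2.0
        t_ms = np.arange(-500, 400) * 1.0
        _, ratio = detect_aep(trials, t_ms)
        assert ratio < 0.02

    def test_zero_variance_baseline_rejected(self):
        trials = np.zeros((3, 900))
        t_ms = np.arange(-500, 400) * 1.0
        with pytest.raises(ValueError, match="zero-variance"):
            detect_aep(trials, t_ms)


class TestComponentMetrics:
    t_ms = np.arange(-500, 400) * 1.0

    def _trials(self, scale=1.0, n=40, noise=0.0, rng=None):
        tpl = erp_template(1000.0, p2_amp_uv=5.0 * scale, p3_amp_uv=4.0 * scale)
        full = np.zeros((n, 900))
        full[:, 500 : 500 + tpl.size] = tpl
        if noise and rng is not None:
            full += rng.standard_normal(full.shape) * noise
        return full

    def test_p2_amplitude_recovered_within_10pct(self, rng):
        trials = self._trials(noise=0.5, rng=rng)
        amp, _ = component_metrics(trials, self.t_ms, "P2")
        assert amp == pytest.approx(5.0, rel=0.10)

    def test_amplitude_linear_in_template_scale(self):
        a1, _ = component_metrics(self._trials(1.0), self.t_ms, "P2")
        a2, _ = component_metrics(self._trials(2.0), self.t_ms, "P2")
        assert a2 == pytest.approx(2 * a1, rel=0.05)
        b1, _ = component_metrics(self._trials(1.0), self.t_ms, "P3")
        b2, _ = component_metrics(self._trials(2.0), self.t_ms, "P3")
        assert b2 == pytest.approx(2 * b1, rel=0.05)

    def test_firing_rate_confined_to_component_window(self):
        trials = self._trials()
        onsets = np.array([10.0, 20.0, 30.0])
        spikes = np.sort(np.concatenate([onsets + 0.25, onsets + 0.27]))  # 250/270 ms post
        _, p3_rate = component_metrics(trials, self.t_ms, "P3", spike_times_s=spikes, onsets_s=onsets)
        _, p2_rate = component_metrics(trials, self.t_ms, "P2", spike_times_s=spikes, onsets_s=onsets)
        assert p3_rate == pytest.approx(2 / 0.1)  # 2 spikes per trial in a 100 ms window
        assert p2_rate == 0.0

    def test_no_spike_train_gives_zero_rate_not_error(self):
        _, rate = component_metrics(self._trials(), self.t_ms, "P2")
        assert rate == 0.0

    def test_unknown_component_rejected(self):
        with pytest.raises(ValueError, match="component"):
            component_metrics(self._trials(), self.t_ms, "N1")


class TestErpResultEndToEnd:
    def test_response_ratio_tracks_injected_probability(self):
        gt = GroundTruth(seed=2, aep_response_prob=0.7)
        rec, _ = gen_auditory_session(gt, "click_train")
        erp = ErpResult.from_session(rec.signals[0], rec.fs, rec.events["onset_s"].to_numpy())
        injected = np.mean(rec.meta["responded"])
        assert erp.response_ratio == pytest.approx(injected, abs=0.03)
        assert set(erp.components) == {"P2", "P3"}


class TestMmnAnalysis:
    def test_identical_responses_give_zero_difference_wave(self):
        gt = GroundTruth(seed=5, mmn_extra_negativity=0.0)
        rec, _ = gen_auditory_session(gt, "oddball", noise_sd_uv=1e-9)
        res = mmn_analysis(rec.signals[0], rec.fs, rec.events)
        for combo in res.combinations.values():
            assert np.abs(combo["difference_wave"]).max() < 1e-6
            assert abs(combo["auc_uv_ms"]) < 1e-4

    def test_injected_negativity_auc_recovered(self):
        gt = GroundTruth(seed=6, mmn_extra_negativity=-3.0)
        rec, _ = gen_auditory_session(gt, "oddball")
        res = mmn_analysis(rec.signals[0], rec.fs, rec.events)
        for combo in res.combinations.values():
            assert combo["auc_uv_ms"] == pytest.approx(-300.0, abs=60.0)

    def test_label_shuffle_centers_auc_at_zero(self, rng):
        gt = GroundTruth(seed=7, mmn_extra_negativity=-3.0)
        rec, _ = gen_auditory_session(gt, "oddball")
        aucs = []
        for _ in range(10):
            ev = rec.events.copy()
            for block in (1, 2):
                idx = ev.index[ev["block"] == block]
                ev.loc[idx, "label"] = rng.permutation(ev.loc[idx, "label"].to_numpy())
                # keep freq consistent with the shuffled role within the block
                f_dev = ev.loc[idx][ev.loc[idx, "label"] == "deviant"]["freq_hz"]
                f_std = ev.loc[idx][ev.loc[idx, "label"] == "standard"]["freq_hz"]
            res = mmn_analysis(rec.signals[0], rec.fs, ev)
            aucs.extend(c["auc_uv_ms"] for c in res.combinations.values())
        assert abs(np.mean(aucs)) < 3 * np.std(aucs, ddof=1) / np.sqrt(len(aucs)) + 30.0

    def test_flip_flop_comparisons_are_frequency_matched(self):
        """Frequency-specific response differences cancel in the difference wave."""
        fs = 1000.0
        n_tr = 200
        onsets = 2.0 + 0.5 * np.arange(n_tr)
        half = n_tr // 2
        rng = np.random.default_rng(0)
        roles1 = np.array(["standard"] * 75 + ["deviant"] * 25)
        rng.shuffle(roles1)
        roles2 = np.array(["standard"] * 75 + ["deviant"] * 25)
        rng.shuffle(roles2)
        roles = np.concatenate([np.tile(roles1, 1), np.tile(roles2, 1)])
        freqs = np.where(
            np.arange(n_tr) < half,
            np.where(roles == "deviant", 8000.0, 6000.0),
            np.where(roles == "deviant", 6000.0, 8000.0),
        )
        blocks = np.where(np.arange(n_tr) < half, 1, 2)
        ev = pd.DataFrame({"onset_s": onsets, "offset_s": onsets + 0.01, "label": roles,
                           "freq_hz": freqs, "block": blocks})
        # response depends ONLY on physical frequency, not on the role
        x = np.zeros(int(onsets[-1] * fs + 1000))
        tpl6 = erp_template(fs, p2_amp_uv=8.0, p3_amp_uv=6.0)
        tpl8 = erp_template(fs, p2_amp_uv=3.0, p3_amp_uv=2.0)
        for on, f in zip(onsets, freqs):
            i = int(on * fs)
            x[i : i + tpl6.size] += tpl6 if f == 6000.0 else tpl8
        res = mmn_analysis(x, fs, ev)
        for combo in res.combinations.values():
            assert abs(combo["auc_uv_ms"]) < 1e-6

    def test_missing_block_warns_partial_result(self):
        gt = GroundTruth(seed=8)
        rec, _ = gen_auditory_session(gt, "oddball", n_oddball_trials=100)
        # block 2 truncated to its standards: 6 kHz then lacks deviant trials
        ev = rec.events[(rec.events["block"] == 1) | (rec.events["label"] == "standard")]
        with pytest.warns(UserWarning, match="skipped"):
            res = mmn_analysis(rec.signals[0], rec.fs, ev)
        assert len(res.combinations) == 1

    def test_missing_columns_rejected(self, rng):
        with pytest.raises(ValueError, match="columns"):
            mmn_analysis(rng.standard_normal(1000), 1000.0, pd.DataFrame({"onset_s": [1.0]}))
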