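import numpy as np
import pytest
from scipy import signal as sps

from circuitsync.core import Recording
from circuitsync.preprocessing import (
    acc_series,
    bin_firing_rate,
    detect_rest_epochs,
    extract_lfp,
    extract_mua,
    robust_sigma,
)
from circuitsync.core import SpikeTrain


def _rec(sig, fs, accel=None, accel_fs=None):
    sig = np.atleast_2d(sig)
    chans = [f"ch{i}" for i in range(sig.shape[0])]
    return Recording(sig, fs, chans, {c: "mPFC" for c in chans}, accel=accel, accel_fs=accel_fs)


class TestExtractLfp:
    def test_passband_sinusoid_amplitude_preserved(self):
        fs = 30000.0
        t = np.arange(int(10 * fs)) / fs
        x = 50.0 * np.sin(2 * np.pi * 10.0 * t)
        lfp = extract_lfp(_rec(x, fs))
        assert lfp.fs == 1000.0
        amp = np.abs(lfp.signals[0][2000:-2000]).max()
        assert amp == pytest.approx(50.0, rel=0.01)

    def test_notch_attenuates_mains_by_20db(self):
        fs = 3000.0
        t = np.arange(int(30 * fs)) / fs
        theta = 20.0 * np.sin(2 * np.pi * 8.0 * t)
        mains = 200.0 * np.sin(2 * np.pi * 50.0 * t)
        lfp_raw = extract_lfp(_rec(theta + mains, fs), notch_hz=0.0)
        lfp_notch = extract_lfp(_rec(theta + mains, fs), notch_hz=50.0)
        def p50(x):
            f, p = sps.welch(x, fs=1000.0, nperseg=4096)
            return p[np.argmin(np.abs(f - 50.0))]
        atten_db = 10 * np.log10(p50(lfp_raw.signals[0]) / p50(lfp_notch.signals[0]))
        assert atten_db >= 20.0

    def test_linear_ramp_removed(self):
        fs = 2000.0
        n = int(10 * fs)
        ramp = np.linspace(0, 1000.0, n)
        lfp = extract_lfp(_rec(ramp + 5.0, fs), notch_hz=0.0)
        slope = np.polyfit(np.arange(lfp.n_samples), lfp.signals[0], 1)[0]
        orig_slope = 1000.0 / n
        assert abs(slope) < 1e-6 * abs(orig_slope) + 1e-9

    def test_noninteger_ratio_warns_and_resamples(self):
        fs = 2500.0
        x = np.sin(2 * np.pi * 10 * np.arange(int(5 * fs)) / fs)
        with pytest.warns(UserWarning, match="integer multiple"):
            lfp = extract_lfp(_rec(x, fs), notch_hz=0.0)
        assert lfp.fs == 1000.0

    def test_sub200hz_band_power_preserved_within_5pct(self):
        fs = 30000.0
        t = np.arange(int(20 * fs)) / fs
        x = 10 * np.sin(2 * np.pi * 40 * t) + 10 * np.sin(2 * np.pi * 150 * t)
        lfp = extract_lfp(_rec(x, fs), notch_hz=0.0)
        assert lfp.signals[0].var() == pytest.approx(x.var(), rel=0.05)


class TestExtractMua:
    fs = 30000.0

    def _noise_rec(self, rng, dur=20.0, sd=10.0):
        n = int(self.fs * dur)
        x = rng.standard_normal(n) * sd
        ref = np.zeros(n)
        return _rec(np.vstack([x, ref]), self.fs)

    def test_injected_8sigma_spikes_recovered(self, rng):
        """Recall and precision >= 0.95 on a constructed sub-threshold background."""
        dur, n = 30.0, int(30.0 * self.fs)
        t = np.arange(n) / self.fs
        # bounded in-band carrier + out-of-band (LFP-like) Gaussian noise:
        # robust sigma of a sinusoid puts the 3-sigma threshold above its peak
        carrier = 8.0 * np.sin(2 * np.pi * 1000.0 * t)
        slow = sps.sosfiltfilt(sps.butter(4, 200, fs=self.fs, output="sos"),
                               rng.standard_normal(n) * 50.0)
        x = carrier + slow
        sos = sps.butter(4, (450, 6000), "bandpass", fs=self.fs, output="sos")
        sigma = robust_sigma(sps.sosfiltfilt(sos, x))
        true_idx = np.sort(rng.choice(np.arange(int(0.5 * self.fs), n - int(0.5 * self.fs), 300), 100, False))
        w = int(0.0005 * self.fs)
        for i in true_idx:
            x[i : i + 2 * w] += -8.0 * sigma * np.hanning(2 * w)
        rec = _rec(np.vstack([x, np.zeros(n)]), self.fs)
        st = extract_mua(rec, "ch0", "ch1")
        det = st["ch0"] * self.fs
        hits = sum(np.any(np.abs(det - i) < 0.002 * self.fs) for i in true_idx)
        fps = sum(not np.any(np.abs(d - true_idx) < 0.002 * self.fs) for d in det)
        recall = hits / 100
        precision = (det.size - fps) / max(det.size, 1)
        assert recall >= 0.95 and precision >= 0.95

    def test_gaussian_noise_crossing_rate_matches_rice_within_2x(self, rng):
        rec = self._noise_rec(rng)
        st = extract_mua(rec, "ch0", "ch1")
        rate = st["ch0"].size / rec.duration
        f1, f2 = 450.0, 6000.0
        # Rice formula for an ideal flat band: level-crossing rate of -3 sigma
        rice = np.sqrt((f2**3 - f1**3) / (3 * (f2 - f1))) * np.exp(-4.5)
        assert rice / 2 < rate < rice * 2

    def test_common_mode_artifact_cancelled(self, rng):
        n = int(5 * self.fs)
        artifact = np.zeros(n)
        for i in range(10000, n - 10000, 12000):
            artifact[i : i + 60] = -500.0 * np.hanning(60)
        base = rng.standard_normal(n) * 0.0
        rec = _rec(np.vstack([base + artifact, artifact]), self.fs)
        st = extract_mua(rec, "ch0", "ch1")
        assert st["ch0"].size == 0

    def test_reference_equals_target_rejected(self, rng):
        rec = self._noise_rec(rng, dur=1.0)
        with pytest.raises(ValueError, match="reference"):
            extract_mua(rec, "ch0", "ch0")

    def test_low_fs_rejected(self, rng):
        rec = _rec(np.vstack([rng.standard_normal(5000)] * 2), 5000.0)
        with pytest.raises(ValueError, match="too low"):
            extract_mua(rec, "ch0", "ch1")


class TestRestEpochs:
    acc_fs = 100.0

    def _accel(self, rng, quiet_mask_fn, dur):
        n = int(dur * self.acc_fs)
        t = np.arange(n) / self.acc_fs
        acc = rng.standard_normal((3, n)) * 0.02
        active = ~quiet_mask_fn(t)
        acc[:, active] += 0.5 * np.sin(2 * np.pi * 3 * t[active]) + rng.standard_normal((3, active.sum())) * 0.2
        return acc

    def test_constructed_quiet_intervals_recovered(self, rng):
        accel = self._accel(rng, lambda t: (t < 5.0) | (t >= 20.0), 24.0)
        rec = _rec(np.zeros((1, 24000)), 1000.0, accel=accel, accel_fs=self.acc_fs)
        eps = detect_rest_epochs(rec, threshold_percentile=40.0)
        assert len(eps) == 2
        assert eps[0].start == pytest.approx(0.0, abs=0.6)
        assert eps[0].end == pytest.approx(5.0, abs=0.6)
        assert eps[1].start == pytest.approx(20.0, abs=0.6)
        assert eps[1].end == pytest.approx(24.0, abs=0.6)

    def test_short_quiet_run_excluded(self, rng):
        accel = self._accel(rng, lambda t: (t >= 10.0) & (t < 11.5), 30.0)
        rec = _rec(np.zeros((1, 30000)), 1000.0, accel=accel, accel_fs=self.acc_fs)
        eps = detect_rest_epochs(rec, threshold_percentile=10.0)
        assert all(not (9.0 < e.start < 12.5) or e.duration >= 2.0 for e in eps)
        assert len(eps) == 0

    def test_long_run_split_and_tiled(self, rng):
        accel = self._accel(rng, lambda t: (t >= 5.0) & (t < 19.0), 40.0)
        rec = _rec(np.zeros((1, 40000)), 1000.0, accel=accel, accel_fs=self.acc_fs)
        eps = detect_rest_epochs(rec, threshold_percentile=40.0)
        inside = [e for e in eps if e.start >= 4.0 and e.end <= 20.0]
        assert all(2.0 - 1e-6 <= e.duration <= 10.0 + 1e-6 for e in inside)
        total = sum(e.duration for e in inside)
        assert total == pytest.approx(14.0, abs=1.2)
        windows = detect_rest_epochs(rec, threshold_percentile=40.0).tile(3.0)
        n_inside = sum(1 for e in windows if e.start >= 4.0 and e.end <= 20.0)
        assert n_inside == 4

    def test_flat_accelerometer_warns(self):
        rec = _rec(np.zeros((1, 10000)), 1000.0, accel=np.zeros((3, 1000)), accel_fs=100.0)
        with pytest.warns(UserWarning, match="flat"):
            detect_rest_epochs(rec)

    def test_acc_series_requires_accelerometer(self):
        with pytest.raises(ValueError, match="accelerometer"):
            acc_series(_rec(np.zeros((1, 100)), 1000.0))


class TestBinFiringRate:
    def test_uniform_spikes_give_expected_rate(self):
        st = SpikeTrain({"ch": np.linspace(0.05, 2.95, 30)}, duration=3.0)
        t, r = bin_firing_rate(st, 3.0)
        assert r.tolist() == [10.0]

    def test_empty_train_all_zero(self):
        st = SpikeTrain({"ch": np.array([])}, duration=9.0)
        _, r = bin_firing_rate(st, 3.0)
        assert r.tolist() == [0.0, 0.0, 0.0]

    def test_poisson_rate_recovered(self, rng):
        dur, lam = 100.0, 20.0
        times = np.sort(rng.uniform(0, dur, rng.poisson(lam * dur)))
        times = np.unique(times)
        st = SpikeTrain({"ch": times}, duration=dur)
        _, r = bin_firing_rate(st, 3.0)
        sem = np.sqrt(lam / 3.0) / np.sqrt(r.size)
        assert abs(r.mean() - lam) < 3 * sem

    def test_nonpositive_window_rejected(self):
        st = SpikeTrain({"ch": np.array([0.1])}, duration=1.0)
        with pytest.raises(ValueError):
            bin_firing_rate(st, 0.0)
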