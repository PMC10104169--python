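"""Synthetic two-region sessions with known ground truth.

The generators emulate the statistical structure that the downstream
estimators target, with every effect size under explicit control:

* a prefrontal (mPFC) and a hippocampal (dHPC) LFP sharing a narrowband
  theta component with a controllable inter-regional lag, on a pink (1/f)
  plus white noise background;
* hippocampal gamma whose amplitude is modulated by theta phase with a
  controllable coupling depth (``pac_depth``);
* multi-unit spike trains phase-locked to theta with a von Mises
  concentration ``kappa``;
* scripted novel-object-recognition visit schedules with an accelerometer
  that is quiescent during visits and active between them;
* auditory click-train and flip-flop oddball sessions with embedded
  evoked-response templates and a controllable deviant extra negativity.

Every generator is deterministic given ``GroundTruth.seed`` and ships the
ground-truth record alongside its data (``Recording.meta``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.special import i0

from .core import Epoch, EpochSet, Recording, SpikeTrain

__all__ = [
    "GroundTruth",
    "erp_template",
    "gen_coupled_lfp",
    "gen_phase_locked_spikes",
    "gen_behavior_session",
    "gen_auditory_session",
]

#: von Mises concentrations at or above this are treated as perfect locking
KAPPA_CAP = 50.0


@dataclass
class GroundTruth:
    """Parameters controlling a synthetic session.

    theta_freq / gamma_freq : oscillation centers, Hz
    pac_depth : fraction of gamma amplitude modulated by theta phase, [0, 1]
    lag_ms    : signed mPFC->dHPC delay of the shared theta component
    kappa     : von Mises concentration of spike phase locking (>= 0)
    spike_rate: mean multi-unit rate, Hz
    aep_response_prob : probability a click evokes a response, [0, 1]
    mmn_extra_negativity : extra deviant-tone deflection, microvolts
                           (negative values model mismatch negativity)
    visit_schedule : list of (object_label, start_s, end_s) visit intervals
    """

    theta_freq: float = 8.0
    gamma_freq: float = 60.0
    pac_depth: float = 0.5
    lag_ms: float = 10.0
    kappa: float = 1.0
    spike_rate: float = 20.0
    aep_response_prob: float = 0.8
    mmn_extra_negativity: float = -3.0
    visit_schedule: Sequence[tuple[str, float, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pac_depth <= 1.0:
            raise ValueError("pac_depth must lie in [0, 1]")
        if not 0.0 <= self.aep_response_prob <= 1.0:
            raise ValueError("aep_response_prob must lie in [0, 1]")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        last_end = -np.inf
        for label, s, e in self.visit_schedule:
            if e <= s:
                raise ValueError(f"visit ({label}, {s}, {e}) has non-positive duration")
            if s < last_end:
                raise ValueError("visit schedule intervals must be ordered and non-overlapping")
            last_end = e

    def to_dict(self) -> dict:
        d = asdict(self)
        d["visit_schedule"] = [list(v) for v in self.visit_schedule]
        return d


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """1/f-amplitude noise with the requested standard deviation."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * scale, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _narrowband(rng: np.random.Generator, n: int, fs: float, low: float, high: float, rms: float) -> np.ndarray:
    """Band-limited Gaussian noise, zero-phase filtered, scaled to ``rms``."""
    sos = sps.butter(2, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    s = x.std()
    return x * (rms / s) if s > 0 else x


def _gaussian_band_noise(
    rng: np.random.Generator, n: int, fs: float, center: float, sigma_f: float, rms: float
) -> np.ndarray:
    """Gaussian-spectral-envelope noise centered at ``center`` Hz.

    Used for the gamma carrier: physiological gamma is spectrally broad,
    so its amplitude modulation survives band-limited envelope
    extraction; a brick-wall narrowband carrier would not.
    """
    white = rng.standard_normal(n)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.exp(-0.5 * ((f - center) / sigma_f) ** 2)
    x = np.fft.irfft(np.fft.rfft(white) * shape, n)
    s = x.std()
    return x * (rms / s) if s > 0 else x


def gen_coupled_lfp(
    gt: GroundTruth,
    duration_s: float,
    fs_hz: float = 1000.0,
    *,
    theta_amp_uv: float = 50.0,
    gamma_amp_uv: float = 20.0,
    pink_sd_uv: float = 15.0,
    white_sd_uv: float = 5.0,
    n_channels_per_region: int = 1,
) -> Recording:
    """Two-region LFP with theta-gamma coupling and an inter-regional lag.

    The mPFC trace carries a narrowband theta component; the dHPC trace
    carries the same theta realization delayed by ``gt.lag_ms`` plus a
    gamma oscillation whose envelope follows
    ``(1 - pac_depth) + pac_depth * (1 + cos(theta_phase)) / 2``,
    so ``pac_depth`` is exactly the modulated fraction of gamma amplitude.
    Each region receives independent pink and white background noise.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs_hz < 1000:
        raise ValueError("fs_hz must be at least 1000 Hz")
    max_lag_ms = 1000.0 / (4.0 * gt.theta_freq)
    if abs(gt.lag_ms) > max_lag_ms:
        raise ValueError(
            f"|lag_ms|={abs(gt.lag_ms):g} exceeds a quarter theta cycle "
            f"({max_lag_ms:g} ms at {gt.theta_freq:g} Hz): phase-unwrapping ambiguous"
        )
    rng = np.random.default_rng(gt.seed)
    n = int(round(duration_s * fs_hz))

    th_low = max(gt.theta_freq - 2.0, 1.0)
    theta1 = _narrowband(rng, n, fs_hz, th_low, gt.theta_freq + 2.0, theta_amp_uv / np.sqrt(2))
    lag_samples = int(round(gt.lag_ms * fs_hz / 1000.0))
    theta2 = np.roll(theta1, lag_samples)  # circular shift: exact delay everywhere

    # theta phase of the hippocampal copy drives the gamma envelope
    phase2 = np.angle(sps.hilbert(theta2))
    envelope = (1.0 - gt.pac_depth) + gt.pac_depth * (1.0 + np.cos(phase2)) / 2.0
    carrier = _gaussian_band_noise(rng, n, fs_hz, gt.gamma_freq, 6.0, gamma_amp_uv / np.sqrt(2))
    gamma2 = envelope * carrier

    region1 = theta1 + _pink_noise(rng, n, pink_sd_uv) + rng.standard_normal(n) * white_sd_uv
    region2 = theta2 + gamma2 + _pink_noise(rng, n, pink_sd_uv) + rng.standard_normal(n) * white_sd_uv

    channels, regions, rows = [], {}, []
    for k in range(n_channels_per_region):
        name = f"mPFC_{k}"
        channels.append(name)
        regions[name] = "mPFC"
        extra = rng.standard_normal(n) * white_sd_uv * 0.5 if n_channels_per_region > 1 else 0.0
        rows.append(region1 + extra)
    for k in range(n_channels_per_region):
        name = f"dHPC_{k}"
        channels.append(name)
        regions[name] = "dHPC"
        extra = rng.standard_normal(n) * white_sd_uv * 0.5 if n_channels_per_region > 1 else 0.0
        rows.append(region2 + extra)

    return Recording(
        signals=np.vstack(rows),
        fs=fs_hz,
        channels=channels,
        regions=regions,
        meta={"ground_truth": gt.to_dict(), "kind": "coupled_lfp"},
    )


def gen_phase_locked_spikes(
    gt: GroundTruth,
    lfp: Recording,
    *,
    channel: str | None = None,
    mu: float = 0.0,
) -> SpikeTrain:
    """Inhomogeneous point process locked to the LFP theta phase.

    Spike intensity is ``rate * exp(kappa * cos(phase - mu)) / I0(kappa)``
    so the time-averaged rate equals ``gt.spike_rate`` for any ``kappa``.
    ``kappa >= KAPPA_CAP`` (or ``inf``) is treated as perfect locking:
    one candidate spike exactly at each upward crossing of phase ``mu``,
    thinned to the target mean rate.  Sampled by Poisson thinning.
    """
    if channel is None:
        hp = lfp.region_channels("dHPC")
        channel = hp[0] if hp else list(lfp.channels)[0]
    x = lfp.get_channel(channel)
    fs = lfp.fs
    low = max(gt.theta_freq - 2.0, 1.0)
    sos = sps.butter(4, [low, gt.theta_freq + 2.0], btype="bandpass", fs=fs, output="sos")
    phase = np.angle(sps.hilbert(sps.sosfiltfilt(sos, x)))
    duration = x.size / fs
    rng = np.random.default_rng(np.random.SeedSequence([int(gt.seed), 0x5B1CE]))

    if not np.isfinite(gt.kappa) or gt.kappa >= KAPPA_CAP:
        d = np.mod(phase - mu + np.pi, 2 * np.pi) - np.pi
        crossings = np.where((d[:-1] < 0) & (d[1:] >= 0))[0] + 1
        times = crossings / fs
        target = gt.spike_rate * duration
        if times.size > target:
            keep = np.sort(rng.choice(times.size, size=int(round(target)), replace=False))
            times = times[keep]
    else:
        lam_max = gt.spike_rate * np.exp(gt.kappa) / i0(gt.kappa)
        n_cand = rng.poisson(lam_max * duration)
        cand = np.sort(rng.uniform(0.0, duration, n_cand))
        idx = np.minimum((cand * fs).astype(int), phase.size - 1)
        lam = gt.spike_rate * np.exp(gt.kappa * np.cos(phase[idx] - mu)) / i0(gt.kappa)
        times = cand[rng.uniform(0.0, lam_max, n_cand) < lam]
    times = np.unique(times)
    return SpikeTrain({channel: times}, duration=duration)


def gen_behavior_session(
    gt: GroundTruth,
    *,
    fs_hz: float = 1000.0,
    accel_fs_hz: float = 100.0,
    pad_s: float = 5.0,
) -> tuple[Recording, EpochSet]:
    """Session with a scripted visit schedule and a consistent accelerometer.

    The accelerometer is quiescent (low variance) during visits and
    strongly active between them, so rest detection and visit epochs agree
    by construction.
    """
    if not gt.visit_schedule:
        rec = gen_coupled_lfp(gt, duration_s=pad_s * 2, fs_hz=fs_hz)
        rec.events = pd.DataFrame(columns=["onset_s", "offset_s", "label"])
        return rec, EpochSet([])
    duration = gt.visit_schedule[-1][2] + pad_s
    rec = gen_coupled_lfp(gt, duration_s=duration, fs_hz=fs_hz)
    rng = np.random.default_rng(np.random.SeedSequence([int(gt.seed), 0xBE4A]))

    n_acc = int(round(duration * accel_fs_hz))
    t = np.arange(n_acc) / accel_fs_hz
    accel = rng.standard_normal((3, n_acc)) * 0.02  # quiescent floor, g
    active = np.ones(n_acc, dtype=bool)
    for _, s, e in gt.visit_schedule:
        active &= ~((t >= s) & (t < e))
    # movement bursts between visits: large-amplitude low-frequency sway
    sway = 0.4 * np.sin(2 * np.pi * 2.0 * t + rng.uniform(0, 2 * np.pi, (3, 1)))
    accel[:, active] += sway[:, active] + rng.standard_normal((3, active.sum())) * 0.15
    accel[2] += 1.0  # gravity on z

    events = pd.DataFrame(
        {
            "onset_s": [s for _, s, _ in gt.visit_schedule],
            "offset_s": [e for _, _, e in gt.visit_schedule],
            "label": [lab for lab, _, _ in gt.visit_schedule],
        }
    )
    rec.accel = accel
    rec.accel_fs = accel_fs_hz
    rec.events = events
    epochs = EpochSet([Epoch(s, e, lab) for lab, s, e in gt.visit_schedule])
    return rec, epochs


def erp_template(
    fs: float,
    *,
    duration_ms: float = 400.0,
    p2_amp_uv: float = 8.0,
    p3_amp_uv: float = 6.0,
    p2_center_ms: float = 55.0,
    p3_center_ms: float = 250.0,
    p2_sd_ms: float = 8.0,
    p3_sd_ms: float = 30.0,
) -> np.ndarray:
    """Evoked-response template: Gaussian P2-like and P3-like deflections."""
    t = np.arange(int(round(duration_ms / 1000 * fs))) / fs * 1000.0
    return p2_amp_uv * np.exp(-0.5 * ((t - p2_center_ms) / p2_sd_ms) ** 2) + p3_amp_uv * np.exp(
        -0.5 * ((t - p3_center_ms) / p3_sd_ms) ** 2
    )


def _mmn_pulse(fs: float, amp_uv: float, *, start_ms: float = 60.0, width_ms: float = 100.0) -> np.ndarray:
    """Smooth deflection whose time integral is ``amp_uv * width_ms`` uV*ms."""
    n = int(round((start_ms + width_ms + 20.0) / 1000 * fs))
    t = np.arange(n) / fs * 1000.0
    w = np.zeros(n)
    inside = (t >= start_ms) & (t < start_ms + width_ms)
    w[inside] = sps.windows.tukey(int(inside.sum()), alpha=0.2)
    integral = np.trapezoid(w, dx=1000.0 / fs)  # ms
    if integral > 0:
        w *= width_ms / integral
    return amp_uv * w


def gen_auditory_session(
    gt: GroundTruth,
    protocol: Literal["click_train", "oddball"],
    *,
    fs_hz: float = 1000.0,
    n_clicks: int = 100,
    click_iti_s: float = 10.0,
    n_oddball_trials: int = 1000,
    oddball_iti_s: float = 0.5,
    deviant_fraction: float = 0.25,
    tone_freqs_hz: tuple[float, float] = (6000.0, 8000.0),
    noise_sd_uv: float = 1.5,
    noise_color: Literal["white", "pink"] = "white",
    template_kw: dict | None = None,
) -> tuple[Recording, EpochSet]:
    """Auditory session: click train (AEP) or flip-flop oddball (MMN).

    click_train: ``n_clicks`` onsets ``click_iti_s`` apart; each click is
    followed with probability ``gt.aep_response_prob`` by the evoked
    template.  oddball: ``n_oddball_trials`` tones at ``oddball_iti_s``
    intervals, two frequencies in (1 - deviant_fraction)/deviant_fraction
    proportion, roles swapped halfway (flip-flop); every tone evokes the
    base template and deviant tones additionally carry a deflection of
    ``gt.mmn_extra_negativity`` uV spread over 100 ms.
    """
    if protocol not in ("click_train", "oddball"):
        raise ValueError(f"unknown protocol {protocol!r}")
    rng = np.random.default_rng(np.random.SeedSequence([int(gt.seed), 0xA0D]))
    tkw = template_kw or {}
    template = erp_template(fs_hz, **tkw)

    if protocol == "click_train":
        onset0, iti, n_tr = 5.0, click_iti_s, n_clicks
        duration = onset0 + iti * n_tr
        onsets = onset0 + iti * np.arange(n_tr)
        responded = rng.uniform(size=n_tr) < gt.aep_response_prob
        labels = ["click"] * n_tr
        events = pd.DataFrame({"onset_s": onsets, "offset_s": onsets + 0.015, "label": labels})
        meta_extra = {"responded": responded.astype(int).tolist()}
    else:
        onset0, iti, n_tr = 2.0, oddball_iti_s, n_oddball_trials
        duration = onset0 + iti * n_tr
        onsets = onset0 + iti * np.arange(n_tr)
        half = n_tr // 2
        n_dev = int(round(half * deviant_fraction))
        f_std1, f_dev1 = tone_freqs_hz
        roles, freqs, blocks = [], [], []
        for block, (f_std, f_dev) in enumerate([(f_std1, f_dev1), (f_dev1, f_std1)], start=1):
            r = np.array(["standard"] * (half - n_dev) + ["deviant"] * n_dev)
            rng.shuffle(r)
            roles.extend(r.tolist())
            freqs.extend([f_dev if x == "deviant" else f_std for x in r])
            blocks.extend([block] * half)
        events = pd.DataFrame(
            {
                "onset_s": onsets,
                "offset_s": onsets + 0.010,
                "label": roles,
                "freq_hz": freqs,
                "block": blocks,
            }
        )
        responded = np.ones(n_tr, dtype=bool)
        meta_extra = {}

    n = int(round(duration * fs_hz))
    # white measurement noise by default: the peak-over-baseline AEP
    # detector assumes drift-free trials (1/f drift would need a high-pass
    # before detection; see the methods note)
    if noise_color == "pink":
        x = _pink_noise(rng, n, noise_sd_uv)
    else:
        x = rng.standard_normal(n) * noise_sd_uv
    mmn_pulse = _mmn_pulse(fs_hz, gt.mmn_extra_negativity)
    for k, on in enumerate(onsets):
        i0_ = int(round(on * fs_hz))
        if responded[k]:
            seg = template[: n - i0_]
            x[i0_ : i0_ + seg.size] += seg
        if protocol == "oddball" and events.loc[k, "label"] == "deviant":
            seg = mmn_pulse[: n - i0_]
            x[i0_ : i0_ + seg.size] += seg

    rec = Recording(
        signals=x[None, :],
        fs=fs_hz,
        channels=["mPFC_0"],
        regions={"mPFC_0": "mPFC"},
        events=events,
        meta={"ground_truth": gt.to_dict(), "kind": protocol, **meta_extra},
    )
    epochs = EpochSet(
        [Epoch(float(r.onset_s), float(r.onset_s) + iti, str(r.label)) for r in events.itertuples()],
        allow_overlap=True,
    )
    return rec, epochs
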