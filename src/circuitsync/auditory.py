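"""Auditory evoked potentials (AEP) and mismatch negativity (MMN).

Click-train sessions yield a trial matrix aligned to tone onsets; a trial
counts as responsive when the peak of its (lightly smoothed) deflection
in the detection window exceeds ``k`` baseline standard deviations, and
the response ratio is responsive/total.  Component quantification uses
the P2 (40-70 ms) and P3 (200-300 ms) windows: amplitude from the
trial-averaged waveform, firing rate from 10 ms multi-unit bins.

Oddball sessions use a flip-flop design: two tone frequencies serve as
standard (75%) and deviant (25%), swapping roles halfway through.  The
difference wave is deviant minus standard *of the same physical
frequency* across the two blocks, so frequency-specific response
differences cancel; MMN is the area under the difference wave in the
analysis window (default 40-200 ms), in uV*ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ErpResult",
    "MmnResult",
    "COMPONENT_WINDOWS_MS",
    "epoch_trials",
    "detect_aep",
    "component_metrics",
    "mmn_analysis",
]

COMPONENT_WINDOWS_MS: dict[str, tuple[float, float]] = {"P2": (40.0, 70.0), "P3": (200.0, 300.0)}
DETECT_WINDOW_MS = (10.0, 350.0)
DETECT_K = 3.0
DETECT_SMOOTH_MS = 20.0
MMN_WINDOW_MS = (40.0, 200.0)
RATE_BIN_MS = 10.0


def epoch_trials(
    x: np.ndarray,
    fs: float,
    onsets_s: np.ndarray,
    pre_ms: float = 500.0,
    post_ms: float = 400.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial snippets around stimulus onsets, baseline-corrected.

    Returns ``(trials, t_ms)`` with ``trials`` of shape (n_trials,
    n_samples) and ``t_ms`` spanning ``[-pre_ms, post_ms)``; each trial
    has the mean of its pre-stimulus window subtracted.  Trials extending
    past the recording are dropped with a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    pre = int(round(pre_ms / 1000.0 * fs))
    post = int(round(post_ms / 1000.0 * fs))
    rows = []
    dropped = 0
    for on in np.asarray(onsets_s, dtype=float):
        i = int(round(on * fs))
        if i - pre < 0 or i + post > x.size:
            dropped += 1
            continue
        seg = x[i - pre : i + post].copy()
        seg -= seg[:pre].mean() if pre else 0.0
        rows.append(seg)
    if dropped:
        warnings.warn(f"{dropped} trial(s) extended past the recording and were dropped", stacklevel=2)
    if not rows:
        raise ValueError("no complete trials")
    t_ms = (np.arange(-pre, post) / fs) * 1000.0
    return np.vstack(rows), t_ms


def _smooth(trials: np.ndarray, fs: float, smooth_ms: float) -> np.ndarray:
    w = max(int(round(smooth_ms / 1000.0 * fs)), 1)
    if w == 1:
        return trials
    kernel = np.ones(w) / w
    return np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, trials)


def detect_aep(
    trials: np.ndarray,
    t_ms: np.ndarray,
    *,
    k: float = DETECT_K,
    window_ms: tuple[float, float] = DETECT_WINDOW_MS,
    smooth_ms: float = DETECT_SMOOTH_MS,
    fs: float | None = None,
) -> tuple[np.ndarray, float]:
    """Per-trial evoked-response detection and the response ratio.

    A trial is responsive when the peak absolute value of its smoothed
    trace inside ``window_ms`` exceeds ``k`` standard deviations of the
    raw (unsmoothed) pre-stimulus baseline.  Smoothing (a ``smooth_ms``
    boxcar, roughly matched to the sharpest evoked component) estimates
    the evoked peak robustly; the baseline SD is deliberately taken on
    the raw samples — the extreme value of a 300+ ms noise window always
    reaches ~3 SD of its own smoothed trace, so an evoked response is
    only called when a sustained deflection rivals the raw sample
    variability, which is how evoked potentials are judged by eye.
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    if fs is None:
        fs = 1000.0 / (t_ms[1] - t_ms[0])
    sm = _smooth(trials, fs, smooth_ms)
    base = trials[:, t_ms < 0.0]
    if base.shape[1] < 2:
        raise ValueError("no pre-stimulus baseline samples")
    sd = base.std(axis=1)
    if (sd == 0.0).any():
        raise ValueError("zero-variance baseline in at least one trial")
    win = (t_ms >= window_ms[0]) & (t_ms < window_ms[1])
    peak = np.abs(sm[:, win]).max(axis=1)
    responsive = peak > k * sd
    return responsive, float(responsive.mean())


def component_metrics(
    trials: np.ndarray,
    t_ms: np.ndarray,
    component: str,
    *,
    spike_times_s: np.ndarray | None = None,
    onsets_s: np.ndarray | None = None,
    rate_bin_ms: float = RATE_BIN_MS,
) -> tuple[float, float]:
    """(amplitude uV, firing rate Hz) for an ERP component window.

    Amplitude is baseline-to-peak on the trial-averaged waveform inside
    the component window.  Firing rate is the mean multi-unit rate over
    ``rate_bin_ms`` bins in the window across trials; with no spike train
    the rate is 0.
    """
    if component not in COMPONENT_WINDOWS_MS:
        raise ValueError(f"component must be one of {sorted(COMPONENT_WINDOWS_MS)}")
    lo, hi = COMPONENT_WINDOWS_MS[component]
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    mean_erp = trials.mean(axis=0)
    base = mean_erp[t_ms < 0.0].mean() if (t_ms < 0.0).any() else 0.0
    win = (t_ms >= lo) & (t_ms < hi)
    if not win.any():
        raise ValueError(f"component window {lo}-{hi} ms outside the trial span")
    amplitude = float(mean_erp[win].max() - base)

    rate = 0.0
    if spike_times_s is not None and onsets_s is not None and len(onsets_s):
        spike_times_s = np.asarray(spike_times_s, dtype=float)
        edges_ms = np.arange(lo, hi + 1e-9, rate_bin_ms)
        counts = np.zeros(edges_ms.size - 1)
        for on in onsets_s:
            rel = (spike_times_s - on) * 1000.0
            counts += np.histogram(rel, bins=edges_ms)[0]
        rate = float(counts.sum() / len(onsets_s) / ((hi - lo) / 1000.0))
    return amplitude, rate


@dataclass
class ErpResult:
    """Trial-aligned evoked-response summary for a click-train session."""

    trials: np.ndarray
    t_ms: np.ndarray
    mean_erp: np.ndarray
    responsive: np.ndarray
    response_ratio: float
    components: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_session(
        cls,
        x: np.ndarray,
        fs: float,
        onsets_s: np.ndarray,
        *,
        spike_times_s: np.ndarray | None = None,
        pre_ms: float = 500.0,
        post_ms: float = 400.0,
        k: float = DETECT_K,
        window_ms: tuple[float, float] = DETECT_WINDOW_MS,
        smooth_ms: float = DETECT_SMOOTH_MS,
    ) -> "ErpResult":
        trials, t_ms = epoch_trials(x, fs, onsets_s, pre_ms, post_ms)
        responsive, ratio = detect_aep(trials, t_ms, k=k, window_ms=window_ms, smooth_ms=smooth_ms, fs=fs)
        comps = {}
        for name in COMPONENT_WINDOWS_MS:
            amp, rate = component_metrics(
                trials, t_ms, name, spike_times_s=spike_times_s, onsets_s=onsets_s
            )
            comps[name] = {"amplitude_uv": amp, "firing_rate_hz": rate, "window_ms": COMPONENT_WINDOWS_MS[name]}
        return cls(
            trials=trials,
            t_ms=t_ms,
            mean_erp=trials.mean(axis=0),
            responsive=responsive,
            response_ratio=ratio,
            components=comps,
        )


@dataclass
class MmnResult:
    """Flip-flop oddball result, one entry per target-frequent combination.

    ``combinations`` maps a label like ``"6000Hz-target"`` to standard /
    deviant mean ERPs, the difference wave (deviant - standard of the
    same physical frequency) and its area under the curve in uV*ms.
    """

    t_ms: np.ndarray
    combinations: dict[str, dict]
    auc_window_ms: tuple[float, float]

    def auc(self, combination: str) -> float:
        return self.combinations[combination]["auc_uv_ms"]


def mmn_analysis(
    x: np.ndarray,
    fs: float,
    events: pd.DataFrame,
    *,
    pre_ms: float = 100.0,
    post_ms: float = 400.0,
    auc_window_ms: tuple[float, float] = MMN_WINDOW_MS,
) -> MmnResult:
    """Frequency-matched deviant-minus-standard analysis of an oddball run.

    ``events`` needs onset_s, label (standard/deviant), freq_hz and block
    columns.  For each physical tone frequency, deviant trials (from the
    block where it is rare) are averaged against standard trials of the
    same frequency (from the other block); comparisons are never made
    across frequencies.  A frequency missing either role yields a partial
    result with a warning.
    """
    required = {"onset_s", "label", "freq_hz", "block"}
    if not required.issubset(events.columns):
        raise ValueError(f"events table must have columns {sorted(required)}")
    combos: dict[str, dict] = {}
    t_ms_out: np.ndarray | None = None
    for freq in sorted(events["freq_hz"].unique()):
        dev = events[(events["freq_hz"] == freq) & (events["label"] == "deviant")]
        std = events[(events["freq_hz"] == freq) & (events["label"] == "standard")]
        if dev.empty or std.empty:
            warnings.warn(f"{freq:g} Hz lacks a deviant or standard block; combination skipped", stacklevel=2)
            continue
        dev_trials, t_ms = epoch_trials(x, fs, dev["onset_s"].to_numpy(), pre_ms, post_ms)
        std_trials, _ = epoch_trials(x, fs, std["onset_s"].to_numpy(), pre_ms, post_ms)
        t_ms_out = t_ms
        dev_erp = dev_trials.mean(axis=0)
        std_erp = std_trials.mean(axis=0)
        diff = dev_erp - std_erp
        win = (t_ms >= auc_window_ms[0]) & (t_ms < auc_window_ms[1])
        auc = float(np.trapezoid(diff[win], t_ms[win]))
        dev_block = int(dev["block"].iloc[0])
        combos[f"{freq:g}Hz-target"] = {
            "standard_erp": std_erp,
            "deviant_erp": dev_erp,
            "difference_wave": diff,
            "auc_uv_ms": auc,
            "n_deviant": len(dev),
            "n_standard": len(std),
            "deviant_block": dev_block,
        }
    if t_ms_out is None:
        raise ValueError("no analyzable target-frequent combination in the event table")
    return MmnResult(t_ms=t_ms_out, combinations=combos, auc_window_ms=auc_window_ms)
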