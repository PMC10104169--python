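"""Raw recording -> LFP, multi-unit spike trains, rates, rest epochs.

LFP extraction follows the standard offline chain: linear detrend, mains
notch, anti-aliased decimation to 1 kHz.  Multi-unit activity (MUA) is
extracted per channel after subtracting a nearby reference channel,
band-passing 450-6,000 Hz, and thresholding at -3 robust standard
deviations.  Rest (quiet alertness) epochs are detected from the variance
of the instantaneous acceleration module, keeping contiguous low-mobility
runs of 2-10 s.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .core import Epoch, EpochSet, LfpSignal, Recording, SpikeTrain

__all__ = [
    "extract_lfp",
    "extract_mua",
    "detect_rest_epochs",
    "bin_firing_rate",
    "robust_sigma",
    "acc_series",
]


def _decimate_to(x: np.ndarray, fs: float, target_fs: float) -> tuple[np.ndarray, float]:
    """Anti-aliased decimation, in stages of factor <= 10."""
    ratio = fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9:
        warnings.warn(
            f"fs={fs:g} is not an integer multiple of {target_fs:g} Hz; using polyphase resampling",
            stacklevel=3,
        )
        from math import gcd

        up, down = int(round(target_fs)), int(round(fs))
        g = gcd(up, down)
        return sps.resample_poly(x, up // g, down // g, axis=-1), target_fs
    factor = int(round(ratio))
    while factor > 1:
        step = factor
        while step > 10:  # decimate in modest stages to keep FIR orders small
            for cand in range(10, 1, -1):
                if factor % cand == 0:
                    step = cand
                    break
            else:
                step = factor
                break
        x = sps.decimate(x, step, ftype="fir", zero_phase=True, axis=-1)
        factor //= step
    return x, target_fs


def extract_lfp(
    rec: Recording,
    *,
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
    target_fs: float = 1000.0,
) -> LfpSignal:
    """Detrend, notch-filter and decimate a raw recording to the LFP band.

    The notch is a second-order IIR (quality ``notch_q``) applied
    zero-phase at the original rate; decimation uses zero-phase FIR
    anti-aliasing in stages of at most 10x (flat passband, so analysis
    bands below 200 Hz keep their power).
    """
    if rec.fs < target_fs:
        raise ValueError(f"recording fs {rec.fs:g} below LFP target {target_fs:g}")
    x = sps.detrend(rec.signals, axis=-1, type="linear")
    if notch_hz:
        b, a = sps.iirnotch(notch_hz, notch_q, fs=rec.fs)
        x = sps.filtfilt(b, a, x, axis=-1)
    if rec.fs != target_fs:
        x, fs = _decimate_to(x, rec.fs, target_fs)
    else:
        fs = rec.fs
    return LfpSignal(
        signals=x,
        fs=fs,
        channels=list(rec.channels),
        regions=dict(rec.regions),
        provenance={
            "source_fs": rec.fs,
            "notch_hz": notch_hz,
            "notch_q": notch_q,
            "detrend": "linear",
            "decimation": "scipy.signal.decimate (FIR, zero-phase)",
        },
    )


def robust_sigma(x: np.ndarray) -> float:
    """Noise SD estimate robust to spikes: median(|x|) / 0.6745."""
    return float(np.median(np.abs(x)) / 0.6745)


def extract_mua(
    rec: Recording,
    channel: str,
    reference_channel: str,
    *,
    band_hz: tuple[float, float] = (450.0, 6000.0),
    threshold_sigma: float = 3.0,
    lockout_ms: float = 1.0,
) -> SpikeTrain:
    """Threshold-crossing multi-unit spike times for one channel.

    The reference channel is subtracted to cancel common-mode movement
    artifacts, the difference is band-passed (zero-phase Butterworth),
    and downward crossings of ``-threshold_sigma * robust SD`` are taken
    as spikes, with a refractory lockout to avoid double counting one
    waveform.  The spike time is the sample of the crossing onset.
    """
    if channel == reference_channel:
        raise ValueError("reference channel must differ from the target channel")
    nyq_needed = 2 * band_hz[1]
    if rec.fs < nyq_needed:
        raise ValueError(f"fs {rec.fs:g} Hz too low for a {band_hz[1]:g} Hz band edge")
    x = rec.get_channel(channel) - rec.get_channel(reference_channel)
    sos = sps.butter(4, band_hz, btype="bandpass", fs=rec.fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    sigma = robust_sigma(y)
    thr = -threshold_sigma * sigma
    below = y < thr
    onsets = np.where(below[1:] & ~below[:-1])[0] + 1
    if below.size and below[0]:
        onsets = np.concatenate([[0], onsets])
    lock = int(round(lockout_ms / 1000.0 * rec.fs))
    kept = []
    last = -np.inf
    for i in onsets:
        if i - last >= lock:
            kept.append(i)
            last = i
    times = np.asarray(kept, dtype=float) / rec.fs
    return SpikeTrain({channel: times}, threshold_sigma=threshold_sigma, duration=rec.duration)


def acc_series(
    rec: Recording,
    *,
    window_s: float = 0.5,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window variance of the instantaneous acceleration module.

    Returns (window center times, ACC values) where ACC is the variance of
    sqrt(X^2 + Y^2 + Z^2) in windows of ``window_s`` with the given
    fractional overlap.
    """
    if rec.accel is None:
        raise ValueError("recording has no accelerometer")
    mod = np.sqrt((np.asarray(rec.accel, dtype=float) ** 2).sum(axis=0))
    fs = rec.accel_fs or rec.fs
    win = max(int(round(window_s * fs)), 2)
    step = max(int(round(win * (1.0 - overlap))), 1)
    starts = np.arange(0, mod.size - win + 1, step)
    acc = np.array([mod[s : s + win].var() for s in starts])
    centers = (starts + win / 2.0) / fs
    return centers, acc


def detect_rest_epochs(
    rec: Recording,
    *,
    window_s: float = 0.5,
    overlap: float = 0.5,
    threshold_percentile: float = 20.0,
    threshold: float | None = None,
    min_s: float = 2.0,
    max_s: float = 10.0,
) -> EpochSet:
    """Low-mobility (quiet alertness) epochs from the accelerometer.

    Contiguous sub-threshold runs shorter than ``min_s`` are discarded;
    runs longer than ``max_s`` are split into segments of at most
    ``max_s`` (a trailing remainder >= ``min_s`` is kept).  The threshold
    defaults to the ``threshold_percentile``-th percentile of the session
    ACC distribution.
    """
    centers, acc = acc_series(rec, window_s=window_s, overlap=overlap)
    if np.allclose(acc, 0.0):
        warnings.warn("accelerometer is flat; the whole session scores as rest", stacklevel=2)
    thr = float(np.percentile(acc, threshold_percentile)) if threshold is None else threshold
    quiet = acc <= thr
    step_s = centers[1] - centers[0] if centers.size > 1 else window_s
    epochs: list[Epoch] = []
    i = 0
    while i < quiet.size:
        if not quiet[i]:
            i += 1
            continue
        j = i
        while j < quiet.size and quiet[j]:
            j += 1
        start = centers[i] - window_s / 2.0
        end = centers[j - 1] + window_s / 2.0
        i = j
        run = end - start
        if run < min_s - 1e-9:
            continue
        s = start
        while end - s > max_s + 1e-9:
            epochs.append(Epoch(s, s + max_s, "rest"))
            s += max_s
        if end - s >= min_s - 1e-9:
            epochs.append(Epoch(s, end, "rest"))
    return EpochSet(epochs)


def bin_firing_rate(
    st: SpikeTrain,
    window_s: float,
    *,
    duration: float | None = None,
    t_start: float = 0.0,
    channel: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Firing rate in non-overlapping windows: counts / window length.

    Returns (window start times, rates in Hz).  With multiple channels the
    rate is summed across channels (multi-unit convention).
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    chans = [channel] if channel is not None else st.channels()
    if duration is None:
        duration = st.duration
    if duration is None:
        duration = max((st[c][-1] for c in chans if st[c].size), default=t_start)
    n_win = int(np.floor((duration - t_start) / window_s + 1e-9))
    edges = t_start + window_s * np.arange(n_win + 1)
    counts = np.zeros(n_win)
    for c in chans:
        counts += np.histogram(st[c], bins=edges)[0]
    return edges[:-1], counts / window_s
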