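"""Multitaper spectra, spectrograms and band-power quantification.

The band scheme used throughout: delta 2-5, slow theta 4-8, theta 8-12,
low gamma 30-48, high gamma 52-100, HFO 100-200 Hz.  The slow-theta and
theta bands deliberately share the 8 Hz edge; half-open integration
``[low, high)`` keeps every other pair disjoint.  A "theta 4-12"
aggregate (slow theta + theta) is available as ``broad_theta``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import EpochSet, LfpSignal

__all__ = ["BandScheme", "PowerSpectrum", "multitaper_psd", "spectrogram", "band_power"]

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (2.0, 5.0),
    "slow_theta": (4.0, 8.0),
    "theta": (8.0, 12.0),
    "broad_theta": (4.0, 12.0),
    "low_gamma": (30.0, 48.0),
    "high_gamma": (52.0, 100.0),
    "hfo": (100.0, 200.0),
}


@dataclass(frozen=True)
class BandScheme:
    """Named frequency bands (Hz)."""

    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BANDS))

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name!r}: low must be below high")

    def __getitem__(self, name: str) -> tuple[float, float]:
        if name not in self.bands:
            raise KeyError(f"unknown band {name!r}; known: {sorted(self.bands)}")
        return self.bands[name]

    def names(self) -> list[str]:
        return list(self.bands)


@dataclass
class PowerSpectrum:
    """One-sided PSD per channel with method metadata.

    psd has shape (n_channels, n_freqs) in uV^2/Hz; integrating the PSD
    over frequency recovers signal variance (Parseval).
    """

    freqs: np.ndarray
    psd: np.ndarray
    channels: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.psd = np.atleast_2d(self.psd)
        if (self.psd < 0).any():
            raise ValueError("PSD must be non-negative")
        if (np.diff(self.freqs) <= 0).any():
            raise ValueError("frequencies must be ascending")

    def channel(self, name: str) -> np.ndarray:
        return self.psd[self.channels.index(name)]


def _mt_psd_1d(x: np.ndarray, fs: float, nw: float, n_tapers: int, nfft: int) -> np.ndarray:
    tapers = sps.windows.dpss(x.size, nw, Kmax=n_tapers)
    tapers = tapers / np.sqrt((tapers**2).sum(axis=1, keepdims=True))
    spec = np.fft.rfft(tapers * x[None, :], n=nfft, axis=1)
    psd = (np.abs(spec) ** 2).mean(axis=0) / fs
    # one-sided: double everything except DC (and Nyquist for even nfft)
    psd[1:] *= 2.0
    if nfft % 2 == 0:
        psd[-1] /= 2.0
    return psd


def multitaper_psd(
    lfp: LfpSignal,
    epochs: EpochSet | None = None,
    *,
    nw: float = 3.0,
    n_tapers: int = 5,
    nfft: int | None = None,
) -> PowerSpectrum:
    """Epoch-averaged multitaper (DPSS) power spectral density.

    Each epoch is tapered with ``n_tapers`` Slepian sequences of
    time-bandwidth ``nw``, periodograms are averaged across tapers and
    epochs on a common ``nfft`` grid.  Epochs shorter than 1 s are skipped
    with a warning (too few cycles for the analysis bands).
    """
    fs = lfp.fs
    if epochs is None or len(epochs) == 0:
        segs = [lfp.signals]
    else:
        segs = []
        for e in epochs:
            seg = lfp.slice(e.start, e.end)
            if seg.shape[1] < fs:  # < 1 s
                warnings.warn(f"epoch [{e.start:g},{e.end:g}) shorter than 1 s; skipped", stacklevel=2)
                continue
            segs.append(seg)
        if not segs:
            raise ValueError("no epoch long enough for spectral analysis")
    if nfft is None:
        nfft = max(int(2 ** np.ceil(np.log2(max(s.shape[1] for s in segs)))), 1024)
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    acc = np.zeros((lfp.signals.shape[0], freqs.size))
    for seg in segs:
        for c in range(seg.shape[0]):
            acc[c] += _mt_psd_1d(seg[c], fs, nw, n_tapers, nfft)
    acc /= len(segs)
    return PowerSpectrum(
        freqs=freqs,
        psd=acc,
        channels=list(lfp.channels),
        metadata={
            "method": "multitaper (DPSS)",
            "nw": nw,
            "n_tapers": n_tapers,
            "nfft": nfft,
            "n_epochs": len(segs),
            "resolution_hz": fs / nfft,
        },
    )


def spectrogram(
    lfp: LfpSignal,
    window_s: float = 1.0,
    step_s: float | None = None,
    *,
    channel: str | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Consecutive short-time Fourier power: (freqs, times, Sxx).

    ``step_s`` defaults to ``window_s`` (non-overlapping consecutive
    transforms); pass a smaller step for overlap.
    """
    x = lfp.get_channel(channel) if channel is not None else lfp.signals[0]
    nper = int(round(window_s * lfp.fs))
    step = int(round((step_s if step_s is not None else window_s) * lfp.fs))
    noverlap = max(nper - step, 0)
    f, t, sxx = sps.spectrogram(x, fs=lfp.fs, nperseg=nper, noverlap=noverlap, window="hann", scaling="density")
    return f, t, sxx


def band_power(ps: PowerSpectrum, scheme: BandScheme, band_name: str, *, channel: str | None = None) -> float | np.ndarray:
    """Integrated PSD over the half-open band ``[low, high)``, uV^2.

    Trapezoidal integration on the discrete frequency grid restricted to
    grid points inside the band.
    """
    lo, hi = scheme[band_name]
    if lo < ps.freqs[0] - 1e-9 or hi > ps.freqs[-1] + 1e-9:
        raise ValueError(f"band {band_name!r} ({lo}-{hi} Hz) outside spectrum range")
    mask = (ps.freqs >= lo) & (ps.freqs < hi)
    if mask.sum() < 2:
        raise ValueError(f"band {band_name!r} covers fewer than 2 frequency bins")
    vals = np.trapezoid(ps.psd[:, mask], ps.freqs[mask], axis=1)
    if channel is not None:
        return float(vals[ps.channels.index(channel)])
    return vals if vals.size > 1 else float(vals[0])
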