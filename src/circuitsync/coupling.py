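"""Theta-gamma phase-amplitude coupling via the entropy modulation index.

The modulation index (MI) bins the instantaneous amplitude of a fast
oscillation by the instantaneous phase of a slow one, normalizes the
binned mean amplitudes to a distribution P, and reports the normalized
Kullback-Leibler divergence of P from uniform:

    MI = (log N - H(P)) / log N,    H(P) = -sum p_j log p_j

so MI = 0 for phase-independent amplitude and MI = 1 when all amplitude
concentrates in a single phase bin.  Comodulograms scan a grid of phase
frequencies 0-15 Hz (1 Hz step, 4 Hz bandwidth) against amplitude
frequencies 10-250 Hz (5 Hz step, 10 Hz bandwidth); phase bands whose
lower edge would fall below 1 Hz are clipped there, so the effective
phase grid starts at 2 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "Comodulogram",
    "bandpass",
    "instantaneous_phase",
    "amplitude_envelope",
    "modulation_index",
    "comodulogram",
    "interregional_pac",
    "pac_quantify",
]

N_PHASE_BINS = 18
PHASE_GRID_HZ = np.arange(2.0, 16.0, 1.0)  # centers; 4 Hz bandwidth
AMP_GRID_HZ = np.arange(10.0, 251.0, 5.0)  # centers; 10 Hz bandwidth
MIN_BAND_EDGE_HZ = 1.0


def bandpass(x: np.ndarray, fs: float, low: float, high: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass."""
    if high >= fs / 2:
        raise ValueError(f"band edge {high:g} Hz at or above Nyquist ({fs / 2:g} Hz)")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    return np.angle(sps.hilbert(x))


def amplitude_envelope(x: np.ndarray) -> np.ndarray:
    return np.abs(sps.hilbert(x))


def _mi_from_phase_amp(phase: np.ndarray, amp: np.ndarray, n_bins: int) -> float:
    bins = np.floor((phase + np.pi) / (2 * np.pi) * n_bins).astype(int)
    np.clip(bins, 0, n_bins - 1, out=bins)
    sums = np.bincount(bins, weights=amp, minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    total = means.sum()
    if total <= 0:
        raise ValueError("amplitude envelope is zero everywhere; MI undefined")
    p = means / total
    nz = p > 0
    entropy = float(-(p[nz] * np.log(p[nz])).sum())
    return (np.log(n_bins) - entropy) / np.log(n_bins)


def modulation_index(
    phase_signal: np.ndarray,
    amp_signal: np.ndarray,
    fs: float,
    phase_band: tuple[float, float],
    amp_band: tuple[float, float],
    n_bins: int = N_PHASE_BINS,
) -> float:
    """Entropy-based modulation index between two (possibly equal) signals.

    Both signals are zero-phase band-passed; phase comes from the analytic
    signal of ``phase_signal``, amplitude from the envelope of
    ``amp_signal``.
    """
    if phase_signal.shape != amp_signal.shape:
        raise ValueError("phase and amplitude signals must have equal length")
    phase = instantaneous_phase(bandpass(phase_signal, fs, *phase_band))
    amp = amplitude_envelope(bandpass(amp_signal, fs, *amp_band))
    return _mi_from_phase_amp(phase, amp, n_bins)


@dataclass
class Comodulogram:
    """Modulation-index matrix over (phase frequency x amplitude frequency).

    ``mi[i, j]`` couples phase band centered at ``phase_freqs[i]`` with
    amplitude band centered at ``amp_freqs[j]``.
    """

    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    mi: np.ndarray
    phase_source: str = ""
    amp_source: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mi.shape != (self.phase_freqs.size, self.amp_freqs.size):
            raise ValueError("MI matrix shape does not match frequency grids")
        if ((self.mi < -1e-12) | (self.mi > 1 + 1e-12)).any():
            raise ValueError("MI values must lie in [0, 1]")

    def peak(self) -> tuple[float, float, float]:
        """(phase_freq, amp_freq, mi) at the global maximum."""
        i, j = np.unravel_index(int(np.argmax(self.mi)), self.mi.shape)
        return float(self.phase_freqs[i]), float(self.amp_freqs[j]), float(self.mi[i, j])

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.mi, index=self.phase_freqs, columns=self.amp_freqs).to_csv(path)


def comodulogram(
    phase_lfp: np.ndarray,
    amp_lfp: np.ndarray,
    fs: float,
    *,
    phase_freqs: np.ndarray = PHASE_GRID_HZ,
    amp_freqs: np.ndarray = AMP_GRID_HZ,
    phase_bw: float = 4.0,
    amp_bw: float = 10.0,
    n_bins: int = N_PHASE_BINS,
    phase_source: str = "",
    amp_source: str = "",
) -> Comodulogram:
    """Full MI grid; >= 25 s of signal recommended for stable estimates.

    Phase bands are ``center +- phase_bw/2`` (lower edges clipped at
    1 Hz), amplitude bands ``center +- amp_bw/2``; bands reaching Nyquist
    are dropped from the grid.
    """
    if phase_lfp.shape != amp_lfp.shape:
        raise ValueError("phase and amplitude signals must have equal length")
    nyq = fs / 2.0
    amp_freqs = np.asarray([f for f in amp_freqs if f + amp_bw / 2 < nyq])
    phase_freqs = np.asarray([f for f in phase_freqs if f + phase_bw / 2 < nyq])

    phases = []
    for pc in phase_freqs:
        lo = max(pc - phase_bw / 2, MIN_BAND_EDGE_HZ)
        phases.append(instantaneous_phase(bandpass(phase_lfp, fs, lo, pc + phase_bw / 2)))
    amps = []
    for ac in amp_freqs:
        lo = max(ac - amp_bw / 2, MIN_BAND_EDGE_HZ)
        amps.append(amplitude_envelope(bandpass(amp_lfp, fs, lo, ac + amp_bw / 2)))

    mi = np.empty((phase_freqs.size, amp_freqs.size))
    for i, ph in enumerate(phases):
        for j, am in enumerate(amps):
            mi[i, j] = _mi_from_phase_amp(ph, am, n_bins)
    return Comodulogram(
        phase_freqs=phase_freqs,
        amp_freqs=amp_freqs,
        mi=mi,
        phase_source=phase_source,
        amp_source=amp_source,
        metadata={"phase_bw": phase_bw, "amp_bw": amp_bw, "n_bins": n_bins, "fs": fs},
    )


def interregional_pac(
    lfp_phase_region: np.ndarray,
    lfp_amp_region: np.ndarray,
    fs: float,
    *,
    phase_source: str = "mPFC",
    amp_source: str = "dHPC",
    **kwargs,
) -> Comodulogram:
    """Comodulogram with phase from one region, amplitude from the other.

    Directional by construction: phase(mPFC)-amplitude(dHPC) generally
    differs from phase(dHPC)-amplitude(mPFC).
    """
    if lfp_phase_region.shape != lfp_amp_region.shape:
        raise ValueError("regions must provide simultaneous, equal-length signals")
    return comodulogram(
        lfp_phase_region,
        lfp_amp_region,
        fs,
        phase_source=phase_source,
        amp_source=amp_source,
        **kwargs,
    )


def pac_quantify(
    cm: Comodulogram,
    phase_range_hz: tuple[float, float],
    amp_range_hz: tuple[float, float],
) -> float:
    """Mean MI over the grid points whose centers fall in both ranges.

    The quantification window (e.g. 6-10 Hz phase with 40-60 Hz amplitude)
    is always an explicit argument: different analyses select different
    comodulogram regions of interest.
    """
    pm = (cm.phase_freqs >= phase_range_hz[0]) & (cm.phase_freqs <= phase_range_hz[1])
    am = (cm.amp_freqs >= amp_range_hz[0]) & (cm.amp_freqs <= amp_range_hz[1])
    if not pm.any() or not am.any():
        raise ValueError("quantification ranges do not intersect the comodulogram grid")
    return float(cm.mi[np.ix_(pm, am)].mean())
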