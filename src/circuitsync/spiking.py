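"""Spike-field coupling via pairwise phase consistency (PPC).

PPC is the average cosine of all pairwise differences between spike
phases,

    PPC = 2 / (N (N - 1)) * sum_{i<j} cos(theta_i - theta_j)
        = ((N * Rbar)^2 - N) / (N (N - 1))

where ``Rbar`` is the resultant length.  Unlike the squared resultant it
is unbiased in the number of spikes, which is why epochs are only
required to clear a minimum spike count (>= 250 spikes per 25 s epoch)
rather than be count-matched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EpochSet, LfpSignal, SpikeTrain
from .coupling import bandpass, instantaneous_phase

__all__ = ["PpcResult", "spike_phases", "ppc", "ppc_by_epochs"]

MIN_SPIKES_PER_EPOCH = 250
PPC_EPOCH_S = 25.0


def spike_phases(
    st: SpikeTrain,
    lfp: LfpSignal,
    band: tuple[float, float],
    *,
    channel: str | None = None,
    lfp_channel: str | None = None,
) -> np.ndarray:
    """Band phase of the LFP at each spike time (radians, (-pi, pi]).

    The LFP is zero-phase band-passed, its analytic-signal phase is
    unwrapped and linearly interpolated at the spike times, then wrapped
    back — interpolation between wrapped samples would corrupt phases at
    the -pi/pi seam.
    """
    if band[1] >= lfp.fs / 2:
        raise ValueError(f"band edge {band[1]:g} Hz at or above Nyquist")
    if channel is None:
        channel = st.channels()[0]
    x = lfp.get_channel(lfp_channel) if lfp_channel is not None else lfp.signals[0]
    phase = np.unwrap(instantaneous_phase(bandpass(x, lfp.fs, *band)))
    t = st[channel]
    if t.size and (t[0] < 0 or t[-1] > lfp.duration + 1e-9):
        raise ValueError("spike times fall outside the LFP time range")
    sample_t = np.arange(x.size) / lfp.fs
    interp = np.interp(t, sample_t, phase)
    return np.angle(np.exp(1j * interp))


def ppc(phases: np.ndarray) -> float:
    """Pairwise phase consistency of a set of phases.

    Computed through the algebraic identity with the resultant length,
    O(N) instead of the O(N^2) pairwise sum.
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n < 2:
        raise ValueError("PPC needs at least 2 phases")
    c = np.cos(phases).sum()
    s = np.sin(phases).sum()
    return float((c * c + s * s - n) / (n * (n - 1)))


@dataclass
class PpcResult:
    band: tuple[float, float]
    ppc: float
    n_spikes: int
    epoch_id: int
    start_s: float
    end_s: float


def ppc_by_epochs(
    st: SpikeTrain,
    lfp: LfpSignal,
    band: tuple[float, float],
    *,
    epochs: EpochSet | None = None,
    epoch_s: float = PPC_EPOCH_S,
    min_spikes: int = MIN_SPIKES_PER_EPOCH,
    channel: str | None = None,
    lfp_channel: str | None = None,
) -> list[PpcResult]:
    """PPC per analysis epoch, skipping epochs with too few spikes.

    Epochs default to consecutive non-overlapping ``epoch_s`` windows over
    the whole recording; pass rest epochs to restrict to quiet alertness
    (each rest epoch is tiled into ``epoch_s`` windows first when longer).
    """
    if channel is None:
        channel = st.channels()[0]
    phases_all = spike_phases(st, lfp, band, channel=channel, lfp_channel=lfp_channel)
    times = st[channel]
    if epochs is None:
        n_win = int(lfp.duration // epoch_s)
        windows = [(k * epoch_s, (k + 1) * epoch_s) for k in range(n_win)]
    else:
        tiled = epochs.tile(epoch_s) if any(e.duration > epoch_s for e in epochs) else epochs
        windows = [(e.start, e.end) for e in tiled]
    out: list[PpcResult] = []
    for k, (s, e) in enumerate(windows):
        mask = (times >= s) & (times < e)
        n = int(mask.sum())
        if n < min_spikes:
            continue
        out.append(PpcResult(band=tuple(band), ppc=ppc(phases_all[mask]), n_spikes=n, epoch_id=k, start_s=s, end_s=e))
    return out
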