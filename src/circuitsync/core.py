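"""Core data containers and on-disk formats.

A session is stored as a flat binary int16 file plus a JSON sidecar
(sampling rate, channel names, region map, scale in microvolt per bit),
an accelerometer binary of the same layout, and an event table CSV with
columns ``onset_s, offset_s, label`` (plus optional extra columns such as
``freq_hz`` / ``block`` for auditory sessions).  All intervals in the
package are half-open ``[start, end)`` in seconds from recording start.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "LfpSignal",
    "SpikeTrain",
    "Epoch",
    "EpochSet",
    "read_recording",
]


@dataclass(frozen=True)
class Epoch:
    """Half-open labeled interval, times in seconds."""

    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"epoch must satisfy start < end, got [{self.start}, {self.end})")
        if not self.label:
            raise ValueError("epoch label must be non-empty")

    @property
    def duration(self) -> float:
        return self.end - self.start


class EpochSet:
    """Ordered collection of labeled half-open intervals.

    Intervals may belong to different labels; overlap is allowed only when
    explicitly requested (e.g. analysis windows tiled over rest periods
    never overlap, behavioral visits never overlap by construction).
    """

    def __init__(self, epochs: Iterable[Epoch] = (), *, allow_overlap: bool = False):
        self.epochs: list[Epoch] = sorted(epochs, key=lambda e: (e.start, e.end))
        if not allow_overlap:
            for a, b in zip(self.epochs, self.epochs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping epochs: [{a.start},{a.end}) and [{b.start},{b.end})")

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def __getitem__(self, i: int) -> Epoch:
        return self.epochs[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, EpochSet) and self.epochs == other.epochs

    def __repr__(self) -> str:
        return f"EpochSet({len(self.epochs)} epochs)"

    @property
    def total_duration(self) -> float:
        return float(sum(e.duration for e in self.epochs))

    def select(self, label: str) -> "EpochSet":
        return EpochSet([e for e in self.epochs if e.label == label], allow_overlap=True)

    def tile(self, window_s: float, *, label: str | None = None) -> "EpochSet":
        """Tile each epoch into non-overlapping ``window_s`` analysis windows.

        Trailing remainders shorter than ``window_s`` are dropped, matching
        the convention of fixed-length analysis windows over rest periods.
        """
        out = []
        for e in self.epochs:
            n = int(np.floor(e.duration / window_s + 1e-9))
            for k in range(n):
                s = e.start + k * window_s
                out.append(Epoch(s, s + window_s, label or e.label))
        return EpochSet(out, allow_overlap=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": [e.start for e in self.epochs],
                "offset_s": [e.end for e in self.epochs],
                "label": [e.label for e in self.epochs],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, *, allow_overlap: bool = False) -> "EpochSet":
        eps = [Epoch(float(r.onset_s), float(r.offset_s), str(r.label)) for r in df.itertuples()]
        return cls(eps, allow_overlap=allow_overlap)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, *, allow_overlap: bool = False) -> "EpochSet":
        return cls.from_frame(pd.read_csv(path), allow_overlap=allow_overlap)


@dataclass
class Recording:
    """Raw continuous multichannel recording in microvolts.

    signals  : (n_channels, n_samples) float array, microvolts
    fs       : sampling rate in Hz
    channels : channel names, length n_channels
    regions  : channel name -> region label (e.g. mPFC, dHPC)
    accel    : optional (3, n_acc_samples) accelerometer in g
    accel_fs : accelerometer sampling rate (defaults to ``fs``)
    events   : optional event table with onset_s, offset_s, label columns
    meta     : free-form sidecar metadata (seed, ground truth path, ...)
    """

    signals: np.ndarray
    fs: float
    channels: Sequence[str]
    regions: Mapping[str, str]
    accel: np.ndarray | None = None
    accel_fs: float | None = None
    events: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channels) != self.signals.shape[0]:
            raise ValueError("channel name count does not match signal rows")
        if self.accel_fs is None:
            self.accel_fs = self.fs
        if self.events is not None and len(self.events):
            dur = self.duration
            on = self.events["onset_s"].to_numpy(dtype=float)
            off = self.events["offset_s"].to_numpy(dtype=float)
            if (on < -1e-9).any() or (off > dur + 1e-6).any():
                raise ValueError("event times fall outside the recording")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        return list(self.channels).index(name)

    def get_channel(self, name: str) -> np.ndarray:
        return self.signals[self.channel_index(name)]

    def region_channels(self, region: str) -> list[str]:
        return [c for c in self.channels if self.regions.get(c) == region]

    def region_signal(self, region: str) -> np.ndarray:
        """Average of all channels assigned to ``region``."""
        chans = self.region_channels(region)
        if not chans:
            raise KeyError(f"no channels in region {region!r}")
        idx = [self.channel_index(c) for c in chans]
        return self.signals[idx].mean(axis=0)

    # ---- on-disk format: flat int16 + JSON sidecar --------------------
    def write(self, basepath: str | Path, *, scale_uv_per_bit: float | None = None) -> None:
        base = Path(basepath)
        base.parent.mkdir(parents=True, exist_ok=True)
        if scale_uv_per_bit is None:
            peak = float(np.abs(self.signals).max()) if self.signals.size else 1.0
            scale_uv_per_bit = max(peak, 1e-12) / 32000.0
        q = np.clip(np.round(self.signals / scale_uv_per_bit), -32768, 32767).astype("<i2")
        q.T.tofile(base.with_suffix(".dat"))  # sample-major interleaved
        sidecar = {
            "fs_hz": self.fs,
            "n_channels": int(self.signals.shape[0]),
            "channels": list(self.channels),
            "regions": dict(self.regions),
            "scale_uv_per_bit": scale_uv_per_bit,
            "dtype": "int16",
            "order": "sample_major",
            "meta": self.meta,
        }
        if self.accel is not None:
            acc = np.asarray(self.accel, dtype="<f4")
            acc.T.tofile(base.with_name(base.stem + "_accel.dat"))
            sidecar["accel"] = {"fs_hz": self.accel_fs, "n_axes": int(acc.shape[0]), "dtype": "float32"}
        base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
        if self.events is not None:
            self.events.to_csv(base.with_name(base.stem + "_events.csv"), index=False)


def read_recording(basepath: str | Path) -> Recording:
    """Read a recording written by :meth:`Recording.write`."""
    base = Path(basepath)
    sidecar = json.loads(base.with_suffix(".json").read_text())
    n_ch = sidecar["n_channels"]
    raw = np.fromfile(base.with_suffix(".dat"), dtype="<i2").reshape(-1, n_ch).T
    signals = raw.astype(float) * sidecar["scale_uv_per_bit"]
    accel = None
    accel_fs = None
    if "accel" in sidecar:
        n_axes = sidecar["accel"]["n_axes"]
        accel = np.fromfile(base.with_name(base.stem + "_accel.dat"), dtype="<f4").reshape(-1, n_axes).T
        accel = accel.astype(float)
        accel_fs = sidecar["accel"]["fs_hz"]
    events_path = base.with_name(base.stem + "_events.csv")
    events = pd.read_csv(events_path) if events_path.exists() else None
    return Recording(
        signals=signals,
        fs=sidecar["fs_hz"],
        channels=sidecar["channels"],
        regions=sidecar["regions"],
        accel=accel,
        accel_fs=accel_fs,
        events=events,
        meta=sidecar.get("meta", {}),
    )


@dataclass
class LfpSignal:
    """Decimated local field potential, nominally 1 kHz.

    ``provenance`` records the preprocessing settings (notch frequency,
    decimation factor, filter designs) that produced the signal.
    """

    signals: np.ndarray
    fs: float
    channels: Sequence[str]
    regions: Mapping[str, str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if np.isnan(self.signals).any():
            raise ValueError("LFP contains NaN")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        return list(self.channels).index(name)

    def get_channel(self, name: str) -> np.ndarray:
        return self.signals[self.channel_index(name)]

    def region_channels(self, region: str) -> list[str]:
        return [c for c in self.channels if self.regions.get(c) == region]

    def region_signal(self, region: str) -> np.ndarray:
        chans = self.region_channels(region)
        if not chans:
            raise KeyError(f"no channels in region {region!r}")
        idx = [self.channel_index(c) for c in chans]
        return self.signals[idx].mean(axis=0)

    def slice(self, start_s: float, end_s: float) -> np.ndarray:
        i0 = int(round(start_s * self.fs))
        i1 = int(round(end_s * self.fs))
        return self.signals[:, i0:i1]


@dataclass
class SpikeTrain:
    """Multi-unit spike times per channel, seconds from recording start."""

    spike_times: Mapping[str, np.ndarray]
    threshold_sigma: float = 3.0
    duration: float | None = None

    def __post_init__(self) -> None:
        clean = {}
        for ch, t in self.spike_times.items():
            t = np.asarray(t, dtype=float)
            if t.size and (np.diff(t) <= 0).any():
                raise ValueError(f"spike times not strictly increasing on channel {ch}")
            if self.duration is not None and t.size and (t[-1] > self.duration + 1e-9 or t[0] < 0):
                raise ValueError(f"spike times outside recording on channel {ch}")
            clean[ch] = t
        self.spike_times = clean

    def __getitem__(self, ch: str) -> np.ndarray:
        return self.spike_times[ch]

    def channels(self) -> list[str]:
        return list(self.spike_times)

    def n_spikes(self, ch: str | None = None) -> int:
        if ch is not None:
            return int(self.spike_times[ch].size)
        return int(sum(t.size for t in self.spike_times.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [(ch, t) for ch, times in self.spike_times.items() for t in times]
        return pd.DataFrame(rows, columns=["channel", "time_s"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "SpikeTrain":
        df = pd.read_csv(path)
        return cls({ch: g["time_s"].to_numpy() for ch, g in df.groupby("channel")}, **kw)
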