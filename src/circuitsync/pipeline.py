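"""End-to-end orchestration of the three experiment types.

``run_rest_analysis``, ``run_nor_analysis`` and ``run_auditory_analysis``
each generate (or load) a session, run the owning modules, and return a
tidy summary table with one row per (session, analysis, target, metric).
Every value in a summary table is reproducible by calling the owning
module directly with the same seed; the pipeline adds no computation of
its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, coupling, spectral, synthetic
from .auditory import ErpResult, mmn_analysis
from .connectivity import psi_with_surrogate
from .core import Epoch, EpochSet, LfpSignal, Recording
from .preprocessing import detect_rest_epochs, extract_lfp
from .spiking import ppc_by_epochs

__all__ = ["SessionConfig", "run_rest_analysis", "run_nor_analysis", "run_auditory_analysis"]

# healthy-baseline style test: longer novel visits early, DI ~ 0.24
DEFAULT_NOR_SCHEDULE = [
    ("novel", 2.0, 5.5),
    ("familiar", 8.0, 10.0),
    ("novel", 14.0, 17.0),
    ("familiar", 20.0, 22.0),
    ("novel", 26.0, 28.5),
    ("familiar", 31.0, 32.5),
]
DEFAULT_FAM_SCHEDULE = [
    ("left", 2.0, 5.0),
    ("right", 8.0, 11.0),
    ("left", 14.0, 16.5),
    ("right", 20.0, 22.0),
    ("left", 25.0, 27.0),
    ("right", 30.0, 32.5),
]


@dataclass
class SessionConfig:
    """Validated configuration for one synthetic or recorded session."""

    seed: int = 0
    raw_fs_hz: float = 3000.0
    lfp_fs_hz: float = 1000.0
    notch_hz: float = 50.0
    rest_duration_s: float = 120.0
    rest_window_s: float = 3.0
    theta_freq: float = 8.0
    gamma_freq: float = 60.0
    pac_depth: float = 0.5
    lag_ms: float = 10.0
    kappa: float = 1.5
    spike_rate: float = 20.0
    aep_response_prob: float = 0.8
    mmn_extra_negativity: float = -3.0
    bands: dict = field(default_factory=lambda: dict(spectral.DEFAULT_BANDS))
    pac_phase_grid: list = field(default_factory=lambda: list(np.arange(2.0, 13.0, 1.0)))
    pac_amp_grid: list = field(default_factory=lambda: list(np.arange(30.0, 101.0, 5.0)))
    pac_quant_phase: tuple = (6.0, 10.0)
    pac_quant_amp: tuple = (40.0, 60.0)
    psi_bands: dict = field(default_factory=lambda: {"theta": (8.0, 12.0), "high_gamma": (52.0, 100.0)})
    psi_epleng_s: float = 60.0
    psi_segleng_s: float = 1.0
    n_shuffles: int = 1000
    ppc_epoch_s: float = 25.0
    ppc_min_spikes: int = 250
    nor_target_s: float = 5.0
    di_min: float = 0.2
    n_clicks: int = 100
    click_iti_s: float = 10.0
    n_oddball_trials: int = 1000
    nor_schedule: list = field(default_factory=lambda: [list(v) for v in DEFAULT_NOR_SCHEDULE])
    fam_schedule: list = field(default_factory=lambda: [list(v) for v in DEFAULT_FAM_SCHEDULE])

    def __post_init__(self) -> None:
        if self.raw_fs_hz < self.lfp_fs_hz:
            raise ValueError("raw_fs_hz must be at least lfp_fs_hz")
        if self.rest_duration_s <= 0 or self.rest_window_s <= 0:
            raise ValueError("durations must be positive")
        if not 0 <= self.pac_depth <= 1:
            raise ValueError("pac_depth must lie in [0, 1]")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def ground_truth(self, *, schedule: list | None = None, seed_offset: int = 0) -> synthetic.GroundTruth:
        return synthetic.GroundTruth(
            theta_freq=self.theta_freq,
            gamma_freq=self.gamma_freq,
            pac_depth=self.pac_depth,
            lag_ms=self.lag_ms,
            kappa=self.kappa,
            spike_rate=self.spike_rate,
            aep_response_prob=self.aep_response_prob,
            mmn_extra_negativity=self.mmn_extra_negativity,
            visit_schedule=[tuple(v) for v in (schedule or [])],
            seed=int(self.seed) + seed_offset,
        )


def _quiet_accel(rng: np.random.Generator, duration_s: float, fs: float = 100.0) -> np.ndarray:
    """Mostly quiescent accelerometer with two scripted movement bursts."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    acc = rng.standard_normal((3, n)) * 0.02
    for s in (0.25 * duration_s, 0.75 * duration_s):
        burst = (t >= s) & (t < s + 3.0)
        acc[:, burst] += 0.4 * np.sin(2 * np.pi * 2.0 * t[burst]) + rng.standard_normal((3, burst.sum())) * 0.15
    acc[2] += 1.0
    return acc


def _row(session, analysis, target, metric, value) -> dict:
    return {"session": session, "analysis": analysis, "target": target, "metric": metric, "value": value}


def run_rest_analysis(cfg: SessionConfig) -> pd.DataFrame:
    """Quiet-alertness analysis: band powers, PAC, PSI, PPC."""
    gt = cfg.ground_truth(seed_offset=0)
    rec = synthetic.gen_coupled_lfp(gt, cfg.rest_duration_s, fs_hz=cfg.raw_fs_hz)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x4E57]))
    rec.accel = _quiet_accel(rng, cfg.rest_duration_s)
    rec.accel_fs = 100.0
    lfp = extract_lfp(rec, notch_hz=cfg.notch_hz, target_fs=cfg.lfp_fs_hz)
    rest = detect_rest_epochs(rec)
    windows = rest.tile(cfg.rest_window_s)

    rows = []
    scheme = spectral.BandScheme(dict(cfg.bands))
    ps = spectral.multitaper_psd(lfp, windows)
    for region in ("mPFC", "dHPC"):
        ch = lfp.region_channels(region)[0]
        for band in ("theta", "high_gamma"):
            rows.append(_row("rest", "band_power", region, band, spectral.band_power(ps, scheme, band, channel=ch)))

    hpc = lfp.region_signal("dHPC")
    pfc = lfp.region_signal("mPFC")
    cm_local = coupling.comodulogram(
        hpc, hpc, lfp.fs,
        phase_freqs=np.asarray(cfg.pac_phase_grid), amp_freqs=np.asarray(cfg.pac_amp_grid),
        phase_source="dHPC", amp_source="dHPC",
    )
    rows.append(_row("rest", "pac", "dHPC", "local_mi", coupling.pac_quantify(cm_local, cfg.pac_quant_phase, cfg.pac_quant_amp)))
    cm_ir = coupling.interregional_pac(
        pfc, hpc, lfp.fs,
        phase_freqs=np.asarray(cfg.pac_phase_grid), amp_freqs=np.asarray(cfg.pac_amp_grid),
    )
    rows.append(_row("rest", "pac", "mPFC_phase-dHPC_amp", "ir_mi", coupling.pac_quantify(cm_ir, cfg.pac_quant_phase, cfg.pac_quant_amp)))

    for band_name, band in cfg.psi_bands.items():
        res = psi_with_surrogate(
            pfc, hpc, lfp.fs, tuple(band),
            n_shuffles=cfg.n_shuffles, seed=np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x951])),
            # at least 2 epochs so the PSI-vs-shuffle t-test is defined
            epleng_s=min(cfg.psi_epleng_s, cfg.rest_duration_s / 2), segleng_s=cfg.psi_segleng_s,
            direction="mPFC->dHPC",
        )
        rows.append(_row("rest", "psi", f"mPFC->dHPC:{band_name}", "psi_corrected", res.psi_corrected))
        rows.append(_row("rest", "psi", f"mPFC->dHPC:{band_name}", "p_value", res.p_value))

    spikes = synthetic.gen_phase_locked_spikes(gt, rec)
    ppcs = ppc_by_epochs(
        spikes, lfp, tuple(cfg.bands["theta"]),
        epoch_s=cfg.ppc_epoch_s, min_spikes=cfg.ppc_min_spikes, lfp_channel=lfp.region_channels("dHPC")[0],
    )
    if ppcs:
        rows.append(_row("rest", "ppc", "dHPC", "theta_ppc", float(np.mean([r.ppc for r in ppcs]))))
        rows.append(_row("rest", "ppc", "dHPC", "n_epochs", float(len(ppcs))))
    df = pd.DataFrame(rows)
    if df["value"].isna().any():
        raise RuntimeError("rest summary contains NaN")
    return df


def _concatenated_epoch_signal(lfp: LfpSignal, epochs: EpochSet) -> np.ndarray:
    return np.concatenate([lfp.slice(e.start, e.end) for e in epochs], axis=1)


def run_nor_analysis(cfg: SessionConfig) -> pd.DataFrame:
    """NOR analysis: DI, early/late familiarization, visit-epoch PSI."""
    rows = []
    fam_gt = cfg.ground_truth(schedule=cfg.fam_schedule, seed_offset=1)
    fam_rec, fam_epochs = synthetic.gen_behavior_session(fam_gt, fs_hz=cfg.raw_fs_hz)
    fam_visits = behavior.visits_from_events(fam_rec.events, phase="familiarization")
    early, late, info = behavior.split_early_late(fam_visits, cfg.nor_target_s)
    rows.append(_row("familiarization", "visits", "all", "total_s", info["total_s"]))
    rows.append(_row("familiarization", "visits", "early", "n_visits_used", info["early"]["n_visits_used"]))
    rows.append(_row("familiarization", "visits", "late", "n_visits_used", info["late"]["n_visits_used"]))

    fam_lfp = extract_lfp(fam_rec, notch_hz=cfg.notch_hz, target_fs=cfg.lfp_fs_hz)
    scheme = spectral.BandScheme(dict(cfg.bands))
    for name, eps in (("early", early), ("late", late)):
        # PSD on the concatenated 5 s of visit time (sub-second visit
        # fragments would otherwise be skipped by the epoch-wise PSD)
        seg = _concatenated_epoch_signal(fam_lfp, eps)
        cat = LfpSignal(seg, fam_lfp.fs, list(fam_lfp.channels), dict(fam_lfp.regions))
        ps = spectral.multitaper_psd(cat)
        for region in ("mPFC", "dHPC"):
            ch = fam_lfp.region_channels(region)[0]
            rows.append(_row("familiarization", "band_power", f"{region}:{name}", "theta",
                             spectral.band_power(ps, scheme, "theta", channel=ch)))

    stm_gt = cfg.ground_truth(schedule=cfg.nor_schedule, seed_offset=2)
    stm_rec, _ = synthetic.gen_behavior_session(stm_gt, fs_hz=cfg.raw_fs_hz)
    visits = behavior.visits_from_events(stm_rec.events, phase="STM")
    score = behavior.discrimination_index(visits)
    rows.append(_row("STM", "nor", "session", "di", score.di))
    rows.append(_row("STM", "nor", "session", "total_exploration_s", score.total_exploration_s))
    rows.append(_row("STM", "nor", "session", "passes_screen", float(behavior.passes_baseline_screen(score, cfg.di_min))))

    stm_lfp = extract_lfp(stm_rec, notch_hz=cfg.notch_hz, target_fs=cfg.lfp_fs_hz)
    epochs, _ = behavior.label_visit_epochs(visits, "STM", cfg.nor_target_s)
    for obj in ("novel", "familiar"):
        eps = EpochSet([e for e in epochs if e.label == f"STM:{obj}"], allow_overlap=True)
        if not len(eps):
            continue
        seg = _concatenated_epoch_signal(stm_lfp, eps)
        pfc = seg[stm_lfp.channel_index(stm_lfp.region_channels("mPFC")[0])]
        hpc = seg[stm_lfp.channel_index(stm_lfp.region_channels("dHPC")[0])]
        res = psi_with_surrogate(
            pfc, hpc, stm_lfp.fs, tuple(cfg.psi_bands["high_gamma"]),
            n_shuffles=cfg.n_shuffles,
            seed=np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x0B, sum(map(ord, obj))])),
            epleng_s=pfc.size / stm_lfp.fs, segleng_s=cfg.psi_segleng_s,
            direction="mPFC->dHPC",
        )
        rows.append(_row("STM", "psi_visits", f"mPFC->dHPC:{obj}", "psi_corrected", res.psi_corrected))
    return pd.DataFrame(rows)


def run_auditory_analysis(cfg: SessionConfig) -> pd.DataFrame:
    """Auditory analysis: AEP response ratio, P2/P3 metrics, MMN AUC."""
    rows = []
    gt = cfg.ground_truth(seed_offset=3)
    click_rec, _ = synthetic.gen_auditory_session(
        gt, "click_train", fs_hz=cfg.lfp_fs_hz, n_clicks=cfg.n_clicks, click_iti_s=cfg.click_iti_s
    )
    spikes = synthetic.gen_phase_locked_spikes(gt, click_rec)
    erp = ErpResult.from_session(
        click_rec.signals[0], click_rec.fs, click_rec.events["onset_s"].to_numpy(),
        spike_times_s=spikes[spikes.channels()[0]],
    )
    rows.append(_row("click_train", "aep", "mPFC", "response_ratio", erp.response_ratio))
    for comp, d in erp.components.items():
        rows.append(_row("click_train", "aep", "mPFC", f"{comp}_amplitude_uv", d["amplitude_uv"]))
        rows.append(_row("click_train", "aep", "mPFC", f"{comp}_firing_rate_hz", d["firing_rate_hz"]))

    odd_gt = cfg.ground_truth(seed_offset=4)
    odd_rec, _ = synthetic.gen_auditory_session(
        odd_gt, "oddball", fs_hz=cfg.lfp_fs_hz, n_oddball_trials=cfg.n_oddball_trials
    )
    mmn = mmn_analysis(odd_rec.signals[0], odd_rec.fs, odd_rec.events)
    for combo, d in mmn.combinations.items():
        rows.append(_row("oddball", "mmn", combo, "auc_uv_ms", d["auc_uv_ms"]))
        rows.append(_row("oddball", "mmn", combo, "n_deviant", float(d["n_deviant"])))
    return pd.DataFrame(rows)
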