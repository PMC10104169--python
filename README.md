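# circuitsync

Analysis pipeline for prefrontal–hippocampal (mPFC–dHPC) circuit dynamics
in rodent electrophysiology, built for studies of NMDA-receptor
hypofunction models of schizophrenia (e.g. subchronic PCP) and their
pharmacological rescue. It covers the full chain from raw multichannel
recordings to the standard biomarkers of that literature:

- **Preprocessing** — LFP extraction (detrend, mains notch, anti-aliased
  decimation to 1 kHz), multi-unit activity (MUA) from 450–6,000 Hz
  threshold crossings at −3 robust SD with reference-channel subtraction,
  rest ("quiet alertness") epochs of 2–10 s from accelerometer variance.
- **Spectral** — multitaper (DPSS) power spectra and band powers over the
  scheme delta 2–5, slow theta 4–8, theta 8–12, low gamma 30–48, high
  gamma 52–100, HFO 100–200 Hz.
- **Coupling** — theta–gamma phase–amplitude coupling via the entropy
  modulation index, MI = (log N − H(P))/log N over N = 18 phase bins,
  with comodulograms on a phase grid up to 15 Hz (1 Hz step, 4 Hz
  bandwidth) × amplitude grid 10–250 Hz (5 Hz step, 10 Hz bandwidth),
  locally and inter-regionally.
- **Connectivity** — directed information flow via the phase slope index,
  PSI = Im(Σ_f C*(f)·C(f+δf)) on 60 s epochs cut into 1 s Hann segments;
  positive = mPFC leads. Significance by a 1,000-fold shuffle surrogate
  (mean-subtracted) and a t-test of epoch PSI against the shuffle.
- **Spiking** — spike–field locking via pairwise phase consistency,
  PPC = 2/(N(N−1))·Σ_{i<j} cos(θᵢ−θⱼ), an unbiased estimator, computed in
  25 s epochs with ≥ 250 spikes.
- **Behavior** — novel-object-recognition scoring:
  DI = (t_novel − t_familiar)/t_total, 5-s visit concatenation,
  early/late familiarization splits, ≥ 10 s validity rule.
- **Auditory** — AEP response ratio with P2 (40–70 ms) and P3
  (200–300 ms) amplitude/firing metrics, and flip-flop oddball mismatch
  negativity as the frequency-matched deviant-minus-standard
  difference-wave AUC.
- **Synthetic sessions** — a first-class generator producing two-region
  LFPs with controllable theta–gamma coupling depth, inter-regional lag,
  spike phase-locking concentration, scripted visit schedules, and
  click/oddball streams with known evoked responses, so every estimator
  can be validated against ground truth.

## Worked example

```python
import circuitsync as cs

# a 120 s two-region session: 8 Hz theta driving 60 Hz gamma at depth 0.9,
# hippocampus lagging prefrontal cortex by 10 ms
gt = cs.GroundTruth(seed=7, pac_depth=0.9, theta_freq=8.0,
                    gamma_freq=60.0, lag_ms=10.0)
rec = cs.gen_coupled_lfp(gt, duration_s=120.0)
hpc = rec.get_channel("dHPC_0")

mi = cs.modulation_index(hpc, hpc, rec.fs, (6, 10), (55, 65))
print(f"theta-gamma MI: {mi:.4f}")

res = cs.psi_with_surrogate(rec.get_channel("mPFC_0"), hpc, rec.fs,
                            band=(8, 12), n_shuffles=200, seed=1, epleng_s=30.0)
print(f"theta PSI (corrected): {res.psi_corrected:+.3f}, p = {res.p_value:.4f}")
```

prints

```
theta-gamma MI: 0.0020
theta PSI (corrected): +0.145, p = 0.0265
```

The MI of ~2×10⁻³ is a strong coupling on the entropy scale (uncoupled
60 s signals score ~10⁻⁵–10⁻⁴), and the positive, significant theta PSI
recovers the injected mPFC→dHPC 10 ms lead.

The same analyses run end-to-end from the command line:

```bash
circuit-sync simulate --seed 1 --kind rest --out session/
circuit-sync rest --seed 1 --out rest_summary.csv
circuit-sync nor  --seed 1 --out nor_summary.csv
circuit-sync aep  --seed 1 --out auditory_summary.csv
```

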