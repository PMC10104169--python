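# Methods

This note documents the models, estimators and design choices behind
`circuitsync`: what each analysis computes, the parameters that matter,
what the synthetic generator does and does not emulate, and the known
limitations.

## Signal model and preprocessing

Raw recordings are multichannel extracellular voltage (microvolts) with
a channel→region map (mPFC, dHPC), an optional 3-axis accelerometer (g)
and an event table of half-open `[onset, offset)` intervals in seconds.
On disk a session is flat little-endian int16 plus a JSON sidecar giving
the sampling rate, channel names, regions, and μV/bit scale; events are
CSV. All analysis intervals are half-open, in seconds from recording
start.

**LFP.** Linear detrend, second-order IIR mains notch (default 50 Hz,
Q = 30, zero-phase), then staged zero-phase FIR decimation to 1 kHz.
FIR anti-aliasing was chosen over the IIR (Chebyshev) alternative
because its flat passband preserves band power below 200 Hz — the
highest analysis band — to better than 1%; the Chebyshev ripple alone
costs ~1.7% on a passband tone. Non-integer rate ratios fall back to
polyphase resampling with a warning.

**MUA.** Per channel: subtract a nearby reference channel (cancels
common-mode movement artifacts exactly), band-pass 450–6,000 Hz
(zero-phase 4th-order Butterworth), detect downward crossings of
−3σ with σ = median(|x|)/0.6745. The robust σ avoids inflation by the
spikes themselves. A 1 ms refractory lockout prevents double-counting
one waveform. Note that for any Gaussian background the −3σ rule fires
at the Rice level-crossing rate (~40/s for an ideal 450–6,000 Hz band),
independent of noise scale; MUA counts on noisy channels therefore
include a stationary noise floor, which is the standard behavior of
threshold-crossing MUA and is verified against the Rice formula in the
tests.

**Rest detection.** ACC = sliding-window variance (0.5 s windows, 50%
overlap) of the instantaneous acceleration module √(X²+Y²+Z²).
Sub-threshold runs of 2–10 s are rest; runs longer than 10 s are split
into ≤10 s pieces rather than discarded (splitting preserves data; only
2–10 s rests are biologically expected, so splits are rare). The
threshold defaults to the 20th percentile of the session ACC and is
configurable — real sessions differ in mobility mix, so no universal
constant exists. Rest epochs are tiled into 3 s non-overlapping windows
for spectral analysis.

## Spectral analysis

Multitaper PSDs use DPSS tapers with time–bandwidth NW = 3 and 5 tapers
(a standard compromise for 3 s windows: ±1 Hz resolution at 3 s),
averaged across epochs on a common FFT grid; Parseval holds within 10%
on white noise by construction of the taper normalization. Band powers
integrate the PSD over half-open `[low, high)` bands with the trapezoid
rule. The band scheme (delta 2–5, slow theta 4–8, theta 8–12, low gamma
30–48, high gamma 52–100, HFO 100–200 Hz) is configurable; slow theta
and theta share the 8 Hz edge by design, and a `broad_theta` (4–12 Hz)
aggregate is provided for analyses phrased on the wider band.
Spectrograms are consecutive (non-overlapping by default) Hann STFTs.

## Phase–amplitude coupling

The modulation index bins the Hilbert amplitude of the fast band by the
Hilbert phase of the slow band (N = 18 bins), normalizes the binned
means to a distribution P, and reports
MI = (log N − H(P))/log N ∈ [0, 1]. Band extraction is zero-phase
4th-order Butterworth. Comodulograms scan phase centers at 1 Hz steps
with 4 Hz bandwidth and amplitude centers 10–250 Hz at 5 Hz steps with
10 Hz bandwidth; phase bands whose lower edge would fall below 1 Hz are
clipped there, so the effective phase grid starts at 2 Hz (a 0 Hz
center has no valid band). Quantification is the mean MI over an
explicit region of interest — the region is always an argument because
different analyses legitimately select different windows (e.g. 6–10 Hz
× 40–60 Hz during rest, 7–10 Hz × 60–80 Hz during memory tasks).
Inter-regional PAC takes phase from one region and amplitude from the
other and is directional by construction.

On the entropy scale, realistic couplings produce small numbers: a
fully modulated synthetic gamma yields MI ≈ 2×10⁻³ while uncoupled 60 s
signals sit at 10⁻⁵–10⁻⁴. Comparisons should always be against a
surrogate or an uncoupled control, not against an absolute cutoff.

## Phase slope index

For two simultaneous signals, data are cut into epochs (default 60 s)
and 1 s Hann segments with 50% overlap; the complex coherency C(f) is
the segment-averaged cross-spectrum normalized by the power spectra, and

    PSI = Im( Σ_f C*(f) · C(f + δf) )

summed over the analysis band. Positive PSI means the first signal
leads (mPFC→dHPC with the package's argument convention). A pooled
estimate normalized by its jackknife SD across epochs is also reported.
Antisymmetry PSI(a,b) = −PSI(b,a) is made exact to the bit by
evaluating the cross-spectral chain on a canonically ordered pair and
flipping the sign (floating-point complex products are not bit-exact
under conjugation).

**Surrogates.** The null randomizes the temporal alignment between the
regions and, when several channels per region exist, the channel
pairing, 1,000 times by default. Two schemes are implemented:
`segment_shift` (default) circularly shifts the sequence of 1 s segment
spectra of one region — this reuses the segment FFTs across all
shuffles, making the 1,000-shuffle null cheap — and `sample_shift`
circularly shifts raw samples and recomputes spectra. The surrogate
mean is subtracted from the raw PSI ("corrected" PSI) and significance
is a two-sided Welch t-test of epoch-level PSI values against the
surrogate distribution. Type-I error of this procedure on independent
noise is ≤ 5% in simulation (40 seeds).

Behavioral visit epochs are shorter than 60 s; for visit-locked PSI the
concatenated 5 s visit epoch is analyzed as a single epoch with the
same 1 s segments.

## Spike–field coupling

Spike phases are read from the band-passed LFP's analytic signal,
unwrapped and linearly interpolated at spike times (interpolating
wrapped phase would corrupt values at the ±π seam). Pairwise phase
consistency is computed through the algebraic identity
PPC = ((N·R̄)² − N)/(N(N−1)) (O(N) instead of the O(N²) pairwise sum,
to which it agrees at 1e-12). PPC is unbiased in N, so epochs need only
clear a minimum count: 25 s epochs with ≥ 250 spikes. For von Mises
phases the population value is (I₁(κ)/I₀(κ))², the check used in the
tests. The spike–delta analysis window (3–6 Hz) is distinct from the
spectral delta band (2–5 Hz); both are available.

## Behavior (novel object recognition)

DI = (t_novel − t_familiar)/(t_novel + t_familiar) ∈ [−1, 1]. Because
several estimators are window-length sensitive, visits are concatenated
until the accumulated time reaches 5 s, the final visit truncated at
the threshold (tail dropped when accumulating forward, head when
accumulating backward); `truncate=False` keeps the whole final visit
for sensitivity analyses. Sessions with less total time return all
visits flagged `short`. Familiarization is valid only with ≥ 10 s of
exploration; memory acquisition contrasts the first vs last 5 s of
accumulated visit time with objects pooled, and the two partitions are
disjoint whenever ≥ 10 s is available. A baseline screen (DI > 0.2,
configurable) models the inclusion criterion for memory analyses.

## Auditory evoked potentials and mismatch negativity

Trials are epoched around tone onsets and baseline-corrected by the
pre-stimulus mean. **Detection rule:** a trial is responsive when the
peak |deflection| of a 20 ms boxcar-smoothed trace within 10–350 ms
post-stimulus exceeds k = 3 SD of the raw pre-stimulus baseline. The
baseline SD is deliberately taken on raw samples: the extreme value of
a 340 ms noise window reaches ~3 SD of its own smoothed trace for any
noise scale or color, so a same-trace threshold cannot be calibrated —
whereas a sustained smoothed deflection rivaling the raw sample
variability matches how evoked responses are judged by eye. With this
rule the false-positive rate on noise trials is ~0 and the response
ratio is an unbiased estimate of the true response probability. The
rule assumes drift-free trials; recordings with strong 1/f drift should
be high-passed before detection (limitation).

Component metrics: amplitude is baseline-to-peak on the trial-averaged
waveform within P2 (40–70 ms) or P3 (200–300 ms); firing rate is the
mean MUA rate in 10 ms bins within the window across trials (0 when no
spike train is supplied). Amplitude is linear in the underlying evoked
amplitude by construction.

MMN uses the flip-flop oddball: two tone frequencies in 75/25
standard/deviant proportion, roles swapped after half the trials. The
difference wave is deviant − standard **of the same physical
frequency** across the two blocks, so frequency-specific response
differences cancel exactly; comparisons are never made across
frequencies. MMN is the trapezoid AUC of the difference wave over
40–200 ms (μV·ms), configurable.

## Synthetic sessions

The generator produces the statistical structure the estimators target,
not a biophysical simulation:

- mPFC carries a narrowband theta component (center ± 2 Hz filtered
  noise, ~50 μV amplitude); dHPC carries the same realization delayed
  by `lag_ms` (circular shift — exact delay everywhere), giving PSI a
  true broadband-within-band lag. Lags beyond a quarter theta cycle are
  rejected (phase ambiguity).
- dHPC gamma is a Gaussian-spectral-envelope carrier (σ = 6 Hz around
  the gamma center) multiplied by
  (1 − d) + d·(1 + cos θ)/2, so `pac_depth` d is exactly the modulated
  amplitude fraction. The spectrally broad carrier matters: amplitude
  modulation at theta rate lives in ±8 Hz sidebands, and a brick-wall
  narrowband carrier would lose its modulation inside a 10 Hz analysis
  band — physiological gamma is broad, and so is the synthetic carrier.
- Backgrounds are pink (1/f) plus white noise, independent per region
  (defaults 15 and 5 μV SD against 50 μV theta).
- Spikes are an inhomogeneous point process with intensity
  rate·exp(κ cos(θ − μ))/I₀(κ), sampled by thinning; κ ≥ 50 (or ∞) is
  treated as perfect locking at phase μ. The time-averaged rate equals
  `spike_rate` for any κ.
- Behavior sessions place quiescent accelerometer noise during scripted
  visits and large sway between them, so rest detection and the event
  table agree by construction.
- Auditory sessions inject a template of Gaussian deflections at 55 ms
  (P2-like, 8 μV) and 250 ms (P3-like, 6 μV) with probability
  `aep_response_prob` per click (100 clicks, 10 s apart), on white
  measurement noise (1.5 μV SD) — see the detection-rule limitation
  above. Oddball streams are 1,000 tones at 500 ms intervals; deviants
  carry an extra deflection whose time integral is
  `mmn_extra_negativity` × 100 ms, placed inside the MMN window.

Everything derives from one seeded generator per session; identical
seeds give bit-identical output, and the ground-truth record travels
with the data. What passing tests show is that the estimators recover
known injected effects on realistic noise; they do not show robustness
to artifacts, electrode drift, volume conduction, or non-stationarity,
none of which the generator emulates.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to keep estimator
variance well inside the asserted tolerances: 60–120 s sessions for
MI/PSI, 200-shuffle surrogates (the full 1,000 remains the library
default), 20-seed ensembles for sign/calibration checks and 40 for
type-I rates. Degenerate inputs are defined rather than silent:
zero amplitude → MI error; < 2 phases → PPC error; zero-variance
t-tests take an exact-equality fast path; flat accelerometers warn;
epochs shorter than the PSI epoch length fall back to a single
full-length epoch with a warning. Group-level statistics beyond the
PSI-vs-shuffle t-test (ANOVAs, post-hocs, correlations with behavior)
are deliberately left to general statistics packages — the package's
scope is the signal pipeline.
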