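# Methods

This note documents the models and procedures implemented in `tcsyn`,
the parameter choices that matter, and what the synthetic validation
does and does not establish about real recordings.

## Conventions

Times are seconds from recording start; analysis windows are half-open
[t, t+w). Vm is in mV, conductance in nS, membrane resistance in MΩ.
The analysis sampling rate is 10 kHz (0.1 ms samples); higher-rate
acquisitions (e.g. 33 kHz) are polyphase-resampled on import. Every
stochastic routine takes an explicit integer seed and is reproducible
bit-for-bit given the same inputs.

## Spike-triggered averaging and jitter correction

The raw STA averages ±10 ms Vm windows around each presynaptic spike;
spikes whose window exceeds the trace are dropped (not padded). The
jittered STA displaces each spike by i.i.d. U(0, J) with J equal to one
stimulus frame (16 ms default, 24 ms configurable) and averages over
100 independent draws (the draw count is our choice; it only de-noises
the jittered estimate). Slow stimulus-locked modulation — with a period
much longer than J — survives jittering, while the sub-frame synaptic
transient is smeared to roughly its time-integral divided by J, so the
corrected STA (raw − jittered) isolates the EPSP. Note the smeared
transient leaves a small pedestal in the jittered STA; the EPSP
amplitude is therefore measured as corrected-STA(peak) − corrected-STA
(onset), which cancels the pedestal to first order. On synthetic pairs
this estimator recovers mean amplitude × (1 − p_fail) to within a few
percent (tested at 15%).

**Confidence band.** The band is a bootstrap *null* band: each of
n_boot = 1000 replicates resamples the spike set with replacement,
jitters it with one fresh draw, and records its STA minus the overall
jittered STA. Per-sample 2.5/97.5% quantiles of these replicates give
the limits a spike-locked transient must escape. Average per-sample
coverage under pure noise is ≈ 94–95% (individual recordings fluctuate
because STA samples are correlated). We band the null rather than the
corrected STA itself because the connection criterion — ≥ 10
consecutive post-spike samples *above* the upper limit (1 ms at
10 kHz; the run length scales with sampling rate) — is a significance
test, not an interval estimate.

**Connection gates.** connected ⇔ supra-band run ≥ 10 samples AND EPSP
onset latency ∈ [1.0, 4.5] ms AND 10–90% rise time < 2 ms. Onset is the
t1 of the derivative-based window (below), measured on the corrected
STA for consistency with the per-spike detector. On 100 unconnected
noise-only pairs the three gates together pass ≤ 5 (tested), dominated
by the run-length requirement.

## Per-spike EPSP detector

For each connected pair the monosynaptic window [t1, t2] is derived
from the corrected STA restricted to 0–6 ms after the spike: the
derivative (first differences, smoothed by a 3-point moving average)
must contain a positive global peak with height above the pre-spike
derivative SD; t1 and t2 are its flanking valleys. A valley is the
first point where the derivative crosses zero (Vm extremum — t1 and t2
thereby correspond to onset and peak of the average EPSP) or where it
rebounds above the running minimum by more than the derivative noise SD
(a genuine new rising phase). The tolerance matters: terminating at any
1-sample dip systematically truncates measured amplitudes under noise.

Each single-spike trace is zeroed at the spike time; its derivative is
smoothed the same way as the STA's (the trial peak search uses "the
same strategy" as the STA search; a config switch disables trial
smoothing). If no qualifying derivative peak lies inside [t1, t2] the
trace is undetectable. Otherwise the onset/end are refined to t1′/t2′
by the same valley search and the amplitude Vm(t2′) − Vm(t1′) must
reach the pair's threshold: mean + 1 SD of the amplitudes (window-mean
ΔVm over [t1, t2]) of ≥ 1000 jittered traces. The threshold is
per-pair; a fixed global threshold is available as an option.
Undetectable traces (including all jittered traces) are assigned the
window-mean ΔVm, which makes the full per-spike amplitude distribution
well defined and lets the mixture mean satisfy the exact identity
mean(all) = (n_det·mean(det) + n_und·mean(und))/n.

Raising the threshold can only demote detectable labels (tested
monotonicity). An optional audit flags detectable traces lacking a
contiguous ≥ 0.3 ms positive-slope run, mirroring a manual-verification
pass.

**Calibration.** On synthetic pairs with ≥ 1000 spikes, 0.3 mV colored
noise and event amplitudes held well above threshold, the estimated
%undetectable falls inside the exact binomial 95% interval of the
generator's failure probability in ≥ 34/36 pairs. Two caveats: (i) the
jittered-trace threshold includes genuine EPSPs that land in jittered
windows, so it rises with synaptic strength and firing rate — at
realistic amplitudes (~1 mV) events below threshold are *operationally*
undetectable, and %undetectable overestimates the true failure
probability by several points; this is a property of the operational
definition, not a bug. (ii) Overlapping events at high presynaptic
rates (> ~15 Hz) can rescue failed spikes or distort windows; the
calibration cohort uses 4 Hz to keep overlap negligible.

## Statistics

* Noise-corrected CV = sqrt(|σ²_all − σ²_noise|)/μ_all with sample
  variances (ddof = 1); σ²_noise from the jittered amplitude sample.
  The absolute value guards the rare case σ²_noise > σ²_all.
* STSP: amplitudes (all spikes, undetectable included) split at the
  50 ms ISI; %change on class means; primary significance is the
  two-sample KS test at α = 0.05 with the t-test reported alongside
  (both are always computed; the KS decides classification). ISI
  distributions of detectable vs undetectable spikes are compared the
  same way. Pairs with < 20 spikes in a class are flagged
  under-powered. No multiplicity correction is applied across pairs by
  default (a Benjamini–Hochberg option can be layered on the reported
  p-values); type-I error of the classification on non-plastic
  synthetic pairs is ≈ 5% (tested at 5 ± 2% over 500 pairs).
* Population correlations are plain Pearson r across pair summaries;
  degenerate (zero-variance) columns yield NaN with a flag.
* Cell-class (RS/FS) contrasts are two-sample KS + t tests on pair
  summaries; class labels are input metadata, never inferred. Two-epoch
  (e.g. noise vs grating) comparisons are paired t-tests matched by
  pair id.
* Pre-spike Vm dependence: baseline Vm in [−5, 0) ms before each spike,
  Pearson r against amplitude, plus %undetectable and CV stratified by
  Vm quartile.

## Synthetic-data generator

The generator emulates the *statistical structure* the analysis relies
on, not retinal/geniculate biophysics:

* **Stimulus**: 16×16-pixel frames, each pixel one of four contrast
  levels in [−1, 1], 16 ms frames in 250-frame blocks separated by 1 s
  gray; 18 blocks span 89 s.
* **LGN cells**: linear–nonlinear–Poisson stand-ins with Gaussian RF
  centers on alternating ON/OFF rows (elongated, simple-cell-like
  population RF), a causal temporal kernel peaking ~3–4 frames
  (~50–70 ms) back, rate = max(0, baseline + gain·drive) with baseline
  per cell U(6, 18) Hz and auto-gain set to 2 SDs of drive per baseline
  (realized rates ≈ 7–24 Hz, the physiological range under white
  noise), thinning-sampled with a 1 ms absolute dead time. The
  modulation depth and clustered RF rows were set so that 50 inputs
  drive the LIF model in the fluctuation-dominated regime observed in
  vivo; weakly modulated, spatially dispersed inputs leave both model
  variants nearly silent.
* **Synapses**: transmitted-event amplitudes are log-normal
  (mean_amp, CV) — a long-tailed family consistent with observed
  amplitude distributions; failures are i.i.d. Bernoulli(p_fail);
  latency is Gaussian (2.5 ± 0.3 ms, clipped at ±3 SD — inside the
  1.0–4.5 ms monosynaptic gate); depression multiplies the mean by
  1 − d·exp(−ISI/τ) (kinetic form is our choice; the analysis only uses
  the short/long contrast). Cohort sampling couples the triplet
  monotonically: larger mean_amp ⇒ smaller p_fail and CV, with
  marginals centered near 0.9 mV, ~35% failures, operational CV ≈ 1.
* **Vm**: rest −65 mV; each transmitted spike adds a peak-normalized
  difference-of-exponentials EPSP (0.5/2 ms) scaled by its drawn
  amplitude; noise = small white component (0.06 mV) + an
  Ornstein–Uhlenbeck process (τ = 10 ms) carrying ~96% of the variance
  — in vivo Vm fluctuations are dominated by slow synaptic background,
  and the white/colored split materially affects detector behavior —
  plus optional stimulus-locked slow modulation and optional negative
  (IPSP-like) events at a Poisson rate (off by default). The truth
  table logs every presynaptic spike's outcome, amplitude and latency.

What passing synthetic tests does **not** show: robustness to
electrode/bridge artifacts, spike contamination of Vm, true vesicular
release statistics (undetectable ≠ release failure), non-stationary
excitability, or real LGN correlation structure (bursting, gap
locking). Results on real data depend on those factors.

## LIF model

Membrane: C·dV/dt with τ_m = 6 ms, R_m = 47 MΩ (C = τ_m/R_m), rest
−65 mV, threshold −55 mV, reset −60 mV, 2 ms refractory, forward Euler
at dt = 0.1 ms (halving dt changes rates < 5%, tested; steady-state Vm
under constant conductance matches the closed form
V_ss = (V_rest + 10⁻³R_m·g·E_exc)/(1 + 10⁻³R_m·g) to 0.1%). Each
transmitted spike injects g(t) = amplitude × unit-peak
(e^(−t/2ms) − e^(−t/0.5ms)); input current I = g_total·(E_exc − Vm)
with E_exc = 0 mV (standard AMPA-like reversal; the driving-force form
is our choice). Subthreshold Vm statistics exclude spike and refractory
samples.

Synapse triplets (mean EPSG, amplitude CV, failure rate) are drawn
jointly from the same coupled cohort model and rescaled so the 50-input
mean EPSG is 0.89 nS; triplets are never mixed across synapses. Modes:
`reliable` (every spike, constant amplitude), `unreliable` (failures +
log-normal amplitudes), `unreliable_const_amp` (failures only), and
`correlated_failure` (failure probability boosted for spikes coincident
within 5 ms with other inputs' spikes, rescaled to preserve the
marginal rate; the coincidence window is configurable). Equal-drive
calibration sets the reliable amplitude to event-mean × (1 − p_fail) so
both models inject the same average conductance (an `event-mean` switch
copies the event mean instead); equal total drive is the default
because the comparison of interest holds mean depolarization fixed.

**Mechanism (validated per seed):** with matched drive the two models'
mean subthreshold Vm is statistically indistinguishable while Vm SD and
firing rate are strictly greater for the unreliable model in every
seed, firing rate increases monotonically with Vm SD (rank r > 0.9),
the constant-amplitude variant falls between the two (amplitude
variability contributes more variance than failures alone), and
enabling depression preserves the ordering. Absolute rates under the
synthetic drive (~0.1 Hz reliable vs ~0.9 Hz unreliable at 50 inputs)
are lower than with real LGN trains, whose burstiness and correlations
exceed the LNP stand-in's; the ratio and orderings, not the absolute
rates, are the validated claims.

Receptive fields of the model cell are recovered by reverse
correlation: each frame weighted by the mean subthreshold Vm deviation
a lag after frame onset; the strongest response sits near 60–80 ms lag
(LGN temporal kernel ≈ 56 ms centroid + frame integration + membrane
smoothing) with ON/OFF subregions matching the input layout.

## Problem sizes

Default validation sizes were chosen to make sampling error small
relative to the tested tolerances while keeping the full suite fast on
one CPU: 36 pairs × ~1100 spikes for detector calibration, 100 + 500
pairs for STSP sign/type-I, 100 noise pairs for false positives, 10
seeds × 89 s for the LIF comparison. The acceptance script re-runs the
same computations end to end from a single seed in a few minutes.

## Known limitations

* The importer for the archived experimental deposit is a best-effort
  adapter (`assign_synapses(source="dataset")` and the HDF5/CSV
  readers); the deposit's internal layout is not fully specified, and
  the mV→nS calibration constant (6×10⁸) is applied opaquely.
* The detector's operational %undetectable is threshold-dependent at
  realistic amplitudes (see above), matching the operational definition
  used on real data rather than true release failure.
* No intracortical recurrence, inhibition, or dendritic structure in
  the model; the high-conductance background option is a balanced-OU
  stand-in and is off by default.
* Latency of the corrected-STA EPSP is measured at the derivative
  onset, which under jitter smearing can lead the true event onset by a
  few hundred µs; the 1.0–4.5 ms gate absorbs this.
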