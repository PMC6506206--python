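"""Automated binary detector for single-spike EPSPs.

Each presynaptic spike defines a "single-spike trace": the postsynaptic
Vm from the spike time to 6 ms later, zeroed at the spike.  The detector
labels every trace as a *detectable* or *undetectable* EPSP using two
pair-specific constraints derived from the jitter-corrected STA:

* a temporal constraint — the candidate depolarization's rising phase
  (derivative peak) must fall inside the pair's monosynaptic window
  [t1, t2], the onset-to-peak interval of the average EPSP;
* an amplitude constraint — the rise measured between the refined onset
  (t1') and end (t2') of the candidate must exceed a noise threshold set
  to mean + 1 SD of the amplitudes of jittered (alignment-free) traces.

Undetectable traces get a window-mean amplitude, so the full amplitude
distribution (detectable + undetectable) is defined for every spike.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

SPAN_MS = 6.0


class WindowNotFound(ValueError):
    """Corrected STA has no positive derivative peak in the analysis span."""


@dataclass
class MonosynapticWindow:
    """Onset (t1), derivative-peak and termination (t2) times, ms."""

    t1_ms: float
    peak_ms: float
    t2_ms: float

    def __post_init__(self):
        if not (0 <= self.t1_ms < self.peak_ms < self.t2_ms <= SPAN_MS):
            raise ValueError(
                f"invalid monosynaptic window {self.t1_ms}, {self.peak_ms}, {self.t2_ms}"
            )


@dataclass
class DetectorConfig:
    """Per-pair detector parameters (all derived from the pair's data)."""

    window: MonosynapticWindow
    threshold_mv: float
    sampling_rate: float
    span_ms: float = SPAN_MS
    smooth_points: int = 3
    smooth_trials: bool = True
    min_prominence_mv: float = 0.0


def _smooth3(x: np.ndarray, npts: int = 3) -> np.ndarray:
    if npts <= 1:
        return x
    k = np.ones(npts) / npts
    return np.convolve(x, k, mode="same")


def _march(d: np.ndarray, start: int, step: int, lo: int, hi: int,
           tol: float = 0.0) -> int:
    """Walk from a derivative peak to its flanking valley.

    Stops at the first non-positive sample (the derivative zero crossing,
    i.e. where Vm actually stops rising) or when the derivative climbs
    more than ``tol`` above the running minimum (a genuine new rising
    phase rather than a noise wiggle).  With ``tol`` = 0 any local
    minimum terminates the walk, ties breaking toward the peak (the
    narrower window).  Clamped to [lo, hi].
    """
    i = start
    best = start
    while True:
        j = i + step
        if j < lo or j > hi:
            return best
        if d[j] <= 0:
            return j
        if d[j] < d[best]:
            best = j
        elif d[j] >= d[best] + max(tol, 0.0) or (tol == 0.0 and d[j] >= d[i]):
            return best
        i = j


def derive_monosynaptic_window(
    corrected_sta: np.ndarray,
    sampling_rate: float,
    window_ms: float = 10.0,
    span_ms: float = SPAN_MS,
    smooth_points: int = 3,
) -> MonosynapticWindow:
    """Locate [t1, t2] from the smoothed derivative of the corrected STA.

    The derivative (first differences between neighbor samples, smoothed
    by a ``smooth_points``-point average) must show a positive global peak
    within 0-6 ms after the spike with prominence above the pre-spike
    derivative noise; t1/t2 are the flanking valleys of that peak.
    """
    v = np.asarray(corrected_sta, dtype=float)
    d = _smooth3(np.diff(v), smooth_points)
    c = (len(v) - 1) // 2  # spike-time sample
    n_span = int(round(span_ms * sampling_rate / 1000.0))
    seg = d[c : c + n_span]
    noise_sd = float(np.std(d[: max(c - 1, 1)]))
    pk = int(np.argmax(seg))
    if seg[pk] <= 0 or seg[pk] < noise_sd or pk in (0, len(seg) - 1):
        raise WindowNotFound(
            "no prominent positive dVm/dt peak in the 0-6 ms span"
        )
    i_pk = c + pk
    i1 = _march(d, i_pk, -1, c, c + n_span - 1, tol=noise_sd)
    i2 = _march(d, i_pk, +1, c, c + n_span - 1, tol=noise_sd)
    ms = 1000.0 / sampling_rate
    t1, t_pk, t2 = (i1 - c) * ms, (i_pk - c) * ms, (i2 - c) * ms
    if not (t1 < t_pk < t2):
        raise WindowNotFound("degenerate monosynaptic window")
    return MonosynapticWindow(t1_ms=t1, peak_ms=t_pk, t2_ms=min(t2, span_ms))


def compute_threshold(
    jittered_traces: np.ndarray,
    window: MonosynapticWindow,
    sampling_rate: float,
) -> float:
    """Mean + 1 SD of jittered-trace amplitudes (window-mean of ΔVm).

    ``jittered_traces`` is an (n, span-samples) array of Vm windows taken
    at jittered spike times; each is zeroed at its first sample and its
    amplitude is the mean ΔVm over [t1, t2].
    """
    jt = np.asarray(jittered_traces, dtype=float)
    if jt.ndim != 2 or jt.shape[0] < 100:
        raise ValueError("need at least 100 jittered traces")
    amps = window_mean_amplitudes(jt, window, sampling_rate)
    sd = amps.std(ddof=1)
    if sd == 0:
        warnings.warn("zero-variance jittered amplitudes; threshold = mean")
    return float(amps.mean() + sd)


def window_mean_amplitudes(
    traces: np.ndarray, window: MonosynapticWindow, fs: float
) -> np.ndarray:
    i1 = int(round(window.t1_ms * fs / 1000.0))
    i2 = int(round(window.t2_ms * fs / 1000.0))
    dv = traces - traces[:, :1]
    return dv[:, i1 : i2 + 1].mean(axis=1)


@dataclass
class DetectionResult:
    """Label and measurements for one single-spike trace."""

    label: str  # "detectable" | "undetectable"
    amplitude_mv: float
    t1p_ms: float = np.nan
    t2p_ms: float = np.nan
    peak_slope_mv_per_ms: float = np.nan
    spike_time_s: float = np.nan
    isi_prev_ms: float = np.nan


def detect_single_spike_epsp(
    trial_vm: np.ndarray, config: DetectorConfig
) -> DetectionResult:
    """Classify one zeroed single-spike trace (samples from t=0 to span).

    Searches the trial's dVm/dt for a peak inside the pair's monosynaptic
    window; if found, refines onset/end to t1'/t2' and measures the
    amplitude Vm(t2') - Vm(t1'); the trace is detectable iff that
    amplitude crosses the pair's noise threshold.  Otherwise the trace is
    undetectable and its amplitude is the mean ΔVm over [t1, t2].
    """
    v = np.asarray(trial_vm, dtype=float)
    if np.isnan(v).any():
        raise ValueError("NaNs in single-spike trace")
    fs = config.sampling_rate
    v = v - v[0]
    d_raw = np.diff(v)
    d = _smooth3(d_raw, config.smooth_points) if config.smooth_trials else d_raw
    w = config.window
    i1 = int(round(w.t1_ms * fs / 1000.0))
    i2 = int(round(w.t2_ms * fs / 1000.0))
    i2d = min(i2, len(d) - 1)
    fallback = float(v[i1 : i2 + 1].mean())

    seg = d[i1 : i2d + 1]
    if len(seg) == 0:
        return DetectionResult(label="undetectable", amplitude_mv=fallback)
    pk = i1 + int(np.argmax(seg))
    at_edge = pk in (0, len(d) - 1)
    if d[pk] <= 0 or d[pk] < config.min_prominence_mv or at_edge:
        return DetectionResult(label="undetectable", amplitude_mv=fallback)
    j1 = _march(d, pk, -1, 0, len(d) - 1, tol=config.min_prominence_mv)
    j2 = _march(d, pk, +1, 0, len(d) - 1, tol=config.min_prominence_mv)
    amp = float(v[j2] - v[j1])
    ms = 1000.0 / fs
    if amp >= config.threshold_mv:
        return DetectionResult(
            label="detectable",
            amplitude_mv=amp,
            t1p_ms=j1 * ms,
            t2p_ms=j2 * ms,
            peak_slope_mv_per_ms=float(d[pk]) / ms,
        )
    return DetectionResult(label="undetectable", amplitude_mv=fallback)


def jittered_trial_traces(
    rec,
    span_ms: float = SPAN_MS,
    jitter_range_ms: float | None = None,
    min_traces: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Single-spike-style traces at jittered spike times (noise control)."""
    if jitter_range_ms is None:
        jitter_range_ms = rec.stimulus_frame_ms
    rng = np.random.default_rng(seed)
    n_sp = len(rec.spikes)
    n_draws = max(1, int(np.ceil(min_traces / max(n_sp, 1))))
    L = int(round(span_ms * rec.sampling_rate / 1000.0)) + 1
    out = []
    for _ in range(n_draws):
        jt = rec.spikes + rng.uniform(0, jitter_range_ms / 1000.0, n_sp)
        idx = np.round(jt * rec.sampling_rate).astype(np.int64)
        ok = (idx >= 0) & (idx + L < len(rec.vm))
        out.append(rec.vm[idx[ok, None] + np.arange(L)[None, :]])
    return np.vstack(out)


def build_config(
    rec,
    corrected_sta: np.ndarray,
    span_ms: float = SPAN_MS,
    smooth_points: int = 3,
    smooth_trials: bool = True,
    fixed_threshold_mv: float | None = None,
    seed: int = 0,
) -> DetectorConfig:
    """Derive the per-pair window, threshold and prominence floor."""
    window = derive_monosynaptic_window(
        corrected_sta, rec.sampling_rate, span_ms=span_ms, smooth_points=smooth_points
    )
    jt = jittered_trial_traces(rec, span_ms, seed=seed)
    threshold = (
        fixed_threshold_mv
        if fixed_threshold_mv is not None
        else compute_threshold(jt, window, rec.sampling_rate)
    )
    dv = np.diff(jt - jt[:, :1], axis=1)
    if smooth_trials:
        k = np.ones(smooth_points) / smooth_points
        dv = np.apply_along_axis(np.convolve, 1, dv, k, "same")
    prominence = float(dv.std())
    return DetectorConfig(
        window=window,
        threshold_mv=threshold,
        sampling_rate=rec.sampling_rate,
        span_ms=span_ms,
        smooth_points=smooth_points,
        smooth_trials=smooth_trials,
        min_prominence_mv=prominence,
    )


def batch_detect(
    rec,
    corrected_sta: np.ndarray,
    span_ms: float = SPAN_MS,
    config: DetectorConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Run the detector on every presynaptic spike of a connected pair.

    Returns a per-spike DataFrame (spike_time_s, label, amplitude_mv,
    t1p_ms, t2p_ms, isi_prev_ms) and a pair summary including
    %undetectable = 100 * undetectable / total.
    """
    cfg = config or build_config(rec, corrected_sta, span_ms=span_ms, seed=seed)
    fs = rec.sampling_rate
    L = int(round(cfg.span_ms * fs / 1000.0)) + 1
    idx = np.round(rec.spikes * fs).astype(np.int64)
    usable = (idx >= 0) & (idx + L < len(rec.vm))
    spikes = rec.spikes[usable]
    trials = rec.vm[idx[usable, None] + np.arange(L)[None, :]]
    isi = np.r_[np.nan, np.diff(spikes) * 1000.0]
    recs = []
    for k in range(trials.shape[0]):
        r = detect_single_spike_epsp(trials[k], cfg)
        r.spike_time_s = float(spikes[k])
        r.isi_prev_ms = float(isi[k])
        recs.append(r)
    df = pd.DataFrame(
        {
            "spike_time_s": [r.spike_time_s for r in recs],
            "label": [r.label for r in recs],
            "amplitude_mv": [r.amplitude_mv for r in recs],
            "t1p_ms": [r.t1p_ms for r in recs],
            "t2p_ms": [r.t2p_ms for r in recs],
            "peak_slope_mv_per_ms": [r.peak_slope_mv_per_ms for r in recs],
            "isi_prev_ms": [r.isi_prev_ms for r in recs],
        }
    )
    n = len(df)
    n_und = int((df["label"] == "undetectable").sum())
    summary = {
        "pair_id": getattr(rec, "pair_id", "pair"),
        "n_spikes": n,
        "n_dropped": int(len(rec.spikes) - n),
        "n_detectable": n - n_und,
        "n_undetectable": n_und,
        "pct_undetectable": 100.0 * n_und / n if n else np.nan,
        "threshold_mv": cfg.threshold_mv,
        "t1_ms": cfg.window.t1_ms,
        "t2_ms": cfg.window.t2_ms,
    }
    return df, summary


def audit_detections(trials: np.ndarray, df: pd.DataFrame, config: DetectorConfig,
                     min_run_ms: float = 0.3) -> np.ndarray:
    """Flag detectable labels lacking a contiguous positive-slope run.

    Mirrors a manual-verification pass: a genuine EPSP should rise
    monotonically for at least ``min_run_ms``.  Returns a boolean mask of
    suspect detectable rows.
    """
    fs = config.sampling_rate
    need = int(round(min_run_ms * fs / 1000.0))
    suspect = np.zeros(len(df), dtype=bool)
    for k, (label) in enumerate(df["label"]):
        if label != "detectable":
            continue
        d = np.diff(trials[k])
        run = best = 0
        for x in d:
            run = run + 1 if x > 0 else 0
            best = max(best, run)
        suspect[k] = best < need
    return suspect
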