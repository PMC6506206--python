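"""Spike-triggered-average connectivity analysis with jitter correction.

A monosynaptic LGN -> V1 connection shows up as a sharp, short-latency
EPSP in the average of postsynaptic Vm segments aligned on presynaptic
spikes (the STA).  Because pre- and postsynaptic cells share the visual
stimulus, the raw STA also contains slow stimulus-locked modulation.
Recomputing the STA after jittering each spike time by a uniform amount
up to one stimulus frame preserves that slow component but smears out the
sub-frame synaptic transient; subtracting the jittered STA from the raw
STA isolates the monosynaptic EPSP.

A pair is classified as connected when the jitter-corrected STA shows a
long enough run of samples above a bootstrap null band, with EPSP onset
inside the 1.0-4.5 ms monosynaptic latency window and a 10-90% rise time
under 2 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LATENCY_GATE_MS = (1.0, 4.5)
RISE_TIME_GATE_MS = 2.0
MIN_SUPRA_RUN = 10  # consecutive samples above the band, at 10 kHz = 1 ms


class EmptyInputError(ValueError):
    """No usable spikes after trimming to the trace extent."""


@dataclass
class PairedRecording:
    """One presynaptic spike train paired with a postsynaptic Vm trace."""

    vm: np.ndarray
    sampling_rate: float
    spikes: np.ndarray
    stimulus_frame_ms: float = 16.0
    pair_id: str = "pair"

    def __post_init__(self):
        self.vm = np.asarray(self.vm, dtype=float)
        self.spikes = np.sort(np.asarray(self.spikes, dtype=float))

    @classmethod
    def from_synthetic(cls, rec, cell_id: int = 0, pair_id: str | None = None,
                       stimulus_frame_ms: float = 16.0) -> "PairedRecording":
        """View one cell of a :class:`~tcsyn.synthdata.SyntheticRecording`."""
        return cls(
            vm=rec.vm,
            sampling_rate=rec.sampling_rate,
            spikes=rec.spike_trains[cell_id],
            stimulus_frame_ms=stimulus_frame_ms,
            pair_id=pair_id or f"syn-{cell_id}",
        )


@dataclass
class STAResult:
    """Raw, jittered and corrected STAs plus the connection verdict."""

    raw_sta: np.ndarray
    jittered_sta: np.ndarray
    corrected_sta: np.ndarray
    sem: np.ndarray
    conf_lower: np.ndarray
    conf_upper: np.ndarray
    window_ms: float
    sampling_rate: float
    n_spikes: int
    connected: bool = False
    reasons: list[str] = field(default_factory=list)
    latency_ms: float = np.nan
    rise_time_10_90_ms: float = np.nan
    amplitude_mv: float = np.nan

    def time_ms(self) -> np.ndarray:
        n = len(self.raw_sta)
        return (np.arange(n) - (n - 1) // 2) * 1000.0 / self.sampling_rate


def _segments(rec: PairedRecording, spike_times: np.ndarray, half: int) -> np.ndarray:
    """Stack vm windows of ±half samples around each spike; drop edge spikes."""
    idx = np.round(spike_times * rec.sampling_rate).astype(np.int64)
    ok = (idx - half >= 0) & (idx + half < len(rec.vm))
    idx = idx[ok]
    if len(idx) == 0:
        return np.empty((0, 2 * half + 1))
    offs = np.arange(-half, half + 1)
    return rec.vm[idx[:, None] + offs[None, :]]


def compute_sta(rec: PairedRecording, window_ms: float = 10.0) -> np.ndarray:
    """Mean of Vm segments in ±window_ms around each presynaptic spike."""
    half = int(round(window_ms * rec.sampling_rate / 1000.0))
    seg = _segments(rec, rec.spikes, half)
    if seg.shape[0] < 2:
        raise EmptyInputError("need at least 2 usable spikes for an STA")
    return seg.mean(axis=0)


def jittered_segments(
    rec: PairedRecording,
    window_ms: float = 10.0,
    n_draws: int = 100,
    jitter_range_ms: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-spike Vm windows averaged over uniform jitter draws.

    Each spike is displaced by i.i.d. U(0, jitter_range) per draw (the
    jitter range defaults to one stimulus frame).  Returns an
    (n_spikes, n_samples) array: row i is spike i's mean jittered window.
    Jittered spikes falling outside the trace are dropped per draw.
    """
    if jitter_range_ms is None:
        jitter_range_ms = rec.stimulus_frame_ms
    half = int(round(window_ms * rec.sampling_rate / 1000.0))
    rng = np.random.default_rng(seed)
    n_sp = len(rec.spikes)
    acc = np.zeros((n_sp, 2 * half + 1))
    cnt = np.zeros(n_sp)
    offs = np.arange(-half, half + 1)
    for _ in range(n_draws):
        jt = rec.spikes + rng.uniform(0, jitter_range_ms / 1000.0, n_sp)
        idx = np.round(jt * rec.sampling_rate).astype(np.int64)
        ok = (idx - half >= 0) & (idx + half < len(rec.vm))
        acc[ok] += rec.vm[idx[ok, None] + offs[None, :]]
        cnt += ok
    keep = cnt > 0
    acc[keep] /= cnt[keep, None]
    return acc[keep]


def compute_jittered_sta(
    rec: PairedRecording,
    window_ms: float = 10.0,
    jitter_range_ms: float | None = None,
    n_draws: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """STA over uniformly jittered spike times, averaged over draws."""
    seg = jittered_segments(rec, window_ms, n_draws, jitter_range_ms, seed)
    if seg.shape[0] == 0:
        raise EmptyInputError("no jittered spikes inside the trace")
    return seg.mean(axis=0)


def bootstrap_confidence(
    rec: PairedRecording,
    window_ms: float = 10.0,
    n_boot: int = 1000,
    alpha: float = 0.05,
    jitter_range_ms: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap null band for the jitter-corrected STA.

    Each bootstrap replicate resamples spikes with replacement, jitters
    them by one fresh uniform draw, and computes the STA of the jittered
    resample minus the overall jittered STA.  Under the null (no
    spike-locked transient) the corrected STA is a sample from this
    distribution; the band is its per-sample alpha/2 and 1 - alpha/2
    quantiles.  A connection must push the corrected STA above the upper
    limit for a sustained run.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if jitter_range_ms is None:
        jitter_range_ms = rec.stimulus_frame_ms
    if len(rec.spikes) < 10:
        import warnings

        warnings.warn("fewer than 10 spikes: confidence band will be wide")
    half = int(round(window_ms * rec.sampling_rate / 1000.0))
    rng = np.random.default_rng(seed)
    jit_sta = compute_jittered_sta(
        rec, window_ms, jitter_range_ms, n_draws=100, seed=seed
    )
    n_sp = len(rec.spikes)
    offs = np.arange(-half, half + 1)
    stats = np.empty((n_boot, 2 * half + 1))
    for b in range(n_boot):
        pick = rng.integers(0, n_sp, n_sp)
        jt = rec.spikes[pick] + rng.uniform(0, jitter_range_ms / 1000.0, n_sp)
        idx = np.round(jt * rec.sampling_rate).astype(np.int64)
        ok = (idx - half >= 0) & (idx + half < len(rec.vm))
        seg = rec.vm[idx[ok, None] + offs[None, :]]
        stats[b] = seg.mean(axis=0) - jit_sta
    lower = np.quantile(stats, alpha / 2, axis=0)
    upper = np.quantile(stats, 1 - alpha / 2, axis=0)
    return lower, upper


def _longest_true_run(mask: np.ndarray) -> int:
    best = cur = 0
    for m in mask:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


def _epsp_geometry(corrected: np.ndarray, fs: float, window_ms: float):
    """Onset latency, rise time and amplitude of the corrected-STA EPSP.

    Onset (t1) and peak are taken from the smoothed derivative of the
    corrected STA within 0-6 ms after the spike (the same procedure the
    per-spike detector uses); amplitude is STA(peak) - STA(t1), which
    cancels the roughly constant jitter-smeared pedestal.
    """
    from tcsyn import detector

    try:
        win = detector.derive_monosynaptic_window(corrected, fs, window_ms=window_ms)
    except detector.WindowNotFound:
        return None
    c = (len(corrected) - 1) // 2
    i1 = c + int(round(win.t1_ms * fs / 1000.0))
    i_pk = c + int(round(win.t2_ms * fs / 1000.0))  # t2 = Vm peak of the STA EPSP
    amp = corrected[i_pk] - corrected[i1]
    if amp <= 0:
        return None
    seg = corrected[i1 : i_pk + 1] - corrected[i1]
    t10 = np.argmax(seg >= 0.1 * amp)
    t90 = np.argmax(seg >= 0.9 * amp)
    rise = (t90 - t10) * 1000.0 / fs
    return win.t1_ms, rise, float(amp), i1, i_pk


def classify_connection(res: STAResult, min_run: int = MIN_SUPRA_RUN) -> STAResult:
    """Apply the three monosynaptic gates and fill the verdict in place.

    Gates: (1) >= ``min_run`` consecutive corrected-STA samples above the
    upper confidence limit after the spike; (2) EPSP onset latency inside
    1.0-4.5 ms; (3) 10-90% rise time < 2 ms.
    """
    reasons = []
    c = (len(res.corrected_sta) - 1) // 2
    supra = res.corrected_sta[c:] > res.conf_upper[c:]
    if _longest_true_run(supra) < min_run:
        reasons.append("no supra-band run")
    geom = _epsp_geometry(res.corrected_sta, res.sampling_rate, res.window_ms)
    if geom is None:
        reasons.append("no EPSP-like deflection in corrected STA")
    else:
        lat, rise, amp, _, _ = geom
        res.latency_ms = lat
        res.rise_time_10_90_ms = rise
        res.amplitude_mv = amp
        if not (LATENCY_GATE_MS[0] <= lat <= LATENCY_GATE_MS[1]):
            reasons.append(f"latency outside {LATENCY_GATE_MS[0]}-{LATENCY_GATE_MS[1]} ms")
        if rise >= RISE_TIME_GATE_MS:
            reasons.append("rise time >= 2 ms")
    res.connected = not reasons
    res.reasons = reasons
    return res


def analyze_pair(
    rec: PairedRecording,
    window_ms: float = 10.0,
    jitter_range_ms: float | None = None,
    n_jitter_draws: int = 100,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> STAResult:
    """Full STA pipeline: raw, jittered, corrected, bands, verdict."""
    half = int(round(window_ms * rec.sampling_rate / 1000.0))
    seg = _segments(rec, rec.spikes, half)
    if seg.shape[0] < 2:
        raise EmptyInputError("need at least 2 usable spikes")
    raw = seg.mean(axis=0)
    sem = seg.std(axis=0, ddof=1) / np.sqrt(seg.shape[0])
    jit = compute_jittered_sta(rec, window_ms, jitter_range_ms, n_jitter_draws, seed)
    corrected = raw - jit
    lo, hi = bootstrap_confidence(
        rec, window_ms, n_boot, alpha, jitter_range_ms, seed=seed + 1
    )
    res = STAResult(
        raw_sta=raw,
        jittered_sta=jit,
        corrected_sta=corrected,
        sem=sem,
        conf_lower=lo,
        conf_upper=hi,
        window_ms=window_ms,
        sampling_rate=rec.sampling_rate,
        n_spikes=seg.shape[0],
    )
    return classify_connection(res)
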