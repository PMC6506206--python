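"""Ground-truth-labeled synthetic paired recordings.

Generates the three ingredients of an LGN -> V1 paired recording:

* a spatiotemporal white-noise stimulus (4-level contrast frames organized
  in blocks separated by uniform-gray gaps),
* stimulus-driven LGN spike trains from a linear-nonlinear-Poisson (LNP)
  population with ON/OFF center-surround stand-ins and an absolute
  refractory period,
* an intracellular V1 membrane-potential (Vm) trace in which each
  presynaptic spike either transmits (adding a double-exponential EPSP of
  a drawn amplitude at a jittered latency) or fails (adding nothing),
  riding on colored Vm noise.

Every stochastic step consumes an explicit seed and every presynaptic
spike is logged in a truth table, so downstream detection and statistics
can be validated against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DEFAULT_CONTRAST_LEVELS = (-1.0, -1.0 / 3.0, 1.0 / 3.0, 1.0)

# Temporal weighting of recent stimulus frames in the LGN rate model
# (index = number of frames back).  Peaked 3-4 frames (~50-70 ms) before
# the response, matching geniculate response latencies to flashed frames.
DEFAULT_TEMPORAL_KERNEL = (0.0, 0.05, 0.20, 0.40, 0.25, 0.10)


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration."""


# ---------------------------------------------------------------------------
# Stimulus
# ---------------------------------------------------------------------------

@dataclass
class WhiteNoiseStimulus:
    """Blocked spatiotemporal white-noise stimulus.

    ``frames`` holds contrast values (one of ``contrast_levels``) per
    (frame, row, col).  Frames play in blocks of ``block_length`` at
    ``frame_duration_ms`` per frame, with ``gray_gap_s`` of zero-contrast
    gray between blocks.
    """

    frames: np.ndarray
    frame_duration_ms: float = 16.0
    contrast_levels: tuple = DEFAULT_CONTRAST_LEVELS
    block_length: int = 250
    gray_gap_s: float = 1.0
    field_size_deg: float = 4.0

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.frames.shape[1] * self.frames.shape[2]

    @property
    def n_blocks(self) -> int:
        return int(np.ceil(self.n_frames / self.block_length))

    @property
    def total_duration_s(self) -> float:
        """Duration including inter-block gray gaps (no trailing gap)."""
        block_s = self.block_length * self.frame_duration_ms / 1000.0
        return self.n_blocks * block_s + (self.n_blocks - 1) * self.gray_gap_s

    def frame_onsets(self) -> np.ndarray:
        """Onset time (s) of every frame, accounting for gray gaps."""
        block_s = self.block_length * self.frame_duration_ms / 1000.0
        idx = np.arange(self.n_frames)
        block = idx // self.block_length
        within = idx % self.block_length
        return block * (block_s + self.gray_gap_s) + within * (
            self.frame_duration_ms / 1000.0
        )

    def frame_index_at(self, t: np.ndarray) -> np.ndarray:
        """Frame shown at each time (s); -1 during gray gaps / outside."""
        onsets = self.frame_onsets()
        j = np.searchsorted(onsets, np.atleast_1d(t), side="right") - 1
        j = np.clip(j, 0, self.n_frames - 1)
        dt_frame = self.frame_duration_ms / 1000.0
        tt = np.atleast_1d(t)
        inside = (tt >= onsets[j]) & (tt < onsets[j] + dt_frame)
        return np.where(inside, j, -1)


def generate_white_noise_stimulus(
    n_blocks: int = 18,
    seed: int = 0,
    shape: tuple[int, int] = (16, 16),
    frame_duration_ms: float = 16.0,
    block_length: int = 250,
    gray_gap_s: float = 1.0,
    contrast_levels: tuple = DEFAULT_CONTRAST_LEVELS,
    allow_nonstandard_levels: bool = False,
) -> WhiteNoiseStimulus:
    """Draw a blocked 4-level white-noise stimulus (deterministic per seed)."""
    if n_blocks < 1:
        raise ConfigurationError("n_blocks must be >= 1")
    if frame_duration_ms <= 0:
        raise ConfigurationError("frame_duration_ms must be > 0")
    if len(contrast_levels) != 4 and not allow_nonstandard_levels:
        raise ConfigurationError(
            "expected exactly 4 contrast levels; pass "
            "allow_nonstandard_levels=True to override"
        )
    rng = np.random.default_rng(seed)
    levels = np.asarray(contrast_levels, dtype=float)
    n_frames = n_blocks * block_length
    idx = rng.integers(0, len(levels), size=(n_frames, *shape))
    return WhiteNoiseStimulus(
        frames=levels[idx],
        frame_duration_ms=frame_duration_ms,
        contrast_levels=tuple(contrast_levels),
        block_length=block_length,
        gray_gap_s=gray_gap_s,
    )


# ---------------------------------------------------------------------------
# LGN population
# ---------------------------------------------------------------------------

@dataclass
class LGNCellModel:
    """LNP stand-in for a recorded LGN relay cell.

    ``sign`` (+1 ON, -1 OFF) flips the polarity of the spatial filter;
    ``gain`` is Hz per unit filtered contrast (``None`` = auto-scaled in
    :func:`simulate_lgn_spikes` so one SD of drive equals ``baseline_rate``,
    i.e. full modulation depth).
    """

    rf_center: tuple[float, float]
    rf_width: float = 0.3
    sign: int = 1
    baseline_rate: float = 10.0
    gain: float | None = None
    modulation_depth: float = 2.0  # SDs of drive per baseline when gain is auto
    refractory_ms: float = 1.0
    temporal_kernel: tuple = DEFAULT_TEMPORAL_KERNEL

    def __post_init__(self):
        if self.baseline_rate < 0:
            raise ConfigurationError("baseline_rate must be >= 0")
        if self.refractory_ms < 0:
            raise ConfigurationError("refractory_ms must be >= 0")
        if self.sign not in (-1, 1):
            raise ConfigurationError("sign must be +1 (ON) or -1 (OFF)")

    def spatial_weights(self, shape: tuple[int, int], field_size_deg: float) -> np.ndarray:
        """Gaussian RF-center weights on the stimulus pixel grid (sum = 1)."""
        rows, cols = shape
        px = field_size_deg / cols
        x = (np.arange(cols) + 0.5) * px
        y = (np.arange(rows) + 0.5) * (field_size_deg / rows)
        xx, yy = np.meshgrid(x, y)
        cx, cy = self.rf_center
        w = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * self.rf_width**2))
        s = w.sum()
        return w / s if s > 0 else w


def generate_lgn_population(
    n_cells: int = 50,
    rf_layout: list[tuple[float, int]] | None = None,
    seed: int = 0,
    field_size_deg: float = 4.0,
    baseline_range_hz: tuple[float, float] = (6.0, 18.0),
    rf_width_deg: float = 0.3,
) -> list[LGNCellModel]:
    """Place ON and OFF cells along parallel elongated rows (simple-cell-like).

    ``rf_layout`` is a list of (row y position in degrees, sign) bands;
    the default is four alternating ON/OFF rows, producing a population RF
    with elongated ON and OFF subregions like a V1 simple cell.
    """
    if n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    if n_cells > 50:
        raise ConfigurationError("n_cells must be <= 50")
    rng = np.random.default_rng(seed)
    if rf_layout is None:
        ys = np.linspace(0.3, 0.7, 4) * field_size_deg
        rf_layout = [(ys[0], 1), (ys[1], -1), (ys[2], 1), (ys[3], -1)]
    cells = []
    for i in range(n_cells):
        y_row, sign = rf_layout[i % len(rf_layout)]
        # spread along the row with a little scatter; rows span the central
        # half of the field so neighboring RFs overlap (correlated drive)
        frac = ((i // len(rf_layout)) + 0.5) / max(1, -(-n_cells // len(rf_layout)))
        x = (0.3 + 0.4 * frac) * field_size_deg + rng.normal(0, 0.04 * field_size_deg)
        y = y_row + rng.normal(0, 0.04 * field_size_deg)
        cells.append(
            LGNCellModel(
                rf_center=(float(x), float(y)),
                rf_width=rf_width_deg,
                sign=int(sign),
                baseline_rate=float(rng.uniform(*baseline_range_hz)),
            )
        )
    return cells


def population_rf(
    cells: list[LGNCellModel],
    shape: tuple[int, int] = (16, 16),
    field_size_deg: float = 4.0,
) -> np.ndarray:
    """Sign-weighted sum of RF-center Gaussians on the pixel grid."""
    rf = np.zeros(shape)
    for c in cells:
        rf += c.sign * c.spatial_weights(shape, field_size_deg)
    return rf


def poisson_train(
    rate_hz: float,
    duration_s: float,
    refractory_ms: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Homogeneous Poisson spike train with an absolute dead time."""
    rng = np.random.default_rng(seed)
    if rate_hz <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * duration_s)
    cand = np.sort(rng.uniform(0, duration_s, size=n))
    return _enforce_refractory(cand, refractory_ms / 1000.0)


def _enforce_refractory(times: np.ndarray, dead_s: float) -> np.ndarray:
    if dead_s <= 0 or len(times) == 0:
        return times
    keep = []
    last = -np.inf
    for t in times:
        if t - last >= dead_s:
            keep.append(t)
            last = t
    return np.asarray(keep)


def lgn_rate_trace(
    stimulus: WhiteNoiseStimulus,
    cell: LGNCellModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame firing rate (Hz) for one cell, plus frame onsets (s).

    rate_j = max(0, baseline + gain * s_j) where s_j is the sign-flipped,
    spatially and temporally filtered contrast of frame j.  The temporal
    filter is causal over recent frames and does not cross block gaps.
    """
    w = cell.spatial_weights(stimulus.frames.shape[1:], stimulus.field_size_deg)
    f = np.tensordot(stimulus.frames, w, axes=([1, 2], [0, 1])) * cell.sign
    k = np.asarray(cell.temporal_kernel, dtype=float)
    k = k / k.sum()
    s = np.zeros_like(f)
    nb = stimulus.block_length
    for b in range(stimulus.n_blocks):
        blk = f[b * nb : (b + 1) * nb]
        s[b * nb : b * nb + len(blk)] = np.convolve(blk, k)[: len(blk)]
    sd = s.std()
    gain = cell.gain if cell.gain is not None else (
        cell.modulation_depth * cell.baseline_rate / sd if sd > 0 else 0.0
    )
    rate = np.clip(cell.baseline_rate + gain * s, 0.0, None)
    return rate, stimulus.frame_onsets()


def simulate_lgn_spikes(
    stimulus: WhiteNoiseStimulus,
    cells: list[LGNCellModel],
    duration_s: float | None = None,
    seed: int = 0,
) -> dict[int, np.ndarray]:
    """Inhomogeneous Poisson spikes (thinning) with absolute refractoriness.

    Rates are piecewise constant at frame resolution; during gray gaps the
    rate falls back to the cell's baseline.  Negative instantaneous rates
    are clipped at zero.
    """
    if duration_s is None:
        duration_s = stimulus.total_duration_s
    rng = np.random.default_rng(seed)
    onsets = stimulus.frame_onsets()
    dt_frame = stimulus.frame_duration_ms / 1000.0
    trains: dict[int, np.ndarray] = {}
    for i, cell in enumerate(cells):
        rate, _ = lgn_rate_trace(stimulus, cell)
        rmax = max(float(rate.max()), cell.baseline_rate, 1e-9)
        n = rng.poisson(rmax * duration_s)
        cand = np.sort(rng.uniform(0, duration_s, size=n))
        j = np.searchsorted(onsets, cand, side="right") - 1
        j = np.clip(j, 0, len(onsets) - 1)
        in_frame = (cand >= onsets[j]) & (cand < onsets[j] + dt_frame)
        r = np.where(in_frame, rate[j], cell.baseline_rate)
        accepted = cand[rng.uniform(0, rmax, size=n) < r]
        trains[i] = _enforce_refractory(accepted, cell.refractory_ms / 1000.0)
    return trains


# ---------------------------------------------------------------------------
# Synapses and Vm synthesis
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthSynapse:
    """Generative parameters of one thalamocortical synapse.

    ``mean_amp``/``amp_cv`` describe the log-normal amplitude distribution
    of *transmitted* events; ``p_fail`` is the per-spike probability that
    the spike adds no EPSP at all (the operational "undetectable" ground
    truth).  ``stsd_depress``/``stsd_tau_ms`` implement short-term
    depression: a spike at inter-spike interval ISI has its mean amplitude
    multiplied by ``1 - stsd_depress * exp(-ISI / stsd_tau_ms)``.
    """

    mean_amp: float = 0.9
    amp_cv: float = 0.5
    p_fail: float = 0.37
    latency_ms: float = 2.5
    latency_jitter_ms: float = 0.3
    stsd_depress: float = 0.0
    stsd_tau_ms: float = 60.0
    min_amp: float = 0.0  # floor on drawn amplitudes (0 = plain log-normal)

    def __post_init__(self):
        # p_fail = 1 is allowed as a degenerate always-fails control
        if not (0 <= self.p_fail <= 1):
            raise ConfigurationError("p_fail must be in [0, 1]")
        if self.mean_amp <= 0:
            raise ConfigurationError("mean_amp must be > 0")


def sample_synapse_cohort(
    n_pairs: int,
    seed: int = 0,
    stsd_depress: float = 0.0,
    stsd_tau_ms: float = 60.0,
) -> list[GroundTruthSynapse]:
    """Draw a cohort of synapses with monotone-coupled parameters.

    Larger mean amplitude implies lower failure probability and lower
    amplitude CV (binomial-release-like coupling).  Marginals approximate
    the in vivo population: detectable-event mean near 0.9 mV, failure
    probabilities mostly between ~10% and ~55%.
    """
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1 + 0.28**2))
    mean_amp = np.clip(
        rng.lognormal(np.log(0.9) - sigma**2 / 2, sigma, n_pairs), 0.35, 2.0
    )
    p_fail = np.clip(
        0.72 - 0.39 * mean_amp + rng.normal(0, 0.07, n_pairs), 0.05, 0.60
    )
    amp_cv = np.clip(
        0.85 - 0.30 * mean_amp + rng.normal(0, 0.08, n_pairs), 0.25, 1.10
    )
    return [
        GroundTruthSynapse(
            mean_amp=float(m),
            amp_cv=float(c),
            p_fail=float(p),
            stsd_depress=stsd_depress,
            stsd_tau_ms=stsd_tau_ms,
        )
        for m, c, p in zip(mean_amp, amp_cv, p_fail)
    ]


@dataclass
class NoiseParams:
    """Vm noise model: white + Ornstein-Uhlenbeck + slow stimulus-locked.

    In vivo Vm fluctuations are dominated by synaptic background with a
    ~10 ms correlation time; broadband instrument noise is small.  The
    default split reflects that (OU carries ~96% of the variance).
    IPSP-like contamination (negative double-exponential events at a
    Poisson rate) is off by default.
    """

    white_sd: float = 0.06
    ou_sd: float = 0.29
    ou_tau_ms: float = 10.0
    slow_amp: float = 0.0
    slow_freq_hz: float = 2.0
    ipsp_rate_hz: float = 0.0
    ipsp_amp_mv: float = 0.3

    @classmethod
    def from_total_sd(cls, total_sd: float, white_var_frac: float = 0.04, **kw) -> "NoiseParams":
        return cls(
            white_sd=float(np.sqrt(white_var_frac) * total_sd),
            ou_sd=float(np.sqrt(1 - white_var_frac) * total_sd),
            **kw,
        )

    @property
    def total_sd(self) -> float:
        return float(np.hypot(self.white_sd, self.ou_sd))


def epsp_kernel(
    sampling_rate: float,
    tau_rise_ms: float = 0.5,
    tau_decay_ms: float = 2.0,
    duration_ms: float = 20.0,
) -> np.ndarray:
    """Peak-normalized difference-of-exponentials EPSP waveform."""
    t = np.arange(0, duration_ms, 1000.0 / sampling_rate)
    k = np.exp(-t / tau_decay_ms) - np.exp(-t / tau_rise_ms)
    return k / k.max()


@dataclass
class SyntheticRecording:
    """One synthetic V1 Vm trace plus presynaptic trains and truth table.

    ``truth`` has exactly one row per presynaptic spike with columns
    cell_id, spike_time_s, transmitted (bool), amplitude_mv (drawn EPSP
    amplitude; NaN for failures) and latency_ms.
    """

    vm: np.ndarray
    sampling_rate: float
    spike_trains: dict[int, np.ndarray]
    truth: pd.DataFrame
    synapses: dict[int, GroundTruthSynapse]
    noise: NoiseParams
    rest_vm: float = -65.0

    @property
    def duration_s(self) -> float:
        return len(self.vm) / self.sampling_rate

    def time(self) -> np.ndarray:
        return np.arange(len(self.vm)) / self.sampling_rate


def _ou_scan(x, a):
    """In-place AR(1) scan: x[i] <- a*x[i-1] + x[i]."""
    for i in range(1, len(x)):
        x[i] = a * x[i - 1] + x[i]
    return x


try:  # optional acceleration; pure-Python scan is the fallback
    from numba import njit as _njit

    _ou_core = _njit(cache=True)(_ou_scan)
except Exception:  # pragma: no cover
    _ou_core = None


def synthesize_vm(
    spike_trains: dict[int, np.ndarray],
    synapses: dict[int, GroundTruthSynapse] | GroundTruthSynapse,
    noise: NoiseParams | None = None,
    duration_s: float | None = None,
    sampling_rate: float = 10_000.0,
    rest_vm: float = -65.0,
    seed: int = 0,
    stimulus: WhiteNoiseStimulus | None = None,
) -> SyntheticRecording:
    """Superpose EPSPs from transmitted spikes on colored Vm noise.

    Each presynaptic spike draws (per its synapse) a Bernoulli transmission
    outcome, a log-normal amplitude scaled by the short-term-depression
    factor of its preceding ISI, and a Gaussian-jittered latency.
    """
    if sampling_rate < 1000:
        raise ConfigurationError(
            "sampling_rate below 1 kHz: detector needs sub-ms resolution"
        )
    if isinstance(synapses, GroundTruthSynapse):
        synapses = {cid: synapses for cid in spike_trains}
    if set(spike_trains) - set(synapses):
        raise ConfigurationError("every spike train needs a synapse")
    noise = noise or NoiseParams()
    if duration_s is None:
        tmax = max((t[-1] for t in spike_trains.values() if len(t)), default=0.0)
        duration_s = tmax + 0.05
    n = int(round(duration_s * sampling_rate)) + 1
    rng = np.random.default_rng(seed)
    vm = np.zeros(n)
    kern = epsp_kernel(sampling_rate)
    rows = []
    for cid in sorted(spike_trains):
        times = np.sort(np.asarray(spike_trains[cid], dtype=float))
        syn = synapses[cid]
        if len(times) == 0:
            continue
        isi_ms = np.r_[np.inf, np.diff(times) * 1000.0]
        depress = 1.0 - syn.stsd_depress * np.exp(-isi_ms / syn.stsd_tau_ms)
        transmitted = rng.uniform(size=len(times)) >= syn.p_fail
        sig = np.sqrt(np.log(1 + syn.amp_cv**2))
        amps = rng.lognormal(np.log(syn.mean_amp) - sig**2 / 2, sig, len(times))
        amps = np.maximum(amps * depress, syn.min_amp)
        lat = syn.latency_ms + np.clip(
            rng.normal(0, syn.latency_jitter_ms, len(times)),
            -3 * syn.latency_jitter_ms,
            3 * syn.latency_jitter_ms,
        )
        for t, ok, a, l in zip(times, transmitted, amps, lat):
            if ok:
                i0 = int(round((t + l / 1000.0) * sampling_rate))
                if 0 <= i0 < n:
                    seg = kern[: n - i0]
                    vm[i0 : i0 + len(seg)] += a * seg
            rows.append((cid, t, bool(ok), a if ok else np.nan, l))
    truth = pd.DataFrame(
        rows, columns=["cell_id", "spike_time_s", "transmitted", "amplitude_mv", "latency_ms"]
    )

    if noise.white_sd > 0:
        vm += rng.normal(0, noise.white_sd, n)
    if noise.ou_sd > 0:
        a = np.exp(-1000.0 / (sampling_rate * noise.ou_tau_ms))
        x = np.empty(n)
        x[0] = rng.normal(0, noise.ou_sd)
        x[1:] = rng.normal(0, noise.ou_sd * np.sqrt(1 - a * a), n - 1)
        if _ou_core is not None:
            vm += _ou_core(x, a)
        else:
            vm += _ou_scan(x, a)
    if noise.slow_amp > 0:
        t = np.arange(n) / sampling_rate
        if stimulus is not None:
            # stimulus-locked slow modulation: smoothed random projection
            # of the frame sequence, scaled to the requested SD
            wrng = np.random.default_rng(12345)
            w = wrng.normal(size=stimulus.frames.shape[1:])
            proj = np.tensordot(stimulus.frames, w, axes=([1, 2], [0, 1]))
            j = stimulus.frame_index_at(t)
            sig = np.where(j >= 0, proj[np.clip(j, 0, None)], 0.0)
            from scipy.ndimage import gaussian_filter1d

            sig = gaussian_filter1d(sig, sigma=0.02 * sampling_rate)
            sd = sig.std()
            if sd > 0:
                vm += noise.slow_amp * sig / sd
        else:
            vm += noise.slow_amp * np.sin(2 * np.pi * noise.slow_freq_hz * t)
    if noise.ipsp_rate_hz > 0:
        ipsp = epsp_kernel(sampling_rate, tau_rise_ms=1.0, tau_decay_ms=6.0)
        n_ev = rng.poisson(noise.ipsp_rate_hz * duration_s)
        for t in rng.uniform(0, duration_s, n_ev):
            i0 = int(round(t * sampling_rate))
            amp = abs(rng.normal(noise.ipsp_amp_mv, 0.3 * noise.ipsp_amp_mv))
            seg = ipsp[: n - i0]
            vm[i0 : i0 + len(seg)] -= amp * seg

    return SyntheticRecording(
        vm=vm + rest_vm,
        sampling_rate=sampling_rate,
        spike_trains={k: np.sort(np.asarray(v, float)) for k, v in spike_trains.items()},
        truth=truth,
        synapses=dict(synapses),
        noise=noise,
        rest_vm=rest_vm,
    )


def sample_detection_table(
    synapse: GroundTruthSynapse,
    n_spikes: int = 2000,
    rate_hz: float = 15.0,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Ground-truth per-spike detection table without Vm synthesis.

    Draws the same per-spike quantities the generator embeds in a Vm
    trace — exponential ISIs, Bernoulli failures, log-normal amplitudes
    scaled by the short-term-depression factor — and emits them in the
    detector's output format (label, amplitude_mv, isi_prev_ms), with
    failed spikes carrying a window-noise amplitude centered on zero.
    Useful for statistics-level analyses where the detector itself is
    not under test.
    """
    rng = np.random.default_rng(seed)
    isi_s = rng.exponential(1.0 / rate_hz, n_spikes)
    times = np.cumsum(isi_s)
    isi_ms = np.r_[np.nan, np.diff(times) * 1000.0]
    depress = 1.0 - synapse.stsd_depress * np.exp(
        -np.nan_to_num(isi_ms, nan=np.inf) / synapse.stsd_tau_ms
    )
    transmitted = rng.uniform(size=n_spikes) >= synapse.p_fail
    sig = np.sqrt(np.log(1 + synapse.amp_cv**2))
    amps = rng.lognormal(np.log(synapse.mean_amp) - sig**2 / 2, sig, n_spikes)
    amps = np.maximum(amps * depress, synapse.min_amp)
    noise_amp = rng.normal(0, noise_sd, n_spikes)
    return pd.DataFrame(
        {
            "spike_time_s": times,
            "label": np.where(transmitted, "detectable", "undetectable"),
            "amplitude_mv": np.where(transmitted, amps + noise_amp, noise_amp),
            "isi_prev_ms": isi_ms,
        }
    )


def generate_pair(
    synapse: GroundTruthSynapse,
    rate_hz: float = 8.0,
    duration_s: float = 125.0,
    noise: NoiseParams | None = None,
    seed: int = 0,
    sampling_rate: float = 10_000.0,
) -> SyntheticRecording:
    """Convenience: one synapse driven by a dead-time Poisson train."""
    train = poisson_train(rate_hz, duration_s, refractory_ms=1.0, seed=seed)
    return synthesize_vm(
        {0: train},
        {0: synapse},
        noise=noise,
        duration_s=duration_s,
        sampling_rate=sampling_rate,
        seed=seed + 1,
    )
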