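"""Conductance-driven leaky integrate-and-fire model of a V1 simple cell.

The model asks what unreliable, variable thalamocortical synapses buy
the cortex: up to 50 LGN spike trains are converted into excitatory
postsynaptic conductances (EPSGs, difference-of-exponentials with 0.5 ms
rise and 2 ms decay) and injected into a single-compartment LIF neuron
(rest -65 mV, threshold -55 mV, reset -60 mV, Rm 47 MOhm, tau_m 6 ms,
2 ms refractory, forward Euler at 0.1 ms).

Two synapse regimes are compared at matched average drive:

* ``reliable`` — every presynaptic spike injects a constant-amplitude
  EPSG;
* ``unreliable`` — a per-synapse fraction of spikes fail outright and
  transmitted amplitudes vary (log-normal), as measured in vivo.

Because mean depolarization stays below threshold, spiking is
fluctuation-driven: the extra membrane-potential variance contributed by
failures and amplitude variability converts into a higher firing rate at
identical mean Vm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from tcsyn import synthdata

DRYAD_ACCESSION = "http://dx.doi.org/10.5061/dryad.57pv818"
MODES = ("reliable", "unreliable", "unreliable_const_amp", "correlated_failure")


@dataclass
class LIFParams:
    """Membrane and integration parameters (mV, ms, MOhm)."""

    v_rest: float = -65.0
    v_thresh: float = -55.0
    v_reset: float = -60.0
    refractory_ms: float = 2.0
    r_m_mohm: float = 47.0
    tau_m_ms: float = 6.0
    dt_ms: float = 0.1
    e_exc_mv: float = 0.0
    duration_s: float = 89.0

    def __post_init__(self):
        if self.v_reset >= self.v_thresh:
            raise ValueError("v_reset must be below v_thresh")
        if self.dt_ms > 0.1:
            raise ValueError("dt must be <= 0.1 ms")

    @property
    def capacitance_nf(self) -> float:
        return self.tau_m_ms / self.r_m_mohm


@dataclass
class EPSGKernel:
    """Unit-peak difference-of-exponentials conductance waveform."""

    tau_rise_ms: float
    tau_decay_ms: float
    dt_ms: float
    samples: np.ndarray

    @property
    def peak_time_ms(self) -> float:
        tr, td = self.tau_rise_ms, self.tau_decay_ms
        return np.log(td / tr) * tr * td / (td - tr)

    @property
    def integral_ms(self) -> float:
        return float(self.samples.sum() * self.dt_ms)


def build_epsg_kernel(
    tau_rise_ms: float = 0.5,
    tau_decay_ms: float = 2.0,
    dt_ms: float = 0.1,
) -> EPSGKernel:
    """Peak-normalized EPSG kernel, truncated at 10 decay constants."""
    if tau_rise_ms <= 0 or tau_decay_ms <= 0:
        raise ValueError("time constants must be positive")
    if tau_rise_ms >= tau_decay_ms:
        raise ValueError("tau_rise must be smaller than tau_decay")
    t = np.arange(0, 10 * tau_decay_ms, dt_ms)
    k = np.exp(-t / tau_decay_ms) - np.exp(-t / tau_rise_ms)
    return EPSGKernel(tau_rise_ms, tau_decay_ms, dt_ms, k / k.max())


@dataclass
class SynapseSpec:
    """Transmission regime and amplitude statistics of one model synapse.

    ``mean_epsg`` is the mean conductance amplitude (nS) of *transmitted*
    events; ``p_fail`` the per-spike failure probability; ``amp_cv`` the
    CV of the log-normal amplitude distribution (ignored for reliable and
    constant-amplitude modes).  ``conversion_factor`` is the opaque
    calibration constant used only when importing measured EPSP
    amplitudes (mV) from the deposited dataset.
    """

    mode: str = "unreliable"
    mean_epsg: float = 0.89
    amp_cv: float = 0.5
    p_fail: float = 0.37
    stsd: tuple[float, float] | None = None  # (depress, tau_ms)
    conversion_factor: float = 6e8

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "reliable" and self.p_fail != 0:
            raise ValueError("reliable synapses cannot fail")
        if not (0 <= self.p_fail < 1):
            raise ValueError("p_fail must be in [0, 1)")


def assign_synapses(
    n_inputs: int,
    source: str = "parametric",
    seed: int = 0,
    mode: str = "unreliable",
    dataset: pd.DataFrame | None = None,
    target_mean_epsg: float = 0.89,
) -> list[SynapseSpec]:
    """Draw jointly coupled (mean, CV, p_fail) triplets for each input.

    ``parametric`` draws triplets from the synthetic cohort model (larger
    mean amplitude -> lower failure rate and CV) and rescales amplitudes
    so the mean EPSG across inputs equals ``target_mean_epsg`` (nS).
    ``dataset`` permutes triplets from an imported table of measured
    pairs (columns mean_amp_mv, amp_cv, p_fail); amplitudes are converted
    from mV with the opaque calibration factor.  Triplets are never mixed
    across synapses.
    """
    if not (1 <= n_inputs <= 50):
        raise ValueError("n_inputs must be in [1, 50]")
    rng = np.random.default_rng(seed)
    if source == "parametric":
        cohort = synthdata.sample_synapse_cohort(n_inputs, seed=seed)
        amps = np.array([s.mean_amp for s in cohort])
        amps *= target_mean_epsg / amps.mean()
        return [
            SynapseSpec(
                mode=mode,
                mean_epsg=float(a),
                amp_cv=s.amp_cv,
                p_fail=0.0 if mode == "reliable" else s.p_fail,
            )
            for a, s in zip(amps, cohort)
        ]
    if source == "dataset":
        if dataset is None:
            raise FileNotFoundError(
                "dataset source requires the deposited pair table "
                f"(Dryad, {DRYAD_ACCESSION})"
            )
        rows = dataset.sample(
            n=n_inputs, replace=n_inputs > len(dataset), random_state=rng.integers(2**31)
        )
        return [
            SynapseSpec(
                mode=mode,
                mean_epsg=float(r.mean_amp_mv) * 6e8 * 1e-9,
                amp_cv=float(r.amp_cv),
                p_fail=0.0 if mode == "reliable" else float(r.p_fail),
            )
            for r in rows.itertuples()
        ]
    raise ValueError(f"unknown source {source!r}")


def calibrate_equal_drive(
    unreliable_specs: list[SynapseSpec], mode: str = "total-drive"
) -> list[SynapseSpec]:
    """Reliable counterparts injecting the same average conductance.

    ``total-drive`` (default) sets the constant reliable amplitude to the
    unreliable synapse's event mean times its transmission probability,
    so the time-averaged injected conductance matches; ``event-mean``
    copies the event mean unchanged.
    """
    if mode not in ("total-drive", "event-mean"):
        raise ValueError("mode must be 'total-drive' or 'event-mean'")
    out = []
    for s in unreliable_specs:
        amp = s.mean_epsg * (1 - s.p_fail) if mode == "total-drive" else s.mean_epsg
        out.append(replace(s, mode="reliable", mean_epsg=amp, p_fail=0.0, amp_cv=0.0))
    return out


def apply_failures(
    spike_train: np.ndarray,
    spec: SynapseSpec,
    others: list[np.ndarray] | None = None,
    seed: int = 0,
    coincidence_ms: float = 5.0,
    boost: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Select failed spikes; returns (transmitted times, failure mask).

    Random modes fail each spike i.i.d. with ``p_fail``.  In
    ``correlated_failure`` mode spikes coincident (within
    ``coincidence_ms``) with any spike of the other inputs fail with a
    boosted probability, rescaled so the marginal failure rate still
    equals ``p_fail``.
    """
    t = np.asarray(spike_train, dtype=float)
    rng = np.random.default_rng(seed)
    if spec.mode == "reliable" or spec.p_fail == 0:
        return t, np.zeros(len(t), dtype=bool)
    if spec.mode == "correlated_failure":
        if not others:
            raise ValueError("correlated_failure needs the other spike trains")
        pool = np.sort(np.concatenate(others))
        d = coincidence_ms / 1000.0
        j = np.searchsorted(pool, t)
        near_lo = np.abs(t - pool[np.clip(j - 1, 0, len(pool) - 1)]) <= d
        near_hi = np.abs(pool[np.clip(j, 0, len(pool) - 1)] - t) <= d
        coinc = near_lo | near_hi
        f = coinc.mean()
        p = spec.p_fail
        p_c = min(boost * p, 0.95)
        if f > 0:
            p_nc = (p - f * p_c) / (1 - f) if f < 1 else p
            if p_nc < 0:  # not enough non-coincident mass; lower the boost
                p_c, p_nc = p / f, 0.0
        else:
            p_nc = p
        prob = np.where(coinc, p_c, p_nc)
        fail = rng.uniform(size=len(t)) < prob
    else:
        fail = rng.uniform(size=len(t)) < spec.p_fail
    return t[~fail], fail


def _draw_amplitudes(spec: SynapseSpec, times: np.ndarray, rng) -> np.ndarray:
    if spec.mode in ("reliable", "unreliable_const_amp") or spec.amp_cv == 0:
        amps = np.full(len(times), spec.mean_epsg)
    else:
        sig = np.sqrt(np.log(1 + spec.amp_cv**2))
        amps = rng.lognormal(np.log(spec.mean_epsg) - sig**2 / 2, sig, len(times))
    if spec.stsd is not None and len(times) > 1:
        depress, tau = spec.stsd
        isi_ms = np.r_[np.inf, np.diff(times) * 1000.0]
        amps = amps * (1 - depress * np.exp(-isi_ms / tau))
    return amps


def _lif_euler_gi(g, gi, dt, tau_m, rm, v_rest, v_thresh, v_reset, e_exc,
                  e_inh, ref_steps):
    """Forward-Euler LIF scan with excitatory and inhibitory conductances.

    Returns (vm, spike sample indices); spike samples carry a 0 mV
    action-potential marker.
    """
    n = len(g)
    vm = np.empty(n)
    spikes = []
    v = v_rest
    ref = 0
    gfac = 1e-3 * rm  # MOhm * nS -> dimensionless conductance ratio
    for i in range(n):
        if ref > 0:
            ref -= 1
            v = v_reset
            vm[i] = v
            continue
        drive = gfac * (g[i] * (e_exc - v) + gi[i] * (e_inh - v))
        v = v + dt * ((v_rest - v) + drive) / tau_m
        if v >= v_thresh:
            spikes.append(i)
            vm[i] = 0.0
            v = v_reset
            ref = ref_steps
        else:
            vm[i] = v
    return vm, np.array(spikes, dtype=np.int64)


def _lif_euler(g, dt, tau_m, rm, v_rest, v_thresh, v_reset, e_exc, ref_steps):
    """Excitation-only wrapper around :func:`_lif_euler_gi`."""
    return _lif_euler_gi(g, np.zeros_like(g), dt, tau_m, rm, v_rest,
                         v_thresh, v_reset, e_exc, -75.0, ref_steps)


try:  # optional acceleration
    from numba import njit as _njit

    _lif_euler_gi_jit = _njit(cache=True)(_lif_euler_gi)
except Exception:  # pragma: no cover
    _lif_euler_gi_jit = None


@dataclass
class BackgroundConductance:
    """Balanced excitatory/inhibitory Ornstein-Uhlenbeck background.

    Point-conductance stand-in for ongoing network activity (the
    high-conductance state): two OU processes added to the synaptic
    excitation and to a separate inhibitory conductance with reversal
    ``e_inh_mv``.  Defaults follow the standard point-conductance
    parameterization scaled to this cell's input resistance.
    """

    g_e_mean: float = 1.0
    g_e_sd: float = 0.25
    tau_e_ms: float = 2.7
    g_i_mean: float = 4.0
    g_i_sd: float = 1.0
    tau_i_ms: float = 10.5
    e_inh_mv: float = -75.0

    def sample(self, n: int, dt_ms: float, rng) -> tuple[np.ndarray, np.ndarray]:
        out = []
        for mean, sd, tau in ((self.g_e_mean, self.g_e_sd, self.tau_e_ms),
                              (self.g_i_mean, self.g_i_sd, self.tau_i_ms)):
            from scipy.signal import lfilter

            a = np.exp(-dt_ms / tau)
            x0 = rng.normal(0.0, sd)
            innov = rng.normal(0.0, sd * np.sqrt(1 - a * a), n - 1)
            dev = lfilter([1.0], [1.0, -a], np.r_[x0, innov])
            out.append(np.clip(mean + dev, 0.0, None))
        return out[0], out[1]


@dataclass
class SimulationResult:
    """Vm, spikes, conductance and subthreshold statistics of one run."""

    vm: np.ndarray
    spike_times_s: np.ndarray
    g_total: np.ndarray
    i_in_na: np.ndarray
    rate_hz: float
    vm_mean: float
    vm_sd: float
    n_inputs: int
    n_presyn_spikes: int
    n_failures: int
    trial_seed: int
    params: LIFParams
    g_in: np.ndarray | None = None


def simulate(
    spike_trains: dict[int, np.ndarray] | list[np.ndarray],
    synapses: list[SynapseSpec],
    params: LIFParams | None = None,
    seed: int = 0,
    store_g: bool = False,
    background: BackgroundConductance | None = None,
) -> SimulationResult:
    """Drive the LIF neuron with EPSGs from the given presynaptic trains.

    Per synapse, failures are drawn, each transmitted spike draws an
    amplitude, and the summed impulse train is convolved with the EPSG
    kernel.  Input current is I = g_total * (E_exc - Vm).  Subthreshold
    Vm statistics exclude spike and refractory samples.
    """
    params = params or LIFParams()
    trains = (
        [spike_trains[k] for k in sorted(spike_trains)]
        if isinstance(spike_trains, dict)
        else list(spike_trains)
    )
    if len(trains) != len(synapses):
        raise ValueError("one SynapseSpec per spike train required")
    dt = params.dt_ms
    n = int(round(params.duration_s * 1000.0 / dt)) + 1
    kernel = build_epsg_kernel(dt_ms=dt)
    rng = np.random.default_rng(seed)
    impulses = np.zeros(n)
    g_in = np.zeros((len(trains), n)) if store_g else None
    n_presyn = 0
    n_fail = 0
    for k, (train, spec) in enumerate(zip(trains, synapses)):
        train = np.asarray(train, dtype=float)
        if len(train) and train.max() > params.duration_s:
            raise ValueError("spike train extends past the simulation duration")
        n_presyn += len(train)
        others = (
            [t for j, t in enumerate(trains) if j != k]
            if spec.mode == "correlated_failure"
            else None
        )
        tx, fail = apply_failures(
            train, spec, others=others, seed=int(rng.integers(2**31))
        )
        n_fail += int(fail.sum())
        amps = _draw_amplitudes(spec, tx, rng)
        idx = np.round(tx * 1000.0 / dt).astype(np.int64)
        ok = (idx >= 0) & (idx < n)
        if store_g:
            imp = np.zeros(n)
            np.add.at(imp, idx[ok], amps[ok])
            g_in[k] = fftconvolve(imp, kernel.samples)[:n]
            impulses += imp
        else:
            np.add.at(impulses, idx[ok], amps[ok])
    g_total = fftconvolve(impulses, kernel.samples)[:n]
    g_total = np.clip(g_total, 0.0, None)  # fft round-off can dip below 0
    g_inh = np.zeros(n)
    e_inh = -75.0
    if background is not None:
        g_bg_e, g_inh = background.sample(n, dt, rng)
        g_total = g_total + g_bg_e
        e_inh = background.e_inh_mv

    core = _lif_euler_gi_jit or _lif_euler_gi
    ref_steps = int(round(params.refractory_ms / dt))
    vm, spike_idx = core(
        g_total, g_inh, dt, params.tau_m_ms, params.r_m_mohm, params.v_rest,
        params.v_thresh, params.v_reset, params.e_exc_mv, e_inh, ref_steps,
    )
    if not np.isfinite(vm).all():
        raise FloatingPointError("membrane potential diverged")
    sub = np.ones(n, dtype=bool)
    for i in spike_idx:
        sub[i : i + ref_steps + 1] = False
    return SimulationResult(
        vm=vm,
        spike_times_s=spike_idx * dt / 1000.0,
        g_total=g_total,
        i_in_na=g_total * (params.e_exc_mv - vm) * 1e-3,
        rate_hz=len(spike_idx) / params.duration_s,
        vm_mean=float(vm[sub].mean()),
        vm_sd=float(vm[sub].std()),
        n_inputs=len(trains),
        n_presyn_spikes=n_presyn,
        n_failures=n_fail,
        trial_seed=seed,
        params=params,
        g_in=g_in,
    )


def sweep_inputs(
    spike_trains: dict[int, np.ndarray],
    params: LIFParams | None = None,
    n_list=(1, 5, 10, 20, 30, 40, 50),
    modes=("reliable", "unreliable"),
    seeds=range(10),
    calibration: str = "total-drive",
) -> pd.DataFrame:
    """Vm mean/SD and firing rate vs number of inputs, per mode and seed.

    Each seed draws a fresh random assignment of synaptic triplets; the
    reliable model is derived from the unreliable one of the same seed by
    equal-drive calibration, so the two modes see identical trains and
    matched average conductance.
    """
    if len(n_list) < 2:
        raise ValueError("need at least 2 values of n_inputs")
    params = params or LIFParams()
    keys = sorted(spike_trains)
    rows = []
    for s in seeds:
        full = assign_synapses(len(keys), seed=s, mode="unreliable")
        for n in n_list:
            sub = {k: spike_trains[k] for k in keys[:n]}
            unrel = full[:n]
            for mode in modes:
                if mode == "reliable":
                    specs = calibrate_equal_drive(unrel, calibration)
                elif mode == "unreliable":
                    specs = unrel
                else:
                    specs = [replace(x, mode=mode) for x in unrel]
                res = simulate(sub, specs, params, seed=1000 * s + n)
                rows.append(
                    {
                        "n_inputs": n,
                        "mode": mode,
                        "seed": s,
                        "vm_mean": res.vm_mean,
                        "vm_sd": res.vm_sd,
                        "rate_hz": res.rate_hz,
                    }
                )
    return pd.DataFrame(rows)


def reverse_correlation_rf(
    vm: np.ndarray,
    stimulus: synthdata.WhiteNoiseStimulus,
    sampling_rate_hz: float,
    lags_ms=np.arange(0.0, 155.0, 5.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Spatiotemporal receptive field by Vm-weighted reverse correlation.

    For each lag, every stimulus frame is weighted by the mean
    subthreshold Vm deviation in the frame-long window starting ``lag``
    after frame onset; the weighted average frame is the RF map at that
    lag.  Returns (rf[lag, row, col], lags_ms).
    """
    n = len(vm)
    dur = n / sampling_rate_hz
    if stimulus.total_duration_s > dur + 1e-9:
        raise ValueError("stimulus outlasts the Vm trace")
    v = np.minimum(vm, np.quantile(vm, 0.999))  # suppress spike markers
    vdev = v - v.mean()
    onsets = stimulus.frame_onsets()
    L = int(round(stimulus.frame_duration_ms / 1000.0 * sampling_rate_hz))
    flat = stimulus.frames.reshape(stimulus.n_frames, -1)
    csum = np.r_[0.0, np.cumsum(vdev)]
    rf = np.zeros((len(lags_ms), stimulus.frames.shape[1], stimulus.frames.shape[2]))
    for li, lag in enumerate(np.asarray(lags_ms, dtype=float)):
        start = np.round((onsets + lag / 1000.0) * sampling_rate_hz).astype(np.int64)
        ok = start + L < n
        if not ok.any():
            continue
        w = (csum[start[ok] + L] - csum[start[ok]]) / L  # window-mean Vm dev
        rf[li] = (w[:, None] * flat[ok]).mean(axis=0).reshape(rf.shape[1:])
    return rf, np.asarray(lags_ms, dtype=float)


def strongest_lag_ms(rf: np.ndarray, lags_ms: np.ndarray) -> float:
    """Lag whose RF map contains the strongest absolute pixel response."""
    return float(lags_ms[np.argmax(np.abs(rf).max(axis=(1, 2)))])
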