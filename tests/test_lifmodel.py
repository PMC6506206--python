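"""LIF model: kernel, synapse assignment, failures, integration, variants."""

import numpy as np
import pytest
from scipy import stats as sps

from tcsyn import lifmodel, synthdata
from tcsyn.lifmodel import (
    LIFParams,
    SynapseSpec,
    apply_failures,
    assign_synapses,
    build_epsg_kernel,
    calibrate_equal_drive,
    simulate,
)


@pytest.fixture(scope="module")
def short_drive():
    """20 s of stimulus-driven LGN spiking from 50 cells (module cache)."""
    stim = synthdata.generate_white_noise_stimulus(n_blocks=4, seed=7)
    cells = synthdata.generate_lgn_population(50, seed=7)
    trains = synthdata.simulate_lgn_spikes(stim, cells, seed=8)
    return stim, trains, LIFParams(duration_s=stim.total_duration_s)


class TestKernel:
    def test_peak_time_matches_closed_form(self):
        k = build_epsg_kernel(dt_ms=0.01)
        # t* = ln(td/tr) * tr*td / (td - tr) = ln(4)/1.5 ~ 0.924 ms
        expect = np.log(4.0) * 0.5 * 2.0 / 1.5
        assert k.peak_time_ms == pytest.approx(expect, abs=1e-12)
        assert np.argmax(k.samples) * 0.01 == pytest.approx(expect, abs=0.01)
        assert k.samples.max() == pytest.approx(1.0)

    def test_vanishing_rise_approaches_pure_decay(self):
        # rise completes within the first sample; thereafter pure decay
        # from the (unit) peak at t = dt
        k = build_epsg_kernel(tau_rise_ms=1e-4, tau_decay_ms=2.0, dt_ms=0.1)
        t = np.arange(len(k.samples)) * 0.1
        np.testing.assert_allclose(k.samples[1:], np.exp(-(t[1:] - 0.1) / 2.0),
                                   rtol=1e-3)

    def test_kernel_nonnegative_finite_integral(self):
        k = build_epsg_kernel()
        assert (k.samples >= 0).all()
        assert 0 < k.integral_ms < np.inf

    def test_invalid_taus_rejected(self):
        with pytest.raises(ValueError):
            build_epsg_kernel(tau_rise_ms=0)
        with pytest.raises(ValueError):
            build_epsg_kernel(tau_rise_ms=3.0, tau_decay_ms=2.0)


class TestParams:
    def test_reset_below_threshold_enforced(self):
        with pytest.raises(ValueError):
            LIFParams(v_reset=-50.0)

    def test_capacitance_from_tau_and_rm(self):
        p = LIFParams()
        assert p.capacitance_nf == pytest.approx(6.0 / 47.0)


class TestAssignSynapses:
    def test_mean_epsg_matches_printed_population_value(self):
        specs = assign_synapses(50, seed=0)
        assert np.mean([s.mean_epsg for s in specs]) == pytest.approx(0.89)

    def test_triplets_jointly_coupled(self):
        specs = assign_synapses(50, seed=1)
        amp = np.array([s.mean_epsg for s in specs])
        pf = np.array([s.p_fail for s in specs])
        assert np.corrcoef(amp, pf)[0, 1] < -0.4

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            assign_synapses(0)
        with pytest.raises(ValueError):
            assign_synapses(51)

    def test_single_input_reproducible(self):
        a = assign_synapses(1, seed=3)[0]
        b = assign_synapses(1, seed=3)[0]
        assert (a.mean_epsg, a.p_fail, a.amp_cv) == (b.mean_epsg, b.p_fail, b.amp_cv)

    def test_missing_dataset_names_accession(self):
        with pytest.raises(FileNotFoundError, match="dryad"):
            assign_synapses(10, source="dataset")


class TestFailures:
    def test_no_failures_when_p_zero(self):
        t = np.linspace(0, 10, 100)
        tx, mask = apply_failures(t, SynapseSpec(mode="reliable", p_fail=0.0))
        assert not mask.any()
        np.testing.assert_array_equal(tx, t)

    def test_bernoulli_fraction_recovered(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 1000, 10_000))
        _, mask = apply_failures(t, SynapseSpec(p_fail=0.4), seed=1)
        lo, hi = sps.binom.interval(0.999, 10_000, 0.4)
        assert lo <= mask.sum() <= hi

    def test_correlated_mode_boosts_conditional_rate_keeps_marginal(self):
        rng = np.random.default_rng(2)
        t = np.sort(rng.uniform(0, 500, 8000))
        others = [np.sort(rng.uniform(0, 500, 8000)) for _ in range(5)]
        spec = SynapseSpec(mode="correlated_failure", p_fail=0.4)
        _, mask = apply_failures(t, spec, others=others, seed=3)
        pool = np.sort(np.concatenate(others))
        j = np.searchsorted(pool, t)
        near = np.minimum(
            np.abs(t - pool[np.clip(j - 1, 0, len(pool) - 1)]),
            np.abs(pool[np.clip(j, 0, len(pool) - 1)] - t),
        ) <= 0.005
        assert mask[near].mean() > mask[~near].mean()
        lo, hi = sps.binom.interval(0.999, len(t), 0.4)
        assert lo <= mask.sum() <= hi


class TestCalibration:
    def test_total_drive_scales_by_transmission_probability(self):
        u = [SynapseSpec(mean_epsg=1.0, p_fail=0.4)]
        r = calibrate_equal_drive(u)[0]
        assert r.mode == "reliable"
        assert r.mean_epsg == pytest.approx(0.6)
        assert r.p_fail == 0.0

    def test_no_failures_makes_modes_identical(self):
        u = [SynapseSpec(mean_epsg=1.0, p_fail=0.0)]
        assert calibrate_equal_drive(u)[0].mean_epsg == \
            calibrate_equal_drive(u, "event-mean")[0].mean_epsg == 1.0


class TestIntegration:
    def test_no_input_stays_at_rest(self):
        p = LIFParams(duration_s=1.0)
        res = simulate([np.empty(0)], [SynapseSpec()], p, seed=0)
        np.testing.assert_allclose(res.vm, -65.0)
        assert res.rate_hz == 0.0

    def test_constant_conductance_steady_state_closed_form(self):
        # V_ss = (v_rest/Rm + g*E) / (1/Rm + g), checked to 0.1% after 5 tau
        p = LIFParams(duration_s=0.5, v_thresh=0.0, v_reset=-1.0)
        g = 1.5  # nS, constant
        n = int(round(p.duration_s * 1000 / p.dt_ms)) + 1
        vm, spk = lifmodel._lif_euler(
            np.full(n, g), p.dt_ms, p.tau_m_ms, p.r_m_mohm, p.v_rest,
            p.v_thresh, p.v_reset, p.e_exc_mv, 0)
        gr = 1e-3 * p.r_m_mohm * g
        v_ss = (p.v_rest + gr * p.e_exc_mv) / (1 + gr)
        assert len(spk) == 0
        assert vm[-1] == pytest.approx(v_ss, rel=1e-3)

    def test_refractory_floor_on_output_isi(self, short_drive):
        _, trains, params = short_drive
        specs = assign_synapses(50, seed=4)
        res = simulate(trains, specs, params, seed=5)
        if len(res.spike_times_s) > 1:
            assert np.diff(res.spike_times_s).min() >= 0.002 - 1e-12

    def test_vm_capped_at_threshold_except_spike_markers(self, short_drive):
        _, trains, params = short_drive
        res = simulate(trains, assign_synapses(50, seed=6), params, seed=6)
        spikes = np.round(res.spike_times_s * 1000 / params.dt_ms).astype(int)
        mask = np.ones(len(res.vm), dtype=bool)
        mask[spikes] = False
        assert (res.vm[mask] <= params.v_thresh + 1e-9).all()

    def test_presynaptic_spike_conservation(self, short_drive):
        _, trains, params = short_drive
        specs = assign_synapses(50, seed=7)
        res = simulate(trains, specs, params, seed=7)
        assert res.n_presyn_spikes == sum(len(t) for t in trains.values())
        assert 0 <= res.n_failures <= res.n_presyn_spikes

    def test_halving_dt_changes_rate_under_5pct(self, short_drive):
        _, trains, params = short_drive
        specs = assign_synapses(50, seed=8)
        r1 = simulate(trains, specs, params, seed=9)
        p2 = LIFParams(duration_s=params.duration_s, dt_ms=0.05)
        r2 = simulate(trains, specs, p2, seed=9)
        assert r2.rate_hz == pytest.approx(r1.rate_hz, rel=0.05)


class TestModelComparison:
    def test_unreliable_beats_reliable_in_sd_and_rate_at_equal_vm(self, short_drive):
        _, trains, params = short_drive
        rows = []
        for s in range(3):
            unrel = assign_synapses(50, seed=20 + s)
            rel = calibrate_equal_drive(unrel)
            ru = simulate(trains, unrel, params, seed=30 + s)
            rr = simulate(trains, rel, params, seed=30 + s)
            rows.append((ru, rr))
        for ru, rr in rows:
            assert ru.vm_sd > rr.vm_sd
            assert ru.rate_hz > rr.rate_hz
            assert abs(ru.vm_mean - rr.vm_mean) < 0.3

    def test_constant_amplitude_variant_sits_between(self, short_drive):
        # failures alone add variance; amplitude variability adds more
        _, trains, params = short_drive
        unrel = assign_synapses(50, seed=40)
        const = [lifmodel.replace(s, mode="unreliable_const_amp") for s in unrel]
        rel = calibrate_equal_drive(unrel)
        sd = {}
        for name, specs in (("rel", rel), ("const", const), ("unrel", unrel)):
            sd[name] = simulate(trains, specs, params, seed=41).vm_sd
        assert sd["rel"] < sd["const"] < sd["unrel"]

    def test_stsd_variant_preserves_ordering(self, short_drive):
        _, trains, params = short_drive
        unrel = [lifmodel.replace(s, stsd=(0.4, 60.0))
                 for s in assign_synapses(50, seed=42)]
        rel = calibrate_equal_drive(unrel)
        ru = simulate(trains, unrel, params, seed=43)
        rr = simulate(trains, rel, params, seed=43)
        assert ru.vm_sd > rr.vm_sd
        assert ru.rate_hz >= rr.rate_hz


class TestSweepAndRF:
    def test_vm_mean_grows_linearly_with_inputs(self, short_drive):
        _, trains, params = short_drive
        df = lifmodel.sweep_inputs(
            trains, params, n_list=(10, 25, 50), modes=("unreliable",),
            seeds=(0, 1))
        m = df.groupby("n_inputs")["vm_mean"].mean()
        depol = m - (-65.0)
        # depolarization per input approximately constant
        ratio = (depol / m.index.to_numpy()).to_numpy()
        assert ratio.max() / ratio.min() < 1.4

    def test_unreliable_sd_exceeds_reliable_for_larger_n(self, short_drive):
        _, trains, params = short_drive
        df = lifmodel.sweep_inputs(
            trains, params, n_list=(10, 50), seeds=(0,))
        piv = df.pivot_table(index="n_inputs", columns="mode", values="vm_sd")
        assert (piv["unreliable"] > piv["reliable"]).all()

    def test_rf_zero_for_stimulus_independent_vm(self):
        stim = synthdata.generate_white_noise_stimulus(n_blocks=2, seed=1)
        rng = np.random.default_rng(2)
        fs = 10_000.0
        vm = rng.normal(-65, 1, int(stim.total_duration_s * fs) + 10)
        rf, lags = lifmodel.reverse_correlation_rf(vm, stim, fs)
        assert np.abs(rf).max() < 0.05

    def test_model_rf_matches_lgn_layout_and_latency(self, short_drive):
        stim, trains, params = short_drive
        specs = assign_synapses(50, seed=50)
        res = simulate(trains, specs, params, seed=51)
        fs = 1000.0 / params.dt_ms
        rf, lags = lifmodel.reverse_correlation_rf(res.vm, stim, fs)
        best = lifmodel.strongest_lag_ms(rf, lags)
        assert 40.0 <= best <= 110.0
        # RF at the best lag has ON and OFF rows like the LGN layout
        m = rf[int(np.where(lags == best)[0][0])]
        prof = m.sum(axis=1)
        assert prof.max() > 0 > prof.min()


class TestBackgroundConductance:
    def test_background_increases_conductance_and_fluctuations(self, short_drive):
        _, trains, params = short_drive
        specs = assign_synapses(50, seed=60)
        plain = simulate(trains, specs, params, seed=61)
        bg = lifmodel.BackgroundConductance()
        high = simulate(trains, specs, params, seed=61, background=bg)
        assert high.g_total.mean() > plain.g_total.mean()
        # balanced inhibition keeps the cell subthreshold on average but
        # the added conductance noise raises Vm variability
        assert high.vm_mean < params.v_thresh
        assert high.vm_sd > 0
        assert np.isfinite(high.vm).all()

    def test_background_off_by_default_matches_plain_run(self, short_drive):
        _, trains, params = short_drive
        specs = assign_synapses(20, seed=62)
        sub = {k: trains[k] for k in sorted(trains)[:20]}
        a = simulate(sub, specs, params, seed=63)
        b = simulate(sub, specs, params, seed=63, background=None)
        np.testing.assert_array_equal(a.vm, b.vm)
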