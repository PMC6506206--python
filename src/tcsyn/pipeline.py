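"""End-to-end pipeline driver.

Runs synthetic-data generation, STA connection detection, per-spike EPSP
detection, population statistics and (optionally) the LIF model from one
:class:`~tcsyn.io.RunConfig`, writing per-stage artifacts and a manifest
with seeds and content hashes so a rerun with the same config is
reproducible and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

import tcsyn
from tcsyn import detector, io, lifmodel, sta, stats, synthdata

log = logging.getLogger("tcsyn")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_pipeline(config: io.RunConfig, out_dir: str | None = None) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    config.validate()
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": tcsyn.__version__, "seed": config.seed, "stages": {}}
    rng = np.random.default_rng(config.seed)
    stage_seeds = {s: int(rng.integers(2**31)) for s in
                   ("synthdata", "sta", "detector", "stats", "lifmodel")}
    manifest["stage_seeds"] = stage_seeds

    recordings = {}
    if "synthdata" in config.stages:
        try:
            noise = synthdata.NoiseParams.from_total_sd(config.noise_sd_mv)
            cohort = synthdata.sample_synapse_cohort(
                config.n_pairs, seed=stage_seeds["synthdata"]
            )
            for i, syn in enumerate(cohort):
                rec = synthdata.generate_pair(
                    syn,
                    rate_hz=config.rate_hz,
                    duration_s=config.duration_s,
                    noise=noise,
                    seed=stage_seeds["synthdata"] + 7 * i + 1,
                )
                recordings[i] = rec
                io.write_spike_table(rec.spike_trains, out / f"pair{i:02d}_spikes.csv")
                io.write_vm_trace(
                    out / f"pair{i:02d}_vm.h5", rec.vm, rec.sampling_rate, rec.truth
                )
            manifest["stages"]["synthdata"] = {
                "n_pairs": config.n_pairs,
                "files": sorted(p.name for p in out.glob("pair*_spikes.csv")),
            }
        except Exception as e:  # noqa: BLE001 - stage-scoped diagnostics
            raise StageError(f"synthdata: {e}") from e

    sta_results = {}
    if "sta" in config.stages:
        try:
            for i, rec in recordings.items():
                pr = sta.PairedRecording.from_synthetic(
                    rec, pair_id=f"pair{i:02d}",
                    stimulus_frame_ms=config.jitter_range_ms,
                )
                res = sta.analyze_pair(
                    pr,
                    n_jitter_draws=config.n_jitter_draws,
                    n_boot=config.n_boot,
                    seed=stage_seeds["sta"] + i,
                )
                sta_results[i] = (pr, res)
            _dump_json(
                {
                    f"pair{i:02d}": {
                        "connected": bool(r.connected),
                        "latency_ms": r.latency_ms,
                        "amplitude_mv": r.amplitude_mv,
                        "n_spikes": r.n_spikes,
                        "reasons": r.reasons,
                    }
                    for i, (_, r) in sta_results.items()
                },
                out / "sta_results.json",
            )
            manifest["stages"]["sta"] = {
                "n_connected": sum(r.connected for _, r in sta_results.values()),
                "hash": _hash(out / "sta_results.json"),
            }
        except Exception as e:
            raise StageError(f"sta: {e}") from e

    detections = {}
    if "detector" in config.stages:
        try:
            for i, (pr, res) in sta_results.items():
                if not res.connected:
                    continue
                df, summ = detector.batch_detect(
                    pr, res.corrected_sta,
                    span_ms=config.detector_span_ms,
                    seed=stage_seeds["detector"] + i,
                )
                detections[i] = (pr, df, summ)
                df.to_csv(out / f"pair{i:02d}_detections.csv", index=False)
            _dump_json(
                {f"pair{i:02d}": s for i, (_, _, s) in detections.items()},
                out / "detector_summary.json",
            )
            manifest["stages"]["detector"] = {
                "n_pairs": len(detections),
                "hash": _hash(out / "detector_summary.json"),
            }
        except Exception as e:
            raise StageError(f"detector: {e}") from e

    if "stats" in config.stages:
        try:
            summaries = []
            stsp = {}
            for i, (pr, df, summ) in detections.items():
                cfg = detector.build_config(
                    pr, sta_results[i][1].corrected_sta,
                    span_ms=config.detector_span_ms,
                    seed=stage_seeds["detector"] + i,
                )
                jt = detector.jittered_trial_traces(
                    pr, config.detector_span_ms, seed=stage_seeds["stats"] + i
                )
                jamps = detector.window_mean_amplitudes(
                    jt, cfg.window, pr.sampling_rate
                )
                summaries.append(
                    stats.summarize_pair(df, jamps, pair_id=f"pair{i:02d}")
                )
                r = stats.stsp_analysis(df, isi_split_ms=config.isi_split_ms)
                stsp[f"pair{i:02d}"] = {
                    "pct_change": r.pct_change,
                    "p_amp_ks": r.p_amp_ks,
                    "classification": r.classification,
                }
            import pandas as pd

            pd.DataFrame([s.to_dict() for s in summaries]).to_csv(
                out / "population_summary.csv", index=False
            )
            _dump_json(stsp, out / "stsp_results.json")
            if len(summaries) >= 3:
                stats.population_correlations(summaries).to_csv(
                    out / "population_correlations.csv", index=False
                )
            manifest["stages"]["stats"] = {
                "n_pairs": len(summaries),
                "hash": _hash(out / "population_summary.csv"),
            }
        except Exception as e:
            raise StageError(f"stats: {e}") from e

    if "lifmodel" in config.stages and config.run_lif:
        try:
            stim = synthdata.generate_white_noise_stimulus(
                n_blocks=max(1, int(config.lif_duration_s // 5)),
                seed=stage_seeds["lifmodel"],
            )
            cells = synthdata.generate_lgn_population(
                config.lif_n_inputs, seed=stage_seeds["lifmodel"]
            )
            params = lifmodel.LIFParams(duration_s=stim.total_duration_s)
            results = {}
            for trial in range(config.lif_trials):
                trains = synthdata.simulate_lgn_spikes(
                    stim, cells, seed=stage_seeds["lifmodel"] + 100 + trial
                )
                unrel = lifmodel.assign_synapses(
                    config.lif_n_inputs, seed=stage_seeds["lifmodel"] + trial
                )
                rel = lifmodel.calibrate_equal_drive(unrel)
                for mode, specs in (("unreliable", unrel), ("reliable", rel)):
                    res = lifmodel.simulate(
                        trains, specs, params,
                        seed=stage_seeds["lifmodel"] + 200 + trial,
                    )
                    results[f"{mode}_trial{trial}"] = {
                        "rate_hz": res.rate_hz,
                        "vm_mean": res.vm_mean,
                        "vm_sd": res.vm_sd,
                    }
            _dump_json(results, out / "lif_results.json")
            manifest["stages"]["lifmodel"] = {
                "n_trials": config.lif_trials,
                "hash": _hash(out / "lif_results.json"),
            }
        except Exception as e:
            raise StageError(f"lifmodel: {e}") from e

    _dump_json(manifest, out / "manifest.json")
    return manifest
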