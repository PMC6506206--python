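"""File formats and run configuration.

Conventions: times are seconds from recording start; windows are
half-open [t, t+w).  Spike tables are CSV with columns
``cell_id, spike_time_s``; Vm traces live in HDF5 containers with
datasets ``/vm`` (units attribute, mV) and ``/time`` or a
``sampling_rate`` attribute; truth tables are stored alongside under
``/truth``; stimuli go to compressed ``.npz`` archives.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from tcsyn import synthdata

log = logging.getLogger("tcsyn")


class SchemaError(ValueError):
    """File does not match the expected layout."""


# ---------------------------------------------------------------------------
# Spike tables
# ---------------------------------------------------------------------------

def write_spike_table(trains: dict[int, np.ndarray], path) -> None:
    rows = [
        {"cell_id": cid, "spike_time_s": t}
        for cid in sorted(trains)
        for t in np.asarray(trains[cid], dtype=float)
    ]
    pd.DataFrame(rows, columns=["cell_id", "spike_time_s"]).to_csv(path, index=False)


def read_spike_table(path) -> dict[int, np.ndarray]:
    """Per-cell sorted spike times from a cell_id/spike_time_s CSV.

    Unsorted input is sorted with a log message; duplicate timestamps
    within a cell are collapsed with a warning; malformed rows raise with
    their line numbers.
    """
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: empty spike table")
        return {}
    missing = {"cell_id", "spike_time_s"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[pd.to_numeric(df["spike_time_s"], errors="coerce").isna()]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise SchemaError(f"{path}: malformed rows at lines {[i + 2 for i in bad]}")
    out: dict[int, np.ndarray] = {}
    for cid, grp in df.groupby("cell_id"):
        t = grp["spike_time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            log.info("%s: cell %s spikes unsorted; sorting", path, cid)
            t = np.sort(t)
        u = np.unique(t)
        if len(u) < len(t):
            warnings.warn(f"{path}: cell {cid} has duplicate timestamps; collapsed")
            t = u
        out[int(cid)] = t
    return out


# ---------------------------------------------------------------------------
# Vm traces
# ---------------------------------------------------------------------------

def write_vm_trace(path, vm: np.ndarray, sampling_rate: float,
                   truth: pd.DataFrame | None = None, units: str = "mV") -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("vm", data=np.asarray(vm, dtype=float))
        d.attrs["units"] = units
        d.attrs["sampling_rate"] = float(sampling_rate)
        f.create_dataset(
            "time", data=np.arange(len(vm)) / sampling_rate, compression="gzip"
        )
        if truth is not None:
            g = f.create_group("truth")
            for col in truth.columns:
                g.create_dataset(col, data=truth[col].to_numpy())


def read_vm_trace(path, resample_to_hz: float | None = None):
    """Vm trace plus sampling metadata; optional rational resampling.

    Returns (vm, sampling_rate).  High-rate acquisitions (e.g. 33 kHz)
    can be resampled to the 10 kHz analysis rate with
    ``resample_to_hz=10_000`` (polyphase anti-aliased).
    """
    with h5py.File(path, "r") as f:
        if "vm" not in f:
            raise SchemaError(f"{path}: missing /vm dataset")
        d = f["vm"]
        if "units" not in d.attrs:
            raise SchemaError(f"{path}: /vm has no units attribute")
        if str(d.attrs["units"]) != "mV":
            raise SchemaError(f"{path}: unsupported Vm units {d.attrs['units']!r}")
        vm = d[...]
        if "sampling_rate" in d.attrs:
            fs = float(d.attrs["sampling_rate"])
        elif "time" in f:
            t = f["time"][:2]
            fs = 1.0 / (t[1] - t[0])
        else:
            raise SchemaError(f"{path}: no sampling_rate attribute or /time dataset")
    if resample_to_hz is not None and resample_to_hz != fs:
        from fractions import Fraction

        from scipy.signal import resample_poly

        frac = Fraction(int(round(resample_to_hz)), int(round(fs))).limit_denominator()
        vm = resample_poly(vm, frac.numerator, frac.denominator)
        fs = float(resample_to_hz)
    return vm, fs


def read_truth_table(path) -> pd.DataFrame:
    with h5py.File(path, "r") as f:
        if "truth" not in f:
            raise SchemaError(f"{path}: missing /truth group")
        g = f["truth"]
        return pd.DataFrame({k: g[k][...] for k in g})


# ---------------------------------------------------------------------------
# Stimuli
# ---------------------------------------------------------------------------

def write_stimulus(path, stim: synthdata.WhiteNoiseStimulus) -> None:
    np.savez_compressed(
        path,
        frames=stim.frames,
        frame_duration_ms=stim.frame_duration_ms,
        contrast_levels=np.asarray(stim.contrast_levels),
        block_length=stim.block_length,
        gray_gap_s=stim.gray_gap_s,
        field_size_deg=stim.field_size_deg,
    )


def read_stimulus(path) -> synthdata.WhiteNoiseStimulus:
    z = np.load(path)
    return synthdata.WhiteNoiseStimulus(
        frames=z["frames"],
        frame_duration_ms=float(z["frame_duration_ms"]),
        contrast_levels=tuple(z["contrast_levels"]),
        block_length=int(z["block_length"]),
        gray_gap_s=float(z["gray_gap_s"]),
        field_size_deg=float(z["field_size_deg"]),
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Seeds, paths and stage parameters for one pipeline run."""

    seed: int = 0
    out_dir: str = "tcsyn_run"
    n_pairs: int = 6
    rate_hz: float = 8.0
    duration_s: float = 125.0
    noise_sd_mv: float = 0.3
    jitter_range_ms: float = 16.0
    n_jitter_draws: int = 100
    n_boot: int = 300
    isi_split_ms: float = 50.0
    detector_span_ms: float = 6.0
    smooth_points: int = 3
    run_lif: bool = True
    lif_n_inputs: int = 50
    lif_trials: int = 3
    lif_duration_s: float = 89.0
    stages: tuple = ("synthdata", "sta", "detector", "stats", "lifmodel")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["stages"] = tuple(d.get("stages", cls.stages))
        return cls(**d)

    def validate(self) -> None:
        order = ("synthdata", "sta", "detector", "stats", "lifmodel")
        deps = {"sta": "synthdata", "detector": "sta", "stats": "detector"}
        for stage, need in deps.items():
            if stage in self.stages and need not in self.stages:
                raise ValueError(f"stage {stage!r} requires {need!r}")
        for s in self.stages:
            if s not in order:
                raise ValueError(f"unknown stage {s!r}")
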