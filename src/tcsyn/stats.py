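"""Per-pair and population synaptic statistics.

Quantifies each connected pair by the reliability, amplitude and
variability of its single-spike EPSPs, including:

* the noise-corrected coefficient of variation
  CV = sqrt(|sigma_all^2 - sigma_noise^2|) / mu_all, where the "noise"
  variance comes from jittered (alignment-free) trace amplitudes;
* the fraction of undetectable single-spike EPSPs (%undetectable);
* short-term synaptic plasticity (STSP): amplitudes conditioned on the
  preceding inter-spike interval, split at 50 ms into short and long ISI
  classes, with %change = (short - long)/long * 100 (negative = synaptic
  depression, positive = facilitation);
* population-level correlations between reliability, amplitude and CV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

ISI_SPLIT_MS = 50.0
ALPHA = 0.05


class UndefinedCVError(ValueError):
    """CV is undefined when the mean amplitude is zero."""


def noise_corrected_cv(amps_all: np.ndarray, amps_jittered: np.ndarray) -> float:
    """Amplitude CV with alignment-free Vm fluctuation variance removed.

    CV = sqrt(|var(all) - var(jittered)|) / mean(all).  The jittered
    sample estimates the spread the amplitude measure would have with no
    presynaptic spike, so subtracting its variance isolates true synaptic
    amplitude variability.
    """
    a = np.asarray(amps_all, dtype=float)
    j = np.asarray(amps_jittered, dtype=float)
    if a.size == 0 or j.size == 0:
        raise ValueError("both amplitude samples must be nonempty")
    mu = a.mean()
    if mu == 0:
        raise UndefinedCVError("mean amplitude is zero")
    return float(np.sqrt(abs(a.var(ddof=1) - j.var(ddof=1))) / mu)


@dataclass
class SynapseSummary:
    """Reliability/variability summary for one connected pair."""

    pair_id: str
    n_spikes: int
    pct_undetectable: float
    avg_amp_all: float
    avg_amp_detectable: float
    avg_amp_undetectable: float
    cv_all: float
    cv_detectable: float
    lgn_rate_hz: float
    cell_class: str = "RS"
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "flags"}
        d["flags"] = ";".join(self.flags)
        return d


def summarize_pair(
    detections: pd.DataFrame,
    jittered_amps: np.ndarray,
    pair_id: str = "pair",
    cell_class: str = "RS",
) -> SynapseSummary:
    """Category means, %undetectable and noise-corrected CVs for one pair.

    ``detections`` is the per-spike table from
    :func:`tcsyn.detector.batch_detect`; ``jittered_amps`` the matching
    jittered-trace amplitude sample (window-mean ΔVm).
    """
    amps = detections["amplitude_mv"].to_numpy()
    det = detections["label"].to_numpy() == "detectable"
    n = len(detections)
    flags = []
    cv_all = noise_corrected_cv(amps, jittered_amps)
    if det.sum() >= 2:
        cv_det = noise_corrected_cv(amps[det], jittered_amps)
        avg_det = float(amps[det].mean())
    else:
        flags.append("no detectable events: cv_detectable undefined")
        cv_det, avg_det = np.nan, np.nan
    ts = detections["spike_time_s"]
    span = ts.max() - ts.min()
    return SynapseSummary(
        pair_id=pair_id,
        n_spikes=n,
        pct_undetectable=100.0 * float((~det).mean()),
        avg_amp_all=float(amps.mean()),
        avg_amp_detectable=avg_det,
        avg_amp_undetectable=float(amps[~det].mean()) if (~det).any() else np.nan,
        cv_all=cv_all,
        cv_detectable=cv_det,
        lgn_rate_hz=float(n / span) if span > 0 else np.nan,
        cell_class=cell_class,
        flags=flags,
    )


@dataclass
class STSPResult:
    """Short-term synaptic plasticity analysis of one pair."""

    isi_split_ms: float
    n_short: int
    n_long: int
    amp_short_mean: float
    amp_long_mean: float
    pct_change: float
    p_amp_ks: float
    p_amp_t: float
    p_isi_by_label_ks: float
    p_isi_by_label_t: float
    classification: str  # "STSD" | "STSF" | "none"
    flags: list[str] = field(default_factory=list)


def stsp_analysis(
    detections: pd.DataFrame,
    isi_split_ms: float = ISI_SPLIT_MS,
    alpha: float = ALPHA,
    min_class_n: int = 20,
) -> STSPResult:
    """Compare single-spike amplitudes at short vs long presynaptic ISIs.

    %change is computed on the mean amplitude over *all* spikes
    (detectable and undetectable) in each ISI class.  Significance is the
    two-sample KS test on the two amplitude distributions (a t-test is
    reported alongside); a significant negative %change is classified as
    depression (STSD), positive as facilitation (STSF).  Also compares
    the ISI distributions of detectable vs undetectable spikes.
    """
    d = detections.dropna(subset=["isi_prev_ms"])
    isi = d["isi_prev_ms"].to_numpy()
    amps = d["amplitude_mv"].to_numpy()
    short = amps[isi <= isi_split_ms]
    long_ = amps[isi > isi_split_ms]
    flags = []
    if len(short) == 0 or len(long_) == 0:
        return STSPResult(
            isi_split_ms, len(short), len(long_), np.nan, np.nan, np.nan,
            np.nan, np.nan, np.nan, np.nan, "none", ["empty ISI class"],
        )
    if min(len(short), len(long_)) < min_class_n:
        flags.append("under-powered: fewer than 20 spikes in an ISI class")
    pct_change = 100.0 * (short.mean() - long_.mean()) / long_.mean()
    p_ks = float(_st.ks_2samp(short, long_).pvalue)
    p_t = float(_st.ttest_ind(short, long_, equal_var=False).pvalue)
    det = d["label"].to_numpy() == "detectable"
    if det.any() and (~det).any():
        p_iks = float(_st.ks_2samp(isi[det], isi[~det]).pvalue)
        p_it = float(_st.ttest_ind(isi[det], isi[~det], equal_var=False).pvalue)
    else:
        p_iks = p_it = np.nan
    if p_ks < alpha and not np.isnan(pct_change):
        cls = "STSD" if pct_change < 0 else "STSF"
    else:
        cls = "none"
    return STSPResult(
        isi_split_ms=isi_split_ms,
        n_short=len(short),
        n_long=len(long_),
        amp_short_mean=float(short.mean()),
        amp_long_mean=float(long_.mean()),
        pct_change=float(pct_change),
        p_amp_ks=p_ks,
        p_amp_t=p_t,
        p_isi_by_label_ks=p_iks,
        p_isi_by_label_t=p_it,
        classification=cls,
        flags=flags,
    )


def isi_binned_sta(
    rec,
    detections: pd.DataFrame,
    bin_edges_ms=(0, 10, 25, 50, 100, 150, np.inf),
    span_ms: float = 6.0,
) -> pd.DataFrame:
    """Average single-spike trace and mean amplitude per ISI bin.

    Returns one row per non-empty bin with the bin edges, spike count,
    mean amplitude, mean amplitude normalized to the longest-ISI bin, and
    the mean zeroed trace (object column).  Empty bins are omitted.
    """
    fs = rec.sampling_rate
    L = int(round(span_ms * fs / 1000.0)) + 1
    edges = np.asarray(bin_edges_ms, dtype=float)
    d = detections.dropna(subset=["isi_prev_ms"])
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = d[(d["isi_prev_ms"] > lo) & (d["isi_prev_ms"] <= hi)]
        if len(sel) == 0:
            continue
        idx = np.round(sel["spike_time_s"].to_numpy() * fs).astype(np.int64)
        ok = (idx >= 0) & (idx + L < len(rec.vm))
        seg = rec.vm[idx[ok, None] + np.arange(L)[None, :]]
        seg = seg - seg[:, :1]
        rows.append(
            {
                "isi_lo_ms": lo,
                "isi_hi_ms": hi,
                "n": len(sel),
                "mean_amp_mv": float(sel["amplitude_mv"].mean()),
                "mean_trace": seg.mean(axis=0),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        ref = out["mean_amp_mv"].iloc[-1]
        out["norm_amp"] = out["mean_amp_mv"] / ref if ref != 0 else np.nan
    return out


def population_correlations(summaries: list[SynapseSummary]) -> pd.DataFrame:
    """Pearson correlations across pairs between reliability and strength.

    Needs >= 3 pairs.  Zero-variance columns yield r = NaN with a flag.
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 pairs")
    df = pd.DataFrame([s.to_dict() for s in summaries])
    combos = [
        ("pct_undetectable", "avg_amp_all"),
        ("pct_undetectable", "avg_amp_detectable"),
        ("pct_undetectable", "cv_all"),
        ("cv_all", "avg_amp_all"),
        ("cv_detectable", "avg_amp_detectable"),
    ]
    rows = []
    for x, y in combos:
        xv, yv = df[x].to_numpy(), df[y].to_numpy()
        ok = np.isfinite(xv) & np.isfinite(yv)
        if ok.sum() < 3 or xv[ok].std() == 0 or yv[ok].std() == 0:
            rows.append({"x": x, "y": y, "r": np.nan, "p": np.nan,
                         "n": int(ok.sum()), "flag": "degenerate"})
            continue
        r, p = _st.pearsonr(xv[ok], yv[ok])
        rows.append({"x": x, "y": y, "r": float(r), "p": float(p),
                     "n": int(ok.sum()), "flag": ""})
    return pd.DataFrame(rows)


def vm_dependence(
    rec,
    detections: pd.DataFrame,
    jittered_amps: np.ndarray | None = None,
    baseline_window_ms: tuple[float, float] = (-5.0, 0.0),
) -> dict:
    """Pre-spike Vm (driving-force proxy) vs amplitude and reliability.

    Returns the per-pair Pearson r between baseline Vm and single-spike
    amplitude, plus %undetectable and noise-corrected CV stratified by
    Vm quartile.
    """
    fs = rec.sampling_rate
    i0 = int(round(baseline_window_ms[0] * fs / 1000.0))
    i1 = int(round(baseline_window_ms[1] * fs / 1000.0))
    idx = np.round(detections["spike_time_s"].to_numpy() * fs).astype(np.int64)
    ok = (idx + i0 >= 0) & (idx + i1 < len(rec.vm))
    offs = np.arange(i0, i1 + 1)
    pre = rec.vm[idx[ok, None] + offs[None, :]].mean(axis=1)
    amps = detections["amplitude_mv"].to_numpy()[ok]
    det = (detections["label"].to_numpy() == "detectable")[ok]
    r, p = (_st.pearsonr(pre, amps) if pre.std() > 0 and amps.std() > 0
            else (np.nan, np.nan))
    q = np.quantile(pre, [0.25, 0.5, 0.75])
    strata = []
    bins = np.digitize(pre, q)
    for k in range(4):
        sel = bins == k
        row = {
            "quartile": k + 1,
            "n": int(sel.sum()),
            "vm_mean": float(pre[sel].mean()) if sel.any() else np.nan,
            "pct_undetectable": 100.0 * float((~det[sel]).mean()) if sel.any() else np.nan,
        }
        if jittered_amps is not None and sel.sum() >= 3 and amps[sel].mean() != 0:
            row["cv"] = noise_corrected_cv(amps[sel], jittered_amps)
        else:
            row["cv"] = np.nan
        strata.append(row)
    return {"r_vm_amplitude": float(r), "p_vm_amplitude": float(p),
            "quartiles": pd.DataFrame(strata)}


def compare_cell_classes(
    summaries: list[SynapseSummary],
    stat_cols=("pct_undetectable", "avg_amp_all", "cv_all"),
) -> pd.DataFrame:
    """Two-sample KS + t tests of pair statistics between RS and FS targets."""
    df = pd.DataFrame([s.to_dict() for s in summaries])
    rows = []
    for col in stat_cols:
        rs = df.loc[df["cell_class"] == "RS", col].dropna()
        fs_ = df.loc[df["cell_class"] == "FS", col].dropna()
        if len(rs) < 2 or len(fs_) < 2:
            rows.append({"stat": col, "p_ks": np.nan, "p_t": np.nan,
                         "n_rs": len(rs), "n_fs": len(fs_)})
            continue
        rows.append({
            "stat": col,
            "p_ks": float(_st.ks_2samp(rs, fs_).pvalue),
            "p_t": float(_st.ttest_ind(rs, fs_, equal_var=False).pvalue),
            "n_rs": len(rs),
            "n_fs": len(fs_),
        })
    return pd.DataFrame(rows)


def compare_epochs(
    epoch_a: list[SynapseSummary],
    epoch_b: list[SynapseSummary],
    stat_cols=("pct_undetectable", "avg_amp_all", "cv_all"),
) -> pd.DataFrame:
    """Paired t-tests of pair statistics across two stimulus epochs.

    Pairs are matched by ``pair_id``; pairs present in only one epoch are
    dropped.
    """
    a = pd.DataFrame([s.to_dict() for s in epoch_a]).set_index("pair_id")
    b = pd.DataFrame([s.to_dict() for s in epoch_b]).set_index("pair_id")
    common = a.index.intersection(b.index)
    rows = []
    for col in stat_cols:
        x = a.loc[common, col].astype(float)
        y = b.loc[common, col].astype(float)
        ok = x.notna() & y.notna()
        p = (float(_st.ttest_rel(x[ok], y[ok]).pvalue) if ok.sum() >= 2 else np.nan)
        rows.append({"stat": col, "p_paired_t": p, "n": int(ok.sum())})
    return pd.DataFrame(rows)
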