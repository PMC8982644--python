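"""Per-burst and per-AP waveform features.

All features follow the conventions of the detection layer: times in ms,
voltages in mV; AHP amplitudes are negative numbers (trough relative to the
burst resting potential); the burst resting potential is the median of the
preceding spike-free interval (trimmed by half the final ISI threshold at
its start and 5 ms at its end) and is inherited from the previous burst when
that interval is shorter than 200 ms.  Non-finite or flagged features
propagate as NaN, never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .trace import APEvent, BurstSegmentation, VmTrace

__all__ = [
    "BurstContext",
    "PreAPFeatures",
    "AHPFeatures",
    "SlowAHPFit",
    "compute_burst_context",
    "pre_ap_features",
    "ahp_features",
    "derived_burst_metrics",
    "slow_ahp_tau",
    "qc_filter_cells",
    "extract_cell_tables",
]

MIN_INTERBURST_MS = 200.0
AHP_SEARCH_MS = 300.0
SLOW_FIT_WINDOW = (50.0, 500.0)
SLOW_MIN_INTERVAL = 500.0


@dataclass
class BurstContext:
    v_rest: float  # mV, median of the preceding interburst window
    fluct_amplitude: float  # mV, max Vm on the same window
    inherited: bool = False
    excluded: bool = False
    reason: str = ""


@dataclass
class PreAPFeatures:
    pre_ap_potential: float
    pre_ap_time: float
    pre_ap_slope: float
    flagged: bool = False


@dataclass
class AHPFeatures:
    peak_time: float
    peak_value: float
    amplitude: float  # peak_value - v_rest (negative below rest)
    slope: float  # mV/ms over the 20-60% recovery band
    duration: float  # ms, AHP peak -> next AP threshold (NaN for last AP)


@dataclass
class SlowAHPFit:
    tau: float  # ms
    amplitude: float  # mV
    offset: float  # mV
    n_bursts_used: int
    fit_window: Tuple[float, float] = SLOW_FIT_WINDOW
    available: bool = True
    reason: str = ""


def _burst_bounds(seg: BurstSegmentation) -> List[Tuple[float, float]]:
    """(first threshold-or-peak time, last peak time) per burst."""
    out = []
    for burst in seg.bursts:
        first = burst[0]
        t0 = first.threshold_time if first.threshold_time is not None else first.peak_time
        out.append((t0, burst[-1].peak_time))
    return out


def compute_burst_context(
    trace: VmTrace,
    seg: BurstSegmentation,
    burst_index: int,
    previous: Optional[BurstContext] = None,
) -> BurstContext:
    """Resting potential and fluctuation ceiling from the interval preceding
    one burst.

    The interval runs from the previous AP (any burst or isolated AP) to the
    start of this burst; the analysis window drops half the final ISI
    threshold at the interval start and 5 ms at its end.  Intervals shorter
    than 200 ms inherit the previous burst's context; a first burst without a
    qualifying interval is excluded.
    """
    bounds = _burst_bounds(seg)
    t_start_burst = bounds[burst_index][0]
    prev_events = [
        ev.peak_time for ev in seg.all_events() if ev.peak_time < t_start_burst
    ]
    t_prev = max(prev_events) if prev_events else trace.t0
    interval = t_start_burst - t_prev
    if interval < MIN_INTERBURST_MS:
        if previous is not None and not previous.excluded:
            return BurstContext(
                previous.v_rest, previous.fluct_amplitude, inherited=True
            )
        return BurstContext(
            float("nan"),
            float("nan"),
            excluded=True,
            reason="interburst interval < 200 ms with no predecessor",
        )
    tisi = seg.final_tisi if math.isfinite(seg.final_tisi) else 0.0
    w0 = t_prev + tisi / 2.0
    w1 = t_start_burst - 5.0
    win = trace.slice_ms(w0, w1)
    if win.size < 3:
        return BurstContext(
            float("nan"), float("nan"), excluded=True, reason="empty context window"
        )
    return BurstContext(float(np.median(win)), float(win.max()))


def pre_ap_features(
    trace: VmTrace,
    ap: APEvent,
    rebound_mv: float = 0.4,
    lookback_ms: float = 300.0,
) -> PreAPFeatures:
    """Pre-AP potential (first hyperpolarized peak before the threshold) and
    the pre-AP slope.

    Stepping backward from the AP threshold in 1 ms steps, stop at the first
    step whose voltage rebounds by at least ``rebound_mv`` above the running
    minimum of the interval from that step up to the threshold.  The pre-AP
    potential is the lowest voltage between the rebound and the threshold.
    The slope is a linear regression over the 5 ms before threshold when the
    pre-AP peak is more than 5 ms away, otherwise over the 20-80% voltage
    band from the pre-AP potential (0%) to the threshold (100%).
    """
    if ap.threshold_time is None:
        return PreAPFeatures(float("nan"), float("nan"), float("nan"), flagged=True)
    dt = trace.dt_ms
    i_thr = trace.index_at(ap.threshold_time)
    step = max(int(round(1.0 / dt)), 1)
    max_steps = int(lookback_ms // 1.0)
    running_min = trace.samples[i_thr]
    found = None
    for k in range(1, max_steps + 1):
        i_k = i_thr - k * step
        if i_k < 0:
            break
        seg = trace.samples[i_k:i_thr + 1]
        running_min = float(seg.min())
        if float(trace.samples[i_k]) - running_min >= rebound_mv - 1e-9:
            found = i_k
            break
    if found is None:
        i_lo = max(i_thr - max_steps * step, 0)
        seg = trace.samples[i_lo:i_thr + 1]
        i_min = i_lo + int(np.argmin(seg))
        return PreAPFeatures(
            float(trace.samples[i_min]), trace.time_at(i_min), float("nan"), flagged=True
        )
    seg = trace.samples[found:i_thr + 1]
    i_min = found + int(np.argmin(seg))
    pre_v = float(trace.samples[i_min])
    pre_t = trace.time_at(i_min)

    thr_v = float(ap.threshold_value)
    if ap.threshold_time - pre_t > 5.0:
        j0 = trace.index_at(ap.threshold_time - 5.0)
        xs = trace.times[j0:i_thr + 1]
        ys = trace.samples[j0:i_thr + 1]
    else:
        lo = pre_v + 0.2 * (thr_v - pre_v)
        hi = pre_v + 0.8 * (thr_v - pre_v)
        band = trace.samples[i_min:i_thr + 1]
        in_band = np.nonzero((band >= lo) & (band <= hi))[0]
        if in_band.size < 3:
            return PreAPFeatures(pre_v, pre_t, float("nan"), flagged=True)
        j0, j1 = i_min + in_band[0], i_min + in_band[-1]
        xs = trace.times[j0:j1 + 1]
        ys = trace.samples[j0:j1 + 1]
    if xs.size < 3:
        return PreAPFeatures(pre_v, pre_t, float("nan"), flagged=True)
    slope = float(linregress(xs, ys).slope)
    return PreAPFeatures(pre_v, pre_t, slope)


def ahp_features(
    trace: VmTrace,
    ap: APEvent,
    next_ap: Optional[APEvent],
    v_rest: float,
    prev_threshold: Optional[float] = None,
) -> AHPFeatures:
    """AHP trough, amplitude, 20-60% recovery slope and duration after one AP.

    The trough is the minimum between this AP and the next (or within 300 ms
    when there is no next AP / the ISI is longer).  The slope regression runs
    over the samples whose voltage lies in the 20-60% band from the trough
    (0%) to the previous AP threshold (100%) -- anchoring on the previous
    threshold lets the AHP after the last burst AP be measured identically.
    """
    t0 = ap.peak_time
    if next_ap is not None and next_ap.threshold_time is not None:
        t_next = next_ap.threshold_time
    elif next_ap is not None:
        t_next = next_ap.peak_time
    else:
        t_next = float("inf")
    t1 = min(t_next, t0 + AHP_SEARCH_MS)
    i0, i1 = trace.index_at(t0), trace.index_at(t1)
    if i1 - i0 < 3:
        return AHPFeatures(*(float("nan"),) * 5)
    seg = trace.samples[i0:i1]
    i_pk = i0 + int(np.argmin(seg))
    peak_t = trace.time_at(i_pk)
    peak_v = float(trace.samples[i_pk])
    amplitude = peak_v - v_rest

    anchor = prev_threshold if prev_threshold is not None else ap.threshold_value
    slope = float("nan")
    if anchor is not None and anchor > peak_v:
        lo = peak_v + 0.2 * (anchor - peak_v)
        hi = peak_v + 0.6 * (anchor - peak_v)
        after = trace.samples[i_pk:i1]
        in_band = np.nonzero((after >= lo) & (after <= hi))[0]
        if in_band.size >= 3:
            j0, j1 = i_pk + in_band[0], i_pk + in_band[-1]
            xs = trace.times[j0:j1 + 1]
            ys = trace.samples[j0:j1 + 1]
            slope = float(linregress(xs, ys).slope)

    duration = float("nan")
    if next_ap is not None and next_ap.threshold_time is not None:
        duration = next_ap.threshold_time - peak_t
    return AHPFeatures(peak_t, peak_v, amplitude, slope, duration)


def derived_burst_metrics(
    thresholds: Sequence[float],
    spike_times: Sequence[float],
    context: BurstContext,
) -> dict:
    """Relative / normalized thresholds, intraburst frequency and size."""
    thr = np.asarray(thresholds, dtype=float)
    times = np.asarray(spike_times, dtype=float)
    if thr.size < 2:
        raise ValueError("a burst needs at least two APs")
    rel = thr - context.v_rest
    span = context.fluct_amplitude - context.v_rest
    if span <= 0 or not math.isfinite(span):
        norm = np.full(thr.size, np.nan)
        norm_flag = True
    else:
        norm = rel / span
        norm_flag = False
    isis = np.diff(times)
    freq = float(np.mean(1000.0 / isis))  # Hz: mean of inverse ISIs
    return {
        "relative_thresholds": rel,
        "normalized_thresholds": norm,
        "normalized_flagged": norm_flag,
        "intraburst_freq": freq,
        "burst_size": int(thr.size),
    }


def slow_ahp_tau(
    trace: VmTrace,
    seg: BurstSegmentation,
    min_interval: float = SLOW_MIN_INTERVAL,
    fit_window: Tuple[float, float] = SLOW_FIT_WINDOW,
    tau_bounds: Tuple[float, float] = (1.0, 5000.0),
) -> SlowAHPFit:
    """Slow AHP time constant from the median post-burst decay.

    Bursts followed by at least ``min_interval`` ms without an AP qualify;
    their post-burst segments are aligned at the AHP trough (nearest sample,
    no interpolation), a median trace is computed and a single exponential
    ``offset + A exp(-t/tau)`` is fitted over ``fit_window`` after the
    trough.  Nonlinear least squares, initialized from a log-linear fit.
    """
    all_times = np.array([ev.peak_time for ev in seg.all_events()])
    segments = []
    need_ms = fit_window[1]
    for burst in seg.bursts:
        t_last = burst[-1].peak_time
        later = all_times[all_times > t_last]
        t_next = later.min() if later.size else float("inf")
        if t_next - t_last < min_interval:
            continue
        i0 = trace.index_at(t_last)
        i1 = trace.index_at(min(t_last + AHP_SEARCH_MS, t_next))
        if i1 - i0 < 3:
            continue
        i_pk = i0 + int(np.argmin(trace.samples[i0:i1]))
        n_need = int(round(need_ms / trace.dt_ms)) + 1
        if i_pk + n_need > trace.n_samples:
            continue
        if trace.time_at(i_pk) + need_ms > t_next:
            continue
        segments.append(trace.samples[i_pk : i_pk + n_need])
    if not segments:
        return SlowAHPFit(
            float("nan"), float("nan"), float("nan"), 0,
            available=False, reason="no burst with a long enough interval",
        )
    median_trace = np.median(np.vstack(segments), axis=0)
    t = np.arange(median_trace.size) * trace.dt_ms
    m = (t >= fit_window[0]) & (t <= fit_window[1])
    ts, ys = t[m], median_trace[m]

    # log-linear initialization: offset from the tail, then slope of the log
    c0 = float(ys[-int(ys.size * 0.05) :].mean())
    resid = ys - c0
    sign = -1.0 if resid[0] < 0 else 1.0
    pos = sign * resid
    ok = pos > max(pos.max() * 1e-3, 1e-9)
    if ok.sum() >= 3:
        b, loga = np.polyfit(ts[ok], np.log(pos[ok]), 1)
        tau0 = float(np.clip(-1.0 / b if b < 0 else 150.0, *tau_bounds))
        a0 = sign * float(np.exp(loga))
    else:
        tau0, a0 = 150.0, float(resid[0])

    def model(tt, a, tau, c):
        return c + a * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(
            model, ts, ys,
            p0=[a0, tau0, c0],
            bounds=([-np.inf, tau_bounds[0], -np.inf], [np.inf, tau_bounds[1], np.inf]),
            maxfev=10000,
        )
    except RuntimeError:
        return SlowAHPFit(
            float("nan"), float("nan"), float("nan"), len(segments),
            available=False, reason="exponential fit failed",
        )
    a, tau, c = popt
    return SlowAHPFit(float(tau), float(a), float(c), len(segments))


def qc_filter_cells(
    cell_summaries: pd.DataFrame,
    min_bursts: int = 4,
    max_resistance_mohm: float = 500.0,
    min_interval_ms: float = MIN_INTERBURST_MS,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic cell-level quality filter.

    Expects columns ``cell_id`` and ``n_bursts``; optional columns
    ``resistance_mohm`` and ``median_interburst_ms``.  Returns
    (kept, dropped) with a machine-readable ``reason`` column on the
    dropped table.
    """
    df = cell_summaries.copy()
    reasons = []
    for _, row in df.iterrows():
        why = []
        if row["n_bursts"] < min_bursts:
            why.append("too few bursts")
        r = row.get("resistance_mohm")
        if r is not None and not (isinstance(r, float) and math.isnan(r)):
            if r > max_resistance_mohm:
                why.append("membrane resistance")
        iv = row.get("median_interburst_ms")
        if iv is not None and not (isinstance(iv, float) and math.isnan(iv)):
            if iv < min_interval_ms:
                why.append("burst intervals too short")
        reasons.append("; ".join(why))
    df["reason"] = reasons
    kept = df[df["reason"] == ""].drop(columns=["reason"]).reset_index(drop=True)
    dropped = df[df["reason"] != ""].reset_index(drop=True)
    return kept, dropped


def extract_cell_tables(
    trace: VmTrace, seg: BurstSegmentation
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy per-AP and per-burst feature tables for one cell.

    Per-AP columns: cell_id, burst, index_in_burst, peak_time, peak_value,
    threshold_time, threshold, pre_ap_potential, pre_ap_slope, ahp_peak_time,
    ahp_peak_value, ahp_amplitude, ahp_slope, ahp_duration, v_rest,
    relative_threshold, normalized_threshold.

    Per-burst columns: cell_id, burst, size, intraburst_freq, v_rest,
    fluct_amplitude, inherited_context, first_ahp_amplitude, first_ahp_slope,
    last_ahp_amplitude, last_ahp_slope, excluded, exclude_reason.
    """
    ap_rows = []
    burst_rows = []
    prev_ctx: Optional[BurstContext] = None
    for b_idx, burst in enumerate(seg.bursts):
        ctx = compute_burst_context(trace, seg, b_idx, previous=prev_ctx)
        prev_ctx = ctx if not ctx.excluded else prev_ctx
        ahp_list = []
        pre_list = []
        for k, ap in enumerate(burst):
            nxt = burst[k + 1] if k + 1 < len(burst) else None
            prev_thr = burst[k].threshold_value
            ahp = ahp_features(trace, ap, nxt, ctx.v_rest, prev_threshold=prev_thr)
            pre = pre_ap_features(trace, ap)
            ahp_list.append(ahp)
            pre_list.append(pre)
        thr = [ap.threshold_value for ap in burst]
        times = [ap.peak_time for ap in burst]
        metrics = None
        if all(v is not None for v in thr) and not ctx.excluded:
            metrics = derived_burst_metrics(thr, times, ctx)
        for k, ap in enumerate(burst):
            ahp, pre = ahp_list[k], pre_list[k]
            ap_rows.append(
                {
                    "cell_id": trace.cell_id,
                    "burst": b_idx,
                    "index_in_burst": k,
                    "peak_time": ap.peak_time,
                    "peak_value": ap.peak_value,
                    "threshold_time": ap.threshold_time,
                    "threshold": ap.threshold_value,
                    "pre_ap_potential": pre.pre_ap_potential,
                    "pre_ap_slope": pre.pre_ap_slope,
                    "ahp_peak_time": ahp.peak_time,
                    "ahp_peak_value": ahp.peak_value,
                    "ahp_amplitude": ahp.amplitude,
                    "ahp_slope": ahp.slope,
                    "ahp_duration": ahp.duration,
                    "v_rest": ctx.v_rest,
                    "relative_threshold": (
                        metrics["relative_thresholds"][k] if metrics else np.nan
                    ),
                    "normalized_threshold": (
                        metrics["normalized_thresholds"][k] if metrics else np.nan
                    ),
                }
            )
        burst_rows.append(
            {
                "cell_id": trace.cell_id,
                "burst": b_idx,
                "size": len(burst),
                "intraburst_freq": metrics["intraburst_freq"] if metrics else np.nan,
                "v_rest": ctx.v_rest,
                "fluct_amplitude": ctx.fluct_amplitude,
                "inherited_context": ctx.inherited,
                "first_ahp_amplitude": ahp_list[0].amplitude,
                "first_ahp_slope": ahp_list[0].slope,
                "last_ahp_amplitude": ahp_list[-1].amplitude,
                "last_ahp_slope": ahp_list[-1].slope,
                "excluded": ctx.excluded,
                "exclude_reason": ctx.reason,
            }
        )
    return pd.DataFrame(ap_rows), pd.DataFrame(burst_rows)
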