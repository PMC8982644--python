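"""Spike detection, AP-threshold location and adaptive burst segmentation.

Spikes are upward crossings of a fixed detection potential; the AP threshold
is found either as the first point of sustained positive voltage
acceleration on the rising phase (second-derivative method, for recorded
traces) or as the first point where dV/dt exceeds a cut (for model traces).
Bursts are segmented with a recursive inter-spike-interval threshold
(median + a multiple of the MAD of intraburst ISIs), iterated until the
threshold stops decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import savgol_filter

from .trace import APEvent, BurstSegmentation, VmTrace

__all__ = [
    "detect_spikes",
    "detect_ap_threshold",
    "detect_bursts_adaptive",
    "annotate_thresholds",
    "DetectionParams",
]

V_DETECT_DEFAULT = -23.0  # mV
MIN_ISI_DEFAULT = 1.0  # ms
TISI0_DEFAULT = 90.0  # ms
MAD_MULT_DEFAULT = 4.0


@dataclass
class DetectionParams:
    """Per-cell detection configuration (supports per-cell overrides such as
    a lower detection potential or a smaller MAD multiplier)."""

    v_detect: float = V_DETECT_DEFAULT
    min_isi: float = MIN_ISI_DEFAULT
    tisi0: float = TISI0_DEFAULT
    mad_mult: float = MAD_MULT_DEFAULT
    min_burst_size: int = 2
    threshold_method: str = "second_derivative"
    smooth_ms: float = 0.3
    dvdt_cut: float = 40.0


def detect_spikes(
    trace: VmTrace,
    v_detect: float = V_DETECT_DEFAULT,
    min_isi: float = MIN_ISI_DEFAULT,
    peak_window_ms: float = 5.0,
) -> List[APEvent]:
    """One event per upward crossing of ``v_detect``.

    Crossings closer than ``min_isi`` to the previous accepted event are
    discarded.  The event peak is the local maximum within
    ``peak_window_ms`` after the crossing.
    """
    v = trace.samples
    if v.size < 2:
        return []
    above = v >= v_detect
    crossings = np.nonzero(~above[:-1] & above[1:])[0] + 1
    events: List[APEvent] = []
    last_t = -np.inf
    win = max(int(round(peak_window_ms / trace.dt_ms)), 1)
    for idx in crossings:
        t_cross = trace.time_at(int(idx))
        if t_cross - last_t < min_isi:
            continue
        seg = v[idx : idx + win]
        i_peak = int(idx) + int(np.argmax(seg))
        events.append(
            APEvent(peak_time=trace.time_at(i_peak), peak_value=float(v[i_peak]))
        )
        last_t = t_cross
    return events


def _rising_phase(trace: VmTrace, i_peak: int, max_back_ms: float = 10.0) -> int:
    """Start index of the rising phase: the last local minimum before the
    peak (bounded lookback), found on a lightly smoothed copy so sample
    noise cannot truncate the phase; always spans at least 1 ms."""
    i_lo = max(i_peak - int(round(max_back_ms / trace.dt_ms)), 0)
    seg = trace.samples[i_lo:i_peak]
    if seg.size < 3:
        return i_lo
    w = max(int(round(0.2 / trace.dt_ms)), 1)
    if w > 1:
        kern = np.ones(w) / w
        seg = np.convolve(seg, kern, mode="same")
    found = i_lo
    for j in range(seg.size - 2, 0, -1):
        if seg[j] <= seg[j - 1] and seg[j] <= seg[j + 1]:
            found = i_lo + j
            break
    min_span = int(round(1.0 / trace.dt_ms))
    return max(min(found, i_peak - min_span), 0)


def detect_ap_threshold(
    trace: VmTrace,
    event: APEvent,
    method: str = "second_derivative",
    dvdt_cut: float = 40.0,
    smooth_ms: float = 0.3,
) -> Tuple[Optional[float], Optional[float]]:
    """Locate the AP threshold for one detected event.

    ``second_derivative``: within the rising phase, find the time of maximum
    positive acceleration, then walk backward while the (smoothed) second
    derivative stays strictly positive; the earliest point of that contiguous
    run is the threshold.

    ``dvdt_cut``: first point of the rising phase where dV/dt exceeds
    ``dvdt_cut`` (mV/ms).

    Returns ``(threshold_time, threshold_value)`` or ``(None, None)`` when no
    qualifying point exists (the event should then be flagged and excluded
    downstream).
    """
    dt = trace.dt_ms
    i_peak = trace.index_at(event.peak_time)
    i_start = _rising_phase(trace, i_peak)
    if i_peak - i_start < max(int(round(0.5 / dt)), 2):
        return None, None
    if method == "dvdt_cut":
        seg = trace.samples[i_start : i_peak + 1]
        dv = np.diff(seg) / dt
        hits = np.nonzero(dv > dvdt_cut)[0]
        if hits.size == 0:
            return None, None
        i = i_start + int(hits[0])
        return trace.time_at(i), float(trace.samples[i])
    if method != "second_derivative":
        raise ValueError(f"unknown threshold method {method!r}")

    # smooth second derivative over a window around the rising phase
    pad = int(round(2.0 / dt))
    j0 = max(i_start - pad, 0)
    j1 = min(i_peak + pad, trace.n_samples - 1)
    seg = trace.samples[j0 : j1 + 1]
    win = int(round(smooth_ms / dt))
    if win % 2 == 0:
        win += 1
    win = max(win, 5)
    if seg.size <= win:
        return None, None
    accel = savgol_filter(seg, window_length=win, polyorder=3, deriv=2, delta=dt)
    lo, hi = i_start - j0, i_peak - j0  # rising-phase bounds within seg
    rise = accel[lo : hi + 1]
    # strict positivity with a relative guard against float roundoff on
    # exactly-linear segments
    pos = rise > 1e-6 * max(float(np.max(np.abs(rise))), 1e-12)
    if not pos.any():
        return None, None
    i_max = int(np.argmax(rise))
    if not pos[i_max]:
        return None, None
    j = i_max
    while j > 0 and pos[j - 1]:
        j -= 1
    i_thr = i_start + j
    return trace.time_at(i_thr), float(trace.samples[i_thr])


def annotate_thresholds(
    trace: VmTrace,
    events: Sequence[APEvent],
    method: str = "second_derivative",
    dvdt_cut: float = 40.0,
    smooth_ms: float = 0.3,
) -> List[APEvent]:
    """Fill threshold_time/threshold_value on each event in place; events
    without a qualifying threshold point are flagged."""
    for ev in events:
        t, v = detect_ap_threshold(trace, ev, method, dvdt_cut, smooth_ms)
        if t is None:
            ev.flagged = True
            ev.flag_reason = "no threshold point"
        else:
            ev.threshold_time = t
            ev.threshold_value = v
    return list(events)


def _group_by_tisi(spike_times: np.ndarray, tisi: float) -> List[List[int]]:
    """Groups of spike indices whose consecutive ISIs are strictly below tisi."""
    groups: List[List[int]] = [[0]]
    for i in range(1, spike_times.size):
        if spike_times[i] - spike_times[i - 1] < tisi:
            groups[-1].append(i)
        else:
            groups.append([i])
    return groups


def detect_bursts_adaptive(
    spike_times: Sequence[float],
    tisi0: float = TISI0_DEFAULT,
    mad_mult: float = MAD_MULT_DEFAULT,
    min_burst_size: int = 2,
    min_tisi: float = MIN_ISI_DEFAULT,
    events: Optional[Sequence[APEvent]] = None,
) -> BurstSegmentation:
    """Segment a spike train into bursts with the recursive adaptive
    inter-spike-interval threshold.

    Start at ``tisi0``; at each iteration the new threshold is
    ``median(intraburst ISIs) + mad_mult * MAD(intraburst ISIs)`` and the
    recursion continues while the new threshold is strictly smaller than the
    previous one (a non-decreasing update terminates the recursion, keeping
    the previous segmentation).  The threshold is floored at ``min_tisi``.

    ``events`` optionally carries APEvent objects matching ``spike_times``
    one-to-one; they are placed into the returned segmentation and their
    ``index_in_burst`` is filled.
    """
    times = np.asarray(list(spike_times), dtype=float)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("spike_times must be strictly increasing")
    if events is not None and len(events) != times.size:
        raise ValueError("events must match spike_times one-to-one")

    def mk_event(i: int) -> APEvent:
        if events is not None:
            return events[i]
        return APEvent(peak_time=float(times[i]), peak_value=np.nan)

    seg = BurstSegmentation()
    if times.size == 0:
        return seg
    if times.size == 1:
        ev = mk_event(0)
        ev.index_in_burst = "isolated"
        seg.isolated_aps.append(ev)
        seg.final_tisi = tisi0
        seg.tisi_history = [tisi0]
        return seg

    tisi = float(tisi0)
    history = [tisi]
    groups = _group_by_tisi(times, tisi)
    while True:
        intra = []
        for g in groups:
            if len(g) >= min_burst_size:
                intra.extend(np.diff(times[g]))
        if not intra:
            seg.warning = "no intraburst ISIs at current threshold"
            break
        intra_arr = np.asarray(intra)
        med = float(np.median(intra_arr))
        mad = float(np.median(np.abs(intra_arr - med)))
        new_tisi = max(med + mad_mult * mad, min_tisi)
        if new_tisi >= tisi:
            break
        tisi = new_tisi
        history.append(tisi)
        groups = _group_by_tisi(times, tisi)

    for g in groups:
        if len(g) >= min_burst_size:
            burst = []
            for rank, i in enumerate(g):
                ev = mk_event(i)
                ev.index_in_burst = rank
                burst.append(ev)
            seg.bursts.append(burst)
        else:
            for i in g:
                ev = mk_event(i)
                ev.index_in_burst = "isolated"
                seg.isolated_aps.append(ev)
    seg.final_tisi = tisi
    seg.tisi_history = history
    return seg
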