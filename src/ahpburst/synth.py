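"""Synthetic current-clamp recordings with exact ground truth.

The generator builds bursting membrane-potential traces that exercise every
downstream stage: a baseline with sinusoidal subthreshold fluctuations plus
AR(1) noise, bursts of stereotyped action potentials stitched at their
threshold crossings, fast intraburst AHPs that recover exponentially toward
the next threshold, and a post-burst decay with a dominant slow exponential
component.  Every AP threshold follows the linear law

    threshold = threshold_base + threshold_vs_preap_slope * (pre_ap - v_rest)

where ``pre_ap`` is the most hyperpolarized voltage preceding the spike
(the carved pre-burst dip for the first AP, the AHP trough otherwise).

Free-form choices that the source analysis does not constrain (AP template
shape, fluctuation spectrum, multiplicative slow-AHP buildup) are documented
here and exposed as parameters; only their downstream detectability matters.
All randomness flows from a single seed through one Generator instance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .trace import VmTrace

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "generate_cell_recording",
    "generate_spike_train",
    "generate_ahp_decay",
]


@dataclass
class GeneratorParams:
    v_rest: float = -60.0  # mV
    fluct_amplitude: float = 1.5  # mV, peak of fluctuation above v_rest
    fluct_freq: float = 4.0  # Hz
    noise_sd: float = 0.1  # mV
    noise_tau: float = 2.0  # ms, AR(1) correlation time
    n_bursts: int = 10
    burst_size_dist: Union[int, Tuple[str, float]] = ("poisson", 4.0)
    intraburst_freq: float = 50.0  # Hz
    isi_jitter: float = 0.1  # fractional ISI jitter
    threshold_base: float = -50.0  # mV
    threshold_vs_preap_slope: float = -0.37  # mV per mV
    preap_depth_range: Tuple[float, float] = (0.5, 3.5)  # mV below v_rest
    ahp_amp: float = -4.0  # mV, trough relative to v_rest (negative)
    ahp_buildup: float = 0.05  # fractional deepening per spike index
    tau_fast: float = 8.0  # ms
    tau_slow: float = 171.66  # ms
    slow_frac: float = 0.6  # slow share of the final AHP amplitude
    ap_peak: float = 30.0  # mV
    ap_rise_ms: float = 0.3
    ap_fall_ms: float = 0.7
    interburst_gap: float = 900.0  # ms of spike-free time after each decay
    warmup_ms: float = 700.0
    fs: float = 25000.0  # Hz
    duration: Optional[float] = None  # s; None -> auto-sized
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError("fs must be > 0")
        if self.ahp_amp >= 0:
            raise ValueError("ahp_amp must be negative")
        if not self.tau_fast < self.tau_slow:
            raise ValueError("tau_fast must be smaller than tau_slow")
        if self.n_bursts < 0:
            raise ValueError("n_bursts must be >= 0")

    def draw_burst_size(self, rng: np.random.Generator) -> int:
        if isinstance(self.burst_size_dist, int):
            size = self.burst_size_dist
        else:
            kind, mean = self.burst_size_dist
            if kind != "poisson":
                raise ValueError(f"unknown burst size distribution {kind!r}")
            size = 2 + int(rng.poisson(max(mean - 2.0, 0.0)))
        if size < 2:
            raise ValueError("burst sizes must be >= 2")
        return size


@dataclass
class GroundTruth:
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))  # ms, peaks
    true_thresholds: np.ndarray = field(default_factory=lambda: np.empty(0))  # mV
    threshold_times: np.ndarray = field(default_factory=lambda: np.empty(0))  # ms
    pre_ap_potentials: np.ndarray = field(default_factory=lambda: np.empty(0))  # mV
    ahp_peak_times: np.ndarray = field(default_factory=lambda: np.empty(0))  # ms
    ahp_peak_values: np.ndarray = field(default_factory=lambda: np.empty(0))  # mV
    burst_assignments: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int)
    )  # burst index per spike (-1 = isolated)
    v_rest_per_burst: np.ndarray = field(default_factory=lambda: np.empty(0))  # mV
    tau_slow_true: float = float("nan")

    def validate(self) -> None:
        if self.spike_times.size > 1 and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike_times must be strictly increasing")
        ba = self.burst_assignments[self.burst_assignments >= 0]
        if ba.size > 1 and np.any(np.diff(ba) < 0):
            raise ValueError("burst_assignments must be non-decreasing")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size


def _cos_ramp(v0: float, v1: float, n: int) -> np.ndarray:
    """Half-cosine transition v0 -> v1 over n samples (endpoint excluded)."""
    u = np.arange(n) / n
    return v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * u))


def generate_cell_recording(
    params: GeneratorParams,
) -> Tuple[VmTrace, GroundTruth]:
    """Build one synthetic cell recording and its ground truth.

    Raises ValueError when the requested bursts cannot be packed into
    ``params.duration``.
    """
    rng = np.random.default_rng(params.seed)
    p = params
    dt = 1000.0 / p.fs  # ms

    # ---- plan the bursts -------------------------------------------------
    decay_ms = 600.0  # post-burst slow-decay window (no fluctuations)
    plans = []
    t_cursor = p.warmup_ms
    for _b in range(p.n_bursts):
        size = p.draw_burst_size(rng)
        depth = rng.uniform(*p.preap_depth_range)
        base_isi = 1000.0 / p.intraburst_freq
        isis = base_isi * rng.uniform(1 - p.isi_jitter, 1 + p.isi_jitter, size - 1)
        plans.append(
            {"t_start": t_cursor, "size": size, "depth": depth, "isis": isis}
        )
        burst_span = 20.0 + float(np.sum(isis)) + 5.0
        t_cursor += burst_span + decay_ms + p.interburst_gap
    needed_ms = t_cursor + 100.0
    if p.duration is None:
        total_ms = needed_ms
    else:
        total_ms = p.duration * 1000.0
        if needed_ms > total_ms:
            raise ValueError(
                f"cannot pack {p.n_bursts} bursts into {p.duration} s "
                f"(needs {needed_ms / 1000.0:.2f} s)"
            )
    n = int(round(total_ms / dt))
    t = np.arange(n) * dt

    # ---- baseline: sinusoidal fluctuation (enveloped) + AR(1) noise ------
    phase = rng.uniform(0, 2 * np.pi)
    sine = p.fluct_amplitude * np.sin(2 * np.pi * p.fluct_freq * t / 1000.0 + phase)
    envelope = np.ones(n)
    signal = np.full(n, p.v_rest)

    gt = GroundTruth(tau_slow_true=p.tau_slow)
    spike_times: List[float] = []
    thresholds: List[float] = []
    thr_times: List[float] = []
    pre_aps: List[float] = []
    ahp_t: List[float] = []
    ahp_v: List[float] = []
    assign: List[int] = []
    vrest_b: List[float] = []

    i_rise = max(int(round(p.ap_rise_ms / dt)), 2)
    i_fall = max(int(round(p.ap_fall_ms / dt)), 2)

    for b_idx, plan in enumerate(plans):
        size, depth, isis = plan["size"], plan["depth"], plan["isis"]
        pre_ap1 = p.v_rest - depth
        thr1 = p.threshold_base + p.threshold_vs_preap_slope * (pre_ap1 - p.v_rest)

        i_thr = int(round(plan["t_start"] / dt))  # first threshold sample
        dip_down, dip_up = int(round(12.0 / dt)), int(round(4.0 / dt))
        i_dip_min = i_thr - dip_up
        i_app0 = i_dip_min - dip_down
        # suppress the sinusoid around the burst and its slow decay
        r0 = max(i_app0 - int(round(50.0 / dt)), 0)
        envelope[r0:i_app0] = np.minimum(
            envelope[r0:i_app0], np.linspace(1.0, 0.0, i_app0 - r0)
        )

        # pre-burst dip and rise to the first threshold; the last 0.8 ms is
        # a fixed-slope linear run-in so the threshold-detection offset is
        # identical for every burst (independent of dip depth)
        n_fin = max(int(round(0.8 / dt)), 2)
        v_fin = thr1 - 1.0
        signal[i_app0:i_dip_min] = _cos_ramp(p.v_rest, pre_ap1, dip_down)
        signal[i_dip_min : i_thr - n_fin] = _cos_ramp(pre_ap1, v_fin, dip_up - n_fin)
        signal[i_thr - n_fin : i_thr] = v_fin + 1.0 * (
            np.arange(n_fin) / n_fin
        )

        thr_i, pre_i = thr1, pre_ap1
        for k in range(size):
            # AP template: cubic rise (positive acceleration throughout),
            # half-cosine fall to the AHP trough
            u = np.arange(i_rise) / i_rise
            signal[i_thr : i_thr + i_rise] = thr_i + (p.ap_peak - thr_i) * u**3
            i_peak = i_thr + i_rise
            amp_k = p.ahp_amp * (1.0 + p.ahp_buildup * k)
            trough = p.v_rest + amp_k
            signal[i_peak : i_peak + i_fall] = _cos_ramp(p.ap_peak, trough, i_fall)
            i_trough = i_peak + i_fall

            spike_times.append(i_peak * dt)
            thresholds.append(thr_i)
            thr_times.append(i_thr * dt)
            pre_aps.append(pre_i)
            assign.append(b_idx)
            ahp_t.append(i_trough * dt)
            ahp_v.append(trough)

            if k < size - 1:
                # recover exponentially so the next threshold is hit exactly
                pre_i = trough
                thr_next = p.threshold_base + p.threshold_vs_preap_slope * (
                    pre_i - p.v_rest
                )
                i_thr_next = i_peak + int(round(isis[k] / dt))
                span = i_thr_next - i_trough
                if span < 3:
                    raise ValueError("intraburst ISI too short for the AP template")
                x = math.exp(-span * dt / p.tau_fast)
                asym = (thr_next - trough * x) / (1.0 - x)
                decay = np.exp(-np.arange(span) * dt / p.tau_fast)
                signal[i_trough:i_thr_next] = asym + (trough - asym) * decay
                thr_i = thr_next
                i_thr = i_thr_next
            else:
                # post-burst AHP: fast + slow exponential toward v_rest
                total_amp = trough - p.v_rest
                a_slow = p.slow_frac * total_amp
                a_fast = total_amp - a_slow
                i_end = i_trough + int(round((decay_ms + p.interburst_gap) / dt))
                i_end = min(i_end, n)
                ts = np.arange(i_end - i_trough) * dt
                signal[i_trough:i_end] = (
                    p.v_rest
                    + a_fast * np.exp(-ts / p.tau_fast)
                    + a_slow * np.exp(-ts / p.tau_slow)
                )
                i_dec_end = min(i_trough + int(round(decay_ms / dt)), n)
                envelope[i_app0:i_dec_end] = 0.0
                r1 = min(i_dec_end + int(round(100.0 / dt)), n)
                if r1 > i_dec_end:
                    envelope[i_dec_end:r1] = np.minimum(
                        envelope[i_dec_end:r1], np.linspace(0.0, 1.0, r1 - i_dec_end)
                    )
        vrest_b.append(p.v_rest)

    vm = signal + envelope * sine
    if p.noise_sd > 0:
        from scipy.signal import lfilter

        rho = math.exp(-dt / p.noise_tau)
        innov = rng.standard_normal(n) * p.noise_sd * math.sqrt(1 - rho**2)
        x0 = rng.standard_normal() * p.noise_sd
        noise, _ = lfilter([1.0], [1.0, -rho], innov, zi=[rho * x0])
        vm = vm + noise

    gt.spike_times = np.array(spike_times)
    gt.true_thresholds = np.array(thresholds)
    gt.threshold_times = np.array(thr_times)
    gt.pre_ap_potentials = np.array(pre_aps)
    gt.ahp_peak_times = np.array(ahp_t)
    gt.ahp_peak_values = np.array(ahp_v)
    gt.burst_assignments = np.array(assign, dtype=int)
    gt.v_rest_per_burst = np.array(vrest_b)
    gt.validate()

    trace = VmTrace(vm, fs=p.fs, t0=0.0, cell_id=f"synth-{p.seed}")
    return trace, gt


def generate_spike_train(
    burst_sizes: Sequence[int],
    intraburst_isi: float = 10.0,
    interburst_gap: float = 1000.0,
    t_start: float = 0.0,
    isolated_after: int = 0,
    jitter: float = 0.0,
    seed: Optional[int] = None,
) -> Tuple[np.ndarray, List[object]]:
    """Deterministic spike-train fixture with ground-truth burst labels.

    Returns (times_ms, labels) where labels are burst indices or
    ``"isolated"``.  A single-AP "burst" (size 1) is labelled isolated.
    Raises when bursts would overlap (gap not longer than the intraburst
    ISI).
    """
    if interburst_gap <= intraburst_isi:
        raise ValueError("interburst gap must exceed the intraburst ISI")
    rng = np.random.default_rng(seed)
    times: List[float] = []
    labels: List[object] = []
    t = t_start
    burst_index = 0
    for size in burst_sizes:
        if size < 1:
            raise ValueError("burst sizes must be >= 1")
        for k in range(size):
            times.append(t)
            labels.append(burst_index if size >= 2 else "isolated")
            if k < size - 1:
                isi = intraburst_isi
                if jitter > 0:
                    isi *= rng.uniform(1 - jitter, 1 + jitter)
                t += isi
        if size >= 2:
            burst_index += 1
        t += interburst_gap
    for _ in range(isolated_after):
        times.append(t)
        labels.append("isolated")
        t += interburst_gap
    return np.array(times), labels


def generate_ahp_decay(
    amplitude: float,
    tau: float,
    noise_sd: float = 0.0,
    fs: float = 25000.0,
    seed: Optional[int] = None,
    v_rest: float = -60.0,
    duration_ms: float = 600.0,
) -> VmTrace:
    """Exponential AHP-decay segment: V(t) = v_rest + amplitude*exp(-t/tau)
    plus white noise.  ``t=0`` is the AHP peak."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_ms * fs / 1000.0))) / fs * 1000.0
    v = v_rest + amplitude * np.exp(-t / tau)
    if noise_sd > 0:
        v = v + rng.standard_normal(t.size) * noise_sd
    return VmTrace(v, fs=fs, t0=0.0, cell_id="ahp-decay")
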