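"""Single-compartment conductance-based neuron model.

Channels: fast sodium (nav), delayed-rectifier potassium (kdr), A-type
potassium (ia, inactivating) and a passive leak.  Gating follows
Hodgkin-Huxley form: each gate x relaxes to a Boltzmann steady state
``x_inf(V) = 1 / (1 + exp((vhalf - V)/k))`` with a voltage-independent time
constant.  ``k > 0`` gives an activation gate, ``k < 0`` an inactivation
gate.  Units: mV, ms, mS/cm^2 internally (configs accept S/cm^2 as printed
in the literature), uF/cm^2, uA/cm^2; absolute currents in pA.

The A-type current ships in two variants: the *original* parameterization
(half-inactivation -110 mV, inactivation slope 0.056 / mV, inactivation time
constant 150 ms) and a *modified* one (-90 mV, 0.1 / mV, 50 ms).  The
activation half-voltage of the A-current is the one kinetic constant not
pinned by published values; it is calibrated (see
:func:`calibrate_ia_activation_vhalf`) so that the base conductance set
(nav 0.02, kdr 2e-4, ia 3e-3, leak 3.33e-5 S/cm^2) rests at exactly -60 mV
with zero injected current, which is the documented operating point of the
model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .trace import VmTrace

__all__ = [
    "GateSpec",
    "ChannelSpec",
    "ModelConfig",
    "Epoch",
    "Protocol",
    "SimResult",
    "simulate_current_clamp",
    "simulate_voltage_clamp",
    "steady_state_vm",
    "holding_current_algebraic",
    "find_holding_current",
    "measure_model_threshold",
    "threshold_shift_curve",
    "activatable_nav",
    "threshold_vs_conductance_curve",
    "train_ahp_buildup",
    "nernst_potential",
    "calibrate_ia_activation_vhalf",
    "base_config",
    "IA_ACTIVATION_VHALF",
]

# Physical constants (CODATA)
_R = 8.314462618  # J / (mol K)
_F = 96485.33212  # C / mol


def nernst_potential(c_in: float, c_out: float, z: int, temperature_k: float) -> float:
    """Nernst equilibrium potential in mV.

    E = (RT / zF) * ln(c_out / c_in)
    """
    if c_in <= 0 or c_out <= 0:
        raise ValueError("concentrations must be positive")
    if z == 0:
        raise ValueError("valence must be nonzero")
    return 1000.0 * (_R * temperature_k) / (z * _F) * math.log(c_out / c_in)


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GateSpec:
    """One Hodgkin-Huxley gate: Boltzmann steady state + time constant.

    The time constant is either fixed (``tau``) or, when ``tau_hyper`` is
    set, a sigmoid between ``tau_hyper`` (hyperpolarized limit) and ``tau``
    (depolarized limit) switching around ``tau_vhalf`` with width ``tau_k``.
    The asymmetric form mirrors rate-based channel models in which recovery
    from inactivation at hyperpolarized potentials is much faster than
    inactivation near rest.
    """

    vhalf: float  # mV
    k: float  # mV; > 0 activation, < 0 inactivation
    tau: float  # ms (depolarized limit when tau_hyper is set)
    power: int = 1
    tau_hyper: Optional[float] = None  # ms
    tau_vhalf: float = -58.0  # mV
    tau_k: float = 1.5  # mV

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("gate time constant must be > 0")
        if self.tau_hyper is not None and not self.tau_hyper > 0:
            raise ValueError("gate time constant must be > 0")

    def inf(self, v: float) -> float:
        return 1.0 / (1.0 + math.exp((self.vhalf - v) / self.k))

    def inf_arr(self, v: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp((self.vhalf - v) / self.k))

    def tau_at(self, v: float) -> float:
        if self.tau_hyper is None:
            return self.tau
        f = 1.0 / (1.0 + math.exp((self.tau_vhalf - v) / self.tau_k))
        return self.tau_hyper + (self.tau - self.tau_hyper) * f


@dataclass(frozen=True)
class ChannelSpec:
    name: str
    gates: Tuple[GateSpec, ...]
    erev: float  # mV

    def open_fraction_inf(self, v: float) -> float:
        p = 1.0
        for g in self.gates:
            p *= g.inf(v) ** g.power
        return p


# A-current activation half-voltage, calibrated so the base configuration
# rests at exactly -60 mV with zero holding current (frozen output of
# calibrate_ia_activation_vhalf(); a unit test re-derives it).
IA_ACTIVATION_VHALF = -46.05972799309371

E_NA_DEFAULT = 90.0
E_K_DEFAULT = -91.0
E_PAS_DEFAULT = -28.878

# inactivation slope 0.056 / mV  ->  k = -1/0.056 mV
_IA_B_K_ORIGINAL = -1.0 / 0.056
_IA_B_K_MODIFIED = -1.0 / 0.1


def nav_spec(e_na: float = E_NA_DEFAULT) -> ChannelSpec:
    return ChannelSpec(
        "nav",
        (
            GateSpec(vhalf=-32.0, k=7.8, tau=0.15, power=3),  # m
            GateSpec(vhalf=-62.0, k=-5.0, tau=1.5, power=1),  # h
        ),
        e_na,
    )


def kdr_spec(e_k: float = E_K_DEFAULT) -> ChannelSpec:
    return ChannelSpec("kdr", (GateSpec(vhalf=-40.0, k=7.0, tau=12.0, power=4),), e_k)


def ia_spec(variant: str = "original", e_k: float = E_K_DEFAULT) -> ChannelSpec:
    """A-type potassium current, 'original' or 'modified' inactivation."""
    a = GateSpec(vhalf=IA_ACTIVATION_VHALF, k=10.0, tau=10.0, power=1)
    if variant == "original":
        b = GateSpec(
            vhalf=-110.0, k=_IA_B_K_ORIGINAL, tau=150.0, power=1, tau_hyper=3.0
        )
    elif variant == "modified":
        b = GateSpec(
            vhalf=-90.0, k=_IA_B_K_MODIFIED, tau=50.0, power=1, tau_hyper=3.0
        )
    else:
        raise ValueError(f"unknown ia variant {variant!r}")
    return ChannelSpec("ia", (a, b), e_k)


# ---------------------------------------------------------------------------
# Model configuration
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    """Densities in S/cm^2 (as conventionally printed), reversals in mV."""

    g_nav: float = 0.02
    g_kdr: float = 0.0002
    g_ia: float = 0.003
    g_pas: float = 3.33e-5
    e_na: float = E_NA_DEFAULT
    e_k: float = E_K_DEFAULT
    e_pas: float = E_PAS_DEFAULT
    cm: float = 1.0  # uF/cm^2
    temperature_c: float = 30.0
    dt: float = 0.1  # ms
    membrane_area: float = 2.9e-5  # cm^2 (~2900 um^2 soma); sets pA <-> density
    holding_current: float = 0.0  # pA
    ia_variant: str = "original"  # none | original | modified
    v_init: float = -60.0

    def __post_init__(self) -> None:
        for name in ("g_nav", "g_kdr", "g_ia", "g_pas"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not self.membrane_area > 0:
            raise ValueError("membrane_area must be > 0")
        if self.ia_variant not in ("none", "original", "modified"):
            raise ValueError(f"unknown ia_variant {self.ia_variant!r}")

    # -- derived -----------------------------------------------------------
    def channels(self) -> List[Tuple[ChannelSpec, float]]:
        """(spec, density mS/cm^2) for every active channel."""
        out = [(nav_spec(self.e_na), self.g_nav * 1e3), (kdr_spec(self.e_k), self.g_kdr * 1e3)]
        if self.ia_variant != "none" and self.g_ia > 0:
            out.append((ia_spec(self.ia_variant, self.e_k), self.g_ia * 1e3))
        return out

    def pa_to_density(self, i_pa: float) -> float:
        """pA -> uA/cm^2."""
        return i_pa * 1e-6 / self.membrane_area

    def density_to_pa(self, i_density: float) -> float:
        return i_density * self.membrane_area * 1e6

    def replace(self, **kwargs) -> "ModelConfig":
        d = asdict(self)
        d.update(kwargs)
        return ModelConfig(**d)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def base_config(**overrides) -> ModelConfig:
    """The documented base model (rests at -60 mV with zero holding)."""
    return ModelConfig(**overrides)


def calibrate_ia_activation_vhalf(
    v_rest: float = -60.0,
    config: Optional[ModelConfig] = None,
) -> float:
    """Solve for the A-current activation half-voltage that zeroes the
    steady-state membrane current of the base configuration at ``v_rest``.

    Provenance of :data:`IA_ACTIVATION_VHALF`.
    """
    cfg = config or ModelConfig()
    nav = nav_spec(cfg.e_na)
    kdr = kdr_spec(cfg.e_k)
    b = ia_spec("original", cfg.e_k).gates[1]
    g_na, g_k, g_a, g_l = (
        cfg.g_nav * 1e3,
        cfg.g_kdr * 1e3,
        cfg.g_ia * 1e3,
        cfg.g_pas * 1e3,
    )
    fixed = (
        g_l * (v_rest - cfg.e_pas)
        + g_na * nav.open_fraction_inf(v_rest) * (v_rest - cfg.e_na)
        + g_k * kdr.open_fraction_inf(v_rest) * (v_rest - cfg.e_k)
    )
    need = -fixed / (g_a * b.inf(v_rest) * (v_rest - cfg.e_k))  # required a_inf
    if not 0 < need < 1:
        raise ValueError("base configuration cannot be balanced by the a-gate")
    # invert Boltzmann for vhalf with k = 10
    return v_rest + 10.0 * math.log(1.0 / need - 1.0)


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Epoch:
    """One constant-stimulus epoch.

    ``amplitude`` is pA in current clamp and mV (command potential) in
    voltage clamp.
    """

    amplitude: float
    duration: float  # ms

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("epoch duration must be > 0")


@dataclass(frozen=True)
class Protocol:
    epochs: Tuple[Epoch, ...]
    mode: str = "iclamp"  # iclamp | vclamp

    def __post_init__(self) -> None:
        if self.mode not in ("iclamp", "vclamp"):
            raise ValueError("mode must be 'iclamp' or 'vclamp'")
        if not self.epochs:
            raise ValueError("protocol needs at least one epoch")

    @property
    def total_duration(self) -> float:
        return sum(e.duration for e in self.epochs)

    @staticmethod
    def current_steps(*steps: Tuple[float, float]) -> "Protocol":
        """Build a current-clamp protocol from (amplitude_pA, duration_ms)."""
        return Protocol(tuple(Epoch(a, d) for a, d in steps), "iclamp")

    @staticmethod
    def voltage_steps(*steps: Tuple[float, float]) -> "Protocol":
        return Protocol(tuple(Epoch(a, d) for a, d in steps), "vclamp")

    @staticmethod
    def pulse_train(
        n_pulses: int,
        rate_hz: float,
        pulse_pa: float,
        pulse_ms: float = 3.0,
        pre_ms: float = 500.0,
        post_ms: float = 1500.0,
    ) -> "Protocol":
        """Current-step train at ``rate_hz`` (amplitudes are added on top of
        the configured holding current)."""
        period = 1000.0 / rate_hz
        if pulse_ms >= period:
            raise ValueError("pulse longer than train period")
        steps: List[Tuple[float, float]] = [(0.0, pre_ms)]
        for i in range(n_pulses):
            steps.append((pulse_pa, pulse_ms))
            if i < n_pulses - 1:
                steps.append((0.0, period - pulse_ms))
        steps.append((0.0, post_ms))
        return Protocol.current_steps(*steps)


def _stimulus_array(protocol: Protocol, dt: float) -> np.ndarray:
    """Per-step stimulus values (length = number of integration steps)."""
    chunks = []
    for ep in protocol.epochs:
        n = max(int(round(ep.duration / dt)), 1)
        chunks.append(np.full(n, ep.amplitude))
    return np.concatenate(chunks)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    trace: VmTrace
    t: np.ndarray  # ms
    gates: Dict[str, np.ndarray]
    currents: Dict[str, np.ndarray]  # uA/cm^2, positive outward
    stimulus: np.ndarray  # pA (iclamp) or mV (vclamp)
    config: ModelConfig

    @property
    def v(self) -> np.ndarray:
        return self.trace.samples


def _init_gates(cfg: ModelConfig, v0: float) -> Dict[str, float]:
    gates = {}
    for spec, _g in cfg.channels():
        for i, gate in enumerate(spec.gates):
            gates[f"{spec.name}.{i}"] = gate.inf(v0)
    return gates


_GATE_LABELS = {"nav.0": "m", "nav.1": "h", "kdr.0": "n", "ia.0": "a", "ia.1": "b"}


def simulate_current_clamp(
    config: ModelConfig,
    protocol: Protocol,
    v_init: Optional[float] = None,
    record_currents: bool = True,
) -> SimResult:
    """Integrate the membrane equation under current clamp.

    Staggered second-order scheme: gates advance half a step with exponential
    Euler, the voltage advances a full step with a trapezoidal
    (Crank-Nicolson) update at the half-step conductances, then the gates
    advance the second half step at the new voltage.  The state is integrated
    internally at dt/2 and recorded on the requested dt grid (the spike
    upstroke is stiff; the refinement keeps thresholds convergent at the
    default 0.1 ms step).  Unconditionally stable and deterministic.
    """
    if protocol.mode != "iclamp":
        raise ValueError("protocol is not current clamp")
    dt_out = config.dt
    dt = dt_out / 2.0  # internal step
    stim_pa = _stimulus_array(protocol, dt_out)
    n_out = stim_pa.size
    stim_pa_h = np.repeat(stim_pa, 2)
    n_steps = stim_pa_h.size
    i_stim = config.pa_to_density(stim_pa_h + config.holding_current)  # uA/cm^2

    channels = config.channels()
    g_leak = config.g_pas * 1e3  # mS/cm^2
    v0 = config.v_init if v_init is None else v_init
    gates = _init_gates(config, v0)

    v_out = np.empty(n_out + 1)
    v_out[0] = v0
    gate_out = {k: np.empty(n_out + 1) for k in gates}
    for k, val in gates.items():
        gate_out[k][0] = val
    cur_out: Dict[str, np.ndarray] = {}
    if record_currents:
        cur_out = {spec.name: np.empty(n_out + 1) for spec, _ in channels}
        cur_out["pas"] = np.empty(n_out + 1)

    # constant half-step decay factors; None marks voltage-dependent taus
    half_decay = {}
    for spec, _g in channels:
        for i, gate in enumerate(spec.gates):
            key = f"{spec.name}.{i}"
            half_decay[key] = (
                math.exp(-dt / (2.0 * gate.tau)) if gate.tau_hyper is None else None
            )

    v = v0
    if record_currents:
        _record_currents(cur_out, 0, v, gates, channels, g_leak, config)
    for step in range(n_steps):
        # first half-step gate update (exponential Euler at current voltage)
        for spec, _g in channels:
            for i, gate in enumerate(spec.gates):
                key = f"{spec.name}.{i}"
                inf = gate.inf(v)
                dec = half_decay[key]
                if dec is None:
                    dec = math.exp(-dt / (2.0 * gate.tau_at(v)))
                gates[key] = inf + (gates[key] - inf) * dec
        # trapezoidal voltage update with half-step conductances
        g_sum = g_leak
        ge_sum = g_leak * config.e_pas
        for spec, g_max in channels:
            p = 1.0
            for i, gate in enumerate(spec.gates):
                p *= gates[f"{spec.name}.{i}"] ** gate.power
            g = g_max * p
            g_sum += g
            ge_sum += g * spec.erev
        a = dt / config.cm
        v = (v * (1.0 - 0.5 * a * g_sum) + a * (ge_sum + i_stim[step])) / (
            1.0 + 0.5 * a * g_sum
        )
        if not math.isfinite(v) or abs(v) > 250.0:
            raise RuntimeError(
                f"numerical divergence at t={step * dt:.3f} ms (V={v:.3g} mV)"
            )
        # second half-step gate update at the new voltage
        for spec, _g in channels:
            for i, gate in enumerate(spec.gates):
                key = f"{spec.name}.{i}"
                inf = gate.inf(v)
                dec = half_decay[key]
                if dec is None:
                    dec = math.exp(-dt / (2.0 * gate.tau_at(v)))
                gates[key] = inf + (gates[key] - inf) * dec
        if step % 2 == 1:  # record on the output grid
            rec = step // 2 + 1
            v_out[rec] = v
            for k, val in gates.items():
                gate_out[k][rec] = val
            if record_currents:
                _record_currents(cur_out, rec, v, gates, channels, g_leak, config)

    t = np.arange(n_out + 1) * dt_out
    trace = VmTrace(v_out, fs=1000.0 / dt_out, t0=0.0, cell_id="model")
    gates_named = {_GATE_LABELS.get(k, k): arr for k, arr in gate_out.items()}
    stim_full = np.concatenate([[stim_pa[0]], stim_pa])
    return SimResult(trace, t, gates_named, cur_out, stim_full, config)


def _record_currents(out, idx, v, gates, channels, g_leak, cfg) -> None:
    for spec, g_max in channels:
        p = 1.0
        for i, gate in enumerate(spec.gates):
            p *= gates[f"{spec.name}.{i}"] ** gate.power
        out[spec.name][idx] = g_max * p * (v - spec.erev)
    out["pas"][idx] = g_leak * (v - cfg.e_pas)


def simulate_voltage_clamp(config: ModelConfig, protocol: Protocol) -> SimResult:
    """Ideal voltage clamp: Vm follows the command exactly; gates relax and
    the recorded clamp current equals the total ionic current."""
    if protocol.mode != "vclamp":
        raise ValueError("protocol is not voltage clamp")
    dt = config.dt
    v_cmd = _stimulus_array(protocol, dt)
    n_steps = v_cmd.size
    channels = config.channels()
    g_leak = config.g_pas * 1e3

    gates = _init_gates(config, v_cmd[0])
    decay = {}
    for spec, _g in channels:
        for i, gate in enumerate(spec.gates):
            key = f"{spec.name}.{i}"
            decay[key] = math.exp(-dt / gate.tau) if gate.tau_hyper is None else None

    v_out = np.empty(n_steps + 1)
    v_out[0] = v_cmd[0]
    gate_out = {k: np.empty(n_steps + 1) for k in gates}
    for k, val in gates.items():
        gate_out[k][0] = val
    cur_out = {spec.name: np.empty(n_steps + 1) for spec, _ in channels}
    cur_out["pas"] = np.empty(n_steps + 1)
    _record_currents(cur_out, 0, v_cmd[0], gates, channels, g_leak, config)

    for step in range(n_steps):
        v = v_cmd[step]
        for spec, _g in channels:
            for i, gate in enumerate(spec.gates):
                key = f"{spec.name}.{i}"
                inf = gate.inf(v)
                dec = decay[key]
                if dec is None:
                    dec = math.exp(-dt / gate.tau_at(v))
                gates[key] = inf + (gates[key] - inf) * dec
        v_out[step + 1] = v
        for k, val in gates.items():
            gate_out[k][step + 1] = val
        _record_currents(cur_out, step + 1, v, gates, channels, g_leak, config)

    t = np.arange(n_steps + 1) * dt
    trace = VmTrace(v_out, fs=1000.0 / dt, t0=0.0, cell_id="model_vc")
    gates_named = {_GATE_LABELS.get(k, k): arr for k, arr in gate_out.items()}
    cur_out["total"] = sum(cur_out.values())
    v_full = np.concatenate([[v_cmd[0]], v_cmd])
    return SimResult(trace, t, gates_named, cur_out, v_full, config)


# ---------------------------------------------------------------------------
# Steady state and holding current
# ---------------------------------------------------------------------------


def _membrane_current_density(config: ModelConfig, v: float) -> float:
    """Total steady-state ionic current (gates at x_inf), uA/cm^2, outward +."""
    i = config.g_pas * 1e3 * (v - config.e_pas)
    for spec, g in config.channels():
        i += g * spec.open_fraction_inf(v) * (v - spec.erev)
    return i


def steady_state_vm(
    config: ModelConfig,
    i_hold_pa: Optional[float] = None,
    method: str = "algebraic",
    settle_ms: float = 2000.0,
    bracket: Tuple[float, float] = (-95.0, -45.0),
) -> float:
    """Resting membrane potential under a constant injected current.

    ``algebraic`` solves the current-balance equation with gates at steady
    state; ``simulate`` integrates for ``settle_ms`` and reads the final value.
    """
    i_pa = config.holding_current if i_hold_pa is None else i_hold_pa
    if method == "simulate":
        cfg = config.replace(holding_current=i_pa)
        proto = Protocol.current_steps((0.0, settle_ms))
        res = simulate_current_clamp(cfg, proto, record_currents=False)
        return float(res.v[-1])
    if method != "algebraic":
        raise ValueError("method must be 'algebraic' or 'simulate'")
    dens = config.pa_to_density(i_pa)

    def f(v: float) -> float:
        return dens - _membrane_current_density(config, v)

    lo, hi = bracket
    if f(lo) * f(hi) > 0:
        raise ValueError("no steady state bracketed in the stable voltage range")
    return float(brentq(f, lo, hi, xtol=1e-10))


def holding_current_algebraic(config: ModelConfig, target_v: float) -> float:
    """Injected current (pA) that balances the membrane at ``target_v``,
    directly from the steady-state current-balance equation."""
    return config.density_to_pa(_membrane_current_density(config, target_v))


def find_holding_current(
    config: ModelConfig,
    target_v: float,
    method: str = "simulate",
    tol_mv: float = 0.01,
    settle_ms: float = 1500.0,
) -> Tuple[float, float]:
    """Root-find (bisection) the injected current holding the model at
    ``target_v``.  Returns ``(pA, uA/cm^2)``.

    The simulation route is the reference operation; the algebraic route is
    a fast equivalent used internally by protocol builders.
    """
    if method == "algebraic":
        i_pa = holding_current_algebraic(config, target_v)
        return i_pa, config.pa_to_density(i_pa)
    guess = holding_current_algebraic(config, target_v)
    span = max(abs(guess) * 0.5, 5.0)
    lo, hi = guess - span, guess + span

    def err(i_pa: float) -> float:
        return (
            steady_state_vm(config, i_pa, method="simulate", settle_ms=settle_ms)
            - target_v
        )

    e_lo, e_hi = err(lo), err(hi)
    for _ in range(8):
        if e_lo * e_hi <= 0:
            break
        lo -= span
        hi += span
        e_lo, e_hi = err(lo), err(hi)
    else:
        raise ValueError("could not bracket the holding current")
    # bisection on the (monotone) steady-state voltage
    while hi - lo > 1e-4:
        mid = 0.5 * (lo + hi)
        e_mid = err(mid)
        if abs(e_mid) < tol_mv:
            lo = hi = mid
            break
        if e_lo * e_mid <= 0:
            hi, e_hi = mid, e_mid
        else:
            lo, e_lo = mid, e_mid
    i_pa = 0.5 * (lo + hi)
    return float(i_pa), config.pa_to_density(i_pa)


# ---------------------------------------------------------------------------
# Threshold protocols
# ---------------------------------------------------------------------------


def measure_model_threshold(
    result_or_trace, dvdt_cut: float = 40.0, t_min: float = 0.0
) -> Optional[float]:
    """Voltage at the first point where dV/dt exceeds ``dvdt_cut`` (mV/ms).

    For a :class:`SimResult` with recorded currents the derivative is taken
    from the membrane equation itself (grid-independent); otherwise a finite
    difference is used.  The crossing voltage is linearly interpolated
    between the bracketing samples.  Returns None when the trace never
    reaches the cut (no spike).
    """
    if isinstance(result_or_trace, SimResult) and result_or_trace.currents:
        res = result_or_trace
        v = res.v
        t = res.t
        cfg = res.config
        total_ion = sum(
            arr for name, arr in res.currents.items() if name != "total"
        )
        i_inj = cfg.pa_to_density(res.stimulus + cfg.holding_current)
        dv = (i_inj - total_ion) / cfg.cm  # mV/ms at the sample points
        start = int(np.searchsorted(t, t_min))
        idx = np.nonzero(dv[start:] > dvdt_cut)[0]
        if idx.size == 0:
            return None
        i = start + int(idx[0])
        if i == 0:
            return float(v[0])
        d0, d1 = dv[i - 1], dv[i]
        frac = (dvdt_cut - d0) / (d1 - d0) if d1 != d0 else 0.0
        return float(v[i - 1] + frac * (v[i] - v[i - 1]))
    if isinstance(result_or_trace, SimResult):
        v = result_or_trace.v
        t = result_or_trace.t
    else:
        v = result_or_trace.samples
        t = result_or_trace.times
    dv = np.diff(v) / np.diff(t)
    start = int(np.searchsorted(t, t_min))
    idx = np.nonzero(dv[start:] > dvdt_cut)[0]
    if idx.size == 0:
        return None
    i = start + int(idx[0])
    if i == 0:
        return float(v[0])
    d0, d1 = dv[i - 1], dv[i]
    frac = (dvdt_cut - d0) / (d1 - d0) if d1 != d0 else 0.0
    return float(v[i] + frac * (v[i + 1] - v[i]))


def _settled_config(config: ModelConfig, target_v: float = -60.0) -> ModelConfig:
    """Config with holding current set (algebraically) to rest at target_v."""
    i_pa = holding_current_algebraic(config, target_v)
    return config.replace(holding_current=i_pa, v_init=target_v)


def _prehyp_step_current(config: ModelConfig, level_mv: float) -> float:
    """Step amplitude (pA, relative to holding) whose steady state is level_mv."""
    return holding_current_algebraic(config, level_mv) - config.holding_current


@dataclass
class ThresholdPoint:
    pre_ap_potential: float  # mV, measured just before the positive step
    threshold: float  # mV (nan when flagged)
    available_g_nav: float  # S/cm^2, h-weighted density before the step
    flagged: bool = False


def spike_with_prehyp(
    config: ModelConfig,
    prehyp_level: Optional[float] = None,
    prehyp_ms: float = 50.0,
    pulse_pa: float = 400.0,
    pulse_ms: float = 3.0,
    settle_ms: float = 500.0,
    tail_ms: float = 50.0,
) -> Tuple[SimResult, ThresholdPoint]:
    """One spike evoked by a brief positive step, optionally preceded by a
    hyperpolarizing step calibrated to reach ``prehyp_level`` (mV)."""
    cfg = _settled_config(config)
    steps: List[Tuple[float, float]] = [(0.0, settle_ms)]
    if prehyp_level is not None:
        steps.append((_prehyp_step_current(cfg, prehyp_level), prehyp_ms))
    steps.append((pulse_pa, pulse_ms))
    steps.append((0.0, tail_ms))
    proto = Protocol.current_steps(*steps)
    res = simulate_current_clamp(cfg, proto)
    t_pulse = settle_ms + (prehyp_ms if prehyp_level is not None else 0.0)
    i_pulse = int(np.searchsorted(res.t, t_pulse))
    pre_v = float(res.v[i_pulse])
    g_avail = activatable_nav(cfg, h=float(res.gates["h"][i_pulse]))
    thr = measure_model_threshold(res, t_min=t_pulse)
    if thr is None:
        return res, ThresholdPoint(pre_v, float("nan"), g_avail, flagged=True)
    return res, ThresholdPoint(pre_v, thr, g_avail)


def activatable_nav(config: ModelConfig, h: float) -> float:
    """Available (non-inactivated) sodium conductance density, S/cm^2."""
    return config.g_nav * h


def threshold_shift_curve(
    config: ModelConfig,
    prehyp_levels: Sequence[float],
    prehyp_ms: float = 50.0,
    pulse_pa: float = 400.0,
) -> Dict[str, np.ndarray]:
    """AP threshold (and shift vs the no-prestep reference) across
    pre-AP potentials; also the least-squares slope of threshold vs pre-AP
    potential over the unflagged levels."""
    _res0, p0 = spike_with_prehyp(config, None, prehyp_ms, pulse_pa)
    pre, thr, avail, flags = [p0.pre_ap_potential], [p0.threshold], [
        p0.available_g_nav
    ], [p0.flagged]
    for level in prehyp_levels:
        _res, pt = spike_with_prehyp(config, level, prehyp_ms, pulse_pa)
        pre.append(pt.pre_ap_potential)
        thr.append(pt.threshold)
        avail.append(pt.available_g_nav)
        flags.append(pt.flagged)
    pre_a, thr_a = np.array(pre), np.array(thr)
    ok = ~np.array(flags)
    slope = float("nan")
    if ok.sum() >= 2:
        slope = float(np.polyfit(pre_a[ok], thr_a[ok], 1)[0])
    return {
        "pre_ap_potential": pre_a,
        "threshold": thr_a,
        "shift": thr_a - thr_a[0],
        "available_g_nav": np.array(avail),
        "flagged": np.array(flags),
        "slope": slope,
    }


def threshold_vs_conductance_curve(
    config: ModelConfig,
    g_nav_values: Sequence[float],
    pulse_pa: float = 1000.0,
) -> Dict[str, np.ndarray]:
    """AP threshold at rest as a function of the activatable sodium
    conductance, over a range of total Na_v densities."""
    thr, avail, flags = [], [], []
    for g in g_nav_values:
        cfg = config.replace(g_nav=g)
        _res, pt = spike_with_prehyp(cfg, None, pulse_pa=pulse_pa)
        thr.append(pt.threshold)
        avail.append(pt.available_g_nav)
        flags.append(pt.flagged)
    return {
        "g_nav": np.asarray(g_nav_values, dtype=float),
        "activatable_g_nav": np.array(avail),
        "threshold": np.array(thr),
        "flagged": np.array(flags),
    }


# ---------------------------------------------------------------------------
# Train / AHP protocols
# ---------------------------------------------------------------------------


@dataclass
class TrainAHPSummary:
    n_spikes: int
    ahp_amplitude: float  # mV relative to rest (negative = below rest)
    ahp_area: float  # mV*ms below rest over the analysis window
    v_slow_onset: float  # mV at the onset of the slow component (nan if none)
    n_detected_spikes: int


def train_ahp_buildup(
    config: ModelConfig,
    n_spikes_list: Sequence[int] = (1, 2, 4, 8, 16),
    rate_hz: float = 40.0,
    pulse_pa: float = 1000.0,
    pulse_ms: float = 3.0,
    analysis_ms: float = 1000.0,
    return_results: bool = False,
):
    """Evoke spike trains and summarize the AHP that follows the last spike.

    Raises when any stimulus in a train fails to trigger a spike.
    """
    cfg = _settled_config(config)
    summaries: List[TrainAHPSummary] = []
    results: List[SimResult] = []
    for n in n_spikes_list:
        proto = Protocol.pulse_train(
            n, rate_hz, pulse_pa, pulse_ms, pre_ms=500.0, post_ms=analysis_ms + 200.0
        )
        res = simulate_current_clamp(cfg, proto)
        period = 1000.0 / rate_hz
        # count spikes: one expected per pulse
        peaks = _count_spikes(res, n, period, pulse_ms)
        if peaks < n:
            raise RuntimeError(
                f"train of {n} pulses elicited only {peaks} spikes "
                f"(first failing pulse index {peaks})"
            )
        t_last_end = 500.0 + (n - 1) * period + pulse_ms
        i0 = int(np.searchsorted(res.t, t_last_end))
        i1 = int(np.searchsorted(res.t, t_last_end + analysis_ms))
        seg = res.v[i0:i1]
        t_seg = res.t[i0:i1] - t_last_end
        v_rest = -60.0
        below = np.minimum(seg - v_rest, 0.0)
        amp = float(seg.min() - v_rest)
        area = float(np.trapezoid(below, t_seg))
        v_onset = _slow_onset_voltage(t_seg, seg)
        summaries.append(TrainAHPSummary(n, amp, area, v_onset, peaks))
        if return_results:
            results.append(res)
    if return_results:
        return summaries, results
    return summaries


def _count_spikes(res: SimResult, n_pulses: int, period: float, pulse_ms: float) -> int:
    count = 0
    for i in range(n_pulses):
        t0 = 500.0 + i * period
        i0 = int(np.searchsorted(res.t, t0))
        i1 = int(np.searchsorted(res.t, t0 + min(period, pulse_ms + 10.0)))
        if res.v[i0:i1].max() > -20.0:
            count += 1
    return count


def _slow_onset_voltage(t: np.ndarray, v: np.ndarray) -> float:
    """Voltage at which the post-burst repolarization switches from the fast
    recovery to the slow component: the point after the AHP trough where the
    repolarization rate first drops below 20% of its post-trough maximum."""
    if v.size < 10:
        return float("nan")
    i_min = int(np.argmin(v))
    dv = np.diff(v[i_min:]) / np.diff(t[i_min:])
    if dv.size < 5:
        return float("nan")
    peak_rate = float(dv[: max(dv.size // 4, 5)].max())
    if peak_rate <= 0:
        return float("nan")
    below = np.nonzero(dv < 0.2 * peak_rate)[0]
    if below.size == 0:
        return float("nan")
    return float(v[i_min + int(below[0])])
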