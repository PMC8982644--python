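import numpy as np
import pytest

from ahpburst.biophys import (
    IA_ACTIVATION_VHALF,
    Epoch,
    ModelConfig,
    Protocol,
    activatable_nav,
    base_config,
    calibrate_ia_activation_vhalf,
    find_holding_current,
    holding_current_algebraic,
    ia_spec,
    measure_model_threshold,
    nav_spec,
    nernst_potential,
    simulate_current_clamp,
    simulate_voltage_clamp,
    spike_with_prehyp,
    steady_state_vm,
    threshold_shift_curve,
    threshold_vs_conductance_curve,
    train_ahp_buildup,
)


class TestNernst:
    def test_equal_concentrations_zero(self):
        assert nernst_potential(10.0, 10.0, 1, 300.0) == pytest.approx(0.0)

    def test_chloride_from_recording_solutions(self):
        # Cl_out = 125 (NaCl) + 4 (KCl) + 2*2 (CaCl2) + 2*1 (MgCl2) = 135 mM
        # Cl_in = 2*1 (MgCl2) = 2 mM, z = -1, 30 C
        e_cl = nernst_potential(2.0, 135.0, -1, 303.15)
        assert round(e_cl) == -110

    def test_potassium_close_to_printed(self):
        # K_out = 4, K_in = 131 (K-gluconate); the computed value is ~ -91 mV
        # (the conventional -92 mV rounding differs slightly)
        e_k = nernst_potential(131.0, 4.0, 1, 303.15)
        assert e_k == pytest.approx(-91.0, abs=0.5)

    def test_ratio_invariance(self):
        a = nernst_potential(2.0, 135.0, -1, 303.15)
        b = nernst_potential(4.0, 270.0, -1, 303.15)
        assert a == pytest.approx(b)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            nernst_potential(0.0, 1.0, -1, 300.0)
        with pytest.raises(ValueError):
            nernst_potential(1.0, 1.0, 0, 300.0)


class TestConfigAndKinetics:
    def test_frozen_calibration_constant_is_reproducible(self):
        assert calibrate_ia_activation_vhalf() == pytest.approx(
            IA_ACTIVATION_VHALF, abs=1e-9
        )

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(g_nav=-1.0)
        with pytest.raises(ValueError):
            ModelConfig(dt=0.0)
        with pytest.raises(ValueError):
            ModelConfig(ia_variant="bogus")

    def test_ia_variants_differ_only_in_inactivation(self):
        orig = ia_spec("original")
        mod = ia_spec("modified")
        assert orig.gates[0] == mod.gates[0]
        assert mod.gates[1].vhalf == -90.0
        assert mod.gates[1].tau == 50.0
        assert orig.gates[1].vhalf == -110.0
        assert orig.gates[1].tau == 150.0

    def test_steady_state_gates_bounded(self):
        for spec in (nav_spec(), ia_spec("original"), ia_spec("modified")):
            for gate in spec.gates:
                for v in np.linspace(-120, 60, 50):
                    assert 0.0 <= gate.inf(v) <= 1.0
                    assert gate.tau_at(v) > 0


class TestSimulation:
    def test_passive_limit_matches_rc_closed_form(self):
        cfg = ModelConfig(g_nav=0.0, g_kdr=0.0, g_ia=0.0, ia_variant="none",
                          v_init=-28.878)
        proto = Protocol.current_steps((0.0, 50.0), (20.0, 200.0))
        res = simulate_current_clamp(cfg, proto)
        g = cfg.g_pas * 1e3  # mS/cm^2
        tau = cfg.cm / g
        i_dens = cfg.pa_to_density(20.0)
        expected = np.where(
            res.t < 50.0,
            cfg.e_pas,
            cfg.e_pas + (i_dens / g) * (1.0 - np.exp(-(res.t - 50.0) / tau)),
        )
        rel_err = np.abs(res.v - expected).max() / (i_dens / g)
        assert rel_err < 1e-3

    def test_base_config_rests_at_minus_60(self, base_model):
        assert steady_state_vm(base_model, method="simulate") == pytest.approx(
            -60.0, abs=0.05
        )

    def test_halving_dt_barely_moves_steady_state(self, base_model):
        v1 = steady_state_vm(base_model, method="simulate")
        v2 = steady_state_vm(base_model.replace(dt=0.05), method="simulate")
        assert abs(v1 - v2) < 0.05

    def test_halving_dt_threshold_convergence(self, base_model):
        _r1, p1 = spike_with_prehyp(base_model)
        _r2, p2 = spike_with_prehyp(base_model.replace(dt=0.05))
        assert abs(p1.threshold - p2.threshold) < 0.2

    def test_gates_stay_in_unit_interval(self, base_model):
        proto = Protocol.pulse_train(4, 40.0, 1000.0, pre_ms=200.0, post_ms=200.0)
        res = simulate_current_clamp(base_model, proto)
        for name, arr in res.gates.items():
            assert arr.min() >= 0.0 and arr.max() <= 1.0, name

    def test_current_signs_between_reversals(self, sim_single_spike):
        res = sim_single_spike
        mid = (res.v > -80.0) & (res.v < 60.0)
        assert np.all(res.currents["nav"][mid] <= 1e-12)  # inward
        assert np.all(res.currents["kdr"][mid] >= -1e-12)  # outward
        assert np.all(res.currents["ia"][mid] >= -1e-12)

    def test_steady_state_independent_of_area(self, base_model):
        v1 = steady_state_vm(base_model)
        v2 = steady_state_vm(base_model.replace(membrane_area=1e-4))
        assert v1 == pytest.approx(v2, abs=1e-9)

    def test_divergence_reported(self):
        cfg = ModelConfig()
        proto = Protocol.current_steps((1e9, 10.0))
        with pytest.raises(RuntimeError, match="divergence"):
            simulate_current_clamp(cfg, proto)

    def test_determinism(self, base_model):
        proto = Protocol.current_steps((0.0, 100.0), (400.0, 3.0), (0.0, 50.0))
        a = simulate_current_clamp(base_model, proto)
        b = simulate_current_clamp(base_model, proto)
        np.testing.assert_array_equal(a.v, b.v)


class TestHoldingCurrent:
    def test_natural_rest_needs_zero(self, base_model):
        i_pa, _dens = find_holding_current(base_model, -60.0, method="algebraic")
        assert i_pa == pytest.approx(0.0, abs=1e-9)

    def test_simulated_bisection_matches_algebraic(self):
        cfg = base_config(ia_variant="none")
        i_alg = holding_current_algebraic(cfg, -60.0)
        i_sim, dens = find_holding_current(cfg, -60.0, method="simulate")
        assert i_sim == pytest.approx(i_alg, abs=0.5)
        assert dens == pytest.approx(cfg.pa_to_density(i_sim))

    def test_holding_scales_linearly_with_area(self):
        cfg = base_config(ia_variant="none")
        i1 = holding_current_algebraic(cfg, -60.0)
        i2 = holding_current_algebraic(cfg.replace(membrane_area=5.8e-5), -60.0)
        assert i2 == pytest.approx(2.0 * i1, rel=1e-9)

    def test_modified_ia_needs_negative_holding(self):
        cfg = base_config(ia_variant="modified")
        i_pa = holding_current_algebraic(cfg, -60.0)
        assert i_pa < -1.0


class TestThresholdProtocols:
    def test_subthreshold_stimulus_gives_none(self, base_model):
        proto = Protocol.current_steps((0.0, 100.0), (20.0, 3.0), (0.0, 50.0))
        res = simulate_current_clamp(base_model, proto)
        assert measure_model_threshold(res) is None

    def test_evoked_threshold_below_peak(self, sim_single_spike):
        thr = measure_model_threshold(sim_single_spike)
        assert thr is not None
        assert thr < sim_single_spike.v.max()

    def test_prehyperpolarization_lowers_threshold(self, base_model):
        _r0, p0 = spike_with_prehyp(base_model)
        _r1, p1 = spike_with_prehyp(base_model, prehyp_level=-70.0)
        assert p1.threshold < p0.threshold
        assert p1.pre_ap_potential < p0.pre_ap_potential

    def test_shift_curve_monotone_and_zero_at_rest(self, base_model):
        curve = threshold_shift_curve(base_model, [-64.0, -67.0, -70.0])
        assert curve["shift"][0] == pytest.approx(0.0)
        assert np.all(np.diff(curve["threshold"]) < 0)
        assert not curve["flagged"].any()

    def test_shift_slope_larger_at_low_density(self, base_model):
        levels = [-64.0, -67.0, -70.0]
        hi = threshold_shift_curve(base_model, levels)
        lo = threshold_shift_curve(base_model.replace(g_nav=0.005), levels)
        assert abs(lo["slope"]) > abs(hi["slope"])

    def test_shift_curve_deterministic(self, base_model):
        a = threshold_shift_curve(base_model, [-66.0])
        b = threshold_shift_curve(base_model, [-66.0])
        np.testing.assert_array_equal(a["threshold"], b["threshold"])


class TestActivatableNav:
    def test_anchors(self, base_model):
        assert activatable_nav(base_model, 1.0) == pytest.approx(base_model.g_nav)
        assert activatable_nav(base_model, 0.0) == 0.0

    def test_deinactivation_by_steady_hyperpolarization(self):
        # steady-state h is monotone decreasing in V (oracle: h_inf curve)
        h = nav_spec().gates[1]
        assert h.inf(-70.0) > h.inf(-60.0)
        _r0, p0 = spike_with_prehyp(base_config())
        _r1, p1 = spike_with_prehyp(base_config(), prehyp_level=-70.0)
        assert p1.available_g_nav > p0.available_g_nav


class TestConductanceCurve:
    def test_duplicate_density_identical(self, base_model):
        out = threshold_vs_conductance_curve(base_model, [0.01, 0.01])
        assert out["threshold"][0] == out["threshold"][1]

    def test_monotone_threshold_vs_activatable(self, base_model):
        out = threshold_vs_conductance_curve(
            base_model, [0.0025, 0.005, 0.01, 0.02, 0.04]
        )
        assert not out["flagged"].any()
        assert np.all(np.diff(out["activatable_g_nav"]) > 0)
        assert np.all(np.diff(out["threshold"]) < 0)

    def test_fixed_delta_h_larger_drop_at_low_density(self, base_model):
        # read the computed curve: a fixed increment of activatable
        # conductance lowers the threshold more at the low-density end
        # (convexity of the threshold-availability relation)
        gs = np.array([0.0025, 0.005, 0.02, 0.04])
        out = threshold_vs_conductance_curve(base_model, gs)
        thr = out["threshold"]
        avail = out["activatable_g_nav"]
        slope_low = (thr[1] - thr[0]) / (avail[1] - avail[0])
        slope_high = (thr[3] - thr[2]) / (avail[3] - avail[2])
        assert abs(slope_low) > abs(slope_high)


class TestVoltageClamp:
    def _peak_na(self, cfg, level, dur):
        proto = Protocol.voltage_steps(
            (-60.0, 200.0), (level, dur), (-10.0, 5.0), (-60.0, 20.0)
        )
        res = simulate_voltage_clamp(cfg, proto)
        t0 = 200.0 + dur
        i0 = int(np.searchsorted(res.t, t0))
        i1 = int(np.searchsorted(res.t, t0 + 5.0))
        return float(res.currents["nav"][i0:i1].min())

    def test_clamp_at_ena_zero_na_current(self, base_model):
        proto = Protocol.voltage_steps((base_model.e_na, 50.0))
        res = simulate_voltage_clamp(base_model, proto)
        assert np.abs(res.currents["nav"]).max() == pytest.approx(0.0, abs=1e-12)

    def test_deeper_prehyperpolarization_grows_peak_na(self, base_model):
        peaks = [self._peak_na(base_model, lv, 25.0) for lv in (-60, -65, -70, -75)]
        assert all(b < a for a, b in zip(peaks, peaks[1:]))  # more inward

    def test_duration_independence_10_to_90ms(self, base_model):
        p10 = self._peak_na(base_model, -70.0, 10.0)
        p90 = self._peak_na(base_model, -70.0, 90.0)
        assert abs(p90 - p10) / abs(p10) < 0.02


class TestTrainAHPBuildup:
    def test_no_ia_no_growth(self, base_model):
        s = train_ahp_buildup(base_model.replace(ia_variant="none"), (1, 4, 16))
        amps = [x.ahp_amplitude for x in s]
        assert abs(amps[2] - amps[0]) < 0.5

    @pytest.mark.parametrize("variant", ["original", "modified"])
    def test_ia_variants_deepen_with_train_length(self, base_model, variant):
        s = train_ahp_buildup(base_model.replace(ia_variant=variant), (1, 4, 16))
        amps = [x.ahp_amplitude for x in s]
        areas = [x.ahp_area for x in s]
        assert amps[2] < amps[1] < amps[0] < -1.0
        assert areas[2] < areas[0]
        assert all(x.n_detected_spikes == x.n_spikes for x in s)

    def test_single_spike_deterministic(self, base_model):
        a = train_ahp_buildup(base_model, (1,))[0]
        b = train_ahp_buildup(base_model, (1,))[0]
        assert a.ahp_amplitude == b.ahp_amplitude
        assert a.ahp_area == b.ahp_area

    def test_spike_failure_reported(self, base_model):
        with pytest.raises(RuntimeError, match="elicited only"):
            train_ahp_buildup(base_model, (4,), pulse_pa=10.0)


class TestProtocolValidation:
    def test_bad_epoch(self):
        with pytest.raises(ValueError):
            Epoch(100.0, 0.0)

    def test_bad_mode(self):
        with pytest.raises(ValueError):
            Protocol((Epoch(0.0, 10.0),), "currentclamp")

    def test_pulse_overlap_rejected(self):
        with pytest.raises(ValueError, match="period"):
            Protocol.pulse_train(4, 400.0, 100.0, pulse_ms=3.0)

    def test_wrong_mode_dispatch(self, base_model):
        vproto = Protocol.voltage_steps((-60.0, 10.0))
        with pytest.raises(ValueError, match="not current clamp"):
            simulate_current_clamp(base_model, vproto)
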