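import numpy as np
import pandas as pd
import pytest

from ahpburst.detect import annotate_thresholds, detect_bursts_adaptive, detect_spikes
from ahpburst.features import (
    AHP_SEARCH_MS,
    ahp_features,
    compute_burst_context,
    derived_burst_metrics,
    extract_cell_tables,
    pre_ap_features,
    qc_filter_cells,
    slow_ahp_tau,
    BurstContext,
)
from ahpburst.synth import GeneratorParams, generate_ahp_decay, generate_cell_recording
from ahpburst.trace import APEvent, BurstSegmentation, VmTrace

FS = 25000.0
DT = 1000.0 / FS


def _trace(v):
    return VmTrace(np.asarray(v, dtype=float), fs=FS)


def _seg_with_bursts(spike_times_per_burst):
    seg = BurstSegmentation(final_tisi=50.0)
    for times in spike_times_per_burst:
        burst = [
            APEvent(peak_time=t, peak_value=30.0, threshold_time=t - 0.5,
                    threshold_value=-45.0, index_in_burst=k)
            for k, t in enumerate(times)
        ]
        seg.bursts.append(burst)
    return seg


class TestBurstContext:
    def test_flat_interval(self):
        n = int(600.0 / DT)
        v = np.full(n, -60.0)
        seg = _seg_with_bursts([[500.0, 520.0]])
        ctx = compute_burst_context(_trace(v), seg, 0)
        assert ctx.v_rest == pytest.approx(-60.0)
        assert ctx.fluct_amplitude == pytest.approx(-60.0)
        assert not ctx.inherited

    def test_short_interval_inherits(self):
        n = int(1000.0 / DT)
        v = np.full(n, -60.0)
        seg = _seg_with_bursts([[500.0, 520.0], [670.0, 690.0]])  # 150 ms apart
        ctx0 = compute_burst_context(_trace(v), seg, 0)
        ctx1 = compute_burst_context(_trace(v), seg, 1, previous=ctx0)
        assert ctx1.inherited
        assert ctx1.v_rest == ctx0.v_rest

    def test_first_burst_short_interval_excluded(self):
        n = int(300.0 / DT)
        v = np.full(n, -60.0)
        seg = _seg_with_bursts([[150.0, 170.0]])
        ctx = compute_burst_context(_trace(v), seg, 0)
        assert ctx.excluded
        assert "no predecessor" in ctx.reason

    def test_sinusoidal_excursion_sets_fluct(self):
        n = int(600.0 / DT)
        t = np.arange(n) * DT
        v = np.full(n, -60.0)
        m = (t > 200) & (t < 300)
        v[m] += 2.0 * np.sin(np.pi * (t[m] - 200) / 100.0)
        seg = _seg_with_bursts([[520.0, 540.0]])
        ctx = compute_burst_context(_trace(v), seg, 0)
        assert ctx.fluct_amplitude - ctx.v_rest == pytest.approx(2.0, abs=0.01)


class TestPreAPFeatures:
    def _event(self, thr_time, thr_value):
        return APEvent(peak_time=thr_time + 0.5, peak_value=30.0,
                       threshold_time=thr_time, threshold_value=thr_value)

    def test_v_shaped_dip_located(self):
        n = int(100.0 / DT)
        t = np.arange(n) * DT
        v = np.full(n, -60.0)
        thr_t = 80.0
        dip_t = thr_t - 3.0
        m = (t >= dip_t - 3.0) & (t <= thr_t)
        v[m] = -60.0 + np.abs(t[m] - dip_t)  # V shape, 1 mV/ms legs
        pre = pre_ap_features(_trace(v), self._event(thr_t, v[int(thr_t / DT)]))
        assert not pre.flagged
        assert pre.pre_ap_time == pytest.approx(dip_t, abs=0.2)
        assert pre.pre_ap_potential == pytest.approx(-60.0, abs=0.01)

    def test_rebound_of_exactly_04_mv_accepted(self):
        # "at least 0.4 mV": boundary value must stop the backward search
        n = int(60.0 / DT)
        t = np.arange(n) * DT
        thr_t = 50.0
        v = np.interp(
            t, [0.0, 20.0, 30.0, thr_t], [-59.6, -59.6, -60.0, -55.0]
        )
        pre = pre_ap_features(_trace(v), self._event(thr_t, -55.0))
        assert not pre.flagged
        assert pre.pre_ap_potential == pytest.approx(-60.0, abs=0.02)

    def test_linear_ramp_slope_recovered(self):
        # pre-AP peak > 5 ms before threshold: regression over the last 5 ms
        n = int(100.0 / DT)
        t = np.arange(n) * DT
        thr_t = 90.0
        dip_t = 70.0
        s = 0.4  # mV/ms
        v = np.full(n, -59.0)
        v[t >= 50.0] = -59.0 - 0.05 * (t[t >= 50.0] - 50.0)
        m = t >= dip_t
        v[m] = v[int(dip_t / DT)] + s * (t[m] - dip_t)
        pre = pre_ap_features(_trace(v), self._event(thr_t, float(v[int(thr_t / DT)])))
        assert pre.pre_ap_slope == pytest.approx(s, rel=1e-3)

    def test_no_rebound_flagged_with_minimum(self):
        # monotone descent into the threshold: no rebound anywhere
        n = int(400.0 / DT)
        t = np.arange(n) * DT
        v = -55.0 - 0.01 * t
        ev = self._event(380.0, float(v[int(380.0 / DT)]))
        pre = pre_ap_features(_trace(v), ev)
        assert pre.flagged
        assert np.isfinite(pre.pre_ap_potential)


class TestAHPFeatures:
    def test_amplitude_definition(self):
        # v_rest -60, minimum -65 between the spikes -> amplitude -5
        n = int(100.0 / DT)
        t = np.arange(n) * DT
        v = np.full(n, -60.0)
        m = (t > 20.0) & (t < 60.0)
        v[m] = -60.0 - 5.0 * np.sin(np.pi * (t[m] - 20.0) / 40.0)
        ap = APEvent(peak_time=18.0, peak_value=30.0, threshold_time=17.5,
                     threshold_value=-45.0)
        nxt = APEvent(peak_time=65.0, peak_value=30.0, threshold_time=62.0,
                      threshold_value=-45.0)
        f = ahp_features(_trace(v), ap, nxt, v_rest=-60.0, prev_threshold=-45.0)
        assert f.amplitude == pytest.approx(-5.0, abs=0.01)
        assert f.duration == pytest.approx(62.0 - f.peak_time)

    def test_linear_recovery_slope(self):
        # linear rise from the trough to the threshold: slope = r in any band
        n = int(80.0 / DT)
        t = np.arange(n) * DT
        r = 0.8
        trough_t, thr_t = 20.0, 60.0
        v = np.full(n, -65.0)
        m = t >= trough_t
        v[m] = -65.0 + r * (t[m] - trough_t)
        v = np.minimum(v, -45.0 + 20.0)
        ap = APEvent(peak_time=2.0, peak_value=30.0, threshold_value=-45.0)
        nxt = APEvent(peak_time=62.0, peak_value=30.0, threshold_time=60.0,
                      threshold_value=-45.0)
        f = ahp_features(_trace(v), ap, nxt, v_rest=-60.0, prev_threshold=-45.0)
        assert f.slope == pytest.approx(r, rel=1e-3)

    def test_long_isi_caps_window_at_300ms(self):
        n = int(500.0 / DT)
        t = np.arange(n) * DT
        v = np.full(n, -60.0)
        v[(t > 350.0) & (t < 380.0)] = -70.0  # dip beyond the 300 ms window
        v[(t > 50.0) & (t < 80.0)] = -63.0  # dip inside it
        ap = APEvent(peak_time=10.0, peak_value=30.0, threshold_value=-45.0)
        nxt = APEvent(peak_time=410.0, peak_value=30.0, threshold_time=408.0,
                      threshold_value=-45.0)
        f = ahp_features(_trace(v), ap, nxt, v_rest=-60.0, prev_threshold=-45.0)
        assert f.peak_time < 10.0 + AHP_SEARCH_MS
        assert f.peak_value == pytest.approx(-63.0)

    def test_amplitude_nonpositive_when_below_rest(self, quick_cell):
        trace, _gt = quick_cell
        events = detect_spikes(trace)
        annotate_thresholds(trace, events)
        seg = detect_bursts_adaptive([e.peak_time for e in events], events=events)
        ap_df, _ = extract_cell_tables(trace, seg)
        below = ap_df[ap_df["ahp_peak_value"] < ap_df["v_rest"]]
        assert (below["ahp_amplitude"] <= 0).all()


class TestDerivedBurstMetrics:
    CTX = BurstContext(v_rest=-60.0, fluct_amplitude=-58.0)

    def test_normalization_anchors(self):
        out = derived_burst_metrics([-60.0, -58.0], [0.0, 20.0], self.CTX)
        np.testing.assert_allclose(out["normalized_thresholds"], [0.0, 1.0])

    def test_intraburst_frequency_is_mean_inverse_isi(self):
        out = derived_burst_metrics(
            [-50.0, -50.0, -50.0], [0.0, 10.0, 30.0], self.CTX
        )
        assert out["intraburst_freq"] == pytest.approx((100.0 + 50.0) / 2.0)
        assert out["burst_size"] == 3

    def test_thresholds_below_rest_give_negative_normalized(self):
        out = derived_burst_metrics([-61.0, -62.0], [0.0, 15.0], self.CTX)
        assert (out["normalized_thresholds"] < 0).all()

    def test_degenerate_span_flagged(self):
        ctx = BurstContext(v_rest=-60.0, fluct_amplitude=-60.0)
        out = derived_burst_metrics([-59.0, -59.0], [0.0, 10.0], ctx)
        assert out["normalized_flagged"]
        assert np.all(np.isnan(out["normalized_thresholds"]))


class TestSlowAHPTau:
    def _seg_for(self, trace, peaks_ms):
        seg = BurstSegmentation(final_tisi=50.0)
        burst = [
            APEvent(peak_time=t, peak_value=30.0, threshold_time=t - 0.5,
                    threshold_value=-45.0)
            for t in peaks_ms
        ]
        seg.bursts.append(burst)
        return seg

    def test_noiseless_single_exponential_recovered_exactly(self):
        tau = 150.0
        n = int(900.0 / DT)
        t = np.arange(n) * DT
        v = np.full(n, -60.0)
        t0 = 100.0
        m = t >= t0
        v[m] = -60.0 - 6.0 * np.exp(-(t[m] - t0) / tau)
        trace = _trace(v)
        seg = self._seg_for(trace, [t0 - 1.0])
        fit = slow_ahp_tau(trace, seg)
        assert fit.available
        assert fit.n_bursts_used == 1
        assert fit.tau == pytest.approx(tau, rel=1e-4)

    def test_generator_recovery_within_5pct(self):
        p = GeneratorParams(n_bursts=10, noise_sd=0.2, seed=3)
        trace, gt = generate_cell_recording(p)
        events = detect_spikes(trace)
        annotate_thresholds(trace, events)
        seg = detect_bursts_adaptive([e.peak_time for e in events], events=events)
        fit = slow_ahp_tau(trace, seg)
        assert fit.available
        assert fit.tau == pytest.approx(gt.tau_slow_true, rel=0.05)

    def test_unavailable_when_intervals_short(self):
        n = int(1400.0 / DT)  # recording ends 280 ms after the last burst
        v = np.full(n, -60.0)
        trace = _trace(v)
        seg = BurstSegmentation(final_tisi=50.0)
        for t0 in (300.0, 700.0, 1100.0):  # 400 ms apart < 500 ms rule
            seg.bursts.append(
                [APEvent(peak_time=t0, peak_value=30.0),
                 APEvent(peak_time=t0 + 20.0, peak_value=30.0)]
            )
        fit = slow_ahp_tau(trace, seg)
        assert not fit.available
        assert fit.n_bursts_used == 0


class TestQCFilter:
    def _summaries(self, **overrides):
        base = {
            "cell_id": ["a", "b", "c"],
            "n_bursts": [10, 10, 10],
            "resistance_mohm": [100.0, 100.0, 100.0],
            "median_interburst_ms": [800.0, 800.0, 800.0],
        }
        base.update(overrides)
        return pd.DataFrame(base)

    def test_too_few_bursts_dropped(self):
        kept, dropped = qc_filter_cells(self._summaries(n_bursts=[3, 10, 10]))
        assert list(dropped["cell_id"]) == ["a"]
        assert dropped["reason"].iloc[0] == "too few bursts"

    def test_high_resistance_dropped(self):
        kept, dropped = qc_filter_cells(
            self._summaries(resistance_mohm=[100.0, 600.0, 100.0])
        )
        assert list(dropped["cell_id"]) == ["b"]
        assert "membrane resistance" in dropped["reason"].iloc[0]

    def test_short_intervals_dropped(self):
        kept, dropped = qc_filter_cells(
            self._summaries(median_interburst_ms=[800.0, 800.0, 150.0])
        )
        assert list(dropped["cell_id"]) == ["c"]
        assert "intervals too short" in dropped["reason"].iloc[0]

    def test_all_pass(self):
        kept, dropped = qc_filter_cells(self._summaries())
        assert len(kept) == 3 and len(dropped) == 0


class TestRoundTripInvariants:
    def test_translation_invariance(self):
        p = GeneratorParams(n_bursts=4, seed=8)
        trace, _gt = generate_cell_recording(p)
        offset = 11.0

        def run(tr, v_detect):
            events = detect_spikes(tr, v_detect=v_detect)
            annotate_thresholds(tr, events)
            seg = detect_bursts_adaptive([e.peak_time for e in events], events=events)
            return extract_cell_tables(tr, seg)

        ap0, _b0 = run(trace, -23.0)
        ap1, _b1 = run(trace.with_offset(offset), -23.0 + offset)
        for col in ("ahp_amplitude", "ahp_slope", "ahp_duration",
                    "relative_threshold", "normalized_threshold"):
            np.testing.assert_allclose(
                ap0[col].to_numpy(dtype=float),
                ap1[col].to_numpy(dtype=float),
                atol=1e-9, err_msg=col,
            )

    def test_full_feature_ground_truth_round_trip(self, quick_cell):
        trace, gt = quick_cell
        events = detect_spikes(trace)
        annotate_thresholds(trace, events)
        seg = detect_bursts_adaptive([e.peak_time for e in events], events=events)
        ap_df, _ = extract_cell_tables(trace, seg)
        assert len(ap_df) == gt.n_spikes
        # thresholds within 0.5 mV
        np.testing.assert_allclose(
            ap_df["threshold"].to_numpy(), gt.true_thresholds, atol=0.5
        )
        # AHP peaks within 1 sample for intraburst troughs
        intr = ap_df["index_in_burst"] < ap_df.groupby("burst")[
            "index_in_burst"
        ].transform("max")
        dt = trace.dt_ms
        err = np.abs(
            ap_df.loc[intr, "ahp_peak_time"].to_numpy()
            - gt.ahp_peak_times[intr.to_numpy()]
        )
        assert err.max() <= dt + 1e-9
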