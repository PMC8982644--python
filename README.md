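# ahpburst

Analysis of bursting activity in current-clamp membrane-potential recordings
— spike/threshold/burst detection, afterhyperpolarization (AHP) feature
extraction, the statistical models linking AHP shape to burst properties —
plus a single-compartment conductance-based neuron model (Na_v, delayed
rectifier, A-type potassium, leak) that reproduces threshold shifts through
sodium-channel deinactivation and slow-AHP buildup through the A-current.

Everything runs on synthetic or simulated data: the `synth` module generates
bursting voltage traces with exact ground truth so the whole pipeline is
testable without recordings.

## Modules

| module | contents |
| --- | --- |
| `ahpburst.synth` | synthetic recordings (`generate_cell_recording`), spike-train fixtures, exponential AHP-decay segments — all seeded and reproducible |
| `ahpburst.detect` | spike detection (upward crossings of −23 mV, 1 ms minimum ISI), AP-threshold location (second-derivative onset or dV/dt > 40 mV/ms), recursive adaptive burst segmentation (median + 4×MAD of intraburst ISIs, iterated from 90 ms) |
| `ahpburst.features` | per-burst resting potential / fluctuation ceiling, pre-AP potential & slope, AHP amplitude/slope/duration, relative & normalized thresholds, intraburst frequency, slow-AHP exponential fit (median trace, 50–500 ms window), cell-level QC filters |
| `ahpburst.stats` | within-cell OLS + Pearson r, Bonferroni–Holm correction, population one-sample t tests (CI = 1.96×SEM, ES = mean/SD), per-cell threshold model with post-burst prediction & overshoot detection, pooled burst-size/frequency models with type-I ANOVA comparison, JZS Bayes factor (Cauchy scale 0.707) |
| `ahpburst.biophys` | conductance-based simulator (exponential-Euler gates + Crank–Nicolson voltage, 0.1 ms steps), current/voltage-clamp protocols, holding-current search, threshold-shift and activatable-conductance curves, 40 Hz train AHP buildup, Nernst utility |
| `ahpburst.io` | CSV / HDF5 traces (ABF behind the optional `pyabf` extra), ground-truth JSON, tidy event tables |
| `ahpburst.pipeline` / `ahpburst.cli` | end-to-end orchestration with a provenance manifest |

## CLI

```bash
ahpburst generate --out-dir out --n-cells 5 --seed 1          # synthetic data + truth
ahpburst detect   --in trace.csv --v-detect -23 --tisi0 90 --out events.csv
ahpburst features --in trace.csv --out-dir out
ahpburst stats    --per-ap out/per_ap.csv --per-burst out/per_burst.csv --out-dir out
ahpburst simulate --model model.json --protocol protocol.json --out sim.csv
ahpburst full     --n-cells 5 --seed 1 --out-dir out          # whole pipeline
```

`model.json` holds `ModelConfig` fields (densities in S/cm², reversals in
mV); `protocol.json` is `{"mode": "iclamp"|"vclamp", "epochs": [[amplitude,
duration_ms], ...]}` with amplitudes in pA (current clamp) or mV (voltage
clamp).

## Output tables

`per_ap.csv`: one row per AP — `cell_id, burst, index_in_burst, peak_time,
peak_value, threshold_time, threshold, pre_ap_potential, pre_ap_slope,
ahp_peak_time, ahp_peak_value, ahp_amplitude, ahp_slope, ahp_duration,
v_rest, relative_threshold, normalized_threshold` (times ms, voltages mV;
AHP amplitudes are negative).

`per_burst.csv`: one row per burst — `size, intraburst_freq, v_rest,
fluct_amplitude, inherited_context, first/last AHP amplitude & slope,
slow_tau, excluded, exclude_reason`.
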