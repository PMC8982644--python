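"""End-to-end orchestration: generate/ingest -> detect -> extract -> model ->
report, with a provenance manifest sufficient to re-run identically."""

from __future__ import annotations

import dataclasses
import json
import platform
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .detect import DetectionParams, annotate_thresholds, detect_bursts_adaptive, detect_spikes
from .features import extract_cell_tables, qc_filter_cells, slow_ahp_tau
from .io import read_trace
from .stats import (
    fit_burst_models,
    holm_correction,
    population_summary,
    within_cell_fit,
)
from .synth import GeneratorParams, generate_cell_recording
from .trace import VmTrace

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "analyze_cell"]


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    input_files: List[str] = field(default_factory=list)
    n_synthetic_cells: int = 0
    generator: Dict[str, object] = field(default_factory=dict)  # GeneratorParams overrides
    detection: Dict[str, object] = field(default_factory=dict)  # DetectionParams overrides
    junction_offset: float = 0.0  # mV applied to loaded traces
    min_bursts: int = 4
    include_burst_models: bool = True
    out_dir: Optional[str] = None
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    per_ap: pd.DataFrame
    per_burst: pd.DataFrame
    cell_summaries: pd.DataFrame
    dropped_cells: pd.DataFrame
    within_cell_fits: pd.DataFrame
    population: Dict[str, object]
    burst_models: Dict[str, object]
    manifest: Dict[str, object]
    failures: List[Dict[str, str]]

    @property
    def ok(self) -> bool:
        return not self.failures


def analyze_cell(trace: VmTrace, det: DetectionParams):
    """Detection + segmentation + feature tables for one trace."""
    events = detect_spikes(trace, v_detect=det.v_detect, min_isi=det.min_isi)
    annotate_thresholds(
        trace, events, method=det.threshold_method,
        dvdt_cut=det.dvdt_cut, smooth_ms=det.smooth_ms,
    )
    seg = detect_bursts_adaptive(
        [e.peak_time for e in events],
        tisi0=det.tisi0,
        mad_mult=det.mad_mult,
        min_burst_size=det.min_burst_size,
        events=events,
    )
    ap_df, burst_df = extract_cell_tables(trace, seg)
    slow = slow_ahp_tau(trace, seg)
    return seg, ap_df, burst_df, slow


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage; stage failures are recorded in the failure manifest
    and do not discard the outputs of earlier stages."""
    failures: List[Dict[str, str]] = []
    det = DetectionParams(**config.detection)

    traces: List[VmTrace] = []
    try:
        for path in config.input_files:
            tr = read_trace(path)
            if config.junction_offset:
                tr = tr.with_offset(config.junction_offset)
            traces.append(tr)
        for i in range(config.n_synthetic_cells):
            params = GeneratorParams(
                **{**config.generator, "seed": config.seed + i}
            )
            tr, _gt = generate_cell_recording(params)
            tr.cell_id = f"synth-{i:03d}"
            traces.append(tr)
    except Exception as exc:  # noqa: BLE001 - recorded, not swallowed silently
        failures.append({"stage": "ingest", "error": repr(exc),
                         "traceback": traceback.format_exc()})

    ap_tables, burst_tables, summaries = [], [], []
    for tr in traces:
        try:
            seg, ap_df, burst_df, slow = analyze_cell(tr, det)
            ap_tables.append(ap_df)
            burst_df = burst_df.assign(slow_tau=slow.tau if slow.available else np.nan)
            burst_tables.append(burst_df)
            interburst = (
                np.diff([b[0].peak_time for b in seg.bursts])
                if seg.n_bursts > 1
                else np.array([np.nan])
            )
            summaries.append(
                {
                    "cell_id": tr.cell_id,
                    "n_spikes": seg.n_spikes,
                    "n_bursts": seg.n_bursts,
                    "n_isolated": len(seg.isolated_aps),
                    "final_tisi": seg.final_tisi,
                    "slow_tau": slow.tau if slow.available else np.nan,
                    "slow_tau_n_bursts": slow.n_bursts_used,
                    "median_interburst_ms": float(np.nanmedian(interburst)),
                    "resistance_mohm": np.nan,
                }
            )
        except Exception as exc:  # noqa: BLE001
            failures.append({"stage": f"detect/features:{tr.cell_id}",
                             "error": repr(exc),
                             "traceback": traceback.format_exc()})

    per_ap = pd.concat(ap_tables, ignore_index=True) if ap_tables else pd.DataFrame()
    per_burst = (
        pd.concat(burst_tables, ignore_index=True) if burst_tables else pd.DataFrame()
    )
    cell_df = pd.DataFrame(summaries)

    kept = cell_df
    dropped = pd.DataFrame()
    if len(cell_df):
        kept, dropped = qc_filter_cells(cell_df, min_bursts=config.min_bursts)

    fits_df = pd.DataFrame()
    population: Dict[str, object] = {}
    try:
        if len(kept) >= 2 and len(per_ap):
            fits = []
            for cid in kept["cell_id"]:
                sub = per_ap[(per_ap["cell_id"] == cid) & (per_ap["index_in_burst"] == 0)]
                fits.append(
                    within_cell_fit(sub["pre_ap_potential"], sub["threshold"], cid)
                )
            valid = [f for f in fits if not f.flagged]
            if valid:
                holm = holm_correction([f.p_raw for f in valid])
                for f, ph in zip(valid, holm):
                    f.p_holm = float(ph)
            fits_df = pd.DataFrame([dataclasses.asdict(f) for f in fits])
            if len(valid) >= 2:
                ps_slope = population_summary([f.slope for f in valid])
                ps_r = population_summary([f.r for f in valid])
                population = {
                    "slope": dataclasses.asdict(ps_slope),
                    "r": dataclasses.asdict(ps_r),
                }
    except Exception as exc:  # noqa: BLE001
        failures.append({"stage": "within_cell_stats", "error": repr(exc),
                         "traceback": traceback.format_exc()})

    burst_models: Dict[str, object] = {}
    if config.include_burst_models:
        try:
            pooled = per_burst[per_burst["cell_id"].isin(kept["cell_id"])]
            models = fit_burst_models(pooled, include_slow_tau=True)
            burst_models = {
                k: dataclasses.asdict(v) for k, v in models.items()
            }
        except Exception as exc:  # noqa: BLE001
            failures.append({"stage": "burst_models", "error": repr(exc),
                             "traceback": traceback.format_exc()})

    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "config": config.to_dict(),
        "detection_params": dataclasses.asdict(det),
        "n_cells_in": len(traces),
        "n_cells_kept": len(kept),
        "n_cells_dropped": len(dropped),
        "failures": failures,
    }
    result = PipelineResult(
        per_ap=per_ap,
        per_burst=per_burst,
        cell_summaries=kept,
        dropped_cells=dropped,
        within_cell_fits=fits_df,
        population=population,
        burst_models=burst_models,
        manifest=manifest,
        failures=failures,
    )
    if config.out_dir:
        _write_bundle(result, Path(config.out_dir))
    return result


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def _write_bundle(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.per_ap.to_csv(out_dir / "per_ap.csv", index=False)
    result.per_burst.to_csv(out_dir / "per_burst.csv", index=False)
    result.cell_summaries.to_csv(out_dir / "cells_kept.csv", index=False)
    result.dropped_cells.to_csv(out_dir / "cells_dropped.csv", index=False)
    result.within_cell_fits.to_csv(out_dir / "within_cell_fits.csv", index=False)
    (out_dir / "population.json").write_text(
        json.dumps(_jsonable(result.population), indent=2)
    )
    (out_dir / "burst_models.json").write_text(
        json.dumps(_jsonable(result.burst_models), indent=2)
    )
    name = "manifest.json" if result.ok else "failure_manifest.json"
    (out_dir / name).write_text(json.dumps(_jsonable(result.manifest), indent=2))
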