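"""Trace and table input/output.

Traces: CSV (columns ``time_ms, vm_mV``), HDF5 (datasets ``/time`` and
``/vm`` plus attributes, optional ``/ground_truth`` group) and, when the
optional ``pyabf`` dependency is installed, Axon Binary Format.  Events and
segmentations are written as tidy CSV tables and JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

from .synth import GroundTruth
from .trace import BurstSegmentation, VmTrace

__all__ = [
    "read_trace",
    "read_csv_trace",
    "read_hdf5_trace",
    "read_abf_trace",
    "write_csv_trace",
    "write_hdf5_trace",
    "ground_truth_to_json",
    "ground_truth_from_json",
    "segmentation_tables",
]

PathLike = Union[str, Path]


def read_trace(path: PathLike, **kwargs) -> VmTrace:
    """Dispatch on file extension (.csv, .h5/.hdf5, .abf)."""
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return read_csv_trace(path, **kwargs)
    if suffix in (".h5", ".hdf5"):
        return read_hdf5_trace(path, **kwargs)
    if suffix == ".abf":
        return read_abf_trace(path, **kwargs)
    raise ValueError(f"unsupported trace format: {suffix!r}")


def read_csv_trace(path: PathLike, cell_id: Optional[str] = None) -> VmTrace:
    df = pd.read_csv(path)
    for col in ("time_ms", "vm_mV"):
        if col not in df.columns:
            raise ValueError(f"CSV trace must have a {col!r} column")
    t = df["time_ms"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trace needs at least two samples")
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
        raise ValueError("trace must be uniformly sampled")
    fs = 1000.0 / dts[0]
    return VmTrace(
        df["vm_mV"].to_numpy(dtype=float),
        fs=fs,
        t0=float(t[0]),
        cell_id=cell_id or Path(path).stem,
    )


def write_csv_trace(trace: VmTrace, path: PathLike) -> None:
    pd.DataFrame({"time_ms": trace.times, "vm_mV": trace.samples}).to_csv(
        path, index=False
    )


def read_hdf5_trace(path: PathLike, cell_id: Optional[str] = None) -> VmTrace:
    import h5py

    with h5py.File(path, "r") as f:
        vm = f["vm"][...]
        fs = float(f.attrs["fs"])
        t0 = float(f.attrs.get("t0", 0.0))
        cid = cell_id or str(f.attrs.get("cell_id", Path(path).stem))
    return VmTrace(vm, fs=fs, t0=t0, cell_id=cid)


def write_hdf5_trace(
    trace: VmTrace, path: PathLike, ground_truth: Optional[GroundTruth] = None
) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("vm", data=trace.samples)
        f.create_dataset("time", data=trace.times)
        f.attrs["fs"] = trace.fs
        f.attrs["t0"] = trace.t0
        f.attrs["cell_id"] = trace.cell_id
        f.attrs["offset_applied"] = trace.offset_applied
        if ground_truth is not None:
            grp = f.create_group("ground_truth")
            for key, val in asdict(ground_truth).items():
                if isinstance(val, np.ndarray):
                    grp.create_dataset(key, data=val)
                else:
                    grp.attrs[key] = val


def read_abf_trace(
    path: PathLike, channel: int = 0, sweep: int = 0, cell_id: Optional[str] = None
) -> VmTrace:
    """Axon Binary Format reader (requires the optional ``pyabf`` extra)."""
    try:
        import pyabf
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "reading ABF files requires the optional dependency 'pyabf' "
            "(pip install ahpburst[abf])"
        ) from exc
    abf = pyabf.ABF(str(path))
    abf.setSweep(sweep, channel=channel)
    return VmTrace(
        np.asarray(abf.sweepY, dtype=float),
        fs=float(abf.dataRate),
        t0=float(abf.sweepX[0]) * 1000.0,
        cell_id=cell_id or Path(path).stem,
    )


def ground_truth_to_json(gt: GroundTruth, path: PathLike) -> None:
    d = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in asdict(gt).items()
    }
    Path(path).write_text(json.dumps(d, indent=2))


def ground_truth_from_json(path: PathLike) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    arrays = {
        k: np.asarray(v) for k, v in d.items() if isinstance(v, list)
    }
    if "burst_assignments" in arrays:
        arrays["burst_assignments"] = arrays["burst_assignments"].astype(int)
    scalars = {k: v for k, v in d.items() if not isinstance(v, list)}
    return GroundTruth(**arrays, **scalars)


def segmentation_tables(
    seg: BurstSegmentation, cell_id: str = ""
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy (per-AP, per-burst) tables for a segmentation."""
    ap_rows = []
    for b_idx, burst in enumerate(seg.bursts):
        for k, ap in enumerate(burst):
            ap_rows.append(
                {
                    "cell_id": cell_id,
                    "burst": b_idx,
                    "index_in_burst": k,
                    "peak_time": ap.peak_time,
                    "peak_value": ap.peak_value,
                    "threshold_time": ap.threshold_time,
                    "threshold": ap.threshold_value,
                    "flagged": ap.flagged,
                }
            )
    for ap in seg.isolated_aps:
        ap_rows.append(
            {
                "cell_id": cell_id,
                "burst": -1,
                "index_in_burst": "isolated",
                "peak_time": ap.peak_time,
                "peak_value": ap.peak_value,
                "threshold_time": ap.threshold_time,
                "threshold": ap.threshold_value,
                "flagged": ap.flagged,
            }
        )
    burst_rows = [
        {
            "cell_id": cell_id,
            "burst": i,
            "size": len(burst),
            "t_first": burst[0].peak_time,
            "t_last": burst[-1].peak_time,
        }
        for i, burst in enumerate(seg.bursts)
    ]
    return pd.DataFrame(ap_rows), pd.DataFrame(burst_rows)
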