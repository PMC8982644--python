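"""Core trace and event containers shared by every analysis stage.

All times are in milliseconds, voltages in millivolts, sampling rates in Hz.
Sample indices are 0-based and event times coincide with sample times (no
sub-sample interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = ["VmTrace", "APEvent", "BurstSegmentation"]


@dataclass
class VmTrace:
    """Uniformly sampled membrane-potential trace.

    Parameters
    ----------
    samples : array of mV values.
    fs : sampling rate in Hz (must be > 0).
    t0 : time of the first sample, ms.
    cell_id : free-form label used in tidy output tables.
    offset_applied : constant offset already applied to ``samples``
        (e.g. a junction-potential correction), mV.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    cell_id: str = "cell0"
    offset_applied: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def dt_ms(self) -> float:
        """Sampling interval in ms."""
        return 1000.0 / self.fs

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt_ms

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms."""
        return self.t0 + np.arange(self.n_samples) * self.dt_ms

    def index_at(self, t_ms: float) -> int:
        """Nearest sample index for a time in ms (clipped to valid range)."""
        i = int(round((t_ms - self.t0) / self.dt_ms))
        return min(max(i, 0), self.n_samples - 1)

    def time_at(self, index: int) -> float:
        return self.t0 + index * self.dt_ms

    def slice_ms(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """View of samples for t in [start_ms, stop_ms)."""
        i0 = max(int(np.ceil((start_ms - self.t0) / self.dt_ms)), 0)
        i1 = min(int(np.ceil((stop_ms - self.t0) / self.dt_ms)), self.n_samples)
        return self.samples[i0:i1]

    def with_offset(self, offset_mv: float) -> "VmTrace":
        """Return a copy shifted by ``offset_mv`` (recorded in metadata)."""
        return replace(
            self,
            samples=self.samples + offset_mv,
            offset_applied=self.offset_applied + offset_mv,
        )


@dataclass
class APEvent:
    """One detected action potential."""

    peak_time: float
    peak_value: float
    threshold_time: Optional[float] = None
    threshold_value: Optional[float] = None
    index_in_burst: Optional[object] = None  # ordinal int or "isolated"
    flagged: bool = False
    flag_reason: str = ""

    def validate(self) -> None:
        if self.threshold_time is not None and not self.flagged:
            if not self.threshold_time < self.peak_time:
                raise ValueError("threshold_time must precede peak_time")
            if not self.threshold_value < self.peak_value:
                raise ValueError("threshold_value must be below peak_value")


@dataclass
class BurstSegmentation:
    """Partition of detected spikes into bursts and isolated APs."""

    bursts: list = field(default_factory=list)  # list[list[APEvent]]
    isolated_aps: list = field(default_factory=list)  # list[APEvent]
    final_tisi: float = float("nan")
    tisi_history: list = field(default_factory=list)
    warning: str = ""

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    @property
    def n_spikes(self) -> int:
        return sum(len(b) for b in self.bursts) + len(self.isolated_aps)

    def all_events(self) -> list:
        """All events in chronological order."""
        evs = [ap for b in self.bursts for ap in b] + list(self.isolated_aps)
        return sorted(evs, key=lambda e: e.peak_time)

    def burst_sizes(self) -> list:
        return [len(b) for b in self.bursts]
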