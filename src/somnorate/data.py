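"""Core domain containers: spike tables, hypnograms and signal traces.

A recording session is represented by three independent pieces:

* :class:`SpikeTable` — per-unit sorted spike times plus unit metadata
  (brain region and putative cell class).  Cell classification itself is an
  input label, not something this package computes.
* :class:`Hypnogram` — the scored brain states (WAKE/NREM/REM, optionally MA)
  as one :class:`~somnorate.intervals.IntervalSet` per state.
* :class:`SignalTrace` — a regularly sampled auxiliary power trace (EMG power
  or LFP band power) used by the substate detectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .intervals import IntervalSet

__all__ = [
    "CellClass",
    "UnitRecord",
    "SpikeTable",
    "Hypnogram",
    "SignalTrace",
    "STATE_LABELS",
    "count_spikes_in",
]

STATE_LABELS = ("WAKE", "NREM", "REM", "MA")


class CellClass(str, Enum):
    PRINCIPAL = "principal"
    INTERNEURON = "interneuron"


@dataclass
class UnitRecord:
    """A single recorded unit: identity, metadata and its spike train."""

    unit_id: str
    region: str
    cell_class: CellClass
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        self.cell_class = CellClass(self.cell_class)
        t = np.asarray(self.spike_times, dtype=float)
        if t.ndim != 1:
            raise ValueError(f"unit {self.unit_id}: spike_times must be 1-D")
        if t.size and (not np.all(np.isfinite(t)) or np.any(t < 0)):
            raise ValueError(f"unit {self.unit_id}: spike times must be finite and >= 0")
        if np.any(np.diff(t) < 0):
            raise ValueError(f"unit {self.unit_id}: spike times must be non-decreasing")
        self.spike_times = t

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


def count_spikes_in(unit: "UnitRecord | np.ndarray", mask: IntervalSet) -> Tuple[int, float]:
    """Spike count of a unit inside a mask, with the occupied duration.

    The half-open rule applies per interval: a spike exactly at an interval
    end is not counted.  Returns ``(count, duration_of_mask_s)``.
    """
    times = unit.spike_times if isinstance(unit, UnitRecord) else np.asarray(unit, float)
    return mask.count_in(times), mask.duration


@dataclass
class SpikeTable:
    """Collection of units forming the recorded population."""

    units: List[UnitRecord]

    def __post_init__(self) -> None:
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate unit_id(s): {dup}")

    def __len__(self) -> int:
        return len(self.units)

    @property
    def unit_ids(self) -> List[str]:
        return [u.unit_id for u in self.units]

    @property
    def principal_mask(self) -> np.ndarray:
        return np.array([u.cell_class is CellClass.PRINCIPAL for u in self.units])

    @property
    def interneuron_mask(self) -> np.ndarray:
        return np.array([u.cell_class is CellClass.INTERNEURON for u in self.units])

    def select(self, mask: Sequence[bool]) -> "SpikeTable":
        return SpikeTable([u for u, m in zip(self.units, mask) if m])

    def pooled_spike_times(self) -> np.ndarray:
        """All spikes of all units, merged and sorted (population train)."""
        if not self.units:
            return np.empty(0)
        return np.sort(np.concatenate([u.spike_times for u in self.units]))

    def sorted_by_unit_id(self) -> "SpikeTable":
        return SpikeTable(sorted(self.units, key=lambda u: u.unit_id))


class Hypnogram:
    """Scored sleep/wake states as labeled, mutually exclusive interval sets."""

    def __init__(
        self,
        states: Dict[str, IntervalSet],
        session_start_s: Optional[float] = None,
        session_end_s: Optional[float] = None,
    ) -> None:
        for label in states:
            if label not in STATE_LABELS:
                raise ValueError(f"unknown state label {label!r}; expected one of {STATE_LABELS}")
        self.states = {k: v.with_label(k) for k, v in states.items()}
        bounds = [(s.starts, s.ends) for s in states.values() if not s.is_empty]
        lo = min((float(b[0][0]) for b in bounds), default=0.0)
        hi = max((float(b[1][-1]) for b in bounds), default=0.0)
        self.session_start_s = lo if session_start_s is None else float(session_start_s)
        self.session_end_s = hi if session_end_s is None else float(session_end_s)
        self._validate()

    def _validate(self) -> None:
        arrs = [s.to_array() for s in self.states.values() if not s.is_empty]
        if not arrs:
            return
        allint = np.vstack(arrs)
        order = np.argsort(allint[:, 0], kind="stable")
        allint = allint[order]
        if np.any(allint[1:, 0] < allint[:-1, 1]):
            raise ValueError("state intervals overlap across labels")
        if allint[0, 0] < self.session_start_s or allint[-1, 1] > self.session_end_s:
            raise ValueError("state intervals exceed the session bounds")

    def get(self, label: str) -> IntervalSet:
        return self.states.get(label, IntervalSet.empty(label))

    def labeled_intervals(self) -> List[Tuple[str, float, float]]:
        """All intervals of all states, time-ordered, as (label, start, end)."""
        rows: List[Tuple[str, float, float]] = []
        for label, iset in self.states.items():
            rows.extend((label, s, e) for s, e in iset)
        rows.sort(key=lambda r: r[1])
        return rows

    def __repr__(self) -> str:  # pragma: no cover
        parts = ", ".join(f"{k}:{len(v)}" for k, v in self.states.items())
        return f"Hypnogram({parts}, [{self.session_start_s:g}, {self.session_end_s:g}))"


@dataclass
class SignalTrace:
    """Regularly sampled power trace; sample k covers [start + k*step, +step)."""

    start_s: float
    step_s: float
    values: np.ndarray
    kind: str = "emg_power"

    def __post_init__(self) -> None:
        if self.step_s <= 0:
            raise ValueError("step_s must be > 0")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("values must be 1-D")
        if v.size and not np.all(np.isfinite(v)):
            raise ValueError("trace values must be finite")
        self.values = v

    @classmethod
    def from_times(cls, times: np.ndarray, values: np.ndarray, kind: str = "emg_power") -> "SignalTrace":
        t = np.asarray(times, dtype=float)
        if t.size < 2:
            raise ValueError("need at least two samples to infer the grid")
        steps = np.diff(t)
        step = float(np.median(steps))
        if not np.allclose(steps, step, rtol=0, atol=1e-6 * max(step, 1.0)):
            raise ValueError("sample times are not a regular grid")
        return cls(float(t[0]), step, np.asarray(values, float), kind=kind)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def end_s(self) -> float:
        return self.start_s + self.n * self.step_s

    @property
    def times(self) -> np.ndarray:
        return self.start_s + self.step_s * np.arange(self.n)

    def sample_mask(self, intervals: IntervalSet) -> np.ndarray:
        """Boolean mask of samples whose timestamp falls inside the set."""
        return intervals.contains(self.times)

    def covers(self, intervals: IntervalSet) -> bool:
        if intervals.is_empty:
            return True
        return self.start_s <= float(intervals.starts[0]) and self.end_s >= float(intervals.ends[-1])
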