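"""Interval algebra on half-open ``[start, end)`` time intervals.

Every state, epoch, sub-period and exclusion mask in the package is carried by
an :class:`IntervalSet`: an ordered, non-overlapping family of half-open
intervals measured in seconds.  The half-open convention means a time ``t``
belongs to ``[a, b)`` iff ``a <= t < b``, which makes adjacent intervals
partition time without double counting.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional, Tuple

import numpy as np

__all__ = ["IntervalSet"]


def _merge_sorted(starts: np.ndarray, ends: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Coalesce overlapping or touching intervals (inputs sorted by start)."""
    if starts.size == 0:
        return starts, ends
    out_s = [starts[0]]
    out_e = [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=float), np.asarray(out_e, dtype=float)


class IntervalSet:
    """Ordered, non-overlapping, half-open labeled time intervals.

    Parameters
    ----------
    intervals
        Iterable of ``(start_s, end_s)`` pairs (or an ``(n, 2)`` array).
    label
        Optional label carried through set operations (e.g. ``"NREM"``,
        ``"OFF"``).
    merge
        If True, overlapping or touching input intervals are coalesced;
        otherwise overlapping inputs raise ``ValueError`` (touching is
        allowed).
    """

    __slots__ = ("starts", "ends", "label")

    def __init__(
        self,
        intervals: Iterable[Tuple[float, float]] = (),
        label: Optional[str] = None,
        *,
        merge: bool = False,
    ) -> None:
        arr = np.asarray(
            intervals if not isinstance(intervals, np.ndarray) else intervals,
            dtype=float,
        )
        if arr.size == 0:
            arr = np.empty((0, 2), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("intervals must be an (n, 2) array of (start, end)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("interval bounds must be finite")
        starts = arr[:, 0].astype(float, copy=True)
        ends = arr[:, 1].astype(float, copy=True)
        if np.any(ends <= starts):
            raise ValueError("every interval requires start < end")
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        if merge:
            starts, ends = _merge_sorted(starts, ends)
        elif np.any(starts[1:] < ends[:-1]):
            raise ValueError("intervals overlap; pass merge=True to coalesce them")
        self.starts = starts
        self.ends = ends
        self.label = label

    # ------------------------------------------------------------------ basics
    @classmethod
    def empty(cls, label: Optional[str] = None) -> "IntervalSet":
        return cls((), label=label)

    @classmethod
    def from_arrays(
        cls, starts: np.ndarray, ends: np.ndarray, label: Optional[str] = None, **kw
    ) -> "IntervalSet":
        return cls(np.column_stack([starts, ends]), label=label, **kw)

    def __len__(self) -> int:
        return int(self.starts.size)

    def __iter__(self) -> Iterator[Tuple[float, float]]:
        return iter(zip(self.starts.tolist(), self.ends.tolist()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return (
            self.starts.shape == other.starts.shape
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        lab = f" label={self.label!r}" if self.label else ""
        return f"IntervalSet(n={len(self)}, duration={self.duration:.6g}s{lab})"

    @property
    def is_empty(self) -> bool:
        return self.starts.size == 0

    @property
    def duration(self) -> float:
        """Total covered time, sum of (end - start)."""
        return float(np.sum(self.ends - self.starts))

    def to_array(self) -> np.ndarray:
        return np.column_stack([self.starts, self.ends])

    def with_label(self, label: Optional[str]) -> "IntervalSet":
        out = IntervalSet.__new__(IntervalSet)
        out.starts, out.ends, out.label = self.starts, self.ends, label
        return out

    # ----------------------------------------------------------- set algebra
    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Set-theoretic intersection (half-open; touching yields nothing)."""
        res = []
        i = j = 0
        a_s, a_e = self.starts, self.ends
        b_s, b_e = other.starts, other.ends
        na, nb = len(a_s), len(b_s)
        while i < na and j < nb:
            s = max(a_s[i], b_s[j])
            e = min(a_e[i], b_e[j])
            if s < e:
                res.append((s, e))
            if a_e[i] <= b_e[j]:
                i += 1
            else:
                j += 1
        return IntervalSet(res, label=self.label)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Set difference ``self \\ other``; conserves time with intersect."""
        res = []
        b_s, b_e = other.starts, other.ends
        m = len(b_s)
        j = 0
        for s, e in zip(self.starts, self.ends):
            while j < m and b_e[j] <= s:
                j += 1
            cur = s
            k = j
            while k < m and b_s[k] < e:
                if b_s[k] > cur:
                    res.append((cur, b_s[k]))
                cur = max(cur, b_e[k])
                if cur >= e:
                    break
                k += 1
            if cur < e:
                res.append((cur, e))
        return IntervalSet(res, label=self.label)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        both = np.vstack([self.to_array(), other.to_array()])
        return IntervalSet(both, label=self.label, merge=True)

    def merge(self) -> "IntervalSet":
        """Coalesce touching intervals into maximal runs."""
        starts, ends = _merge_sorted(self.starts, self.ends)
        return IntervalSet.from_arrays(starts, ends, label=self.label)

    def clip(self, start: float, end: float) -> "IntervalSet":
        """Restrict coverage to ``[start, end)``."""
        if end <= start:
            return IntervalSet.empty(self.label)
        return self.intersect(IntervalSet([(start, end)]))

    # ------------------------------------------------------------ membership
    def contains(self, times) -> np.ndarray:
        """Boolean membership test for each time (half-open per interval)."""
        t = np.asarray(times, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        out = np.zeros(t.shape, dtype=bool)
        if self.starts.size:
            idx = np.searchsorted(self.starts, t, side="right") - 1
            ok = idx >= 0
            out[ok] = t[ok] < self.ends[idx[ok]]
        return bool(out[0]) if scalar else out

    def count_in(self, sorted_times: np.ndarray) -> int:
        """Number of (sorted) time stamps falling inside the set."""
        t = np.asarray(sorted_times, dtype=float)
        hi = np.searchsorted(t, self.ends, side="left")
        lo = np.searchsorted(t, self.starts, side="left")
        return int(np.sum(hi - lo))
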