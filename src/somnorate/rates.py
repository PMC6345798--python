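"""Firing-rate computation, quintile assignment and population CV.

Rates are always counts over occupied duration, where the occupied duration
is the time of the (possibly mask-restricted) observation window — so
excluding OFF/LOW/MA substates simply shrinks the denominator and removes
the spikes falling in the excluded time.

Principal cells are sorted into five quintiles by rank-ordered firing rate
(quintile 1 = lowest); interneurons are never quintiled and are summarized
by their plain group mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np

from .data import SpikeTable
from .intervals import IntervalSet

__all__ = [
    "RateMatrix",
    "QuintileAssignment",
    "CVResult",
    "QuintileTraces",
    "period_rates",
    "sliding_rates",
    "time_normalized_rates",
    "assign_quintiles",
    "quintile_traces",
    "population_cv",
]

IntervalLike = Union[Tuple[float, float], IntervalSet]


def _as_interval_set(period: IntervalLike) -> IntervalSet:
    if isinstance(period, IntervalSet):
        return period
    return IntervalSet([period])


# --------------------------------------------------------------- basic rates
def period_rates(
    spikes: SpikeTable,
    period: IntervalLike,
    mask: Optional[IntervalSet] = None,
) -> Tuple[np.ndarray, float]:
    """Mean rate of every unit over a period, optionally mask-restricted.

    ``mask`` is an exclusion set (e.g. OFF states): the rate is computed on
    ``period \\ mask``.  Returns ``(rates_hz, occupied_duration_s)``.
    """
    window = _as_interval_set(period)
    if mask is not None:
        window = window.subtract(mask)
    dur = window.duration
    if dur <= 0:
        return np.full(len(spikes), np.nan), 0.0
    counts = np.array([window.count_in(u.spike_times) for u in spikes.units], dtype=float)
    return counts / dur, dur


@dataclass
class RateMatrix:
    """cells x bins mean firing rates with per-bin occupancy."""

    cell_ids: np.ndarray
    bin_starts: np.ndarray
    bin_ends: np.ndarray
    rates: np.ndarray  # (n_cells, n_bins), Hz; NaN where occupancy == 0
    occupancy_s: np.ndarray  # (n_bins,)
    mask_applied: Optional[IntervalSet] = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_starts + self.bin_ends)

    @property
    def n_bins(self) -> int:
        return int(self.bin_starts.size)


def _binned_rates(
    spikes: SpikeTable,
    bin_starts: np.ndarray,
    bin_ends: np.ndarray,
    mask: Optional[IntervalSet],
    min_occupancy_frac: float,
    drop_empty: bool,
) -> RateMatrix:
    n_bins = bin_starts.size
    if mask is None:
        occupancy = bin_ends - bin_starts
        counts = np.empty((len(spikes), n_bins))
        for i, u in enumerate(spikes.units):
            hi = np.searchsorted(u.spike_times, bin_ends, side="left")
            lo = np.searchsorted(u.spike_times, bin_starts, side="left")
            counts[i] = hi - lo
    else:
        occupancy = np.empty(n_bins)
        counts = np.empty((len(spikes), n_bins))
        for b in range(n_bins):
            window = IntervalSet([(bin_starts[b], bin_ends[b])]).subtract(mask)
            occupancy[b] = window.duration
            for i, u in enumerate(spikes.units):
                counts[i, b] = window.count_in(u.spike_times)
    nominal = bin_ends - bin_starts
    usable = occupancy > min_occupancy_frac * nominal
    rates = np.full_like(counts, np.nan)
    rates[:, usable] = counts[:, usable] / occupancy[usable]
    if drop_empty:
        keep = usable
        return RateMatrix(
            cell_ids=np.asarray(spikes.unit_ids),
            bin_starts=bin_starts[keep],
            bin_ends=bin_ends[keep],
            rates=rates[:, keep],
            occupancy_s=occupancy[keep],
            mask_applied=mask,
        )
    return RateMatrix(
        cell_ids=np.asarray(spikes.unit_ids),
        bin_starts=bin_starts,
        bin_ends=bin_ends,
        rates=rates,
        occupancy_s=occupancy,
        mask_applied=mask,
    )


def sliding_rates(
    spikes: SpikeTable,
    session_bounds: Tuple[float, float],
    window_s: float = 60.0,
    step_s: float = 20.0,
    mask: Optional[IntervalSet] = None,
    min_occupancy_frac: float = 0.1,
) -> RateMatrix:
    """Sliding-window rates (1-min windows, 20-s steps by default).

    Windows ``[t0 + k*step, t0 + k*step + window)`` cover the session; with a
    mask, occupancy-corrected rates are used and windows with less than
    ``min_occupancy_frac`` of their nominal duration are omitted.
    """
    if not (window_s >= step_s > 0):
        raise ValueError("need window_s >= step_s > 0")
    t0, t1 = session_bounds
    if t1 <= t0:
        raise ValueError("empty session")
    starts = np.arange(t0, t1 - window_s + 1e-9, step_s)
    if starts.size == 0:
        starts = np.array([t0])
    ends = np.minimum(starts + window_s, t1)
    return _binned_rates(spikes, starts, ends, mask, min_occupancy_frac, drop_empty=True)


def time_normalized_rates(
    spikes: SpikeTable,
    epoch: Tuple[float, float],
    n_bins: int,
    mask: Optional[IntervalSet] = None,
    min_occupancy_frac: float = 0.1,
) -> RateMatrix:
    """Rates in ``n_bins`` equal-duration bins partitioning one epoch.

    NREM epochs are conventionally split into 30 bins and REM epochs into 10
    (NREM epochs being generally longer).  Bins fully removed by the mask are
    reported as missing (NaN), not zero.
    """
    s, e = epoch
    if n_bins < 1 or e <= s:
        raise ValueError("need n_bins >= 1 and a positive-duration epoch")
    edges = s + (e - s) * np.arange(n_bins + 1) / n_bins
    edges[-1] = e
    return _binned_rates(spikes, edges[:-1], edges[1:], mask, min_occupancy_frac, drop_empty=False)


# ------------------------------------------------------------------ quintiles
@dataclass
class QuintileAssignment:
    """Principal-cell quintile membership (1 = lowest firing)."""

    unit_ids: np.ndarray
    quintile: np.ndarray  # int in 1..n_groups per cell
    sorting_mode: str  # "whole_window" or "epoch_i"
    n_groups: int = 5

    def members(self, q: int) -> np.ndarray:
        return np.flatnonzero(self.quintile == q)

    def as_dict(self) -> Dict[str, int]:
        return {str(u): int(q) for u, q in zip(self.unit_ids, self.quintile)}


def quintile_of_rank(rank: np.ndarray, n: int, n_groups: int = 5) -> np.ndarray:
    """Group of a 1-based ascending rank: ``ceil(n_groups * r / n)``."""
    return -(-(n_groups * np.asarray(rank, dtype=np.int64)) // n)


def assign_quintiles(
    rates: np.ndarray,
    unit_ids: Sequence[str],
    mode: str = "whole_window",
    n_groups: int = 5,
) -> QuintileAssignment:
    """Rank cells by rate (ascending) and split into near-equal groups.

    Cell with 1-based rank ``r`` of ``n`` gets group ``ceil(n_groups*r/n)``;
    ties (including multiple zero-rate cells) break by ascending unit_id so
    the assignment is reproducible.
    """
    rates = np.asarray(rates, dtype=float)
    ids = np.asarray(unit_ids)
    n = rates.size
    if n < n_groups:
        raise ValueError(f"need at least {n_groups} cells to form {n_groups} groups (got {n})")
    if ids.size != n:
        raise ValueError("unit_ids must align with rates")
    order = np.lexsort((ids, rates))  # primary: rate; tie-break: unit_id
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(1, n + 1)
    return QuintileAssignment(
        unit_ids=ids,
        quintile=quintile_of_rank(rank, n, n_groups).astype(int),
        sorting_mode=mode,
        n_groups=n_groups,
    )


@dataclass
class QuintileTraces:
    """Per-quintile mean rate traces, raw and reference-normalized."""

    bin_centers: np.ndarray
    raw: np.ndarray  # (n_groups, n_bins)
    normalized: np.ndarray  # (n_groups, n_bins); NaN rows where flagged
    reference_means: np.ndarray  # (n_groups,)
    flagged: np.ndarray  # (n_groups,) bool: reference mean was 0/undefined


def quintile_traces(
    matrix: RateMatrix,
    assignment: QuintileAssignment,
    reference_period: Tuple[float, float],
) -> QuintileTraces:
    """Quintile-mean traces normalized by each quintile's reference mean.

    The reference period (e.g. the last third of the first state) selects the
    bins whose centers fall inside it; each quintile trace is divided by its
    own mean over those bins, so every normalized trace averages exactly 1
    there.  Quintiles whose reference mean is zero are flagged, not divided.
    """
    centers = matrix.bin_centers
    ref_lo, ref_hi = reference_period
    ref_bins = (centers >= ref_lo) & (centers < ref_hi)
    if not np.any(ref_bins):
        raise ValueError("reference period overlaps no bins")
    n_groups = assignment.n_groups
    raw = np.full((n_groups, matrix.n_bins), np.nan)
    for q in range(1, n_groups + 1):
        members = assignment.members(q)
        if members.size:
            raw[q - 1] = np.nanmean(matrix.rates[members], axis=0)
    ref_means = np.nanmean(raw[:, ref_bins], axis=1)
    flagged = ~np.isfinite(ref_means) | (ref_means == 0)
    normalized = np.full_like(raw, np.nan)
    ok = ~flagged
    normalized[ok] = raw[ok] / ref_means[ok, None]
    return QuintileTraces(
        bin_centers=centers,
        raw=raw,
        normalized=normalized,
        reference_means=ref_means,
        flagged=flagged,
    )


# ------------------------------------------------------------------------ CV
@dataclass
class CVResult:
    cv: float
    n_cells: int
    undefined: bool = False


def population_cv(rates: np.ndarray) -> CVResult:
    """Coefficient of variation (sample SD / mean) of per-cell rates.

    Tracks the width of the population rate distribution: homogenization
    lowers it, diversification raises it.  Undefined (flagged) when the mean
    rate is zero.
    """
    rates = np.asarray(rates, dtype=float)
    rates = rates[np.isfinite(rates)]
    if rates.size < 2:
        raise ValueError("population CV needs at least 2 cells")
    mean = float(np.mean(rates))
    if mean == 0.0:
        return CVResult(cv=np.nan, n_cells=rates.size, undefined=True)
    return CVResult(cv=float(np.std(rates, ddof=1) / mean), n_cells=rates.size)
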