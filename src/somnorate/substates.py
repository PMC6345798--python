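"""Detection of OFF states, microarousals (MA) and LOW states within NREM.

NREM sleep is not homogeneous: population firing pauses of slow-oscillation
DOWN/OFF states (tens of milliseconds), brief EMG-detected microarousals
(0.1-40 s) and longer broadband LFP power drops (LOW states) all suppress
firing.  These detectors locate the three substate families inside the
scored NREM intervals so they can be excluded (masked out) from rate
computations.

Detection rules
---------------
* OFF: any gap strictly longer than 75 ms in the *pooled* population spike
  train inside an NREM interval, with flanking spikes inside that interval.
* MA: maximal supra-threshold runs of the EMG power trace within NREM with
  duration strictly between 0.1 s and 40 s; threshold is mean + 0.5 SD of
  the NREM EMG samples, or the valley of a bimodal EMG power histogram.
* LOW: maximal sub-threshold runs of the broadband (0.625-50 Hz) LFP band
  power trace within NREM; the per-session threshold is the valley between
  the two largest modes of a smoothed histogram of log10 power in NREM,
  falling back to a percentile when the histogram is unimodal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .data import SignalTrace, SpikeTable
from .intervals import IntervalSet

__all__ = [
    "DetectionConfig",
    "detect_off_states",
    "detect_microarousals",
    "detect_low_states",
    "exclusion_mask",
]

log = logging.getLogger(__name__)


@dataclass
class DetectionConfig:
    """Tunable thresholds for the three substate detectors (seconds / Hz)."""

    off_min_gap_s: float = 0.075
    off_min_units: int = 10
    ma_min_s: float = 0.1
    ma_max_s: float = 40.0
    ma_threshold_mode: str = "mean_plus_k_sd"  # or "histogram_valley"
    ma_threshold_k: float = 0.5
    low_band_hz: Tuple[float, float] = (0.625, 50.0)  # metadata; trace is input
    low_window_s: float = 1.0
    low_step_s: float = 0.1
    low_threshold_mode: str = "histogram_valley"  # or "percentile_fallback"
    low_fallback_percentile: float = 10.0
    valley_bins: int = 100
    valley_smooth_bins: float = 3.0

    def __post_init__(self) -> None:
        if self.off_min_gap_s <= 0 or self.low_window_s <= 0 or self.low_step_s <= 0:
            raise ValueError("durations must be > 0")
        if not self.ma_min_s < self.ma_max_s:
            raise ValueError("ma_min_s must be < ma_max_s")


# ------------------------------------------------------------------- OFF
def detect_off_states(
    spikes: SpikeTable,
    nrem: IntervalSet,
    cfg: Optional[DetectionConfig] = None,
) -> IntervalSet:
    """Population-silence (OFF) intervals inside NREM.

    Within each NREM interval, every inter-spike gap of the pooled
    population train strictly longer than ``off_min_gap_s`` is emitted as
    ``(t_last_spike, t_next_spike)``.  Gaps at epoch boundaries are not
    emitted: an OFF state requires flanking spikes inside the same NREM
    interval, so state-transition silence is not mistaken for one.
    """
    cfg = cfg or DetectionConfig()
    pooled = spikes.pooled_spike_times()
    if pooled.size == 0:
        raise ValueError("cannot detect OFF states from an empty spike table")
    if len(spikes) < cfg.off_min_units:
        log.warning(
            "OFF detection with %d units (< %d): population silence may be uninformative",
            len(spikes), cfg.off_min_units,
        )
    out: List[Tuple[float, float]] = []
    for s, e in nrem:
        lo = np.searchsorted(pooled, s, side="left")
        hi = np.searchsorted(pooled, e, side="left")
        seg = pooled[lo:hi]
        if seg.size < 2:
            continue
        gaps = np.diff(seg)
        idx = np.flatnonzero(gaps > cfg.off_min_gap_s)
        out.extend(zip(seg[idx].tolist(), seg[idx + 1].tolist()))
    return IntervalSet(out, label="OFF")


# --------------------------------------------------------------------- MA
def _histogram_valley(values: np.ndarray, bins: int, smooth_bins: float) -> Optional[float]:
    """Valley of a kernel-smoothed histogram between its two largest modes.

    Returns None when the smoothed histogram has fewer than two local
    maxima (unimodal data).  Deterministic given the values.
    """
    if values.size < 10 or np.ptp(values) == 0:
        return None
    counts, edges = np.histogram(values, bins=bins)
    smoothed = gaussian_filter1d(counts.astype(float), sigma=smooth_bins, mode="nearest")
    interior = np.arange(1, len(smoothed) - 1)
    is_peak = (smoothed[interior] > smoothed[interior - 1]) & (
        smoothed[interior] >= smoothed[interior + 1]
    )
    peaks = interior[is_peak]
    if peaks.size < 2:
        return None
    top_two = peaks[np.argsort(smoothed[peaks])[-2:]]
    lo, hi = int(top_two.min()), int(top_two.max())
    if hi - lo < 2:
        return None
    valley = lo + 1 + int(np.argmin(smoothed[lo + 1 : hi]))
    return float(0.5 * (edges[valley] + edges[valley + 1]))


def _threshold_runs(
    trace: SignalTrace,
    nrem: IntervalSet,
    above: np.ndarray,
) -> List[Tuple[float, float]]:
    """Maximal runs of flagged samples, constrained within one NREM interval.

    A sample at time ``t`` covers ``[t, t + step)``; a run of consecutive
    flagged samples therefore covers ``[t_first, t_last + step)``.
    """
    times = trace.times
    in_nrem = nrem.contains(times)
    # Break runs at NREM interval changes so no run spans two intervals.
    interval_id = np.searchsorted(nrem.starts, times, side="right")
    flagged = above & in_nrem
    runs: List[Tuple[float, float]] = []
    i = 0
    n = len(flagged)
    while i < n:
        if not flagged[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and flagged[j + 1] and interval_id[j + 1] == interval_id[i]:
            j += 1
        runs.append((float(times[i]), float(times[j] + trace.step_s)))
        i = j + 1
    return runs


def detect_microarousals(
    emg: SignalTrace,
    nrem: IntervalSet,
    cfg: Optional[DetectionConfig] = None,
) -> IntervalSet:
    """Transient EMG power elevations within NREM (microarousals).

    The per-session threshold is mean + k*SD of the EMG samples within NREM
    (``mean_plus_k_sd``) or the valley of a bimodal EMG power histogram
    (``histogram_valley``; falls back with a warning when unimodal).
    Supra-threshold runs keep only durations strictly inside
    ``(ma_min_s, ma_max_s)``.
    """
    cfg = cfg or DetectionConfig()
    if not emg.covers(nrem):
        raise ValueError("EMG trace does not cover the NREM intervals")
    nrem_vals = emg.values[emg.sample_mask(nrem)]
    if nrem_vals.size == 0:
        return IntervalSet.empty("MA")
    threshold: Optional[float] = None
    if cfg.ma_threshold_mode == "histogram_valley":
        threshold = _histogram_valley(nrem_vals, cfg.valley_bins, cfg.valley_smooth_bins)
        if threshold is None:
            log.warning("EMG histogram unimodal; falling back to mean + %.2g SD", cfg.ma_threshold_k)
    if threshold is None:
        threshold = float(np.mean(nrem_vals) + cfg.ma_threshold_k * np.std(nrem_vals))
    runs = _threshold_runs(emg, nrem, emg.values > threshold)
    kept = [(s, e) for s, e in runs if cfg.ma_min_s < (e - s) < cfg.ma_max_s]
    return IntervalSet(kept, label="MA")


# -------------------------------------------------------------------- LOW
def detect_low_states(
    power: SignalTrace,
    nrem: IntervalSet,
    cfg: Optional[DetectionConfig] = None,
) -> IntervalSet:
    """Broadband LFP power drops (LOW states) within NREM.

    The input is the already-computed band power series (0.1-s step sliding
    1-s windows by convention); the threshold is the valley between the two
    largest modes of the smoothed histogram of log10 power within NREM.  A
    unimodal histogram falls back to a low percentile with a warning.
    """
    cfg = cfg or DetectionConfig()
    if not power.covers(nrem):
        raise ValueError("power trace does not cover the NREM intervals")
    nrem_vals = power.values[power.sample_mask(nrem)]
    if nrem_vals.size == 0:
        return IntervalSet.empty("LOW")
    if np.any(nrem_vals <= 0):
        raise ValueError("band power values must be > 0 for log-histogram thresholding")
    logv = np.log10(nrem_vals)
    threshold_log: Optional[float] = None
    if cfg.low_threshold_mode == "histogram_valley":
        threshold_log = _histogram_valley(logv, cfg.valley_bins, cfg.valley_smooth_bins)
        if threshold_log is None:
            log.warning(
                "power histogram unimodal; falling back to %.3g-th percentile",
                cfg.low_fallback_percentile,
            )
    if threshold_log is None:
        threshold_log = float(np.percentile(logv, cfg.low_fallback_percentile))
    threshold = 10.0 ** threshold_log
    runs = _threshold_runs(power, nrem, power.values < threshold)
    return IntervalSet(runs, label="LOW")


# ----------------------------------------------------------- exclusion mask
def exclusion_mask(nrem: IntervalSet, *substates: IntervalSet) -> IntervalSet:
    """NREM minus the union of substates (each second subtracted once)."""
    if not substates:
        return nrem
    union = substates[0]
    for s in substates[1:]:
        union = union.union(s)
    return nrem.subtract(union.merge())
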