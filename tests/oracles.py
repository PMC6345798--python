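"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: membership is tested
point by point on a fine grid, spike counting loops over spikes, and the
shuffle null is enumerated exhaustively over all flip patterns.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Sequence, Tuple

import numpy as np


def grid_coverage(intervals: Sequence[Tuple[float, float]], t0: float, t1: float, dt: float = 1e-3) -> np.ndarray:
    """Boolean coverage of mid-grid points by a list of (start, end) pairs."""
    points = np.arange(t0, t1, dt) + dt / 2.0
    cov = np.zeros(points.size, dtype=bool)
    for s, e in intervals:
        cov |= (points >= s) & (points < e)
    return cov


def brute_force_count(spikes: np.ndarray, intervals: Sequence[Tuple[float, float]]) -> int:
    """Spike count inside a union of half-open intervals, by plain loop."""
    count = 0
    for t in spikes:
        for s, e in intervals:
            if s <= t < e:
                count += 1
                break
    return count


def rank_groups(rates: np.ndarray, n_groups: int) -> np.ndarray:
    """Group per cell via ceil(n_groups*rank/n), ties by original index."""
    n = rates.size
    order = sorted(range(n), key=lambda c: (rates[c], c))
    group = np.empty(n, dtype=int)
    for pos, c in enumerate(order):
        group[c] = math.ceil(n_groups * (pos + 1) / n)
    return group


def group_ci_of_means(a: np.ndarray, b: np.ndarray) -> float:
    keep = (a > 0) | (b > 0)
    if not keep.any():
        return float("nan")
    ma, mb = a[keep].mean(), b[keep].mean()
    return (ma - mb) / (ma + mb)


def exhaustive_flip_surrogates(
    fr_i: np.ndarray, fr_k: np.ndarray, n_groups: int
) -> Dict[str, np.ndarray]:
    """Group CIs under every one of the 2^n i/k flip patterns.

    With flip probability 1/2 per cell, all patterns are equally likely, so
    these values are the exact surrogate distribution.
    """
    n = fr_i.size
    out: Dict[str, List[float]] = {f"q{g}": [] for g in range(1, n_groups + 1)}
    for bits in itertools.product((False, True), repeat=n):
        flip = np.asarray(bits)
        a = np.where(flip, fr_k, fr_i)
        b = np.where(flip, fr_i, fr_k)
        groups = rank_groups(a, n_groups)
        for g in range(1, n_groups + 1):
            out[f"q{g}"].append(group_ci_of_means(a[groups == g], b[groups == g]))
    return {k: np.asarray(v) for k, v in out.items()}
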