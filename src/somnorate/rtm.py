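"""Change index, shuffle surrogates and the deflection index.

The change index (CI) of a cell group between two periods i and j is

    CI = (FR_i_bar - FR_j_bar) / (FR_i_bar + FR_j_bar)

where ``FR_x_bar`` is the mean over the group's cells of each cell's mean
rate in period x.  CI is bounded in [-1, 1] and scale-free, which keeps it
regular when rates approach zero (unlike a log-rate difference).

Grouping cells into rate quintiles *by their period-i rates* biases raw CI
through regression to the mean (RTM): cells selected as extreme in i drift
back toward the mean in j even with no true change.  The correction builds a
surrogate null from a *control* period k of the same state as i: each cell's
(FR_i, FR_k) pair is randomly flipped, quintiles are re-derived from the
post-flip period-i rates, and the group CI is computed between the flipped
pair — a within-state change running forward or backward in time, always
anchored at epoch i.  The deflection index (DI) is the observed CI minus the
surrogate mean; its 95% band and empirical p-value come from the same
surrogate distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .rates import QuintileAssignment, assign_quintiles

__all__ = [
    "CIResult",
    "SurrogateDistribution",
    "DIResult",
    "cell_change_index",
    "group_change_index",
    "change_index",
    "delta_log_fr",
    "shuffle_surrogates",
    "deflection_index",
    "report_tests",
    "TestResult",
]


# ----------------------------------------------------------------- change index
def cell_change_index(fr_i: np.ndarray, fr_j: np.ndarray) -> np.ndarray:
    """Per-cell CI; NaN where a cell is silent in both periods."""
    fr_i = np.asarray(fr_i, dtype=float)
    fr_j = np.asarray(fr_j, dtype=float)
    if fr_i.shape != fr_j.shape:
        raise ValueError("rate vectors must be aligned")
    if np.any(fr_i < 0) or np.any(fr_j < 0):
        raise ValueError("rates must be >= 0")
    denom = fr_i + fr_j
    out = np.full(fr_i.shape, np.nan)
    ok = denom > 0
    out[ok] = (fr_i[ok] - fr_j[ok]) / denom[ok]
    return out


def group_change_index(
    fr_i: np.ndarray, fr_j: np.ndarray, members: Optional[np.ndarray] = None
) -> float:
    """Group CI: CI of the group-mean rates, excluding both-silent cells."""
    fr_i = np.asarray(fr_i, dtype=float)
    fr_j = np.asarray(fr_j, dtype=float)
    if members is not None:
        fr_i, fr_j = fr_i[members], fr_j[members]
    keep = (fr_i > 0) | (fr_j > 0)
    if not np.any(keep):
        return np.nan
    mi = float(np.mean(fr_i[keep]))
    mj = float(np.mean(fr_j[keep]))
    return (mi - mj) / (mi + mj)


@dataclass
class CIResult:
    """Observed per-cell and per-group change indices for one comparison."""

    per_cell: np.ndarray  # CI per cell (NaN where both periods silent)
    groups: Dict[str, float]  # group label -> group CI
    n_excluded: int  # cells silent in both periods
    assignment: Optional[QuintileAssignment] = None


def change_index(
    fr_i: np.ndarray,
    fr_j: np.ndarray,
    *,
    principal: Optional[np.ndarray] = None,
    interneuron: Optional[np.ndarray] = None,
    unit_ids: Optional[Sequence[str]] = None,
    assignment: Optional[QuintileAssignment] = None,
    n_groups: int = 5,
) -> CIResult:
    """Per-cell CI plus quintile / interneuron group CIs.

    Quintiles are taken from ``assignment`` when given, otherwise derived
    from the principal cells' period-i rates (``epoch_i`` mode).
    """
    fr_i = np.asarray(fr_i, dtype=float)
    fr_j = np.asarray(fr_j, dtype=float)
    per_cell = cell_change_index(fr_i, fr_j)
    if np.all(np.isnan(per_cell)):
        raise ValueError("all cells silent in both periods; CI undefined")
    n = fr_i.size
    principal = np.ones(n, bool) if principal is None else np.asarray(principal, bool)
    interneuron = (
        ~principal if interneuron is None else np.asarray(interneuron, bool)
    ) & ~principal
    groups: Dict[str, float] = {}
    if assignment is None:
        ids = np.asarray(unit_ids) if unit_ids is not None else np.char.zfill(
            np.arange(int(principal.sum())).astype(str), 6
        )
        assignment = assign_quintiles(fr_i[principal], ids, mode="epoch_i", n_groups=n_groups)
    p_idx = np.flatnonzero(principal)
    for q in range(1, assignment.n_groups + 1):
        groups[f"q{q}"] = group_change_index(fr_i, fr_j, p_idx[assignment.members(q)])
    if np.any(interneuron):
        groups["interneuron"] = group_change_index(fr_i, fr_j, np.flatnonzero(interneuron))
    return CIResult(
        per_cell=per_cell,
        groups=groups,
        n_excluded=int(np.sum((fr_i == 0) & (fr_j == 0))),
        assignment=assignment,
    )


def delta_log_fr(fr_i: np.ndarray, fr_j: np.ndarray) -> Tuple[np.ndarray, int]:
    """log10(FR_j) - log10(FR_i) per cell; singular cells are excluded.

    Returns ``(dlog, n_excluded)`` where cells with a zero rate in either
    period carry NaN and are counted in ``n_excluded``.  Kept as an
    alternative metric; CI is preferred because it stays bounded near zero
    rates.
    """
    fr_i = np.asarray(fr_i, dtype=float)
    fr_j = np.asarray(fr_j, dtype=float)
    ok = (fr_i > 0) & (fr_j > 0)
    out = np.full(fr_i.shape, np.nan)
    out[ok] = np.log10(fr_j[ok]) - np.log10(fr_i[ok])
    return out, int(np.sum(~ok))


# -------------------------------------------------------------- shuffle engine
@dataclass
class SurrogateDistribution:
    """Per-group surrogate group-CI values from random i/k flips."""

    values: Dict[str, np.ndarray]  # group label -> (n_shuffles,) array
    n_shuffles: int
    seed: Optional[int] = None
    flip_scheme: str = "independent_half_per_cell"

    def mean(self, group: str) -> float:
        return float(np.nanmean(self.values[group]))

    def band(self, group: str, level: float = 95.0) -> Tuple[float, float]:
        lo = (100.0 - level) / 2.0
        v = self.values[group]
        return (float(np.nanpercentile(v, lo)), float(np.nanpercentile(v, 100.0 - lo)))


def _quintile_slices(n: int, n_groups: int) -> List[Tuple[int, int]]:
    """Rank ranges (0-based, half-open) covered by each group under ceil."""
    ranks = np.arange(1, n + 1)
    q = -(-(n_groups * ranks) // n)
    slices = []
    for g in range(1, n_groups + 1):
        idx = np.flatnonzero(q == g)
        slices.append((int(idx[0]), int(idx[-1]) + 1))
    return slices


def shuffle_surrogates(
    fr_i: np.ndarray,
    fr_k: np.ndarray,
    *,
    principal: Optional[np.ndarray] = None,
    interneuron: Optional[np.ndarray] = None,
    n_shuffles: int = 2000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    n_groups: int = 5,
    chunk_size: int = 512,
) -> SurrogateDistribution:
    """Surrogate group CIs from random flipping of FR_i and FR_k per cell.

    Each shuffle independently swaps, with probability 1/2 per cell, that
    cell's period-i and control-period rates; quintiles are re-derived from
    the post-flip period-i rates of the principal cells (so surrogate group
    membership varies with the flips, as in the observed epoch-i grouping);
    the group CI is then computed between the flipped pair.  Deterministic
    under ``seed`` (or a supplied generator).

    Cells are expected in ascending ``unit_id`` order so rank ties resolve
    the same way as in :func:`~somnorate.rates.assign_quintiles`.
    """
    fr_i = np.asarray(fr_i, dtype=float)
    fr_k = np.asarray(fr_k, dtype=float)
    if fr_i.shape != fr_k.shape:
        raise ValueError("fr_i and fr_k must be aligned")
    n = fr_i.size
    principal = np.ones(n, bool) if principal is None else np.asarray(principal, bool)
    interneuron = (
        ~principal if interneuron is None else np.asarray(interneuron, bool)
    ) & ~principal
    n_p = int(principal.sum())
    if n_p < n_groups:
        raise ValueError(f"need >= {n_groups} principal cells")
    if rng is None:
        rng = np.random.default_rng(seed)

    fi_p, fk_p = fr_i[principal], fr_k[principal]
    exc_p = (fi_p == 0) & (fk_p == 0)  # flip-invariant: silent in both
    slices = _quintile_slices(n_p, n_groups)
    labels = [f"q{g}" for g in range(1, n_groups + 1)]
    out = {lab: np.empty(n_shuffles) for lab in labels}
    has_inter = bool(np.any(interneuron))
    if has_inter:
        fi_n, fk_n = fr_i[interneuron], fr_k[interneuron]
        keep_n = (fi_n > 0) | (fk_n > 0)
        out["interneuron"] = np.empty(n_shuffles)

    done = 0
    while done < n_shuffles:
        m = min(chunk_size, n_shuffles - done)
        flips = rng.random((m, n)) < 0.5
        fp = flips[:, principal]
        a = np.where(fp, fk_p, fi_p)  # post-flip period-i rates
        b = np.where(fp, fi_p, fk_p)  # post-flip control rates
        order = np.argsort(a, axis=1, kind="stable")
        a_s = np.take_along_axis(a, order, axis=1)
        b_s = np.take_along_axis(b, order, axis=1)
        exc_s = np.take_along_axis(np.broadcast_to(exc_p, a.shape), order, axis=1)
        for lab, (lo, hi) in zip(labels, slices):
            cnt = (hi - lo) - exc_s[:, lo:hi].sum(axis=1)
            cnt = np.where(cnt > 0, cnt, np.nan)
            ma = a_s[:, lo:hi].sum(axis=1) / cnt  # silent-both cells add 0
            mb = b_s[:, lo:hi].sum(axis=1) / cnt
            denom = ma + mb
            with np.errstate(invalid="ignore", divide="ignore"):
                out[lab][done : done + m] = np.where(denom > 0, (ma - mb) / denom, np.nan)
        if has_inter:
            fn = flips[:, interneuron][:, keep_n]
            ai = np.where(fn, fk_n[keep_n], fi_n[keep_n])
            bi = np.where(fn, fi_n[keep_n], fk_n[keep_n])
            ma = ai.mean(axis=1)
            mb = bi.mean(axis=1)
            denom = ma + mb
            with np.errstate(invalid="ignore", divide="ignore"):
                out["interneuron"][done : done + m] = np.where(
                    denom > 0, (ma - mb) / denom, np.nan
                )
        done += m
    return SurrogateDistribution(values=out, n_shuffles=n_shuffles, seed=seed)


# --------------------------------------------------------------- deflection
@dataclass
class GroupDI:
    observed_ci: float
    surrogate_mean: float
    di: float
    band_lo: float
    band_hi: float
    p_empirical: float
    n_shuffles: int


@dataclass
class DIResult:
    """Per-group deflection indices with surrogate bands and p-values."""

    groups: Dict[str, GroupDI] = field(default_factory=dict)

    def di(self, group: str) -> float:
        return self.groups[group].di

    def quintile_dis(self, n_groups: int = 5) -> np.ndarray:
        return np.array([self.groups[f"q{g}"].di for g in range(1, n_groups + 1)])


def deflection_index(
    ci: "CIResult | Dict[str, float]",
    surrogates: SurrogateDistribution,
    band_level: float = 95.0,
) -> DIResult:
    """DI = observed group CI minus the surrogate mean, with its band.

    The empirical two-tailed p uses +1 smoothing:
    ``p = (1 + #{|s - mean| >= |observed - mean|}) / (n + 1)``.
    """
    observed = ci.groups if isinstance(ci, CIResult) else ci
    out = DIResult()
    for group, obs in observed.items():
        if group not in surrogates.values:
            continue
        vals = surrogates.values[group]
        vals = vals[np.isfinite(vals)]
        mean = float(np.mean(vals))
        lo, hi = surrogates.band(group, band_level)
        n = vals.size
        p = (1.0 + float(np.sum(np.abs(vals - mean) >= abs(obs - mean)))) / (n + 1.0)
        out.groups[group] = GroupDI(
            observed_ci=float(obs),
            surrogate_mean=mean,
            di=float(obs) - mean,
            band_lo=lo,
            band_hi=hi,
            p_empirical=p,
            n_shuffles=surrogates.n_shuffles,
        )
    return out


# ------------------------------------------------------------ standard tests
@dataclass
class TestResult:
    design: str
    statistic: float
    p_value: float
    n: int
    flagged: bool = False
    note: str = ""


def report_tests(design: str, *samples: np.ndarray) -> TestResult:
    """Standard-test wrappers used for reporting.

    Designs: ``paired_signed_rank`` (one vector of per-sequence differences,
    Wilcoxon signed-rank), ``ks_2sample`` (two pooled rate samples,
    Kolmogorov-Smirnov), ``anova`` (one-way ANOVA across groups, e.g. the
    five quintiles).
    """
    if design == "paired_signed_rank":
        (values,) = samples
        values = np.asarray(values, float)
        values = values[np.isfinite(values)]
        n = values.size
        if n < 5:
            return TestResult(design, np.nan, np.nan, n, flagged=True, note="n below test minimum")
        if np.all(values == 0):
            return TestResult(design, 0.0, 1.0, n, note="all differences zero")
        stat, p = stats.wilcoxon(values)
        return TestResult(design, float(stat), float(p), n)
    if design == "ks_2sample":
        a, b = (np.asarray(s, float) for s in samples)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if a.size < 2 or b.size < 2:
            return TestResult(design, np.nan, np.nan, a.size + b.size, flagged=True,
                              note="n below test minimum")
        res = stats.ks_2samp(a, b)
        return TestResult(design, float(res.statistic), float(res.pvalue), a.size + b.size)
    if design == "anova":
        groups = [np.asarray(s, float) for s in samples]
        groups = [g[np.isfinite(g)] for g in groups]
        if any(g.size < 2 for g in groups) or len(groups) < 2:
            return TestResult(design, np.nan, np.nan, sum(g.size for g in groups),
                              flagged=True, note="n below test minimum")
        stat, p = stats.f_oneway(*groups)
        return TestResult(design, float(stat), float(p), sum(g.size for g in groups))
    raise ValueError(f"unknown test design {design!r}")
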