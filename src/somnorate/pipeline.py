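"""End-to-end analysis orchestration.

:func:`run_transition_analysis` drives the full chain for each requested
sequence kind: duration-filter the hypnogram, extract sequences, pick
control periods, compute per-sequence rates (optionally on NREM exclusive of
detected substates), apply the 20% non-firing rule, derive epoch-i
quintiles, and pool observed and surrogate group change indices across
sequences into deflection indices with bands and empirical p-values — plus
the per-sequence CV change (paired signed-rank) and the pooled
rate-distribution comparison (Kolmogorov-Smirnov).

Pooling convention: the observed group statistic is the mean across included
sequences of the per-sequence group CI; the surrogate distribution of that
pooled mean is the elementwise mean of the per-sequence surrogate vectors
(independent flips per sequence), so bands and p-values refer to the pooled
statistic.  Everything is deterministic given the config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import Hypnogram, SignalTrace, SpikeTable
from .intervals import IntervalSet
from .rates import assign_quintiles, period_rates, population_cv
from .rtm import (
    DIResult,
    SurrogateDistribution,
    TestResult,
    change_index,
    deflection_index,
    report_tests,
    shuffle_surrogates,
)
from .sequences import (
    StateSequence,
    extract_sequences,
    filter_epochs,
    nonfiring_exclusion,
    select_control_period,
    select_wake_control,
)
from .substates import DetectionConfig, detect_low_states, detect_microarousals, detect_off_states

__all__ = [
    "AnalysisConfig",
    "KindReport",
    "AnalysisReport",
    "run_transition_analysis",
    "run_exclusion_variants",
]


@dataclass
class AnalysisConfig:
    """Settings for one end-to-end analysis run."""

    kinds: Tuple[str, ...] = ("NREM_REM", "REM_NREM")
    n_shuffles: int = 2000
    seed: int = 0
    min_nrem_s: float = 150.0
    min_rem_s: float = 100.0
    nonfiring_threshold: float = 0.20
    exclusions: Tuple[str, ...] = ()  # subset of {"OFF", "MA", "LOW"}
    max_gap_s: float = np.inf
    max_wake_interruption_s: float = 60.0
    require_same_bout: bool = True
    n_quintiles: int = 5
    detection: DetectionConfig = field(default_factory=DetectionConfig)

    def __post_init__(self) -> None:
        unknown = set(self.exclusions) - {"OFF", "MA", "LOW"}
        if unknown:
            raise ValueError(f"unknown exclusion set(s) {sorted(unknown)}")


@dataclass
class KindReport:
    """All statistics for one sequence kind."""

    kind: str
    n_sequences: int
    n_included: int
    exclusion_counts: Dict[str, int]
    di: Optional[DIResult]
    per_sequence_ci: pd.DataFrame  # sequence idx x group
    delta_cv: np.ndarray  # per included sequence, CV_j - CV_i
    delta_cv_test: Optional[TestResult]
    ks_pooled_rates: Optional[TestResult]
    cell_epochs: int  # included principal cell-epochs

    def di_table(self) -> pd.DataFrame:
        if self.di is None:
            return pd.DataFrame()
        rows = []
        for group, g in self.di.groups.items():
            rows.append(
                {
                    "kind": self.kind,
                    "group": group,
                    "observed_ci": g.observed_ci,
                    "surrogate_mean": g.surrogate_mean,
                    "di": g.di,
                    "band_lo": g.band_lo,
                    "band_hi": g.band_hi,
                    "p_empirical": g.p_empirical,
                    "n_sequences": self.n_included,
                    "n_shuffles": g.n_shuffles,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class AnalysisReport:
    config: AnalysisConfig
    kinds: Dict[str, KindReport]
    mask: Optional[IntervalSet]
    substates: Dict[str, IntervalSet]
    manifest: Dict[str, object]

    def di_table(self) -> pd.DataFrame:
        frames = [k.di_table() for k in self.kinds.values() if k.di is not None]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def _build_mask(
    cfg: AnalysisConfig,
    spikes: SpikeTable,
    hypnogram: Hypnogram,
    emg: Optional[SignalTrace],
    power: Optional[SignalTrace],
    substates: Optional[Dict[str, IntervalSet]],
) -> Tuple[Optional[IntervalSet], Dict[str, IntervalSet]]:
    """Union of the requested substate sets (detected unless supplied)."""
    found: Dict[str, IntervalSet] = dict(substates or {})
    nrem = hypnogram.get("NREM")
    for name in cfg.exclusions:
        if name in found:
            continue
        if name == "OFF":
            found["OFF"] = detect_off_states(spikes, nrem, cfg.detection)
        elif name == "MA":
            if emg is None:
                raise ValueError("MA exclusion requires an EMG trace")
            found["MA"] = detect_microarousals(emg, nrem, cfg.detection)
        elif name == "LOW":
            if power is None:
                raise ValueError("LOW exclusion requires a band-power trace")
            found["LOW"] = detect_low_states(power, nrem, cfg.detection)
    if not cfg.exclusions:
        return None, found
    mask: Optional[IntervalSet] = None
    for name in cfg.exclusions:
        mask = found[name] if mask is None else mask.union(found[name])
    return (mask.merge() if mask is not None else None), found


def _sequence_rates(
    spikes: SpikeTable,
    seq: StateSequence,
    mask: Optional[IntervalSet],
) -> Dict[str, np.ndarray]:
    out = {}
    for key, period in (("i", seq.period_i), ("j", seq.period_j), ("k", seq.period_k)):
        if period is None:
            out[key] = None
            continue
        rates, dur = period_rates(spikes, period.as_interval_set(), mask=mask)
        out[key] = rates if dur > 0 else None
    return out


def run_transition_analysis(
    spikes: SpikeTable,
    hypnogram: Hypnogram,
    cfg: AnalysisConfig,
    emg: Optional[SignalTrace] = None,
    power: Optional[SignalTrace] = None,
    substates: Optional[Dict[str, IntervalSet]] = None,
) -> AnalysisReport:
    """Run the pooled CI/DI, CV and distribution analyses for each kind."""
    spikes = spikes.sorted_by_unit_id()
    principal = spikes.principal_mask
    interneuron = spikes.interneuron_mask
    ids = np.asarray(spikes.unit_ids)
    epochs = filter_epochs(hypnogram, cfg.min_nrem_s, cfg.min_rem_s)
    mask, found = _build_mask(cfg, spikes, hypnogram, emg, power, substates)
    root_ss = np.random.SeedSequence(cfg.seed)
    kind_reports: Dict[str, KindReport] = {}
    for kind_idx, kind in enumerate(cfg.kinds):
        seqs = extract_sequences(
            epochs, kind, max_gap_s=cfg.max_gap_s,
            max_wake_interruption_s=cfg.max_wake_interruption_s,
        )
        kind_ss = np.random.SeedSequence([cfg.seed, kind_idx])
        seq_seeds = kind_ss.generate_state(max(2 * len(seqs), 1)) % (2**31)
        excl_counts: Dict[str, int] = {}
        obs_rows: List[Dict[str, float]] = []
        surr_sum: Dict[str, np.ndarray] = {}
        delta_cv: List[float] = []
        pooled_i: List[np.ndarray] = []
        pooled_j: List[np.ndarray] = []
        cell_epochs = 0
        n_included = 0
        for s_idx, seq in enumerate(seqs):
            # control period
            if seq.period_i.state == "WAKE":
                wake_epoch = next(
                    e for e in epochs if e.index_in_session == seq.period_i.epoch_index
                )
                ctrl_rng = np.random.default_rng(int(seq_seeds[2 * s_idx]))
                seq.period_k = select_wake_control(wake_epoch, seq.period_i, ctrl_rng)
                if seq.period_k is None:
                    seq.exclude("wake_epoch_too_short")
            else:
                select_control_period(
                    seq, epochs,
                    require_same_bout=cfg.require_same_bout,
                    max_wake_interruption_s=cfg.max_wake_interruption_s,
                )
            if seq.excluded:
                excl_counts[seq.exclusion_reason or "?"] = (
                    excl_counts.get(seq.exclusion_reason or "?", 0) + 1
                )
                continue
            r = _sequence_rates(spikes, seq, mask)
            if r["i"] is None or r["j"] is None or r["k"] is None:
                seq.exclude("period_fully_masked")
                excl_counts["period_fully_masked"] = excl_counts.get("period_fully_masked", 0) + 1
                continue
            if nonfiring_exclusion(r["i"][principal], r["j"][principal], cfg.nonfiring_threshold):
                seq.exclude("nonfiring_fraction")
                excl_counts["nonfiring_fraction"] = excl_counts.get("nonfiring_fraction", 0) + 1
                continue
            assignment = assign_quintiles(
                r["i"][principal], ids[principal], mode="epoch_i", n_groups=cfg.n_quintiles
            )
            obs = change_index(
                r["i"], r["j"],
                principal=principal, interneuron=interneuron,
                assignment=assignment, n_groups=cfg.n_quintiles,
            )
            surr = shuffle_surrogates(
                r["i"], r["k"],
                principal=principal, interneuron=interneuron,
                n_shuffles=cfg.n_shuffles,
                seed=int(seq_seeds[2 * s_idx + 1]),
                n_groups=cfg.n_quintiles,
            )
            obs_rows.append(dict(obs.groups))
            for group, vals in surr.values.items():
                surr_sum[group] = surr_sum.get(group, 0.0) + vals
            cv_i = population_cv(r["i"][principal])
            cv_j = population_cv(r["j"][principal])
            delta_cv.append(cv_j.cv - cv_i.cv)
            pooled_i.append(r["i"][principal])
            pooled_j.append(r["j"][principal])
            cell_epochs += 2 * int(principal.sum())
            n_included += 1
        if n_included:
            per_seq = pd.DataFrame(obs_rows)
            pooled_obs = {g: float(np.nanmean(per_seq[g])) for g in per_seq.columns}
            pooled_surr = SurrogateDistribution(
                values={g: v / n_included for g, v in surr_sum.items()},
                n_shuffles=cfg.n_shuffles,
                seed=cfg.seed,
            )
            di = deflection_index(pooled_obs, pooled_surr)
            dcv = np.asarray(delta_cv)
            dcv_test = report_tests("paired_signed_rank", dcv)
            ks = report_tests("ks_2sample", np.concatenate(pooled_i), np.concatenate(pooled_j))
        else:
            per_seq = pd.DataFrame()
            di, dcv, dcv_test, ks = None, np.empty(0), None, None
        kind_reports[kind] = KindReport(
            kind=kind,
            n_sequences=len(seqs),
            n_included=n_included,
            exclusion_counts=excl_counts,
            di=di,
            per_sequence_ci=per_seq,
            delta_cv=dcv,
            delta_cv_test=dcv_test,
            ks_pooled_rates=ks,
            cell_epochs=cell_epochs,
        )
    import somnorate

    manifest = {
        "seed": cfg.seed,
        "n_shuffles": cfg.n_shuffles,
        "kinds": list(cfg.kinds),
        "exclusions": list(cfg.exclusions),
        "somnorate_version": somnorate.__version__,
        "numpy_version": np.__version__,
    }
    return AnalysisReport(
        config=cfg, kinds=kind_reports, mask=mask, substates=found, manifest=manifest
    )


def run_exclusion_variants(
    spikes: SpikeTable,
    hypnogram: Hypnogram,
    cfg: AnalysisConfig,
    emg: Optional[SignalTrace] = None,
    power: Optional[SignalTrace] = None,
    variants: Sequence[Tuple[str, Tuple[str, ...]]] = (
        ("intact", ()),
        ("no_off", ("OFF",)),
    ),
    substates: Optional[Dict[str, IntervalSet]] = None,
) -> Dict[str, AnalysisReport]:
    """Repeat the analysis under each substate-exclusion condition.

    Also asserts the structural fact that excluding OFF (population-silence)
    time can never lower a unit's NREM rate: removing only silent time
    shrinks the denominator without removing spikes.
    """
    out: Dict[str, AnalysisReport] = {}
    for name, exclusions in variants:
        variant_cfg = AnalysisConfig(
            kinds=cfg.kinds,
            n_shuffles=cfg.n_shuffles,
            seed=cfg.seed,
            min_nrem_s=cfg.min_nrem_s,
            min_rem_s=cfg.min_rem_s,
            nonfiring_threshold=cfg.nonfiring_threshold,
            exclusions=tuple(exclusions),
            max_gap_s=cfg.max_gap_s,
            max_wake_interruption_s=cfg.max_wake_interruption_s,
            require_same_bout=cfg.require_same_bout,
            n_quintiles=cfg.n_quintiles,
            detection=cfg.detection,
        )
        out[name] = run_transition_analysis(
            spikes, hypnogram, variant_cfg, emg=emg, power=power, substates=substates
        )
    # structural check: OFF exclusion never decreases a unit's NREM rate
    off_variants = [r for r in out.values() if r.config.exclusions == ("OFF",)]
    if off_variants:
        nrem = hypnogram.get("NREM")
        off = off_variants[0].substates.get("OFF")
        if off is not None and not nrem.is_empty:
            intact, _ = period_rates(spikes, nrem)
            excluded, _ = period_rates(spikes, nrem.subtract(off))
            if np.any(excluded + 1e-12 < intact):
                raise AssertionError("OFF exclusion lowered an NREM rate (invariant violated)")
    return out


# small convenience used by the CLI
def nrem_rates_with_without_off(
    spikes: SpikeTable, hypnogram: Hypnogram, cfg: Optional[DetectionConfig] = None
) -> pd.DataFrame:
    nrem = hypnogram.get("NREM")
    off = detect_off_states(spikes, nrem, cfg)
    intact, _ = period_rates(spikes, nrem)
    excluded, _ = period_rates(spikes, nrem.subtract(off))
    return pd.DataFrame(
        {"unit_id": spikes.unit_ids, "nrem_rate_hz": intact, "nrem_rate_no_off_hz": excluded}
    )
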