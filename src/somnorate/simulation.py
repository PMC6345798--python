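"""Synthetic populations and sessions for exercising the pipeline.

Two generators live here:

* :func:`simulate_population` — the three-epoch rate-table simulator used to
  study the change/deflection indices: 5000 cells with log-normal baseline
  rates (linear mean 0.59 Hz, SD 0.84 Hz, the hippocampal-NREM preset),
  multiplicative noise per epoch (SD proportional to each cell's rate:
  relative SD 0.35, so a 1-Hz cell has absolute noise SD 0.35 Hz), and an
  optional additive (+0.05 Hz) or multiplicative (x1.1) rate change
  confined to epoch j.
* :func:`simulate_session` — a full synthetic recording: hypnogram with
  realistic epoch durations (no WAKE->REM transitions), inhomogeneous-
  Poisson spike trains whose intensity is baseline x state-modulation x
  substate gating, planted OFF/MA/LOW substates, and matching EMG and LFP
  band-power traces.  A ground-truth ledger records everything planted so
  detector and pipeline recovery can be asserted exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .data import CellClass, Hypnogram, SignalTrace, SpikeTable, UnitRecord
from .intervals import IntervalSet
from .rates import assign_quintiles
from .rtm import (
    CIResult,
    DIResult,
    SurrogateDistribution,
    change_index,
    deflection_index,
    shuffle_surrogates,
)

__all__ = [
    "SimulationConfig",
    "PopulationRates",
    "lognormal_params_from_moments",
    "draw_baseline_rates",
    "simulate_population",
    "ScenarioResult",
    "run_population_scenario",
    "run_population_scenarios",
    "SessionSpec",
    "SyntheticSession",
    "simulate_session",
]


# ------------------------------------------------------------- log-normal fit
def lognormal_params_from_moments(mean_hz: float, sd_hz: float) -> Tuple[float, float]:
    """(mu, sigma) of the underlying normal from linear-scale mean and SD.

    ``sigma^2 = ln(1 + sd^2/mean^2)``, ``mu = ln(mean) - sigma^2/2``; the
    log-normal with these parameters has exactly the requested linear
    moments.  ``sd = 0`` degenerates to a point mass at ``mean``.
    """
    if mean_hz <= 0:
        raise ValueError("mean_hz must be > 0")
    if sd_hz < 0:
        raise ValueError("sd_hz must be >= 0")
    sigma2 = math.log1p((sd_hz / mean_hz) ** 2)
    mu = math.log(mean_hz) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


# --------------------------------------------------------- population simulator
@dataclass
class SimulationConfig:
    """Three-epoch population simulator settings (hippocampal-NREM preset)."""

    n_cells: int = 5000
    baseline_mean_hz: float = 0.59
    baseline_sd_hz: float = 0.84
    noise_relative_sd: float = 0.35  # noise SD per unit rate (1 Hz cell -> 0.35 Hz)
    change: str = "none"  # "none" | "additive" | "multiplicative"
    additive_delta_hz: float = 0.05
    multiplicative_factor: float = 1.1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_cells < 5:
            raise ValueError("n_cells must be >= 5")
        if self.baseline_mean_hz <= 0 or self.baseline_sd_hz <= 0:
            raise ValueError("baseline moments must be > 0")
        if self.multiplicative_factor <= 0:
            raise ValueError("multiplicative_factor must be > 0")
        if self.noise_relative_sd < 0:
            raise ValueError("noise_relative_sd must be >= 0")
        if self.change not in ("none", "additive", "multiplicative"):
            raise ValueError(f"unknown change scenario {self.change!r}")


def draw_baseline_rates(cfg: SimulationConfig, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Log-normal baseline rates with the configured linear moments."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    mu, sigma = lognormal_params_from_moments(cfg.baseline_mean_hz, cfg.baseline_sd_hz)
    return rng.lognormal(mean=mu, sigma=sigma, size=cfg.n_cells)


@dataclass
class PopulationRates:
    """Simulated per-cell rates in epochs i, j and control epoch k."""

    baseline_hz: np.ndarray
    fr_i: np.ndarray
    fr_j: np.ndarray
    fr_k: np.ndarray
    truncated_fraction: float  # rate values clipped at 0


def simulate_population(cfg: SimulationConfig) -> PopulationRates:
    """Draw the three-epoch rate table for one scenario.

    Per cell: baseline ``b ~ LogNormal``; per epoch ``FR = max(0, b_e*(1+eps))``
    with ``eps ~ N(0, noise_relative_sd)``, so the absolute noise SD is
    proportional to the cell's rate.  Epoch j carries the planted change
    (``b + delta`` or ``b * factor``); epochs i and k stay at baseline (k is
    a control period of the same state as i).  Negative noisy rates truncate
    at 0; the clipped fraction is reported (about 0.2% at the default noise).
    """
    rng = np.random.default_rng(cfg.seed)
    b = draw_baseline_rates(cfg, rng)
    b_by_epoch = {"i": b, "j": b.copy(), "k": b}
    if cfg.change == "additive":
        b_by_epoch["j"] = b + cfg.additive_delta_hz
    elif cfg.change == "multiplicative":
        b_by_epoch["j"] = b * cfg.multiplicative_factor
    rel = cfg.noise_relative_sd
    raw = {e: bb * (1.0 + rng.normal(0.0, rel, size=cfg.n_cells)) for e, bb in b_by_epoch.items()}
    n_neg = sum(int(np.sum(v < 0)) for v in raw.values())
    fr = {e: np.maximum(v, 0.0) for e, v in raw.items()}
    return PopulationRates(
        baseline_hz=b,
        fr_i=fr["i"],
        fr_j=fr["j"],
        fr_k=fr["k"],
        truncated_fraction=n_neg / (3.0 * cfg.n_cells),
    )


@dataclass
class ScenarioResult:
    config: SimulationConfig
    rates: PopulationRates
    observed: CIResult
    surrogates: "SurrogateDistribution"
    di: DIResult


def run_population_scenario(
    cfg: SimulationConfig,
    n_shuffles: int = 2000,
    shuffle_seed: Optional[int] = None,
) -> ScenarioResult:
    """Simulate one scenario and run the full CI -> surrogate -> DI chain.

    Quintiles are derived from the epoch-i rates (the grouping that exposes
    RTM), the observed quintile CI compares epochs i and j, and the
    surrogates flip i against the control epoch k.
    """
    rates = simulate_population(cfg)
    ids = np.char.zfill(np.arange(cfg.n_cells).astype(str), 6)
    assignment = assign_quintiles(rates.fr_i, ids, mode="epoch_i")
    observed = change_index(rates.fr_i, rates.fr_j, assignment=assignment, unit_ids=ids)
    surr = shuffle_surrogates(
        rates.fr_i,
        rates.fr_k,
        n_shuffles=n_shuffles,
        seed=shuffle_seed if shuffle_seed is not None else cfg.seed,
    )
    return ScenarioResult(
        config=cfg,
        rates=rates,
        observed=observed,
        surrogates=surr,
        di=deflection_index(observed, surr),
    )


def run_population_scenarios(
    seed: Optional[int] = None,
    n_shuffles: int = 2000,
    base_config: Optional[SimulationConfig] = None,
) -> Dict[str, ScenarioResult]:
    """Run the no-change, additive and multiplicative scenarios."""
    base = base_config or SimulationConfig()
    out = {}
    for idx, change in enumerate(("none", "additive", "multiplicative")):
        cfg_seed = None if seed is None else int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))
        cfg = SimulationConfig(
            n_cells=base.n_cells,
            baseline_mean_hz=base.baseline_mean_hz,
            baseline_sd_hz=base.baseline_sd_hz,
            noise_relative_sd=base.noise_relative_sd,
            change=change,
            additive_delta_hz=base.additive_delta_hz,
            multiplicative_factor=base.multiplicative_factor,
            seed=cfg_seed,
        )
        out[change] = run_population_scenario(cfg, n_shuffles=n_shuffles)
    return out


# ----------------------------------------------------------- session generator
@dataclass
class SessionSpec:
    """Design of a full synthetic session (the planted-effect test harness).

    State-duration means/CVs and the quintile modulation tables are artifact
    conventions chosen to mimic the qualitative structure of rodent sleep
    recordings (REM widens the rate distribution, NREM narrows it,
    interneurons gain in REM); they are separate from the population
    simulator's preset moments, which stay on the principal-cell baselines.
    """

    n_principal: int = 100
    n_interneurons: int = 10
    principal_rate_mean_hz: float = 0.59
    principal_rate_sd_hz: float = 0.84
    interneuron_rate_mean_hz: float = 8.0
    interneuron_rate_sd_hz: float = 4.0
    # hypnogram structure
    n_bouts: int = 2
    n_cycles_per_bout: int = 4  # NREM-REM alternations per sleep bout
    nrem_duration_mean_s: float = 600.0
    rem_duration_mean_s: float = 180.0
    wake_duration_mean_s: float = 900.0
    duration_cv: float = 0.4
    nrem_min_s: float = 60.0
    rem_min_s: float = 40.0
    wake_min_s: float = 90.0
    # state modulation (per quintile of baseline rate, principal cells)
    nrem_quintile_gain: Tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    rem_quintile_gain: Tuple[float, ...] = (0.6, 0.8, 0.9, 1.0, 1.1)
    wake_quintile_gain: Tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    interneuron_state_gain: Dict[str, float] = field(
        default_factory=lambda: {"WAKE": 1.0, "NREM": 0.8, "REM": 1.3}
    )
    # planted substates (per NREM epoch), all inside NREM with margins
    off_rate_per_min: float = 2.0
    off_duration_range_s: Tuple[float, float] = (0.08, 0.2)
    ma_rate_per_min: float = 0.2
    ma_duration_range_s: Tuple[float, float] = (1.0, 10.0)
    ma_rate_gain: float = 0.5
    low_rate_per_min: float = 0.2
    low_duration_range_s: Tuple[float, float] = (5.0, 20.0)
    low_rate_gain: float = 0.5
    # auxiliary traces
    trace_step_s: float = 0.1
    emg_baseline: float = 1.0
    emg_noise_sd: float = 0.05
    emg_ma_level: float = 5.0
    log10_power_baseline: float = 0.0
    log10_power_noise_sd: float = 0.05
    log10_power_low_level: float = -1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        gains = (
            list(self.nrem_quintile_gain)
            + list(self.rem_quintile_gain)
            + list(self.wake_quintile_gain)
            + list(self.interneuron_state_gain.values())
            + [self.ma_rate_gain, self.low_rate_gain]
        )
        if any(g < 0 for g in gains):
            raise ValueError("modulation gains must be >= 0 (negative intensity is infeasible)")
        if self.n_principal < 5:
            raise ValueError("need >= 5 principal cells for quintiles")


@dataclass
class SyntheticSession:
    """A generated session plus the ground truth that produced it."""

    spikes: SpikeTable
    hypnogram: Hypnogram
    emg: SignalTrace
    band_power: SignalTrace
    ground_truth: Dict[str, object]


def _lognormal_duration(rng: np.random.Generator, mean_s: float, cv: float, min_s: float) -> float:
    mu, sigma = lognormal_params_from_moments(mean_s, cv * mean_s)
    return max(float(rng.lognormal(mu, sigma)), min_s)


def _plant_intervals(
    rng: np.random.Generator,
    epoch: Tuple[float, float],
    rate_per_min: float,
    dur_range: Tuple[float, float],
    occupied: List[Tuple[float, float]],
    margin_s: float = 1.0,
    snap_s: Optional[float] = None,
    max_tries: int = 50,
) -> List[Tuple[float, float]]:
    """Place disjoint intervals inside an epoch, avoiding already-used time."""
    s, e = epoch
    count = rng.poisson(rate_per_min * (e - s) / 60.0)
    placed: List[Tuple[float, float]] = []
    for _ in range(count):
        for _try in range(max_tries):
            dur = rng.uniform(*dur_range)
            if snap_s is not None:
                dur = max(round(dur / snap_s), 1) * snap_s
            lo, hi = s + margin_s, e - margin_s - dur
            if hi <= lo:
                break
            start = rng.uniform(lo, hi)
            if snap_s is not None:
                # snap to exact grid multiples so trace samples align bit-exactly
                n0 = round(start / snap_s)
                n1 = n0 + round(dur / snap_s)
                start, end = n0 * snap_s, n1 * snap_s
                if start < lo or end > e - margin_s:
                    continue
                cand = (start, end)
            else:
                cand = (start, start + dur)
            busy = occupied + placed

            if all(cand[1] + margin_s <= a or cand[0] - margin_s >= b for a, b in busy):
                placed.append(cand)
                break
    placed.sort()
    return placed


def simulate_session(spec: SessionSpec) -> SyntheticSession:
    """Generate a full synthetic session with planted, ledgered effects.

    The hypnogram alternates WAKE and sleep bouts of NREM-REM cycles (never
    WAKE->REM).  Spikes are piecewise-homogeneous Poisson: intensity is the
    cell baseline times its state gain, thinned inside planted MA/LOW
    substates and zeroed inside planted OFF states; each OFF interval is
    flanked by population spikes exactly at its bounds, mimicking the edge
    synchrony of DOWN states and making the planted bounds recoverable.  The
    EMG trace is elevated inside MAs and the band-power trace lowered inside
    LOWs; both are sampled on a regular ``trace_step_s`` grid.
    """
    rng = np.random.default_rng(spec.seed)

    # ---- hypnogram -------------------------------------------------------
    labeled: List[Tuple[str, float, float]] = []
    t = 0.0

    def add(state: str, dur: float) -> None:
        nonlocal t
        labeled.append((state, t, t + dur))
        t += dur

    add("WAKE", _lognormal_duration(rng, spec.wake_duration_mean_s, spec.duration_cv, spec.wake_min_s))
    for _bout in range(spec.n_bouts):
        for _cyc in range(spec.n_cycles_per_bout):
            add("NREM", _lognormal_duration(rng, spec.nrem_duration_mean_s, spec.duration_cv, spec.nrem_min_s))
            add("REM", _lognormal_duration(rng, spec.rem_duration_mean_s, spec.duration_cv, spec.rem_min_s))
        add("WAKE", _lognormal_duration(rng, spec.wake_duration_mean_s, spec.duration_cv, spec.wake_min_s))
    session_end = t
    states: Dict[str, List[Tuple[float, float]]] = {"WAKE": [], "NREM": [], "REM": []}
    for state, s, e in labeled:
        states[state].append((s, e))
    hypnogram = Hypnogram(
        {k: IntervalSet(v, label=k) for k, v in states.items() if v},
        session_start_s=0.0,
        session_end_s=session_end,
    )

    # ---- baselines and ground-truth quintiles ---------------------------
    mu_p, sig_p = lognormal_params_from_moments(spec.principal_rate_mean_hz, spec.principal_rate_sd_hz)
    mu_n, sig_n = lognormal_params_from_moments(spec.interneuron_rate_mean_hz, spec.interneuron_rate_sd_hz)
    base_p = rng.lognormal(mu_p, sig_p, size=spec.n_principal)
    base_n = rng.lognormal(mu_n, sig_n, size=spec.n_interneurons)
    p_ids = np.array([f"p{idx:04d}" for idx in range(spec.n_principal)])
    n_ids = np.array([f"i{idx:04d}" for idx in range(spec.n_interneurons)])
    truth_assign = assign_quintiles(base_p, p_ids, mode="whole_window")
    gains = {
        "NREM": np.asarray(spec.nrem_quintile_gain, float),
        "REM": np.asarray(spec.rem_quintile_gain, float),
        "WAKE": np.asarray(spec.wake_quintile_gain, float),
    }

    # ---- planted substates ----------------------------------------------
    snap = spec.trace_step_s
    off_list: List[Tuple[float, float]] = []
    ma_list: List[Tuple[float, float]] = []
    low_list: List[Tuple[float, float]] = []
    for s, e in states["NREM"]:
        occupied: List[Tuple[float, float]] = []
        ma = _plant_intervals(rng, (s, e), spec.ma_rate_per_min, spec.ma_duration_range_s,
                              occupied, snap_s=snap)
        occupied += ma
        low = _plant_intervals(rng, (s, e), spec.low_rate_per_min, spec.low_duration_range_s,
                               occupied, snap_s=snap)
        occupied += low
        off = _plant_intervals(rng, (s, e), spec.off_rate_per_min, spec.off_duration_range_s,
                               occupied, margin_s=0.5)
        ma_list += ma
        low_list += low
        off_list += off
    off_set = IntervalSet(off_list, label="OFF")
    ma_set = IntervalSet(ma_list, label="MA")
    low_set = IntervalSet(low_list, label="LOW")

    # ---- spikes ----------------------------------------------------------
    def cell_gain(state: str, is_principal: bool, quintile: int) -> float:
        if is_principal:
            return float(gains[state][quintile - 1])
        return float(spec.interneuron_state_gain.get(state, 1.0))

    units: List[UnitRecord] = []
    all_base = np.concatenate([base_p, base_n])
    all_ids = np.concatenate([p_ids, n_ids])
    is_principal = np.concatenate(
        [np.ones(spec.n_principal, bool), np.zeros(spec.n_interneurons, bool)]
    )
    quintile_of = np.concatenate(
        [truth_assign.quintile, np.zeros(spec.n_interneurons, int)]
    )
    spike_lists: List[List[np.ndarray]] = [[] for _ in range(all_base.size)]
    for state, s, e in labeled:
        dur = e - s
        for c in range(all_base.size):
            lam = all_base[c] * cell_gain(state, bool(is_principal[c]), int(quintile_of[c]))
            n_sp = rng.poisson(lam * dur)
            if n_sp:
                spike_lists[c].append(s + dur * rng.random(n_sp))
    # substate gating: thin in MA/LOW, silence in OFF
    for c in range(all_base.size):
        if not spike_lists[c]:
            continue
        times = np.sort(np.concatenate(spike_lists[c]))
        keep = np.ones(times.size, bool)
        for subset, gain in ((ma_set, spec.ma_rate_gain), (low_set, spec.low_rate_gain)):
            if gain < 1.0 and not subset.is_empty:
                inside = subset.contains(times)
                keep &= ~inside | (rng.random(times.size) < gain)
        if not off_set.is_empty:
            keep &= ~off_set.contains(times)
        spike_lists[c] = [times[keep]]
    # population spikes exactly at planted OFF bounds (edge synchrony)
    for s, e in off_set:
        for edge in (s, e):
            c = int(rng.integers(0, spec.n_principal))
            spike_lists[c].append(np.array([edge]))
    for c in range(all_base.size):
        times = np.sort(np.concatenate(spike_lists[c])) if spike_lists[c] else np.empty(0)
        units.append(
            UnitRecord(
                unit_id=str(all_ids[c]),
                region="synthetic",
                cell_class=CellClass.PRINCIPAL if is_principal[c] else CellClass.INTERNEURON,
                spike_times=times,
            )
        )
    spikes = SpikeTable(sorted(units, key=lambda u: u.unit_id))

    # ---- traces ----------------------------------------------------------
    n_samples = int(np.ceil(session_end / snap))
    grid = snap * np.arange(n_samples)
    emg_vals = spec.emg_baseline + rng.normal(0.0, spec.emg_noise_sd, n_samples)
    if not ma_set.is_empty:
        in_ma = ma_set.contains(grid)
        emg_vals[in_ma] = spec.emg_ma_level + rng.normal(0.0, spec.emg_noise_sd, int(in_ma.sum()))
    logp = spec.log10_power_baseline + rng.normal(0.0, spec.log10_power_noise_sd, n_samples)
    if not low_set.is_empty:
        in_low = low_set.contains(grid)
        logp[in_low] = spec.log10_power_low_level + rng.normal(
            0.0, spec.log10_power_noise_sd, int(in_low.sum())
        )
    emg = SignalTrace(0.0, snap, emg_vals, kind="emg_power")
    power = SignalTrace(0.0, snap, 10.0 ** logp, kind="lfp_band_power")

    ground_truth: Dict[str, object] = {
        "baseline_hz": dict(zip(all_ids.tolist(), all_base.tolist())),
        "quintile": truth_assign.as_dict(),
        "state_gains": {k: v.tolist() for k, v in gains.items()},
        "interneuron_state_gain": dict(spec.interneuron_state_gain),
        "off": off_set,
        "ma": ma_set,
        "low": low_set,
    }
    return SyntheticSession(
        spikes=spikes,
        hypnogram=hypnogram,
        emg=emg,
        band_power=power,
        ground_truth=ground_truth,
    )
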