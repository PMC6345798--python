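"""Epoch filtering, state-sequence extraction and control-period selection.

The analysis unit is the *epoch*: one maximal contiguous interval of a single
scored state.  Short epochs give unreliable rate estimates, so only NREM
epochs strictly longer than 150 s and REM epochs strictly longer than 100 s
are analyzed (WAKE epochs are kept regardless).  Filtered-out epochs are
invisible to pattern matching: they neither join nor break sequences.

A *sequence* pairs two analysis periods (``period_i`` before ``period_j``)
drawn from a pattern of consecutive surviving epochs, plus — once selected —
a *control* period ``period_k`` of the same state as ``period_i``, used by
the shuffle surrogate that removes regression-to-the-mean bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .data import Hypnogram
from .intervals import IntervalSet

__all__ = [
    "Epoch",
    "Period",
    "StateSequence",
    "SEQUENCE_KINDS",
    "filter_epochs",
    "epoch_thirds",
    "extract_sequences",
    "sleep_bout_ids",
    "select_control_period",
    "select_wake_control",
    "nonfiring_exclusion",
]

SLEEP_STATES = ("NREM", "REM")

SEQUENCE_KINDS = (
    "NREM_REM",
    "REM_NREM",
    "WAKE_NREM",
    "NREM_WAKE",
    "REM_WAKE",
    "NREM_REM_NREM",
    "REM_NREM_REM",
    "SLEEP_first_last_NREM",
    "WAKE_SLEEP_WAKE",
    "within_NREM",
    "within_REM",
)

_PAIR_PATTERNS = {
    "NREM_REM": ("NREM", "REM"),
    "REM_NREM": ("REM", "NREM"),
    "WAKE_NREM": ("WAKE", "NREM"),
    "NREM_WAKE": ("NREM", "WAKE"),
    "REM_WAKE": ("REM", "WAKE"),
}
_TRIPLET_PATTERNS = {
    "NREM_REM_NREM": ("NREM", "REM", "NREM"),
    "REM_NREM_REM": ("REM", "NREM", "REM"),
}
_WITHIN_PATTERNS = {"within_NREM": "NREM", "within_REM": "REM"}


@dataclass(frozen=True)
class Epoch:
    """One duration-filtered state interval with its position in the session."""

    state: str
    start_s: float
    end_s: float
    index_in_session: int

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def interval(self) -> Tuple[float, float]:
        return (self.start_s, self.end_s)


@dataclass(frozen=True)
class Period:
    """An analysis sub-interval anchored in an epoch.

    ``position`` records which part of the parent epoch the period covers
    (``first_third``/``last_third``/``first_60s``/``last_60s``/``random_60s``)
    so control periods can be taken from the *corresponding* part of another
    epoch of the same state.
    """

    start_s: float
    end_s: float
    epoch_index: int
    state: str
    position: str

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def as_interval_set(self) -> IntervalSet:
        return IntervalSet([(self.start_s, self.end_s)])


@dataclass
class StateSequence:
    kind: str
    epoch_indices: Tuple[int, ...]
    period_i: Period
    period_j: Period
    period_k: Optional[Period] = None
    excluded: bool = False
    exclusion_reason: Optional[str] = None

    def exclude(self, reason: str) -> None:
        self.excluded = True
        self.exclusion_reason = reason


# ------------------------------------------------------------------ filtering
def filter_epochs(
    hypnogram: Hypnogram,
    min_nrem_s: float = 150.0,
    min_rem_s: float = 100.0,
) -> List[Epoch]:
    """Duration-filtered epochs in session order.

    NREM must be strictly longer than ``min_nrem_s`` and REM strictly longer
    than ``min_rem_s``; WAKE epochs always pass.  ``index_in_session``
    refers to the unfiltered ordering, so adjacency logic can reason about
    dropped epochs.
    """
    epochs = []
    for idx, (state, s, e) in enumerate(hypnogram.labeled_intervals()):
        if state == "MA":
            continue
        dur = e - s
        if state == "NREM" and not dur > min_nrem_s:
            continue
        if state == "REM" and not dur > min_rem_s:
            continue
        epochs.append(Epoch(state=state, start_s=s, end_s=e, index_in_session=idx))
    return epochs


def epoch_thirds(epoch: "Epoch | Tuple[float, float]") -> IntervalSet:
    """Three equal, contiguous, half-open intervals partitioning the epoch."""
    s, e = (epoch.start_s, epoch.end_s) if isinstance(epoch, Epoch) else epoch
    if e <= s:
        raise ValueError("epoch duration must be > 0")
    edges = s + (e - s) * np.array([0.0, 1 / 3, 2 / 3, 1.0])
    edges[-1] = e  # exact partition despite rounding
    return IntervalSet(np.column_stack([edges[:-1], edges[1:]]))


def _third(epoch: Epoch, which: str) -> Period:
    thirds = epoch_thirds(epoch)
    idx = 0 if which == "first_third" else 2
    return Period(
        start_s=float(thirds.starts[idx]),
        end_s=float(thirds.ends[idx]),
        epoch_index=epoch.index_in_session,
        state=epoch.state,
        position=which,
    )


def _edge_minute(epoch: Epoch, which: str, duration_s: float = 60.0) -> Optional[Period]:
    if epoch.duration_s < duration_s:
        return None
    if which == "last_60s":
        s = epoch.end_s - duration_s
    else:
        s = epoch.start_s
    return Period(s, s + duration_s, epoch.index_in_session, epoch.state, which)


# ------------------------------------------------------------- sleep bouts
def sleep_bout_ids(epochs: Sequence[Epoch], max_wake_interruption_s: float = 60.0) -> np.ndarray:
    """Bout id per epoch (-1 for WAKE epochs breaking the bout).

    Continuous sleep is a maximal run of NREM/REM epochs; WAKE epochs no
    longer than ``max_wake_interruption_s`` count as interruptions within a
    bout (they get the bout's id), longer WAKE epochs terminate it.
    """
    ids = np.full(len(epochs), -1, dtype=int)
    bout = -1
    in_bout = False
    for pos, ep in enumerate(epochs):
        if ep.state in SLEEP_STATES:
            if not in_bout:
                bout += 1
                in_bout = True
            ids[pos] = bout
        elif in_bout and ep.duration_s <= max_wake_interruption_s:
            ids[pos] = bout  # brief wake inside sleep
        else:
            in_bout = False
    # A bout must actually contain sleep after each interruption; trailing
    # interruptions that end a run keep the id harmlessly.
    return ids


# -------------------------------------------------------------- extraction
def extract_sequences(
    epochs: Sequence[Epoch],
    kind: str,
    max_gap_s: float = np.inf,
    max_wake_interruption_s: float = 60.0,
) -> List[StateSequence]:
    """All maximal matches of a state pattern over consecutive epochs.

    Pair kinds compare the last third of the first epoch with the first
    third of the second; ``within_*`` kinds compare first versus last third
    of one epoch; triplets compare corresponding (last) thirds of the two
    flanking same-state epochs; ``WAKE_SLEEP_WAKE`` compares the last minute
    of the wake before a sleep bout with the first minute of the wake after
    it; ``SLEEP_first_last_NREM`` compares the first and last NREM epoch of
    a bout (corresponding last thirds).
    """
    if kind not in SEQUENCE_KINDS:
        raise ValueError(f"unknown sequence kind {kind!r}")
    epochs = list(epochs)
    out: List[StateSequence] = []

    def gap_ok(a: Epoch, b: Epoch) -> bool:
        return (b.start_s - a.end_s) <= max_gap_s

    if kind in _WITHIN_PATTERNS:
        state = _WITHIN_PATTERNS[kind]
        for ep in epochs:
            if ep.state != state:
                continue
            out.append(
                StateSequence(
                    kind=kind,
                    epoch_indices=(ep.index_in_session,),
                    period_i=_third(ep, "first_third"),
                    period_j=_third(ep, "last_third"),
                )
            )
    elif kind in _PAIR_PATTERNS:
        s1, s2 = _PAIR_PATTERNS[kind]
        for a, b in zip(epochs, epochs[1:]):
            if (a.state, b.state) == (s1, s2) and gap_ok(a, b):
                out.append(
                    StateSequence(
                        kind=kind,
                        epoch_indices=(a.index_in_session, b.index_in_session),
                        period_i=_third(a, "last_third"),
                        period_j=_third(b, "first_third"),
                    )
                )
    elif kind in _TRIPLET_PATTERNS:
        s1, s2, s3 = _TRIPLET_PATTERNS[kind]
        for a, b, c in zip(epochs, epochs[1:], epochs[2:]):
            if (a.state, b.state, c.state) == (s1, s2, s3) and gap_ok(a, b) and gap_ok(b, c):
                out.append(
                    StateSequence(
                        kind=kind,
                        epoch_indices=(a.index_in_session, b.index_in_session, c.index_in_session),
                        period_i=_third(a, "last_third"),
                        period_j=_third(c, "last_third"),
                    )
                )
    elif kind == "SLEEP_first_last_NREM":
        bouts = sleep_bout_ids(epochs, max_wake_interruption_s)
        for bout in range(int(bouts.max(initial=-1)) + 1):
            nrems = [ep for ep, b in zip(epochs, bouts) if b == bout and ep.state == "NREM"]
            if len(nrems) < 2:
                continue
            first, last = nrems[0], nrems[-1]
            out.append(
                StateSequence(
                    kind=kind,
                    epoch_indices=(first.index_in_session, last.index_in_session),
                    period_i=_third(first, "last_third"),
                    period_j=_third(last, "last_third"),
                )
            )
    elif kind == "WAKE_SLEEP_WAKE":
        bouts = sleep_bout_ids(epochs, max_wake_interruption_s)
        for bout in range(int(bouts.max(initial=-1)) + 1):
            members = [pos for pos, b in enumerate(bouts) if b == bout]
            if not members:
                continue
            lo, hi = members[0], members[-1]
            if lo == 0 or hi == len(epochs) - 1:
                continue
            w1, w2 = epochs[lo - 1], epochs[hi + 1]
            if w1.state != "WAKE" or w2.state != "WAKE":
                continue
            if not (gap_ok(w1, epochs[lo]) and gap_ok(epochs[hi], w2)):
                continue
            pi = _edge_minute(w1, "last_60s")
            pj = _edge_minute(w2, "first_60s")
            if pi is None or pj is None:
                continue
            seq = StateSequence(
                kind=kind,
                epoch_indices=(w1.index_in_session, w2.index_in_session),
                period_i=pi,
                period_j=pj,
            )
            out.append(seq)
    return out


# ------------------------------------------------------------ control periods
def select_control_period(
    seq: StateSequence,
    epochs: Sequence[Epoch],
    *,
    require_same_bout: bool = True,
    max_wake_interruption_s: float = 60.0,
) -> StateSequence:
    """Fill ``period_k`` from the nearest adjacent same-state epoch.

    The control is the *corresponding* sub-interval (same third position as
    ``period_i``) of the nearest epoch of the same state that passes the
    duration filters and is not already used by the sequence; by default it
    must lie in the same sleep bout.  Without a qualifying neighbor the
    sequence is flagged excluded (not an error).
    """
    if seq.period_i.state not in SLEEP_STATES:
        raise ValueError("select_control_period applies to NREM/REM anchored sequences; "
                         "use select_wake_control for wake-anchored ones")
    used = set(seq.epoch_indices)
    anchor = next(e for e in epochs if e.index_in_session == seq.period_i.epoch_index)
    bouts = sleep_bout_ids(epochs, max_wake_interruption_s)
    bout_of = {e.index_in_session: b for e, b in zip(epochs, bouts)}
    candidates = [
        e
        for e in epochs
        if e.state == seq.period_i.state and e.index_in_session not in used
    ]
    if require_same_bout:
        candidates = [e for e in candidates if bout_of[e.index_in_session] == bout_of[anchor.index_in_session]]
    if not candidates:
        seq.exclude("no_control_period")
        return seq
    nearest = min(candidates, key=lambda e: (abs(e.start_s - anchor.start_s), e.index_in_session))
    position = seq.period_i.position
    if position not in ("first_third", "last_third"):
        position = "last_third"
    seq.period_k = _third(nearest, position)
    return seq


def select_wake_control(
    wake_epoch: Epoch,
    period_i: Period,
    rng: np.random.Generator,
    duration_s: float = 60.0,
    max_tries: int = 100,
) -> Optional[Period]:
    """Uniformly random 60-s control sub-interval of the same wake epoch.

    Reproducible under the supplied generator.  When the epoch is long
    enough, re-draws avoid returning exactly ``period_i`` (bounded rejection,
    then overlap is accepted).  Returns None for epochs shorter than
    ``duration_s`` (the sequence is then excluded).
    """
    span = wake_epoch.duration_s - duration_s
    if span < 0:
        return None
    start = wake_epoch.start_s
    for _ in range(max_tries):
        s = wake_epoch.start_s + rng.uniform(0.0, span) if span > 0 else wake_epoch.start_s
        if span == 0 or abs(s - period_i.start_s) > 1e-9:
            start = s
            break
    else:  # pragma: no cover - pathological epoch exactly 60 s twice
        start = s
    return Period(
        start_s=float(start),
        end_s=float(start + duration_s),
        epoch_index=wake_epoch.index_in_session,
        state="WAKE",
        position="random_60s",
    )


# ---------------------------------------------------------- sequence QC rule
def nonfiring_exclusion(fr_i: np.ndarray, fr_j: np.ndarray, threshold: float = 0.20) -> bool:
    """True iff the sequence must be excluded for too many silent cells.

    A sequence is dropped when strictly more than ``threshold`` of the cells
    fired zero spikes in period i *or* in period j (the lowest quintile's
    change cannot be measured in that case).
    """
    fr_i = np.asarray(fr_i, dtype=float)
    fr_j = np.asarray(fr_j, dtype=float)
    if fr_i.size == 0 or fr_i.shape != fr_j.shape:
        raise ValueError("rate vectors must be non-empty and aligned")
    frac_i = np.mean(fr_i == 0.0)
    frac_j = np.mean(fr_j == 0.0)
    return bool(frac_i > threshold or frac_j > threshold)
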