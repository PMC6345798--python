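"""Epoch filtering, thirds, pattern extraction and control selection."""

import numpy as np
import pytest
from scipy import stats

from somnorate import (
    Hypnogram,
    IntervalSet,
    epoch_thirds,
    extract_sequences,
    filter_epochs,
    nonfiring_exclusion,
    select_control_period,
    select_wake_control,
)
from somnorate.sequences import Epoch


def hyp(*rows):
    states = {}
    for state, s, e in rows:
        states.setdefault(state, []).append((s, e))
    return Hypnogram({k: IntervalSet(v) for k, v in states.items()})


class TestDurationFilters:
    """NREM must exceed 150 s and REM 100 s, strictly."""

    @pytest.mark.parametrize(
        "state,duration,kept",
        [
            ("NREM", 150.0, False),
            ("NREM", 150.5, True),
            ("REM", 100.0, False),
            ("REM", 101.0, True),
            ("WAKE", 5.0, True),
        ],
    )
    def test_strict_thresholds(self, state, duration, kept):
        epochs = filter_epochs(hyp((state, 0.0, duration)))
        assert (len(epochs) == 1) is kept

    def test_indices_refer_to_unfiltered_ordering(self):
        h = hyp(("WAKE", 0, 10), ("NREM", 10, 100), ("NREM", 100, 300), ("REM", 300, 450))
        epochs = filter_epochs(h)
        assert [(e.state, e.index_in_session) for e in epochs] == [
            ("WAKE", 0),
            ("NREM", 2),
            ("REM", 3),
        ]


class TestThirds:
    def test_example(self):
        thirds = epoch_thirds((0.0, 9.0))
        assert list(thirds) == [(0.0, 3.0), (3.0, 6.0), (6.0, 9.0)]

    def test_partition_conserves_duration(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            s = rng.uniform(0, 1e4)
            e = s + rng.uniform(0.01, 5e3)
            thirds = epoch_thirds((s, e))
            assert thirds.duration == pytest.approx(e - s, abs=1e-9)
            assert thirds.starts[0] == s and thirds.ends[-1] == e
            # contiguous and disjoint
            np.testing.assert_allclose(thirds.ends[:-1], thirds.starts[1:])


class TestExtraction:
    def test_five_epoch_toy(self, toy_hypnogram):
        epochs = filter_epochs(toy_hypnogram)
        counts = {
            kind: len(extract_sequences(epochs, kind))
            for kind in (
                "NREM_REM",
                "REM_NREM",
                "NREM_REM_NREM",
                "WAKE_NREM",
                "NREM_WAKE",
                "SLEEP_first_last_NREM",
                "WAKE_SLEEP_WAKE",
                "within_NREM",
            )
        }
        assert counts == {
            "NREM_REM": 1,
            "REM_NREM": 1,
            "NREM_REM_NREM": 1,
            "WAKE_NREM": 1,
            "NREM_WAKE": 1,
            "SLEEP_first_last_NREM": 1,
            "WAKE_SLEEP_WAKE": 1,
            "within_NREM": 2,
        }

    def test_pair_periods_are_adjacent_thirds(self, toy_hypnogram):
        epochs = filter_epochs(toy_hypnogram)
        (seq,) = extract_sequences(epochs, "NREM_REM")
        assert seq.period_i.position == "last_third"
        assert seq.period_j.position == "first_third"
        assert seq.period_i.end_s == pytest.approx(600.0)
        assert seq.period_j.start_s == pytest.approx(600.0)

    def test_short_middle_rem_breaks_triplet(self):
        h = hyp(("NREM", 0, 200), ("REM", 200, 290), ("NREM", 290, 500))
        epochs = filter_epochs(h)  # 90 s REM dropped
        assert extract_sequences(epochs, "NREM_REM_NREM") == []
        assert extract_sequences(epochs, "NREM_REM") == []

    def test_single_wake_gives_no_wake_sleep_wake(self):
        h = hyp(("WAKE", 0, 300), ("NREM", 300, 500))
        assert extract_sequences(filter_epochs(h), "WAKE_SLEEP_WAKE") == []

    def test_extraction_is_deterministic(self, toy_hypnogram):
        epochs = filter_epochs(toy_hypnogram)
        a = extract_sequences(epochs, "NREM_REM")
        b = extract_sequences(epochs, "NREM_REM")
        assert a == b

    def test_max_gap_blocks_distant_pairs(self):
        # NREM ends 300, REM starts 400: 100 s gap of unscored time
        h = hyp(("NREM", 0, 300), ("REM", 400, 520))
        epochs = filter_epochs(h)
        assert len(extract_sequences(epochs, "NREM_REM", max_gap_s=np.inf)) == 1
        assert extract_sequences(epochs, "NREM_REM", max_gap_s=50.0) == []


class TestControlSelection:
    def test_triplet_uses_flanking_same_state_epoch(self, toy_hypnogram):
        epochs = filter_epochs(toy_hypnogram)
        (seq,) = extract_sequences(epochs, "NREM_REM")
        seq = select_control_period(seq, epochs)
        assert not seq.excluded
        # control = last third of the other NREM (780-1000)
        assert seq.period_k.state == "NREM"
        assert seq.period_k.position == "last_third"
        assert seq.period_k.start_s == pytest.approx(780 + 220 * 2 / 3)

    def test_within_nrem_control_is_corresponding_first_third(self, toy_hypnogram):
        epochs = filter_epochs(toy_hypnogram)
        seqs = extract_sequences(epochs, "within_NREM")
        seq = select_control_period(seqs[0], epochs)
        assert seq.period_k.position == "first_third"
        assert seq.period_k.epoch_index != seq.period_i.epoch_index

    def test_isolated_epoch_flags_exclusion(self):
        h = hyp(("NREM", 0, 200), ("REM", 200, 320))
        epochs = filter_epochs(h)
        (seq,) = extract_sequences(epochs, "NREM_REM")
        seq = select_control_period(seq, epochs)
        assert seq.excluded and seq.exclusion_reason == "no_control_period"

    def test_wake_control_forced_when_epoch_is_exactly_60s(self):
        ep = Epoch("WAKE", 0.0, 60.0, 0)
        from somnorate.sequences import Period

        pi = Period(0.0, 60.0, 0, "WAKE", "last_60s")
        ctrl = select_wake_control(ep, pi, np.random.default_rng(0))
        assert (ctrl.start_s, ctrl.end_s) == (0.0, 60.0)

    def test_wake_control_reproducible_and_uniform(self):
        from somnorate.sequences import Period

        ep = Epoch("WAKE", 0.0, 360.0, 0)
        pi = Period(300.0, 360.0, 0, "WAKE", "last_60s")
        a = select_wake_control(ep, pi, np.random.default_rng(5))
        b = select_wake_control(ep, pi, np.random.default_rng(5))
        assert a == b
        rng = np.random.default_rng(6)
        starts = np.array(
            [select_wake_control(ep, pi, rng).start_s for _ in range(10_000)]
        )
        # uniform on [0, 300]
        assert stats.kstest(starts / 300.0, "uniform").pvalue > 0.01

    def test_short_wake_epoch_returns_none(self):
        from somnorate.sequences import Period

        ep = Epoch("WAKE", 0.0, 45.0, 0)
        pi = Period(0.0, 45.0, 0, "WAKE", "last_60s")
        assert select_wake_control(ep, pi, np.random.default_rng(0)) is None


class TestNonfiringRule:
    def test_exactly_twenty_percent_keeps(self):
        fr_i = np.array([0, 0, 1, 1, 1, 1, 1, 1, 1, 1], float)
        fr_j = np.ones(10)
        assert nonfiring_exclusion(fr_i, fr_j) is False

    def test_above_twenty_percent_excludes(self):
        fr_j = np.array([0, 0, 0, 1, 1, 1, 1, 1, 1, 1], float)
        assert nonfiring_exclusion(np.ones(10), fr_j) is True

    def test_all_firing_keeps(self):
        assert nonfiring_exclusion(np.ones(8), np.ones(8)) is False

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            nonfiring_exclusion(np.array([]), np.array([]))
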