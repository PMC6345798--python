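"""Shared fixtures: toy hypnograms, spike tables and synthetic sessions."""

from __future__ import annotations

import numpy as np
import pytest

from somnorate import (
    CellClass,
    Hypnogram,
    IntervalSet,
    SessionSpec,
    SpikeTable,
    UnitRecord,
    simulate_session,
)


@pytest.fixture
def toy_hypnogram() -> Hypnogram:
    """W, N, R, N, W with every epoch passing the duration filters."""
    return Hypnogram(
        {
            "WAKE": IntervalSet([(0.0, 300.0), (1000.0, 1400.0)]),
            "NREM": IntervalSet([(300.0, 600.0), (780.0, 1000.0)]),
            "REM": IntervalSet([(600.0, 780.0)]),
        }
    )


def make_unit(unit_id: str, times, region: str = "hpc", cls: CellClass = CellClass.PRINCIPAL) -> UnitRecord:
    return UnitRecord(unit_id=unit_id, region=region, cell_class=cls, spike_times=np.asarray(times, float))


@pytest.fixture
def regular_spikes() -> SpikeTable:
    """Six principal units firing regularly at 1..6 Hz plus one interneuron."""
    units = [
        make_unit(f"u{r}", np.arange(0.0, 300.0, 1.0 / r) + 0.01 * r) for r in range(1, 7)
    ]
    units.append(make_unit("zint", np.arange(0.0, 300.0, 0.1), cls=CellClass.INTERNEURON))
    return SpikeTable(units)


@pytest.fixture(scope="session")
def planted_session():
    """Sparse 55-unit session with REM widening and default substates.

    The REM quintile gains (0.6 .. 1.1) widen the principal rate
    distribution during REM relative to NREM, the planted ground truth the
    recovery tests assert against.
    """
    spec = SessionSpec(
        seed=11,
        n_principal=50,
        n_interneurons=5,
        interneuron_rate_mean_hz=5.0,
        interneuron_rate_sd_hz=2.0,
        n_bouts=1,
        n_cycles_per_bout=22,
        nrem_duration_mean_s=300.0,
        rem_duration_mean_s=140.0,
        duration_cv=0.25,
        nrem_min_s=155.0,
        rem_min_s=105.0,
    )
    return simulate_session(spec)


@pytest.fixture(scope="session")
def dense_session():
    """Dense, fast-firing session where population silences are unambiguous.

    With ~600 Hz pooled firing, a spontaneous pooled gap > 75 ms has
    negligible probability, so every detected OFF state is a planted one.
    """
    spec = SessionSpec(
        seed=42,
        n_principal=200,
        n_interneurons=0,
        principal_rate_mean_hz=3.0,
        principal_rate_sd_hz=2.0,
        n_bouts=1,
        n_cycles_per_bout=4,
        nrem_duration_mean_s=600.0,
        rem_duration_mean_s=180.0,
    )
    return simulate_session(spec)
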