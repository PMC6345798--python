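"""Readers and writers for spike, hypnogram, substate and trace files.

All tabular formats are header-bearing delimited text (tab or comma,
auto-detected on read, tab on write).  The Neurosuite-style reader pairs a
``.res`` file (spike sample indices, one per line) with a ``.clu`` file
(first line = number of clusters, then one cluster id per spike) and needs a
sampling rate; an optional metadata sidecar maps cluster ids to unit ids,
regions and cell classes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .data import STATE_LABELS, CellClass, Hypnogram, SignalTrace, SpikeTable, UnitRecord
from .intervals import IntervalSet

__all__ = [
    "FormatError",
    "read_spike_table",
    "write_spike_table",
    "read_hypnogram",
    "write_hypnogram",
    "read_intervals",
    "write_intervals",
    "read_signal_trace",
    "write_signal_trace",
]

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


def _read_delimited(path: PathLike) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:  # pragma: no cover - passthrough context
        raise FormatError(f"{path}: could not parse delimited text ({exc})") from exc


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: PathLike) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


# --------------------------------------------------------------------- spikes
def read_spike_table(
    path: PathLike,
    format: str = "tabular",
    *,
    sampling_rate_hz: Optional[float] = None,
    metadata_path: Optional[PathLike] = None,
    duplicate_tol_s: float = 1e-6,
) -> SpikeTable:
    """Read a spike table in ``tabular`` or ``neurosuite`` format.

    Tabular files carry columns ``unit_id, spike_time_s, region, cell_class``.
    Spike times are sorted per unit; ties within a unit closer than
    ``duplicate_tol_s`` collapse to a single spike.
    """
    if format == "tabular":
        return _read_spike_tabular(path, duplicate_tol_s)
    if format == "neurosuite":
        if sampling_rate_hz is None:
            raise FormatError("neurosuite format requires sampling_rate_hz")
        return _read_spike_neurosuite(path, sampling_rate_hz, metadata_path, duplicate_tol_s)
    raise FormatError(f"unknown spike table format {format!r}")


def _dedupe(times: np.ndarray, tol: float) -> np.ndarray:
    times = np.sort(np.asarray(times, dtype=float))
    if times.size < 2 or tol <= 0:
        return times
    keep = np.empty(times.size, dtype=bool)
    keep[0] = True
    np.greater(np.diff(times), tol, out=keep[1:])
    return times[keep]


def _read_spike_tabular(path: PathLike, tol: float) -> SpikeTable:
    df = _read_delimited(path)
    _require_columns(df, ["unit_id", "spike_time_s", "region", "cell_class"], path)
    times = pd.to_numeric(df["spike_time_s"], errors="coerce")
    bad = np.flatnonzero(times.isna().to_numpy())
    if bad.size:
        # +2: header line plus 1-based numbering.
        raise FormatError(f"{path}: non-numeric spike_time_s on line {int(bad[0]) + 2}")
    df = df.assign(spike_time_s=times.astype(float))
    units = []
    for unit_id, grp in df.groupby("unit_id", sort=True):
        classes = set(grp["cell_class"].astype(str))
        if len(classes) > 1:
            raise FormatError(f"{path}: unit {unit_id!r} has conflicting cell_class values {sorted(classes)}")
        cls = classes.pop()
        if cls not in (c.value for c in CellClass):
            raise FormatError(f"{path}: unknown cell_class {cls!r} for unit {unit_id!r}")
        units.append(
            UnitRecord(
                unit_id=str(unit_id),
                region=str(grp["region"].iloc[0]),
                cell_class=CellClass(cls),
                spike_times=_dedupe(grp["spike_time_s"].to_numpy(), tol),
            )
        )
    return SpikeTable(units)


def _read_spike_neurosuite(
    base: PathLike,
    sampling_rate_hz: float,
    metadata_path: Optional[PathLike],
    tol: float,
) -> SpikeTable:
    base = Path(base)
    res_path = base if base.suffix == ".res" else base.with_suffix(base.suffix + ".res")
    clu_path = Path(str(res_path)[: -len(".res")] + ".clu")
    if not res_path.exists() or not clu_path.exists():
        raise FormatError(f"neurosuite pair not found: {res_path} / {clu_path}")
    res = np.loadtxt(res_path, dtype=float, ndmin=1)
    clu = np.loadtxt(clu_path, dtype=int, ndmin=1)
    if clu.size < 1:
        raise FormatError(f"{clu_path}: empty .clu file")
    clu = clu[1:]  # first line is the cluster count
    if clu.size != res.size:
        raise FormatError(f"{clu_path}: {clu.size} cluster ids for {res.size} spikes")
    meta: Dict[int, dict] = {}
    if metadata_path is not None:
        mdf = _read_delimited(metadata_path)
        _require_columns(mdf, ["cluster_id", "unit_id", "region", "cell_class"], metadata_path)
        for row in mdf.itertuples(index=False):
            meta[int(row.cluster_id)] = {
                "unit_id": str(row.unit_id),
                "region": str(row.region),
                "cell_class": str(row.cell_class),
            }
        cluster_ids = sorted(meta)
    else:
        # Neurosuite convention: clusters 0 (noise) and 1 (multi-unit) skipped.
        cluster_ids = sorted(c for c in np.unique(clu) if c >= 2)
    units = []
    for cid in cluster_ids:
        info = meta.get(
            int(cid),
            {"unit_id": f"clu{cid}", "region": "unknown", "cell_class": CellClass.PRINCIPAL.value},
        )
        if info["cell_class"] not in (c.value for c in CellClass):
            raise FormatError(f"{metadata_path}: unknown cell_class {info['cell_class']!r}")
        times = res[clu == cid] / float(sampling_rate_hz)
        units.append(
            UnitRecord(
                unit_id=info["unit_id"],
                region=info["region"],
                cell_class=CellClass(info["cell_class"]),
                spike_times=_dedupe(times, tol),
            )
        )
    return SpikeTable(units)


def write_spike_table(table: SpikeTable, path: PathLike) -> None:
    rows = []
    for u in table.units:
        for t in u.spike_times:
            rows.append((u.unit_id, t, u.region, u.cell_class.value))
    df = pd.DataFrame(rows, columns=["unit_id", "spike_time_s", "region", "cell_class"])
    df.to_csv(path, sep="\t", index=False, float_format="%.9f")


# ------------------------------------------------------------------ hypnogram
def read_hypnogram(
    path: PathLike,
    *,
    merge_same_label: bool = True,
    session_start_s: Optional[float] = None,
    session_end_s: Optional[float] = None,
) -> Hypnogram:
    """Read an interval table ``(state, start_s, end_s)`` into a hypnogram.

    Overlapping rows with the same label are merged when ``merge_same_label``
    is set; overlapping rows of different labels always raise.
    """
    df = _read_delimited(path)
    _require_columns(df, ["state", "start_s", "end_s"], path)
    unknown = sorted(set(df["state"].astype(str)) - set(STATE_LABELS))
    if unknown:
        raise FormatError(f"{path}: unknown state label(s) {unknown}")
    for col in ("start_s", "end_s"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if bad.size:
            raise FormatError(f"{path}: non-numeric {col} on line {int(bad[0]) + 2}")
        df[col] = vals.astype(float)
    if np.any(df["end_s"].to_numpy() <= df["start_s"].to_numpy()):
        i = int(np.flatnonzero(df["end_s"].to_numpy() <= df["start_s"].to_numpy())[0])
        raise FormatError(f"{path}: non-positive duration on line {i + 2}")
    states = {}
    for label, grp in df.groupby("state", sort=True):
        pairs = grp[["start_s", "end_s"]].to_numpy()
        try:
            states[str(label)] = IntervalSet(pairs, label=str(label), merge=merge_same_label)
        except ValueError as exc:
            raise FormatError(f"{path}: overlapping {label} rows ({exc})") from exc
    try:
        return Hypnogram(states, session_start_s=session_start_s, session_end_s=session_end_s)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_hypnogram(hyp: Hypnogram, path: PathLike) -> None:
    rows = hyp.labeled_intervals()
    df = pd.DataFrame(rows, columns=["state", "start_s", "end_s"])
    df.to_csv(path, sep="\t", index=False, float_format="%.9f")


# -------------------------------------------------- substate interval tables
def read_intervals(path: PathLike, label: Optional[str] = None) -> Dict[str, IntervalSet]:
    """Read a labeled interval table (same dialect as the hypnogram)."""
    df = _read_delimited(path)
    _require_columns(df, ["state", "start_s", "end_s"], path)
    out: Dict[str, IntervalSet] = {}
    for lab, grp in df.groupby("state", sort=True):
        if label is not None and str(lab) != label:
            continue
        out[str(lab)] = IntervalSet(grp[["start_s", "end_s"]].to_numpy(float), label=str(lab))
    return out


def write_intervals(sets: Iterable[IntervalSet], path: PathLike) -> None:
    rows = []
    for iset in sets:
        lab = iset.label or "?"
        rows.extend((lab, s, e) for s, e in iset)
    rows.sort(key=lambda r: r[1])
    pd.DataFrame(rows, columns=["state", "start_s", "end_s"]).to_csv(
        path, sep="\t", index=False, float_format="%.9f"
    )


# --------------------------------------------------------------- signal trace
def read_signal_trace(path: PathLike, kind: str = "emg_power") -> SignalTrace:
    """Read a two-column ``(time_s, value)`` trace on a regular grid."""
    df = _read_delimited(path)
    _require_columns(df, ["time_s", "value"], path)
    return SignalTrace.from_times(
        df["time_s"].to_numpy(float), df["value"].to_numpy(float), kind=kind
    )


def write_signal_trace(trace: SignalTrace, path: PathLike) -> None:
    pd.DataFrame({"time_s": trace.times, "value": trace.values}).to_csv(
        path, sep="\t", index=False, float_format="%.9f"
    )
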