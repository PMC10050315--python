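"""Blockage-event tables: data model, CSV/TSV I/O, filtering, event frequency.

A blockage event is one transient reduction of the open-pore ionic current,
summarised by the blockage ratio I_b/I_0 (residual over open current, in
(0, 1]) and the dwell time in milliseconds. Optionally each event carries its
onset time in seconds, from which arrival frequencies are computed.

The on-disk dialect is a CSV/TSV file with columns
``glycan, ib_over_i0, dwell_ms[, t_start_s]`` (comma or tab auto-detected).
Internally events live in a :class:`pandas.DataFrame` with columns
``ratio``, ``dwell_ms`` and optionally ``t_start_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BlockageEvent",
    "EventTable",
    "EventTableError",
    "read_event_table",
    "write_event_table",
    "filter_events",
    "event_frequency",
    "pool_tables",
]

#: canonical CSV header -> internal column name
_CSV_COLUMNS = {"ib_over_i0": "ratio", "dwell_ms": "dwell_ms", "t_start_s": "t_start_s"}
_REQUIRED = ("ib_over_i0", "dwell_ms")


class EventTableError(ValueError):
    """Raised for malformed event tables or invalid event values."""


@dataclass(frozen=True)
class BlockageEvent:
    """One nanopore blockage observation.

    Attributes
    ----------
    ratio
        Blockage ratio I_b/I_0, dimensionless, in (0, 1].
    dwell_ms
        Dwell time in milliseconds, > 0.
    t_start_s
        Optional event onset time in seconds, >= 0.
    """

    ratio: float
    dwell_ms: float
    t_start_s: float | None = None

    def __post_init__(self) -> None:
        if not (self.ratio > 0):
            raise EventTableError(f"ratio must be > 0, got {self.ratio}")
        if self.ratio > 1:
            raise EventTableError(f"ratio must be <= 1, got {self.ratio}")
        if not (self.dwell_ms > 0):
            raise EventTableError(f"dwell_ms must be > 0, got {self.dwell_ms}")
        if self.t_start_s is not None and not (self.t_start_s >= 0):
            raise EventTableError(f"t_start_s must be >= 0, got {self.t_start_s}")


@dataclass
class EventTable:
    """A labelled collection of blockage events.

    ``events`` is a DataFrame with columns ``ratio`` and ``dwell_ms`` (floats),
    optionally ``t_start_s`` and hidden provenance columns written by the
    synthetic generator. ``meta`` holds recording metadata such as
    ``duration_s``, plus reports attached by operations (parsing, filtering).
    """

    label: str
    events: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = {"ratio", "dwell_ms"} - set(self.events.columns)
        if missing:
            raise EventTableError(f"event frame missing columns: {sorted(missing)}")
        self.events = self.events.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------------
    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def ratio(self) -> np.ndarray:
        return self.events["ratio"].to_numpy(dtype=float)

    @property
    def dwell_ms(self) -> np.ndarray:
        return self.events["dwell_ms"].to_numpy(dtype=float)

    @property
    def t_start_s(self) -> np.ndarray | None:
        if "t_start_s" in self.events.columns and self.events["t_start_s"].notna().all():
            return self.events["t_start_s"].to_numpy(dtype=float)
        return None

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n_events

    def validate(self) -> None:
        """Check every row against the event invariants; raise on violation."""
        bad = _invalid_row_mask(self.events)
        if bad.any():
            rows = np.flatnonzero(bad)[:10].tolist()
            raise EventTableError(
                f"{int(bad.sum())} event(s) violate invariants (rows {rows}...)"
            )
        t = self.t_start_s
        dur = self.meta.get("duration_s")
        if t is not None and t.size and dur is not None and dur < t.max():
            raise EventTableError("duration_s smaller than the last event onset")

    @classmethod
    def from_events(cls, label: str, events: Iterable[BlockageEvent], meta: dict | None = None) -> "EventTable":
        evs = list(events)
        frame = pd.DataFrame(
            {
                "ratio": [e.ratio for e in evs],
                "dwell_ms": [e.dwell_ms for e in evs],
            }
        )
        if any(e.t_start_s is not None for e in evs):
            frame["t_start_s"] = [e.t_start_s for e in evs]
        return cls(label=label, events=frame, meta=dict(meta or {}))


def _invalid_row_mask(frame: pd.DataFrame) -> np.ndarray:
    ratio = frame["ratio"].to_numpy(dtype=float)
    dwell = frame["dwell_ms"].to_numpy(dtype=float)
    bad = ~(np.isfinite(ratio) & (ratio > 0) & (ratio <= 1))
    bad |= ~(np.isfinite(dwell) & (dwell > 0))
    if "t_start_s" in frame.columns:
        t = frame["t_start_s"].to_numpy(dtype=float)
        bad |= np.isfinite(t) & (t < 0)
    return bad


def read_event_table(path: str | Path, label: str | None = None, strict: bool = True) -> EventTable:
    """Read a CSV/TSV event table.

    The header must name at least ``ib_over_i0`` and ``dwell_ms``; the
    separator (comma or tab) is auto-detected. Rows violating the event
    invariants abort the read in strict mode (default); with ``strict=False``
    they are dropped individually and counted in ``meta["parse_report"]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
        frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:  # non-numeric cells, ragged rows
        raise EventTableError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise EventTableError(f"{path}: missing mandatory column(s) {missing}")
    if label is None:
        if "glycan" in frame.columns and len(frame):
            label = str(frame["glycan"].iloc[0])
        else:
            label = path.stem
    keep = [c for c in _CSV_COLUMNS if c in frame.columns]
    data = frame[keep].rename(columns=_CSV_COLUMNS)
    for col in data.columns:
        try:
            data[col] = pd.to_numeric(data[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(data[col], errors="coerce").isna() & data[col].notna()
            row = int(np.flatnonzero(bad.to_numpy())[0]) if bad.any() else -1
            raise EventTableError(f"{path}: non-numeric value in column {col!r}, row {row}") from exc

    bad = _invalid_row_mask(data)
    n_bad = int(bad.sum())
    if n_bad and strict:
        rows = np.flatnonzero(bad)[:10].tolist()
        raise EventTableError(f"{path}: {n_bad} row(s) violate event invariants (rows {rows})")
    table = EventTable(label=label, events=data.loc[~bad].reset_index(drop=True))
    table.meta["parse_report"] = {"n_rows": len(frame), "n_rejected": n_bad}
    return table


def write_event_table(table: EventTable, path: str | Path) -> None:
    """Write ``table`` in the canonical CSV dialect (full float precision).

    Reading the file back reproduces the events exactly.
    """
    path = Path(path)
    out = pd.DataFrame(
        {
            "glycan": np.repeat(table.label, table.n_events),
            "ib_over_i0": table.events["ratio"].to_numpy(),
            "dwell_ms": table.events["dwell_ms"].to_numpy(),
        }
    )
    if table.t_start_s is not None:
        out["t_start_s"] = table.t_start_s
    out.to_csv(path, index=False)


def filter_events(table: EventTable, max_ratio: float = 0.99) -> EventTable:
    """Exclude events whose blockage ratio exceeds ``max_ratio``.

    Events with I_b/I_0 above the threshold correspond to an essentially
    unoccupied pore and are excluded from all downstream statistics. The
    default threshold 0.99 is the convention for this assay. Order is
    preserved; retained/removed counts are reported in ``meta["filter"]``.
    """
    if not (0 < max_ratio <= 1):
        raise ValueError(f"max_ratio must be in (0, 1], got {max_ratio}")
    keep = table.events["ratio"].to_numpy(dtype=float) <= max_ratio
    out = EventTable(
        label=table.label,
        events=table.events.loc[keep].reset_index(drop=True),
        meta=dict(table.meta),
    )
    out.meta["filter"] = {
        "max_ratio": max_ratio,
        "retained": int(keep.sum()),
        "removed": int((~keep).sum()),
    }
    return out


def event_frequency(table: EventTable) -> float:
    """Event arrival frequency in events per second.

    Uses the recording duration from ``meta["duration_s"]`` when present,
    otherwise the span of event onset times. The frequency is the standard
    concentration/activity readout: arrivals are well modelled as a Poisson
    process whose rate is proportional to analyte concentration.
    """
    duration = table.meta.get("duration_s")
    if duration is None:
        t = table.t_start_s
        if t is None or t.size == 0:
            raise EventTableError("no timing information: need duration_s metadata or t_start_s")
        duration = float(t.max() - t.min())
    duration = float(duration)
    if duration <= 0:
        raise EventTableError(f"non-positive recording duration: {duration}")
    return table.n_events / duration


def pool_tables(tables: Sequence[EventTable], label: str = "pooled") -> EventTable:
    """Concatenate several event tables into one pooled table."""
    if len(tables) == 0:
        raise ValueError("pool_tables requires at least one table")
    frames = [t.events for t in tables]
    pooled = pd.concat(frames, ignore_index=True, sort=False)
    return EventTable(label=label, events=pooled, meta={"sources": [t.label for t in tables]})
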