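"""Marker panels, gating thresholds and event-level preprocessing.

A *marker panel* describes how each continuous cytometry channel is cut into
discrete expression states (negative/positive, or negative/low/high, ...) by
``n_k - 1`` ascending intensity thresholds obtained from manual gating, plus an
optional Out-of-Bound (OOB) ceiling above which a cell is treated as an
acquisition artifact and removed.

Events enter as one table per sample (rows = cells, columns = markers) from CSV
or FCS 3.0/3.1 list-mode files, and leave as a :class:`StateMatrix` of integer
state indices (1-based; state ``k`` means the value fell in the k-th threshold
interval, boundaries belonging to the higher state).
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("cytocomb")

__all__ = [
    "MarkerDef",
    "MarkerPanel",
    "EventTable",
    "StateMatrix",
    "ConfigurationError",
    "DataError",
    "default_state_labels",
    "read_panel_csv",
    "write_panel_csv",
    "apply_oob_filter",
    "discretize_events",
    "read_events_csv",
    "read_fcs",
    "write_fcs",
    "read_events",
]


class ConfigurationError(ValueError):
    """Inconsistent panel/config/inputs (marker mismatch, bad thresholds, ...)."""


class DataError(ValueError):
    """Malformed event data (non-finite intensity, unreadable file, ...)."""


def default_state_labels(n_states: int) -> tuple[str, ...]:
    """Default labels: ``-``/``+`` for 2 states, ``-``/``+``/``++`` for 3, etc."""
    if n_states < 2:
        raise ConfigurationError("a marker needs at least 2 states")
    return ("-",) + tuple("+" * i for i in range(1, n_states))


@dataclass(frozen=True)
class MarkerDef:
    """One marker channel: name, gating thresholds and state labels.

    ``thresholds`` are strictly increasing intensities; ``len(thresholds) + 1``
    discrete states result.  ``oob_limit`` is an optional ceiling: cells with a
    value strictly above it on this channel are dropped by the OOB filter.
    """

    name: str
    thresholds: tuple[float, ...]
    state_labels: tuple[str, ...] = ()
    oob_limit: float | None = None

    def __post_init__(self) -> None:
        thr = tuple(float(t) for t in self.thresholds)
        object.__setattr__(self, "thresholds", thr)
        if len(thr) < 1:
            raise ConfigurationError(f"marker {self.name!r}: needs >= 1 threshold")
        if any(b <= a for a, b in zip(thr, thr[1:])):
            raise ConfigurationError(
                f"marker {self.name!r}: thresholds must be strictly increasing"
            )
        labels = tuple(self.state_labels) or default_state_labels(len(thr) + 1)
        object.__setattr__(self, "state_labels", labels)
        if len(labels) != len(thr) + 1:
            raise ConfigurationError(
                f"marker {self.name!r}: {len(labels)} labels for "
                f"{len(thr) + 1} states"
            )

    @property
    def n_states(self) -> int:
        return len(self.thresholds) + 1


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered collection of :class:`MarkerDef` with unique names."""

    markers: tuple[MarkerDef, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ConfigurationError("marker names must be unique")
        if not names:
            raise ConfigurationError("panel has no markers")

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def n_states(self) -> np.ndarray:
        """``n_k`` per marker."""
        return np.array([m.n_states for m in self.markers], dtype=np.int64)

    @property
    def radices(self) -> np.ndarray:
        """Mixed-radix base per marker: ``n_k + 1`` (state 0 = neutral)."""
        return self.n_states + 1

    def marker(self, name: str) -> MarkerDef:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "markers": [
                {
                    "name": m.name,
                    "thresholds": list(m.thresholds),
                    "state_labels": list(m.state_labels),
                    "oob_limit": m.oob_limit,
                }
                for m in self.markers
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MarkerPanel":
        return cls(
            tuple(
                MarkerDef(
                    name=m["name"],
                    thresholds=tuple(m["thresholds"]),
                    state_labels=tuple(m["state_labels"]),
                    oob_limit=m.get("oob_limit"),
                )
                for m in d["markers"]
            )
        )


@dataclass
class EventTable:
    """Continuous intensities for one sample: cells x markers."""

    sample_id: str
    values: pd.DataFrame

    @property
    def n_cells(self) -> int:
        return len(self.values)

    @property
    def marker_names(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class StateMatrix:
    """Discretized states for one sample; entry for marker k in ``1..n_k``."""

    sample_id: str
    states: np.ndarray  # (cells, markers) int

    @property
    def n_cells(self) -> int:
        return self.states.shape[0]


# ---------------------------------------------------------------------------
# Gating-threshold table I/O
# ---------------------------------------------------------------------------
# CSV schema: marker,thresholds,oob_limit,state_labels with |-separated lists,
# e.g.  CD4,0.8|2.1,6.0,-|+|++

def read_panel_csv(path: str | Path) -> MarkerPanel:
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"marker", "thresholds"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"gating table {path}: needs columns {sorted(required)}"
        )
    defs = []
    for _, row in df.iterrows():
        thresholds = tuple(float(x) for x in str(row["thresholds"]).split("|") if x)
        labels: tuple[str, ...] = ()
        if "state_labels" in df.columns and row.get("state_labels"):
            labels = tuple(str(row["state_labels"]).split("|"))
        oob = None
        if "oob_limit" in df.columns and row.get("oob_limit"):
            oob = float(row["oob_limit"])
        defs.append(
            MarkerDef(
                name=str(row["marker"]).strip(),
                thresholds=thresholds,
                state_labels=labels,
                oob_limit=oob,
            )
        )
    return MarkerPanel(tuple(defs))


def write_panel_csv(panel: MarkerPanel, path: str | Path) -> None:
    rows = [
        {
            "marker": m.name,
            "thresholds": "|".join(repr(t) for t in m.thresholds),
            "oob_limit": "" if m.oob_limit is None else repr(m.oob_limit),
            "state_labels": "|".join(m.state_labels),
        }
        for m in panel
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Out-of-Bound filter and discretization
# ---------------------------------------------------------------------------

def _check_columns(events: EventTable, panel: MarkerPanel) -> None:
    if events.marker_names != panel.names:
        raise ConfigurationError(
            f"sample {events.sample_id!r}: event columns {events.marker_names} "
            f"do not match panel markers {panel.names}"
        )


def apply_oob_filter(events: EventTable, panel: MarkerPanel) -> EventTable:
    """Drop cells whose intensity strictly exceeds any marker's OOB limit.

    A cell over the ceiling on several channels is still removed exactly once.
    Markers without a limit never trigger removal.
    """
    _check_columns(events, panel)
    limited = [(i, m.oob_limit) for i, m in enumerate(panel) if m.oob_limit is not None]
    if not limited:
        return events
    vals = events.values.to_numpy()
    bad = np.zeros(len(vals), dtype=bool)
    for i, limit in limited:
        bad |= vals[:, i] > limit
    n_removed = int(bad.sum())
    if n_removed:
        log.info(
            "sample %s: OOB filter removed %d of %d cells",
            events.sample_id, n_removed, len(vals),
        )
    return EventTable(events.sample_id, events.values.loc[~bad].reset_index(drop=True))


def discretize_events(events: EventTable, panel: MarkerPanel) -> StateMatrix:
    """Map continuous intensities to 1-based state indices per marker.

    A value below the first threshold is state 1; a value in
    ``[t_j, t_{j+1})`` is state ``j + 1``; a value exactly on a threshold goes
    to the higher state (the gate line belongs to the positive population).
    """
    _check_columns(events, panel)
    vals = events.values.to_numpy(dtype=float)
    if vals.size and not np.isfinite(vals).all():
        r, c = np.argwhere(~np.isfinite(vals))[0]
        raise DataError(
            f"sample {events.sample_id!r}: non-finite intensity at row {r}, "
            f"marker {panel.names[c]!r}"
        )
    states = np.empty(vals.shape, dtype=np.int64)
    for i, m in enumerate(panel):
        # side='right' puts a value equal to a threshold into the higher state
        states[:, i] = np.searchsorted(m.thresholds, vals[:, i], side="right") + 1
    return StateMatrix(events.sample_id, states)


# ---------------------------------------------------------------------------
# Event file I/O: CSV and minimal FCS 3.0/3.1 list mode
# ---------------------------------------------------------------------------

def read_events_csv(path: str | Path, sample_id: str | None = None) -> EventTable:
    """Read a CSV event matrix (header row = marker names)."""
    df = pd.read_csv(path)
    sid = sample_id if sample_id is not None else Path(path).stem
    return EventTable(sid, df)


_FCS_BYTEORD = {"1,2,3,4": "<", "4,3,2,1": ">"}
_FCS_DTYPE = {"F": "f4", "D": "f8", "I": "u"}


def read_fcs(path: str | Path, sample_id: str | None = None) -> EventTable:
    """Read an FCS 3.0/3.1 list-mode file into an :class:`EventTable`.

    Supports the common case: ``$MODE L``, ``$DATATYPE`` F/D/I with uniform
    bit width, little- or big-endian.  Keyword parsing follows the FCS TEXT
    segment rules (single-byte delimiter, doubled delimiters escaped).
    """
    raw = Path(path).read_bytes()
    version = raw[:6].decode("ascii", "replace")
    if not version.startswith("FCS3"):
        raise DataError(f"{path}: unsupported FCS version {version!r}")

    def _offset(lo: int, hi: int) -> int:
        return int(raw[lo:hi].decode("ascii").strip() or 0)

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)

    delim = raw[text_start:text_start + 1].decode("latin-1")
    body = raw[text_start + 1:text_end + 1].decode("latin-1")
    # doubled delimiters escape a literal delimiter inside a value
    parts = [p.replace("\0", delim) for p in body.replace(delim + delim, "\0").split(delim)]
    if parts and parts[-1] == "":
        parts = parts[:-1]
    kw = {k.strip().upper(): v for k, v in zip(parts[::2], parts[1::2])}

    if kw.get("$MODE", "L").upper() != "L":
        raise DataError(f"{path}: only list-mode ($MODE L) FCS is supported")
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    if not data_start:
        data_start = int(kw.get("$BEGINDATA", 0))
        data_end = int(kw.get("$ENDDATA", 0))
    order = _FCS_BYTEORD.get(kw.get("$BYTEORD", "1,2,3,4"))
    if order is None:
        raise DataError(f"{path}: unsupported $BYTEORD {kw.get('$BYTEORD')!r}")
    dtype_code = kw.get("$DATATYPE", "F").upper()
    if dtype_code not in _FCS_DTYPE:
        raise DataError(f"{path}: unsupported $DATATYPE {dtype_code!r}")
    bits = {int(kw[f"$P{i}B"]) for i in range(1, n_par + 1)}
    if len(bits) != 1:
        raise DataError(f"{path}: mixed per-parameter bit widths are unsupported")
    nbytes = bits.pop() // 8
    if dtype_code == "I":
        dt = np.dtype(f"{order}u{nbytes}")
    else:
        dt = np.dtype(f"{order}{_FCS_DTYPE[dtype_code]}")
        if dt.itemsize != nbytes:
            raise DataError(f"{path}: $PnB inconsistent with $DATATYPE")
    names = [
        kw.get(f"$P{i}S") or kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)
    ]
    data = np.frombuffer(raw[data_start:data_end + 1], dtype=dt, count=n_tot * n_par)
    values = pd.DataFrame(
        data.reshape(n_tot, n_par).astype(np.float64), columns=names
    )
    sid = sample_id if sample_id is not None else Path(path).stem
    return EventTable(sid, values)


def write_fcs(events: EventTable, path: str | Path) -> None:
    """Write a minimal single-dataset FCS 3.1 file (float32 list mode)."""
    vals = events.values.to_numpy(dtype=np.float32)
    n_tot, n_par = vals.shape
    kw: dict[str, str] = {
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(events.marker_names, start=1):
        kw[f"$P{i}N"] = str(name)
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = str(int(np.nanmax(vals[:, i - 1], initial=0)) + 1)
    data = vals.astype("<f4").tobytes()

    def render(text_start: int) -> bytes:
        body = "/" + "".join(f"{k}/{v}/" for k, v in kw.items())
        data_start = text_start + len(body)
        return body.encode("latin-1"), data_start

    text_start = 58
    # iterate: BEGIN/ENDDATA lengths can shift the data offset
    for _ in range(3):
        kw["$BEGINDATA"] = str(0)
        body, data_start = render(text_start)
        kw["$BEGINDATA"] = str(data_start)
        kw["$ENDDATA"] = str(data_start + len(data) - 1)
        body, data_start2 = render(text_start)
        if data_start2 == int(kw["$BEGINDATA"]):
            break
        kw["$BEGINDATA"] = str(data_start2)
        kw["$ENDDATA"] = str(data_start2 + len(data) - 1)
    body, data_start = render(text_start)
    text_end = text_start + len(body) - 1
    header = (
        b"FCS3.1    "
        + f"{text_start:8d}{text_end:8d}".encode()
        + f"{data_start:8d}{data_start + len(data) - 1:8d}".encode()
        + f"{0:8d}{0:8d}".encode()
    )
    assert len(header) == 58
    Path(path).write_bytes(header + body + data)


def read_events(path: str | Path, sample_id: str | None = None) -> EventTable:
    """Dispatch on extension: ``.fcs`` -> FCS reader, otherwise CSV."""
    if str(path).lower().endswith(".fcs"):
        return read_fcs(path, sample_id)
    return read_events_csv(path, sample_id)
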