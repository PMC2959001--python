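"""Behavioral event data model and delimited-text I/O.

An operant-chamber experiment is represented as a stream of time-stamped
events, one row per action: a rat pressing the correct or incorrect lever,
opening the reinforcer-cubicle door with or without water present, or a
reinforcer delivery.  Sessions are partitioned into equal-duration segments;
every downstream statistic is computed on per-segment counts.

Event tables are plain :class:`pandas.DataFrame` objects with the columns
``rat_id, strain, session, time_s, event_type`` and are exchanged on disk as
UTF-8 delimited text (comma by default, tab accepted) with exactly that
header.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_TYPES",
    "EVENT_COLUMNS",
    "SessionStructure",
    "EventFileError",
    "assign_segment",
    "read_events",
    "write_events",
    "validate_events",
]

#: The five recognised event types.
EVENT_TYPES = (
    "correct_lever",
    "incorrect_lever",
    "correct_door",
    "incorrect_door",
    "reinforcer",
)

#: Canonical column order of an event table / event file header.
EVENT_COLUMNS = ["rat_id", "strain", "session", "time_s", "event_type"]


class EventFileError(ValueError):
    """Raised when an event file violates the format or an invariant."""


@dataclass(frozen=True)
class SessionStructure:
    """Temporal layout of one experimental session.

    Parameters
    ----------
    session_duration_s
        Total session length in seconds.  Default 5400 s (90 min).
    n_segments
        Number of equal segments the session is divided into.  Default 5,
        i.e. 18-min segments.  Segment ``k`` (0-based) covers the half-open
        interval ``[k*d, (k+1)*d)`` with ``d = session_duration_s/n_segments``;
        an event exactly on a boundary belongs to the later segment.
    """

    session_duration_s: float = 5400.0
    n_segments: int = 5

    def __post_init__(self) -> None:
        if not np.isfinite(self.session_duration_s) or self.session_duration_s <= 0:
            raise ValueError("session_duration_s must be a positive finite number")
        if int(self.n_segments) != self.n_segments or self.n_segments < 1:
            raise ValueError("n_segments must be a positive integer")

    @property
    def segment_duration_s(self) -> float:
        return self.session_duration_s / self.n_segments

    def segment_edges(self) -> np.ndarray:
        """Boundaries of the segments, length ``n_segments + 1``."""
        return np.linspace(0.0, self.session_duration_s, self.n_segments + 1)


def assign_segment(time_s, structure: SessionStructure | None = None):
    """Map a time (seconds from session start) to its 0-based segment index.

    Accepts a scalar or array.  Times must lie in
    ``[0, session_duration_s)``; the partition is half-open, so a time
    exactly at a segment boundary maps to the later segment.
    """
    structure = structure or SessionStructure()
    t = np.asarray(time_s, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t < 0) or np.any(t >= structure.session_duration_s):
        raise ValueError(
            f"time_s must lie in [0, {structure.session_duration_s}); got {time_s!r}"
        )
    seg = np.floor(t / structure.segment_duration_s).astype(int)
    # guard against float round-off at the top edge
    seg = np.minimum(seg, structure.n_segments - 1)
    return seg if seg.ndim else int(seg)


def _sniff_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def validate_events(events: pd.DataFrame, structure: SessionStructure | None = None,
                    *, line_offset: int = 0) -> pd.DataFrame:
    """Validate an in-memory event table against the data-model invariants.

    Returns the table sorted by ``(rat_id, session, time_s)`` with ties broken
    by original row order (stable sort).  Raises :class:`EventFileError`
    naming the first offending line (``line_offset`` + 0-based row + 1) and
    field.
    """
    structure = structure or SessionStructure()
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise EventFileError(f"missing required column(s): {', '.join(missing)}")
    ev = events.loc[:, EVENT_COLUMNS].reset_index(drop=True)

    def bad(mask: pd.Series, fieldname: str, why: str):
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0])
            raise EventFileError(
                f"line {line_offset + row + 1}: field '{fieldname}' {why} "
                f"(value: {ev.iloc[row][fieldname]!r})"
            )

    time = pd.to_numeric(ev["time_s"], errors="coerce")
    bad(time.isna() | ~np.isfinite(time), "time_s", "is not a finite number")
    bad(time < 0, "time_s", "is negative")
    bad(
        time >= structure.session_duration_s,
        "time_s",
        f"is outside the session [0, {structure.session_duration_s}) (half-open)",
    )
    ev["time_s"] = time.astype(float)

    session = pd.to_numeric(ev["session"], errors="coerce")
    bad(session.isna() | (session != session.round()) | (session < 1),
        "session", "must be an integer >= 1")
    ev["session"] = session.astype(int)

    bad(~ev["event_type"].isin(EVENT_TYPES), "event_type",
        f"must be one of {EVENT_TYPES}")

    ev["rat_id"] = ev["rat_id"].astype(str)
    ev["strain"] = ev["strain"].astype(str)
    bad(ev["rat_id"].str.len() == 0, "rat_id", "must be non-empty")

    # one strain label per rat
    n_strains = ev.groupby("rat_id")["strain"].nunique()
    if (n_strains > 1).any():
        offender = n_strains[n_strains > 1].index[0]
        raise EventFileError(f"rat {offender!r} appears with more than one strain label")

    ev = ev.sort_values(["rat_id", "session", "time_s"], kind="stable")
    return ev.reset_index(drop=True)


def read_events(path, structure: SessionStructure | None = None,
                delimiter: str | None = None) -> pd.DataFrame:
    """Read and validate an event file.

    The file must carry the header ``rat_id,strain,session,time_s,event_type``
    (any column order).  Rows violating an invariant raise
    :class:`EventFileError` naming the line number and field.  The returned
    table is sorted by ``(rat_id, session, time_s)``, ties kept in file order.
    """
    delimiter = delimiter or _sniff_delimiter(path)
    try:
        raw = pd.read_csv(path, sep=delimiter, dtype={"rat_id": str, "strain": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise EventFileError(f"could not parse {path}: {exc}") from exc
    # header is line 1, first data row is line 2
    return validate_events(raw, structure, line_offset=1)


def write_events(events: pd.DataFrame, path, delimiter: str = ",",
                 decimals: int = 4) -> None:
    """Write an event table as delimited text.

    Times are printed with ``decimals`` decimal places (default 4); a table
    whose times are already rounded to that precision round-trips exactly
    through :func:`read_events`.
    """
    out = events.loc[:, EVENT_COLUMNS]
    out.to_csv(path, sep=delimiter, index=False,
               float_format=f"%.{decimals}f")
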