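"""Domain types and tabular I/O for smoking-topography pipelines.

The pipeline observes a smoking session through three instruments: a wrist-worn
3-axis accelerometer sampled on a uniform grid (:class:`AccelTrace`), a
mouthpiece topography device that logs one record per detected puff
(:class:`CressLog`), and human annotation of video (per-hand visual puff
counts stored on :class:`SessionMeta`).  Everything downstream is expressed in
integer-friendly milliseconds since session start, with puff intervals treated
as half-open ``[start_ms, end_ms)`` so that puff duration is exactly
``end_ms - start_ms`` and adjacency is unambiguous.

All readers/writers use plain comma-separated UTF-8 text with one header row;
each reader/writer pair is a lossless round trip on valid inputs.  Type
invariants are enforced at construction time: invalid data raises
:class:`ValidationError` rather than being silently coerced.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "ParseError",
    "ConfigurationError",
    "HANDS",
    "SOURCES",
    "AccelTrace",
    "PuffEvent",
    "validate_events",
    "TopographySeries",
    "CressRecord",
    "CressLog",
    "SessionMeta",
    "ProtocolSegment",
    "ProtocolSchedule",
    "samples_to_ms",
    "read_accel_table",
    "write_accel_table",
    "read_cress_table",
    "write_cress_table",
    "read_events",
    "write_events",
    "read_session_meta",
    "write_session_meta",
]


class ValidationError(ValueError):
    """An in-memory object violates a domain invariant."""


class ParseError(ValueError):
    """A file could not be parsed into a domain object."""


class ConfigurationError(ValueError):
    """A configuration is internally inconsistent or infeasible."""


HANDS = ("left", "right", "unknown")
SOURCES = ("aspire", "cress", "cress_corrected", "truth")

#: Spacing slack (ms) allowed on top of the 5% rate tolerance, to absorb the
#: 33/34 ms alternation that integer timestamps produce at 30 Hz.
_SPACING_SLACK_MS = 1.5


def samples_to_ms(n_samples: int, sampling_rate: float) -> int:
    """Convert a sample count to milliseconds at a known sampling rate.

    Returns ``n_samples * 1000 / sampling_rate`` rounded half-up to the
    nearest integer millisecond.  Monotone non-decreasing in ``n_samples``
    and exactly linear before rounding.
    """
    if n_samples < 0:
        raise ValidationError(f"n_samples must be >= 0, got {n_samples}")
    if sampling_rate <= 0:
        raise ValidationError(f"sampling_rate must be > 0, got {sampling_rate}")
    return int(math.floor(n_samples * 1000.0 / sampling_rate + 0.5))


# ---------------------------------------------------------------------------
# core observables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AccelTrace:
    """Uniformly sampled 3-axis acceleration, timestamps in ms since start.

    ``t_ms`` must be strictly increasing with spacing consistent with
    ``sampling_rate`` (within 5% plus ~1 ms integer-rounding slack); the axis
    arrays hold acceleration in m/s² and must be finite.
    """

    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sampling_rate: float = 30.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "t_ms", np.asarray(self.t_ms, dtype=np.int64))
        for name in ("x", "y", "z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t_ms)
        for name in ("x", "y", "z"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValidationError(
                    f"axis {name!r} has length {len(arr)}, expected {n}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"axis {name!r} contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be > 0")
        if n >= 2:
            gaps = np.diff(self.t_ms)
            if np.any(gaps <= 0):
                bad = int(np.argmax(gaps <= 0))
                raise ValidationError(
                    f"timestamps not strictly increasing at sample {bad + 1} "
                    f"(t={self.t_ms[bad + 1]} after t={self.t_ms[bad]})"
                )
            period = 1000.0 / self.sampling_rate
            tol = max(0.05 * period, _SPACING_SLACK_MS)
            off = np.abs(gaps - period)
            if np.any(off > tol):
                bad = int(np.argmax(off > tol))
                raise ValidationError(
                    f"non-uniform spacing at sample {bad + 1}: gap {gaps[bad]} ms "
                    f"vs expected {period:.2f} ms (tolerance {tol:.2f} ms)"
                )

    @property
    def n_samples(self) -> int:
        return len(self.t_ms)

    @property
    def duration_ms(self) -> int:
        if self.n_samples == 0:
            return 0
        return int(self.t_ms[-1] - self.t_ms[0]) + samples_to_ms(1, self.sampling_rate)


@dataclass(frozen=True, order=True)
class PuffEvent:
    """One puff as a half-open interval ``[start_ms, end_ms)`` with hand label."""

    start_ms: int
    end_ms: int
    hand: str = "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "start_ms", int(self.start_ms))
        object.__setattr__(self, "end_ms", int(self.end_ms))
        if self.start_ms >= self.end_ms:
            raise ValidationError(
                f"puff start {self.start_ms} must precede end {self.end_ms}"
            )
        if self.hand not in HANDS:
            raise ValidationError(f"hand must be one of {HANDS}, got {self.hand!r}")

    @property
    def duration_ms(self) -> int:
        return self.end_ms - self.start_ms

    @property
    def mid_ms(self) -> float:
        return 0.5 * (self.start_ms + self.end_ms)


def validate_events(events: Sequence[PuffEvent]) -> None:
    """Check that a session's event list is sorted and non-overlapping."""
    for i in range(len(events) - 1):
        if events[i].start_ms > events[i + 1].start_ms:
            raise ValidationError(
                f"events not sorted by start: index {i} starts at "
                f"{events[i].start_ms}, index {i + 1} at {events[i + 1].start_ms}"
            )
        if events[i].end_ms > events[i + 1].start_ms:
            raise ValidationError(
                f"events {i} and {i + 1} overlap "
                f"({events[i].end_ms} > {events[i + 1].start_ms})"
            )


@dataclass(frozen=True)
class TopographySeries:
    """Per-session puff durations and interpuff intervals, in ms.

    ``source`` records provenance: the watch pipeline (``aspire``), the raw
    mouthpiece log (``cress``), the corrected log (``cress_corrected``), or
    simulator ground truth (``truth``).  When derived from one continuous
    event list, ``len(ipi_ms) == max(0, len(pd_ms) - 1)``; a raw device series
    that retains the leading device-on interval may instead have equal
    lengths, so that relation is not enforced here.
    """

    pd_ms: tuple
    ipi_ms: tuple
    source: str = "aspire"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pd_ms", tuple(float(v) for v in self.pd_ms))
        object.__setattr__(self, "ipi_ms", tuple(float(v) for v in self.ipi_ms))
        if self.source not in SOURCES:
            raise ValidationError(f"source must be one of {SOURCES}, got {self.source!r}")
        if any(not math.isfinite(v) or v <= 0 for v in self.pd_ms):
            raise ValidationError("all pd_ms must be finite and > 0")
        if any(not math.isfinite(v) or v < 0 for v in self.ipi_ms):
            raise ValidationError("all ipi_ms must be finite and >= 0")

    @property
    def n_puffs(self) -> int:
        return len(self.pd_ms)


@dataclass(frozen=True)
class CressRecord:
    """One per-puff record mirroring the mouthpiece device's detailed view.

    ``ipi_ms`` is the interval *preceding* the puff; the first record's
    interval spans device power-on to the first puff.  Flow and volume fields
    are carried opaquely (units as exported by the device) and may be absent.
    """

    pd_ms: float
    ipi_ms: float
    puff_volume_ml: Optional[float] = None
    avg_flow: Optional[float] = None
    peak_flow: Optional[float] = None
    time_of_peak_flow_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.pd_ms) or self.pd_ms <= 0:
            raise ValidationError(f"pd_ms must be finite and > 0, got {self.pd_ms}")
        if not math.isfinite(self.ipi_ms) or self.ipi_ms < 0:
            raise ValidationError(f"ipi_ms must be finite and >= 0, got {self.ipi_ms}")


@dataclass(frozen=True)
class CressLog:
    """Ordered per-puff records from one mouthpiece-device session."""

    records: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        for rec in self.records:
            if not isinstance(rec, CressRecord):
                raise ValidationError("CressLog entries must be CressRecord instances")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass(frozen=True)
class SessionMeta:
    """Per-participant bookkeeping: visual counts and recording completeness."""

    participant_id: str
    visual_puff_count_left: Optional[int] = None
    visual_puff_count_right: Optional[int] = None
    complete_aspire: bool = True
    complete_cress: bool = True

    def __post_init__(self) -> None:
        for name in ("visual_puff_count_left", "visual_puff_count_right"):
            v = getattr(self, name)
            if v is not None:
                if int(v) < 0:
                    raise ValidationError(f"{name} must be >= 0, got {v}")
                object.__setattr__(self, name, int(v))

    @property
    def visual_puff_count_total(self) -> Optional[int]:
        left, right = self.visual_puff_count_left, self.visual_puff_count_right
        if left is None and right is None:
            return None
        return (left or 0) + (right or 0)


# ---------------------------------------------------------------------------
# protocol schedule
# ---------------------------------------------------------------------------

ActivityLabel = Literal["rest", "smoking_left", "smoking_right", "packing", "other_movement"]


class ProtocolSegment(BaseModel):
    """One timed activity block of the laboratory protocol."""

    model_config = ConfigDict(frozen=True)

    activity: ActivityLabel
    duration_s: float = Field(gt=0)


class ProtocolSchedule(BaseModel):
    """Ordered activity segments making up one laboratory session."""

    model_config = ConfigDict(frozen=True)

    segments: tuple[ProtocolSegment, ...] = Field(min_length=1)

    @property
    def total_s(self) -> float:
        return sum(s.duration_s for s in self.segments)

    def windows_ms(self) -> list[tuple[str, int, int]]:
        """Return ``(activity, start_ms, end_ms)`` for each segment."""
        out = []
        t = 0.0
        for seg in self.segments:
            t1 = t + seg.duration_s * 1000.0
            out.append((seg.activity, int(round(t)), int(round(t1))))
            t = t1
        return out

    def smoking_window_ms(self, hand: str) -> tuple[int, int]:
        """Window (ms) of the smoking segment performed with ``hand``."""
        label = f"smoking_{hand}"
        for activity, a, b in self.windows_ms():
            if activity == label:
                return a, b
        raise ValidationError(f"schedule has no segment {label!r}")


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

_TIME_ALIASES = ("t_ms", "time_ms", "t", "time")


def _numeric_column(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.index[vals.isna() & df[col].notna()]
    if len(bad) > 0:
        # +2: header row plus 1-based numbering
        raise ParseError(
            f"{path}: malformed value {df[col].iloc[bad[0]]!r} in column "
            f"{col!r} at line {int(bad[0]) + 2}"
        )
    if vals.isna().any():
        bad0 = int(vals.index[vals.isna()][0])
        raise ParseError(f"{path}: missing value in column {col!r} at line {bad0 + 2}")
    return vals.to_numpy()


def read_accel_table(path, sampling_rate: Optional[float] = None) -> AccelTrace:
    """Read an accelerometer trace from CSV (columns ``t_ms,x,y,z``).

    Rows are re-sorted by time.  When ``sampling_rate`` is omitted it is
    inferred from the median inter-sample gap (rounded to the nearest integer
    rate).  Non-uniform spacing or duplicate timestamps raise
    :class:`ValidationError`; malformed cells raise :class:`ParseError`
    naming the offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"{path}: {exc}") from exc
    cols = {c.strip().lower(): c for c in df.columns}
    tcol = next((cols[a] for a in _TIME_ALIASES if a in cols), None)
    if tcol is None or not all(a in cols for a in ("x", "y", "z")):
        raise ParseError(
            f"{path}: header must name a time column ({'/'.join(_TIME_ALIASES)}) "
            f"and x, y, z; got {list(df.columns)}"
        )
    t = _numeric_column(df, tcol, path)
    x = _numeric_column(df, cols["x"], path)
    y = _numeric_column(df, cols["y"], path)
    z = _numeric_column(df, cols["z"], path)
    order = np.argsort(t, kind="stable")
    t, x, y, z = t[order], x[order], y[order], z[order]
    if sampling_rate is None:
        if len(t) < 2:
            sampling_rate = 30.0
        else:
            med_gap = float(np.median(np.diff(t)))
            if med_gap <= 0:
                raise ValidationError(f"{path}: duplicate timestamps")
            sampling_rate = max(1.0, float(round(1000.0 / med_gap)))
    return AccelTrace(t_ms=t, x=x, y=y, z=z, sampling_rate=sampling_rate)


def write_accel_table(trace: AccelTrace, path) -> None:
    df = pd.DataFrame(
        {"t_ms": trace.t_ms, "x": trace.x, "y": trace.y, "z": trace.z}
    )
    df.to_csv(path, index=False)


_CRESS_REQUIRED = ("pd_ms", "ipi_ms")
_CRESS_OPTIONAL = ("puff_volume_ml", "avg_flow", "peak_flow", "time_of_peak_flow_ms")


def read_cress_table(path) -> CressLog:
    """Read a mouthpiece-device log from CSV.

    Requires ``pd_ms`` and ``ipi_ms`` columns; volume/flow columns are
    optional and a warning is logged when they are absent.  An empty data
    section yields an empty log (with a warning).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    cols = {c.strip().lower(): c for c in df.columns}
    missing = [c for c in _CRESS_REQUIRED if c not in cols]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    absent = [c for c in _CRESS_OPTIONAL if c not in cols]
    if absent:
        logger.warning("%s: optional columns absent: %s", path, ", ".join(absent))
    if len(df) == 0:
        logger.warning("%s: empty data section, returning empty log", path)
        return CressLog(records=())
    if "puff_index" in cols:
        df = df.sort_values(cols["puff_index"], kind="stable").reset_index(drop=True)
    data = {}
    for c in _CRESS_REQUIRED:
        data[c] = _numeric_column(df, cols[c], path)
    for c in _CRESS_OPTIONAL:
        if c in cols:
            vals = pd.to_numeric(df[cols[c]], errors="coerce").to_numpy()
            data[c] = [None if not math.isfinite(v) else float(v) for v in vals]
        else:
            data[c] = [None] * len(df)
    records = []
    for i in range(len(df)):
        if data["pd_ms"][i] <= 0:
            raise ValidationError(
                f"{path}: non-positive pd_ms at line {i + 2}: {data['pd_ms'][i]}"
            )
        records.append(
            CressRecord(
                pd_ms=float(data["pd_ms"][i]),
                ipi_ms=float(data["ipi_ms"][i]),
                puff_volume_ml=data["puff_volume_ml"][i],
                avg_flow=data["avg_flow"][i],
                peak_flow=data["peak_flow"][i],
                time_of_peak_flow_ms=data["time_of_peak_flow_ms"][i],
            )
        )
    return CressLog(records=tuple(records))


def write_cress_table(log: CressLog, path) -> None:
    rows = []
    for i, rec in enumerate(log):
        rows.append(
            {
                "puff_index": i,
                "puff_volume_ml": rec.puff_volume_ml,
                "avg_flow": rec.avg_flow,
                "peak_flow": rec.peak_flow,
                "time_of_peak_flow_ms": rec.time_of_peak_flow_ms,
                "pd_ms": rec.pd_ms,
                "ipi_ms": rec.ipi_ms,
            }
        )
    cols = ["puff_index", "puff_volume_ml", "avg_flow", "peak_flow",
            "time_of_peak_flow_ms", "pd_ms", "ipi_ms"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_events(path) -> list[PuffEvent]:
    """Read a puff-event list from CSV (columns ``start_ms,end_ms,hand``)."""
    path = Path(path)
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    for c in ("start_ms", "end_ms"):
        if c not in cols:
            raise ParseError(f"{path}: missing column {c!r}")
    if len(df) == 0:
        return []
    starts = _numeric_column(df, cols["start_ms"], path)
    ends = _numeric_column(df, cols["end_ms"], path)
    hands = df[cols["hand"]].astype(str) if "hand" in cols else ["unknown"] * len(df)
    events = [
        PuffEvent(int(s), int(e), h) for s, e, h in zip(starts, ends, hands)
    ]
    validate_events(events)
    return events


def write_events(events: Sequence[PuffEvent], path) -> None:
    """Write a puff-event list to CSV; overlapping events are rejected."""
    validate_events(list(events))
    df = pd.DataFrame(
        {
            "start_ms": [e.start_ms for e in events],
            "end_ms": [e.end_ms for e in events],
            "hand": [e.hand for e in events],
        }
    )
    df.to_csv(path, index=False)


_META_COLS = [
    "participant_id",
    "visual_puff_count_left",
    "visual_puff_count_right",
    "complete_aspire",
    "complete_cress",
]


def write_session_meta(metas: Sequence[SessionMeta], path) -> None:
    df = pd.DataFrame(
        [
            {
                "participant_id": m.participant_id,
                "visual_puff_count_left": m.visual_puff_count_left,
                "visual_puff_count_right": m.visual_puff_count_right,
                "complete_aspire": m.complete_aspire,
                "complete_cress": m.complete_cress,
            }
            for m in metas
        ],
        columns=_META_COLS,
    )
    df.to_csv(path, index=False)


def read_session_meta(path) -> list[SessionMeta]:
    path = Path(path)
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "participant_id" not in cols:
        raise ParseError(f"{path}: missing column 'participant_id'")
    metas = []
    for _, row in df.iterrows():
        def _opt_int(name):
            if name not in cols:
                return None
            v = row[cols[name]]
            return None if pd.isna(v) else int(v)

        def _flag(name):
            if name not in cols:
                return True
            v = row[cols[name]]
            if isinstance(v, str):
                return v.strip().lower() in ("true", "1", "yes")
            return bool(v)

        metas.append(
            SessionMeta(
                participant_id=str(row[cols["participant_id"]]),
                visual_puff_count_left=_opt_int("visual_puff_count_left"),
                visual_puff_count_right=_opt_int("visual_puff_count_right"),
                complete_aspire=_flag("complete_aspire"),
                complete_cress=_flag("complete_cress"),
            )
        )
    return metas
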