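"""Puff detection in wrist accelerometer traces.

Operationalises the annotation signature used for hand-to-mouth smoking
gestures: from a per-session resting pose, a puff onset is a simultaneous
drop of the y axis by ~4 m/s² and the z axis by ~8 m/s² (the x change is
negligible and is ignored), followed by an equilibrated plateau while the
cigarette is held at the mouth, and ending with a return of all axes to the
resting state.

The detector is a hysteresis state machine on smoothed signals:

* onset: first sample where the smoothed y/z drops exceed
  ``onset_fraction`` of the nominal deltas (default half-amplitude);
* plateau check: within the supra-threshold region there must be a
  contiguous run of at least ``min_plateau_ms`` in which smoothed y and z
  stay within ``plateau_tolerance`` of the region's running plateau
  estimate (its median);
* offset: first sample where the drops recover below the onset thresholds
  (the symmetric half-amplitude crossing), confirmed by the signal holding
  inside ``offset_return_tolerance`` of rest for at least ``min_return_ms``.

Half-amplitude boundaries on both edges make the measured puff duration
independent of the transition-ramp length.  Rapid re-onsets occurring before
the rest hold completes are merged into one event — mouthpiece devices report
such rapid multi-puffs, but neither the wrist signal nor video can separate
them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .session_model import (
    AccelTrace,
    PuffEvent,
    ValidationError,
    samples_to_ms,
    validate_events,
)

__all__ = [
    "SegmentationParams",
    "RestingPose",
    "estimate_resting_pose",
    "detect_puffs",
    "MatchResult",
    "match_events",
    "restrict_to_window",
]


class SegmentationParams(BaseModel):
    """Tunables of the gesture detector (accelerations in m/s², times in ms)."""

    model_config = ConfigDict(frozen=True)

    baseline_window_s: float = Field(default=30.0, gt=0)
    onset_fraction: float = Field(default=0.5, gt=0, le=1)
    onset_delta_y: float = Field(default=4.0, gt=0)
    onset_delta_z: float = Field(default=8.0, gt=0)
    plateau_tolerance: float = Field(default=1.5, gt=0)
    min_plateau_ms: float = Field(default=500.0, gt=0)
    offset_return_tolerance: float = Field(default=1.5, gt=0)
    min_return_ms: float = Field(default=300.0, gt=0)
    smoothing_window_samples: int = Field(default=5, ge=1)


@dataclass(frozen=True)
class RestingPose:
    """Per-session baseline wrist orientation and its per-axis dispersion."""

    x: float
    y: float
    z: float
    dispersion: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for v in (self.x, self.y, self.z):
            if not math.isfinite(v):
                raise ValidationError("resting pose must be finite")
        if any(d < 0 for d in self.dispersion):
            raise ValidationError("dispersion must be >= 0")


def _smooth(arr: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return np.asarray(arr, dtype=float)
    return (
        pd.Series(arr).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def estimate_resting_pose(trace: AccelTrace, params: SegmentationParams) -> RestingPose:
    """Estimate the resting pose from the lowest-motion baseline window.

    Finds the window of length ``baseline_window_s`` minimising the summed
    per-axis rolling variance, then reports per-axis medians as the pose and
    per-axis median absolute deviations as dispersion.  A session that is one
    long plateau will lock onto the plateau — unguarded by design, but not a
    realistic shape for the 20-minute protocol.
    """
    w = int(round(params.baseline_window_s * trace.sampling_rate))
    if trace.n_samples < w or w < 2:
        raise ValidationError(
            f"trace ({trace.n_samples} samples) shorter than baseline window ({w})"
        )
    axes = np.stack([trace.x, trace.y, trace.z])
    total_var = np.zeros(trace.n_samples - w + 1)
    for ax in axes:
        s = pd.Series(ax).rolling(w).var().to_numpy()[w - 1:]
        total_var += s
    start = int(np.argmin(total_var))
    sl = slice(start, start + w)
    med = np.median(axes[:, sl], axis=1)
    mad = np.median(np.abs(axes[:, sl] - med[:, None]), axis=1)
    return RestingPose(
        x=float(med[0]), y=float(med[1]), z=float(med[2]),
        dispersion=(float(mad[0]), float(mad[1]), float(mad[2])),
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open (start, stop) index pairs."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def _longest_tolerated_run(values: list[np.ndarray], tol: float) -> int:
    """Longest contiguous run (samples) where every series stays within tol
    of its own median."""
    ok = np.ones(len(values[0]), dtype=bool)
    for v in values:
        ok &= np.abs(v - np.median(v)) <= tol
    runs = _runs(ok)
    return max((b - a for a, b in runs), default=0)


def _rest_confirmed(
    rest_runs: list[tuple[int, int]], j: int, nxt: Optional[int], min_ret: int
) -> bool:
    for a, b in rest_runs:
        if a < j:
            continue
        if nxt is not None and a >= nxt:
            break
        stop = b if nxt is None else min(b, nxt)
        if stop - a >= min_ret:
            return True
    return False


def detect_puffs(
    trace: AccelTrace, pose: RestingPose, params: SegmentationParams
) -> list[PuffEvent]:
    """Detect puff events in a trace given the session's resting pose.

    Returns sorted, non-overlapping events, each at least ``min_plateau_ms``
    long; an empty list when nothing matches the gesture signature.
    """
    w = params.smoothing_window_samples
    xs, ys, zs = (_smooth(a, w) for a in (trace.x, trace.y, trace.z))
    dy = pose.y - ys
    dz = pose.z - zs
    f = params.onset_fraction
    on = (dy >= f * params.onset_delta_y) & (dz >= f * params.onset_delta_z)
    tol_r = params.offset_return_tolerance
    at_rest = (
        (np.abs(xs - pose.x) <= tol_r)
        & (np.abs(ys - pose.y) <= tol_r)
        & (np.abs(zs - pose.z) <= tol_r)
    )
    period_ms = 1000.0 / trace.sampling_rate
    min_plat = max(1, math.ceil(params.min_plateau_ms / period_ms))
    min_ret = max(1, math.ceil(params.min_return_ms / period_ms))

    on_runs = _runs(on)
    rest_runs = _runs(at_rest)
    events: list[PuffEvent] = []
    k = 0
    n_runs = len(on_runs)
    n = trace.n_samples
    while k < n_runs:
        i = on_runs[k][0]
        m = k
        while True:
            j = on_runs[m][1]
            nxt = on_runs[m + 1][0] if m + 1 < n_runs else None
            if nxt is None or _rest_confirmed(rest_runs, j, nxt, min_ret):
                break
            m += 1
        j = on_runs[m][1]
        plateau_run = _longest_tolerated_run(
            [ys[i:j], zs[i:j]], params.plateau_tolerance
        )
        if plateau_run >= min_plat:
            start_ms = int(trace.t_ms[i])
            end_ms = (
                int(trace.t_ms[j])
                if j < n
                else int(trace.t_ms[-1]) + samples_to_ms(1, trace.sampling_rate)
            )
            events.append(PuffEvent(start_ms, end_ms, "unknown"))
        k = m + 1
    validate_events(events)
    return events


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching detected events against truth events."""

    true_positives: int
    false_positives: int
    misses: int
    pairs: tuple  # (detected_index, truth_index)

    @property
    def precision(self) -> float:
        d = self.true_positives + self.false_positives
        return self.true_positives / d if d else float("nan")

    @property
    def recall(self) -> float:
        d = self.true_positives + self.misses
        return self.true_positives / d if d else float("nan")

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if not (p == p and r == r) or p + r == 0:  # NaN-safe
            return 0.0
        return 2 * p * r / (p + r)


def match_events(
    detected: Sequence[PuffEvent],
    truth: Sequence[PuffEvent],
    max_offset_ms: float,
) -> MatchResult:
    """Greedy one-to-one matching of detections to truth by midpoint distance.

    Candidate pairs with midpoint distance <= ``max_offset_ms`` are assigned
    in order of increasing distance; the resulting true-positive /
    false-positive / miss counts partition both lists.
    """
    validate_events(list(detected))
    validate_events(list(truth))
    cands = []
    for di, d in enumerate(detected):
        for ti, t in enumerate(truth):
            dist = abs(d.mid_ms - t.mid_ms)
            if dist <= max_offset_ms:
                cands.append((dist, di, ti))
    cands.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    pairs = []
    for _, di, ti in cands:
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        pairs.append((di, ti))
    tp = len(pairs)
    return MatchResult(
        true_positives=tp,
        false_positives=len(detected) - tp,
        misses=len(truth) - tp,
        pairs=tuple(sorted(pairs)),
    )


def restrict_to_window(
    events: Sequence[PuffEvent], window_start_ms: int, window_end_ms: int
) -> list[PuffEvent]:
    """Keep events lying fully inside ``[window_start_ms, window_end_ms)``.

    Events straddling a boundary are dropped, not truncated.
    """
    if window_start_ms >= window_end_ms:
        raise ValidationError("window_start_ms must precede window_end_ms")
    return [
        e
        for e in events
        if e.start_ms >= window_start_ms and e.end_ms <= window_end_ms
    ]
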