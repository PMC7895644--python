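"""Topography series and summary statistics from puff-event lists.

Puff duration (PD) is the time a smoker inhales in one intake; the interpuff
interval (IPI) runs from the end of one puff to the beginning of the next.
For a continuous event list the two series tile the session exactly:
``sum(PD) + sum(IPI) = last end - first start``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .session_model import (
    CressLog,
    PuffEvent,
    TopographySeries,
    ValidationError,
    validate_events,
)

__all__ = [
    "TopographySummary",
    "events_to_topography",
    "cress_to_topography",
    "summarize",
    "histogram",
    "DEFAULT_PD_BIN_MS",
    "DEFAULT_IPI_BIN_MS",
]

#: Default histogram bin widths (ms) for pooled PD / IPI distributions.
DEFAULT_PD_BIN_MS = 250.0
DEFAULT_IPI_BIN_MS = 2000.0


@dataclass(frozen=True)
class TopographySummary:
    """Session-level summary of a topography series.

    ``total_smoking_ms`` spans first puff start to last puff end (i.e.
    ``sum(PD) + sum(IPI)`` for a continuous series); ``total_puffing_ms`` is
    the summed puff time only.  Statistics are ``None`` where undefined
    (empty series; single-value standard deviations).
    """

    n_puffs: int
    median_pd_ms: Optional[float]
    mean_pd_ms: Optional[float]
    sd_pd_ms: Optional[float]
    median_ipi_ms: Optional[float]
    mean_ipi_ms: Optional[float]
    sd_ipi_ms: Optional[float]
    total_smoking_ms: float
    total_puffing_ms: float

    def __post_init__(self) -> None:
        if self.n_puffs < 0:
            raise ValidationError("n_puffs must be >= 0")
        if self.total_puffing_ms > self.total_smoking_ms + 1e-9:
            raise ValidationError("total_puffing_ms cannot exceed total_smoking_ms")

    def to_dict(self) -> dict:
        return {
            "n_puffs": self.n_puffs,
            "median_pd_ms": self.median_pd_ms,
            "mean_pd_ms": self.mean_pd_ms,
            "sd_pd_ms": self.sd_pd_ms,
            "median_ipi_ms": self.median_ipi_ms,
            "mean_ipi_ms": self.mean_ipi_ms,
            "sd_ipi_ms": self.sd_ipi_ms,
            "total_smoking_ms": self.total_smoking_ms,
            "total_puffing_ms": self.total_puffing_ms,
        }


def events_to_topography(
    events: Sequence[PuffEvent], source: str = "aspire"
) -> TopographySeries:
    """Convert an ordered event list to PD/IPI series.

    ``pd_ms[i] = end[i] - start[i]``; ``ipi_ms[i] = start[i+1] - end[i]``;
    ``len(ipi_ms) == max(0, len(pd_ms) - 1)``.
    """
    events = list(events)
    validate_events(events)
    pds = [float(e.duration_ms) for e in events]
    ipis = [
        float(events[i + 1].start_ms - events[i].end_ms)
        for i in range(len(events) - 1)
    ]
    return TopographySeries(pd_ms=pds, ipi_ms=ipis, source=source)


def cress_to_topography(log: CressLog, drop_leading_ipi: bool = True) -> TopographySeries:
    """Convert a mouthpiece log to PD/IPI series.

    Each record's ``ipi_ms`` precedes its puff, so record 1 carries the
    device-on→first-puff interval; with ``drop_leading_ipi`` (the default)
    that interval is excluded and the IPI list holds the true inter-puff
    gaps of records ``2..n``.
    """
    pds = [rec.pd_ms for rec in log]
    ipis = [rec.ipi_ms for rec in log]
    if drop_leading_ipi and ipis:
        ipis = ipis[1:]
    return TopographySeries(pd_ms=pds, ipi_ms=ipis, source="cress")


def _stats(values: Sequence[float]) -> tuple[Optional[float], Optional[float], Optional[float]]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return None, None, None
    med = float(np.median(arr))
    mean = float(np.mean(arr))
    sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else None
    return med, mean, sd


def summarize(series: TopographySeries) -> TopographySummary:
    """Session-level medians, means, SDs and totals of a topography series."""
    med_pd, mean_pd, sd_pd = _stats(series.pd_ms)
    med_ipi, mean_ipi, sd_ipi = _stats(series.ipi_ms)
    total_puffing = float(sum(series.pd_ms))
    total_smoking = total_puffing + float(sum(series.ipi_ms))
    return TopographySummary(
        n_puffs=series.n_puffs,
        median_pd_ms=med_pd,
        mean_pd_ms=mean_pd,
        sd_pd_ms=sd_pd,
        median_ipi_ms=med_ipi,
        mean_ipi_ms=mean_ipi,
        sd_ipi_ms=sd_ipi,
        total_smoking_ms=total_smoking,
        total_puffing_ms=total_puffing,
    )


def histogram(
    values: Sequence[float],
    bin_width_ms: float,
    value_range: Optional[tuple[float, float]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Left-closed right-open histogram, returning ``(edges, counts)``.

    When ``value_range`` is omitted the bins start at 0 and extend to cover
    the data.  Counts always sum to the number of input values; values
    outside an explicit range raise :class:`ValidationError` rather than
    being silently dropped.
    """
    if bin_width_ms <= 0:
        raise ValidationError("bin_width_ms must be > 0")
    arr = np.asarray(values, dtype=float)
    if value_range is None:
        lo = 0.0
        hi = float(arr.max()) + bin_width_ms if arr.size else bin_width_ms
    else:
        lo, hi = map(float, value_range)
        if lo >= hi:
            raise ValidationError("range lower bound must precede upper bound")
    n_bins = max(1, math.ceil((hi - lo) / bin_width_ms - 1e-9))
    edges = lo + bin_width_ms * np.arange(n_bins + 1)
    if arr.size == 0:
        return edges, np.zeros(n_bins, dtype=int)
    idx = np.floor((arr - lo) / bin_width_ms).astype(int)
    if (idx < 0).any() or (idx >= n_bins).any():
        bad = arr[(idx < 0) | (idx >= n_bins)][0]
        raise ValidationError(
            f"value {bad} outside histogram range [{lo}, {edges[-1]})"
        )
    counts = np.bincount(idx, minlength=n_bins)
    return edges, counts
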