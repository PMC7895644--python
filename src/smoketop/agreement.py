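"""Method-agreement statistics between watch, mouthpiece, and visual counts.

Per participant, individual puff durations and interpuff intervals from two
sources are paired by puff index (truncating to the shorter list — no
alignment is attempted) and compared via the squared Pearson correlation.
Pooled, the per-participant medians are correlated across the cohort, and
puff counts are compared to visual counts via the concordance-within-±tol
proportion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .session_model import SessionMeta, TopographySeries, ValidationError
from .topography import summarize

logger = logging.getLogger(__name__)

__all__ = [
    "filter_complete",
    "pearson_r2",
    "puff_count_concordance",
    "paired_series_r2",
    "ParticipantData",
    "AgreementSummary",
    "run_comparison",
    "render_report",
]


def filter_complete(cohort: Sequence[SessionMeta]) -> list[SessionMeta]:
    """Retain participants with complete data from both devices.

    Logs exclusion counts by cause; raises when nobody remains.
    """
    n_cress = sum(1 for m in cohort if not m.complete_cress)
    n_aspire = sum(1 for m in cohort if not m.complete_aspire)
    kept = [m for m in cohort if m.complete_aspire and m.complete_cress]
    logger.info(
        "analytic roster: %d/%d retained (%d CReSS-incomplete, %d ASPIRE-incomplete)",
        len(kept), len(cohort), n_cress, n_aspire,
    )
    if not kept:
        raise ValidationError("no participant has complete data from both devices")
    return kept


def pearson_r2(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Squared Pearson product-moment correlation.

    Requires equal lengths >= 2 and nonzero variance in both inputs.
    """
    xa = np.asarray(xs, dtype=float)
    ya = np.asarray(ys, dtype=float)
    if xa.shape != ya.shape:
        raise ValidationError(f"length mismatch: {xa.shape} vs {ya.shape}")
    if xa.size < 2:
        raise ValidationError("need at least 2 pairs for a correlation")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValidationError("correlation undefined: an input has zero variance")
    r = stats.pearsonr(xa, ya).statistic
    return float(r * r)


def puff_count_concordance(
    counts_a: Sequence[int], counts_b: Sequence[int], tol: int = 2
) -> float:
    """Fraction of sessions whose two puff counts agree within ±tol."""
    a = np.asarray(counts_a)
    b = np.asarray(counts_b)
    if a.size == 0:
        raise ValidationError("no counts to compare")
    if a.shape != b.shape:
        raise ValidationError("count vectors must have equal length")
    return float(np.mean(np.abs(a - b) <= tol))


def paired_series_r2(
    series_a: TopographySeries,
    series_b: TopographySeries,
    pairing: str = "by_index_truncate",
) -> tuple[float, float]:
    """Index-paired (r²_PD, r²_IPI) between two topography series.

    PD pairs by puff index and IPI by gap index, truncated to the shorter
    list (logged).  Fewer than 2 pairs on either series raises.
    """
    if pairing != "by_index_truncate":
        raise ValidationError(f"unknown pairing {pairing!r}")
    if series_a.n_puffs == 0 or series_b.n_puffs == 0:
        raise ValidationError("both series must be non-empty")
    n_pd = min(len(series_a.pd_ms), len(series_b.pd_ms))
    n_ipi = min(len(series_a.ipi_ms), len(series_b.ipi_ms))
    if len(series_a.pd_ms) != len(series_b.pd_ms):
        logger.info(
            "pairing truncates PDs to %d (%d vs %d)",
            n_pd, len(series_a.pd_ms), len(series_b.pd_ms),
        )
    r2_pd = pearson_r2(series_a.pd_ms[:n_pd], series_b.pd_ms[:n_pd])
    r2_ipi = pearson_r2(series_a.ipi_ms[:n_ipi], series_b.ipi_ms[:n_ipi])
    return r2_pd, r2_ipi


@dataclass(frozen=True)
class ParticipantData:
    """One analytic participant's per-source series and puff counts."""

    participant_id: str
    watch: TopographySeries
    cress: Optional[TopographySeries] = None
    corrected: Optional[TopographySeries] = None
    visual_count: Optional[int] = None
    cress_count: Optional[int] = None

    @property
    def watch_count(self) -> int:
        return self.watch.n_puffs


@dataclass(frozen=True)
class AgreementSummary:
    """Per-participant and pooled agreement statistics."""

    per_participant: dict
    pooled: dict

    def to_dict(self) -> dict:
        return {"per_participant": self.per_participant, "pooled": self.pooled}


def _device_series(p: ParticipantData) -> Optional[TopographySeries]:
    return p.corrected if p.corrected is not None else p.cress


def run_comparison(
    participants: Sequence[ParticipantData], count_tol: int = 2
) -> AgreementSummary:
    """Compute the full agreement summary for an analytic cohort.

    Per participant: index-paired r² for PD and IPI between the watch series
    and the (corrected, else raw) device series, plus the three puff counts.
    Pooled: r² of per-participant median PD and median IPI across the
    cohort, and the concordance of device vs visual puff counts within
    ``count_tol``.  Pooled statistics are ``None`` (with a warning) when the
    cohort is too small.
    """
    if not participants:
        raise ValidationError("analytic roster is empty")
    per: dict = {}
    med_pd_watch, med_pd_dev = [], []
    med_ipi_watch, med_ipi_dev = [], []
    visual, watch_counts, cress_counts = [], [], []
    for p in participants:
        dev = _device_series(p)
        entry = {
            "r2_pd": None,
            "r2_ipi": None,
            "n_pairs": 0,
            "puff_count_watch": p.watch_count,
            "puff_count_cress": p.cress_count
            if p.cress_count is not None
            else (p.cress.n_puffs if p.cress is not None else None),
            "puff_count_visual": p.visual_count,
        }
        if dev is not None:
            try:
                r2_pd, r2_ipi = paired_series_r2(p.watch, dev)
                entry["r2_pd"], entry["r2_ipi"] = r2_pd, r2_ipi
            except ValidationError as exc:
                logger.warning("%s: per-puff r2 unavailable: %s", p.participant_id, exc)
            entry["n_pairs"] = min(p.watch.n_puffs, dev.n_puffs)
            sw, sd = summarize(p.watch), summarize(dev)
            if sw.median_pd_ms is not None and sd.median_pd_ms is not None:
                med_pd_watch.append(sw.median_pd_ms)
                med_pd_dev.append(sd.median_pd_ms)
            if sw.median_ipi_ms is not None and sd.median_ipi_ms is not None:
                med_ipi_watch.append(sw.median_ipi_ms)
                med_ipi_dev.append(sd.median_ipi_ms)
        if p.visual_count is not None and entry["puff_count_cress"] is not None:
            visual.append(p.visual_count)
            cress_counts.append(entry["puff_count_cress"])
        watch_counts.append(p.watch_count)
        per[p.participant_id] = entry

    pooled: dict = {
        "r2_median_pd": None,
        "r2_median_ipi": None,
        "concordance_within_tol": None,
        "tol": count_tol,
        "n_participants": len(participants),
    }
    for key, (a, b) in {
        "r2_median_pd": (med_pd_watch, med_pd_dev),
        "r2_median_ipi": (med_ipi_watch, med_ipi_dev),
    }.items():
        try:
            pooled[key] = pearson_r2(a, b)
        except ValidationError as exc:
            logger.warning("pooled %s unavailable: %s", key, exc)
    if visual:
        pooled["concordance_within_tol"] = puff_count_concordance(
            cress_counts, visual, tol=count_tol
        )
    return AgreementSummary(per_participant=per, pooled=pooled)


def render_report(summary: AgreementSummary) -> str:
    """Human-readable text rendering of an agreement summary."""
    lines = ["participant  n_pairs  r2_pd   r2_ipi  watch  cress  visual"]
    for pid, e in summary.per_participant.items():
        def _fmt(v, w=6):
            return f"{v:.3f}" if isinstance(v, float) else "-"
        lines.append(
            f"{pid:<12} {e['n_pairs']:>7}  {_fmt(e['r2_pd'])}  {_fmt(e['r2_ipi'])}"
            f"  {e['puff_count_watch'] if e['puff_count_watch'] is not None else '-':>5}"
            f"  {e['puff_count_cress'] if e['puff_count_cress'] is not None else '-':>5}"
            f"  {e['puff_count_visual'] if e['puff_count_visual'] is not None else '-':>6}"
        )
    p = summary.pooled
    lines.append("")
    lines.append(
        "pooled: r2(median PD)={} r2(median IPI)={} concordance(±{})={}".format(
            *(f"{v:.4f}" if isinstance(v, float) else "n/a"
              for v in (p["r2_median_pd"], p["r2_median_ipi"])),
            p["tol"],
            f"{p['concordance_within_tol']:.3f}"
            if isinstance(p["concordance_within_tol"], float)
            else "n/a",
        )
    )
    return "\n".join(lines)
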