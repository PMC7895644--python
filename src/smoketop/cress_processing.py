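"""Plausibility cleaning and outlier correction for mouthpiece topography logs.

Mouthpiece devices exhibit two characteristic artifacts: a spurious leading
interval spanning device power-on to the first puff (often over a minute),
and implausibly short puff records (milliseconds long) produced when a single
physical puff is split into several records.  :func:`clean_cress` handles
both — by default a short fragment is merged back into its neighbouring puff
(conserving recorded time) rather than deleted.  :func:`correct_ipis`
implements the outlier-substitution correction: IPIs flagged as abnormally
short or long are replaced by the arithmetic mean of the remaining IPIs.
:func:`ccress_pipeline` composes the stages into the corrected-series
("cCReSS") pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .session_model import CressLog, TopographySeries, ValidationError
from .topography import cress_to_topography

__all__ = [
    "CleaningParams",
    "OutlierRule",
    "clean_cress",
    "correct_ipis",
    "CcressResult",
    "ccress_pipeline",
]


class CleaningParams(BaseModel):
    """Plausibility-cleaning thresholds.

    ``min_plausible_pd_ms`` defaults to 300 ms — well below any credible
    inhalation, but far above the millisecond-scale fragments the device
    emits.  The leading interval is dropped either unconditionally or only
    when it exceeds ``leading_ipi_threshold_ms`` (default one minute).
    """

    model_config = ConfigDict(frozen=True)

    min_plausible_pd_ms: float = Field(default=300.0, gt=0)
    leading_ipi_rule: Literal["always_drop", "drop_if_over_ms"] = "drop_if_over_ms"
    leading_ipi_threshold_ms: float = Field(default=60000.0, gt=0)
    merge_fragments: bool = True


class OutlierRule(BaseModel):
    """Flagging rule for abnormally short or long IPIs.

    ``range`` flags IPIs outside ``[min_ipi_ms, max_ipi_ms]``; ``mad`` flags
    IPIs more than ``mad_k`` raw median-absolute-deviations from the median
    (requires at least 3 IPIs, otherwise nothing is flagged).
    """

    model_config = ConfigDict(frozen=True)

    method: Literal["mad", "range"] = "range"
    mad_k: float = Field(default=3.0, gt=0)
    min_ipi_ms: float = Field(default=1000.0, gt=0)
    max_ipi_ms: float = Field(default=120000.0, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "OutlierRule":
        if self.min_ipi_ms >= self.max_ipi_ms:
            raise ValueError("outlier_rule: min_ipi_ms must be below max_ipi_ms")
        return self


def clean_cress(
    log: CressLog, params: Optional[CleaningParams] = None
) -> tuple[CressLog, list[dict]]:
    """Remove device artifacts from a log; returns ``(cleaned, report)``.

    The leading interval is zeroed per ``leading_ipi_rule``.  Records with
    ``pd_ms`` below ``min_plausible_pd_ms`` are absorbed into the preceding
    record's PD together with the flanking IPI (``merge_fragments``, the
    default; a first-record fragment merges forward instead) — this conserves
    ``sum(PD) + sum(IPI)``.  With ``merge_fragments=False`` the record is
    deleted and its time reassigned to the following gap.  Every action is
    reported with the original record index.
    """
    params = params or CleaningParams()
    report: list[dict] = []
    recs = [
        {"orig_index": i, "rec": rec} for i, rec in enumerate(log)
    ]
    if recs:
        lead = recs[0]["rec"].ipi_ms
        if params.leading_ipi_rule == "always_drop" or (
            params.leading_ipi_rule == "drop_if_over_ms"
            and lead > params.leading_ipi_threshold_ms
        ):
            if lead > 0:
                report.append(
                    {"action": "drop_leading_ipi", "index": 0, "ipi_ms": lead}
                )
                recs[0]["rec"] = replace(recs[0]["rec"], ipi_ms=0.0)

    thresh = params.min_plausible_pd_ms
    changed = True
    while changed:
        changed = False
        for pos, item in enumerate(recs):
            rec = item["rec"]
            if rec.pd_ms >= thresh:
                continue
            if params.merge_fragments and len(recs) > 1:
                if pos > 0:
                    prev = recs[pos - 1]["rec"]
                    recs[pos - 1]["rec"] = replace(
                        prev, pd_ms=prev.pd_ms + rec.pd_ms + rec.ipi_ms
                    )
                    report.append(
                        {
                            "action": "merge_into_preceding",
                            "index": item["orig_index"],
                            "pd_ms": rec.pd_ms,
                            "ipi_ms": rec.ipi_ms,
                        }
                    )
                else:
                    nxt = recs[1]["rec"]
                    recs[1]["rec"] = replace(
                        nxt,
                        pd_ms=nxt.pd_ms + rec.pd_ms + nxt.ipi_ms,
                        ipi_ms=rec.ipi_ms,
                    )
                    report.append(
                        {
                            "action": "merge_into_following",
                            "index": item["orig_index"],
                            "pd_ms": rec.pd_ms,
                            "ipi_ms": rec.ipi_ms,
                        }
                    )
            else:
                if pos + 1 < len(recs):
                    nxt = recs[pos + 1]["rec"]
                    recs[pos + 1]["rec"] = replace(
                        nxt, ipi_ms=nxt.ipi_ms + rec.pd_ms + rec.ipi_ms
                    )
                report.append(
                    {
                        "action": "delete",
                        "index": item["orig_index"],
                        "pd_ms": rec.pd_ms,
                        "ipi_ms": rec.ipi_ms,
                    }
                )
            del recs[pos]
            changed = True
            break
    cleaned = CressLog(records=tuple(item["rec"] for item in recs))
    return cleaned, report


def correct_ipis(
    series: TopographySeries, rule: Optional[OutlierRule] = None
) -> tuple[TopographySeries, np.ndarray]:
    """Replace flagged IPIs with the mean of the unflagged IPIs.

    The PD list is untouched and the IPI count preserved; the boolean flag
    vector is returned alongside.  Raises :class:`ValidationError` when no
    unflagged IPI remains to serve as the reference set (including an empty
    IPI list).  Idempotent: a second application under the same rule flags
    nothing new, since the substituted mean lies inside the accepted range.
    """
    rule = rule or OutlierRule()
    ipis = np.asarray(series.ipi_ms, dtype=float)
    if ipis.size == 0:
        raise ValidationError(
            "cannot correct IPIs: series has no IPIs to form a reference set"
        )
    if rule.method == "range":
        flags = (ipis < rule.min_ipi_ms) | (ipis > rule.max_ipi_ms)
    else:  # mad
        if ipis.size < 3:
            flags = np.zeros(ipis.size, dtype=bool)
        else:
            med = np.median(ipis)
            mad = np.median(np.abs(ipis - med))
            if mad == 0:
                flags = np.zeros(ipis.size, dtype=bool)
            else:
                flags = np.abs(ipis - med) > rule.mad_k * mad
    if flags.all():
        raise ValidationError(
            "all IPIs flagged as outliers: no reference set remains"
        )
    if flags.any():
        ref_mean = float(np.mean(ipis[~flags]))
        ipis = ipis.copy()
        ipis[flags] = ref_mean
    corrected = TopographySeries(
        pd_ms=series.pd_ms, ipi_ms=tuple(ipis.tolist()), source=series.source
    )
    return corrected, flags


@dataclass(frozen=True)
class CcressResult:
    """Corrected-series pipeline output with its per-stage audit trail."""

    series: TopographySeries
    cleaning_report: tuple
    outlier_flags: tuple


def ccress_pipeline(
    log: CressLog,
    cleaning: Optional[CleaningParams] = None,
    outlier_rule: Optional[OutlierRule] = None,
) -> CcressResult:
    """Clean a log, derive its topography (leading interval dropped), and
    substitute outlier IPIs; the result is tagged ``cress_corrected``."""
    cleaned, report = clean_cress(log, cleaning)
    series = cress_to_topography(cleaned, drop_leading_ipi=True)
    corrected, flags = correct_ipis(series, outlier_rule)
    tagged = TopographySeries(
        pd_ms=corrected.pd_ms, ipi_ms=corrected.ipi_ms, source="cress_corrected"
    )
    return CcressResult(
        series=tagged,
        cleaning_report=tuple(report),
        outlier_flags=tuple(bool(f) for f in flags),
    )
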