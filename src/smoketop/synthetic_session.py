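"""Synthetic laboratory smoking sessions with known ground truth.

The generator emulates a 20-minute laboratory protocol: two adjacent 3-minute
smoking blocks (one per hand — a single cigarette with a mid-session hand
switch), a 52-second cigarette-pack "packing" block, further unscripted
movement blocks, and rest.  During each puff the wrist pose ramps linearly
from a resting orientation (default ``(9, -1, 5)`` m/s²) to the
cigarette-at-mouth plateau (default ``(9, -5, -3)`` m/s²) over
``transition_ms``, holds, and ramps back; this realises the per-axis onset
deltas of roughly ``(±1, -4, -8)`` m/s² that characterise the gesture.

Truth-event convention: a puff's ``start_ms``/``end_ms`` are the
*half-transition crossing times* (the instants the pose is halfway between
rest and plateau), so the drawn puff duration equals plateau hold plus one
full transition and is independent of any detector convention.

Puff durations and interpuff intervals are drawn from truncated log-normal
distributions (positive, right-skewed).  Only puffs performed with the watch
hand leave a trace in the accelerometer signal; the others exist in the truth
list (and hence in the mouthpiece log) but not in the watch-visible window,
emulating the hand switch without transferring the watch.

The paired mouthpiece log inherits the truth topography and can inject the
device's characteristic artifacts: a long leading interval spanning device-on
to the first puff, splitting of single puffs into two records separated by a
sub-second gap (the spurious fragment defaulting to 5 ms), and Gaussian
measurement jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .session_model import (
    AccelTrace,
    ConfigurationError,
    CressLog,
    CressRecord,
    ProtocolSchedule,
    ProtocolSegment,
    PuffEvent,
    SessionMeta,
    validate_events,
)

__all__ = [
    "default_schedule",
    "SimulationConfig",
    "CressArtifactConfig",
    "CohortSession",
    "simulate_session",
    "simulate_cress_log",
    "simulate_cohort",
]


def default_schedule() -> ProtocolSchedule:
    """The default 20-minute laboratory schedule.

    6 minutes of smoking split evenly between hands (adjacent blocks), 52 s
    of packing, 480 s of other movements in total, rest elsewhere.
    """
    return ProtocolSchedule(
        segments=(
            ProtocolSegment(activity="rest", duration_s=60),
            ProtocolSegment(activity="packing", duration_s=52),
            ProtocolSegment(activity="other_movement", duration_s=188),
            ProtocolSegment(activity="smoking_left", duration_s=180),
            ProtocolSegment(activity="smoking_right", duration_s=180),
            ProtocolSegment(activity="other_movement", duration_s=240),
            ProtocolSegment(activity="rest", duration_s=300),
        )
    )


class SimulationConfig(BaseModel):
    """Parameters of one synthetic session.

    ``pd_median_ms``/``ipi_median_ms`` with their sigmas parameterise the
    log-normal draws; draws below ``min_pd_ms``/``min_ipi_ms`` are redrawn so
    every gesture is resolvable at the sampling rate given the transition
    ramp.  ``noise_sd`` is additive white Gaussian noise applied everywhere.
    """

    model_config = ConfigDict(frozen=True)

    seed: int = Field(default=0, ge=0)
    schedule: ProtocolSchedule = Field(default_factory=default_schedule)
    n_puffs_per_hand: int = Field(default=6, ge=0)
    pd_median_ms: float = Field(default=1500.0, gt=0)
    pd_sigma: float = Field(default=0.25, ge=0)
    min_pd_ms: float = Field(default=1100.0, gt=0)
    ipi_median_ms: float = Field(default=20000.0, gt=0)
    ipi_sigma: float = Field(default=0.3, ge=0)
    min_ipi_ms: float = Field(default=3000.0, gt=0)
    rest_pose: tuple[float, float, float] = (9.0, -1.0, 5.0)
    plateau_pose: tuple[float, float, float] = (9.0, -5.0, -3.0)
    transition_ms: float = Field(default=500.0, gt=0)
    noise_sd: float = Field(default=0.2, ge=0)
    sampling_rate: float = Field(default=30.0, gt=0)
    watch_hand: str = Field(default="left", pattern="^(left|right)$")
    packing_amplitude: float = Field(default=2.0, ge=0)
    packing_freq_hz: float = Field(default=1.5, gt=0)
    other_movement_sd: float = Field(default=1.2, ge=0)
    max_retries: int = Field(default=100, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.min_pd_ms <= self.transition_ms:
            raise ValueError(
                "min_pd_ms must exceed transition_ms so every puff has a plateau"
            )
        if self.min_ipi_ms <= self.transition_ms:
            raise ValueError("min_ipi_ms must exceed transition_ms")
        return self


class CressArtifactConfig(BaseModel):
    """Artifact injection for synthetic mouthpiece logs.

    With all rates and jitter at zero the log reproduces the truth topography
    exactly, apart from the configured leading device-on interval carried by
    record 1.
    """

    model_config = ConfigDict(frozen=True)

    seed: int = Field(default=0, ge=0)
    leading_ipi_ms: float = Field(default=65000.0, ge=0)
    split_probability: float = Field(default=0.15, ge=0, le=1)
    split_fragment_pd_ms: float = Field(default=5.0, gt=0)
    split_gap_median_ms: float = Field(default=330.0, gt=0)
    split_gap_sigma: float = Field(default=0.5, ge=0)
    jitter_sd_ms: float = Field(default=50.0, ge=0)


# margins (ms) kept free at the edges of each smoking segment
_EDGE_MARGIN_MS = 1000.0


def _draw_trunc_lognormal(
    rng: np.random.Generator, median: float, sigma: float, floor: float, size: int
) -> np.ndarray:
    """Log-normal draws (given median and log-sd) redrawn until >= floor."""
    mu = math.log(median)
    vals = rng.lognormal(mu, sigma, size)
    for _ in range(1000):
        bad = vals < floor
        if not bad.any():
            break
        vals[bad] = rng.lognormal(mu, sigma, int(bad.sum()))
    else:
        raise ConfigurationError(
            f"could not draw values >= {floor} from lognormal(median={median}, "
            f"sigma={sigma})"
        )
    return vals


def _segment_events(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    seg_start_ms: float,
    seg_end_ms: float,
    hand: str,
) -> list[PuffEvent]:
    """Draw a feasible puff train for one smoking segment."""
    n = cfg.n_puffs_per_hand
    if n == 0:
        return []
    seg_ms = seg_end_ms - seg_start_ms
    half_t = cfg.transition_ms / 2.0
    for _ in range(cfg.max_retries):
        pds = np.round(
            _draw_trunc_lognormal(rng, cfg.pd_median_ms, cfg.pd_sigma, cfg.min_pd_ms, n)
        )
        ipis = np.round(
            _draw_trunc_lognormal(
                rng, cfg.ipi_median_ms, cfg.ipi_sigma, cfg.min_ipi_ms, max(0, n - 1)
            )
        )
        footprint = pds.sum() + ipis.sum() + cfg.transition_ms + 2 * _EDGE_MARGIN_MS
        if footprint <= seg_ms:
            slack = seg_ms - footprint
            lead = _EDGE_MARGIN_MS + half_t + math.floor(rng.uniform(0, slack + 1))
            start = seg_start_ms + lead
            events = []
            for i in range(n):
                s = int(round(start))
                e = int(round(start + pds[i]))
                events.append(PuffEvent(s, e, hand))
                if i < n - 1:
                    start = e + ipis[i]
            return events
    raise ConfigurationError(
        f"could not fit {n} puffs into a {seg_ms:.0f} ms smoking segment after "
        f"{cfg.max_retries} attempts; reduce n_puffs_per_hand or the interval medians"
    )


def _band_limited_noise(
    rng: np.random.Generator, n: int, sd: float, width: int = 15
) -> np.ndarray:
    """Low-pass-filtered Gaussian noise rescaled to the requested sd."""
    white = rng.normal(0.0, 1.0, n + width - 1)
    kernel = np.ones(width) / width
    smooth = np.convolve(white, kernel, mode="valid")
    return smooth * (sd * math.sqrt(width))


def simulate_session(
    config: SimulationConfig,
) -> tuple[AccelTrace, list[PuffEvent], ProtocolSchedule]:
    """Generate one session: accelerometer trace, truth events, schedule.

    The trace spans the full schedule at ``sampling_rate``.  Truth events for
    both hands are returned (ordered, non-overlapping); only watch-hand
    gestures appear in the trace.  Identical config (including seed) yields
    bit-identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    schedule = config.schedule
    rate = config.sampling_rate
    n_samples = int(round(schedule.total_s * rate))
    t_ms = np.floor(np.arange(n_samples) * 1000.0 / rate + 0.5).astype(np.int64)

    rest = np.array(config.rest_pose, dtype=float)
    plateau = np.array(config.plateau_pose, dtype=float)
    half_t = config.transition_ms / 2.0

    # pass 1 (schedule order): draw puff trains and confounder noise
    truth: list[PuffEvent] = []
    confounders: list[tuple[str, int, int, np.ndarray]] = []
    for activity, a, b in schedule.windows_ms():
        if activity in ("smoking_left", "smoking_right"):
            hand = activity.split("_", 1)[1]
            truth.extend(_segment_events(rng, config, a, b, hand))
        elif activity == "other_movement":
            mask = (t_ms >= a) & (t_ms < b)
            n_seg = int(mask.sum())
            noise = np.stack(
                [
                    _band_limited_noise(rng, n_seg, config.other_movement_sd)
                    for _ in range(3)
                ]
            )
            confounders.append(("other_movement", a, b, noise))
        elif activity == "packing":
            confounders.append(("packing", a, b, np.empty(0)))
    validate_events(truth)

    # piecewise-linear pose for watch-hand gestures
    bx: list[float] = []
    bv: list[np.ndarray] = []
    for ev in truth:
        if ev.hand != config.watch_hand:
            continue
        bx.extend(
            [ev.start_ms - half_t, ev.start_ms + half_t, ev.end_ms - half_t, ev.end_ms + half_t]
        )
        bv.extend([rest, plateau, plateau, rest])
    sig = np.empty((3, n_samples))
    if bx:
        bxa = np.asarray(bx)
        bva = np.stack(bv)
        for ax in range(3):
            sig[ax] = np.interp(t_ms, bxa, bva[:, ax], left=rest[ax], right=rest[ax])
    else:
        sig[:] = rest[:, None]

    # confounder motion
    for kind, a, b, noise in confounders:
        mask = (t_ms >= a) & (t_ms < b)
        if kind == "packing":
            tt = (t_ms[mask] - a) / 1000.0
            sig[2, mask] += config.packing_amplitude * np.sin(
                2 * math.pi * config.packing_freq_hz * tt
            )
        else:
            sig[:, mask] += noise[:, : int(mask.sum())]

    if config.noise_sd > 0:
        sig += rng.normal(0.0, config.noise_sd, sig.shape)

    trace = AccelTrace(
        t_ms=t_ms, x=sig[0], y=sig[1], z=sig[2], sampling_rate=rate
    )
    return trace, truth, schedule


def simulate_cress_log(
    truth: Sequence[PuffEvent], artifact: Optional[CressArtifactConfig] = None
) -> CressLog:
    """Derive a mouthpiece log from truth events, with optional artifacts.

    Record ``i``'s ``ipi_ms`` is the interval preceding puff ``i``; record 1
    carries the device-on→first-puff interval (``leading_ipi_ms``).  Each
    split turns one true puff into a main record plus a short fragment record
    (``split_fragment_pd_ms``) separated by a sub-second gap, conserving the
    puff's total time.  Volume/flow fields are filled with plausible values
    and carried opaquely downstream.
    """
    artifact = artifact or CressArtifactConfig(
        split_probability=0.0, jitter_sd_ms=0.0, leading_ipi_ms=65000.0
    )
    validate_events(list(truth))
    rng = np.random.default_rng(np.random.SeedSequence(artifact.seed))
    records: list[CressRecord] = []
    prev_end: Optional[int] = None
    for k, ev in enumerate(truth):
        ipi = artifact.leading_ipi_ms if k == 0 else float(ev.start_ms - prev_end)
        prev_end = ev.end_ms
        pd_val = float(ev.duration_ms)
        do_split = rng.random() < artifact.split_probability
        if artifact.jitter_sd_ms > 0:
            pd_val = max(1.0, pd_val + rng.normal(0.0, artifact.jitter_sd_ms))
            if k > 0:
                ipi = max(0.0, ipi + rng.normal(0.0, artifact.jitter_sd_ms))
        volume = float(rng.lognormal(math.log(45.0), 0.3))
        avg_flow = volume / (pd_val / 1000.0)
        peak_flow = 1.6 * avg_flow
        tpf = 0.4 * pd_val

        def _rec(pd_v, ipi_v):
            return CressRecord(
                pd_ms=pd_v,
                ipi_ms=ipi_v,
                puff_volume_ml=volume,
                avg_flow=avg_flow,
                peak_flow=peak_flow,
                time_of_peak_flow_ms=tpf,
            )

        frag = artifact.split_fragment_pd_ms
        if do_split and pd_val > frag + 100.0:
            gap = _draw_trunc_lognormal(
                rng, artifact.split_gap_median_ms, artifact.split_gap_sigma, 1.0, 1
            )[0]
            gap = min(float(gap), 999.0, pd_val - frag - 1.0)
            records.append(_rec(pd_val - frag - gap, ipi))
            records.append(_rec(frag, gap))
        else:
            records.append(_rec(pd_val, ipi))
    return CressLog(records=tuple(records))


@dataclass(frozen=True)
class CohortSession:
    """One simulated participant: metadata, raw trace, truth, device log."""

    meta: SessionMeta
    config: SimulationConfig
    trace: AccelTrace
    truth: tuple
    cress_log: Optional[CressLog]


def _child_seed(base: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(base), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(
    n_participants: int,
    template: SimulationConfig,
    artifact: Optional[CressArtifactConfig] = None,
    n_incomplete_cress: int = 0,
    n_incomplete_aspire: int = 0,
    pd_median_spread_sigma: float = 0.15,
    ipi_median_spread_sigma: float = 0.15,
) -> list[CohortSession]:
    """Simulate a cohort with per-participant topography parameter draws.

    Each participant's PD/IPI medians are log-normal perturbations of the
    template medians (so medians genuinely vary across the cohort).  Visual
    puff counts are set from the truth events.  The first
    ``n_incomplete_cress`` participants are flagged CReSS-incomplete and the
    next ``n_incomplete_aspire`` ASPIRE-incomplete (disjoint sets), emulating
    recording errors.
    """
    if n_participants < 1:
        raise ConfigurationError("n_participants must be >= 1")
    if n_incomplete_cress + n_incomplete_aspire > n_participants:
        raise ConfigurationError("more incomplete sessions requested than participants")
    sessions: list[CohortSession] = []
    for i in range(n_participants):
        prng = np.random.default_rng(
            np.random.SeedSequence([int(template.seed), i, 7])
        )
        cfg = template.model_copy(
            update={
                "seed": _child_seed(template.seed, i, 1),
                "pd_median_ms": float(
                    template.pd_median_ms * prng.lognormal(0.0, pd_median_spread_sigma)
                ),
                "ipi_median_ms": float(
                    template.ipi_median_ms * prng.lognormal(0.0, ipi_median_spread_sigma)
                ),
            }
        )
        trace, truth, _ = simulate_session(cfg)
        log = None
        if artifact is not None:
            art = artifact.model_copy(update={"seed": _child_seed(artifact.seed, i, 2)})
            log = simulate_cress_log(truth, art)
        meta = SessionMeta(
            participant_id=f"P{i + 1:02d}",
            visual_puff_count_left=sum(1 for e in truth if e.hand == "left"),
            visual_puff_count_right=sum(1 for e in truth if e.hand == "right"),
            complete_cress=not (i < n_incomplete_cress),
            complete_aspire=not (n_incomplete_cress <= i < n_incomplete_cress + n_incomplete_aspire),
        )
        sessions.append(
            CohortSession(meta=meta, config=cfg, trace=trace, truth=tuple(truth), cress_log=log)
        )
    return sessions
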