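"""End-to-end orchestration: simulate → detect → topography → clean → compare.

One :class:`RunConfig` (YAML-serialisable) drives a fully reproducible run: a
single global seed derives per-stage seeds by stable offsets, every
intermediate is written in the package's tabular formats, and a manifest
records inputs, seeds, versions, per-stage counts and file checksums.
Identical configs produce byte-identical summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError as PydanticValidationError

from . import __version__
from .agreement import ParticipantData, filter_complete, run_comparison
from .cress_processing import CleaningParams, OutlierRule, ccress_pipeline
from .puff_segmentation import (
    SegmentationParams,
    detect_puffs,
    estimate_resting_pose,
    restrict_to_window,
)
from .session_model import (
    ConfigurationError,
    write_accel_table,
    write_cress_table,
    write_events,
    write_session_meta,
)
from .synthetic_session import (
    CressArtifactConfig,
    SimulationConfig,
    simulate_cohort,
)
from .topography import cress_to_topography, events_to_topography, summarize

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_all"]


class RunConfig(BaseModel):
    """Configuration of one full pipeline run."""

    model_config = ConfigDict(frozen=True)

    seed: int = Field(default=0, ge=0)
    n_participants: int = Field(default=27, ge=1)
    n_incomplete_cress: int = Field(default=0, ge=0)
    n_incomplete_aspire: int = Field(default=0, ge=0)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    artifacts: CressArtifactConfig = Field(default_factory=CressArtifactConfig)
    segmentation: SegmentationParams = Field(default_factory=SegmentationParams)
    cleaning: CleaningParams = Field(default_factory=CleaningParams)
    outlier_rule: OutlierRule = Field(default_factory=OutlierRule)
    output_dir: str = "smoketop_run"
    write_traces: bool = True


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run config.

    Every violated invariant is reported with its field path; a valid config
    is returned intact.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: cannot parse YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except PydanticValidationError as exc:
        msgs = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigurationError(
            f"{path}: {len(msgs)} invalid field(s):\n  " + "\n  ".join(msgs)
        ) from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, stage: int) -> int:
    import numpy as np

    return int(np.random.SeedSequence([int(seed), stage]).generate_state(1)[0] % (2**31))


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and return (and write) the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = config.simulation.model_copy(
        update={"seed": _stage_seed(config.seed, 1)}
    )
    art_cfg = config.artifacts.model_copy(
        update={"seed": _stage_seed(config.seed, 2)}
    )
    try:
        cohort = simulate_cohort(
            config.n_participants,
            sim_cfg,
            artifact=art_cfg,
            n_incomplete_cress=config.n_incomplete_cress,
            n_incomplete_aspire=config.n_incomplete_aspire,
        )
    except Exception as exc:
        raise ConfigurationError(f"stage simulate: {exc}") from exc

    write_session_meta([s.meta for s in cohort], out / "session_meta.csv")
    roster = filter_complete([s.meta for s in cohort])
    roster_ids = {m.participant_id for m in roster}

    participants = []
    files = [out / "session_meta.csv"]
    counts = {"simulated": len(cohort), "analytic": len(roster)}
    watch_hand = sim_cfg.watch_hand
    for sess in cohort:
        if sess.meta.participant_id not in roster_ids:
            continue
        pid = sess.meta.participant_id
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        try:
            pose = estimate_resting_pose(sess.trace, config.segmentation)
            detected = detect_puffs(sess.trace, pose, config.segmentation)
            window = sess.config.schedule.smoking_window_ms(watch_hand)
            watch_events = restrict_to_window(detected, *window)
        except Exception as exc:
            raise ConfigurationError(f"stage detect ({pid}): {exc}") from exc
        try:
            watch_series = events_to_topography(watch_events, source="aspire")
            raw_series = cress_to_topography(sess.cress_log, drop_leading_ipi=True)
            ccress = ccress_pipeline(
                sess.cress_log, config.cleaning, config.outlier_rule
            )
        except Exception as exc:
            raise ConfigurationError(f"stage topography/ccress ({pid}): {exc}") from exc

        if config.write_traces:
            write_accel_table(sess.trace, pdir / "trace.csv")
            files.append(pdir / "trace.csv")
        write_events(sess.truth, pdir / "truth_events.csv")
        write_events(detected, pdir / "detected_events.csv")
        write_cress_table(sess.cress_log, pdir / "cress_log.csv")
        files += [
            pdir / "truth_events.csv",
            pdir / "detected_events.csv",
            pdir / "cress_log.csv",
        ]
        topo = {
            "aspire": summarize(watch_series).to_dict(),
            "cress": summarize(raw_series).to_dict(),
            "cress_corrected": summarize(ccress.series).to_dict(),
        }
        (pdir / "topography.json").write_text(json.dumps(topo, indent=2, sort_keys=True))
        files.append(pdir / "topography.json")

        visual = (
            sess.meta.visual_puff_count_left
            if watch_hand == "left"
            else sess.meta.visual_puff_count_right
        )
        # visual total vs device total for the count concordance
        participants.append(
            ParticipantData(
                participant_id=pid,
                watch=watch_series,
                cress=raw_series,
                corrected=ccress.series,
                visual_count=sess.meta.visual_puff_count_total,
                cress_count=len(sess.cress_log),
            )
        )
    counts["detected_events_total"] = sum(p.watch.n_puffs for p in participants)

    try:
        summary = run_comparison(participants)
    except Exception as exc:
        raise ConfigurationError(f"stage compare: {exc}") from exc
    (out / "summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2, sort_keys=True)
    )
    files.append(out / "summary.json")

    manifest = {
        "smoketop_version": __version__,
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "counts": counts,
        "files": {
            str(f.relative_to(out)): _sha256(f) for f in sorted(files)
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("run complete: %d analytic participants, outputs in %s", len(roster), out)
    return manifest
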