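"""Temporal gait parameters from event sequences, and the pipeline driver.

Four parameters are derived from the time-sorted heel-strike (HS) / toe-off
(TO) event list:

* stance time — HS to the next ipsilateral TO (foot on the ground);
* swing time — TO to the next ipsilateral HS (foot in the air);
* step time — consecutive heel strikes of opposite feet, named after the
  trailing leg;
* double-support time — contralateral HS to ipsilateral TO while both feet
  are on the ground; L2R denotes support transferring from the left leg to
  the right leg, i.e. the interval [HS_right, TO_left], and R2L its mirror.

Only complete cycles are emitted: a parameter appears iff both bounding
events exist, are correctly ordered, and no same-leg event of the other kind
intervenes.  Incomplete bounds are skipped and logged, never guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import StageError, ValidationError
from .events import (
    HEEL_STRIKE,
    TOE_OFF,
    EventDetectionConfig,
    GaitEvent,
    detect_gait_events,
)
from .keypoints import KeypointSeries, apply_visibility_floor, read_keypoints
from .preprocess import FilterSpec, preprocess_series

logger = logging.getLogger(__name__)

PARAMETERS = ("stance_time", "swing_time", "step_time", "double_support_time")
RECORD_COLUMNS = (
    "subject_id", "cycle_index", "parameter", "leg_or_transition",
    "value_s", "start_time_s",
)
EVENT_COLUMNS = ("subject_id", "kind", "leg", "frame", "time_s")


@dataclass
class GaitParameters:
    """Per-cycle temporal gait parameters for one subject.

    ``records`` is a long DataFrame with one row per emitted parameter value
    (columns: subject_id, cycle_index, parameter, leg_or_transition, value_s,
    start_time_s).  ``start_time_s`` is the time of the defining first event
    and is used to pair cycles between two systems.
    """

    subject_id: str
    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(RECORD_COLUMNS))
    )

    def __post_init__(self) -> None:
        missing = set(RECORD_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValidationError(f"records missing columns: {sorted(missing)}")

    def values(self, parameter: str, leg_or_transition: str) -> np.ndarray:
        sel = self.records[
            (self.records["parameter"] == parameter)
            & (self.records["leg_or_transition"] == leg_or_transition)
        ]
        return sel["value_s"].to_numpy(dtype=float)


def compute_parameters(
    events: list[GaitEvent], fps: float, subject_id: str = "subject"
) -> GaitParameters:
    """Derive stance/swing/step/double-support times from sorted events.

    Raises
    ------
    ValidationError
        If the event list is not time-sorted or fps is not positive.
    """
    if not fps > 0:
        raise ValidationError("fps must be positive")
    times = [e.time_s for e in events]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValidationError("events must be sorted by time")

    rows: list[dict] = []

    def emit(parameter: str, side: str, start: float, end: float) -> None:
        value = end - start
        if value <= 0:
            logger.info(
                "skipping non-positive %s (%s): %.3f s", parameter, side, value
            )
            return
        rows.append(
            {"subject_id": subject_id, "parameter": parameter,
             "leg_or_transition": side, "value_s": value, "start_time_s": start}
        )

    # stance & swing: adjacent same-leg event pairs (HS->TO and TO->HS);
    # adjacency in the per-leg sequence enforces "no intervening ipsilateral
    # event" automatically.
    for leg in ("left", "right"):
        seq = [e for e in events if e.leg == leg]
        for a, b in zip(seq, seq[1:]):
            if a.kind == HEEL_STRIKE and b.kind == TOE_OFF:
                emit("stance_time", leg, a.time_s, b.time_s)
            elif a.kind == TOE_OFF and b.kind == HEEL_STRIKE:
                emit("swing_time", leg, a.time_s, b.time_s)
            else:
                logger.info(
                    "skipping %s leg pair %s->%s at %.2f s (incomplete cycle)",
                    leg, a.kind, b.kind, a.time_s,
                )

    # step time: consecutive heel strikes of opposite legs, named after the
    # trailing (second) leg.
    heel_strikes = [e for e in events if e.kind == HEEL_STRIKE]
    for a, b in zip(heel_strikes, heel_strikes[1:]):
        if a.leg != b.leg:
            emit("step_time", b.leg, a.time_s, b.time_s)
        else:
            logger.info(
                "skipping repeated %s heel strikes at %.2f s (missed event)",
                a.leg, a.time_s,
            )

    # double support: contralateral HS immediately followed by ipsilateral
    # TO within the merged two-event-kind subsequence.
    for transition, hs_leg, to_leg in (("L2R", "right", "left"), ("R2L", "left", "right")):
        seq = [
            e for e in events
            if (e.kind == HEEL_STRIKE and e.leg == hs_leg)
            or (e.kind == TOE_OFF and e.leg == to_leg)
        ]
        for a, b in zip(seq, seq[1:]):
            if a.kind == HEEL_STRIKE and b.kind == TOE_OFF:
                emit("double_support_time", transition, a.time_s, b.time_s)

    records = pd.DataFrame(rows, columns=[c for c in RECORD_COLUMNS if c != "cycle_index"])
    records = records.sort_values(["parameter", "leg_or_transition", "start_time_s"])
    records["cycle_index"] = records.groupby(
        ["parameter", "leg_or_transition"]
    ).cumcount()
    records = records[list(RECORD_COLUMNS)].reset_index(drop=True)
    return GaitParameters(subject_id=subject_id, records=records)


def summarize_subject(params: GaitParameters) -> pd.DataFrame:
    """Mean and sample SD per (parameter, leg/transition).

    A parameter with a single cycle reports its value as the mean and a
    missing SD; parameters with no cycles are omitted (logged).
    """
    if params.records.empty:
        logger.info("subject %s: no parameters to summarize", params.subject_id)
        return pd.DataFrame(
            columns=["subject_id", "parameter", "leg_or_transition", "n", "mean_s", "sd_s"]
        )
    grouped = params.records.groupby(["parameter", "leg_or_transition"])["value_s"]
    out = grouped.agg(n="count", mean_s="mean", sd_s=lambda v: v.std(ddof=1))
    out = out.reset_index()
    out.insert(0, "subject_id", params.subject_id)
    return out


def write_parameters_csv(
    params: GaitParameters,
    path: str | Path,
    summary_path: str | Path | None = None,
) -> None:
    """Write per-cycle parameters and the per-subject summary as CSV.

    Values are written in seconds with six decimals.  ``summary_path``
    defaults to the parameters path with a ``_summary`` suffix.
    """
    path = Path(path)
    out = params.records[
        ["subject_id", "cycle_index", "parameter", "leg_or_transition", "value_s"]
    ]
    out.to_csv(path, index=False, float_format="%.6f")
    if summary_path is None:
        summary_path = path.with_name(path.stem + "_summary" + path.suffix)
    summarize_subject(params).to_csv(summary_path, index=False, float_format="%.6f")


def write_events_csv(
    events: list[GaitEvent], path: str | Path, subject_id: str = "subject"
) -> None:
    rows = [
        {"subject_id": subject_id, "kind": e.kind, "leg": e.leg,
         "frame": e.frame, "time_s": e.time_s}
        for e in events
    ]
    pd.DataFrame(rows, columns=list(EVENT_COLUMNS)).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_events_csv(path: str | Path) -> list[GaitEvent]:
    df = pd.read_csv(path)
    return sorted(
        GaitEvent(kind=r.kind, leg=r.leg, frame=int(r.frame), time_s=float(r.time_s))
        for r in df.itertuples()
    )


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, YAML-loadable."""

    filter: FilterSpec = field(default_factory=FilterSpec)
    events: EventDetectionConfig = field(default_factory=EventDetectionConfig)
    visibility_floor: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        ev = dict(raw.get("events", {}))
        # nested peak_fraction: {left, right} mirrors the config file layout
        pf = ev.pop("peak_fraction", None)
        if isinstance(pf, dict):
            ev["peak_fraction_left"] = pf.get("left", 0.35)
            ev["peak_fraction_right"] = pf.get("right", 0.46)
        if "min_separation_s" in ev:
            ev["min_event_separation_s"] = ev.pop("min_separation_s")
        kp = raw.get("keypoints", {})
        return cls(
            filter=FilterSpec(**raw.get("filter", {})),
            events=EventDetectionConfig(**ev),
            visibility_floor=kp.get("visibility_floor", 0.5),
        )


def run_pipeline(
    source: str | Path | KeypointSeries,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    subject_id: str | None = None,
) -> tuple[GaitParameters, list[GaitEvent], dict]:
    """Keypoints -> preprocessing -> events -> temporal parameters.

    ``source`` may be a keypoint CSV/JSON path or an in-memory
    ``KeypointSeries``.  When ``out_dir`` is given, per-subject parameter,
    summary and event CSVs are written there.  Returns the parameters, the
    event list and a diagnostics dict (gap counts, valid window, inferred
    direction, event counts).
    """
    config = config or PipelineConfig()
    sid = subject_id

    stage = "keypoints"
    try:
        if isinstance(source, KeypointSeries):
            series = apply_visibility_floor(source, config.visibility_floor)
        else:
            series = read_keypoints(
                source, subject_id=subject_id,
                visibility_floor=config.visibility_floor,
            )
        sid = sid or series.subject_id
        diagnostics: dict = {
            "n_frames": series.n_frames,
            "n_missing_samples": int(series.missing_mask().sum()),
        }

        stage = "preprocess"
        clean = preprocess_series(series, config.filter)

        stage = "events"
        from .events import infer_walking_direction, relative_distance_signal

        if config.events.direction == "auto":
            direction = infer_walking_direction(clean)
        else:
            direction = int(config.events.direction)
        diagnostics["direction"] = direction
        windows = {}
        for leg in ("left", "right"):
            sig = relative_distance_signal(clean, leg, direction, config.events.hip_reference)
            windows[leg] = sig.valid_window
        diagnostics["valid_window"] = windows
        events = detect_gait_events(clean, config.events)
        diagnostics["n_events"] = {
            kind: sum(1 for e in events if e.kind == kind)
            for kind in (HEEL_STRIKE, TOE_OFF)
        }

        stage = "temporal"
        params = compute_parameters(events, clean.fps, subject_id=sid)
        diagnostics["n_parameter_records"] = len(params.records)

        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            write_parameters_csv(
                params,
                out_dir / f"{sid}_parameters.csv",
                out_dir / f"{sid}_summary.csv",
            )
            write_events_csv(events, out_dir / f"{sid}_events.csv", subject_id=sid)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, sid or str(source), exc) from exc

    return params, events, diagnostics
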