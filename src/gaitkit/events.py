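"""Gait-event detection from hip-to-foot horizontal distance signals.

For each leg the forward-positive horizontal distance between the hip and the
foot-index landmark is computed in pixels.  During stance the foot is planted
while the hip advances, so the distance falls from its maximum to its
minimum; during swing the foot overtakes the hip and the distance rises
again.  Heel strikes therefore sit at the signal's local maxima and toe-offs
at its local minima.

Spurious extrema are rejected with two rules: a minimum separation in time
between same-kind events (default 0.8 s), and an amplitude floor expressed as
a fraction of the signal's global extremum — peaks must reach 35% (left) or
46% (right) of the maximum distance, minima must be at least 18% as deep as
the deepest trough.  The minima rule presumes the signal crosses zero (foot
behind the hip at toe-off gives negative values); a warning is emitted when
it does not.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AmbiguousDirectionError, InsufficientDataError, ValidationError
from .keypoints import (
    LEFT_FOOT_INDEX,
    LEFT_HIP,
    RIGHT_FOOT_INDEX,
    RIGHT_HIP,
    KeypointSeries,
    to_pixels,
)
from .preprocess import valid_window

logger = logging.getLogger(__name__)

HEEL_STRIKE = "heel_strike"
TOE_OFF = "toe_off"
LEGS = ("left", "right")

_KIND_ORDER = {HEEL_STRIKE: 0, TOE_OFF: 1}
_LEG_ORDER = {"left": 0, "right": 1}


@dataclass(frozen=True)
class EventDetectionConfig:
    """Thresholds governing heel-strike / toe-off detection."""

    min_event_separation_s: float = 0.8
    peak_fraction_left: float = 0.35
    peak_fraction_right: float = 0.46
    minima_fraction: float = 0.18
    direction: str | int = "auto"     # 'auto', +1 (increasing x) or -1
    hip_reference: str = "ipsilateral"  # or 'midhip'
    subframe_refinement: bool = False

    def __post_init__(self) -> None:
        if not self.min_event_separation_s > 0:
            raise ValidationError("min_event_separation_s must be positive")
        for name in ("peak_fraction_left", "peak_fraction_right", "minima_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        if self.direction not in ("auto", 1, -1, +1):
            raise ValidationError("direction must be 'auto', +1 or -1")
        if self.hip_reference not in ("ipsilateral", "midhip"):
            raise ValidationError("hip_reference must be 'ipsilateral' or 'midhip'")

    def peak_fraction(self, leg: str) -> float:
        return self.peak_fraction_left if leg == "left" else self.peak_fraction_right


@dataclass
class GaitSignal:
    """One leg's forward-positive hip-to-foot-index distance in pixels."""

    leg: str
    values: np.ndarray  # NaN outside valid_window
    fps: float
    valid_window: tuple[int, int]

    def __post_init__(self) -> None:
        if self.leg not in LEGS:
            raise ValidationError(f"leg must be 'left' or 'right', got {self.leg!r}")
        if not self.fps > 0:
            raise ValidationError("fps must be positive")


@dataclass(frozen=True, order=True)
class GaitEvent:
    """A single heel-strike or toe-off occurrence."""

    sort_key: tuple = field(init=False, repr=False, compare=True)
    kind: str = field(compare=False)
    leg: str = field(compare=False)
    frame: int = field(compare=False)
    time_s: float = field(compare=False)

    def __post_init__(self) -> None:
        if self.kind not in (HEEL_STRIKE, TOE_OFF):
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.leg not in LEGS:
            raise ValidationError(f"unknown leg {self.leg!r}")
        object.__setattr__(
            self, "sort_key",
            (self.time_s, _KIND_ORDER[self.kind], _LEG_ORDER[self.leg]),
        )


def infer_walking_direction(series: KeypointSeries) -> int:
    """Sign of the subject's net horizontal progression (+1 = increasing x).

    Uses the mid-hip pixel x displacement between the first and last frames
    where both hips are present.

    Raises
    ------
    AmbiguousDirectionError
        If the net displacement is under one pixel.
    """
    left = to_pixels(series, LEFT_HIP, "x")
    right = to_pixels(series, RIGHT_HIP, "x")
    mid = (left + right) / 2.0
    valid = np.flatnonzero(np.isfinite(mid))
    if valid.size < 2:
        raise AmbiguousDirectionError("hip landmarks present in fewer than 2 frames")
    net = mid[valid[-1]] - mid[valid[0]]
    if abs(net) < 1.0:
        raise AmbiguousDirectionError(
            f"net mid-hip displacement {net:.3f} px is under 1 px; "
            "supply events.direction in the config"
        )
    return 1 if net > 0 else -1


def relative_distance_signal(
    series: KeypointSeries,
    leg: str,
    direction: int,
    hip_reference: str = "ipsilateral",
) -> GaitSignal:
    """Forward-positive hip-to-foot-index horizontal distance for one leg.

    ``values[t] = direction * (x_foot_index[t] - x_hip[t])`` in pixels, so
    displacement along the progression direction is positive regardless of
    which way the subject crosses the frame.
    """
    if leg not in LEGS:
        raise ValidationError(f"leg must be 'left' or 'right', got {leg!r}")
    if direction not in (1, -1):
        raise ValidationError(f"direction must be +1 or -1, got {direction!r}")
    foot_idx = LEFT_FOOT_INDEX if leg == "left" else RIGHT_FOOT_INDEX
    foot = to_pixels(series, foot_idx, "x")
    if hip_reference == "midhip":
        hip = (to_pixels(series, LEFT_HIP, "x") + to_pixels(series, RIGHT_HIP, "x")) / 2.0
    else:
        hip = to_pixels(series, LEFT_HIP if leg == "left" else RIGHT_HIP, "x")
    values = direction * (foot - hip)
    try:
        window = valid_window(values)
    except InsufficientDataError:
        raise InsufficientDataError(
            f"{leg} leg: hip and foot index share no valid frames"
        ) from None
    return GaitSignal(leg=leg, values=values, fps=series.fps, valid_window=window)


# ---------------------------------------------------------------------------
# Extremum detection
# ---------------------------------------------------------------------------

def _local_maxima_candidates(values: np.ndarray, first: int, last: int) -> np.ndarray:
    """Frames of local maxima in values[first..last], plateaus -> first frame.

    A run of equal values is a single candidate anchored at its first frame;
    it qualifies only if the neighbouring runs on both sides exist and are
    lower — window edges cannot be confirmed as extrema and never qualify.
    """
    v = values[first : last + 1]
    n = v.size
    if n < 3:
        return np.empty(0, dtype=int)
    # run-length encode
    starts = [0]
    for i in range(1, n):
        if v[i] != v[i - 1]:
            starts.append(i)
    starts.append(n)
    out = []
    n_runs = len(starts) - 1
    for r in range(1, n_runs - 1):
        s = starts[r]
        if v[starts[r - 1]] < v[s] and v[starts[r + 1]] < v[s]:
            out.append(s)
    return np.asarray(out, dtype=int) + first


def _enforce_separation(
    frames: np.ndarray, magnitudes: np.ndarray, min_sep_frames: int
) -> np.ndarray:
    """Greedy selection by descending magnitude under a spacing constraint.

    Ties in magnitude are broken toward the earlier frame, keeping the
    selection deterministic.
    """
    order = np.lexsort((frames, -magnitudes))
    kept: list[int] = []
    for i in order:
        f = frames[i]
        if all(abs(f - k) >= min_sep_frames for k in kept):
            kept.append(int(f))
    return np.asarray(sorted(kept), dtype=int)


def detect_extrema(
    signal: GaitSignal, config: EventDetectionConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Heel-strike (peak) and toe-off (minimum) frames for one leg's signal.

    Peaks are local maxima at least ``peak_fraction(leg)`` of the global
    maximum, thinned so any two retained peaks are >= the minimum separation
    apart (the larger peak wins a conflict).  Minima are handled
    symmetrically on the negated signal with the 18% depth rule.
    """
    config = config or EventDetectionConfig()
    first, last = signal.valid_window
    min_sep = int(round(config.min_event_separation_s * signal.fps))
    values = signal.values

    vmax = np.nanmax(values[first : last + 1])
    vmin = np.nanmin(values[first : last + 1])
    if vmin >= 0:
        warnings.warn(
            f"{signal.leg} leg distance signal never goes negative "
            f"(min {vmin:.2f} px); the toe-off depth rule is degenerate — "
            "check the walking direction and hip reference",
            stacklevel=2,
        )

    peaks = _local_maxima_candidates(values, first, last)
    peaks = peaks[values[peaks] >= config.peak_fraction(signal.leg) * vmax]
    peaks = _enforce_separation(peaks, values[peaks], min_sep)

    minima = _local_maxima_candidates(-values, first, last)
    minima = minima[values[minima] <= config.minima_fraction * vmin]
    minima = _enforce_separation(minima, -values[minima], min_sep)
    return peaks, minima


def _refine_subframe(values: np.ndarray, frame: int) -> float:
    """Parabolic sub-frame vertex through the sample and its neighbours."""
    if frame <= 0 or frame >= values.size - 1:
        return float(frame)
    y0, y1, y2 = values[frame - 1 : frame + 2]
    denom = y0 - 2 * y1 + y2
    if denom == 0 or not np.isfinite(denom):
        return float(frame)
    delta = 0.5 * (y0 - y2) / denom
    return float(frame) + float(np.clip(delta, -0.5, 0.5))


def detect_gait_events(
    series: KeypointSeries, config: EventDetectionConfig | None = None
) -> list[GaitEvent]:
    """Detect heel strikes and toe-offs on both legs, time-sorted.

    Ties at the same instant are ordered heel-strike before toe-off and left
    before right.  A leg yielding no events produces a logged warning, not an
    error.
    """
    config = config or EventDetectionConfig()
    if config.direction == "auto":
        direction = infer_walking_direction(series)
    else:
        direction = int(config.direction)

    events: list[GaitEvent] = []
    for leg in LEGS:
        sig = relative_distance_signal(series, leg, direction, config.hip_reference)
        peaks, minima = detect_extrema(sig, config)
        if peaks.size == 0 and minima.size == 0:
            logger.warning("no gait events detected on the %s leg", leg)
            continue
        for kind, frames in ((HEEL_STRIKE, peaks), (TOE_OFF, minima)):
            for f in frames:
                if config.subframe_refinement:
                    ref = sig.values if kind == HEEL_STRIKE else -sig.values
                    t = _refine_subframe(ref, int(f)) / series.fps
                else:
                    t = f / series.fps
                events.append(GaitEvent(kind=kind, leg=leg, frame=int(f), time_s=float(t)))
    return sorted(events)
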