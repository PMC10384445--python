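"""Synthetic sagittal-plane gait sequences with exact ground truth.

The generator emulates the capture conditions the pipeline targets: a
subject walking at constant speed across a 960x540 frame filmed at 25 fps
from the side.  Rather than simulating limb dynamics, it constructs each
leg's forward-positive hip-to-foot-index distance waveform directly —

* stance: a linear fall from +A at heel strike to -A at toe-off, which
  (with A = speed x stance / 2) makes the foot exactly stationary in world
  coordinates while the hip advances over it;
* swing: a monotone smoothstep rise from -A back to +A, so the foot
  overtakes the hip with zero relative velocity at touchdown;

and derives the foot trajectory as hip + distance.  The waveform's maxima
and minima therefore fall exactly on the constructed heel-strike and
toe-off times, making the ground truth an exact oracle rather than an
approximation.  The signal crosses zero (foot behind the hip at toe-off),
matching the sign assumption of the toe-off depth rule.

The two legs run the same waveform offset by ``step_phase_offset`` of a
stride (0.5 = symmetric gait).  Optional Gaussian pixel noise and
visibility gaps in the foot landmarks exercise the gap-filling and
filtering stages.  The remaining 29 landmarks ride along as static offsets
from the hip so file-format and I/O paths see a full 33-landmark skeleton.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .events import HEEL_STRIKE, TOE_OFF, GaitEvent
from .keypoints import (
    LANDMARK_INDEX,
    LEFT_FOOT_INDEX,
    N_LANDMARKS,
    RIGHT_FOOT_INDEX,
    KeypointSeries,
)
from .temporal import GaitParameters, compute_parameters

_EDGE_MARGIN_PX = 60.0  # clearance kept between the skeleton and frame edges


@dataclass(frozen=True)
class SyntheticGaitSpec:
    """Parameters of one synthetic walking sequence.

    Defaults mirror a healthy adult at comfortable pace: stride 1.21 s
    (stance 0.81 s + swing 0.40 s, i.e. duty factor 0.66), symmetric legs,
    captured at 960x540 @ 25 fps.
    """

    n_strides: int = 10
    stride_time_s: float = 1.21
    duty_factor: float = 0.66
    walking_speed_px_s: float = 55.0
    step_phase_offset: float = 0.5
    fps: float = 25.0
    image_width: int = 960
    image_height: int = 540
    noise_sd_px: float = 0.0
    gap_fraction: float = 0.0
    direction: int = -1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strides < 2:
            raise ValidationError("n_strides must be >= 2")
        if self.stride_time_s * self.fps < 10:
            raise ValidationError("stride_time_s x fps must be >= 10 frames")
        if not 0.5 < self.duty_factor < 0.8:
            raise ValidationError("duty_factor must be in (0.5, 0.8)")
        if not 0.0 < self.step_phase_offset < 1.0:
            raise ValidationError("step_phase_offset must be in (0, 1)")
        if self.direction not in (1, -1):
            raise ValidationError("direction must be +1 or -1")
        if not 0.0 <= self.gap_fraction < 1.0:
            raise ValidationError("gap_fraction must be in [0, 1)")
        if self.noise_sd_px < 0:
            raise ValidationError("noise_sd_px must be >= 0")
        if not self.walking_speed_px_s > 0:
            raise ValidationError("walking_speed_px_s must be positive")

    @property
    def stance_time_s(self) -> float:
        return self.duty_factor * self.stride_time_s

    @property
    def swing_time_s(self) -> float:
        return (1.0 - self.duty_factor) * self.stride_time_s

    @property
    def duration_s(self) -> float:
        # half a stride of lead-in before the first heel strike, and the
        # same margin after the last event, so no event sits on a window edge
        return (self.n_strides + 1) * self.stride_time_s

    @property
    def amplitude_px(self) -> float:
        """Half the stance-phase relative-distance sweep (exact foot plant)."""
        return 0.5 * self.walking_speed_px_s * self.stance_time_s


@dataclass
class GroundTruth:
    """Exact event times and the parameters they imply."""

    events: list[GaitEvent]
    parameters: GaitParameters


def _distance_waveform(phase: np.ndarray, duty: float, amplitude: float) -> np.ndarray:
    """Relative distance as a function of stride phase (HS at phase 0)."""
    phase = np.mod(phase, 1.0)
    d = np.empty_like(phase)
    stance = phase < duty
    d[stance] = amplitude * (1.0 - 2.0 * phase[stance] / duty)
    u = (phase[~stance] - duty) / (1.0 - duty)
    d[~stance] = amplitude * (-1.0 + 2.0 * (3.0 * u**2 - 2.0 * u**3))
    return d


# static pixel offsets (dx, dy) from the hip centre for the non-gait
# landmarks; y is image-down, the subject is ~380 px tall
_STATIC_OFFSETS: dict[str, tuple[float, float]] = {
    "nose": (12.0, -150.0),
    "left_eye_inner": (13.0, -155.0), "left_eye": (14.0, -155.0),
    "left_eye_outer": (15.0, -155.0), "right_eye_inner": (11.0, -155.0),
    "right_eye": (10.0, -155.0), "right_eye_outer": (9.0, -155.0),
    "left_ear": (6.0, -152.0), "right_ear": (5.0, -152.0),
    "mouth_left": (13.0, -144.0), "mouth_right": (11.0, -144.0),
    "left_shoulder": (2.0, -110.0), "right_shoulder": (-2.0, -110.0),
    "left_elbow": (6.0, -55.0), "right_elbow": (-6.0, -55.0),
    "left_wrist": (10.0, -5.0), "right_wrist": (-10.0, -5.0),
    "left_pinky": (12.0, 5.0), "right_pinky": (-12.0, 5.0),
    "left_index": (13.0, 5.0), "right_index": (-13.0, 5.0),
    "left_thumb": (11.0, 3.0), "right_thumb": (-11.0, 3.0),
    "left_hip": (0.0, 0.0), "right_hip": (0.0, 0.0),
    "left_knee": (3.0, 90.0), "right_knee": (-3.0, 90.0),
    "left_ankle": (3.0, 175.0), "right_ankle": (-3.0, 175.0),
    "left_heel": (0.0, 185.0), "right_heel": (-1.0, 185.0),
}


def generate(spec: SyntheticGaitSpec) -> tuple[KeypointSeries, GroundTruth]:
    """One synthetic subject: keypoint series plus exact ground truth.

    Raises
    ------
    ValidationError
        If the hip would leave the frame at the requested speed/duration;
        the message states the maximum feasible speed.
    """
    n_frames = int(round(spec.duration_s * spec.fps)) + 1
    t = np.arange(n_frames) / spec.fps
    travel = spec.walking_speed_px_s * spec.duration_s
    usable = spec.image_width - 2.0 * _EDGE_MARGIN_PX
    if travel > usable:
        raise ValidationError(
            f"hip travels {travel:.0f} px but only {usable:.0f} px are inside "
            f"the frame margins; reduce walking_speed_px_s below "
            f"{usable / spec.duration_s:.1f}"
        )
    if spec.direction > 0:
        x0 = _EDGE_MARGIN_PX
    else:
        x0 = spec.image_width - _EDGE_MARGIN_PX
    hip_x = x0 + spec.direction * spec.walking_speed_px_s * t
    hip_y = np.full(n_frames, 0.45 * spec.image_height)

    t0 = 0.5 * spec.stride_time_s  # first left heel strike
    amp = spec.amplitude_px
    phase_left = (t - t0) / spec.stride_time_s
    phase_right = phase_left - spec.step_phase_offset

    data = np.full((n_frames, N_LANDMARKS, 4), np.nan)
    data[:, :, 3] = 1.0  # fully visible unless gapped

    for name, (dx, dy) in _STATIC_OFFSETS.items():
        lm = LANDMARK_INDEX[name]
        data[:, lm, 0] = hip_x + spec.direction * dx
        data[:, lm, 1] = hip_y + dy
        data[:, lm, 2] = 0.0

    foot_y = hip_y[0] + 0.35 * spec.image_height
    for foot_lm, phase in ((LEFT_FOOT_INDEX, phase_left), (RIGHT_FOOT_INDEX, phase_right)):
        d = _distance_waveform(phase, spec.duty_factor, amp)
        data[:, foot_lm, 0] = hip_x + spec.direction * d
        # small foot lift during swing (image-down y decreases when lifted)
        ph = np.mod(phase, 1.0)
        swing = ph >= spec.duty_factor
        u = (ph - spec.duty_factor) / (1.0 - spec.duty_factor)
        lift = np.where(swing, 20.0 * 4.0 * u * (1.0 - u), 0.0)
        data[:, foot_lm, 1] = foot_y - lift
        data[:, foot_lm, 2] = 0.0

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd_px > 0:
        data[:, :, 0] += rng.normal(0.0, spec.noise_sd_px, (n_frames, N_LANDMARKS))
        data[:, :, 1] += rng.normal(0.0, spec.noise_sd_px, (n_frames, N_LANDMARKS))
    if spec.gap_fraction > 0:
        n_gap = int(np.floor(spec.gap_fraction * n_frames))
        gap_frames = rng.choice(n_frames, size=n_gap, replace=False)
        gap_feet = rng.choice([LEFT_FOOT_INDEX, RIGHT_FOOT_INDEX], size=n_gap)
        data[gap_frames, gap_feet, :] = np.nan

    data[:, :, 0] = np.clip(data[:, :, 0], 0.0, spec.image_width) / spec.image_width
    data[:, :, 1] = np.clip(data[:, :, 1], 0.0, spec.image_height) / spec.image_height

    series = KeypointSeries(
        data=data, fps=spec.fps, image_width=spec.image_width,
        image_height=spec.image_height, subject_id=f"synth-{spec.seed}",
    )

    # the waveform is periodic, so partial cycles at the sequence ends also
    # produce extrema: enumerate every event whose frame is strictly interior
    # (an extremum on the very first/last frame cannot be confirmed as such)
    events: list[GaitEvent] = []
    for leg, offset in (("left", 0.0), ("right", spec.step_phase_offset)):
        for k in range(-2, spec.n_strides + 2):
            hs = t0 + (k + offset) * spec.stride_time_s
            to = hs + spec.stance_time_s
            for kind, time in ((HEEL_STRIKE, hs), (TOE_OFF, to)):
                frame = int(round(time * spec.fps))
                if 1 <= frame <= n_frames - 2:
                    events.append(GaitEvent(
                        kind=kind, leg=leg, frame=frame, time_s=float(time),
                    ))
    events.sort()
    parameters = compute_parameters(events, spec.fps, subject_id=series.subject_id)
    return series, GroundTruth(events=events, parameters=parameters)


def generate_cohort(
    n_subjects: int,
    base_spec: SyntheticGaitSpec | None = None,
    stride_jitter_sd_s: float = 0.0,
    seed: int = 0,
) -> list[tuple[KeypointSeries, GroundTruth]]:
    """A cohort with between-subject stride-time variation.

    Each subject's stride time is drawn from a normal around the base spec
    (truncated to the generator's valid range) and each gets a distinct
    derived seed, so agreement statistics see genuine between-subject
    variance.
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    if stride_jitter_sd_s < 0:
        raise ValidationError("stride_jitter_sd_s must be >= 0")
    base_spec = base_spec or SyntheticGaitSpec()
    rng = np.random.default_rng(seed)
    low = max(0.5, 10.0 / base_spec.fps)
    high = 2.5
    cohort = []
    for i in range(n_subjects):
        stride = base_spec.stride_time_s
        if stride_jitter_sd_s > 0:
            stride = float(rng.normal(base_spec.stride_time_s, stride_jitter_sd_s))
            stride = float(np.clip(stride, low, high))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(base_spec, stride_time_s=stride, seed=sub_seed)
        series, truth = generate(spec)
        series.subject_id = f"synth{i:02d}"
        truth.parameters.subject_id = series.subject_id
        truth.parameters.records["subject_id"] = series.subject_id
        cohort.append((series, truth))
    return cohort
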