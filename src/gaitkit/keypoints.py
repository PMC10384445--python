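"""Keypoint data model and I/O.

The pipeline consumes per-frame body keypoints in the 33-landmark BlazePose
topology.  Coordinates are stored normalized: ``x`` as a fraction of image
width, ``y`` as a fraction of image height, both in [0, 1]; ``z`` is a
unitless depth relative to the hip midpoint (smaller = nearer the camera) and
is carried through I/O but unused by the gait computations, which operate on
horizontal pixel distances only.  ``visibility`` in [0, 1] scores how likely
the landmark is actually visible.

A landmark sample is *missing* when it is absent from the input file or, if a
visibility floor is applied, when its visibility falls below that floor.
Missing samples are represented as NaN.

File format (long CSV, one row per frame x landmark)::

    # gaitkit-keypoints v1
    # fps: 25.0
    # image_width: 960
    # image_height: 540
    # subject_id: s01
    frame,landmark_index,landmark_name,x,y,z,visibility

Missing fields are empty cells; a (frame, landmark) pair absent from the file
is also treated as missing.  A JSON equivalent with the same row content under
``meta`` / ``rows`` keys is accepted and produced as well.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np

from .errors import BackendUnavailableError, ParseError, ValidationError

# BlazePose 33-landmark topology (index -> canonical name).
LANDMARK_NAMES: tuple[str, ...] = (
    "nose",
    "left_eye_inner",
    "left_eye",
    "left_eye_outer",
    "right_eye_inner",
    "right_eye",
    "right_eye_outer",
    "left_ear",
    "right_ear",
    "mouth_left",
    "mouth_right",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_pinky",
    "right_pinky",
    "left_index",
    "right_index",
    "left_thumb",
    "right_thumb",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
    "left_heel",
    "right_heel",
    "left_foot_index",
    "right_foot_index",
)

N_LANDMARKS = len(LANDMARK_NAMES)
LANDMARK_INDEX: dict[str, int] = {name: i for i, name in enumerate(LANDMARK_NAMES)}

# The four landmarks the gait computations require.
LEFT_HIP = LANDMARK_INDEX["left_hip"]          # 23
RIGHT_HIP = LANDMARK_INDEX["right_hip"]        # 24
LEFT_FOOT_INDEX = LANDMARK_INDEX["left_foot_index"]    # 31
RIGHT_FOOT_INDEX = LANDMARK_INDEX["right_foot_index"]  # 32
GAIT_LANDMARKS = (LEFT_HIP, RIGHT_HIP, LEFT_FOOT_INDEX, RIGHT_FOOT_INDEX)

_CHANNELS = ("x", "y", "z", "visibility")
_FORMAT_TAG = "gaitkit-keypoints v1"


def resolve_landmark(landmark: int | str) -> int:
    """Map a landmark index or canonical name to its index.

    Raises
    ------
    ValidationError
        If the name is unknown or the index out of range.
    """
    if isinstance(landmark, str):
        try:
            return LANDMARK_INDEX[landmark]
        except KeyError:
            raise ValidationError(f"unknown landmark name: {landmark!r}") from None
    idx = int(landmark)
    if not 0 <= idx < N_LANDMARKS:
        raise ValidationError(f"landmark index out of range: {idx}")
    return idx


@dataclass(frozen=True)
class PoseBackendConfig:
    """Configuration handed to a pose-estimation backend.

    The detector locates the person once; a tracker then follows the pose
    from frame to frame, so both confidence thresholds matter.
    """

    min_tracking_confidence: float = 0.5
    min_detection_confidence: float = 0.5
    model_name: str = "default"

    def __post_init__(self) -> None:
        for name in ("min_tracking_confidence", "min_detection_confidence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")


@dataclass
class KeypointSeries:
    """A contiguous per-frame keypoint time series.

    ``data`` has shape (n_frames, 33, 4) with channels (x, y, z, visibility);
    NaN marks a missing value.  Frame indices are implicit 0..n_frames-1:
    ingestion materializes skipped frames as all-missing.
    """

    data: np.ndarray
    fps: float
    image_width: int
    image_height: int
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1:] != (N_LANDMARKS, len(_CHANNELS)):
            raise ValidationError(
                f"keypoint data must have shape (n, {N_LANDMARKS}, {len(_CHANNELS)}), "
                f"got {self.data.shape}"
            )
        if not self.fps > 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")
        with np.errstate(invalid="ignore"):
            xy = self.data[:, :, :2]
            bad = (xy < 0.0) | (xy > 1.0)
        if np.any(bad):
            f, l, _ = np.argwhere(bad)[0]
            raise ValidationError(
                f"normalized coordinate outside [0, 1] at frame {f}, "
                f"landmark {LANDMARK_NAMES[l]}"
            )
        vis = self.data[:, :, 3]
        with np.errstate(invalid="ignore"):
            if np.any((vis < 0.0) | (vis > 1.0)):
                raise ValidationError("visibility outside [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def copy(self) -> "KeypointSeries":
        return replace(self, data=self.data.copy())

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_frames, 33) mask, True where x or y is missing."""
        return np.isnan(self.data[:, :, 0]) | np.isnan(self.data[:, :, 1])


def apply_visibility_floor(series: KeypointSeries, floor: float) -> KeypointSeries:
    """Mark landmark samples with visibility below ``floor`` as missing.

    Mirrors the tracker's own confidence threshold: a low-visibility sample
    is treated as a gap to be spline-filled rather than trusted as-is.
    """
    if not 0.0 <= floor <= 1.0:
        raise ValidationError(f"visibility floor must be in [0, 1], got {floor}")
    out = series.copy()
    vis = out.data[:, :, 3]
    with np.errstate(invalid="ignore"):
        low = vis < floor
    out.data[low, :] = np.nan
    return out


def to_pixels(series: KeypointSeries, landmark: int | str, axis: str) -> np.ndarray:
    """One landmark's trajectory along ``axis`` ('x' or 'y') in pixels.

    Missing samples stay NaN.
    """
    idx = resolve_landmark(landmark)
    if axis == "x":
        return series.data[:, idx, 0] * series.image_width
    if axis == "y":
        return series.data[:, idx, 1] * series.image_height
    raise ValidationError(f"axis must be 'x' or 'y', got {axis!r}")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_keypoints(series: KeypointSeries, path: str | Path) -> None:
    """Write a series to the documented long CSV (or JSON if *.json).

    Every (frame, landmark) pair gets a row; missing values are empty cells,
    so missingness round-trips exactly.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        _write_json(series, path)
        return
    def cell(v: float) -> str:
        return "" if np.isnan(v) else repr(float(v))

    lines = [
        f"# {_FORMAT_TAG}",
        f"# fps: {series.fps!r}",
        f"# image_width: {series.image_width}",
        f"# image_height: {series.image_height}",
        f"# subject_id: {series.subject_id}",
        "frame,landmark_index,landmark_name,x,y,z,visibility",
    ]
    for f in range(series.n_frames):
        for l in range(N_LANDMARKS):
            x, y, z, vis = series.data[f, l]
            lines.append(
                f"{f},{l},{LANDMARK_NAMES[l]},{cell(x)},{cell(y)},{cell(z)},{cell(vis)}"
            )
    path.write_text("\n".join(lines) + "\n")


def _write_json(series: KeypointSeries, path: Path) -> None:
    def val(v: float):
        return None if np.isnan(v) else float(v)

    rows = []
    for f in range(series.n_frames):
        for l in range(N_LANDMARKS):
            x, y, z, vis = series.data[f, l]
            rows.append(
                {"frame": f, "landmark_index": l, "x": val(x), "y": val(y),
                 "z": val(z), "visibility": val(vis)}
            )
    obj = {
        "format": _FORMAT_TAG,
        "meta": {
            "fps": series.fps,
            "image_width": series.image_width,
            "image_height": series.image_height,
            "subject_id": series.subject_id,
        },
        "rows": rows,
    }
    path.write_text(json.dumps(obj))


def read_keypoints(
    path: str | Path,
    fps: float | None = None,
    image_size: tuple[int, int] | None = None,
    subject_id: str | None = None,
    visibility_floor: float | None = None,
) -> KeypointSeries:
    """Read a keypoint series from the long CSV or JSON layout.

    ``fps`` / ``image_size`` override any sidecar metadata in the file; one
    of the two sources must provide each.  Skipped frames are materialized as
    all-missing so the returned series is contiguous from frame 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        meta, rows = _read_json_rows(path)
    else:
        meta, rows = _read_csv_rows(path)

    fps = fps if fps is not None else meta.get("fps")
    if image_size is not None:
        width, height = image_size
    else:
        width, height = meta.get("image_width"), meta.get("image_height")
    if fps is None or width is None or height is None:
        raise ValidationError(
            "fps and image size must be given as arguments or file metadata"
        )
    subject_id = subject_id or meta.get("subject_id") or path.stem

    n_frames = max(r[0] for r in rows) + 1 if rows else 0
    data = np.full((n_frames, N_LANDMARKS, len(_CHANNELS)), np.nan)
    for frame, lm, vals in rows:
        data[frame, lm, :] = vals
    series = KeypointSeries(
        data=data, fps=float(fps), image_width=int(width),
        image_height=int(height), subject_id=str(subject_id),
    )
    if visibility_floor is not None:
        series = apply_visibility_floor(series, visibility_floor)
    return series


def _read_csv_rows(path: Path):
    meta: dict = {}
    rows: list[tuple[int, int, list[float]]] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = _coerce_meta(key.strip(), value.strip())
                continue
            if not header_seen:
                header_seen = True
                expected = "frame,landmark_index,landmark_name,x,y,z,visibility"
                if line.replace(" ", "") != expected:
                    raise ParseError(
                        f"{path}:{lineno}: unexpected header {line!r}"
                    )
                continue
            parts = line.split(",")
            if len(parts) != 7:
                raise ParseError(f"{path}:{lineno}: expected 7 fields, got {len(parts)}")
            try:
                frame = int(parts[0])
                lm = int(parts[1])
                vals = [float(p) if p.strip() != "" else np.nan for p in parts[3:7]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if frame < 0 or not 0 <= lm < N_LANDMARKS:
                raise ParseError(f"{path}:{lineno}: frame/landmark out of range")
            rows.append((frame, lm, vals))
    return meta, rows


def _coerce_meta(key: str, value: str):
    if key == "fps":
        return float(value)
    if key in ("image_width", "image_height"):
        return int(value)
    return value


def _read_json_rows(path: Path):
    try:
        obj = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON: {exc}") from None
    meta = obj.get("meta", {})
    rows = []
    for i, r in enumerate(obj.get("rows", [])):
        try:
            frame, lm = int(r["frame"]), int(r["landmark_index"])
            vals = [
                np.nan if r.get(c) is None else float(r[c])
                for c in ("x", "y", "z", "visibility")
            ]
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from None
        rows.append((frame, lm, vals))
    return meta, rows


# ---------------------------------------------------------------------------
# Video extraction (pluggable backend)
# ---------------------------------------------------------------------------

class PoseBackend(Protocol):
    """Contract for a pose-estimation backend.

    The backend owns the neural network.  It must honor the detector-tracker
    pipeline: the person detector runs on the first frame (or after tracking
    loss) and a tracker follows thereafter.  ``extract`` returns per-frame
    keypoints in normalized coordinates plus a per-frame tracking confidence.
    """

    def extract(
        self, video_path: str | Path, config: PoseBackendConfig
    ) -> tuple[np.ndarray, np.ndarray, float, int, int]:
        """Return (data (n, 33, 4), confidence (n,), fps, width, height)."""
        ...


def extract_from_video(
    video_path: str | Path,
    backend: PoseBackend | None,
    config: PoseBackendConfig | None = None,
    subject_id: str | None = None,
) -> KeypointSeries:
    """Run a pose backend over a video and return the keypoint series.

    Frames whose tracking confidence falls below
    ``config.min_tracking_confidence`` come back all-missing.  The frame
    count, fps and image size are taken from the video container via the
    backend; one output frame per input frame, never more.
    """
    if backend is None:
        raise BackendUnavailableError(
            "no pose-estimation backend is installed; extract keypoints "
            "elsewhere and load them with read_keypoints() from the "
            "documented CSV/JSON layout instead"
        )
    config = config or PoseBackendConfig()
    data, confidence, fps, width, height = backend.extract(video_path, config)
    data = np.array(data, dtype=float)
    confidence = np.asarray(confidence, dtype=float)
    if data.shape[0] != confidence.shape[0]:
        raise ValidationError("backend returned mismatched frame/confidence counts")
    data[confidence < config.min_tracking_confidence, :, :] = np.nan
    return KeypointSeries(
        data=data, fps=float(fps), image_width=int(width), image_height=int(height),
        subject_id=subject_id or Path(video_path).stem,
    )
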