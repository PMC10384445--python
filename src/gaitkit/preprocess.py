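"""Trajectory cleaning: cubic-spline gap filling and zero-phase low-pass.

Tracking failures leave gaps in the landmark trajectories; interior gaps are
filled with a not-a-knot cubic spline through the valid samples.  Leading and
trailing gaps are never extrapolated (spline extrapolation is unbounded and
would fabricate events) — the analysis window simply shrinks.

High-frequency jitter is removed with a 10th-order Butterworth low-pass
filter at a normalized cutoff of 0.1752 (fraction of Nyquist; 2.19 Hz at
25 fps), applied forward-backward so events are not delayed.  The filter is
realized as cascaded second-order sections: a 10th-order transfer function in
direct form is numerically ill-conditioned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .errors import InsufficientDataError, ValidationError
from .keypoints import LANDMARK_NAMES, KeypointSeries

logger = logging.getLogger(__name__)

MIN_SPLINE_SAMPLES = 4  # a cubic needs four support points


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter parameters.

    ``normalized_cutoff`` is a fraction of the Nyquist frequency under the
    default ``cutoff_convention='nyquist'`` (the dominant signal-library
    convention); set ``cutoff_convention='fs'`` to read it as a fraction of
    the sampling rate instead (which doubles the effective cutoff passed to
    the design routine).
    """

    order: int = 10
    normalized_cutoff: float = 0.1752
    cutoff_convention: str = "nyquist"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValidationError(f"filter order must be >= 1, got {self.order}")
        if not 0.0 < self.normalized_cutoff < 1.0:
            raise ValidationError(
                f"normalized cutoff must be in (0, 1), got {self.normalized_cutoff}"
            )
        if self.cutoff_convention not in ("nyquist", "fs"):
            raise ValidationError(
                f"cutoff_convention must be 'nyquist' or 'fs', "
                f"got {self.cutoff_convention!r}"
            )

    @property
    def wn(self) -> float:
        """Cutoff as a fraction of Nyquist (the scipy design convention)."""
        if self.cutoff_convention == "nyquist":
            return self.normalized_cutoff
        return 2.0 * self.normalized_cutoff

    def min_signal_length(self) -> int:
        # forward-backward padding of 3*order samples per end
        return 3 * self.order + 1


def valid_window(values: np.ndarray) -> tuple[int, int]:
    """Indices of the first and last finite samples (inclusive).

    Raises
    ------
    InsufficientDataError
        If no sample is finite.
    """
    finite = np.flatnonzero(np.isfinite(values))
    if finite.size == 0:
        raise InsufficientDataError("signal has no valid samples")
    return int(finite[0]), int(finite[-1])


def fill_gaps(values: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """Fill interior NaN gaps with a not-a-knot cubic spline.

    Returns the filled signal (same length) and the valid window
    ``(first, last)``; samples outside the window stay NaN.

    Raises
    ------
    InsufficientDataError
        With fewer than four valid samples.
    """
    values = np.asarray(values, dtype=float)
    valid = np.isfinite(values)
    n_valid = int(valid.sum())
    if n_valid < MIN_SPLINE_SAMPLES:
        raise InsufficientDataError(
            f"gap filling needs >= {MIN_SPLINE_SAMPLES} valid samples, got {n_valid}"
        )
    first, last = valid_window(values)
    out = values.copy()
    gap_idx = np.flatnonzero(~valid[first : last + 1]) + first
    if gap_idx.size:
        t = np.flatnonzero(valid)
        spline = CubicSpline(t, values[t], bc_type="not-a-knot")
        out[gap_idx] = spline(gap_idx)
    return out, (first, last)


def design_lowpass(spec: FilterSpec) -> np.ndarray:
    """Butterworth low-pass design, returned as second-order sections.

    The magnitude response satisfies |H(w)|^2 = 1 / (1 + (w/wc)^(2*order)):
    unit gain at DC and 1/sqrt(2) at the cutoff.
    """
    return sps.butter(spec.order, spec.wn, btype="low", output="sos")


def apply_zero_phase(spec: FilterSpec, values: np.ndarray) -> np.ndarray:
    """Forward-backward (zero-phase) application of the low-pass filter.

    Two passes double the effective magnitude attenuation (-6 dB at the
    cutoff) and cancel the phase, so extrema are not shifted in time.  Edges
    are handled with odd-reflection padding of 3*order samples, which keeps
    the first and last gait events free of start-up transients.

    Raises
    ------
    InsufficientDataError
        If the signal is shorter than 3*order + 1 samples.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("apply_zero_phase requires a gap-free signal")
    if values.size < spec.min_signal_length():
        raise InsufficientDataError(
            f"zero-phase filtering needs > {3 * spec.order} samples, "
            f"got {values.size}"
        )
    sos = design_lowpass(spec)
    return sps.sosfiltfilt(sos, values, padtype="odd", padlen=3 * spec.order)


def clean_trajectory(values: np.ndarray, spec: FilterSpec) -> tuple[np.ndarray, tuple[int, int]]:
    """Gap-fill then zero-phase filter one trajectory over its valid window."""
    filled, (first, last) = fill_gaps(values)
    window = filled[first : last + 1]
    if window.size < spec.min_signal_length():
        raise InsufficientDataError(
            f"valid window of {window.size} samples is too short to filter "
            f"(needs > {3 * spec.order})"
        )
    out = np.full_like(filled, np.nan)
    out[first : last + 1] = apply_zero_phase(spec, window)
    return out, (first, last)


def preprocess_series(
    series: KeypointSeries,
    spec: FilterSpec | None = None,
    on_insufficient: str = "skip",
) -> KeypointSeries:
    """Gap-fill and filter every landmark's x, y and z trajectories.

    Each channel is cleaned independently over its own valid window.  The
    spline and filter are linear operators, so cleaning normalized
    coordinates is identical to cleaning pixel coordinates up to the constant
    image-size scale.

    Landmarks with too few valid samples are left untouched when
    ``on_insufficient='skip'`` (all-missing landmarks are common and benign);
    with ``'raise'`` the error propagates annotated with the landmark name.
    """
    if on_insufficient not in ("skip", "raise"):
        raise ValidationError("on_insufficient must be 'skip' or 'raise'")
    spec = spec or FilterSpec()
    out = series.copy()
    for lm in range(series.data.shape[1]):
        for ch in range(3):  # x, y, z; visibility passes through
            traj = series.data[:, lm, ch]
            if not np.any(np.isfinite(traj)):
                continue
            try:
                cleaned, _ = clean_trajectory(traj, spec)
            except InsufficientDataError as exc:
                if on_insufficient == "raise":
                    raise InsufficientDataError(
                        f"landmark {LANDMARK_NAMES[lm]} ({'xyz'[ch]}): {exc}"
                    ) from exc
                logger.debug(
                    "skipping landmark %s (%s): %s", LANDMARK_NAMES[lm], "xyz"[ch], exc
                )
                continue
            out.data[:, lm, ch] = np.clip(cleaned, 0.0, 1.0) if ch < 2 else cleaned
    return out
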