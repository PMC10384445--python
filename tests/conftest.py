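import numpy as np
import pytest

import gaitkit as gk


@pytest.fixture(scope="session")
def noiseless_subject():
    """One clean synthetic walk: 10 strides, 1.2 s stride, duty 0.66, 25 fps."""
    spec = gk.SyntheticGaitSpec(
        n_strides=10, stride_time_s=1.2, duty_factor=0.66, fps=25.0, seed=42
    )
    return gk.generate(spec)


@pytest.fixture(scope="session")
def noiseless_pipeline(noiseless_subject):
    series, truth = noiseless_subject
    params, events, diagnostics = gk.run_pipeline(series)
    return params, events, diagnostics, truth


@pytest.fixture(scope="session")
def noisy_cohort():
    """31 subjects at the validation-study scale: 2 px noise, 5% foot gaps,
    0.08 s between-subject stride jitter."""
    base = gk.SyntheticGaitSpec(noise_sd_px=2.0, gap_fraction=0.05)
    return gk.generate_cohort(31, base, stride_jitter_sd_s=0.08, seed=42)


@pytest.fixture(scope="session")
def noisy_cohort_detections(noisy_cohort):
    """Pipeline output for every cohort subject (computed once per session)."""
    import warnings

    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for series, truth in noisy_cohort:
            params, events, _ = gk.run_pipeline(series)
            out.append((params, events, truth))
    return out


def make_series_from_tracks(tracks: dict, fps=25.0, width=960, height=540,
                            n_frames=None):
    """Build a KeypointSeries with given per-landmark pixel-x tracks.

    ``tracks`` maps landmark index -> array of pixel x positions; y is held
    constant mid-frame, all other landmarks stay missing.
    """
    n = n_frames or max(len(v) for v in tracks.values())
    data = np.full((n, gk.keypoints.N_LANDMARKS, 4), np.nan)
    for lm, xs in tracks.items():
        xs = np.asarray(xs, dtype=float)
        data[: len(xs), lm, 0] = xs / width
        data[: len(xs), lm, 1] = 0.5
        data[: len(xs), lm, 2] = 0.0
        data[: len(xs), lm, 3] = 1.0
    return gk.KeypointSeries(data=data, fps=fps, image_width=width, image_height=height)
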