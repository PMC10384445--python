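"""Agreement statistics between detected and reference gait measurements.

Implements the validation protocol used to compare a markerless pipeline
against a reference motion-capture system:

* one-to-one event matching within a tolerance (true/false positives and
  per-event timing errors, reference minus test);
* descriptive error statistics (mean error, SD, mean absolute error, range);
* an independent-samples t-test, Pearson's r, and the two-way random-effects
  absolute-agreement single-measure intraclass correlation ICC(2,1), with
  the conventional category bands poor (<0.500), moderate (0.500-0.750),
  good (0.750-0.900) and excellent (>=0.900);
* a per-parameter report at the gait-cycle level or the subject-mean level.

ICC(2,1) is computed from the two-way ANOVA decomposition

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with n subjects, k raters (here k = 2), MSR the between-subject, MSC the
between-rater and MSE the residual mean square.  Absolute agreement
penalizes a constant offset between systems, unlike consistency forms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError, ValidationError
from .events import GaitEvent
from .temporal import GaitParameters

logger = logging.getLogger(__name__)

DEFAULT_MATCH_TOLERANCE_S = 0.25

REPORT_COLUMNS = (
    "parameter", "leg_or_transition", "n",
    "mean_ref", "sd_ref", "mean_test", "sd_test",
    "mean_error", "sd_error", "mean_absolute_error", "error_min", "error_max",
    "t_statistic", "p_two_tailed", "pearson_r", "icc_2_1", "icc_category",
)


@dataclass(frozen=True)
class IccGuideline:
    """Category boundaries for ICC interpretation (strictly increasing)."""

    moderate: float = 0.500
    good: float = 0.750
    excellent: float = 0.900

    def __post_init__(self) -> None:
        if not self.moderate < self.good < self.excellent:
            raise ValidationError("ICC guideline boundaries must be increasing")


@dataclass
class EventMatchResult:
    """Outcome of pairing detected events against reference events."""

    pairs: list[tuple[GaitEvent, GaitEvent, float]]  # (reference, detected, ref - det)
    n_reference: int
    n_detected: int

    @property
    def n_true_positive(self) -> int:
        return len(self.pairs)

    @property
    def n_false_positive(self) -> int:
        return self.n_detected - self.n_true_positive

    @property
    def n_missed(self) -> int:
        return self.n_reference - self.n_true_positive

    @property
    def errors_s(self) -> np.ndarray:
        return np.array([p[2] for p in self.pairs], dtype=float)


def match_events(
    reference: Sequence[GaitEvent],
    detected: Sequence[GaitEvent],
    tolerance_s: float = DEFAULT_MATCH_TOLERANCE_S,
) -> EventMatchResult:
    """Greedy nearest-time one-to-one pairing within ``tolerance_s``.

    Both lists must contain a single event kind and leg.  Candidate pairs
    are taken in order of increasing |time difference| (ties broken by
    earlier reference, then earlier detected event); each event is used at
    most once.  Matched detected events are true positives, unmatched
    detected events false positives, unmatched reference events misses.
    """
    if not tolerance_s > 0:
        raise ValidationError("tolerance must be positive")
    kinds = {e.kind for e in reference} | {e.kind for e in detected}
    legs = {e.leg for e in reference} | {e.leg for e in detected}
    if len(kinds) > 1 or len(legs) > 1:
        raise ValidationError(
            f"match_events expects one event kind and leg, got {kinds} / {legs}"
        )
    candidates = []
    for i, r in enumerate(reference):
        for j, d in enumerate(detected):
            dt = abs(r.time_s - d.time_s)
            if dt <= tolerance_s:
                candidates.append((dt, i, j))
    candidates.sort()
    used_ref: set[int] = set()
    used_det: set[int] = set()
    pairs = []
    for _, i, j in candidates:
        if i in used_ref or j in used_det:
            continue
        used_ref.add(i)
        used_det.add(j)
        pairs.append((reference[i], detected[j], reference[i].time_s - detected[j].time_s))
    pairs.sort(key=lambda p: p[0].time_s)
    return EventMatchResult(pairs=pairs, n_reference=len(reference), n_detected=len(detected))


def error_stats(errors: Iterable[float]) -> dict:
    """Mean, sample SD, mean absolute error and range of a set of errors."""
    e = np.asarray(list(errors), dtype=float)
    if e.size == 0:
        raise InsufficientDataError("error_stats needs at least one error")
    return {
        "mean": float(e.mean()),
        "sd": float(e.std(ddof=1)) if e.size > 1 else float("nan"),
        "mean_absolute": float(np.abs(e).mean()),
        "range": (float(e.min()), float(e.max())),
    }


def t_test_independent(
    sample_a: Iterable[float], sample_b: Iterable[float], equal_var: bool = True
) -> dict:
    """Two-sample t-test (pooled-variance by default, Welch optional)."""
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("t-test needs n >= 2 per sample")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return {"t": float(res.statistic), "p_two_tailed": float(res.pvalue)}


def pearson_r(x: Iterable[float], y: Iterable[float]) -> float:
    """Sample Pearson correlation coefficient."""
    xv = np.asarray(list(x), dtype=float)
    yv = np.asarray(list(y), dtype=float)
    if xv.size != yv.size:
        raise ValidationError("pearson_r needs equal-length inputs")
    if xv.size < 3:
        raise InsufficientDataError("pearson_r needs n >= 3")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DegenerateDataError("correlation undefined for constant input")
    return float(stats.pearsonr(xv, yv).statistic)


def icc_2_1(ratings: np.ndarray | pd.DataFrame) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is an n-subjects x k-raters table (k = 2 in the validation
    protocol, but any k >= 2 works); rows containing missing cells are
    dropped (listwise deletion).
    """
    table = np.asarray(ratings, dtype=float)
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValidationError("ratings must be an n x k table with k >= 2")
    table = table[~np.isnan(table).any(axis=1)]
    n, k = table.shape
    if n < 3:
        raise InsufficientDataError(f"ICC needs >= 3 complete rows, got {n}")
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_total = ((table - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_error = ss_total - ss_rows - ss_cols
    if ss_total == 0:
        raise DegenerateDataError("ICC undefined: zero total variance")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_error / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise DegenerateDataError("ICC undefined: zero denominator")
    return float((msr - mse) / denom)


def categorize_icc(value: float, guideline: IccGuideline | None = None) -> str:
    """Map an ICC value to poor / moderate / good / excellent.

    Boundary values fall in the higher bin (0.500 is moderate, 0.900
    excellent), consistent with "poor (<0.500)".
    """
    if not math.isfinite(value):
        raise ValidationError("ICC value must be finite")
    g = guideline or IccGuideline()
    if value < g.moderate:
        return "poor"
    if value < g.good:
        return "moderate"
    if value < g.excellent:
        return "good"
    return "excellent"


# ---------------------------------------------------------------------------
# Parameter-level report
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Per-parameter agreement table (one row per parameter x leg)."""

    level: str
    table: pd.DataFrame
    alpha: float = 0.05

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6f")


def _as_param_list(params) -> list[GaitParameters]:
    if isinstance(params, GaitParameters):
        return [params]
    return list(params)


def _pair_per_cycle(
    ref: pd.DataFrame, test: pd.DataFrame, tolerance_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pair cycle records of one parameter by nearest start time per subject."""
    ref_vals, test_vals = [], []
    for sid, rgrp in ref.groupby("subject_id"):
        tgrp = test[test["subject_id"] == sid]
        if tgrp.empty:
            continue
        cand = []
        rt = rgrp["start_time_s"].to_numpy()
        tt = tgrp["start_time_s"].to_numpy()
        for i in range(rt.size):
            for j in range(tt.size):
                dt = abs(rt[i] - tt[j])
                if dt <= tolerance_s:
                    cand.append((dt, i, j))
        cand.sort()
        used_r, used_t = set(), set()
        rv = rgrp["value_s"].to_numpy()
        tv = tgrp["value_s"].to_numpy()
        for _, i, j in cand:
            if i in used_r or j in used_t:
                continue
            used_r.add(i)
            used_t.add(j)
            ref_vals.append(rv[i])
            test_vals.append(tv[j])
    return np.asarray(ref_vals), np.asarray(test_vals)


def _pair_per_subject(
    ref: pd.DataFrame, test: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    rm = ref.groupby("subject_id")["value_s"].mean()
    tm = test.groupby("subject_id")["value_s"].mean()
    joined = pd.concat([rm.rename("ref"), tm.rename("test")], axis=1, join="inner")
    return joined["ref"].to_numpy(), joined["test"].to_numpy()


def agreement_report(
    reference_params,
    test_params,
    level: str = "per_cycle",
    alpha: float = 0.05,
    tolerance_s: float = DEFAULT_MATCH_TOLERANCE_S,
    equal_var: bool = True,
    guideline: IccGuideline | None = None,
) -> AgreementReport:
    """Full agreement table between two systems' gait parameters.

    ``reference_params`` / ``test_params`` are a ``GaitParameters`` or a list
    of them (one per subject).  At ``level='per_cycle'`` cycles are paired by
    the start time of their defining event within ``tolerance_s``; at
    ``'per_subject'`` subject means are paired by subject id.  Parameters
    with fewer than three pairs are omitted with a log entry.
    """
    if level not in ("per_cycle", "per_subject"):
        raise ValidationError("level must be 'per_cycle' or 'per_subject'")
    ref_all = pd.concat([p.records for p in _as_param_list(reference_params)],
                        ignore_index=True)
    test_all = pd.concat([p.records for p in _as_param_list(test_params)],
                         ignore_index=True)

    rows = []
    keys = (
        ref_all[["parameter", "leg_or_transition"]]
        .drop_duplicates()
        .sort_values(["parameter", "leg_or_transition"])
    )
    for parameter, side in keys.itertuples(index=False):
        rsel = ref_all[(ref_all["parameter"] == parameter)
                       & (ref_all["leg_or_transition"] == side)]
        tsel = test_all[(test_all["parameter"] == parameter)
                        & (test_all["leg_or_transition"] == side)]
        if level == "per_cycle":
            rv, tv = _pair_per_cycle(rsel, tsel, tolerance_s)
        else:
            rv, tv = _pair_per_subject(rsel, tsel)
        if rv.size < 3:
            logger.info(
                "omitting %s (%s): only %d pairable values", parameter, side, rv.size
            )
            continue
        errors = rv - tv
        est = error_stats(errors)
        try:
            r = pearson_r(rv, tv)
        except DegenerateDataError:
            r = float("nan")
        try:
            icc = icc_2_1(np.column_stack([rv, tv]))
            category = categorize_icc(icc, guideline)
        except DegenerateDataError:
            icc, category = float("nan"), "undefined"
        tt = t_test_independent(rv, tv, equal_var=equal_var)
        rows.append({
            "parameter": parameter, "leg_or_transition": side, "n": int(rv.size),
            "mean_ref": float(rv.mean()), "sd_ref": float(rv.std(ddof=1)),
            "mean_test": float(tv.mean()), "sd_test": float(tv.std(ddof=1)),
            "mean_error": est["mean"], "sd_error": est["sd"],
            "mean_absolute_error": est["mean_absolute"],
            "error_min": est["range"][0], "error_max": est["range"][1],
            "t_statistic": tt["t"], "p_two_tailed": tt["p_two_tailed"],
            "pearson_r": r, "icc_2_1": icc, "icc_category": category,
        })
    table = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    return AgreementReport(level=level, table=table, alpha=alpha)
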