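import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

import gaitkit as gk
from gaitkit.agreement import (
    agreement_report,
    categorize_icc,
    error_stats,
    icc_2_1,
    match_events,
    pearson_r,
    t_test_independent,
)
from gaitkit.events import GaitEvent

HS, TO = gk.HEEL_STRIKE, gk.TOE_OFF


def ev(kind, leg, t, fps=25.0):
    return GaitEvent(kind=kind, leg=leg, frame=int(round(t * fps)), time_s=t)


def hand_icc_2_1(table: np.ndarray) -> float:
    """Independent oracle: ICC(2,1) from explicitly written ANOVA sums."""
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestMatchEvents:
    def test_identity_all_true_positive(self):
        ref = [ev(HS, "left", t) for t in (1.0, 2.2, 3.4)]
        m = match_events(ref, ref, tolerance_s=0.25)
        assert m.n_true_positive == 3 and m.n_false_positive == 0
        assert m.n_missed == 0
        np.testing.assert_array_equal(m.errors_s, 0.0)

    def test_constant_offset_recovered(self):
        ref = [ev(HS, "left", t) for t in (1.0, 2.2, 3.4)]
        det = [ev(HS, "left", t - 0.02) for t in (1.0, 2.2, 3.4)]
        m = match_events(ref, det, tolerance_s=0.25)
        assert m.n_true_positive == 3
        np.testing.assert_allclose(m.errors_s, 0.02, atol=1e-12)

    def test_extra_detection_is_false_positive(self):
        ref = [ev(HS, "left", 1.0)]
        det = [ev(HS, "left", 1.01), ev(HS, "left", 1.9)]
        m = match_events(ref, det, tolerance_s=0.25)
        assert m.n_true_positive == 1 and m.n_false_positive == 1

    def test_out_of_tolerance_is_missed(self):
        m = match_events([ev(HS, "left", 1.0)], [ev(HS, "left", 1.4)],
                         tolerance_s=0.25)
        assert m.n_true_positive == 0
        assert m.n_missed == 1 and m.n_false_positive == 1

    def test_nearest_pairing_wins(self):
        ref = [ev(HS, "left", 1.0), ev(HS, "left", 2.0)]
        det = [ev(HS, "left", 1.05)]
        m = match_events(ref, det, tolerance_s=0.25)
        assert m.pairs[0][0].time_s == 1.0

    def test_mixed_kinds_rejected(self):
        with pytest.raises(gk.ValidationError):
            match_events([ev(HS, "left", 1.0)], [ev(TO, "left", 1.0)])

    def test_swap_symmetry(self):
        ref = [ev(HS, "left", t) for t in (1.0, 2.2, 3.4, 4.6)]
        det = [ev(HS, "left", t) for t in (1.02, 2.18, 4.61, 5.8)]
        a = match_events(ref, det, tolerance_s=0.25)
        b = match_events(det, ref, tolerance_s=0.25)
        assert a.n_true_positive == b.n_true_positive
        np.testing.assert_allclose(np.sort(a.errors_s), -np.sort(b.errors_s)[::-1])


class TestErrorStats:
    def test_worked_example(self):
        s = error_stats(np.array([0.01, -0.03, 0.02]))
        assert s["mean"] == pytest.approx(0.0, abs=1e-12)
        assert s["mean_absolute"] == pytest.approx(0.02, abs=1e-12)
        assert s["range"] == (-0.03, 0.02)

    def test_naive_summation_oracle(self):
        rng = np.random.default_rng(3)
        e = rng.normal(0, 0.02, 200)
        s = error_stats(e)
        assert s["mean"] == pytest.approx(sum(e) / len(e), abs=1e-12)
        assert s["mean_absolute"] == pytest.approx(
            sum(abs(x) for x in e) / len(e), abs=1e-12
        )


class TestTTest:
    def test_identical_samples(self):
        x = np.array([0.6, 0.62, 0.61, 0.63])
        res = t_test_independent(x, x)
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p_two_tailed"] == pytest.approx(1.0, abs=1e-12)

    def test_separated_samples_significant(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.60, 0.01, 30)
        b = rng.normal(0.75, 0.01, 30)
        assert t_test_independent(a, b)["p_two_tailed"] < 0.001

    def test_closed_form_oracle(self):
        # pooled-variance two-sample t computed from first principles
        rng = np.random.default_rng(6)
        a, b = rng.normal(0.6, 0.05, 12), rng.normal(0.62, 0.04, 15)
        res = t_test_independent(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert res["t"] == pytest.approx(t_hand, abs=1e-12)
        assert res["p_two_tailed"] == pytest.approx(
            2 * sstats.t.sf(abs(t_hand), na + nb - 2), abs=1e-12
        )


class TestPearson:
    def test_perfect_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_definitional_oracle(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=(2, 50))
        r = pearson_r(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_hand = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        assert r == pytest.approx(r_hand, abs=1e-12)

    def test_constant_input_degenerate(self):
        with pytest.raises(gk.DegenerateDataError):
            pearson_r(np.ones(5), np.arange(5.0))


class TestIcc:
    def test_identical_raters_give_one(self):
        x = np.array([0.6, 0.7, 0.65, 0.8, 0.72])
        table = np.column_stack([x, x])
        assert icc_2_1(table) == pytest.approx(1.0, abs=1e-12)

    def test_uncorrelated_raters_give_low(self):
        rng = np.random.default_rng(11)
        table = rng.normal(0.7, 0.05, (20, 2))
        assert icc_2_1(table) < 0.5

    def test_matches_hand_anova_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(3, 15))
            k = int(rng.integers(2, 5))
            subject = rng.normal(0.7, 0.1, (n, 1))
            table = subject + rng.normal(0, 0.02, (n, k))
            assert icc_2_1(table) == pytest.approx(
                hand_icc_2_1(table), abs=1e-9
            )

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(13)
        table = rng.normal(0.7, 0.1, (10, 1)) + rng.normal(0, 0.02, (10, 2))
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(10), 2),
            "raters": np.tile(["a", "b"], 10),
            "ratings": table.ravel(),
        })
        out = pingouin.intraclass_corr(
            data=df, targets="targets", raters="raters", ratings="ratings"
        )
        icc2 = out.loc[out["Type"] == "ICC(A,1)", "ICC"].iloc[0]
        assert icc_2_1(table) == pytest.approx(icc2, abs=1e-9)

    def test_shift_both_raters_invariant(self):
        rng = np.random.default_rng(14)
        table = rng.normal(0.7, 0.1, (12, 1)) + rng.normal(0, 0.02, (12, 2))
        assert icc_2_1(table + 0.3) == pytest.approx(icc_2_1(table), abs=1e-12)

    def test_shift_one_rater_decreases(self):
        rng = np.random.default_rng(15)
        table = rng.normal(0.7, 0.1, (12, 1)) + rng.normal(0, 0.01, (12, 2))
        shifted = table.copy()
        shifted[:, 1] += 0.15
        assert icc_2_1(shifted) < icc_2_1(table)

    def test_nan_rows_dropped(self):
        x = np.array([0.6, 0.7, 0.65, 0.8])
        table = np.column_stack([x, x])
        with_nan = np.vstack([table, [np.nan, 0.5]])
        assert icc_2_1(with_nan) == pytest.approx(1.0, abs=1e-12)

    def test_too_few_subjects(self):
        with pytest.raises(gk.InsufficientDataError):
            icc_2_1(np.array([[0.6, 0.61], [0.7, 0.69]]))

    def test_zero_variance_degenerate(self):
        with pytest.raises(gk.DegenerateDataError):
            icc_2_1(np.full((5, 2), 0.7))

    @pytest.mark.parametrize("value,category", [
        (0.945, "excellent"), (0.469, "poor"), (0.500, "moderate"),
        (0.750, "good"), (0.900, "excellent"), (0.82, "good"), (0.6, "moderate"),
    ])
    def test_categorization(self, value, category):
        assert categorize_icc(value) == category


class TestAgreementReport:
    @staticmethod
    def _identity_params(noiseless_pipeline):
        params, _, _, _ = noiseless_pipeline
        return params

    @pytest.mark.parametrize("level", ["per_cycle"])
    def test_identity_perfect_agreement(self, noiseless_pipeline, level):
        params = self._identity_params(noiseless_pipeline)
        report = agreement_report([params], [params], level=level)
        table = report.table
        assert len(table) > 0
        np.testing.assert_allclose(table["mean_absolute_error"], 0.0, atol=1e-12)
        np.testing.assert_allclose(table["icc_2_1"], 1.0, atol=1e-9)
        np.testing.assert_allclose(table["pearson_r"], 1.0, atol=1e-9)
        np.testing.assert_allclose(table["p_two_tailed"], 1.0, atol=1e-9)
        assert set(table["icc_category"]) == {"excellent"}

    def test_hand_computed_per_subject_fixture(self):
        def mk(sid, values):
            rec = pd.DataFrame({
                "subject_id": sid, "cycle_index": range(len(values)),
                "parameter": "step_time", "leg_or_transition": "left",
                "value_s": values,
                "start_time_s": 1.2 * np.arange(len(values)),
            })
            return gk.GaitParameters(sid, rec)

        ref = [mk("a", [0.60, 0.62, 0.61]), mk("b", [0.70, 0.72, 0.71]),
               mk("c", [0.80, 0.82, 0.81])]
        test = [mk("a", [0.62, 0.64, 0.63]), mk("b", [0.72, 0.74, 0.73]),
               mk("c", [0.82, 0.84, 0.83])]
        report = agreement_report(ref, test, level="per_subject")
        row = report.table.iloc[0]
        # every subject mean is exactly 0.02 s high
        assert row["mean_error"] == pytest.approx(-0.02, abs=1e-12)
        assert row["mean_absolute_error"] == pytest.approx(0.02, abs=1e-12)
        assert row["pearson_r"] == pytest.approx(1.0, abs=1e-12)
        table = np.array([[0.61, 0.63], [0.71, 0.73], [0.81, 0.83]])
        assert row["icc_2_1"] == pytest.approx(hand_icc_2_1(table), abs=1e-12)
        assert row["n"] == 3

    def test_cycle_pairing_uses_start_times(self):
        def mk(values, starts):
            rec = pd.DataFrame({
                "subject_id": "a", "cycle_index": range(len(values)),
                "parameter": "step_time", "leg_or_transition": "left",
                "value_s": values, "start_time_s": starts,
            })
            return gk.GaitParameters("a", rec)

        ref = mk([0.60, 0.62, 0.61, 0.64], [0.0, 1.2, 2.4, 3.6])
        # detection missed the second cycle: remaining ones must still pair up
        test = mk([0.61, 0.60, 0.66], [0.02, 2.38, 3.64])
        report = agreement_report([ref], [test], level="per_cycle")
        row = report.table.iloc[0]
        assert row["n"] == 3
        assert row["mean_absolute_error"] == pytest.approx(
            np.mean([0.01, 0.01, 0.02]), abs=1e-12
        )

    def test_insufficient_pairs_row_omitted(self, caplog):
        def mk(sid, values):
            rec = pd.DataFrame({
                "subject_id": sid, "cycle_index": range(len(values)),
                "parameter": "stance_time", "leg_or_transition": "left",
                "value_s": values, "start_time_s": 1.2 * np.arange(len(values)),
            })
            return gk.GaitParameters(sid, rec)

        report = agreement_report([mk("a", [0.8, 0.81])],
                                  [mk("a", [0.8, 0.81])], level="per_cycle")
        assert len(report.table) == 0

    def test_report_csv_round_trip(self, tmp_path, noiseless_pipeline):
        params = self._identity_params(noiseless_pipeline)
        report = agreement_report([params], [params])
        out = tmp_path / "report.csv"
        report.to_csv(out)
        back = pd.read_csv(out)
        assert list(back.columns) == list(report.table.columns)
        assert len(back) == len(report.table)
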