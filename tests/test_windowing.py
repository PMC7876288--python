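"""Study-day alignment, two-week pooling and z-standardization."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from mobimood.windowing import (
    attach_outcomes,
    pool_windows,
    standardize,
    study_day,
    to_study_days,
)


class TestStudyDays:
    def test_enrollment_date_is_day_one(self):
        assert study_day(date(2020, 4, 15), date(2020, 4, 15)) == 1

    def test_day_thirty_by_date_arithmetic(self):
        assert study_day(date(2020, 5, 14), date(2020, 4, 15)) == 30

    def test_out_of_window_rows_dropped_and_ledgered(self):
        daily = pd.DataFrame(
            {
                "participant": ["a", "a", "a"],
                "local_date": [date(2020, 4, 15), date(2020, 5, 14), date(2020, 5, 20)],
                "x": [1.0, 2.0, 3.0],
            }
        )
        out, ledger = to_study_days(daily, {"a": date(2020, 4, 15)})
        assert list(out["study_day"]) == [1, 30]
        assert ledger["out_of_window"] == 1

    def test_unknown_participant_rejected(self):
        daily = pd.DataFrame({"participant": ["b"], "local_date": [date(2020, 4, 15)], "x": [1.0]})
        with pytest.raises(ValueError):
            to_study_days(daily, {"a": date(2020, 4, 15)})


def daily_frame(values_by_day: dict[int, float], feature="tst", pid="a"):
    return pd.DataFrame(
        {
            "participant": pid,
            "study_day": list(values_by_day),
            feature: list(values_by_day.values()),
        }
    )


class TestPoolWindows:
    def test_constant_daily_value_pools_to_itself(self):
        daily = daily_frame({d: 7.5 for d in range(1, 31)})
        pooled = pool_windows(daily, ("tst",))
        assert pooled["tst"].tolist() == [7.5, 7.5]

    def test_window_one_mean_of_1_to_15(self):
        daily = daily_frame({d: float(d) for d in range(1, 16)})
        pooled = pool_windows(daily, ("tst",))
        w1 = pooled[pooled["window"] == 1]["tst"].iloc[0]
        assert w1 == pytest.approx(8.0)

    def test_below_minimum_coverage_undefined(self):
        daily = daily_frame({1: 1.0, 2: 2.0, 3: 3.0})
        pooled = pool_windows(daily, ("tst",), min_coverage=5)
        assert np.isnan(pooled[pooled["window"] == 1]["tst"].iloc[0])

    def test_day_16_belongs_to_window_two_only(self):
        daily = daily_frame({16: 100.0, **{d: 1.0 for d in range(1, 16)}})
        pooled = pool_windows(daily, ("tst",), min_coverage=1)
        assert pooled[pooled["window"] == 1]["tst"].iloc[0] == pytest.approx(1.0)
        assert pooled[pooled["window"] == 2]["tst"].iloc[0] == pytest.approx(100.0)

    def test_pooling_invariant_to_participant_relabeling(self):
        rng = np.random.default_rng(0)
        daily = pd.concat(
            [daily_frame({d: float(rng.normal()) for d in range(1, 31)}, pid=p) for p in ("a", "b")],
            ignore_index=True,
        )
        relabeled = daily.copy()
        relabeled["participant"] = relabeled["participant"].map({"a": "b", "b": "a"})
        p1 = pool_windows(daily, ("tst",))
        p2 = pool_windows(relabeled, ("tst",))
        # relabeling permutes rows but must not change any pooled value
        assert sorted(p1["tst"]) == pytest.approx(sorted(p2["tst"]))
        a1 = p1[p1["participant"] == "a"].set_index("window")["tst"]
        b2 = p2[p2["participant"] == "b"].set_index("window")["tst"]
        assert np.allclose(a1, b2)


class TestStandardize:
    def test_simple_column_centered_and_scaled(self):
        t = pd.DataFrame({"tst": [1.0, 2.0, 3.0, 4.0]})
        out, std = standardize(t, ("tst",))
        assert out["tst"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["tst"].std(ddof=1) == pytest.approx(1.0)
        assert std.params["tst"] == (pytest.approx(2.5), pytest.approx(t["tst"].std(ddof=1)))

    def test_constant_column_flagged_unchanged(self):
        t = pd.DataFrame({"tst": [2.0, 2.0, 2.0]})
        out, std = standardize(t, ("tst",))
        assert "tst" in std.zero_sd_columns
        assert out["tst"].tolist() == [2.0, 2.0, 2.0]

    def test_inverse_transform_roundtrip(self):
        t = pd.DataFrame({"tst": [10.0, 20.0, 40.0]})
        out, std = standardize(t, ("tst",))
        back = std.inverse("tst", out["tst"].to_numpy())
        assert back == pytest.approx([10.0, 20.0, 40.0])

    def test_missing_values_ignored_in_grand_statistics(self):
        t = pd.DataFrame({"tst": [1.0, np.nan, 3.0]})
        out, _ = standardize(t, ("tst",))
        assert out["tst"].dropna().mean() == pytest.approx(0.0, abs=1e-12)


class TestAttachOutcomes:
    def test_window_assessment_pairing(self):
        pooled = pd.DataFrame({"participant": ["a", "a"], "window": [1, 2], "tst": [1.0, 2.0]})
        scores = pd.DataFrame(
            {
                "participant": ["a", "a", "a"],
                "assessment_point": ["T0", "T1", "T2"],
                "depression": [1, 5, 9],
                "anxiety": [0, 1, 2],
                "stress": [2, 3, 4],
            }
        )
        out = attach_outcomes(pooled, scores)
        assert out[out["window"] == 1]["depression"].iloc[0] == 5  # T1 with days 1-15
        assert out[out["window"] == 2]["depression"].iloc[0] == 9  # T2 with days 16-30

    def test_missing_assessment_stays_nan(self):
        pooled = pd.DataFrame({"participant": ["a"], "window": [1], "tst": [1.0]})
        scores = pd.DataFrame(
            {"participant": ["a"], "assessment_point": ["T2"], "depression": [9], "anxiety": [1], "stress": [1]}
        )
        out = attach_outcomes(pooled, scores)
        assert np.isnan(out["depression"].iloc[0])
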