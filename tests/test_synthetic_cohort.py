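"""Synthetic cohort generators: planted effects, artifacts, MAR masking."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from mobimood.gps_mobility import (
    clean_trace,
    cluster_stationary,
    extract_mobility_features,
    haversine_km,
    label_states,
    localize,
)
from mobimood.inference import fit_mlm
from mobimood.synthetic_cohort import (
    CohortConfig,
    ParticipantProfile,
    apply_mar_missingness,
    generate_cohort,
    generate_gps_trace,
    mar_mask,
    simulate_model_table,
    true_window_gps_features,
)
from mobimood.dass import SUBSCALE_ITEMS


def profile(**kw):
    defaults = dict(
        participant="p0",
        home=(60.17, 24.94),
        anchors=[(60.19, 24.94)],
        schedule={},
        jitter_sd_m=0.0,
        sampling_interval_s=60.0,
    )
    defaults.update(kw)
    return ParticipantProfile(**defaults)


class TestConfigValidation:
    def test_rates_must_be_fractions(self):
        with pytest.raises(ValueError, match="rate"):
            CohortConfig(n_participants=5, dass_missing_rate=1.5)

    def test_minimum_two_participants(self):
        with pytest.raises(ValueError, match="participants"):
            CohortConfig(n_participants=1)

    def test_unknown_planted_feature_rejected(self):
        with pytest.raises(ValueError, match="unrecognized"):
            CohortConfig(n_participants=5, planted_betas={"not_a_feature": 0.2})


class TestGpsTrace:
    def test_home_only_trace_stays_within_a_metre(self):
        trace, _ = generate_gps_trace(profile(), range(1, 3), seed=0)
        d_km = haversine_km(trace["latitude"], trace["longitude"], 60.17, 24.94)
        assert (d_km * 1000 <= 1.0).all()
        # stationary fraction is 1 by construction
        labeled = label_states(trace.assign(accuracy=5.0))
        assert (labeled["state"] == "stationary").all()

    def test_injected_artifact_counts_match_recount(self):
        p = profile(sampling_interval_s=86.4, duplicate_rate=0.05, zero_coord_rate=0.02)
        trace, counts = generate_gps_trace(p, range(1, 2), seed=1)  # 1000 base samples
        dup_recount = int(trace.duplicated(["timestamp", "latitude", "longitude"]).sum())
        zero_recount = int(((trace["latitude"] == 0.0) & (trace["longitude"] == 0.0)).sum())
        assert dup_recount == counts["duplicate"]
        assert zero_recount == counts["zero_coord"]

    def test_round_trip_distance_recovered_after_cleaning(self):
        # one 2 km-away anchor, one round trip at 5 km/h -> 4 km planted
        dlat = 2.0 / (np.pi * 6371.0088 / 180.0)
        p = profile(
            anchors=[(60.17 + dlat, 24.94)],
            schedule={1: [(12 * 3600.0, 14 * 3600.0, 0)]},
            duplicate_rate=0.02,
            zero_coord_rate=0.01,
        )
        trace, _ = generate_gps_trace(p, range(1, 2), seed=2)
        tz = pd.DataFrame({"timestamp": [0], "timezone": ["UTC"]})
        loc = localize(trace, tz)
        clean, _ = clean_trace(loc)
        labeled = label_states(clean)
        total = labeled["step_km"].sum()
        assert total == pytest.approx(4.0, rel=0.05)

    def test_overlapping_schedule_rejected(self):
        p = profile(
            anchors=[(60.19, 24.94), (60.15, 24.94)],
            schedule={1: [(10 * 3600.0, 12 * 3600.0, 0), (11 * 3600.0, 13 * 3600.0, 1)]},
        )
        with pytest.raises(ValueError, match="overlapping"):
            generate_gps_trace(p, range(1, 2), seed=0)

    def test_schedule_true_features_match_extraction_on_noiseless_trace(self):
        dlat = 1.5 / (np.pi * 6371.0088 / 180.0)
        p = profile(
            anchors=[(60.17 + dlat, 24.94)],
            schedule={d: [(10 * 3600.0, 16 * 3600.0, 0)] for d in range(1, 4)},
        )
        trace, _ = generate_gps_trace(p, range(1, 4), seed=3)
        tz = pd.DataFrame({"timestamp": [0], "timezone": ["UTC"]})
        labeled = label_states(localize(trace, tz))
        model = cluster_stationary(labeled, seed=0)
        days = sorted(labeled["local_date"].unique())
        feats = extract_mobility_features(labeled, model, days)
        truth = true_window_gps_features(p, range(1, 4))
        assert feats.total_distance == pytest.approx(truth["total_distance"] * 3, rel=0.005)
        assert feats.homestay == pytest.approx(truth["homestay"], abs=0.02)
        assert feats.entropy == pytest.approx(truth["entropy"], abs=0.02)


class TestModelTableSimulator:
    def test_same_seed_identical_output(self):
        t1, _ = simulate_model_table(30, 2, {"tib": 0.2}, seed=5)
        t2, _ = simulate_model_table(30, 2, {"tib": 0.2}, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_null_betas_give_unbiased_null_slopes(self):
        # small replicate of the null-recovery property at reduced size
        ests = []
        for rep in range(20):
            tab, _ = simulate_model_table(100, 4, {}, seed=100 + rep)
            fit = fit_mlm(tab, "depression", ("tib",), random_slopes=())
            ests.append(fit.params["tib"])
        assert abs(np.mean(ests)) < 0.03

    def test_usage_frequency_correlates_with_outcome(self):
        tab, _ = simulate_model_table(400, 2, {"tib": 0.25}, seed=6)
        person = tab.groupby("participant")[["usage_frequency", "depression"]].mean()
        r = np.corrcoef(person["usage_frequency"], person["depression"])[0, 1]
        assert r > 0.1  # shared trait makes the MAR driver informative


class TestMarMissingness:
    def test_masking_rate_close_to_target(self):
        tab, _ = simulate_model_table(500, 2, seed=7)
        masked = apply_mar_missingness(tab, ["depression"], 0.10, seed=8)
        rate = masked["depression"].isna().mean()
        assert abs(rate - 0.10) <= 0.03

    def test_missingness_is_predictable_from_driver(self):
        import statsmodels.api as sm

        tab, _ = simulate_model_table(600, 2, seed=9)
        masked = apply_mar_missingness(tab, ["depression"], 0.15, seed=10)
        y = masked["depression"].isna().astype(float)
        z = (tab["usage_frequency"] - tab["usage_frequency"].mean()) / tab["usage_frequency"].std()
        res = sm.Logit(y, sm.add_constant(z)).fit(disp=0)
        # logistic fit recovers a clearly nonzero driver coefficient
        assert res.params.iloc[1] > 0.5
        assert res.pvalues.iloc[1] < 1e-6

    def test_mar_mask_is_deterministic_given_seed(self):
        z = np.linspace(-2, 2, 200)
        rng1 = np.random.default_rng(3)
        rng2 = np.random.default_rng(3)
        assert (mar_mask(z, 0.2, rng1) == mar_mask(z, 0.2, rng2)).all()


@pytest.fixture(scope="module")
def small_cohort():
    cfg = CohortConfig(
        n_participants=6,
        planted_betas={"location_variance": -0.21},
        seed=11,
        sampling_interval_s=600.0,
    )
    return cfg, generate_cohort(cfg)


class TestGenerateCohort:

    def test_streams_sorted_and_inside_study_window(self, small_cohort):
        cfg, (raw, truth) = small_cohort
        for pid, trace in raw.gps.items():
            ts = trace["timestamp"].to_numpy()
            assert (np.diff(ts) >= 0).all()
            span_days = (ts[-1] - ts[0]) / 86_400_000
            assert span_days <= cfg.study_days

    def test_dass_items_sum_to_simulated_subscores(self, small_cohort):
        _, (raw, truth) = small_cohort
        latent = truth.latent_outcomes.set_index(["participant", "assessment_point", "outcome"])
        for row in raw.dass.itertuples(index=False):
            for outcome, items in SUBSCALE_ITEMS.items():
                total = sum(getattr(row, f"item_{i}") for i in items)
                expected = latent.loc[(row.participant, row.assessment_point, outcome), "subscore"]
                assert total == expected

    def test_masked_assessments_absent_from_dass_table(self, small_cohort):
        _, (raw, truth) = small_cohort
        present = set(zip(raw.dass["participant"], raw.dass["assessment_point"]))
        for pid, pt in truth.masked_assessments:
            assert (pid, pt) not in present

    def test_masked_sensing_days_removed_from_wearable(self, small_cohort):
        _, (raw, truth) = small_cohort
        for pid, days in truth.masked_sensing_days.items():
            enr = raw.enrollment[pid]
            masked_dates = {enr + pd.Timedelta(days=d - 1).to_pytimedelta() for d in days}
            assert not masked_dates & set(raw.wearable[pid]["date"])

    def test_determinism_same_seed(self, small_cohort):
        cfg, (raw, _) = small_cohort
        raw2, _ = generate_cohort(cfg)
        for pid in raw.gps:
            pd.testing.assert_frame_equal(raw.gps[pid], raw2.gps[pid])
            pd.testing.assert_frame_equal(raw.wearable[pid], raw2.wearable[pid])
        pd.testing.assert_frame_equal(raw.dass, raw2.dass)
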