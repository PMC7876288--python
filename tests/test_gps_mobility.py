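"""GPS cleaning, state labelling, clustering and location features."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics.pairwise import haversine_distances

from mobimood.gps_mobility import (
    EARTH_RADIUS_KM,
    ClusterModel,
    clean_trace,
    cluster_stationary,
    extract_mobility_features,
    haversine_km,
    label_states,
    localize,
)

from conftest import make_stationary_labeled

KM_PER_DEG_LAT = np.pi * EARTH_RADIUS_KM / 180.0


def gps_frame(rows):
    return pd.DataFrame(rows, columns=["timestamp", "latitude", "longitude", "accuracy"])


class TestHaversine:
    def test_matches_sklearn_haversine(self):
        rng = np.random.default_rng(3)
        a = np.column_stack([rng.uniform(-80, 80, 50), rng.uniform(-179, 179, 50)])
        b = np.column_stack([rng.uniform(-80, 80, 50), rng.uniform(-179, 179, 50)])
        expected = np.diag(haversine_distances(np.radians(a), np.radians(b))) * EARTH_RADIUS_KM
        got = haversine_km(a[:, 0], a[:, 1], b[:, 0], b[:, 1])
        assert np.allclose(got, expected, atol=1e-9)


class TestLocalize:
    def test_epoch_in_utc(self):
        tz = pd.DataFrame({"timestamp": [0], "timezone": ["UTC"]})
        out = localize(gps_frame([(0, 60.0, 24.0, 5.0)]), tz)
        assert out["local_dt"].iloc[0] == pd.Timestamp("1970-01-01T00:00:00")

    def test_epoch_in_helsinki_is_plus_two(self, helsinki_tz_records):
        out = localize(gps_frame([(0, 60.0, 24.0, 5.0)]), helsinki_tz_records)
        assert out["local_dt"].iloc[0] == pd.Timestamp("1970-01-01T02:00:00")

    def test_zone_switch_mid_study_shifts_later_samples(self):
        tz = pd.DataFrame(
            {"timestamp": [0, 1_000_000], "timezone": ["UTC", "Etc/GMT-3"]}
        )
        out = localize(gps_frame([(500_000, 0.1, 0.1, 5.0), (2_000_000, 0.1, 0.1, 5.0)]), tz)
        d0 = out["local_dt"].iloc[0] - pd.Timestamp("1970-01-01T00:08:20")
        d1 = out["local_dt"].iloc[1] - pd.Timestamp("1970-01-01T00:33:20")
        assert d0 == pd.Timedelta(0)
        assert d1 == pd.Timedelta(hours=3)

    def test_sample_before_first_record_uses_first_zone(self):
        tz = pd.DataFrame({"timestamp": [10_000], "timezone": ["Etc/GMT-2"]})
        out = localize(gps_frame([(0, 0.1, 0.1, 5.0)]), tz)
        assert out["local_dt"].iloc[0] == pd.Timestamp("1970-01-01T02:00:00")


class TestCleanTrace:
    def test_duplicate_removal_counted(self):
        rows = [(i * 1000, 60.0 + i * 1e-4, 24.0, 5.0) for i in range(7)]
        rows += [rows[0], rows[2], rows[4]]
        clean, ledger = clean_trace(gps_frame(rows))
        assert len(clean) == 7
        assert ledger["duplicate"] == 3

    def test_zero_coordinate_removed(self):
        rows = [(0, 60.0, 24.0, 5.0), (1000, 0.0, 0.0, 5.0), (2000, 60.1, 24.1, 5.0)]
        clean, ledger = clean_trace(gps_frame(rows))
        assert ledger["zero_coord"] == 1
        assert not ((clean["latitude"] == 0) & (clean["longitude"] == 0)).any()

    def test_accuracy_filter_matches_brute_force_percentile(self):
        rng = np.random.default_rng(11)
        acc = rng.permutation(np.arange(1.0, 101.0))
        rows = [(i * 1000, 60.0 + i * 1e-3, 24.0, a) for i, a in enumerate(acc)]
        clean, ledger = clean_trace(gps_frame(rows), accuracy_percentile=80)
        thr = np.percentile(acc, 80)  # independent type-7 computation
        survivors = int((acc <= thr).sum())
        assert len(clean) == survivors
        assert ledger["low_accuracy"] == 100 - survivors
        assert clean["accuracy"].max() <= thr

    def test_idempotent_with_fixed_accuracy_pool(self):
        rng = np.random.default_rng(5)
        rows = [
            (i * 1000, 60.0 + rng.normal(0, 1e-3), 24.0, rng.uniform(1, 50))
            for i in range(200)
        ]
        df = gps_frame(rows)
        pool = df["accuracy"].to_numpy()
        once, _ = clean_trace(df, accuracy_pool=pool)
        twice, ledger = clean_trace(once, accuracy_pool=pool)
        pd.testing.assert_frame_equal(once, twice)
        assert ledger["duplicate"] == ledger["zero_coord"] == ledger["low_accuracy"] == 0

    def test_empty_input(self):
        clean, ledger = clean_trace(gps_frame([]))
        assert clean.empty and ledger["duplicate"] == 0


class TestLabelStates:
    def test_one_km_in_thirty_minutes_is_transition(self):
        dlat = 1.0 / KM_PER_DEG_LAT  # exactly 1 km north
        df = gps_frame([(0, 60.0, 24.0, 5.0), (1_800_000, 60.0 + dlat, 24.0, 5.0)])
        out = label_states(df, gap_threshold_s=3600)
        assert out["speed_kmh"].iloc[1] == pytest.approx(2.0, rel=1e-6)
        assert out["state"].iloc[1] == "transition"

    def test_identical_positions_are_stationary(self):
        df = gps_frame([(0, 60.0, 24.0, 5.0), (60_000, 60.0, 24.0, 5.0)])
        out = label_states(df)
        assert list(out["state"]) == ["stationary", "stationary"]

    @pytest.mark.parametrize("kmh,state", [(0.99, "stationary"), (1.0, "stationary"), (1.01, "transition")])
    def test_strict_inequality_at_one_kmh(self, kmh, state):
        # one hour of travel; nudge the displacement down by ulps until the
        # haversine distance is <= the target so speed == kmh (not above)
        dlat = kmh / KM_PER_DEG_LAT
        while haversine_km(60.0, 24.0, 60.0 + dlat, 24.0) > kmh:
            dlat = np.nextafter(dlat, 0.0)
        df = gps_frame([(0, 60.0, 24.0, 5.0), (3_600_000, 60.0 + dlat, 24.0, 5.0)])
        out = label_states(df, gap_threshold_s=7200)
        assert out["speed_kmh"].iloc[1] == pytest.approx(kmh, rel=1e-9)
        assert out["state"].iloc[1] == state

    def test_gap_splits_segments_and_credits_no_dwell(self):
        df = gps_frame(
            [(0, 60.0, 24.0, 5.0), (60_000, 60.0, 24.0, 5.0), (7_200_000, 60.0, 24.0, 5.0)]
        )
        out = label_states(df, gap_threshold_s=900)
        assert list(out["segment"]) == [0, 0, 1]
        assert out["dwell_s"].iloc[0] == 60.0
        assert out["dwell_s"].iloc[1] == 0.0  # gap interval credits nothing

    def test_first_sample_inherits_following_speed(self):
        dlat = 2.0 / KM_PER_DEG_LAT
        df = gps_frame([(0, 60.0, 24.0, 5.0), (3_600_000, 60.0 + dlat, 24.0, 5.0)])
        out = label_states(df, gap_threshold_s=7200)
        assert out["speed_kmh"].iloc[0] == pytest.approx(2.0, rel=1e-6)

    def test_zero_elapsed_distinct_positions_dropped(self):
        df = gps_frame([(0, 60.0, 24.0, 5.0), (0, 61.0, 24.0, 5.0), (60_000, 60.0, 24.0, 5.0)])
        out = label_states(df)
        assert len(out) == 2


def _blob(lat, lon, n, spread_deg, rng, t0=0):
    return [
        (t0 + i * 60_000, lat + rng.normal(0, spread_deg), lon + rng.normal(0, spread_deg), 5.0)
        for i in range(n)
    ]


class TestClusterStationary:
    def _label(self, rows):
        df = gps_frame(rows)
        out = label_states(df, gap_threshold_s=10**9)
        out["local_seconds"] = 3600.0
        out["local_date"] = date(2020, 4, 15)
        return out

    def test_tight_blob_gives_single_cluster(self):
        rng = np.random.default_rng(0)
        labeled = self._label(_blob(60.0, 24.0, 30, 1e-5, rng))
        model = cluster_stationary(labeled, seed=0)
        assert model.k == 1 and not model.capped

    def test_two_blobs_two_km_apart_recovered(self):
        rng = np.random.default_rng(1)
        dlat = 2.0 / KM_PER_DEG_LAT
        rows = _blob(60.0, 24.0, 25, 1e-5, rng) + _blob(60.0 + dlat, 24.0, 25, 1e-5, rng, t0=10**7)
        labeled = self._label(rows)
        model = cluster_stationary(labeled, seed=0)
        assert model.k == 2
        # brute-force nearest-anchor membership
        truth = np.array([0] * 25 + [1] * 25)
        got = model.labels.to_numpy()
        agreement = max((got == truth).mean(), (got == 1 - truth).mean())
        assert agreement == 1.0

    def test_k_max_cap_flagged(self):
        rng = np.random.default_rng(2)
        dlat = 5.0 / KM_PER_DEG_LAT
        rows = []
        for b in range(3):
            rows += _blob(60.0 + b * dlat, 24.0, 10, 1e-6, rng, t0=b * 10**7)
        labeled = self._label(rows)
        model = cluster_stationary(labeled, k_max=2, seed=0)
        assert model.k == 2 and model.capped

    def test_no_stationary_samples_undefined(self):
        labeled = self._label([(0, 60.0, 24.0, 5.0)])
        labeled["state"] = "transition"
        model = cluster_stationary(labeled, seed=0)
        assert not model.defined and model.reason == "no_stationary_samples"


class TestMobilityFeatures:
    DAY = date(2020, 4, 15)

    def test_equal_dwell_two_clusters_entropy_ln2(self):
        labeled, model = make_stationary_labeled([(60.0, 24.0), (60.02, 24.0)], [1800.0, 1800.0])
        f = extract_mobility_features(labeled, model, [self.DAY])
        assert f.entropy == pytest.approx(np.log(2), abs=1e-12)
        assert f.normalized_entropy == pytest.approx(1.0, abs=1e-12)

    def test_single_cluster_entropy_zero(self):
        labeled, model = make_stationary_labeled([(60.0, 24.0)], [3600.0])
        f = extract_mobility_features(labeled, model, [self.DAY])
        assert f.entropy == 0.0
        assert f.normalized_entropy == 0.0

    def test_unequal_dwell_entropy_closed_form(self):
        labeled, model = make_stationary_labeled([(60.0, 24.0), (60.02, 24.0)], [2520.0, 1080.0])
        f = extract_mobility_features(labeled, model, [self.DAY])
        expected = -(0.7 * np.log(0.7) + 0.3 * np.log(0.3))
        assert f.entropy == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_normalized_entropy_one_at_uniform_dwell(self, n):
        anchors = [(60.0 + 0.02 * i, 24.0) for i in range(n)]
        labeled, model = make_stationary_labeled(anchors, [600.0] * n)
        f = extract_mobility_features(labeled, model, [self.DAY])
        assert f.normalized_entropy == pytest.approx(1.0, abs=1e-12)

    def test_merging_clusters_never_increases_entropy(self):
        for shares in [(0.5, 0.3, 0.2), (0.8, 0.1, 0.1), (0.4, 0.4, 0.2)]:
            anchors = [(60.0, 24.0), (60.02, 24.0), (60.04, 24.0)]
            dwell = [s * 3600 for s in shares]
            labeled, model = make_stationary_labeled(anchors, dwell)
            f3 = extract_mobility_features(labeled, model, [self.DAY])
            merged_anchors = [(60.0, 24.0), (60.02, 24.0)]
            merged_dwell = [(shares[0] + shares[1]) * 3600, shares[2] * 3600]
            labeled2, model2 = make_stationary_labeled(merged_anchors, merged_dwell)
            f2 = extract_mobility_features(labeled2, model2, [self.DAY])
            assert f2.entropy <= f3.entropy + 1e-12

    def test_total_distance_invariant_to_collinear_midpoint(self):
        lat0, lat1 = 60.0, 60.1
        base = gps_frame([(0, lat0, 24.0, 5.0), (600_000, lat1, 24.0, 5.0)])
        mid = gps_frame(
            [(0, lat0, 24.0, 5.0), (300_000, (lat0 + lat1) / 2, 24.0, 5.0), (600_000, lat1, 24.0, 5.0)]
        )
        feats = []
        for df in (base, mid):
            lab = label_states(df, gap_threshold_s=10**9)
            lab["local_date"] = self.DAY
            lab["local_seconds"] = 3600.0
            model = cluster_stationary(lab, seed=0) if (lab["state"] == "stationary").any() else None
            f = extract_mobility_features(lab, model or ClusterModel(0, np.empty((0, 2)), pd.Series(dtype=int), reason="x"), [self.DAY])
            feats.append(f.total_distance)
        assert abs(feats[0] - feats[1]) < 1e-9

    def test_homestay_uses_night_cluster_and_24h_denominator(self):
        labeled, model = make_stationary_labeled(
            [(60.0, 24.0), (60.02, 24.0)], [6 * 3600.0, 2 * 3600.0], night_anchor=0
        )
        f = extract_mobility_features(labeled, model, [self.DAY])
        assert model.home_cluster == 0
        assert f.homestay == pytest.approx(6 * 3600 / 86400, abs=1e-12)

    def test_location_variance_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        # ~1 m jitter keeps consecutive speeds well under 1 km/h (stationary)
        rows = [(i * 60_000, 60.0 + rng.normal(0, 1e-5), 24.0 + rng.normal(0, 2e-5), 5.0) for i in range(50)]
        lab = label_states(gps_frame(rows), gap_threshold_s=10**9)
        lab["local_date"] = self.DAY
        lab["local_seconds"] = 3600.0
        stat = lab[lab["state"] == "stationary"]
        model = cluster_stationary(lab, seed=0)
        f = extract_mobility_features(lab, model, [self.DAY])
        expected = np.log(np.var(stat["latitude"]) + np.var(stat["longitude"]))
        assert f.location_variance == pytest.approx(expected, abs=1e-12)

    def test_degenerate_variance_undefined_with_reason(self):
        labeled, model = make_stationary_labeled([(60.0, 24.0)], [3600.0])
        f = extract_mobility_features(labeled, model, [self.DAY])
        assert f.location_variance is None
        assert f.reasons["location_variance"] == "zero_variance"
        # other features unaffected
        assert f.entropy == 0.0
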