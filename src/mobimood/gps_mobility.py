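"""GPS trace cleaning, stay-point clustering and location feature extraction.

Raw smartphone GPS streams (AWARE-style rows of UNIX-ms timestamp,
latitude, longitude, accuracy) are cleaned, each sample is labelled
stationary or transition by its instantaneous speed, stationary samples
are clustered into stay locations with K-means, and five location
features are computed per day set: total distance travelled, location
variance, location entropy, normalized entropy and homestay.

Conventions:

* speed > 1 km/h (strict) defines a transition state;
* gaps longer than 15 min split the trace into segments, crediting no
  dwell time and no travelled distance across the gap;
* distances are haversine on a sphere of radius 6371.0088 km;
* entropy uses natural logarithms and dwell-time shares; the home
  cluster is the one holding the most stationary samples between
  00:00 and 06:00 local time (half-open window).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088
SPEED_THRESHOLD_KMH = 1.0
GAP_THRESHOLD_S = 15 * 60
NIGHT_WINDOW = (0, 6 * 3600)  # [00:00, 06:00) in seconds since local midnight

#: Canonical column names for a GPS sample table.
GPS_COLUMNS = ["timestamp", "latitude", "longitude", "accuracy"]


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between coordinate arrays (degrees)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def localize(samples: pd.DataFrame, tz_records: pd.DataFrame) -> pd.DataFrame:
    """Attach zone-resolved local civil time to each sample.

    ``tz_records`` has columns ``timestamp`` (UNIX ms) and ``timezone``
    (IANA name); each sample uses the most recent record at or before its
    timestamp. Samples before the first record fall back to the first
    record (logged). Adds ``local_dt`` (naive local datetime),
    ``local_date`` and ``local_seconds`` (seconds since local midnight).
    """
    if tz_records.empty:
        raise ValueError("at least one timezone record is required")
    out = samples.sort_values("timestamp", kind="mergesort").reset_index(drop=True).copy()
    recs = tz_records.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    if len(out) and out["timestamp"].iloc[0] < recs["timestamp"].iloc[0]:
        log.warning("samples precede first timezone record; using first record's zone")
    # index of governing record per sample
    idx = np.searchsorted(recs["timestamp"].to_numpy(), out["timestamp"].to_numpy(), side="right") - 1
    idx = np.clip(idx, 0, len(recs) - 1)
    local = np.empty(len(out), dtype="datetime64[ns]")
    ts_utc = pd.to_datetime(out["timestamp"].to_numpy(), unit="ms", utc=True)
    for rec_i in np.unique(idx):
        mask = idx == rec_i
        zone = ZoneInfo(recs["timezone"].iloc[rec_i])
        local[mask] = ts_utc[mask].tz_convert(zone).tz_localize(None).to_numpy()
    out["local_dt"] = local
    out["local_date"] = pd.Series(local).dt.date.to_numpy()
    midnight = pd.Series(local).dt.normalize()
    out["local_seconds"] = ((pd.Series(local) - midnight).dt.total_seconds()).to_numpy()
    return out


def clean_trace(
    samples: pd.DataFrame,
    accuracy_percentile: float = 80.0,
    accuracy_pool: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Remove duplicates, (0, 0) sensing errors and low-accuracy samples.

    Exact duplicates share timestamp, latitude and longitude. The accuracy
    filter removes samples with accuracy strictly greater than the given
    percentile (type-7, linear interpolation) of ``accuracy_pool`` -- the
    pooled accuracies of *all* participants; by default the pool is this
    trace's own raw accuracies. Returns the cleaned trace plus a removal
    ledger keyed by reason (the applied threshold is recorded under
    ``accuracy_threshold``).
    """
    ledger: dict[str, float] = {"duplicate": 0, "zero_coord": 0, "low_accuracy": 0}
    if samples.empty:
        ledger["accuracy_threshold"] = float("nan")
        return samples.copy(), ledger
    df = samples.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    pool = np.asarray(accuracy_pool if accuracy_pool is not None else df["accuracy"], dtype=float)
    threshold = float(np.percentile(pool, accuracy_percentile))  # linear interpolation

    dup = df.duplicated(subset=["timestamp", "latitude", "longitude"], keep="first")
    ledger["duplicate"] = int(dup.sum())
    df = df[~dup]

    zero = (df["latitude"] == 0.0) & (df["longitude"] == 0.0)
    ledger["zero_coord"] = int(zero.sum())
    df = df[~zero]

    bad_acc = df["accuracy"] > threshold  # strictly greater
    ledger["low_accuracy"] = int(bad_acc.sum())
    df = df[~bad_acc]

    ledger["accuracy_threshold"] = threshold
    return df.reset_index(drop=True), ledger


def label_states(
    trace: pd.DataFrame,
    gap_threshold_s: float = GAP_THRESHOLD_S,
    speed_threshold_kmh: float = SPEED_THRESHOLD_KMH,
) -> pd.DataFrame:
    """Label each sample stationary/transition and credit dwell time.

    Speed at sample i is the haversine distance from sample i-1 divided by
    the elapsed time; the first sample of each segment inherits the
    following interval's speed. Intervals longer than ``gap_threshold_s``
    start a new segment and credit no dwell. Samples with zero elapsed
    time but distinct positions are dropped (logged). Adds ``speed_kmh``,
    ``state``, ``segment``, ``dwell_s`` and ``step_km`` (distance from the
    previous within-segment sample).
    """
    df = trace.sort_values("timestamp", kind="mergesort").reset_index(drop=True).copy()
    n = len(df)
    if n == 0:
        for col in ("speed_kmh", "dwell_s", "step_km"):
            df[col] = np.array([], dtype=float)
        df["state"] = np.array([], dtype=object)
        df["segment"] = np.array([], dtype=int)
        return df

    ts = df["timestamp"].to_numpy(dtype=np.int64)
    lat = df["latitude"].to_numpy(dtype=float)
    lon = df["longitude"].to_numpy(dtype=float)
    dt_s = np.diff(ts) / 1000.0
    dist_km = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])

    # zero elapsed time between distinct positions is unphysical -> drop later sample
    degenerate = (dt_s == 0) & (dist_km > 0)
    if degenerate.any():
        log.warning("dropping %d samples with zero elapsed time but distinct positions", degenerate.sum())
        keep = np.ones(n, dtype=bool)
        keep[1:][degenerate] = False
        return label_states(df[keep], gap_threshold_s, speed_threshold_kmh)

    gap = dt_s > gap_threshold_s
    segment = np.zeros(n, dtype=int)
    segment[1:] = np.cumsum(gap)

    with np.errstate(divide="ignore", invalid="ignore"):
        interval_speed = np.where(dt_s > 0, dist_km / (dt_s / 3600.0), 0.0)
    speed = np.zeros(n, dtype=float)
    speed[1:] = interval_speed
    # interval crossing a gap is not informative for the sample after the gap:
    # that sample starts a segment and inherits the *next* interval's speed
    seg_start = np.ones(n, dtype=bool)
    seg_start[1:] = gap
    for i in np.flatnonzero(seg_start):
        if i + 1 < n and segment[i + 1] == segment[i]:
            speed[i] = interval_speed[i]
        else:
            speed[i] = 0.0
    df["speed_kmh"] = speed
    df["segment"] = segment
    df["state"] = np.where(speed > speed_threshold_kmh, "transition", "stationary")

    # dwell: time to the next within-segment sample; none across gaps or at the end
    dwell = np.zeros(n, dtype=float)
    within = ~gap
    dwell[:-1][within] = dt_s[within]
    dwell[df["state"].to_numpy() == "transition"] = 0.0
    df["dwell_s"] = dwell

    step = np.zeros(n, dtype=float)
    step[1:][within] = dist_km[within]
    df["step_km"] = step
    return df


@dataclass
class ClusterModel:
    """Fitted stay-location clustering over a window's stationary samples."""

    k: int
    centroids: np.ndarray  # (k, 2) lat/lon
    labels: pd.Series  # cluster index per stationary sample (indexed like the input)
    home_cluster: int | None = None
    reason: str | None = None
    capped: bool = False

    @property
    def defined(self) -> bool:
        return self.reason is None


def _project_m(lat: np.ndarray, lon: np.ndarray, lat0: float, lon0: float):
    """Equirectangular projection to metres about (lat0, lon0)."""
    r = EARTH_RADIUS_KM * 1000.0
    x = np.radians(lon - lon0) * np.cos(np.radians(lat0)) * r
    y = np.radians(lat - lat0) * r
    return np.column_stack([x, y])


def cluster_stationary(
    labeled: pd.DataFrame,
    max_intracluster_distance_m: float = 500.0,
    k_max: int = 20,
    seed: int = 0,
) -> ClusterModel:
    """K-means over stationary samples with distance-threshold K selection.

    K-means is run for k = 1, 2, ... (n_init=10, fixed seed); the selected
    k is the smallest for which every stationary sample lies within
    ``max_intracluster_distance_m`` of its centroid, capped at ``k_max``
    (capping is flagged and logged).
    """
    stat = labeled[labeled["state"] == "stationary"]
    if stat.empty:
        return ClusterModel(0, np.empty((0, 2)), pd.Series(dtype=int), reason="no_stationary_samples")
    lat = stat["latitude"].to_numpy(dtype=float)
    lon = stat["longitude"].to_numpy(dtype=float)
    lat0, lon0 = float(lat.mean()), float(lon.mean())
    xy = _project_m(lat, lon, lat0, lon0)
    n_unique = len(np.unique(xy, axis=0))
    cap = min(k_max, n_unique)

    best = None
    for k in range(1, cap + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(xy)
        d = np.linalg.norm(xy - km.cluster_centers_[km.labels_], axis=1)
        best = km
        if d.max() <= max_intracluster_distance_m:
            break
    capped = bool(np.linalg.norm(xy - best.cluster_centers_[best.labels_], axis=1).max() > max_intracluster_distance_m)
    if capped:
        log.warning("K selection capped at k_max=%d before meeting the %.0f m threshold", cap, max_intracluster_distance_m)
    r = EARTH_RADIUS_KM * 1000.0
    cent_lat = lat0 + np.degrees(best.cluster_centers_[:, 1] / r)
    cent_lon = lon0 + np.degrees(best.cluster_centers_[:, 0] / (r * np.cos(np.radians(lat0))))
    model = ClusterModel(
        k=best.n_clusters,
        centroids=np.column_stack([cent_lat, cent_lon]),
        labels=pd.Series(best.labels_, index=stat.index),
        capped=capped,
    )
    model.home_cluster = _identify_home(labeled, model)
    return model


def _identify_home(labeled: pd.DataFrame, model: ClusterModel) -> int | None:
    """Home = cluster with the most stationary samples in [00:00, 06:00)."""
    stat = labeled.loc[model.labels.index]
    night = stat[(stat["local_seconds"] >= NIGHT_WINDOW[0]) & (stat["local_seconds"] < NIGHT_WINDOW[1])]
    if night.empty:
        return None
    counts = model.labels.loc[night.index].value_counts()
    top = counts.max()
    # deterministic tie-break: lowest cluster index among the most-populated
    return int(min(counts[counts == top].index))


def attach_clusters(labeled: pd.DataFrame, model: ClusterModel) -> pd.DataFrame:
    """Add a ``cluster`` column (NaN for transition samples)."""
    out = labeled.copy()
    out["cluster"] = np.nan
    if model.defined:
        out.loc[model.labels.index, "cluster"] = model.labels.astype(float)
    return out


@dataclass
class MobilityFeatures:
    """The five location features over a day set; missing parts carry reasons."""

    total_distance: float | None = None
    location_variance: float | None = None
    entropy: float | None = None
    normalized_entropy: float | None = None
    homestay: float | None = None
    reasons: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float | None]:
        return {
            "total_distance": self.total_distance,
            "location_variance": self.location_variance,
            "entropy": self.entropy,
            "normalized_entropy": self.normalized_entropy,
            "homestay": self.homestay,
        }


def extract_mobility_features(
    labeled: pd.DataFrame,
    model: ClusterModel,
    days: Iterable,
    homestay_tracked_denominator: bool = False,
) -> MobilityFeatures:
    """Compute the five location features over the given local dates.

    * total distance: sum of within-segment consecutive-sample haversine
      distances whose interval starts inside the day set (km);
    * location variance: ln(var(lat) + var(lon)) over stationary samples
      (undefined below 3 stationary samples or at zero variance);
    * entropy: -sum p_i ln p_i with p_i the dwell-time share of cluster i;
    * normalized entropy: entropy / ln(model.k), 0 for a single cluster;
    * homestay: home-cluster dwell / (86400 s x number of days), clipped
      to [0, 1]; with ``homestay_tracked_denominator`` the denominator is
      the total credited dwell time instead.
    """
    days = set(days)
    feats = MobilityFeatures()
    win = labeled[labeled["local_date"].isin(days)]
    if win.empty:
        feats.reasons = {f: "no_samples" for f in feats.as_dict()}
        return feats

    # distance: attribute each interval to the day of its starting sample;
    # step_km at row i is the distance from row i-1, so shift day membership
    in_days = win.index.to_numpy()
    prev_in = labeled.index.isin(in_days)
    step_rows = np.zeros(len(labeled), dtype=bool)
    step_rows[1:] = prev_in[:-1]
    feats.total_distance = float(labeled.loc[step_rows, "step_km"].sum())

    stat = win[win["state"] == "stationary"]
    if len(stat) < 3:
        feats.reasons["location_variance"] = "fewer_than_3_stationary_samples"
    else:
        var = float(np.var(stat["latitude"])) + float(np.var(stat["longitude"]))
        if var <= 0:
            feats.reasons["location_variance"] = "zero_variance"
        else:
            feats.location_variance = float(np.log(var))

    if not model.defined:
        for f in ("entropy", "normalized_entropy", "homestay"):
            feats.reasons[f] = model.reason or "no_cluster_model"
        return feats

    clustered = stat.drop(columns=["cluster"], errors="ignore").join(
        model.labels.rename("cluster"), how="inner"
    )
    dwell_by_cluster = clustered.groupby("cluster")["dwell_s"].sum()
    total_dwell = float(dwell_by_cluster.sum())
    if total_dwell <= 0:
        feats.reasons["entropy"] = "no_dwell_time"
        feats.reasons["normalized_entropy"] = "no_dwell_time"
    else:
        p = (dwell_by_cluster / total_dwell).to_numpy()
        p = p[p > 0]
        feats.entropy = float(-np.sum(p * np.log(p)))
        feats.normalized_entropy = 0.0 if model.k == 1 else float(feats.entropy / np.log(model.k))

    if model.home_cluster is None:
        feats.reasons["homestay"] = "no_night_samples"
    else:
        home_dwell = float(dwell_by_cluster.get(model.home_cluster, 0.0))
        if homestay_tracked_denominator:
            denom = total_dwell
        else:
            denom = 86400.0 * len(days)
        if denom <= 0:
            feats.reasons["homestay"] = "no_dwell_time"
        else:
            feats.homestay = float(np.clip(home_dwell / denom, 0.0, 1.0))
    return feats


def read_aware_locations(path) -> pd.DataFrame:
    """Read an AWARE-style locations CSV into the canonical sample table."""
    df = pd.read_csv(path)
    ren = {"double_latitude": "latitude", "double_longitude": "longitude"}
    df = df.rename(columns=ren)
    cols = GPS_COLUMNS + (["device_id"] if "device_id" in df.columns else [])
    return df[cols]


def read_aware_timezones(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    cols = ["timestamp", "timezone"] + (["device_id"] if "device_id" in df.columns else [])
    return df[cols]
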