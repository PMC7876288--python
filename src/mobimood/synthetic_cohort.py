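"""Synthetic study cohort with planted effects and MAR missingness.

Two generators cover the pipeline's needs:

* :func:`simulate_model_table` works directly at the participant x window
  level: standardized features with a person-level component, outcomes
  built from planted standardized slopes plus a person random intercept
  (optionally person-varying slopes) and residual noise. It is the
  workhorse for parameter-recovery, type-I-error and missing-data
  simulations.

* :func:`generate_cohort` emits full raw study streams -- GPS samples
  with injected sensing artifacts, screen events, daily wearable
  summaries, EMA mood responses, DASS-21 item ratings and timezone
  records -- whose *noiseless* schedule-level features drive the planted
  outcome model, so the complete extraction pipeline can be validated
  end to end against stored ground truth.

Missingness is missing-at-random by construction: the masking
probability is a logistic function of the always-observed phone-usage
covariate, with its offset calibrated so the marginal rate matches the
configured values (10% of symptom assessments, 9.1% of sensing days).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
from scipy import optimize

from .dass import SUBSCALE_ITEMS
from .gps_mobility import haversine_km
from .windowing import FEATURES, OUTCOMES

log = logging.getLogger(__name__)

#: Baseline subscore location/scale used to map the standardized latent
#: outcome onto raw 0-21 DASS subscores (cohort-level means and SDs of a
#: general-population sample under movement restrictions).
SUBSCORE_SCALE = {
    "depression": (3.78, 3.48),
    "anxiety": (2.73, 2.68),
    "stress": (6.00, 3.82),
}

DEFAULT_TIMEZONE = "Europe/Helsinki"
MAR_DRIVER = "usage_frequency"
MAR_STRENGTH = 1.5


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    n_participants: int
    study_days: int = 30
    assessment_days: tuple[int, ...] = (1, 16, 31)
    planted_betas: dict[str, float] = field(default_factory=dict)
    between_person_sd: float = 0.7
    within_person_sd: float = 0.6
    dass_missing_rate: float = 0.10
    sensing_missing_rate: float = 0.091
    seed: int = 0
    sampling_interval_s: float = 60.0
    start_date: date = date(2020, 4, 15)

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        for r in (self.dass_missing_rate, self.sensing_missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missingness rate {r} outside [0, 1]")
        unknown = set(self.planted_betas) - set(FEATURES)
        if unknown:
            raise ValueError(f"planted_betas has unrecognized features {sorted(unknown)}")


@dataclass
class TrueParameters:
    """Generation-time ground truth stored for recovery tests."""

    planted_betas: dict[str, float]
    trait: dict[str, float]  # per-participant latent trait
    random_intercepts: dict[str, dict[str, float]]  # outcome -> participant -> b0
    true_window_features: pd.DataFrame | None = None
    latent_outcomes: pd.DataFrame | None = None
    masked_sensing_days: dict[str, list[int]] = field(default_factory=dict)
    masked_assessments: list[tuple[str, str]] = field(default_factory=list)
    clipped_subscores: int = 0

    def to_json(self, path) -> None:
        payload = {
            "planted_betas": self.planted_betas,
            "trait": self.trait,
            "random_intercepts": self.random_intercepts,
            "masked_sensing_days": self.masked_sensing_days,
            "masked_assessments": [list(t) for t in self.masked_assessments],
            "clipped_subscores": self.clipped_subscores,
        }
        if self.true_window_features is not None:
            payload["true_window_features"] = self.true_window_features.to_dict(orient="list")
        if self.latent_outcomes is not None:
            payload["latent_outcomes"] = self.latent_outcomes.to_dict(orient="list")
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# MAR machinery
# ---------------------------------------------------------------------------


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def calibrate_mar_offset(driver_z: np.ndarray, rate: float, strength: float = MAR_STRENGTH) -> float:
    """Offset a with mean(sigmoid(a + strength * z)) = rate on the realized z."""
    z = np.asarray(driver_z, dtype=float)
    if rate <= 0:
        return -np.inf
    if rate >= 1:
        return np.inf
    f = lambda a: _sigmoid(a + strength * z).mean() - rate
    return float(optimize.brentq(f, -40.0, 40.0))


def mar_mask(driver_z: np.ndarray, rate: float, rng: np.random.Generator, strength: float = MAR_STRENGTH) -> np.ndarray:
    """Bernoulli MAR mask whose probability is logistic in the observed driver."""
    a = calibrate_mar_offset(driver_z, rate, strength)
    p = _sigmoid(a + strength * np.asarray(driver_z, dtype=float))
    return rng.random(len(p)) < p


# ---------------------------------------------------------------------------
# window-level simulator
# ---------------------------------------------------------------------------

_PERSON_SD = 0.6  # person-level SD of each feature (total variance 1)
_BEH_WEIGHT = 0.8  # behavioural-trait share of a feature's person component
_USAGE_PSY_WEIGHT = 0.6  # usage additionally loads on the psychological trait
_PSY_WEIGHT = 0.85  # psychological-trait share of the outcome intercept


def simulate_model_table(
    n_participants: int,
    n_windows: int = 2,
    planted_betas: dict[str, float] | None = None,
    outcome: str = "depression",
    between_person_sd: float = 0.7,
    within_person_sd: float = 0.6,
    slope_sd: float = 0.0,
    features: tuple[str, ...] = FEATURES,
    seed: int = 0,
) -> tuple[pd.DataFrame, TrueParameters]:
    """Participant x window table with planted standardized associations.

    Two person-level traits shape the cohort. A *behavioural* trait loads
    on every feature's person component, so features correlate with each
    other; a *psychological* trait loads on the outcome's random
    intercept. Phone-usage frequency -- the MAR driver -- loads on both,
    which makes usage-driven missingness informative about the outcome
    (complete-case analysis is genuinely biased) while keeping the other
    features independent of the random intercept, so the mixed model
    estimates the planted slopes consistently. Features have unit total
    variance (person SD 0.6). The outcome is

        y_jt = sum_f (beta_f + slope_sd * b_fj) x_fjt + b0_j + eps_jt

    with sd(b0) = ``between_person_sd`` and eps ~ N(0, within_person_sd^2).
    """
    betas = dict(planted_betas or {})
    unknown = set(betas) - set(features)
    if unknown:
        raise ValueError(f"unrecognized planted features {sorted(unknown)}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    J, T = n_participants, n_windows

    a_beh = rng.standard_normal(J)
    a_psy = rng.standard_normal(J)
    within_sd = np.sqrt(max(1.0 - _PERSON_SD**2, 0.0))
    X = {}
    for f in features:
        if f == MAR_DRIVER:
            w_b, w_p = _BEH_WEIGHT, _USAGE_PSY_WEIGHT
            person = _PERSON_SD * (
                w_b * a_beh + w_p * a_psy
                + np.sqrt(max(1 - w_b**2 - w_p**2, 0.0)) * rng.standard_normal(J)
            )
        else:
            person = _PERSON_SD * (
                _BEH_WEIGHT * a_beh + np.sqrt(1 - _BEH_WEIGHT**2) * rng.standard_normal(J)
            )
        X[f] = person[:, None] + within_sd * rng.standard_normal((J, T))

    a = a_psy  # stored as the cohort's latent trait
    b0 = between_person_sd * (_PSY_WEIGHT * a_psy + np.sqrt(1 - _PSY_WEIGHT**2) * rng.standard_normal(J))
    y = b0[:, None] + within_person_sd * rng.standard_normal((J, T))
    slopes: dict[str, np.ndarray] = {}
    for f, beta in betas.items():
        slope_j = beta + slope_sd * rng.standard_normal(J)
        slopes[f] = slope_j
        y = y + slope_j[:, None] * X[f]

    pids = [f"p{j:04d}" for j in range(J)]
    table = pd.DataFrame(
        {
            "participant": np.repeat(pids, T),
            "window": np.tile(np.arange(1, T + 1), J),
            **{f: X[f].ravel() for f in features},
            outcome: y.ravel(),
        }
    )
    truth = TrueParameters(
        planted_betas=betas,
        trait=dict(zip(pids, a)),
        random_intercepts={outcome: dict(zip(pids, b0))},
    )
    return table, truth


def apply_mar_missingness(
    table: pd.DataFrame,
    columns: list[str],
    rate: float,
    driver: str = MAR_DRIVER,
    seed: int = 0,
    strength: float = MAR_STRENGTH,
) -> pd.DataFrame:
    """Mask the given columns MAR, driven by an always-observed covariate."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = table.copy()
    z = out[driver].to_numpy(dtype=float)
    z = (z - z.mean()) / (z.std() or 1.0)
    for c in columns:
        mask = mar_mask(z, rate, rng, strength)
        out.loc[mask, c] = np.nan
    return out


# ---------------------------------------------------------------------------
# raw-stream generation
# ---------------------------------------------------------------------------


@dataclass
class ParticipantProfile:
    """Movement and behaviour knobs for one synthetic participant."""

    participant: str
    home: tuple[float, float]
    anchors: list[tuple[float, float]]  # secondary stay locations
    schedule: dict[int, list[tuple[float, float, int]]]  # day -> [(start_s, end_s, anchor_idx)]
    speed_kmh: float = 5.0
    jitter_sd_m: float = 0.0
    sampling_interval_s: float = 60.0
    accuracy_median_m: float = 10.0
    accuracy_log_sd: float = 0.5
    duplicate_rate: float = 0.0
    zero_coord_rate: float = 0.0
    accuracy_outlier_rate: float = 0.0
    timezone: str = DEFAULT_TIMEZONE


_M_PER_DEG_LAT = 111_194.9  # spherical metres per degree latitude


def _offset_deg(lat0: float, dx_m: float, dy_m: float) -> tuple[float, float]:
    dlat = dy_m / _M_PER_DEG_LAT
    dlon = dx_m / (_M_PER_DEG_LAT * np.cos(np.radians(lat0)))
    return dlat, dlon


def _validated_day_plan(profile: ParticipantProfile, day: int):
    """Visits with travel margins; rejects overlapping schedule entries."""
    visits = sorted(profile.schedule.get(day, []), key=lambda v: v[0])
    plan = []
    for vs, ve, k in visits:
        if not 0 <= vs < ve <= 86400:
            raise ValueError(f"visit ({vs}, {ve}) outside the day")
        d_km = haversine_km(profile.home[0], profile.home[1], *profile.anchors[k])
        travel_s = float(d_km) / profile.speed_kmh * 3600.0
        plan.append((vs - travel_s, vs, ve, ve + travel_s, k, float(d_km)))
    for prev, cur in zip(plan, plan[1:]):
        if cur[0] < prev[3]:
            raise ValueError(f"overlapping schedule entries on day {day}")
    if plan and (plan[0][0] < 0 or plan[-1][3] > 86400):
        raise ValueError(f"schedule (with travel) leaves day {day}")
    return plan


def _positions_for_day(profile: ParticipantProfile, day: int, times_s: np.ndarray) -> np.ndarray:
    """Noiseless lat/lon at each second-of-day, following the day's plan."""
    plan = _validated_day_plan(profile, day)
    lat = np.full(len(times_s), profile.home[0])
    lon = np.full(len(times_s), profile.home[1])
    for dep, vs, ve, ret, k, _ in plan:
        alat, alon = profile.anchors[k]
        at = (times_s >= vs) & (times_s < ve)
        lat[at], lon[at] = alat, alon
        out = (times_s >= dep) & (times_s < vs)
        if out.any() and vs > dep:
            frac = (times_s[out] - dep) / (vs - dep)
            lat[out] = profile.home[0] + frac * (alat - profile.home[0])
            lon[out] = profile.home[1] + frac * (alon - profile.home[1])
        back = (times_s >= ve) & (times_s < ret)
        if back.any() and ret > ve:
            frac = (times_s[back] - ve) / (ret - ve)
            lat[back] = alat + frac * (profile.home[0] - alat)
            lon[back] = alon + frac * (profile.home[1] - alon)
    return np.column_stack([lat, lon])


def generate_gps_trace(
    profile: ParticipantProfile,
    day_range: range,
    seed: int = 0,
    day_epoch_ms: dict[int, int] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Raw GPS samples for the profile over the given study days.

    Emits dwell and movement segments at the configured sampling interval
    with Gaussian positional jitter and lognormal accuracies, then injects
    artifacts at the configured rates: exact duplicate rows, (0, 0)
    sensing-error coordinates and large accuracy outliers. Returns the
    stream plus the injected-artifact counts.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if day_epoch_ms is None:
        day_epoch_ms = {d: (d - 1) * 86_400_000 for d in day_range}
    frames = []
    counts = {"duplicate": 0, "zero_coord": 0, "accuracy_outlier": 0}
    for day in day_range:
        t = np.arange(0.0, 86400.0, profile.sampling_interval_s)
        pos = _positions_for_day(profile, day, t)
        if profile.jitter_sd_m > 0:
            dy = rng.normal(0, profile.jitter_sd_m, len(t))
            dx = rng.normal(0, profile.jitter_sd_m, len(t))
            dlat, dlon = _offset_deg(profile.home[0], dx, dy)
            pos = pos + np.column_stack([dlat, dlon])
        acc = np.exp(rng.normal(np.log(profile.accuracy_median_m), profile.accuracy_log_sd, len(t)))
        out_hi = rng.random(len(t)) < profile.accuracy_outlier_rate
        acc[out_hi] *= 25.0
        counts["accuracy_outlier"] += int(out_hi.sum())
        ts = day_epoch_ms[day] + (t * 1000.0).astype(np.int64)
        df = pd.DataFrame(
            {"timestamp": ts, "latitude": pos[:, 0], "longitude": pos[:, 1], "accuracy": acc}
        )
        # one draw assigns each row at most one artifact class, so the
        # injected counts can be recovered exactly from the emitted stream
        u = rng.random(len(df))
        zero = u < profile.zero_coord_rate
        df.loc[zero, ["latitude", "longitude"]] = 0.0
        counts["zero_coord"] += int(zero.sum())
        dup = np.flatnonzero((u >= profile.zero_coord_rate) & (u < profile.zero_coord_rate + profile.duplicate_rate))
        if len(dup):
            df = (
                pd.concat([df, df.iloc[dup]], ignore_index=True)
                .sort_values("timestamp", kind="mergesort")
                .reset_index(drop=True)
            )
        counts["duplicate"] += len(dup)
        frames.append(df)
    trace = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["timestamp", "latitude", "longitude", "accuracy"]
    )
    return trace, counts


def true_daily_gps_features(profile: ParticipantProfile, day: int) -> dict:
    """Noiseless schedule-level mobility quantities for one day.

    Returns dwell seconds per anchor index (-1 = home), the travelled
    distance (km) and the day's homestay fraction.
    """
    plan = _validated_day_plan(profile, day)
    dwell = {-1: 86400.0}
    distance = 0.0
    for dep, vs, ve, ret, k, d_km in plan:
        dwell[-1] -= ret - dep
        dwell[k] = dwell.get(k, 0.0) + (ve - vs)
        distance += 2.0 * d_km
    return {"dwell": dwell, "distance_km": distance, "homestay": dwell[-1] / 86400.0}


def true_window_gps_features(profile: ParticipantProfile, days: range) -> dict[str, float]:
    """Window-level true mobility features aggregated from the schedule."""
    dwell: dict[int, float] = {}
    distance = 0.0
    homestay = []
    for day in days:
        d = true_daily_gps_features(profile, day)
        distance += d["distance_km"]
        homestay.append(d["homestay"])
        for k, v in d["dwell"].items():
            dwell[k] = dwell.get(k, 0.0) + v
    total = sum(dwell.values())
    p = np.array([v / total for v in dwell.values() if v > 0])
    entropy = float(-np.sum(p * np.log(p)))
    n_clusters = len(p)
    norm_entropy = 0.0 if n_clusters == 1 else entropy / np.log(n_clusters)
    coords = {-1: profile.home, **{i: a for i, a in enumerate(profile.anchors)}}
    lats = np.array([coords[k][0] for k in dwell])
    lons = np.array([coords[k][1] for k in dwell])
    w = np.array([dwell[k] for k in dwell])
    w = w / w.sum()
    var = float(np.sum(w * (lats - np.sum(w * lats)) ** 2) + np.sum(w * (lons - np.sum(w * lons)) ** 2))
    return {
        "total_distance": distance / len(list(days)),  # daily mean, like the pipeline
        "location_variance": float(np.log(var)) if var > 0 else np.nan,
        "entropy": entropy,
        "normalized_entropy": float(norm_entropy),
        "homestay": float(np.mean(homestay)),
    }


@dataclass
class RawStudyData:
    """Raw per-participant streams, as the pipeline's readers expect them."""

    gps: dict[str, pd.DataFrame]
    screen: dict[str, pd.DataFrame]
    wearable: dict[str, pd.DataFrame]
    ema: dict[str, pd.DataFrame]
    dass: pd.DataFrame  # participant, assessment_point, item_1..item_21
    timezones: dict[str, pd.DataFrame]
    enrollment: dict[str, date]
    profiles: dict[str, ParticipantProfile] = field(default_factory=dict)


def _epoch_ms(day_date: date, seconds: float, zone: ZoneInfo) -> int:
    local = datetime.combine(day_date, datetime.min.time(), tzinfo=zone) + timedelta(seconds=float(seconds))
    return int(local.timestamp() * 1000)


def _items_from_subscore(subscore: int, items: tuple[int, ...]) -> dict[int, int]:
    """Distribute a 0-21 subscore over 7 items (largest-remainder, ratings <= 3)."""
    base, rem = divmod(int(subscore), 7)
    return {item: base + (1 if i < rem else 0) for i, item in enumerate(items)}


def generate_cohort(config: CohortConfig) -> tuple[RawStudyData, TrueParameters]:
    """Full raw study data with planted feature-symptom associations.

    The outcome model operates on the *noiseless* window-level features
    implied by each participant's generative parameters: GPS features come
    from the planted schedules, usage/wearable/EMA features from their
    planted daily levels. Standardized true features enter the latent
    outcome with the planted slopes; DASS item ratings are generated so
    the subscale sums reproduce the simulated subscores. Sensing days and
    T1/T2 assessments are then masked MAR at the configured rates, driven
    by the observed phone-usage level.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    zone = ZoneInfo(DEFAULT_TIMEZONE)
    J = config.n_participants
    pids = [f"p{j:04d}" for j in range(J)]
    enrollment = {pid: config.start_date + timedelta(days=int(j % 7)) for j, pid in enumerate(pids)}

    a_beh = rng.standard_normal(J)  # behavioural trait -> feature levels
    a_psy = rng.standard_normal(J)  # psychological trait -> symptom level
    a = a_psy

    def person_z(weight: float = _BEH_WEIGHT) -> np.ndarray:
        return weight * a_beh + np.sqrt(1 - weight**2) * rng.standard_normal(J)

    z_mobility = person_z()
    # usage (the MAR driver) loads on both traits, linking missingness to
    # the outcome through observed data only
    z_usage_freq = (
        _BEH_WEIGHT * a_beh + _USAGE_PSY_WEIGHT * a_psy
        + np.sqrt(max(1 - _BEH_WEIGHT**2 - _USAGE_PSY_WEIGHT**2, 0.0)) * rng.standard_normal(J)
    )
    z_usage_time = person_z()
    z_wear = {f: person_z() for f in ("steps", "met", "tst", "sol", "waso", "tib", "hrv")}
    z_mood = {"valence": person_z(), "arousal": person_z()}

    gps: dict[str, pd.DataFrame] = {}
    screen: dict[str, pd.DataFrame] = {}
    wearable: dict[str, pd.DataFrame] = {}
    ema: dict[str, pd.DataFrame] = {}
    timezones: dict[str, pd.DataFrame] = {}
    profiles: dict[str, ParticipantProfile] = {}
    daily_true: list[dict] = []

    for j, pid in enumerate(pids):
        prng = np.random.default_rng(np.random.SeedSequence((config.seed, 1, j)))
        home = (60.17 + prng.uniform(-0.08, 0.08), 24.94 + prng.uniform(-0.15, 0.15))
        n_anchors = int(prng.integers(1, 5))
        anchors = []
        for _ in range(n_anchors):
            bearing = prng.uniform(0, 2 * np.pi)
            dist_m = prng.uniform(600, 3000)
            dlat, dlon = _offset_deg(home[0], dist_m * np.cos(bearing), dist_m * np.sin(bearing))
            anchors.append((home[0] + dlat, home[1] + dlon))
        # daily visit schedule: outing intensity scales with the mobility trait
        lam = float(np.exp(0.1 + 0.45 * z_mobility[j]))
        schedule: dict[int, list[tuple[float, float, int]]] = {}
        for day in range(1, config.study_days + 1):
            n_visits = min(int(prng.poisson(lam)), 3)
            visits = []
            cursor = 8 * 3600.0
            for _ in range(n_visits):
                start = cursor + prng.uniform(0.75, 2.0) * 3600
                dur = prng.uniform(0.5, 2.5) * 3600
                if start + dur > 21 * 3600:
                    break
                k = int(prng.integers(0, n_anchors))
                visits.append((start, start + dur, k))
                cursor = start + dur + 0.6 * 3600  # leave travel headroom
            schedule[day] = visits
        profile = ParticipantProfile(
            participant=pid,
            home=home,
            anchors=anchors,
            schedule=schedule,
            jitter_sd_m=8.0,
            sampling_interval_s=config.sampling_interval_s,
            duplicate_rate=0.01,
            zero_coord_rate=0.004,
            accuracy_outlier_rate=0.01,
        )
        profiles[pid] = profile

        enr = enrollment[pid]
        day_dates = {d: enr + timedelta(days=d - 1) for d in range(1, config.study_days + 1)}
        day_epoch = {d: _epoch_ms(day_dates[d], 0.0, zone) for d in day_dates}
        trace, _ = generate_gps_trace(
            profile, range(1, config.study_days + 1), seed=int(prng.integers(2**31)), day_epoch_ms=day_epoch
        )
        gps[pid] = trace
        timezones[pid] = pd.DataFrame(
            {"timestamp": [day_epoch[1] - 3_600_000], "timezone": [DEFAULT_TIMEZONE]}
        )

        # screen events and true usage levels
        freq_level = float(np.exp(np.log(25.0) + 0.35 * z_usage_freq[j]))
        sess_mean_min = float(4.0 * np.exp(0.3 * z_usage_time[j]))
        ev_rows = []
        wear_rows = []
        ema_rows = []
        for d in range(1, config.study_days + 1):
            n_unlock = max(int(prng.poisson(freq_level)), 1)
            starts = np.sort(prng.uniform(6.5 * 3600, 23.5 * 3600, n_unlock))
            durs = prng.exponential(sess_mean_min * 60.0, n_unlock)
            for s, du in zip(starts, durs):
                ev_rows.append((_epoch_ms(day_dates[d], s, zone), "unlocked"))
                ev_rows.append((_epoch_ms(day_dates[d], min(s + du, 86_399.0), zone), "locked"))
            tst = max(prng.normal(420 + 35 * z_wear["tst"][j], 20), 180.0)
            sol = max(prng.normal(15 + 6 * z_wear["sol"][j], 4), 1.0)
            waso = max(prng.normal(30 + 12 * z_wear["waso"][j], 8), 0.0)
            tib = tst + sol + waso + max(prng.normal(8 + 10 * z_wear["tib"][j], 5), 0.0)
            wear_rows.append(
                {
                    "date": day_dates[d],
                    "steps": max(prng.normal(7000 + 2500 * z_wear["steps"][j], 1500), 0.0),
                    "met_avg": max(prng.normal(1.4 + 0.15 * z_wear["met"][j], 0.05), 0.8),
                    "tst": tst,
                    "sol": sol,
                    "waso": waso,
                    "tib": tib,
                    "hrv_rmssd": min(max(prng.normal(45 + 12 * z_wear["hrv"][j], 6), 5.0), 250.0),
                }
            )
            for slot in (9.0, 14.5, 20.0):
                t_s = slot * 3600 + prng.uniform(-900, 900)
                val = int(np.clip(np.rint(prng.normal(0.8 + 1.3 * z_mood["valence"][j], 1.2)), -4, 4))
                aro = int(np.clip(np.rint(prng.normal(-0.2 + 1.3 * z_mood["arousal"][j], 1.2)), -4, 4))
                ema_rows.append((_epoch_ms(day_dates[d], t_s, zone), val, aro))
            td = true_daily_gps_features(profile, d)
            daily_true.append(
                {
                    "participant": pid,
                    "study_day": d,
                    "usage_frequency": float(n_unlock),
                    "usage_time": float(durs.sum() / 60.0),
                    **{k: wear_rows[-1][m] for k, m in
                       [("steps", "steps"), ("met", "met_avg"), ("tst", "tst"), ("sol", "sol"),
                        ("waso", "waso"), ("tib", "tib"), ("hrv", "hrv_rmssd")]},
                    "valence": float(np.mean([r[1] for r in ema_rows[-3:]])),
                    "arousal": float(np.mean([r[2] for r in ema_rows[-3:]])),
                    "homestay_day": td["homestay"],
                    "distance_day": td["distance_km"],
                }
            )
        screen[pid] = pd.DataFrame(ev_rows, columns=["timestamp", "status"]).sort_values("timestamp").reset_index(drop=True)
        wearable[pid] = pd.DataFrame(wear_rows)
        ema[pid] = pd.DataFrame(ema_rows, columns=["timestamp", "valence", "arousal"])

    # ---- true window-level features ----
    daily_df = pd.DataFrame(daily_true)
    rows = []
    for pid in pids:
        for w, days in ((1, range(1, 16)), (2, range(16, 31))):
            sub = daily_df[(daily_df["participant"] == pid) & daily_df["study_day"].isin(days)]
            gps_true = true_window_gps_features(profiles[pid], days)
            row = {"participant": pid, "window": w, **gps_true}
            for f in ("usage_frequency", "usage_time", "steps", "met", "tst", "sol", "waso", "tib", "hrv", "valence", "arousal"):
                row[f] = float(sub[f].mean())
            rows.append(row)
    true_win = pd.DataFrame(rows)

    # ---- planted outcome model on standardized true features ----
    z = true_win.copy()
    for f in FEATURES:
        v = z[f].astype(float)
        sd = v.std(ddof=1)
        z[f] = (v - v.mean()) / (sd if sd > 0 else 1.0)

    b0 = {
        oc: config.between_person_sd
        * (_PSY_WEIGHT * a_psy + np.sqrt(1 - _PSY_WEIGHT**2) * rng.standard_normal(J))
        for oc in OUTCOMES
    }
    latent_rows = []
    clipped = 0
    dass_rows = []
    for j, pid in enumerate(pids):
        for point in ("T0", "T1", "T2"):
            items_all: dict[str, dict[int, int]] = {}
            rec = {"participant": pid, "assessment_point": point}
            for oc in OUTCOMES:
                eta = b0[oc][j] + config.within_person_sd * rng.standard_normal()
                if point != "T0":
                    w = 1 if point == "T1" else 2
                    zrow = z[(z["participant"] == pid) & (z["window"] == w)].iloc[0]
                    eta += sum(beta * float(zrow[f]) for f, beta in config.planted_betas.items())
                mean, sd = SUBSCORE_SCALE[oc]
                raw = mean + sd * eta
                sub = int(np.rint(raw))
                if not 0 <= sub <= 21:
                    clipped += 1
                    sub = int(np.clip(sub, 0, 21))
                items_all[oc] = _items_from_subscore(sub, SUBSCALE_ITEMS[oc])
                latent_rows.append({"participant": pid, "assessment_point": point, "outcome": oc, "latent": eta, "subscore": sub})
            for oc in OUTCOMES:
                for item, rating in items_all[oc].items():
                    rec[f"item_{item}"] = rating
            dass_rows.append(rec)
    if clipped:
        log.warning("%d planted subscores fell outside [0, 21] and were clipped", clipped)
    dass = pd.DataFrame(dass_rows)

    # ---- MAR missingness ----
    usage_person = daily_df.groupby("participant")["usage_frequency"].mean().reindex(pids)
    z_use = ((usage_person - usage_person.mean()) / usage_person.std(ddof=0)).to_numpy()

    masked_days: dict[str, list[int]] = {pid: [] for pid in pids}
    day_grid = daily_df[["participant", "study_day"]].copy()
    z_day = day_grid["participant"].map(dict(zip(pids, z_use))).to_numpy()
    sens_mask = mar_mask(z_day, config.sensing_missing_rate, rng)
    for (pid, d), masked in zip(day_grid.itertuples(index=False), sens_mask):
        if masked:
            masked_days[pid].append(int(d))
    for pid in pids:
        if not masked_days[pid]:
            continue
        enr = enrollment[pid]
        dates = {enr + timedelta(days=d - 1) for d in masked_days[pid]}
        ms_lo = {d: _epoch_ms(enr + timedelta(days=d - 1), 0.0, zone) for d in masked_days[pid]}
        ms_hi = {d: _epoch_ms(enr + timedelta(days=d), 0.0, zone) for d in masked_days[pid]}
        for stream in (gps, screen, ema):
            df = stream[pid]
            drop = np.zeros(len(df), dtype=bool)
            for d in masked_days[pid]:
                drop |= (df["timestamp"] >= ms_lo[d]) & (df["timestamp"] < ms_hi[d])
            stream[pid] = df[~drop].reset_index(drop=True)
        wearable[pid] = wearable[pid][~wearable[pid]["date"].isin(dates)].reset_index(drop=True)

    masked_assessments: list[tuple[str, str]] = []
    points = [(pid, pt) for pid in pids for pt in ("T1", "T2")]
    z_pt = np.array([z_use[pids.index(pid)] for pid, _ in points])
    dass_mask = mar_mask(z_pt, config.dass_missing_rate, rng)
    keep = np.ones(len(dass), dtype=bool)
    for (pid, pt), masked in zip(points, dass_mask):
        if masked:
            masked_assessments.append((pid, pt))
            keep &= ~((dass["participant"] == pid) & (dass["assessment_point"] == pt))
    dass = dass[keep].reset_index(drop=True)

    raw = RawStudyData(
        gps=gps, screen=screen, wearable=wearable, ema=ema, dass=dass,
        timezones=timezones, enrollment=enrollment, profiles=profiles,
    )
    truth = TrueParameters(
        planted_betas=dict(config.planted_betas),
        trait=dict(zip(pids, a)),
        random_intercepts={oc: dict(zip(pids, b0[oc])) for oc in OUTCOMES},
        true_window_features=true_win,
        latent_outcomes=pd.DataFrame(latent_rows),
        masked_sensing_days=masked_days,
        masked_assessments=masked_assessments,
        clipped_subscores=clipped,
    )
    return raw, truth


# ---------------------------------------------------------------------------
# AWARE-style writers
# ---------------------------------------------------------------------------


def write_cohort(raw: RawStudyData, truth: TrueParameters, outdir) -> dict[str, Path]:
    """Write the cohort as AWARE-style CSV tables plus a truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    loc = pd.concat(
        [df.assign(device_id=pid) for pid, df in raw.gps.items()], ignore_index=True
    ).rename(columns={"latitude": "double_latitude", "longitude": "double_longitude"})
    paths["locations"] = outdir / "locations.csv"
    loc[["timestamp", "device_id", "double_latitude", "double_longitude", "accuracy"]].to_csv(paths["locations"], index=False)

    status_to_code = {"off": 0, "on": 1, "locked": 2, "unlocked": 3}
    scr = pd.concat([df.assign(device_id=pid) for pid, df in raw.screen.items()], ignore_index=True)
    scr["screen_status"] = scr["status"].map(status_to_code)
    paths["screen"] = outdir / "screen.csv"
    scr[["timestamp", "device_id", "screen_status"]].to_csv(paths["screen"], index=False)

    tz = pd.concat([df.assign(device_id=pid) for pid, df in raw.timezones.items()], ignore_index=True)
    paths["timezone"] = outdir / "timezone.csv"
    tz[["timestamp", "device_id", "timezone"]].to_csv(paths["timezone"], index=False)

    wear = pd.concat([df.assign(participant=pid) for pid, df in raw.wearable.items()], ignore_index=True)
    paths["wearable"] = outdir / "wearable.csv"
    wear.to_csv(paths["wearable"], index=False)

    ema = pd.concat([df.assign(participant=pid) for pid, df in raw.ema.items()], ignore_index=True)
    paths["ema"] = outdir / "ema.csv"
    ema.to_csv(paths["ema"], index=False)

    paths["dass"] = outdir / "dass.csv"
    raw.dass.to_csv(paths["dass"], index=False)

    enr = pd.DataFrame(
        {"participant": list(raw.enrollment), "enrollment_date": [d.isoformat() for d in raw.enrollment.values()]}
    )
    paths["enrollment"] = outdir / "enrollment.csv"
    enr.to_csv(paths["enrollment"], index=False)

    paths["truth"] = outdir / "truth.json"
    truth.to_json(paths["truth"])
    return paths
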