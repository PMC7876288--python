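"""Study-day alignment, two-week pooling and z-standardization.

Every participant's streams are expressed on their own study days 1..30
(day 1 = enrollment date). Daily features are pooled into two 15-day
windows -- days 1-15 paired with the midpoint (T1) symptom assessment and
days 16-30 with the endpoint (T2) -- and the resulting participant x
window table is z-standardized (grand mean/SD over all observed rows,
predictors and outcomes alike) before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

#: The 16 window-level features, grouped into the four predictor clusters.
FEATURE_CLUSTERS: dict[str, tuple[str, ...]] = {
    "GPS": ("location_variance", "total_distance", "entropy", "normalized_entropy", "homestay"),
    "usage": ("usage_time", "usage_frequency"),
    "wearable": ("steps", "met", "tst", "sol", "waso", "tib", "hrv"),
    "EMA": ("valence", "arousal"),
}
FEATURES: tuple[str, ...] = tuple(f for fs in FEATURE_CLUSTERS.values() for f in fs)
OUTCOMES = ("depression", "anxiety", "stress")

STUDY_DAYS = 30
WINDOWS = {1: range(1, 16), 2: range(16, 31)}  # day sets; T1 sits on day 16, T2 on day 31
WINDOW_ASSESSMENT = {1: "T1", 2: "T2"}
MIN_COVERAGE_DAYS = 5


def study_day(local_date: date, enrollment: date) -> int:
    """1-based study day index of a local calendar date."""
    return (local_date - enrollment).days + 1


def to_study_days(
    daily: pd.DataFrame, enrollment: dict[str, date], n_days: int = STUDY_DAYS
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Map per-participant local dates to study days 1..n_days.

    ``daily`` has columns ``participant`` and ``local_date`` (plus feature
    columns). Rows outside the study window are dropped and counted in the
    returned ledger.
    """
    df = daily.copy()
    enr = df["participant"].map(enrollment)
    if enr.isna().any():
        missing = sorted(df.loc[enr.isna(), "participant"].unique())
        raise ValueError(f"no enrollment date for participants {missing}")
    df["study_day"] = [
        study_day(d, e) for d, e in zip(df["local_date"], enr)
    ]
    out_of_window = (df["study_day"] < 1) | (df["study_day"] > n_days)
    ledger = {"out_of_window": int(out_of_window.sum())}
    df = df[~out_of_window].drop(columns=["local_date"]).reset_index(drop=True)
    return df, ledger


def pool_windows(
    daily: pd.DataFrame,
    features: tuple[str, ...] = FEATURES,
    min_coverage: int = MIN_COVERAGE_DAYS,
) -> pd.DataFrame:
    """Average daily features into the two 15-day windows.

    A window feature is the mean over its defined daily values; it is left
    undefined when fewer than ``min_coverage`` days are defined. Returns
    one row per participant x window.
    """
    present = [f for f in features if f in daily.columns]
    rows = []
    for pid, grp in daily.groupby("participant", sort=True):
        for w, days in WINDOWS.items():
            sub = grp[grp["study_day"].isin(days)]
            row: dict = {"participant": pid, "window": w}
            for f in present:
                vals = sub[f].dropna()
                row[f] = float(vals.mean()) if len(vals) >= min_coverage else np.nan
            rows.append(row)
    return pd.DataFrame(rows, columns=["participant", "window", *present])


def attach_outcomes(pooled: pd.DataFrame, dass_scores: pd.DataFrame) -> pd.DataFrame:
    """Pair window 1 with T1 and window 2 with T2 subscores.

    ``dass_scores`` has columns participant, assessment_point and the
    three subscores; undefined assessments stay NaN.
    """
    out = pooled.copy()
    key = out["window"].map(WINDOW_ASSESSMENT)
    scores = dass_scores.set_index(["participant", "assessment_point"])
    for oc in OUTCOMES:
        vals = []
        for pid, ap in zip(out["participant"], key):
            try:
                vals.append(float(scores.loc[(pid, ap), oc]))
            except (KeyError, TypeError, ValueError):
                vals.append(np.nan)
        out[oc] = vals
    return out


@dataclass
class Standardization:
    """Grand-mean/SD transform parameters, kept for inverse mapping."""

    params: dict[str, tuple[float, float]] = field(default_factory=dict)
    zero_sd_columns: list[str] = field(default_factory=list)

    def inverse(self, column: str, values: np.ndarray) -> np.ndarray:
        mean, sd = self.params[column]
        return np.asarray(values) * sd + mean


def standardize(
    table: pd.DataFrame, columns: tuple[str, ...] | None = None
) -> tuple[pd.DataFrame, Standardization]:
    """z-standardize columns over all observed participant-window rows.

    Means and SDs (ddof=1) are grand statistics over observed values only;
    zero-SD columns are left unscaled and flagged.
    """
    if columns is None:
        columns = tuple(c for c in [*FEATURES, *OUTCOMES] if c in table.columns)
    out = table.copy()
    std = Standardization()
    for c in columns:
        vals = out[c].astype(float)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if not np.isfinite(sd) or sd == 0:
            std.zero_sd_columns.append(c)
            std.params[c] = (mean, 1.0)
            continue
        out[c] = (vals - mean) / sd
        std.params[c] = (mean, sd)
    return out, std
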