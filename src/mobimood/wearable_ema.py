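"""Wearable daily summaries and EMA mood aggregation.

Wearable records are consumed as ring-style daily outputs: step count,
24-h MET average, total sleep time (TST), sleep onset latency (SOL),
wake after sleep onset (WASO), time in bed (TIB, all minutes) and nightly
RMSSD heart-rate variability (ms). Validation never raises: fields that
violate plausibility invariants are set undefined with a reason, the rest
of the record survives.

EMA mood responses are momentary valence/arousal self-reports on the
integer grid -4..4 (circumplex model), up to three per day; the daily
mood is the unweighted mean of that day's responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

WEARABLE_FIELDS = ("steps", "met_avg", "tst", "sol", "waso", "tib", "hrv_rmssd")

#: Slack (minutes) allowed in the sleep-architecture consistency check
#: sol + waso <= tib - tst + slack.
SLEEP_CONSISTENCY_SLACK_MIN = 30.0
HRV_MAX_MS = 500.0


@dataclass
class DailyWearableRecord:
    date: date
    steps: float | None = None
    met_avg: float | None = None
    tst: float | None = None
    sol: float | None = None
    waso: float | None = None
    tib: float | None = None
    hrv_rmssd: float | None = None
    flags: dict[str, str] = field(default_factory=dict)


def validate_wearable(record: DailyWearableRecord) -> DailyWearableRecord:
    """Range- and consistency-check a daily record; flag, never raise.

    Checks: all measures non-negative; TST <= TIB; SOL + WASO <= TIB - TST
    + 30 min slack; RMSSD <= 500 ms. Offending fields are set to None with
    the reason recorded in ``flags``.
    """
    rec = DailyWearableRecord(date=record.date, flags=dict(record.flags))
    for f in WEARABLE_FIELDS:
        v = getattr(record, f)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            setattr(rec, f, None)
            continue
        if v < 0:
            rec.flags[f] = "negative"
            setattr(rec, f, None)
        else:
            setattr(rec, f, float(v))
    if rec.tst is not None and rec.tib is not None and rec.tst > rec.tib:
        rec.flags["tst"] = "exceeds_time_in_bed"
        rec.tst = None
    if all(getattr(rec, f) is not None for f in ("tst", "sol", "waso", "tib")):
        if rec.sol + rec.waso > rec.tib - rec.tst + SLEEP_CONSISTENCY_SLACK_MIN:
            rec.flags["sol"] = "sleep_architecture_inconsistent"
            rec.flags["waso"] = "sleep_architecture_inconsistent"
            rec.sol = rec.waso = None
    if rec.hrv_rmssd is not None and rec.hrv_rmssd > HRV_MAX_MS:
        rec.flags["hrv_rmssd"] = "implausibly_high"
        rec.hrv_rmssd = None
    return rec


def daily_mood(responses: pd.DataFrame, day: date) -> tuple[float, float] | None:
    """Mean (valence, arousal) of a day's EMA responses; None if absent.

    ``responses`` needs ``local_date``, ``valence``, ``arousal`` columns
    with integer ratings in -4..4.
    """
    sub = responses[responses["local_date"] == day]
    if sub.empty:
        return None
    v = sub["valence"].astype(float)
    a = sub["arousal"].astype(float)
    if (v.abs() > 4).any() or (a.abs() > 4).any():
        raise ValueError("EMA ratings must lie on the -4..4 grid")
    return float(v.mean()), float(a.mean())


def read_wearable_daily(path) -> list[DailyWearableRecord]:
    """Read daily wearable summaries from CSV with the canonical field names."""
    df = pd.read_csv(path)
    recs = []
    for row in df.itertuples(index=False):
        kwargs = {f: getattr(row, f, None) for f in WEARABLE_FIELDS}
        d = row.date
        if not isinstance(d, date):
            d = pd.Timestamp(d).date()
        recs.append(DailyWearableRecord(date=d, **kwargs))
    return recs


def records_from_frame(df: pd.DataFrame) -> list[DailyWearableRecord]:
    """Build daily records from a DataFrame with the canonical field names."""
    recs = []
    for row in df.itertuples(index=False):
        d = row.date
        if not isinstance(d, date):
            d = pd.Timestamp(d).date()
        recs.append(
            DailyWearableRecord(date=d, **{f: getattr(row, f, None) for f in WEARABLE_FIELDS})
        )
    return recs


def wearable_to_frame(records: list[DailyWearableRecord]) -> pd.DataFrame:
    rows = [{"date": r.date, **{f: getattr(r, f) for f in WEARABLE_FIELDS}} for r in records]
    cols = ["date", *WEARABLE_FIELDS]
    return pd.DataFrame(rows, columns=cols)
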