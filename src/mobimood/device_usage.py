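"""Phone-usage features from screen event streams.

A usage session runs from an unlock event to the next lock event.
Consecutive unlocks without an intervening lock close the earlier session
at the next unlock; a trailing unmatched unlock is closed at the stream's
last event; sessions longer than a cap (default 12 h, guarding against
lost lock events) are truncated. Sessions crossing local midnight are
split at midnight so each day is credited its own minutes.

Daily features: usage frequency = number of unlock events that local day;
usage duration = summed session minutes attributed to the day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, datetime, timedelta

import pandas as pd

log = logging.getLogger(__name__)

MAX_SESSION_S = 12 * 3600

#: AWARE screen_status integer codes.
SCREEN_STATUS_CODES = {0: "off", 1: "on", 2: "locked", 3: "unlocked"}


@dataclass(frozen=True)
class UsageSession:
    start: datetime  # local, naive
    end: datetime
    truncated: bool = False

    @property
    def duration_min(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0


def sessionize(events: pd.DataFrame, max_session_s: float = MAX_SESSION_S) -> list[UsageSession]:
    """Pair unlock/lock events into usage sessions, split at local midnight.

    ``events`` needs columns ``local_dt`` (naive local datetime) and
    ``status`` (one of off/on/locked/unlocked). Lock events with no open
    session are ignored (logged).
    """
    ev = events.sort_values("local_dt", kind="mergesort")
    sessions: list[UsageSession] = []
    open_start: datetime | None = None
    last_dt: datetime | None = None

    def close(start: datetime, end: datetime) -> None:
        truncated = False
        if (end - start).total_seconds() > max_session_s:
            end = start + timedelta(seconds=max_session_s)
            truncated = True
            log.warning("session starting %s exceeded cap; truncated", start)
        sessions.extend(_split_at_midnight(start, end, truncated))

    for row in ev.itertuples(index=False):
        dt = pd.Timestamp(row.local_dt).to_pydatetime()
        status = row.status
        last_dt = dt
        if status == "unlocked":
            if open_start is not None:
                close(open_start, dt)  # lost lock: close at next unlock
            open_start = dt
        elif status == "locked":
            if open_start is None:
                log.debug("lock at %s with no open session; ignored", dt)
            else:
                close(open_start, dt)
                open_start = None
    if open_start is not None and last_dt is not None:
        close(open_start, last_dt)  # unmatched trailing unlock
    return sessions


def _split_at_midnight(start: datetime, end: datetime, truncated: bool) -> list[UsageSession]:
    parts: list[UsageSession] = []
    cur = start
    while cur.date() < end.date():
        midnight = datetime.combine(cur.date() + timedelta(days=1), datetime.min.time())
        parts.append(UsageSession(cur, midnight, truncated))
        cur = midnight
    parts.append(UsageSession(cur, end, truncated))
    return parts


def daily_usage_features(
    sessions: list[UsageSession], events: pd.DataFrame, day: date
) -> tuple[int, float]:
    """(usage_frequency, usage_duration_min) for one local calendar day.

    Frequency counts raw unlock events on the day regardless of how
    sessionization resolved them; duration sums session minutes attributed
    to the day after midnight splitting. Absent data yields (0, 0.0).
    """
    if events.empty:
        freq = 0
    else:
        dts = pd.to_datetime(events["local_dt"])
        freq = int(((events["status"] == "unlocked") & (dts.dt.date == day)).sum())
    duration = sum(s.duration_min for s in sessions if s.start.date() == day)
    return freq, float(duration)


def read_aware_screen(path, status_codes: dict[int, str] | None = None) -> pd.DataFrame:
    """Read an AWARE-style screen CSV (timestamp, device_id, screen_status)."""
    codes = status_codes or SCREEN_STATUS_CODES
    df = pd.read_csv(path)
    df["status"] = df["screen_status"].map(codes)
    if df["status"].isna().any():
        bad = sorted(df.loc[df["status"].isna(), "screen_status"].unique())
        raise ValueError(f"unknown screen_status codes {bad}")
    cols = ["timestamp", "status"] + (["device_id"] if "device_id" in df.columns else [])
    return df[cols]
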