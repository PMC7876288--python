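from datetime import date

import numpy as np
import pandas as pd
import pytest

from mobimood.gps_mobility import ClusterModel


def make_stationary_labeled(
    anchors: list[tuple[float, float]],
    dwell_s: list[float],
    samples_per_anchor: int = 10,
    day: date = date(2020, 4, 15),
    night_anchor: int | None = 0,
) -> tuple[pd.DataFrame, ClusterModel]:
    """A labeled stationary trace with exact dwell-time shares per anchor.

    Each anchor contributes ``samples_per_anchor`` stationary samples whose
    summed dwell equals the requested seconds; night-time samples (01:00)
    at ``night_anchor`` pin the home cluster. Also returns a matching
    hand-built cluster model (one cluster per anchor).
    """
    rows = []
    labels = []
    t = 0
    for ci, ((lat, lon), dw) in enumerate(zip(anchors, dwell_s)):
        per = dw / samples_per_anchor
        for s in range(samples_per_anchor):
            sec = 3600 + t * 60 if (night_anchor is not None and ci == night_anchor and s == 0) else 8 * 3600 + t * 60
            rows.append(
                {
                    "timestamp": t * 60_000,
                    "latitude": lat,
                    "longitude": lon,
                    "accuracy": 10.0,
                    "local_date": day,
                    "local_seconds": float(sec),
                    "speed_kmh": 0.0,
                    "state": "stationary",
                    "segment": ci,
                    "dwell_s": per,
                    "step_km": 0.0,
                }
            )
            labels.append(ci)
            t += 1
    df = pd.DataFrame(rows)
    model = ClusterModel(
        k=len(anchors),
        centroids=np.asarray(anchors, dtype=float),
        labels=pd.Series(labels, index=df.index),
        home_cluster=night_anchor,
    )
    return df, model


@pytest.fixture
def helsinki_tz_records() -> pd.DataFrame:
    return pd.DataFrame({"timestamp": [0], "timezone": ["Europe/Helsinki"]})
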