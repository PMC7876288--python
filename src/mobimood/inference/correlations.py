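"""Spearman correlations with cluster-wise Holm adjustment, and ICC.

Feature-outcome correlations are Spearman rank correlations (Pearson on
mid-ranks, average ties; p from the t approximation). The Holm step-down
adjustment is applied separately within each feature cluster x outcome
family -- adjusting only within clusters keeps the exploratory screen
from over-correcting across unrelated sensor families.

The intraclass correlation ICC(1,1) comes from one-way random-effects
ANOVA variance components and quantifies how much outcome variance sits
between participants; values above ~0.05 motivate multilevel modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    # step-down: running maximum of (m - j) * p_(j), then cap at 1
    scaled = (m - np.arange(m)) * p[order]
    adj_sorted = np.maximum.accumulate(scaled)
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    outcome: str
    cluster: str
    n: int
    rho: float | None
    p_raw: float | None
    p_adjusted: float | None
    reason: str | None = None


def spearman_with_holm(
    table: pd.DataFrame,
    cluster_map: dict[str, tuple[str, ...]],
    outcomes: tuple[str, ...],
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Feature-outcome Spearman correlations, Holm-adjusted per cluster.

    ``cluster_map`` maps cluster labels (GPS, usage, wearable, EMA) to
    feature column names. Pairs with fewer than ``min_pairs`` complete
    rows are left undefined and excluded from their adjustment family.
    """
    rows: list[CorrelationResult] = []
    for cluster, feats in cluster_map.items():
        for outcome in outcomes:
            family: list[int] = []
            for f in feats:
                sub = table[[f, outcome]].dropna()
                if len(sub) < min_pairs:
                    rows.append(CorrelationResult(f, outcome, cluster, len(sub), None, None, None, "insufficient_pairs"))
                    continue
                rho, p = stats.spearmanr(sub[f], sub[outcome])
                family.append(len(rows))
                rows.append(CorrelationResult(f, outcome, cluster, len(sub), float(rho), float(p), None))
            if family:
                adj = holm_adjust(np.array([rows[i].p_raw for i in family]))
                for i, a in zip(family, adj):
                    r = rows[i]
                    rows[i] = CorrelationResult(r.feature, r.outcome, r.cluster, r.n, r.rho, r.p_raw, float(a))
    return pd.DataFrame([r.__dict__ for r in rows])


def icc(values: np.ndarray, groups: np.ndarray) -> float | None:
    """ICC(1,1) from one-way random-effects variance components.

    Between-group variance is estimated by the ANOVA method-of-moments
    estimator with the unbalanced-design average group size n0, floored
    at 0. Returns None for degenerate groupings (fewer than 2 groups, or
    no within-group replication).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    ok = np.isfinite(v)
    v, g = v[ok], g[ok]
    labels, inverse, counts = np.unique(g, return_inverse=True, return_counts=True)
    J, N = len(labels), len(v)
    if J < 2 or N == J:
        return None
    grand = v.mean()
    group_means = np.bincount(inverse, weights=v) / counts
    ssb = float(np.sum(counts * (group_means - grand) ** 2))
    ssw = float(np.sum((v - group_means[inverse]) ** 2))
    msb = ssb / (J - 1)
    msw = ssw / (N - J)
    n0 = (N - np.sum(counts**2) / N) / (J - 1)
    sigma_b = max((msb - msw) / n0, 0.0)
    denom = sigma_b + msw
    if denom <= 0:
        return None
    return float(sigma_b / denom)
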