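"""Rubin pooling of multiply-imputed fits and the pooled likelihood-ratio test.

Fixed effects from the m per-imputation fits are combined with Rubin's
rules: pooled estimate = mean, total variance T = W + (1 + 1/m) B with W
the mean within-imputation variance and B the between-imputation variance
of the estimates; t-tests use Barnard-Rubin adjusted degrees of freedom.

Nested model comparison uses the D3 statistic (Meng-Rubin): the mean
likelihood-ratio statistic across imputations is recalibrated by
re-evaluating both models' likelihoods at their pooled parameter values
on every completed dataset, yielding an F reference with df1 = number of
constrained parameters. With a single complete dataset (m = 1) the
statistic reduces exactly to the classical chi-square likelihood-ratio
test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mlm import MlmFit


@dataclass
class PooledFit:
    """Rubin-pooled fixed effects over m imputations."""

    outcome: str
    predictors: tuple[str, ...]
    m: int
    estimates: pd.Series
    se: pd.Series
    within: pd.Series
    between: pd.Series
    df: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    mean_loglike: float
    boundary_any: bool = False

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.estimates,
                "se": self.se,
                "t": self.tvalues,
                "df": self.df,
                "p": self.pvalues,
            }
        )


@dataclass
class PooledLrt:
    """D3-pooled likelihood-ratio comparison of two nested fits."""

    f_stat: float
    df1: int
    df2: float
    pvalue: float
    m: int


def pool_rubin(fits: list[MlmFit]) -> PooledFit:
    """Combine per-imputation fixed effects with Rubin's rules."""
    m = len(fits)
    if m == 0:
        raise ValueError("need at least one fit to pool")
    names = list(fits[0].params.index)
    for f in fits[1:]:
        if list(f.params.index) != names or f.outcome != fits[0].outcome:
            raise ValueError("all fits must share the same model formula")

    q = np.vstack([f.params.to_numpy() for f in fits])
    u = np.vstack([f.se.to_numpy() ** 2 for f in fits])
    qbar = q.mean(axis=0)
    W = u.mean(axis=0)
    B = q.var(axis=0, ddof=1) if m > 1 else np.zeros_like(qbar)
    T = W + (1.0 + 1.0 / m) * B
    se = np.sqrt(T)

    dfcom = np.vstack([f.df.to_numpy() for f in fits]).mean(axis=0)
    df = np.empty_like(qbar)
    for i in range(len(qbar)):
        df[i] = _barnard_rubin_df(m, W[i], B[i], T[i], dfcom[i])
    tvals = qbar / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    return PooledFit(
        outcome=fits[0].outcome,
        predictors=fits[0].predictors,
        m=m,
        estimates=pd.Series(qbar, index=names),
        se=pd.Series(se, index=names),
        within=pd.Series(W, index=names),
        between=pd.Series(B, index=names),
        df=pd.Series(df, index=names),
        tvalues=pd.Series(tvals, index=names),
        pvalues=pd.Series(pvals, index=names),
        mean_loglike=float(np.mean([f.loglike for f in fits])),
        boundary_any=any(f.boundary for f in fits),
    )


def _barnard_rubin_df(m: int, W: float, B: float, T: float, dfcom: float) -> float:
    if m == 1 or B <= 0 or T <= 0:
        return float(dfcom)
    lam = (1.0 + 1.0 / m) * B / T
    lam = min(max(lam, 1e-12), 1.0 - 1e-12)
    df_old = (m - 1) / lam**2
    df_obs = (dfcom + 1.0) / (dfcom + 3.0) * dfcom * (1.0 - lam)
    return float(1.0 / (1.0 / df_old + 1.0 / df_obs))


def lrt_pooled(null_fits: list[MlmFit], alt_fits: list[MlmFit]) -> PooledLrt:
    """D3 pooled likelihood-ratio test of nested ML mixed-model fits.

    The null model's predictors must be a subset of the alternative's;
    df1 is the number of constrained fixed effects. Each fit must carry
    its design (``data``/``theta``) so likelihoods can be re-evaluated at
    the pooled parameters.
    """
    m = len(null_fits)
    if m != len(alt_fits) or m == 0:
        raise ValueError("need matching non-empty fit lists")
    p_null = set(null_fits[0].predictors)
    p_alt = set(alt_fits[0].predictors)
    if not p_null <= p_alt:
        raise ValueError(
            f"models are not nested: null {sorted(p_null)} vs alternative {sorted(p_alt)}"
        )
    if p_null == p_alt:
        # self-comparison: no constraint tested, evidence is null by definition
        return PooledLrt(f_stat=0.0, df1=1, df2=float("inf"), pvalue=1.0, m=m)
    k = len(p_alt) - len(p_null)

    d_per = np.array([2.0 * (a.loglike - n.loglike) for n, a in zip(null_fits, alt_fits)])
    dbar = float(d_per.mean())
    if m == 1:
        d = max(dbar, 0.0)
        return PooledLrt(f_stat=d / k, df1=k, df2=float("inf"), pvalue=float(stats.chi2.sf(d, k)), m=1)

    beta_null = np.vstack([f.params.to_numpy() for f in null_fits]).mean(axis=0)
    beta_alt = np.vstack([f.params.to_numpy() for f in alt_fits]).mean(axis=0)
    theta_null = np.vstack([f.theta for f in null_fits]).mean(axis=0)
    theta_alt = np.vstack([f.theta for f in alt_fits]).mean(axis=0)
    dtilde = float(
        np.mean(
            [
                2.0
                * (
                    a.data.marginal_loglike(beta_alt, theta_alt)
                    - n.data.marginal_loglike(beta_null, theta_null)
                )
                for n, a in zip(null_fits, alt_fits)
            ]
        )
    )
    dtilde = max(dtilde, 0.0)
    r3 = max((m + 1.0) / (k * (m - 1.0)) * (dbar - dtilde), 0.0)
    f_stat = dtilde / (k * (1.0 + r3))
    km = k * (m - 1.0)
    if r3 <= 0:
        df2 = float("inf")
    elif km > 4:
        df2 = 4.0 + (km - 4.0) * (1.0 + (1.0 - 2.0 / km) / r3) ** 2
    else:
        df2 = km * (1.0 + 1.0 / k) * (1.0 + 1.0 / r3) ** 2 / 2.0
    if np.isinf(df2):
        pvalue = float(stats.chi2.sf(k * f_stat, k))
    else:
        pvalue = float(stats.f.sf(f_stat, k, df2))
    return PooledLrt(f_stat=float(f_stat), df1=k, df2=df2, pvalue=pvalue, m=m)
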