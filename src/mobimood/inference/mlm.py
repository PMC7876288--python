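"""Linear mixed models with random intercepts and random slopes.

Models are fitted by maximum likelihood through statsmodels' MixedLM with
uncorrelated random effects (a per-participant random intercept plus an
independent variance component per requested random slope). With at most
a handful of observations per participant a full random-effects
covariance is not identifiable, so uncorrelated effects are the default
and a fit whose slope variance collapses to the boundary is refitted as
random-intercept-only and flagged.

Fixed-effect degrees of freedom use the Satterthwaite approximation,
computed from this module's own marginal log-likelihood evaluator via
numeric derivatives of the fixed-effect covariance with respect to the
variance parameters. The same evaluator scores the likelihood at pooled
parameter values for the multiply-imputed likelihood-ratio test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec

_LOG2PI = np.log(2.0 * np.pi)


class LmmData:
    """Per-group design arrays for a mixed model y = X b + Z u + e.

    Z columns are (intercept, slope variables...) with independent
    variances; theta = (var_intercept, var_slope_1, ..., var_residual).
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray, Z: np.ndarray):
        order = np.argsort(groups, kind="stable")
        y, X, Z, groups = y[order], X[order], Z[order], groups[order]
        self.group_labels, starts = np.unique(groups, return_index=True)
        bounds = np.append(np.sort(starts), len(y))
        self.blocks = [
            (y[a:b], X[a:b], Z[a:b]) for a, b in zip(bounds[:-1], bounds[1:])
        ]
        self.n_obs = len(y)
        self.n_fe = X.shape[1]
        self.n_re = Z.shape[1]
        sizes = np.diff(bounds)
        self._balanced = bool(len(sizes) and (sizes == sizes[0]).all())
        if self._balanced:
            n = int(sizes[0])
            J = len(self.blocks)
            self._Y3 = y.reshape(J, n)
            self._X3 = X.reshape(J, n, self.n_fe)
            self._Z3 = Z.reshape(J, n, self.n_re)

    def _batched_V(self, theta: np.ndarray) -> np.ndarray:
        d = np.asarray(theta[:-1], dtype=float)
        s2 = float(theta[-1])
        n = self._Y3.shape[1]
        return s2 * np.eye(n) + np.einsum("jnk,k,jmk->jnm", self._Z3, d, self._Z3)

    def marginal_loglike(self, beta: np.ndarray, theta: np.ndarray) -> float:
        """Exact ML marginal log-likelihood at fixed beta and theta."""
        d = np.asarray(theta[:-1], dtype=float)
        s2 = float(theta[-1])
        if self._balanced:
            V = self._batched_V(theta)
            r = self._Y3 - self._X3 @ beta
            sign, logdet = np.linalg.slogdet(V)
            if (sign <= 0).any():
                return -np.inf
            quad = np.einsum("jn,jn->", r, np.linalg.solve(V, r[..., None])[..., 0])
            return float(-0.5 * (self.n_obs * _LOG2PI + logdet.sum() + quad))
        ll = 0.0
        for yj, Xj, Zj in self.blocks:
            V = s2 * np.eye(len(yj)) + (Zj * d) @ Zj.T
            r = yj - Xj @ beta
            sign, logdet = np.linalg.slogdet(V)
            if sign <= 0:
                return -np.inf
            ll += -0.5 * (len(yj) * _LOG2PI + logdet + r @ np.linalg.solve(V, r))
        return float(ll)

    def gls(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """GLS fixed effects and their covariance at given theta."""
        d = np.asarray(theta[:-1], dtype=float)
        s2 = float(theta[-1])
        if self._balanced:
            V = self._batched_V(theta)
            Vi_X = np.linalg.solve(V, self._X3)
            XtVX = np.einsum("jnp,jnq->pq", self._X3, Vi_X)
            XtVy = np.einsum("jnp,jn->p", Vi_X, self._Y3)
            cov = np.linalg.inv(XtVX)
            return cov @ XtVy, cov
        XtVX = np.zeros((self.n_fe, self.n_fe))
        XtVy = np.zeros(self.n_fe)
        for yj, Xj, Zj in self.blocks:
            V = s2 * np.eye(len(yj)) + (Zj * d) @ Zj.T
            Vi_X = np.linalg.solve(V, Xj)
            XtVX += Xj.T @ Vi_X
            XtVy += Vi_X.T @ yj
        cov = np.linalg.inv(XtVX)
        return cov @ XtVy, cov

    def profile_loglike(self, theta: np.ndarray) -> float:
        beta, _ = self.gls(theta)
        return self.marginal_loglike(beta, theta)


@dataclass
class MlmFit:
    """An ML mixed-model fit with Satterthwaite fixed-effect inference."""

    outcome: str
    predictors: tuple[str, ...]
    random_slopes: tuple[str, ...]
    params: pd.Series
    se: pd.Series
    tvalues: pd.Series
    df: pd.Series
    pvalues: pd.Series
    vc: dict[str, float]  # variance components incl. "intercept" and "residual"
    loglike: float
    n_obs: int
    n_groups: int
    converged: bool
    boundary: bool = False
    data: LmmData | None = field(default=None, repr=False)
    theta: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_params(self) -> int:
        return len(self.params) + len(self.vc)

    def formula(self) -> str:
        rhs = " + ".join(self.predictors) if self.predictors else "1"
        re = ", ".join(("intercept",) + self.random_slopes)
        return f"{self.outcome} ~ {rhs} + ({re} | participant)"


_BOUNDARY_TOL = 1e-6


def fit_mlm(
    table: pd.DataFrame,
    outcome: str,
    predictors: tuple[str, ...] | list[str] = (),
    random_slopes: tuple[str, ...] | list[str] | None = None,
    group_col: str = "participant",
    min_groups: int = 10,
) -> MlmFit:
    """Fit outcome ~ predictors with random intercept and random slopes by ML.

    ``random_slopes`` defaults to all predictors. Rows with a missing
    value in any used column are dropped (missingness is handled upstream
    by multiple imputation). If a random-slope variance collapses to the
    zero boundary the model is refitted random-intercept-only and the
    result flagged ``boundary``.
    """
    predictors = tuple(predictors)
    random_slopes = tuple(random_slopes) if random_slopes is not None else predictors
    if not set(random_slopes) <= set(predictors):
        raise ValueError("random slopes must be a subset of the predictors")
    cols = [group_col, outcome, *predictors]
    data = table[cols].dropna().reset_index(drop=True)
    n_groups = data[group_col].nunique()
    if n_groups < min_groups:
        raise ValueError(f"need >= {min_groups} participants, got {n_groups}")

    fit = _fit_once(data, outcome, predictors, random_slopes, group_col)
    if random_slopes and fit.boundary:
        refit = _fit_once(data, outcome, predictors, (), group_col)
        refit.boundary = True
        return refit
    return fit


def _fit_once(data, outcome, predictors, random_slopes, group_col) -> MlmFit:
    # statsmodels splits groups in sorted order; sort once so the VCSpec
    # group blocks line up
    data = data.sort_values(group_col, kind="mergesort").reset_index(drop=True)
    y = data[outcome].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(data))] + [data[p].to_numpy(dtype=float) for p in predictors])
    Z = np.column_stack([np.ones(len(data))] + [data[p].to_numpy(dtype=float) for p in random_slopes])
    groups = data[group_col].to_numpy()
    fe_names = ["Intercept", *predictors]

    lmm = LmmData(y, X, groups, Z)

    exog_vc = None
    if random_slopes:
        labels, starts = np.unique(groups, return_index=True)
        bounds = np.append(np.sort(starts), len(y))
        mats, colnames = [], []
        for p in random_slopes:
            col = data[p].to_numpy(dtype=float)[:, None]
            mats.append([col[a:b] for a, b in zip(bounds[:-1], bounds[1:])])
            colnames.append([[p]] * len(labels))
        exog_vc = VCSpec([f"slope_{p}" for p in random_slopes], colnames, mats)
    model = MixedLM(y, X, groups, exog_re=np.ones((len(y), 1)), exog_vc=exog_vc)
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell"):
            try:
                cand = model.fit(reml=False, method=method, maxiter=2000)
            except (np.linalg.LinAlgError, ValueError):
                continue
            res = cand
            if res.converged:
                break

    if res is not None:
        v_int = float(np.asarray(res.cov_re)[0, 0])
        v_slopes = {p: float(res.vcomp[i]) for i, p in enumerate(random_slopes)}
        s2 = float(res.scale)
        theta = np.array([v_int, *[v_slopes[p] for p in random_slopes], s2])
        est = np.asarray(res.fe_params, dtype=float)  # same column order as X
        llf = float(res.llf)
        converged = bool(res.converged)
    else:
        # degenerate designs can break statsmodels' post-fit covariance step;
        # optimize this module's own profiled ML likelihood instead
        theta, llf, converged = _native_ml(lmm)
        est, _ = lmm.gls(np.maximum(theta, 1e-10))
        v_int = float(theta[0])
        v_slopes = {p: float(theta[1 + i]) for i, p in enumerate(random_slopes)}
        s2 = float(theta[-1])
    # a slope variance that is negligible against the total variance is a
    # boundary fit in all but name: the parameter is unidentified and its
    # flat likelihood direction would poison Satterthwaite df
    total_var = v_int + s2 + sum(v_slopes.values())
    boundary = any(v < max(_BOUNDARY_TOL, 0.01 * total_var) for v in v_slopes.values())
    vc = {"intercept": v_int, **{f"slope_{p}": v for p, v in v_slopes.items()}, "residual": s2}
    _, cov_beta = lmm.gls(np.maximum(theta, 1e-10))
    se = np.sqrt(np.diag(cov_beta))
    df = satterthwaite_df(lmm, theta)
    tvals = est / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    return MlmFit(
        outcome=outcome,
        predictors=predictors,
        random_slopes=random_slopes,
        params=pd.Series(est, index=fe_names),
        se=pd.Series(se, index=fe_names),
        tvalues=pd.Series(tvals, index=fe_names),
        df=pd.Series(df, index=fe_names),
        pvalues=pd.Series(pvals, index=fe_names),
        vc=vc,
        loglike=llf,
        n_obs=len(y),
        n_groups=len(lmm.blocks),
        converged=converged,
        boundary=boundary,
        data=lmm,
        theta=theta,
    )


def _native_ml(lmm: LmmData) -> tuple[np.ndarray, float, bool]:
    """ML variance-parameter fit by direct optimization of the profiled
    likelihood; used only when statsmodels' optimizer errors out."""
    from scipy import optimize

    var0 = 1.0
    if lmm.n_obs > lmm.n_fe:
        beta0, _ = lmm.gls(np.array([0.0] * (lmm.n_re) + [1.0]))
        resid = np.concatenate([yj - Xj @ beta0 for yj, Xj, _ in lmm.blocks])
        var0 = max(float(resid.var()), 1e-8)
    x0 = np.array([var0 / 2] * lmm.n_re + [var0 / 2])
    res = optimize.minimize(
        lambda t: -lmm.profile_loglike(np.maximum(t, 1e-10)),
        x0,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * lmm.n_re + [(1e-10, None)],
    )
    theta = np.maximum(res.x, 0.0)
    return theta, float(-res.fun), bool(res.success)


def _fallback_df(lmm: LmmData) -> float:
    return float(max(lmm.n_obs - lmm.n_fe - (len(lmm.blocks) - 1), 1))


def satterthwaite_df(lmm: LmmData, theta: np.ndarray) -> np.ndarray:
    """Satterthwaite degrees of freedom for each fixed effect.

    df_c = 2 f^2 / (g' A g) with f = Var(beta_c | theta), g its gradient in
    theta (central differences) and A the inverse observed information of
    the profiled ML log-likelihood. Falls back to a between-within count
    when the information matrix is not usable.
    """
    theta = np.asarray(theta, dtype=float)
    nt = len(theta)
    h = np.maximum(1e-4, 1e-3 * np.abs(theta))

    def cov_diag(t):
        t = np.maximum(t, 0.0)
        if t[-1] <= 0:
            t = t.copy()
            t[-1] = max(t[-1], 1e-10)
        _, cov = lmm.gls(t)
        return np.diag(cov).copy()

    f0 = cov_diag(theta)
    grads = np.zeros((nt, lmm.n_fe))
    for k in range(nt):
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h[k]
        tm[k] -= h[k]
        grads[k] = (cov_diag(tp) - cov_diag(tm)) / (2 * h[k])

    H = np.zeros((nt, nt))
    ll0 = lmm.profile_loglike(np.maximum(theta, 1e-10))
    for k in range(nt):
        for l in range(k, nt):
            tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
            tpp[k] += h[k]; tpp[l] += h[l]
            tpm[k] += h[k]; tpm[l] -= h[l]
            tmp[k] -= h[k]; tmp[l] += h[l]
            tmm[k] -= h[k]; tmm[l] -= h[l]
            if k == l:
                val = (lmm.profile_loglike(np.maximum(tpp, 1e-10)) - 2 * ll0 + lmm.profile_loglike(np.maximum(tmm, 1e-10))) / (h[k] ** 2)
            else:
                val = (
                    lmm.profile_loglike(np.maximum(tpp, 1e-10))
                    - lmm.profile_loglike(np.maximum(tpm, 1e-10))
                    - lmm.profile_loglike(np.maximum(tmp, 1e-10))
                    + lmm.profile_loglike(np.maximum(tmm, 1e-10))
                ) / (4 * h[k] * h[l])
            H[k, l] = H[l, k] = val

    fallback = _fallback_df(lmm)
    try:
        A = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return np.full(lmm.n_fe, fallback)
    df = np.empty(lmm.n_fe)
    for c in range(lmm.n_fe):
        g = grads[:, c]
        denom = float(g @ A @ g)
        if not np.isfinite(denom) or denom <= 0:
            df[c] = fallback
        else:
            df[c] = 2.0 * f0[c] ** 2 / denom
    # df can never exceed the residual count of the fixed-effects-only model
    return np.clip(df, 1.0, max(lmm.n_obs - lmm.n_fe, 1.0))
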