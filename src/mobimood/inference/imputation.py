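"""Multilevel predictive-mean-matching multiple imputation.

Chained equations over the incomplete columns of the participant x window
model table. Each incomplete column is imputed by predictive mean
matching against a two-level predictor: for every other variable the
regressor set contains the participant mean (between-person part) and the
within-person deviation from that mean, plus the participant's
leave-one-out mean of the target's observed values, which carries the
person random intercept into the prediction -- a two-level surrogate that
lets the imputation model respect the nesting of windows in participants.

Per sweep and column: a Bayesian linear regression draw (beta from its
posterior normal, sigma^2 from the scaled inverse chi-square) predicts the
missing cases; each missing case then receives the *observed* value of a
donor drawn at random from the ``donors`` observed cases whose (non-drawn)
predictions are closest. m independent chains of ``iterations`` sweeps
yield m completed tables; chain means/SDs of the imputed values are kept
for convergence inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_RIDGE = 1e-6


@dataclass
class ImputationSet:
    """m completed tables plus per-chain convergence statistics."""

    tables: list[pd.DataFrame]
    chain_stats: pd.DataFrame  # columns: chain, iteration, column, mean, sd
    seed: int
    imputed_columns: tuple[str, ...] = ()

    @property
    def m(self) -> int:
        return len(self.tables)


def impute_mpmm(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    predictors: list[str] | None = None,
    m: int = 20,
    iterations: int = 15,
    donors: int = 5,
    seed: int = 0,
    group_col: str = "participant",
) -> ImputationSet:
    """Impute the table's missing values with multilevel PMM.

    ``columns`` defaults to every numeric column containing missing
    values; ``predictors`` (the imputation model's variables, including
    MAR-related auxiliaries) defaults to all numeric columns except the
    window index. A column with no observed values aborts.
    """
    numeric = [c for c in table.columns if c != group_col and pd.api.types.is_numeric_dtype(table[c])]
    predictors = list(predictors) if predictors is not None else [c for c in numeric if c != "window"]
    if columns is None:
        columns = [c for c in predictors if table[c].isna().any()]
    for c in columns:
        if c not in predictors:
            raise ValueError(f"imputed column {c!r} must be part of the imputation model")
        if table[c].notna().sum() == 0:
            raise ValueError(f"column {c!r} has no observed values to impute from")

    empty_stats = pd.DataFrame(columns=["chain", "iteration", "column", "mean", "sd"])
    if not columns:
        return ImputationSet([table.copy() for _ in range(m)], empty_stats, seed, ())

    base = table[predictors].to_numpy(dtype=float)
    codes, _ = pd.factorize(table[group_col], sort=True)
    n_groups = codes.max() + 1
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    col_idx = {c: predictors.index(c) for c in columns}
    obs_masks = {c: table[c].notna().to_numpy() for c in columns}

    root = np.random.SeedSequence(seed)
    tables: list[pd.DataFrame] = []
    stats_rows: list[dict] = []
    for chain, child in enumerate(root.spawn(m)):
        rng = np.random.default_rng(child)
        work = base.copy()
        for c in columns:
            miss = ~obs_masks[c]
            obs_vals = base[obs_masks[c], col_idx[c]]
            work[miss, col_idx[c]] = rng.choice(obs_vals, size=miss.sum(), replace=True)
        for it in range(iterations):
            for c in columns:
                j = col_idx[c]
                _impute_column(work, j, obs_masks[c], codes, counts, donors, rng)
                imputed = work[~obs_masks[c], j]
                stats_rows.append(
                    {
                        "chain": chain,
                        "iteration": it,
                        "column": c,
                        "mean": float(imputed.mean()),
                        "sd": float(imputed.std()),
                    }
                )
        filled = table.copy()
        for c in columns:
            filled[c] = work[:, col_idx[c]]
        tables.append(filled)
    return ImputationSet(tables, pd.DataFrame(stats_rows), seed, tuple(columns))


def _impute_column(
    work: np.ndarray,
    j: int,
    obs: np.ndarray,
    codes: np.ndarray,
    counts: np.ndarray,
    donors: int,
    rng: np.random.Generator,
) -> None:
    # two-level regressors: intercept + (participant mean, within deviation)
    # of every other variable + the participant's leave-one-out mean of the
    # *observed* target values (the random-intercept carrier: a person's
    # other windows are the best predictor of their missing one)
    others = np.delete(np.arange(work.shape[1]), j)
    M = work[:, others]
    sums = np.zeros((len(counts), M.shape[1]))
    np.add.at(sums, codes, M)
    row_means = sums[codes] / counts[codes][:, None]

    yfull = work[:, j]
    obs_f = obs.astype(float)
    ysum = np.bincount(codes, weights=yfull * obs_f, minlength=len(counts))
    ycnt = np.bincount(codes, weights=obs_f, minlength=len(counts))
    loo_sum = ysum[codes] - yfull * obs_f
    loo_cnt = ycnt[codes] - obs_f
    grand = yfull[obs].mean() if obs.any() else 0.0
    loo_mean = np.where(loo_cnt > 0, loo_sum / np.maximum(loo_cnt, 1.0), grand)

    R = np.concatenate(
        [np.ones((len(work), 1)), loo_mean[:, None], row_means, M - row_means], axis=1
    )

    y = work[:, j]
    Ro, yo = R[obs], y[obs]
    Rm = R[~obs]
    n, p = Ro.shape

    gram = Ro.T @ Ro + _RIDGE * np.eye(p)
    gram_inv = np.linalg.inv(gram)
    beta_hat = gram_inv @ Ro.T @ yo
    resid = yo - Ro @ beta_hat
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    chol = np.linalg.cholesky(gram_inv * sigma2 + _RIDGE * np.eye(p))
    beta_draw = beta_hat + chol @ rng.standard_normal(p)

    pred_obs = Ro @ beta_hat  # type-1 matching: obs by beta_hat, mis by the draw
    pred_mis = Rm @ beta_draw
    k = min(donors, n)
    # donor pool: k observed cases with the closest predictions
    d = np.abs(pred_obs[None, :] - pred_mis[:, None])
    pools = np.argpartition(d, k - 1, axis=1)[:, :k]
    picks = pools[np.arange(len(pred_mis)), rng.integers(0, k, len(pred_mis))]
    work[~obs, j] = yo[picks]
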