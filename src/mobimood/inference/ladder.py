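"""Single-predictor screening and the combined-model ladder.

The modelling strategy proceeds in two steps. First, one mixed model per
feature ("single-predictor models") screens each of the 16 features
against the outcome; a feature enters later stages only when its pooled
two-sided p < 0.05. Second, a ladder of increasingly rich models is
compared by pooled likelihood-ratio tests:

  baseline (intercept only) -> EMA model -> GPS model ->
  extended digital phenotyping (GPS + wearable) ->
  combined (EMA + GPS + wearable)

Each stage keeps only its clusters' screened-in predictors; stages with
no surviving predictor are reported as "No predictors identified" rather
than silently skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ..windowing import FEATURE_CLUSTERS
from .mlm import MlmFit, fit_mlm
from .pooling import PooledFit, PooledLrt, lrt_pooled, pool_rubin

ALPHA = 0.05

#: ladder stage -> (clusters contributing predictors, parent stage compared against)
LADDER_STAGES: tuple[tuple[str, tuple[str, ...], str | None], ...] = (
    ("baseline", (), None),
    ("EMA", ("EMA",), "baseline"),
    ("GPS", ("GPS",), "baseline"),
    ("extended", ("GPS", "wearable"), "GPS"),
    ("combined", ("EMA", "GPS", "wearable"), "extended"),
)


@dataclass
class LadderStage:
    name: str
    predictors: tuple[str, ...]
    pooled: PooledFit | None  # None when the stage has no predictors and no fit
    comparison: PooledLrt | None
    compared_against: str | None
    note: str | None = None


@dataclass
class ModelLadder:
    outcome: str
    single_predictor: dict[str, PooledFit]
    stages: list[LadderStage] = field(default_factory=list)

    def stage(self, name: str) -> LadderStage:
        return next(s for s in self.stages if s.name == name)

    def significant_features(self) -> dict[str, list[str]]:
        """Screened-in features per cluster from the single-predictor fits."""
        out: dict[str, list[str]] = {}
        for cluster, feats in FEATURE_CLUSTERS.items():
            out[cluster] = [
                f
                for f in feats
                if f in self.single_predictor
                and float(self.single_predictor[f].pvalues.get(f, 1.0)) < ALPHA
            ]
        return out


def _fit_all(tables: list[pd.DataFrame], outcome: str, predictors: tuple[str, ...]) -> list[MlmFit]:
    fits = [fit_mlm(t, outcome, predictors) for t in tables]
    # a boundary fallback in any imputation changes the random structure;
    # keep the structure identical across imputations so pooling is valid
    if predictors and any(f.random_slopes != fits[0].random_slopes or f.boundary for f in fits):
        fits = [fit_mlm(t, outcome, predictors, random_slopes=()) for t in tables]
        for f in fits:
            f.boundary = True
    return fits


def single_predictor_fits(
    tables: list[pd.DataFrame], outcome: str, features: tuple[str, ...]
) -> dict[str, PooledFit]:
    """One pooled random-intercept/random-slope model per feature."""
    out: dict[str, PooledFit] = {}
    for f in features:
        if not all(f in t.columns and t[f].notna().any() for t in tables):
            continue
        out[f] = pool_rubin(_fit_all(tables, outcome, (f,)))
    return out


def build_model_ladder(
    tables: list[pd.DataFrame],
    outcome: str,
    features: tuple[str, ...] | None = None,
) -> ModelLadder:
    """Screen single predictors, then build and compare the model ladder."""
    if features is None:
        features = tuple(f for fs in FEATURE_CLUSTERS.values() for f in fs)
    ladder = ModelLadder(outcome=outcome, single_predictor=single_predictor_fits(tables, outcome, features))
    sig = ladder.significant_features()

    fits_by_stage: dict[str, list[MlmFit] | None] = {}
    for name, clusters, parent in LADDER_STAGES:
        predictors = tuple(f for c in clusters for f in sig.get(c, []))
        note = None
        if name != "baseline" and not predictors:
            fits_by_stage[name] = None
            ladder.stages.append(LadderStage(name, (), None, None, parent, "No predictors identified"))
            continue
        fits = _fit_all(tables, outcome, predictors)
        fits_by_stage[name] = fits
        pooled = pool_rubin(fits)

        comparison = None
        compared_against = parent
        if parent is not None:
            # fall back past empty parents to the nearest fitted ancestor
            anc = parent
            while anc is not None and fits_by_stage.get(anc) is None:
                anc = next(p for n, _, p in LADDER_STAGES if n == anc)
            compared_against = anc
            parent_fits = fits_by_stage.get(anc)
            if parent_fits is not None:
                parent_preds = set(parent_fits[0].predictors)
                if parent_preds < set(predictors):
                    comparison = lrt_pooled(parent_fits, fits)
                elif parent_preds == set(predictors):
                    note = "identical to compared stage"
                else:
                    note = "not nested with compared stage"
        ladder.stages.append(LadderStage(name, predictors, pooled, comparison, compared_against, note))
    return ladder


def ladder_report(ladder: ModelLadder) -> str:
    """Human-readable comparison table in the combined-prediction layout."""
    lines = [f"Model comparison for the prediction of {ladder.outcome}", "=" * 60]
    header = f"{'':<18}{'Estimate':>9}{'SE':>7}{'t':>8}{'df':>7}{'p':>8}"
    for stage in ladder.stages:
        title = {
            "baseline": "Baseline model",
            "EMA": "EMA model",
            "GPS": "GPS model",
            "extended": "Extended digital phenotyping model: GPS and wearable data",
            "combined": "Combined model: EMA and digital phenotyping",
        }[stage.name]
        lines.append("")
        lines.append(title)
        if stage.pooled is None:
            lines.append("  No predictors identified")
            continue
        lines.append(header)
        for name in stage.pooled.estimates.index:
            est = stage.pooled.estimates[name]
            se = stage.pooled.se[name]
            t = stage.pooled.tvalues[name]
            df = stage.pooled.df[name]
            p = stage.pooled.pvalues[name]
            lines.append(f"{name:<18}{est:>9.2f}{se:>7.2f}{t:>8.2f}{df:>7.0f}{p:>8.3f}")
        if stage.comparison is not None:
            c = stage.comparison
            df2 = "inf" if c.df2 == float("inf") else f"{c.df2:.0f}"
            lines.append(
                f"  LRT vs {stage.compared_against}: F = {c.f_stat:.2f}, "
                f"df = ({c.df1}, {df2}), p = {c.pvalue:.3f}"
            )
        elif stage.note:
            lines.append(f"  ({stage.note})")
    return "\n".join(lines)
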