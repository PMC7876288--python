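"""Pipeline orchestration: simulate -> extract -> analyze -> report.

Each stage reads and writes plain CSV/JSON artifacts so every
intermediate is inspectable; a run manifest records the configuration and
root seed. Per-stage seeds are derived from the root seed so a rerun with
the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import dass as dass_mod
from . import device_usage, gps_mobility, wearable_ema, windowing
from .inference import build_model_ladder, icc, impute_mpmm, spearman_with_holm
from .inference.ladder import ModelLadder
from .synthetic_cohort import CohortConfig, generate_cohort, write_cohort
from .windowing import FEATURE_CLUSTERS, FEATURES, OUTCOMES

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable thresholds of the whole pipeline, with study defaults."""

    n_participants: int = 10
    study_days: int = 30
    planted_betas: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    speed_threshold_kmh: float = 1.0
    accuracy_percentile: float = 80.0
    cluster_threshold_m: float = 500.0
    k_max: int = 20
    gap_threshold_min: float = 15.0
    min_coverage_days: int = 5
    m_imputations: int = 20
    imputation_iterations: int = 15
    donors: int = 5
    sampling_interval_s: float = 60.0
    homestay_tracked_denominator: bool = False
    min_groups: int = 10

    def __post_init__(self) -> None:
        for name in ("speed_threshold_kmh", "cluster_threshold_m", "gap_threshold_min", "sampling_interval_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def stage_simulate(cfg: PipelineConfig, outdir) -> dict:
    """Generate a synthetic cohort and write its AWARE-style tables."""
    cohort_cfg = CohortConfig(
        n_participants=cfg.n_participants,
        study_days=cfg.study_days,
        planted_betas=dict(cfg.planted_betas),
        seed=cfg.stage_seed("simulate"),
        sampling_interval_s=cfg.sampling_interval_s,
    )
    raw, truth = generate_cohort(cohort_cfg)
    paths = write_cohort(raw, truth, outdir)
    counts = {"participants": cfg.n_participants, "gps_rows": int(sum(len(df) for df in raw.gps.values()))}
    log.info("simulate: wrote %s", {k: str(v) for k, v in paths.items()})
    return counts


def _daily_features_for_participant(
    pid: str,
    gps: pd.DataFrame,
    tz: pd.DataFrame,
    screen: pd.DataFrame,
    wearable: pd.DataFrame,
    ema: pd.DataFrame,
    enrollment: date,
    cfg: PipelineConfig,
    accuracy_pool: np.ndarray,
) -> tuple[pd.DataFrame, dict]:
    ledger: dict[str, float] = {}
    days = {d: enrollment + timedelta(days=d - 1) for d in range(1, cfg.study_days + 1)}
    daily: dict[int, dict] = {d: {"participant": pid, "local_date": days[d]} for d in days}

    # --- GPS mobility ---
    if not gps.empty:
        loc = gps_mobility.localize(gps, tz)
        clean, led = gps_mobility.clean_trace(loc, cfg.accuracy_percentile, accuracy_pool)
        ledger.update({f"gps_{k}": v for k, v in led.items()})
        labeled = gps_mobility.label_states(clean, cfg.gap_threshold_min * 60.0, cfg.speed_threshold_kmh)
        for w, day_idx in windowing.WINDOWS.items():
            win_dates = {days[d] for d in day_idx if d in days}
            win = labeled[labeled["local_date"].isin(win_dates)]
            if win.empty:
                continue
            model = gps_mobility.cluster_stationary(
                win, cfg.cluster_threshold_m, cfg.k_max, seed=cfg.stage_seed(f"cluster:{pid}:{w}")
            )
            for d in day_idx:
                if d not in days:
                    continue
                feats = gps_mobility.extract_mobility_features(
                    labeled, model, [days[d]], cfg.homestay_tracked_denominator
                )
                day_samples = labeled[labeled["local_date"] == days[d]]
                if day_samples.empty:
                    continue
                for k, v in feats.as_dict().items():
                    daily[d][k] = v if v is not None else np.nan

    # --- phone usage ---
    if not screen.empty:
        ev = gps_mobility.localize(screen, tz)
        sessions = device_usage.sessionize(ev)
        for d in days:
            freq, dur = device_usage.daily_usage_features(sessions, ev, days[d])
            if freq > 0 or dur > 0:
                daily[d]["usage_frequency"] = float(freq)
                daily[d]["usage_time"] = float(dur)

    # --- wearable ---
    for rec in (wearable_ema.records_from_frame(wearable) if not wearable.empty else []):
        valid = wearable_ema.validate_wearable(rec)
        d = windowing.study_day(valid.date, enrollment)
        if d in days:
            for feat, attr in [("steps", "steps"), ("met", "met_avg"), ("tst", "tst"), ("sol", "sol"),
                               ("waso", "waso"), ("tib", "tib"), ("hrv", "hrv_rmssd")]:
                v = getattr(valid, attr)
                if v is not None:
                    daily[d][feat] = v

    # --- EMA mood ---
    if not ema.empty:
        ema_loc = gps_mobility.localize(ema, tz)
        for d in days:
            mood = wearable_ema.daily_mood(ema_loc, days[d])
            if mood is not None:
                daily[d]["valence"], daily[d]["arousal"] = mood

    df = pd.DataFrame(list(daily.values()))
    return df, ledger


def stage_extract(indir, outdir, cfg: PipelineConfig) -> dict:
    """Raw AWARE-style tables -> daily features -> standardized model table."""
    indir, outdir = Path(indir), Path(outdir)
    required = ["locations.csv", "screen.csv", "timezone.csv", "wearable.csv", "ema.csv", "dass.csv", "enrollment.csv"]
    missing = [f for f in required if not (indir / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"missing inputs {missing} in {indir}; run the simulate stage (or point --in at raw exports)"
        )
    loc = gps_mobility.read_aware_locations(indir / "locations.csv")
    scr = device_usage.read_aware_screen(indir / "screen.csv")
    tz = gps_mobility.read_aware_timezones(indir / "timezone.csv")
    wear = pd.read_csv(indir / "wearable.csv", parse_dates=["date"])
    wear["date"] = wear["date"].dt.date
    ema = pd.read_csv(indir / "ema.csv")
    dass_df = pd.read_csv(indir / "dass.csv")
    enr = pd.read_csv(indir / "enrollment.csv")
    enrollment = {r.participant: date.fromisoformat(r.enrollment_date) for r in enr.itertuples(index=False)}

    accuracy_pool = loc["accuracy"].to_numpy(dtype=float)  # pooled across all participants
    frames, ledgers = [], {}
    for pid in sorted(enrollment):
        df, led = _daily_features_for_participant(
            pid,
            loc[loc["device_id"] == pid].drop(columns=["device_id"]),
            tz[tz["device_id"] == pid].drop(columns=["device_id"]),
            scr[scr["device_id"] == pid].drop(columns=["device_id"]),
            wear[wear["participant"] == pid].drop(columns=["participant"]),
            ema[ema["participant"] == pid].drop(columns=["participant"]),
            enrollment[pid],
            cfg,
            accuracy_pool,
        )
        frames.append(df)
        ledgers[pid] = led
    daily = pd.concat(frames, ignore_index=True)
    daily, day_ledger = windowing.to_study_days(daily, enrollment, cfg.study_days)

    pooled = windowing.pool_windows(daily, FEATURES, cfg.min_coverage_days)

    scores = []
    for row in dass_df.itertuples(index=False):
        items = {i: getattr(row, f"item_{i}") for i in range(1, 22)}
        sub = dass_mod.score_dass(items)
        scores.append({"participant": row.participant, "assessment_point": row.assessment_point, **sub.as_dict()})
    scores_df = pd.DataFrame(scores)

    table = windowing.attach_outcomes(pooled, scores_df)
    table, std = windowing.standardize(table)

    outdir.mkdir(parents=True, exist_ok=True)
    daily.to_csv(outdir / "daily_features.csv", index=False)
    scores_df.to_csv(outdir / "dass_scores.csv", index=False)
    table.to_csv(outdir / "model_table.csv", index=False)
    (outdir / "standardization.json").write_text(json.dumps(
        {"params": std.params, "zero_sd_columns": std.zero_sd_columns}, indent=1))
    (outdir / "extract_ledger.json").write_text(json.dumps({"per_participant": ledgers, **day_ledger}, indent=1))
    return {"daily_rows": len(daily), "model_rows": len(table)}


def stage_analyze(indir, outdir, cfg: PipelineConfig) -> dict:
    """Correlations, ICC, multilevel imputation and the model ladders."""
    indir, outdir = Path(indir), Path(outdir)
    table_path = indir / "model_table.csv"
    if not table_path.exists():
        raise FileNotFoundError(f"{table_path} not found; run the extract stage first")
    table = pd.read_csv(table_path)
    outdir.mkdir(parents=True, exist_ok=True)

    corr = spearman_with_holm(table, FEATURE_CLUSTERS, OUTCOMES)
    corr.to_csv(outdir / "correlations.csv", index=False)

    iccs = {oc: icc(table[oc].to_numpy(), table["participant"].to_numpy()) for oc in OUTCOMES}
    (outdir / "icc.json").write_text(json.dumps(iccs, indent=1))

    imp = impute_mpmm(
        table,
        m=cfg.m_imputations,
        iterations=cfg.imputation_iterations,
        donors=cfg.donors,
        seed=cfg.stage_seed("impute"),
    )
    imp.chain_stats.to_csv(outdir / "imputation_chains.csv", index=False)

    ladders = {}
    for oc in OUTCOMES:
        ladder = build_model_ladder(imp.tables, oc)
        ladders[oc] = ladder
        (outdir / f"ladder_{oc}.json").write_text(json.dumps(ladder_to_dict(ladder), indent=1))
    return {"correlations": len(corr), "icc": iccs, "m": imp.m}


def ladder_to_dict(ladder: ModelLadder) -> dict:
    def pooled_dict(p):
        if p is None:
            return None
        return {
            "predictors": list(p.predictors),
            "estimates": p.estimates.to_dict(),
            "se": p.se.to_dict(),
            "t": p.tvalues.to_dict(),
            "df": p.df.to_dict(),
            "p": p.pvalues.to_dict(),
        }

    return {
        "outcome": ladder.outcome,
        "single_predictor": {
            f: {"estimate": float(p.estimates.get(f, np.nan)), "se": float(p.se.get(f, np.nan)),
                "df": float(p.df.get(f, np.nan)), "p": float(p.pvalues.get(f, np.nan))}
            for f, p in ladder.single_predictor.items()
        },
        "stages": [
            {
                "name": s.name,
                "predictors": list(s.predictors),
                "pooled": pooled_dict(s.pooled),
                "comparison": None if s.comparison is None else {
                    "F": s.comparison.f_stat, "df1": s.comparison.df1,
                    "df2": s.comparison.df2, "p": s.comparison.pvalue,
                },
                "compared_against": s.compared_against,
                "note": s.note,
            }
            for s in ladder.stages
        ],
    }


def render_report(analysis_dir) -> str:
    """Text report mirroring the correlation and model-comparison tables."""
    analysis_dir = Path(analysis_dir)
    lines = ["Digital phenotyping analysis report", "=" * 60, ""]

    icc_path = analysis_dir / "icc.json"
    if icc_path.exists():
        iccs = json.loads(icc_path.read_text())
        lines.append("Intraclass correlations (participant level):")
        for oc, v in iccs.items():
            lines.append(f"  {oc:<12} ICC = {v:.3f}" if v is not None else f"  {oc:<12} ICC undefined")
        lines.append("")

    corr = pd.read_csv(analysis_dir / "correlations.csv")
    lines.append("Correlations between sensor features and symptom severity")
    lines.append(f"{'feature':<22}{'outcome':<12}{'rho':>7}{'p':>8}{'p adj':>8}")
    for cluster in corr["cluster"].unique():
        lines.append(f"-- {cluster} features --")
        for r in corr[corr["cluster"] == cluster].itertuples(index=False):
            if r.rho is None or (isinstance(r.rho, float) and np.isnan(r.rho)):
                lines.append(f"{r.feature:<22}{r.outcome:<12}{'undefined':>23}")
            else:
                star = "*" if (r.p_adjusted is not None and r.p_adjusted < 0.05) else " "
                lines.append(f"{r.feature:<22}{r.outcome:<12}{r.rho:>7.2f}{r.p_raw:>8.3f}{r.p_adjusted:>7.3f}{star}")
    lines.append("")

    stage_titles = {
        "baseline": "Baseline model",
        "EMA": "EMA model",
        "GPS": "GPS model",
        "extended": "Extended digital phenotyping model: GPS and wearable data",
        "combined": "Combined model: EMA and digital phenotyping",
    }
    for oc in OUTCOMES:
        path = analysis_dir / f"ladder_{oc}.json"
        if not path.exists():
            continue
        d = json.loads(path.read_text())
        lines.append(f"Model comparison for the prediction of {oc}")
        lines.append("-" * 60)
        for s in d["stages"]:
            lines.append(stage_titles.get(s["name"], s["name"]))
            if s["pooled"] is None:
                lines.append("  No predictors identified")
                continue
            lines.append(f"  {'':<18}{'Estimate':>9}{'SE':>7}{'t':>8}{'df':>7}{'p':>8}")
            p = s["pooled"]
            for name in p["estimates"]:
                lines.append(
                    f"  {name:<18}{p['estimates'][name]:>9.2f}{p['se'][name]:>7.2f}"
                    f"{p['t'][name]:>8.2f}{p['df'][name]:>7.0f}{p['p'][name]:>8.3f}"
                )
            if s["comparison"] is not None:
                c = s["comparison"]
                df2 = "inf" if c["df2"] == float("inf") else f"{c['df2']:.0f}"
                lines.append(
                    f"  LRT vs {s['compared_against']}: F = {c['F']:.2f}, df = ({c['df1']}, {df2}), p = {c['p']:.3f}"
                )
        lines.append("")
    return "\n".join(lines)


def stage_report(indir, outdir) -> dict:
    indir, outdir = Path(indir), Path(outdir)
    if not (indir / "correlations.csv").exists():
        raise FileNotFoundError(f"{indir}/correlations.csv not found; run the analyze stage first")
    outdir.mkdir(parents=True, exist_ok=True)
    text = render_report(indir)
    (outdir / "report.txt").write_text(text)
    return {"report": str(outdir / "report.txt")}


def run_pipeline(cfg: PipelineConfig, workdir, stages: tuple[str, ...] = ("simulate", "extract", "analyze", "report")) -> dict:
    """Run the requested stages in order under one working directory."""
    workdir = Path(workdir)
    raw, feat, ana, rep = workdir / "raw", workdir / "features", workdir / "analysis", workdir / "report"
    results: dict[str, dict] = {}
    for stage in stages:
        log.info("running stage %s", stage)
        if stage == "simulate":
            results[stage] = stage_simulate(cfg, raw)
        elif stage == "extract":
            results[stage] = stage_extract(raw, feat, cfg)
        elif stage == "analyze":
            results[stage] = stage_analyze(feat, ana, cfg)
        elif stage == "report":
            results[stage] = stage_report(ana, rep)
        else:
            raise ValueError(f"unknown stage {stage!r}")
    manifest = {
        "config": cfg.to_dict(),
        "stages": list(stages),
        "results": results,
        "config_hash": hashlib.sha256(json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()).hexdigest(),
    }
    workdir.mkdir(parents=True, exist_ok=True)
    (workdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return results
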