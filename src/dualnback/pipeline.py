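"""End-to-end orchestration: simulate -> score -> analyze -> report.

Every stage writes plain CSV (and a text rendering for the summary
tables) under the configured output directory, together with a copy of
the configuration and a stage log, so a run is fully reproducible from
config + seed.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Union

import numpy as np
import pandas as pd

from .cohort import Population, simulate_cohort
from .config import PipelineConfig
from .inference import TestResult, friedman, mixed_model, one_sample_t, pearson_test, rm_anova
from .reporting import render_text_table, summary_table
from .scoring import (
    DELTA_OUTCOMES,
    delta_table,
    discrepancy_table,
    rank_table,
    score_cohort,
    scores_to_long,
)
from .specs import MODALITIES

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "simulate_stage", "score_stage", "analyze_stage", "report_stage"]

_FLOAT_FMT = "%.6g"


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    logger.info("wrote %s (%d rows)", path.name, len(df))


def _df(results: List[TestResult], **context) -> pd.DataFrame:
    rows = []
    for res in results:
        df = res.df
        df1, df2 = (df if isinstance(df, tuple) else (df, np.nan))
        rows.append(
            dict(
                context,
                effect=res.effect_label,
                statistic=res.statistic,
                df1=df1,
                df2=df2,
                p=res.p_value,
                adjustment=res.adjustment,
                **{k: v for k, v in res.extras.items()},
            )
        )
    return pd.DataFrame(rows)


def simulate_stage(config: PipelineConfig, outdir: Path) -> Dict[str, pd.DataFrame]:
    trial_log, profiles = simulate_cohort(config.design(), Population(), config.seed)
    profiles.insert(0, "seed", config.seed)
    _write(trial_log, outdir / "trial_log.csv")
    _write(profiles, outdir / "profiles.csv")
    return {"trial_log": trial_log, "profiles": profiles}


def score_stage(
    config: PipelineConfig, outdir: Path, trial_log: pd.DataFrame
) -> Dict[str, pd.DataFrame]:
    scores = score_cohort(trial_log, rt_pool=config.rt_pool)
    deltas = delta_table(scores)
    discrepancies = discrepancy_table(scores)
    _write(scores, outdir / "scores_wide.csv")
    _write(scores_to_long(scores), outdir / "scores_long.csv")
    _write(deltas, outdir / "deltas.csv")
    _write(discrepancies, outdir / "discrepancies.csv")
    return {"scores": scores, "deltas": deltas, "discrepancies": discrepancies}


def analyze_stage(
    config: PipelineConfig,
    outdir: Path,
    scores: pd.DataFrame,
    deltas: pd.DataFrame,
    profiles: pd.DataFrame,
) -> Dict[str, pd.DataFrame]:
    frames: Dict[str, List[pd.DataFrame]] = {
        "delta_tests": [], "friedman": [], "correlations": [], "anova": [], "mixed": [],
    }
    whole = scores[scores["segment"] == "whole"]

    for modality in MODALITIES:
        dmod = deltas[deltas["modality"] == modality]
        for condition, grp in dmod.groupby("condition", observed=True):
            for outcome in DELTA_OUTCOMES:
                vals = grp[f"delta_{outcome}"].dropna().to_numpy()
                if vals.size < 2 or vals.std(ddof=1) == 0:
                    continue
                res = one_sample_t(values=vals, effect_label=f"delta_{outcome}")
                frames["delta_tests"].append(
                    _df([res], modality=modality, condition=condition, outcome=outcome)
                )

        wmod = whole[whole["modality"] == modality]
        for outcome in ("H", "F", "a_prime", "wm", "rt_mean", "rt_sd"):
            ranks = rank_table(
                scores, outcome, modality, ascending=config.rank_ascending
            )
            complete = ranks.dropna()
            if complete.shape[0] >= 2 and complete.shape[1] >= 2:
                res = friedman(complete, effect_label="condition")
                frames["friedman"].append(
                    _df([res], modality=modality, outcome=outcome)
                )
            if wmod["subject_id"].nunique() >= 3:
                results = rm_anova(
                    wmod, dv=outcome, within="condition", subject="subject_id"
                )
                frames["anova"].append(
                    _df(results, modality=modality, outcome=outcome)
                )
        for condition, grp in wmod.groupby("condition", observed=True):
            for outcome in ("H", "F", "a_prime", "wm"):
                sub = grp.dropna(subset=["rt_mean", outcome])
                if len(sub) < 3 or sub[outcome].std() == 0 or sub["rt_mean"].std() == 0:
                    continue
                res = pearson_test(
                    sub["rt_mean"], sub[outcome], effect_label=f"rt_mean vs {outcome}"
                )
                frames["correlations"].append(
                    _df([res], modality=modality, condition=condition, outcome=outcome)
                )

    covs = profiles[["subject_id", "sex", "age", "volume"]]
    for outcome in ("H", "F", "a_prime", "wm", "rt_mean"):
        data = whole.merge(covs, on="subject_id")
        try:
            results = mixed_model(data, dv=outcome)
        except Exception as err:  # singular tiny designs: report, don't abort
            logger.warning("mixed model for %s failed: %s", outcome, err)
            continue
        frames["mixed"].append(_df(results, outcome=outcome))

    out: Dict[str, pd.DataFrame] = {}
    for name, parts in frames.items():
        df = (
            pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
        )
        out[name] = df
        _write(df, outdir / f"{name}.csv")
    return out


def report_stage(
    config: PipelineConfig,
    outdir: Path,
    scores: pd.DataFrame,
    deltas: pd.DataFrame,
    profiles: pd.DataFrame,
) -> Dict[str, pd.DataFrame]:
    tables = {}
    for modality in MODALITIES:
        for by, tag in (("condition", "by_condition"), ("time_block", "by_block")):
            table = summary_table(scores, deltas, profiles, modality, by=by)
            name = f"summary_{modality}_{tag}"
            tables[name] = table
            _write(table, outdir / f"{name}.csv")
            (outdir / f"{name}.txt").write_text(render_text_table(table) + "\n")
    return tables


def run_pipeline(
    config: PipelineConfig, outdir: Union[str, Path, None] = None
) -> Path:
    """Run all stages and return the artifact directory."""
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("dualnback")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        config.to_yaml(outdir / "config.yaml")
        sim = simulate_stage(config, outdir)
        sc = score_stage(config, outdir, sim["trial_log"])
        analyze_stage(config, outdir, sc["scores"], sc["deltas"], sim["profiles"])
        report_stage(config, outdir, sc["scores"], sc["deltas"], sim["profiles"])
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir
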