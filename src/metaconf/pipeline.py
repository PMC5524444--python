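"""End-to-end orchestration of the confidence-analysis pipeline.

``run_pipeline`` reads (or simulates) a trial table, validates it, and
emits the study's result surfaces as machine-readable reports:

* ``performance``       — per participant x difficulty cell: accuracy,
  RTs, efficiency, EZ-diffusion v/a/Ter (a Table-1-style decomposition);
* ``confidence_profile``— pooled error rate per confidence level plus
  per-participant Spearman confidence-accuracy correlations;
* ``regression``        — per-participant standardized-beta models
  M0..M3 with R^2/BIC and second-order tests across participants;
* ``metacognition``     — per participant x cell A_ROC and B_ROC, the
  2x2 ANOVAs, and the medium-cell (difficulty-matched) contrasts with
  JZS Bayes factors.

Every number in the reports is produced by the owning module's public
operation on the validated table; the pipeline only routes data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .bayes import DEFAULT_PRIOR_SCALE, jzs_bf_ttest
from .condition import (
    MODELS,
    aggregate_cells,
    anova_2x2_rm,
    fit_condition_regression,
    medium_rt_difference,
    median_split_subgroup,
    one_sample_t,
    paired_t,
)
from .io import read_trials, validate_trials, write_trials
from .observer import DesignSpec, ObserverParams, simulate_experiment
from .perf import cell_performance, ez_fit
from .type2 import confidence_error_profile, score_metacognition

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

_CELLS = [("high", "low"), ("high", "high"), ("low", "low"), ("low", "high")]
_STAGES = ("performance", "confidence_profile", "regression", "metacognition")


@dataclass
class PipelineConfig:
    """What to run, on what input, and where to write it."""

    input_path: Optional[str] = None
    n_participants: int = 20
    seed: int = 0
    stages: Tuple[str, ...] = _STAGES
    output_dir: str = "metaconf_output"
    deadline: float = 1500.0
    bf_prior_scale: float = DEFAULT_PRIOR_SCALE
    with_meta_d: bool = False
    observer_overrides: Dict[str, object] = field(default_factory=dict)
    design_overrides: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; choose from {_STAGES}")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML or JSON mapping."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return PipelineConfig(**raw)


def _obtain_trials(config: PipelineConfig) -> pd.DataFrame:
    if config.input_path is not None:
        return read_trials(config.input_path)
    rng = np.random.default_rng(config.seed)
    design = DesignSpec(**config.design_overrides)
    params = ObserverParams(**config.observer_overrides)
    return simulate_experiment(config.n_participants, design, params, rng)


def _performance_stage(trials: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    rows = []
    for p in sorted(trials["participant"].unique()):
        for m, v in _CELLS:
            perf = cell_performance(
                trials, participant=p, mean_level=m, variance_level=v
            )
            fit = ez_fit(
                perf.accuracy, perf.mean_correct_rt, perf.var_correct_rt, n=perf.n
            )
            rows.append(
                {
                    "participant": p,
                    "mean_level": m,
                    "variance_level": v,
                    "n": perf.n,
                    "accuracy": perf.accuracy,
                    "error_rate_pct": 100.0 * (1.0 - perf.accuracy),
                    "median_correct_rt": perf.median_correct_rt,
                    "mean_correct_rt": perf.mean_correct_rt,
                    "efficiency": perf.efficiency,
                    "v": fit.v,
                    "a": fit.a,
                    "ter": fit.ter,
                }
            )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby(["mean_level", "variance_level"])
        .agg(
            error_rate_pct=("error_rate_pct", "mean"),
            mean_correct_rt=("mean_correct_rt", "mean"),
            efficiency=("efficiency", "mean"),
            v=("v", "mean"),
            a=("a", "mean"),
        )
        .reset_index()
    )
    return {"performance": table, "performance_summary": summary}


def _profile_stage(trials: pd.DataFrame) -> Tuple[pd.DataFrame, dict]:
    rates, rho, p = confidence_error_profile(trials)
    pooled = pd.DataFrame(
        {"confidence": range(1, 7), "error_rate": rates}
    )
    per_p = {}
    for pid in sorted(trials["participant"].unique()):
        try:
            _, r, pv = confidence_error_profile(trials, participant=pid)
            per_p[str(pid)] = {"rho": r, "p": pv}
        except ValueError as exc:  # too few occupied bins
            per_p[str(pid)] = {"excluded": str(exc)}
    return pooled, {"pooled_rho": rho, "pooled_p": p, "participants": per_p}


def _regression_stage(trials: pd.DataFrame, r_scale: float) -> Tuple[pd.DataFrame, dict]:
    cells = aggregate_cells(trials)
    rows = []
    for p, g in cells.groupby("participant", sort=True):
        for model_id in MODELS:
            res = fit_condition_regression(g, model_id)
            row = {"participant": p, "model": model_id, "r2": res.r2, "bic": res.bic}
            row.update({f"beta_{k}": b for k, b in res.betas.items()})
            rows.append(row)
    table = pd.DataFrame(rows)

    tests: Dict[str, dict] = {"betas": {}, "bic_comparisons": {}, "mean_bic": {}}
    for model_id, preds in MODELS.items():
        sub = table[table["model"] == model_id]
        tests["mean_bic"][model_id] = float(sub["bic"].mean())
        for pred in preds:
            t, df, pv = one_sample_t(sub[f"beta_{pred}"])
            bf = jzs_bf_ttest(t, df + 1, r_scale)
            tests["betas"][f"{model_id}:{pred}"] = {
                "mean_beta": float(sub[f"beta_{pred}"].mean()),
                "t": t, "df": df, "p": pv, "bf10": bf.bf10,
            }
    for m1, m2 in [("M0", "M1"), ("M1", "M2a"), ("M1", "M2b"),
                   ("M2a", "M3"), ("M2b", "M3")]:
        a = table[table["model"] == m1].sort_values("participant")["bic"].to_numpy()
        b = table[table["model"] == m2].sort_values("participant")["bic"].to_numpy()
        t, df, pv = paired_t(a, b)
        tests["bic_comparisons"][f"{m1}_vs_{m2}"] = {"t": t, "df": df, "p": pv}
    return table, tests


def _metacognition_stage(
    trials: pd.DataFrame, r_scale: float, with_meta_d: bool
) -> Tuple[pd.DataFrame, dict]:
    rows = []
    for p in sorted(trials["participant"].unique()):
        for m, v in _CELLS:
            sc = score_metacognition(
                trials, with_meta_d=with_meta_d,
                participant=p, mean_level=m, variance_level=v,
            )
            rows.append(
                {
                    "participant": p, "mean_level": m, "variance_level": v,
                    "a_roc": sc.a_roc, "b_roc": sc.b_roc,
                    "d_prime": sc.d_prime, "meta_d_prime": sc.meta_d_prime,
                    "n": sc.n_trials,
                }
            )
    table = pd.DataFrame(rows)

    tests: Dict[str, dict] = {"anova": {}, "medium_contrasts": {}}
    for measure in ("a_roc", "b_roc"):
        long = table.rename(columns={measure: "value"})
        tests["anova"][measure] = [
            asdict(r) for r in anova_2x2_rm(long, value="value")
        ]

    def _medium(measure_table: pd.DataFrame, col: str):
        hh = measure_table[
            (measure_table.mean_level == "high") & (measure_table.variance_level == "high")
        ].sort_values("participant")[col].to_numpy()
        ll = measure_table[
            (measure_table.mean_level == "low") & (measure_table.variance_level == "low")
        ].sort_values("participant")[col].to_numpy()
        t, df, pv = paired_t(hh, ll)
        bf = jzs_bf_ttest(t, df + 1, r_scale)
        return {
            "mean_high_high": float(hh.mean()), "mean_low_low": float(ll.mean()),
            "t": t, "df": df, "p": pv, "bf10": bf.bf10, "bf_null": bf.bf_null,
            "category": bf.category,
        }

    for col in ("a_roc", "b_roc"):
        tests["medium_contrasts"][col] = _medium(table, col)

    # confidence in the matched cells, split by accuracy
    conf_rows = []
    keep = trials[~trials["miss"].astype(bool)]
    for acc, label in ((1, "correct"), (0, "error")):
        agg = (
            keep[keep["accuracy"] == acc]
            .groupby(["participant", "mean_level", "variance_level"])["confidence"]
            .mean()
            .reset_index()
        )
        tests["medium_contrasts"][f"confidence_{label}"] = _medium(agg, "confidence")
        conf_rows.append(agg.assign(accuracy=label))
    conf_table = pd.concat(conf_rows, ignore_index=True)

    # RT-matched subgroup re-run of the confidence contrasts
    subgroup = median_split_subgroup(medium_rt_difference(trials))
    sub_trials = trials[trials["participant"].isin(subgroup)]
    tests["rt_matched_subgroup"] = {"participants": [str(s) for s in subgroup]}
    if len(subgroup) < 2:  # paired tests need at least two participants
        return table, {"tests": tests, "confidence_by_cell": conf_table}
    for acc, label in ((1, "correct"), (0, "error")):
        agg = (
            sub_trials[(~sub_trials["miss"].astype(bool)) & (sub_trials["accuracy"] == acc)]
            .groupby(["participant", "mean_level", "variance_level"])["confidence"]
            .mean()
            .reset_index()
        )
        tests["rt_matched_subgroup"][f"confidence_{label}"] = _medium(agg, "confidence")
    return table, {"tests": tests, "confidence_by_cell": conf_table}


def _jsonable(obj):
    """Recursively convert config values into JSON-serializable form."""
    if isinstance(obj, dict):
        return {
            (",".join(k) if isinstance(k, tuple) else str(k)): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Run the configured stages; returns the report bundle and writes files.

    Deterministic given ``config.seed``.  Outputs: one TSV per tabular
    report, one JSON per test battery, the validated trial table, and a
    ``manifest.json`` recording versions, seed and a config hash.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    raw = _obtain_trials(config)
    trials, validation = validate_trials(raw, deadline=config.deadline)
    bundle: Dict[str, object] = {"validation": validation}
    write_trials(trials, out / "trials.tsv")

    stage = "validate"
    try:
        if "performance" in config.stages:
            stage = "performance"
            for name, tbl in _performance_stage(trials).items():
                bundle[name] = tbl
                tbl.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        if "confidence_profile" in config.stages:
            stage = "confidence_profile"
            pooled, prof = _profile_stage(trials)
            bundle["confidence_profile"] = pooled
            bundle["confidence_profile_tests"] = prof
            pooled.to_csv(out / "confidence_profile.tsv", sep="\t", index=False)
            (out / "confidence_profile_tests.json").write_text(
                json.dumps(prof, indent=2)
            )
        if "regression" in config.stages:
            stage = "regression"
            table, tests = _regression_stage(trials, config.bf_prior_scale)
            bundle["regression"] = table
            bundle["regression_tests"] = tests
            table.to_csv(out / "regression.tsv", sep="\t", index=False)
            (out / "regression_tests.json").write_text(json.dumps(tests, indent=2))
        if "metacognition" in config.stages:
            stage = "metacognition"
            table, extra = _metacognition_stage(
                trials, config.bf_prior_scale, config.with_meta_d
            )
            bundle["metacognition"] = table
            bundle["metacognition_tests"] = extra["tests"]
            table.to_csv(out / "metacognition.tsv", sep="\t", index=False)
            (out / "metacognition_tests.json").write_text(
                json.dumps(extra["tests"], indent=2)
            )
            extra["confidence_by_cell"].to_csv(
                out / "confidence_by_cell.tsv", sep="\t", index=False
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    cfg = _jsonable(asdict(config))
    manifest = {
        "metaconf_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "validation": {k: v for k, v in validation.items()
                       if k != "cells_covered_per_participant"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle
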