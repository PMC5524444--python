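"""Condition-cell aggregation and group-level statistics.

The design yields eight cells per participant (2 evidence-mean levels x
2 evidence-variance levels x 2 color categories).  Confidence is
modelled per participant by small OLS regressions on these eight cell
means, with nested predictor sets:

    M0  {accuracy}                M2a {accuracy, RT, mean}
    M1  {accuracy, RT}            M2b {accuracy, RT, variance}
    M3  {accuracy, RT, mean, variance}

Outcome and predictors are z-scored within participant so the betas are
standardized and comparable across predictors; models are compared via
BIC and the per-participant betas/BICs are carried to second-order
(across-participant) t tests.  Accuracy enters as the continuity-
corrected log-odds of the error rate, sign-flipped so that a positive
beta means "more accurate -> more confident"; mean/variance levels are
contrast-coded -1/+1 (high mean = +1, high variance = +1) before
standardization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MODELS",
    "RegressionResult",
    "AnovaResult",
    "aggregate_cells",
    "logodds_error",
    "fit_condition_regression",
    "bic",
    "one_sample_t",
    "paired_t",
    "anova_2x2_rm",
    "medium_rt_difference",
    "median_split_subgroup",
]

#: predictor sets of the nested model family
MODELS: Dict[str, Tuple[str, ...]] = {
    "M0": ("accuracy",),
    "M1": ("accuracy", "rt"),
    "M2a": ("accuracy", "rt", "mean"),
    "M2b": ("accuracy", "rt", "variance"),
    "M3": ("accuracy", "rt", "mean", "variance"),
}


@dataclass(frozen=True)
class RegressionResult:
    model_id: str
    betas: Dict[str, float]
    r2: float
    bic: float
    n: int
    k: int


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    f: float
    df: Tuple[int, int]
    p: float
    partial_eta_sq: float


def logodds_error(error_rate: float, n: int) -> float:
    """Continuity-corrected log-odds of an error rate.

    With x = error count out of n, the corrected rate (x + 0.5)/(n + 1)
    keeps the log-odds finite at observed rates of 0 and 1.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    x = error_rate * n
    e = (x + 0.5) / (n + 1.0)
    return math.log(e / (1.0 - e))


def aggregate_cells(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant summaries of the 8 design cells (misses excluded).

    Mean confidence is aggregated over correct and error trials; correct
    RT is the mean over correct trials only.  Raises if any participant
    is missing a cell or a cell has no correct trials.
    """
    keep = trials[~trials["miss"].astype(bool)] if "miss" in trials.columns else trials
    keep = keep[keep["confidence"].notna()]
    rows: List[dict] = []
    for (p, m, v, c), g in keep.groupby(
        ["participant", "mean_level", "variance_level", "color"], sort=True
    ):
        corr = g[g["accuracy"] == 1]
        if len(corr) == 0:
            raise ValueError(f"cell ({p}, {m}, {v}, {c}) has no correct trials")
        err = 1.0 - g["accuracy"].mean()
        rows.append(
            {
                "participant": p,
                "mean_level": m,
                "variance_level": v,
                "color": c,
                "n": len(g),
                "mean_confidence": g["confidence"].mean(),
                "mean_correct_rt": corr["rt"].mean(),
                "error_rate": err,
                "logodds_error": logodds_error(err, len(g)),
            }
        )
    cells = pd.DataFrame(rows)
    counts = cells.groupby("participant").size()
    bad = counts[counts != 8]
    if len(bad):
        raise ValueError(
            f"participants without all 8 design cells: {list(bad.index)}"
        )
    return cells


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant variable cannot be standardized (singular design)")
    return (x - x.mean()) / sd


def _design_columns(cells: pd.DataFrame) -> Dict[str, np.ndarray]:
    return {
        # flip log-odds error so positive beta = more accurate, more confident
        "accuracy": -cells["logodds_error"].to_numpy(dtype=float),
        "rt": cells["mean_correct_rt"].to_numpy(dtype=float),
        "mean": np.where(cells["mean_level"] == "high", 1.0, -1.0),
        "variance": np.where(cells["variance_level"] == "high", 1.0, -1.0),
    }


def bic(r2: float, n: int, k: int) -> float:
    """BIC of an OLS fit from its R^2: n ln(1 - R^2) + k ln(n).

    ``k`` counts predictors excluding the intercept.  Lower is better;
    R^2 = 1 returns -inf (degenerate perfect fit).
    """
    if n <= k:
        raise ValueError("need n > k")
    if r2 >= 1.0:
        return -math.inf
    return n * math.log(1.0 - r2) + k * math.log(n)


def fit_condition_regression(cells: pd.DataFrame, model_id: str) -> RegressionResult:
    """Standardized OLS of mean confidence on one participant's 8 cells."""
    if model_id not in MODELS:
        raise ValueError(f"unknown model {model_id!r}; choose from {list(MODELS)}")
    if len(cells) != 8:
        raise ValueError(f"expected 8 cell rows, got {len(cells)}")
    predictors = MODELS[model_id]
    cols = _design_columns(cells)
    y = _zscore(cells["mean_confidence"].to_numpy(dtype=float))
    X = np.column_stack([_zscore(cols[p]) for p in predictors])
    Xi = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(Xi, y, rcond=None)
    resid = y - Xi @ coef
    r2 = 1.0 - resid @ resid / (y @ y)  # y is centered: y@y = SST
    k = len(predictors)
    return RegressionResult(
        model_id=model_id,
        betas={p: float(b) for p, b in zip(predictors, coef[1:])},
        r2=float(r2),
        bic=bic(float(r2), len(y), k),
        n=len(y),
        k=k,
    )


def one_sample_t(values: Sequence[float], popmean: float = 0.0) -> Tuple[float, int, float]:
    """One-sample t test; returns (t, df, two-sided p)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if x.std(ddof=1) == 0:
        raise ValueError("zero variance across participants: t undefined")
    res = stats.ttest_1samp(x, popmean)
    return float(res.statistic), x.size - 1, float(res.pvalue)


def paired_t(a: Sequence[float], b: Sequence[float]) -> Tuple[float, int, float]:
    """Paired t test (e.g. BICs of two models); returns (t, df, two-sided p)."""
    return one_sample_t(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def anova_2x2_rm(data: pd.DataFrame, value: str = "value") -> List[AnovaResult]:
    """2x2 repeated-measures ANOVA over mean_level x variance_level.

    ``data`` is long-format with columns participant, mean_level,
    variance_level and the outcome ``value`` (one row per participant x
    cell, color already pooled).  Each effect is tested against its own
    participant-by-effect error term, F(1, n-1); for two-level factors
    this equals the squared one-sample t of the per-participant effect
    contrast, and eta_p^2 = F / (F + n - 1).
    """
    piv = data.pivot_table(
        index="participant", columns=["mean_level", "variance_level"], values=value
    )
    expected = [("high", "high"), ("high", "low"), ("low", "high"), ("low", "low")]
    if sorted(piv.columns.tolist()) != expected or piv.isna().any().any():
        raise ValueError("need complete balanced 2x2 data for every participant")
    n = len(piv)
    y = {c: piv[c].to_numpy(dtype=float) for c in expected}
    contrasts = {
        "mean": (y[("high", "high")] + y[("high", "low")]) / 2
        - (y[("low", "high")] + y[("low", "low")]) / 2,
        "variance": (y[("high", "high")] + y[("low", "high")]) / 2
        - (y[("high", "low")] + y[("low", "low")]) / 2,
        "interaction": (y[("high", "high")] - y[("high", "low")])
        - (y[("low", "high")] - y[("low", "low")]),
    }
    out = []
    for name, L in contrasts.items():
        sd = L.std(ddof=1)
        if sd == 0:
            f = 0.0 if np.allclose(L, 0) else math.inf
        else:
            t = L.mean() / (sd / math.sqrt(n))
            f = t * t
        p = float(stats.f.sf(f, 1, n - 1)) if math.isfinite(f) else 0.0
        eta = f / (f + n - 1) if math.isfinite(f) else 1.0
        out.append(AnovaResult(effect=name, f=float(f), df=(1, n - 1), p=p,
                               partial_eta_sq=float(eta)))
    return out


def medium_rt_difference(trials: pd.DataFrame) -> pd.Series:
    """Per-participant |correct-RT difference| between the two medium cells.

    The medium cells are (high mean, high variance) and (low mean, low
    variance); a small value means the participant's speed was matched
    across them.
    """
    keep = trials[~trials["miss"].astype(bool)]
    keep = keep[keep["accuracy"] == 1]

    def _cell_rt(g, m, v):
        sel = g[(g["mean_level"] == m) & (g["variance_level"] == v)]
        if len(sel) == 0:
            raise ValueError("participant missing a medium cell")
        return sel["rt"].mean()

    diffs = {}
    for p, g in keep.groupby("participant", sort=True):
        diffs[p] = abs(_cell_rt(g, "high", "high") - _cell_rt(g, "low", "low"))
    return pd.Series(diffs, name="medium_rt_difference")


def median_split_subgroup(statistic: pd.Series) -> List:
    """Participants at or below the median of ``statistic``.

    Returns the "minimal difference" subgroup: the ceil(n/2) smallest
    values, ties broken by stable participant order so membership is
    reproducible.
    """
    if len(statistic) < 2:
        raise ValueError("need at least 2 participants")
    order = statistic.reset_index()
    order.columns = ["participant", "value"]
    order = order.sort_values("value", kind="stable")
    h = (len(order) + 1) // 2
    return order["participant"].iloc[:h].tolist()
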