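"""Type II signal detection analysis of confidence ratings.

Given trial-level confidence ratings (1 = certainly wrong ... 6 =
certainly correct) and first-order accuracy, these routines quantify

* metacognitive *sensitivity* — how well ratings discriminate correct
  from incorrect responses — via the distribution-free area under the
  Type II ROC (``a_roc``), and
* metacognitive *bias* — the overall tendency to classify one's
  responses as correct, over and above objective accuracy — via a
  distribution-free criterion-based index (``b_roc``).

The Type II ROC sweeps a criterion over the rating scale from the
"certainly correct" end downward, plotting the hit rate
P(conf >= c | correct) against the false-alarm rate
P(conf >= c | error).  No distributional assumptions are made; this is
the standard remedy for the frequently violated Gaussian assumptions of
parametric Type II fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RatingCounts",
    "ROCCurve",
    "MetacogScores",
    "tabulate_ratings",
    "type2_roc",
    "a_roc",
    "b_roc",
    "confidence_error_profile",
    "score_metacognition",
]

N_RATINGS = 6


@dataclass
class RatingCounts:
    """Confidence-rating counts split by first-order accuracy.

    ``correct_by_rating[i]`` / ``error_by_rating[i]`` count trials rated
    ``i + 1``.  ``by_stim_resp`` optionally holds the (stimulus color,
    response) -> per-rating counts needed for meta-d'.  ``degenerate``
    flags tables in which one accuracy class is empty (the ROC is then
    undefined but the counts remain usable).
    """

    correct_by_rating: np.ndarray
    error_by_rating: np.ndarray
    by_stim_resp: Optional[Dict[Tuple[str, str], np.ndarray]] = None
    degenerate: bool = field(init=False)

    def __post_init__(self) -> None:
        self.correct_by_rating = np.asarray(self.correct_by_rating, dtype=float)
        self.error_by_rating = np.asarray(self.error_by_rating, dtype=float)
        for arr in (self.correct_by_rating, self.error_by_rating):
            if arr.shape != (N_RATINGS,):
                raise ValueError(f"expected {N_RATINGS} rating counts, got {arr.shape}")
            if (arr < 0).any():
                raise ValueError("counts must be non-negative")
        self.degenerate = (
            self.correct_by_rating.sum() == 0 or self.error_by_rating.sum() == 0
        )

    @property
    def n_trials(self) -> int:
        return int(self.correct_by_rating.sum() + self.error_by_rating.sum())


@dataclass(frozen=True)
class ROCCurve:
    """Ordered Type II ROC operating points, endpoints (0,0) and (1,1) included."""

    false_alarm: np.ndarray
    hit: np.ndarray

    def __post_init__(self) -> None:
        f, h = np.asarray(self.false_alarm), np.asarray(self.hit)
        if f.shape != h.shape or f.ndim != 1:
            raise ValueError("coordinates must be 1-d and equal length")
        if (np.diff(f) < -1e-12).any() or (np.diff(h) < -1e-12).any():
            raise ValueError("ROC coordinates must be non-decreasing")
        if not (f[0] == h[0] == 0.0 and f[-1] == h[-1] == 1.0):
            raise ValueError("ROC must run from (0,0) to (1,1)")


@dataclass(frozen=True)
class MetacogScores:
    """Per-participant (x condition) metacognition summary."""

    a_roc: float
    b_roc: float
    d_prime: Optional[float] = None
    meta_d_prime: Optional[float] = None
    n_trials: int = 0


def tabulate_ratings(
    trials: pd.DataFrame,
    with_stim_resp: bool = False,
    **cell_filter,
) -> RatingCounts:
    """Count ratings 1..6 by accuracy for the trials selected by ``cell_filter``.

    Keyword filters are column -> value equality constraints (e.g.
    ``participant=3, mean_level="high"``).  Misses are always excluded.
    """
    sel = trials
    for col, val in cell_filter.items():
        sel = sel[sel[col] == val]
    if "miss" in sel.columns:
        sel = sel[~sel["miss"].astype(bool)]
    sel = sel[sel["confidence"].notna()]
    if len(sel) == 0:
        raise ValueError(f"no trials left after filtering on {cell_filter!r}")

    conf = sel["confidence"].to_numpy(dtype=int)
    acc = sel["accuracy"].to_numpy(dtype=int)
    if conf.min() < 1 or conf.max() > N_RATINGS:
        raise ValueError("confidence ratings must lie in 1..6")

    correct = np.bincount(conf[acc == 1], minlength=N_RATINGS + 1)[1:]
    error = np.bincount(conf[acc == 0], minlength=N_RATINGS + 1)[1:]

    by_sr = None
    if with_stim_resp:
        by_sr = {}
        for s in ("red", "blue"):
            for r in ("red", "blue"):
                m = (sel["color"] == s) & (sel["choice"] == r)
                by_sr[(s, r)] = np.bincount(
                    conf[m.to_numpy()], minlength=N_RATINGS + 1
                )[1:].astype(float)
    return RatingCounts(correct, error, by_sr)


def type2_roc(counts: RatingCounts) -> ROCCurve:
    """Build the 7-point Type II ROC, cumulating from the highest rating down.

    Empty rating bins are kept as zero-width steps so the point count is
    always ``N_RATINGS + 1``.
    """
    if counts.degenerate:
        raise ValueError("degenerate ROC: one accuracy class has no trials")
    nc, ne = counts.correct_by_rating.sum(), counts.error_by_rating.sum()
    # criterion c = 7, 6, ..., 1 -> P(conf >= c)
    h = np.concatenate(([0.0], np.cumsum(counts.correct_by_rating[::-1]) / nc))
    f = np.concatenate(([0.0], np.cumsum(counts.error_by_rating[::-1]) / ne))
    h[-1] = f[-1] = 1.0  # exact endpoints
    return ROCCurve(f, h)


def a_roc(curve: ROCCurve) -> float:
    """Trapezoidal area under the Type II ROC.

    0.5 when ratings carry no information about accuracy; 1.0 for
    perfect separation of correct and error responses.
    """
    return float(np.trapezoid(curve.hit, curve.false_alarm))


def _grier_midpoint(counts: RatingCounts) -> float:
    # central-criterion distribution-free bias: operating point at conf >= 4
    h = counts.correct_by_rating[3:].sum() / counts.correct_by_rating.sum()
    f = counts.error_by_rating[3:].sum() / counts.error_by_rating.sum()
    num = f * (1.0 - f) - h * (1.0 - h)
    den = f * (1.0 - f) + h * (1.0 - h)
    if den == 0.0:
        # all mass on one side of the midpoint in both classes
        return float(np.sign(h + f - 1.0))
    return float(num / den)


def b_roc(
    counts: RatingCounts,
    formula: Callable[[RatingCounts], float] = _grier_midpoint,
) -> float:
    """Distribution-free metacognitive bias index.

    Higher values mean a stronger overall tendency to classify one's
    responses as correct (relatively higher confidence), independent of
    sensitivity.  The default is a Grier-type B'' evaluated at the scale
    midpoint (conf >= 4): with H = P(conf >= 4 | correct) and
    F = P(conf >= 4 | error),

        B = [F(1-F) - H(1-H)] / [F(1-F) + H(1-H)]

    signed so that pushing both H and F toward 1 (blanket confidence)
    drives B toward +1.  ``formula`` is pluggable so an alternative bias
    definition can be dropped in without touching callers.
    """
    if counts.degenerate:
        raise ValueError("degenerate counts: one accuracy class has no trials")
    return formula(counts)


def confidence_error_profile(
    trials: pd.DataFrame, **cell_filter
) -> Tuple[np.ndarray, float, float]:
    """Error rate per confidence bin and its Spearman rank correlation.

    Returns ``(error_rates, rho, p)``.  ``error_rates`` has one entry
    per rating 1..6; bins with no trials are NaN.  The correlation is
    computed over occupied bins only (mid-rank tie handling); with fewer
    than two occupied bins no stable estimate exists and an error is
    raised, matching the standard exclusion of such participants.
    """
    counts = tabulate_ratings(trials, **cell_filter)
    total = counts.correct_by_rating + counts.error_by_rating
    with np.errstate(invalid="ignore"):
        rates = np.where(total > 0, counts.error_by_rating / total, np.nan)
    occupied = total > 0
    if occupied.sum() < 2:
        raise ValueError("fewer than 2 occupied confidence bins: correlation undefined")
    rho, p = stats.spearmanr(np.arange(1, N_RATINGS + 1)[occupied], rates[occupied])
    return rates, float(rho), float(p)


def score_metacognition(
    trials: pd.DataFrame,
    with_meta_d: bool = False,
    **cell_filter,
) -> MetacogScores:
    """A_ROC, B_ROC (and optionally d', meta-d') for one participant/cell."""
    counts = tabulate_ratings(trials, with_stim_resp=with_meta_d, **cell_filter)
    curve = type2_roc(counts)
    d = md = None
    if with_meta_d:
        from .metad import meta_d  # local import: optimizer-heavy

        d, md = meta_d(counts.by_stim_resp)
    return MetacogScores(
        a_roc=a_roc(curve),
        b_roc=b_roc(counts),
        d_prime=d,
        meta_d_prime=md,
        n_trials=counts.n_trials,
    )
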