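"""First-order performance decomposition: efficiency and EZ-diffusion fits.

The efficiency score (median correct RT / accuracy) folds speed and
accuracy into a single difficulty index; it is the quantity used to
match conditions of nominally different stimulus composition.

The EZ-diffusion estimator inverts three observable moments — accuracy,
mean correct RT and variance of correct RT — into the drift rate v,
boundary separation a and non-decision time Ter of an unbiased
drift-diffusion model in closed form.  v indexes evidence quality,
a response caution.  RTs enter in milliseconds; v, a follow the
seconds-based scaling convention s = 0.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DDMFit",
    "CellPerformance",
    "efficiency",
    "ez_forward",
    "ez_fit",
    "cell_performance",
]

DEFAULT_SCALE = 0.1  # conventional diffusion scale (seconds units)


@dataclass(frozen=True)
class DDMFit:
    """Closed-form diffusion parameter estimates for one condition cell."""

    v: float
    a: float
    ter: float
    s: float = DEFAULT_SCALE

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("boundary separation must be positive")


@dataclass(frozen=True)
class CellPerformance:
    """Observable first-order summary of one condition cell."""

    n: int
    accuracy: float
    median_correct_rt: float
    mean_correct_rt: float
    var_correct_rt: float
    efficiency: float


def efficiency(median_correct_rt: float, accuracy: float) -> float:
    """Efficiency score: median correct RT divided by accuracy (ms).

    Equal to the median RT at perfect accuracy and inflated as accuracy
    drops, so harder cells score higher.
    """
    if accuracy <= 0:
        raise ValueError("efficiency undefined at zero accuracy")
    return median_correct_rt / accuracy


def ez_forward(
    v: float, a: float, ter: float, s: float = DEFAULT_SCALE
) -> Tuple[float, float, float]:
    """Closed-form EZ predictions (accuracy, mean correct RT ms, var ms^2).

    Unbiased start; v and a in the seconds-based s = 0.1 convention,
    ter in ms.  Inverse of :func:`ez_fit` on the admissible region.
    """
    if v == 0:
        raise ValueError("forward predictions undefined at v = 0")
    if a <= 0:
        raise ValueError("boundary separation must be positive")
    s2 = s * s
    y = -v * a / s2
    ey = math.exp(y)
    acc = 1.0 / (1.0 + ey)
    mdt = (a / (2.0 * v)) * (1.0 - ey) / (1.0 + ey)  # seconds
    vrt = (a * s2 / (2.0 * v**3)) * (2.0 * y * ey - math.exp(2.0 * y) + 1.0) / (ey + 1.0) ** 2
    return acc, mdt * 1000.0 + ter, vrt * 1e6


def ez_fit(
    accuracy: float,
    mean_correct_rt: float,
    var_correct_rt: float,
    n: Optional[int] = None,
    s: float = DEFAULT_SCALE,
) -> DDMFit:
    """Closed-form EZ inversion of (accuracy, mean RT ms, RT variance ms^2).

    Boundary accuracies are edge-corrected before inversion: with ``n``
    trials, accuracy is clamped to [1/(2n), 1 - 1/(2n)] and an exact 0.5
    is nudged up by 1/(2n) (the logit and hence the inversion are
    undefined at 0, 0.5 and 1).  Without ``n`` an exact edge raises.
    """
    if var_correct_rt <= 0:
        raise ValueError("correct-RT variance must be positive")
    pc = accuracy
    if n is not None:
        edge = 1.0 / (2.0 * n)
        pc = min(max(pc, edge), 1.0 - edge)
        if pc == 0.5:
            pc += edge
    if pc <= 0.0 or pc >= 1.0 or pc == 0.5:
        raise ValueError(
            f"accuracy {accuracy} is at an inversion singularity; pass n for "
            "edge correction"
        )
    mrt = mean_correct_rt / 1000.0  # seconds
    vrt = var_correct_rt / 1e6
    s2 = s * s
    logit = math.log(pc / (1.0 - pc))
    x = logit * (logit * pc * pc - logit * pc + pc - 0.5) / vrt
    v = math.copysign(1.0, pc - 0.5) * s * x**0.25
    a = s2 * logit / v
    y = -v * a / s2
    mdt = (a / (2.0 * v)) * (1.0 - math.exp(y)) / (1.0 + math.exp(y))
    return DDMFit(v=v, a=a, ter=(mrt - mdt) * 1000.0, s=s)


def cell_performance(trials: pd.DataFrame, **cell_filter) -> CellPerformance:
    """Observable performance summary of a filtered cell, misses excluded."""
    sel = trials
    for col, val in cell_filter.items():
        sel = sel[sel[col] == val]
    if "miss" in sel.columns:
        sel = sel[~sel["miss"].astype(bool)]
    if len(sel) == 0:
        raise ValueError(f"no trials left after filtering on {cell_filter!r}")
    acc = sel["accuracy"].mean()
    rts = sel.loc[sel["accuracy"] == 1, "rt"].to_numpy(dtype=float)
    if rts.size == 0:
        raise ValueError("cell has no correct trials; RT summaries undefined")
    med = float(np.median(rts))
    return CellPerformance(
        n=len(sel),
        accuracy=float(acc),
        median_correct_rt=med,
        mean_correct_rt=float(rts.mean()),
        var_correct_rt=float(rts.var(ddof=1)) if rts.size > 1 else float("nan"),
        efficiency=efficiency(med, acc),
    )
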