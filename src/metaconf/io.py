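"""Trial-table reading, writing and validation.

The on-disk dialect is a UTF-8 CSV or TSV with a mandatory header and
one row per trial: participant, block, mean_level, variance_level,
color, sample_mean, sample_sd, choice, accuracy, rt (ms), confidence
(1-6, blank for misses), miss.  Validation coerces types, rejects
out-of-range ratings, flags over-deadline rows as misses and reports
per-participant cell coverage, so that every downstream stage can rely
on a clean table.
"""

from __future__ import annotations

from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd

from .observer import TRIAL_COLUMNS

__all__ = ["read_trials", "write_trials", "validate_trials"]

REQUIRED = [
    "participant",
    "block",
    "mean_level",
    "variance_level",
    "color",
    "choice",
    "accuracy",
    "rt",
    "confidence",
]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial table (separator inferred from the extension)."""
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path))


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table; miss trials carry an empty confidence field."""
    path = Path(path)
    out = trials.copy()
    cols = [c for c in TRIAL_COLUMNS if c in out.columns]
    out = out[cols + [c for c in out.columns if c not in cols]]
    out.to_csv(path, sep=_sep_for(path), index=False)


def validate_trials(
    trials: pd.DataFrame, deadline: float = 1500.0
) -> Tuple[pd.DataFrame, dict]:
    """Coerce and screen a trial table; returns (clean table, report).

    Rows with ratings outside 1..6 are rejected (their indices are
    reported); rows with rt > deadline are flagged as misses and their
    confidence is cleared.  The report lists per-participant coverage of
    the 8 design cells.
    """
    missing = [c for c in REQUIRED if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing required columns: {missing}")
    df = trials.copy()
    df["rt"] = pd.to_numeric(df["rt"], errors="raise").astype(float)
    df["accuracy"] = pd.to_numeric(df["accuracy"], errors="raise").astype(int)
    df["confidence"] = pd.to_numeric(df["confidence"], errors="coerce")
    if (df["rt"] <= 0).any():
        bad = df.index[df["rt"] <= 0].tolist()
        raise ValueError(f"non-positive RTs at rows {bad}")

    rated = df["confidence"].notna()
    bad_rating = rated & (~df["confidence"].isin(range(1, 7)))
    rejected = df.index[bad_rating].tolist()
    df = df[~bad_rating].copy()

    if "miss" in df.columns:
        df["miss"] = df["miss"].astype(bool)
    else:
        df["miss"] = False
    late = df["rt"] > deadline
    flagged = int((late & ~df["miss"]).sum())
    df.loc[late, "miss"] = True
    df.loc[df["miss"], "confidence"] = np.nan

    coverage = (
        df[~df["miss"]]
        .groupby(["participant", "mean_level", "variance_level", "color"])
        .size()
        .groupby("participant")
        .size()
        .to_dict()
    )
    report = {
        "n_rows_in": len(trials),
        "n_rows_out": len(df),
        "rejected_rating_rows": rejected,
        "late_rows_flagged_miss": flagged,
        "miss_rate": float(df["miss"].mean()) if len(df) else float("nan"),
        "cells_covered_per_participant": coverage,
    }
    return df, report
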