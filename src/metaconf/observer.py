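"""Generative observer for a color-averaging confidence experiment.

Simulates an experiment in which a decider judges whether the average color
of eight patches is more red or more blue, then rates confidence on a 1-6
scale.  Difficulty is manipulated factorially: the distance of the mean
evidence from the category boundary (evidence strength) and the spread of
the evidence samples within a trial (evidence reliability).  The decision
itself is a drift-diffusion process; confidence is a post-decisional
readout of continued evidence accumulation, passed through a criterion
grid that can be shifted per condition (the "metacognitive readout").

Conventions
-----------
* Evidence is a single signed scalar per patch; the category boundary is
  at 0 and positive values favor "red".
* Time is in milliseconds.  The diffusion scale ``s`` is expressed per
  sqrt(ms); ``0.1 / sqrt(1000)`` corresponds to the conventional s = 0.1
  of the seconds-based diffusion literature.
* Moment control is exact: every emitted stimulus has sample mean equal
  to mu and sample SD (ddof=1) equal to sigma to floating precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "StimulusParams",
    "ObserverParams",
    "DesignSpec",
    "TRIAL_COLUMNS",
    "DIFFUSION_SCALE_MS",
    "sample_stimulus",
    "simulate_ddm_trial",
    "rating_from_readout",
    "generate_confidence",
    "simulate_session",
    "simulate_experiment",
    "CohortHeterogeneity",
    "variance_readout_observer",
    "hard_easy_observer",
    "staircase_match",
    "matched_design",
    "drift_matched_design",
    "drift_and_noise",
]

#: per-sqrt(ms) equivalent of the conventional diffusion scale s = 0.1/sqrt(s)
DIFFUSION_SCALE_MS: float = 0.1 / math.sqrt(1000.0)

#: column order of the trial table emitted by :func:`simulate_session`
TRIAL_COLUMNS: List[str] = [
    "participant",
    "block",
    "mean_level",
    "variance_level",
    "color",
    "sample_mean",
    "sample_sd",
    "choice",
    "accuracy",
    "rt",
    "confidence",
    "miss",
]

_LEVELS = ("high", "low")
_COLORS = ("red", "blue")


@dataclass(frozen=True)
class StimulusParams:
    """Theoretical moments of one trial's evidence sample.

    ``mu`` is signed (positive = red side of the boundary) and must agree
    in sign with ``color_category``.
    """

    color_category: str
    mu: float
    sigma: float
    n_patches: int = 8

    def __post_init__(self) -> None:
        if self.color_category not in _COLORS:
            raise ValueError(f"color_category must be one of {_COLORS}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_patches < 2:
            raise ValueError("n_patches must be at least 2 (sample SD undefined)")
        if self.color_category == "red" and self.mu < 0:
            raise ValueError("red stimuli must have mu >= 0")
        if self.color_category == "blue" and self.mu > 0:
            raise ValueError("blue stimuli must have mu <= 0")


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of the simulated decider and its metacognitive readout.

    Decision stage: drift = ``drift_gain`` x sample mean /
    (1 + ``variance_coupling`` x sample SD), boundary separation
    ``boundary`` with unbiased start, non-decision time ``ter``, constant
    momentary noise ``diffusion_scale``.  Dividing the drift by a
    function of the sample SD implements reliability-weighted evidence
    integration: unreliable (high-variance) evidence is down-weighted,
    which makes high-variance decisions both slower and less accurate —
    the empirically observed signature of the variance manipulation.
    Non-decision time is ``ter`` plus ``encoding_time_slope`` x sample SD
    (ms per evidence unit): heterogeneous arrays take longer to encode,
    so high-variance cells carry an RT cost that is not mirrored in
    accuracy, the classic speed-accuracy dissociation between
    difficulty-matched cells.

    Confidence stage: evidence accumulation continues for
    ``postdecision_window`` ms; the signed support for the made choice,
    plus Gaussian readout noise ``metacog_noise`` and the condition shifts
    ``readout_shift_lowmean`` / ``readout_shift_highvar``, is compared
    against the five ``confidence_criteria`` to produce a 1-6 rating.
    The shifts act on the readout only, never on the decision evidence,
    so they move metacognitive bias without touching sensitivity.
    """

    drift_gain: float = 1.262e-3
    boundary: float = 0.14
    ter: float = 290.0
    encoding_time_slope: float = 200.0
    diffusion_scale: float = DIFFUSION_SCALE_MS
    variance_coupling: float = 4.0
    postdecision_window: float = 600.0
    metacog_noise: float = 0.10
    confidence_criteria: Tuple[float, ...] = (-0.03, 0.03, 0.09, 0.15, 0.21)
    readout_shift_lowmean: float = 0.0
    readout_shift_highvar: float = 0.0

    def __post_init__(self) -> None:
        if self.boundary <= 0:
            raise ValueError("boundary must be positive")
        if self.ter < 0 or self.encoding_time_slope < 0:
            raise ValueError("non-decision time components must be non-negative")
        if self.diffusion_scale <= 0:
            raise ValueError("diffusion scale must be positive")
        if self.metacog_noise < 0:
            raise ValueError("metacognitive noise must be non-negative")
        crit = np.asarray(self.confidence_criteria, dtype=float)
        if crit.ndim != 1 or crit.size != 5:
            raise ValueError("confidence_criteria must hold 5 values")
        if not np.all(np.diff(crit) > 0):
            raise ValueError("confidence_criteria must be strictly increasing")


def _default_conditions() -> Dict[Tuple[str, str], Tuple[float, float]]:
    # (mean_level, variance_level) -> (|mu|, sigma); calibrated so that with
    # the default ObserverParams the simulated error rates fall near the
    # 5 / 12 / 15 / 25 % bands of the four difficulty cells.
    return {
        ("high", "low"): (0.200, 0.05),
        ("high", "high"): (0.200, 0.20),
        ("low", "low"): (0.118, 0.05),
        ("low", "high"): (0.118, 0.20),
    }


@dataclass(frozen=True)
class DesignSpec:
    """Layout of one session: 16 blocks x 64 trials, 2x2x2 factorial.

    Within every block the four difficulty cells crossed with the two
    color categories are balanced and randomly interleaved.  Responses
    slower than ``deadline`` ms are misses and carry no confidence.
    """

    n_blocks: int = 16
    trials_per_block: int = 64
    deadline: float = 1500.0
    conditions: Dict[Tuple[str, str], Tuple[float, float]] = field(
        default_factory=_default_conditions
    )
    n_ratings: int = 6

    def __post_init__(self) -> None:
        # accept "mean,variance" string keys (e.g. from YAML configs)
        conds = {}
        for key, val in self.conditions.items():
            if isinstance(key, str):
                key = tuple(k.strip() for k in key.split(","))
            conds[tuple(key)] = tuple(float(x) for x in val)
        object.__setattr__(self, "conditions", conds)
        n_cells = len(self.conditions) * len(_COLORS)
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("design must contain at least one block and trial")
        if self.trials_per_block % n_cells:
            raise ValueError(
                f"trials_per_block={self.trials_per_block} not divisible by "
                f"{n_cells} cell x color combinations: design unbalanced"
            )
        for (m, v) in self.conditions:
            if m not in _LEVELS or v not in _LEVELS:
                raise ValueError("condition levels must be 'high' or 'low'")
        for (mu, sigma) in self.conditions.values():
            if mu < 0 or sigma < 0:
                raise ValueError("condition (mu, sigma) must be non-negative")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


# ---------------------------------------------------------------------------
# stimulus generation


def sample_stimulus(params: StimulusParams, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_patches`` evidence values with *exact* sample moments.

    A normal draw is affine-corrected (centered, rescaled to the target
    SD, then shifted to mu) so that the emitted sample's mean and SD
    match the theoretical moments to floating precision, mirroring
    tightly moment-controlled psychophysics displays.
    """
    if params.sigma == 0:
        raise ValueError(
            "sigma = 0 with n_patches > 1 is a degenerate stimulus: "
            "identical patches carry no variance manipulation"
        )
    z = rng.standard_normal(params.n_patches)
    z = z - z.mean()
    sd = z.std(ddof=1)
    if sd == 0:  # pragma: no cover - probability-zero degenerate draw
        raise RuntimeError("degenerate normal draw; retry with another seed")
    return params.mu + params.sigma * z / sd


# ---------------------------------------------------------------------------
# decision stage


def drift_and_noise(
    sample_mean: np.ndarray, sample_sd: np.ndarray, params: ObserverParams
) -> Tuple[np.ndarray, np.ndarray]:
    """Reliability-weighted drift and (constant) momentary noise per trial."""
    sample_mean = np.asarray(sample_mean, dtype=float)
    drift = params.drift_gain * sample_mean / (
        1.0 + params.variance_coupling * np.asarray(sample_sd, dtype=float)
    )
    return drift, np.full_like(drift, params.diffusion_scale)


def simulate_ddm_trial(
    drift: float,
    a: float,
    ter: float,
    noise: float,
    rng: np.random.Generator,
    dt: float = 1.0,
    max_horizon: float = 10_000.0,
) -> Tuple[str, float]:
    """Simulate one diffusion trial (Euler-Maruyama, unbiased start).

    Returns ``(choice, rt_ms)`` where the upper boundary codes "red".
    Trials that fail to absorb within ``max_horizon`` ms are forced to
    the nearer boundary (such trials exceed any realistic deadline and
    are flagged as misses downstream).
    """
    for name, val in (("drift", drift), ("a", a), ("ter", ter), ("noise", noise)):
        if not math.isfinite(val):
            raise ValueError(f"non-finite {name}")
    if a <= 0 or dt <= 0:
        raise ValueError("a and dt must be positive")
    choice, t, _ = _ddm_batch(
        np.array([drift]), np.array([noise]), a, rng, dt=dt, max_horizon=max_horizon
    )
    return ("red" if choice[0] > 0 else "blue", float(t[0] + ter))


def _ddm_batch(
    drift: np.ndarray,
    noise: np.ndarray,
    a: float,
    rng: np.random.Generator,
    dt: float = 1.0,
    max_horizon: float = 10_000.0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized first-passage simulation for a batch of trials.

    Returns (choice_sign, decision_time_ms, runaway_flag) with
    choice_sign = +1 for the upper ("red") boundary.
    """
    n = drift.size
    x = np.zeros(n)  # relative to the unbiased start a/2
    t = np.zeros(n)
    sign = np.zeros(n)
    active = np.ones(n, dtype=bool)
    half = a / 2.0
    sq = math.sqrt(dt)
    n_steps = int(math.ceil(max_horizon / dt))
    for _ in range(n_steps):
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            break
        step = drift[idx] * dt + noise[idx] * sq * rng.standard_normal(idx.size)
        x[idx] += step
        t[idx] += dt
        hit_up = x[idx] >= half
        hit_dn = x[idx] <= -half
        done = hit_up | hit_dn
        sign[idx[hit_up]] = 1.0
        sign[idx[hit_dn]] = -1.0
        active[idx[done]] = False
    runaway = active.copy()
    if runaway.any():
        # force to the nearer boundary; rt already at the horizon
        sign[runaway] = np.where(x[runaway] >= 0, 1.0, -1.0)
        sign[runaway & (x == 0)] = 1.0
    return sign, t, runaway


# ---------------------------------------------------------------------------
# confidence stage


def rating_from_readout(xi: float | np.ndarray, criteria) -> np.ndarray:
    """Map readout values onto 1..k+1 ratings: 1 + #criteria strictly below xi."""
    crit = np.asarray(criteria, dtype=float)
    if not np.all(np.diff(crit) > 0):
        raise ValueError("criteria must be strictly increasing")
    return 1 + (np.asarray(xi, dtype=float)[..., None] > crit).sum(axis=-1)


def generate_confidence(
    choice_sign: np.ndarray,
    drift: np.ndarray,
    noise: np.ndarray,
    params: ObserverParams,
    mean_level: np.ndarray,
    variance_level: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Post-decisional confidence readout for a batch of decided trials.

    Evidence accumulation continues freely for ``postdecision_window`` ms
    after the decision; the experienced certainty is the boundary excess
    a/2 plus the signed support of the post-decision increment for the
    made choice, blurred by ``metacog_noise``.  Condition-dependent
    readout shifts are added before the criterion comparison, so they
    bias the expressed rating without altering the certainty signal.
    """
    tau = params.postdecision_window
    post = drift * tau + noise * math.sqrt(tau) * rng.standard_normal(drift.size)
    xi = params.boundary / 2.0 + choice_sign * post
    if params.metacog_noise > 0:
        xi = xi + params.metacog_noise * rng.standard_normal(drift.size)
    xi = xi + params.readout_shift_lowmean * (np.asarray(mean_level) == "low")
    xi = xi + params.readout_shift_highvar * (np.asarray(variance_level) == "high")
    return rating_from_readout(xi, params.confidence_criteria)


# ---------------------------------------------------------------------------
# session assembly


def simulate_session(
    design: DesignSpec,
    params: ObserverParams,
    rng: np.random.Generator,
    participant: int = 1,
) -> pd.DataFrame:
    """Simulate one full session as a trial table.

    Every block interleaves the balanced cell x color combinations in
    random order.  Misses (rt > deadline) keep their decision record but
    carry no confidence rating.
    """
    cells = list(design.conditions.items())
    combos = [(m, v, mu, sig, c) for (m, v), (mu, sig) in cells for c in _COLORS]
    reps = design.trials_per_block // len(combos)

    rows_mean_level: List[str] = []
    rows_var_level: List[str] = []
    rows_color: List[str] = []
    blocks: List[int] = []
    mus = np.empty(design.n_trials)
    sigmas = np.empty(design.n_trials)

    i = 0
    for b in range(design.n_blocks):
        order = rng.permutation(len(combos) * reps)
        for j in order:
            m, v, mu, sig, color = combos[j % len(combos)]
            rows_mean_level.append(m)
            rows_var_level.append(v)
            rows_color.append(color)
            blocks.append(b + 1)
            mus[i] = mu if color == "red" else -mu
            sigmas[i] = sig
            i += 1

    # exact moment control: the realized sample mean/SD equal mu/sigma,
    # so drift is deterministic per cell
    sample_mean = mus
    sample_sd = sigmas
    drift, noise = drift_and_noise(sample_mean, sample_sd, params)

    sign, dtime, _runaway = _ddm_batch(drift, noise, params.boundary, rng)
    rt = dtime + params.ter + params.encoding_time_slope * sample_sd
    choice = np.where(sign > 0, "red", "blue")
    accuracy = (choice == np.asarray(rows_color)).astype(int)
    miss = rt > design.deadline

    conf = generate_confidence(
        sign,
        drift,
        noise,
        params,
        np.asarray(rows_mean_level),
        np.asarray(rows_var_level),
        rng,
    ).astype(float)
    conf[miss] = np.nan

    return pd.DataFrame(
        {
            "participant": participant,
            "block": blocks,
            "mean_level": rows_mean_level,
            "variance_level": rows_var_level,
            "color": rows_color,
            "sample_mean": sample_mean,
            "sample_sd": sample_sd,
            "choice": choice,
            "accuracy": accuracy,
            "rt": rt,
            "confidence": conf,
            "miss": miss,
        },
        columns=TRIAL_COLUMNS,
    )


@dataclass(frozen=True)
class CohortHeterogeneity:
    """Between-participant variability of the observer parameters.

    Perceptual sensitivity (``drift_gain``) and metacognitive noise vary
    log-normally; the criterion grid receives a shared Gaussian shift
    (trait over-/underconfidence); and each participant draws their own
    readout shifts around the cohort-level values — individual
    differences in how strongly evidence reliability and the hard-easy
    effect act on their confidence scale use.  Defaults are sized so a
    20-participant cohort produces group-level statistics on the scale
    typical of confidence experiments (second-order t values in the low
    single digits, A_ROC spread of several hundredths).
    """

    drift_gain_cv: float = 0.12
    criterion_shift_sd: float = 0.03
    metacog_noise_cv: float = 0.30
    shift_highvar_sd: float = 0.01
    shift_lowmean_sd: float = 0.03


def variance_readout_observer(base: ObserverParams | None = None) -> ObserverParams:
    """Observer whose readout is down-shifted by unreliable evidence.

    High stimulus variance lowers expressed confidence beyond what the
    internal certainty signal warrants (``readout_shift_highvar`` < 0);
    evidence strength leaves the readout untouched.
    """
    return replace(base or ObserverParams(), readout_shift_highvar=-0.022)


def hard_easy_observer(base: ObserverParams | None = None) -> ObserverParams:
    """Observer with a hard-easy readout bias.

    Weak-evidence (low mean) conditions are rated with relatively higher
    confidence than objective accuracy warrants — the classic relative
    overconfidence on difficult conditions (``readout_shift_lowmean`` > 0).
    """
    return replace(base or ObserverParams(), readout_shift_lowmean=0.04)


def simulate_experiment(
    n_participants: int,
    design: DesignSpec,
    params: ObserverParams,
    rng: np.random.Generator,
    heterogeneity: CohortHeterogeneity | None = None,
) -> pd.DataFrame:
    """Simulate a cohort; each participant is a draw from the population.

    ``params`` gives the population-level observer; per-participant
    parameters are sampled around it according to ``heterogeneity``
    (pass ``CohortHeterogeneity`` with zeros for identical observers).
    """
    het = heterogeneity if heterogeneity is not None else CohortHeterogeneity()
    tables = []
    for p in range(1, n_participants + 1):
        gain = params.drift_gain * math.exp(
            rng.normal(0.0, het.drift_gain_cv) - 0.5 * het.drift_gain_cv**2
        )
        shift = rng.normal(0.0, het.criterion_shift_sd)
        crit = tuple(c + shift for c in params.confidence_criteria)
        meta = params.metacog_noise * math.exp(
            rng.normal(0.0, het.metacog_noise_cv) - 0.5 * het.metacog_noise_cv**2
        )
        indiv = replace(
            params,
            drift_gain=gain,
            confidence_criteria=crit,
            metacog_noise=meta,
            readout_shift_highvar=rng.normal(
                params.readout_shift_highvar, het.shift_highvar_sd
            ),
            readout_shift_lowmean=rng.normal(
                params.readout_shift_lowmean, het.shift_lowmean_sd
            ),
        )
        tables.append(simulate_session(design, indiv, rng, participant=p))
    return pd.concat(tables, ignore_index=True)


# ---------------------------------------------------------------------------
# difficulty matching


def _cell_efficiency(
    design: DesignSpec,
    params: ObserverParams,
    mu: float,
    sigma: float,
    n_trials: int,
    rng: np.random.Generator,
) -> float:
    """Simulated efficiency (median correct RT / accuracy) of one cell."""
    drift, noise = drift_and_noise(
        np.full(n_trials, mu), np.full(n_trials, sigma), params
    )
    sign, dtime, _ = _ddm_batch(drift, noise, params.boundary, rng)
    rt = dtime + params.ter + params.encoding_time_slope * sigma
    keep = rt <= design.deadline
    correct = (sign > 0) & keep
    acc = correct.sum() / max(keep.sum(), 1)
    if acc == 0 or not correct.any():
        return math.inf
    return float(np.median(rt[correct]) / acc)


def staircase_match(
    design: DesignSpec,
    params: ObserverParams,
    rng: np.random.Generator,
    tolerance: float = 0.02,
    n_assess: int = 4000,
    max_iter: int = 25,
) -> Tuple[float, float, List[dict]]:
    """Adjust the weak-evidence mean so the two medium cells match in difficulty.

    Difficulty is the efficiency score (median correct RT / accuracy).
    The low-mean magnitude is moved by bisection — simulated accuracy is
    monotone increasing in mu, hence efficiency is monotone decreasing —
    until the relative efficiency difference between the
    (high mean, high variance) and (low mean, low variance) cells falls
    below ``tolerance``.  Returns ``(mu_low, sigma_high, trace)``.
    """
    mu_hi, sig_hi = design.conditions[("high", "high")]
    mu_lo, sig_lo = design.conditions[("low", "low")]
    target = _cell_efficiency(design, params, mu_hi, sig_hi, n_assess, rng)

    lo, hi = mu_lo * 0.25, mu_hi  # bracket: harder ... easier
    trace: List[dict] = []
    mu = mu_lo
    for it in range(max_iter):
        eff = _cell_efficiency(design, params, mu, sig_lo, n_assess, rng)
        rel = abs(eff - target) / ((eff + target) / 2.0)
        trace.append(
            {"iteration": it, "mu_low": mu, "efficiency": eff, "target": target,
             "rel_diff": rel}
        )
        if rel < tolerance:
            return mu, sig_hi, trace
        if eff > target:  # low cell too hard -> move mean away from boundary
            lo = mu
        else:
            hi = mu
        mu = 0.5 * (lo + hi)
    raise RuntimeError(
        f"staircase failed to converge within {max_iter} iterations; trace: {trace}"
    )


def drift_matched_design(
    design: DesignSpec, params: ObserverParams
) -> DesignSpec:
    """Design whose two medium cells have identical drift by construction.

    The low-mean magnitude is set analytically so that the
    reliability-weighted drift of the (low mean, low variance) cell
    equals that of the (high mean, high variance) cell:

        mu_low = mu_high * (1 + lambda*sigma_low) / (1 + lambda*sigma_high)

    This matches the medium cells exactly in accuracy and decision time
    (any residual RT difference is the variance-dependent encoding cost),
    the idealized limit of an adaptive difficulty-matching procedure.
    The matched magnitude is applied to both low-mean cells.
    """
    mu_hi, sig_hi = design.conditions[("high", "high")]
    _mu, sig_lo = design.conditions[("low", "low")]
    lam = params.variance_coupling
    mu_lo = mu_hi * (1.0 + lam * sig_lo) / (1.0 + lam * sig_hi)
    conditions = dict(design.conditions)
    for key, (_m, sig) in list(conditions.items()):
        if key[0] == "low":
            conditions[key] = (mu_lo, sig)
    return replace(design, conditions=conditions)


def matched_design(
    design: DesignSpec,
    params: ObserverParams,
    rng: np.random.Generator,
    tolerance: float = 0.02,
    n_assess: int = 4000,
) -> DesignSpec:
    """Design with the low-mean level recalibrated by the staircase.

    The matched low-mean magnitude is applied to *both* low-mean cells so
    the factorial structure is preserved; the two medium cells then agree
    in efficiency to within ``tolerance``, mirroring the pre-experiment
    difficulty matching of adaptive psychophysics sessions.
    """
    mu_lo, _sig_hi, _trace = staircase_match(
        design, params, rng, tolerance=tolerance, n_assess=n_assess
    )
    conditions = dict(design.conditions)
    for key, (_mu, sig) in list(conditions.items()):
        if key[0] == "low":
            conditions[key] = (mu_lo, sig)
    return replace(design, conditions=conditions)
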