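"""Maximum-likelihood meta-d': SDT-ideal sensitivity implied by ratings.

meta-d' asks: what first-order sensitivity would an SDT-ideal observer
need in order to produce the observed *confidence-rating* data?  It is
expressed on the same scale as d', so meta-d' = d' means the ratings use
all the information in the decision variable, and meta-d' < d' means
metacognition is lossy.  Unlike A_ROC, the comparison is valid across
conditions that differ in first-order accuracy.

Model: equal-variance Gaussian SDT with stimulus distributions
N(-d/2, 1) and N(+d/2, 1) and type-1 criterion c.  The meta level
replicates this geometry at sensitivity meta-d', holding the *relative*
type-1 criterion fixed (meta-c = c * meta-d'/d'), and fits
response-conditional type-2 criteria (5 below meta-c for one response,
5 above for the other) to the rating counts by maximum likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy import optimize
from scipy.stats import norm

__all__ = ["MetaDFit", "meta_d", "type1_sdt"]

N_RATINGS = 6
_PAD = 1.0 / (2 * N_RATINGS)  # cell padding; ML degenerates on empty cells


@dataclass(frozen=True)
class MetaDFit:
    d_prime: float
    meta_d_prime: float
    criterion: float
    meta_criterion: float
    log_likelihood: float
    converged: bool


def _padded(counts: Dict[Tuple[str, str], np.ndarray]) -> Dict[Tuple[str, str], np.ndarray]:
    out = {}
    for s in ("red", "blue"):
        for r in ("red", "blue"):
            key = (s, r)
            if key not in counts:
                raise ValueError(f"missing stimulus x response cell {key}")
            arr = np.asarray(counts[key], dtype=float)
            if arr.shape != (N_RATINGS,):
                raise ValueError(f"cell {key} must hold {N_RATINGS} rating counts")
            out[key] = arr + _PAD
    return out


def type1_sdt(counts: Dict[Tuple[str, str], np.ndarray]) -> Tuple[float, float]:
    """First-order (d', c) from padded stimulus x response totals.

    "red" responses to "red" stimuli are hits; "red" responses to "blue"
    stimuli are false alarms.
    """
    c = _padded(counts)
    n_red = c[("red", "red")].sum() + c[("red", "blue")].sum()
    n_blue = c[("blue", "red")].sum() + c[("blue", "blue")].sum()
    hr = c[("red", "red")].sum() / n_red
    far = c[("blue", "red")].sum() / n_blue
    d = norm.ppf(hr) - norm.ppf(far)
    crit = -0.5 * (norm.ppf(hr) + norm.ppf(far))
    return float(d), float(crit)


def _rating_probs(meta_dp: float, meta_c: float, t2c_lo: np.ndarray, t2c_hi: np.ndarray):
    """P(rating | stimulus, response) under the meta-level SDT model.

    ``t2c_lo`` are the 5 type-2 criteria below meta-c (response "blue",
    descending confidence as x rises toward meta-c); ``t2c_hi`` the 5
    above (response "red").  Returns dict (stim, resp) -> 6 probs.
    """
    edges_red = np.concatenate(([meta_c], t2c_hi, [np.inf]))       # ratings 1..6
    edges_blue = np.concatenate(([-np.inf], t2c_lo[::-1], [meta_c]))  # ratings 6..1
    probs = {}
    for s, mu in (("red", meta_dp / 2.0), ("blue", -meta_dp / 2.0)):
        cdf_red = norm.cdf(edges_red, loc=mu)
        p_red = np.diff(cdf_red)
        p_red = p_red / max(p_red.sum(), 1e-300)
        cdf_blue = norm.cdf(edges_blue, loc=mu)
        p_blue = np.diff(cdf_blue)[::-1]  # reorder to ratings 1..6
        p_blue = p_blue / max(p_blue.sum(), 1e-300)
        probs[(s, "red")] = p_red
        probs[(s, "blue")] = p_blue
    return probs


def _neg_log_lik(theta: np.ndarray, counts, c_rel: float) -> float:
    meta_dp = theta[0]
    meta_c = c_rel * meta_dp
    t2c_lo = meta_c - np.cumsum(np.exp(theta[1:6]))
    t2c_hi = meta_c + np.cumsum(np.exp(theta[6:11]))
    probs = _rating_probs(meta_dp, meta_c, t2c_lo, t2c_hi)
    ll = 0.0
    for key, n in counts.items():
        p = np.clip(probs[key], 1e-12, None)
        ll += float(np.dot(n, np.log(p)))
    return -ll


def meta_d(
    counts: Dict[Tuple[str, str], np.ndarray],
    full: bool = False,
) -> Tuple[float, float] | MetaDFit:
    """Fit meta-d' to stimulus x response x rating counts.

    Returns ``(d_prime, meta_d_prime)`` or, with ``full=True``, a
    :class:`MetaDFit` with criteria and likelihood diagnostics.  The
    type-1 criterion is held at its observed *relative* position
    (c' = c/d') while meta-d' and the ten response-conditional type-2
    criteria are free.
    """
    padded = _padded(counts)
    d, crit = type1_sdt(counts)
    if not np.isfinite(d) or abs(d) < 1e-8:
        raise ValueError("type-1 d' is degenerate; meta-d' undefined")
    c_rel = crit / d

    # moment-based starting criteria: spread either side of meta-c
    x0 = np.concatenate(([d], np.full(10, np.log(0.4))))
    best = None
    for scale in (1.0, 0.5, 2.0):  # restart ladder for robustness
        start = x0.copy()
        start[0] = d * scale
        res = optimize.minimize(
            _neg_log_lik,
            start,
            args=(padded, c_rel),
            method="Nelder-Mead",
            options={"maxiter": 20_000, "xatol": 1e-6, "fatol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("meta-d' fit failed to converge")
    fit = MetaDFit(
        d_prime=d,
        meta_d_prime=float(best.x[0]),
        criterion=crit,
        meta_criterion=float(c_rel * best.x[0]),
        log_likelihood=-float(best.fun),
        converged=bool(best.success),
    )
    if not fit.converged and not np.isfinite(fit.log_likelihood):
        raise RuntimeError(f"meta-d' fit failed: {best.message}")
    return fit if full else (fit.d_prime, fit.meta_d_prime)
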