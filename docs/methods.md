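# Methods

This note documents the generative model, the analysis definitions, the
default parameter values and the reasoning behind the open design choices.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Generative observer

**Stimuli.** A trial is 8 scalar evidence samples on a signed axis
(boundary at 0, positive = "red"). Samples are drawn normal and then
affine-corrected so the sample mean equals ±μ and the sample SD (ddof = 1)
equals σ exactly (|error| < 1e−12). Exact moment control is the strictest
reading of a tightly controlled psychophysics display, and it makes the
per-cell drift deterministic, which the closed-form calibration below
exploits. Real displays have residual sample-to-sample moment jitter that
this idealization removes; a consequence is that within-cell variability in
the simulation comes only from the diffusion noise and the readout, not
from the stimulus.

**Decision stage.** Evidence accumulates as a drift-diffusion process with
unbiased start, boundary separation *a* (absorbing boundaries ±a/2),
Euler–Maruyama steps of dt = 1 ms, and momentary noise
s = 0.1/√1000 per √ms (the conventional s = 0.1 of the seconds-based
literature; trials that fail to absorb within 10 s are forced to the nearer
boundary and end up flagged as misses). Drift is *reliability-weighted*:

    v = k · (sample mean) / (1 + λ · sample SD)

An alternative coupling — constant drift with momentary noise scaled up by
the sample SD — was implemented first and rejected: added momentary noise
*accelerates* absorption, so high-variance decisions came out faster than
low-variance ones, the efficiency-based difficulty matching degenerated
(the matched low-mean magnitude collapsed onto the high-mean value), and
the canonical orderings could not be reproduced. Drift attenuation is also
the form suggested by reliability-weighted integration accounts of
perceptual averaging: unreliable evidence is down-weighted, making
decisions slower *and* less accurate.

Non-decision time is Ter + (encoding-time slope)·(sample SD): encoding a
heterogeneous array takes longer. This gives high-variance cells an RT
cost not mirrored in accuracy — the speed–accuracy dissociation typically
observed between difficulty-matched cells — and it is what lets the
regression stage separate RT from accuracy as predictors.

**Confidence stage.** After the decision, accumulation continues freely
for τ = 600 ms (the response-to-scale interval). Experienced certainty is

    ξ = a/2 + (choice sign)·(post-decision increment) + N(0, σ_meta²)
        + δ_mean·1[mean level = low] + δ_var·1[variance level = high]

and the rating is 1 + #criteria strictly below ξ, with five fixed criteria.
The condition shifts δ act at the readout only — they relabel the same
internal signal — so they move metacognitive bias (B_ROC) without
changing sensitivity (A_ROC). Misses (RT > 1500 ms) carry no rating and
are excluded from every analysis.

**Defaults.** k = 1.262e−3 /ms, a = 0.14, Ter = 290 ms, encoding slope
200 ms per evidence unit, λ = 4, σ_meta = 0.10, criteria
(−0.03, 0.03, 0.09, 0.15, 0.21); condition moments μ ∈ {0.200, 0.118},
σ ∈ {0.05, 0.20}. These were calibrated once, analytically via
P(correct) = 1/(1+exp(−v·a/s²)) and mean decision time (a/2v)·tanh(va/2s²),
so that the four cells land near the canonical difficulty bands (error
rates ≈ 5/12/14/23 %, mean RTs ≈ 600/660/690/740 ms) — fixture-like
values, not empirical claims. The encoding slope is sized so the two
medium cells differ by ≈ 30 ms at matched drift.

**Difficulty matching.** Two routes are provided. `staircase_match`
bisects the low-mean magnitude until the simulated efficiency
(median correct RT / accuracy) of the two medium cells agrees to
tolerance, returning the convergence trace — the simulation analogue of an
adaptive pre-experiment staircase (the exact step rule of such procedures
varies; only the matching target is contractual here).
`drift_matched_design` instead sets μ_low = μ_high·(1+λσ_low)/(1+λσ_high)
analytically, equalizing the medium cells' drift — the idealized limit of
matching, used by the recovery study because it leaves no residual
systematic accuracy or A_ROC gap between the cells.

**Cohorts.** `simulate_experiment` draws each participant from a
population: log-normal jitter on drift gain (CV 0.12) and readout noise
(CV 0.30), a shared Gaussian shift of the criterion grid (SD 0.03, trait
over-/underconfidence), and Gaussian jitter of both readout shifts
(SD 0.01 for δ_var, SD 0.03 for δ_mean — individual differences in
hard–easy susceptibility). Magnitudes were chosen once so that a
20-participant cohort produces second-order statistics on the scale such
experiments report (second-order t values in the low single digits rather
than the 30s that identical observers would give). Named configurations:
`variance_readout_observer` (δ_var = −0.022, δ_mean = 0) and
`hard_easy_observer` (δ_mean = +0.04, δ_var = 0).

## Analysis definitions

**Type II ROC.** Operating points cumulate from the "certainly correct"
end: for criterion c = 7…1, H = P(conf ≥ c | correct),
F = P(conf ≥ c | error); empty rating bins are kept as zero-width steps so
the curve always has 7 points. A_ROC is the trapezoidal area. B_ROC
defaults to a Grier-type B″ at the scale midpoint (conf ≥ 4):
B = [F(1−F) − H(1−H)] / [F(1−F) + H(1−H)], signed so that blanket high
confidence → +1; a degenerate denominator returns sign(H+F−1). The bias
formula is pluggable (`b_roc(counts, formula=...)`) because several
distribution-free bias definitions circulate; the default preserves the
ordering claims the pipeline tests. A_ROC and B_ROC are computed per
participant × difficulty cell, pooling colors.

**meta-d′.** Equal-variance Gaussian SDT; d′ and c from the padded
stimulus × response totals (padding 1/12 per cell), meta-c held at the
observed relative criterion (meta-c = c·meta-d′/d′), meta-d′ and ten
response-conditional type-2 criteria fitted by maximum likelihood
(Nelder–Mead with a restart ladder; criteria parameterized as ordered
cumulative offsets so monotonicity is structural).

**EZ-diffusion.** Standard closed forms under s = 0.1: logit accuracy
L = va/s² gives Pc; mean decision time (a/2v)(1−e^y)/(1+e^y), y = −va/s²;
correct-RT variance (as²/2v³)(2ye^y − e^{2y} + 1)/(e^y+1)². The fit
inverts these exactly; accuracy is edge-corrected to
[1/(2n), 1−1/(2n)] and an exact 0.5 is nudged by 1/(2n) before inversion.
RTs are handled in ms at the interface, seconds internally.

**Condition regressions.** Outcome: mean confidence per cell (correct and
error trials pooled), 8 cells per participant. Predictors: accuracy as
continuity-corrected log-odds error, (x+0.5)/(n+1), sign-flipped so a
positive beta reads "more accurate → more confident"; mean correct RT;
mean and variance levels contrast-coded −1/+1 (high = +1). All variables
z-scored within participant (an intercept is kept; on standardized data it
is ≈ 0; color enters through the 8-cell structure only). Models:
M0 {acc}, M1 {acc, RT}, M2a {+mean}, M2b {+variance}, M3 {all four}.
BIC = n·ln(1−R²) + k·ln(n) with k the predictor count excluding the
intercept — the variant whose magnitudes are consistent with per-model
means at n = 8. Second-order inference: one-sample t of betas, paired t of
BICs.

**ANOVA.** 2×2 within-participants, each effect tested against its own
participant-by-effect error term; for two-level factors F(1, n−1) equals
the squared one-sample t of the per-participant contrast and
η_p² = F/(F+n−1).

**Median split.** Participants are ranked by |correct-RT difference
between the medium cells|; the ⌈n/2⌉ smallest form the "minimal RT
difference" subgroup (ties broken by stable participant order), and the
medium-cell confidence contrasts are re-run on it.

**Bayes factors.** BF10 for a one-sample/paired t: Cauchy(0, r) prior on
effect size written as a normal–inverse-gamma mixture, marginal likelihood
integrated over the mixing variance by adaptive quadrature (relative error
well under 1e−6); r defaults to √2⁄2, n = df + 1. Labels: <3 "not worth
more than a bare mention", 3–20 "positive", 20–150 "strong", >150 "very
strong".

## The recovery study and its interpretation

The headline analysis asks whether a variance-sensitive readout shift is
recoverable from cohort data as (a) lower confidence in the
unreliable-evidence medium cell on correct and error trials, (b) a
reliable negative variance beta in M2b with no reliable mean beta in M2a,
and (c) a B_ROC difference between the matched cells without an A_ROC
difference.

One structural fact matters for (b): across the 8 cells, accuracy and RT
are functions of the same drift, which is itself a function of the mean
and variance codes. Conditional on the performance predictors, the two
condition codes are therefore substantially collinear, and a
variance-specific effect leaks roughly half its weight onto the mean beta.
"Variance beta significant, mean beta not" is consequently a
*window* property — it holds when the variance effect is strong enough to
detect but not so strong that its leak also reaches significance — and any
single 20-participant cohort sits stochastically within that window. The
recovery study therefore runs three replicate cohorts and reports the
median second-order statistic: a variance-reduction device, with every
cohort at the full design size. The encoding-time RT component is what
keeps the leak modest, by giving RT variance-specific information that
absorbs part of the omitted-variable effect.

## What the simulator does and does not establish

The generator reproduces the statistical structure the analyses assume —
factorial difficulty, matched medium cells, post-decisional confidence
with readout shifts, realistic cohort heterogeneity. Passing tests show
the *pipeline* recovers known ground truth under that structure. They do
not show that human confidence is generated this way: the simulator omits,
among other things, sequential and learning effects, lapses, RT-dependent
confidence heuristics, stimulus-moment jitter, and any interaction between
color category and difficulty. Quantities that depend on idiosyncrasies
of a human sample (exact cell statistics, printed F values and betas) are
out of scope by construction.

## Numerical choices and degenerate inputs

Euler dt = 1 ms introduces a small first-passage discretization bias
(accuracy inflated by ≈ 0.003 at Pc ≈ 0.95); oracle comparisons against
closed forms use dt = 0.1 ms where the bias is below Monte-Carlo noise at
the sample sizes used. σ = 0 stimuli, single-patch stimuli, empty
accuracy classes, constant predictors, zero-variance second-order inputs,
and missing design cells raise informative errors rather than propagate
NaNs. A rating exactly at a criterion goes to the lower category (strict
inequality). Runaway diffusion trials are capped at 10 s and surface as
misses. The rating scale is fixed at six categories; counts tables are
validated for shape and non-negativity on construction.

## Problem sizes

Default test and acceptance runs use: 1024-trial sessions; 10⁵ trials for
the independence (A_ROC = 0.5) and meta-d′ fidelity checks; 100 parameter
triples for the EZ round trip; and 3 × (20 × 1024) cohort replicates per
observer variant for the recovery study — sizes at which every targeted
effect is comfortably resolved while a full run of suite plus acceptance
script completes in a few minutes.
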