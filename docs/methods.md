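# Methods

## The model

Per-repetition performance is the composite score
`90 − 0.3·time_s + 0.5·edge`, which maps the rubric-feasible domain (time
0–300 s, edge 0–20) exactly onto [0, 100]. Flesh score and perforations
never enter the composite; they appear only inside candidate "accuracy"
features when the score itself is validated.

The learning curve of subject *i* on device *d* is modeled as

    y_idt = f(t; P0_d, A_d + a_i, r_d + ρ_i, c_d) + ε_idt

with trial number *t* = 1…20 counted within device (it resets at
crossover), `f` one of seven saturating curves, per-subject Gaussian
deviations `a_i ~ N(0, σ_A²)` on the plateau and `ρ_i ~ N(0, σ_r²)` on the
rate (independent, shared across the subject's two device phases), and
i.i.d. Gaussian residuals. Fixed effects for the plateau `A` and rate `r`
are device-specific; the initial level `P0` and shape `c` are pooled across
devices by default (both can be freed via `shared=`). Random effects are
placed on `A` and `r` because those are the two coefficients the analysis
reports and compares; deviations on `P0`/`c` are absorbed into the residual.

### The curve menu

All seven forms satisfy `f(t) → A` as `t → ∞` and are non-decreasing in `t`
when `A ≥ P0`. The rate is parameterized on an unconstrained log scale so a
reported "learning rate" can be negative; larger `r` always means faster
approach to the plateau. The modified Weibull
`A + (P0 − A)·exp(−(t·e^r)^c)` is the flagged default. The other forms:
exponential `A + (P0 − A)·e^(−e^r t)`; power `A − (A − P0)·t^(−e^r)`;
hyperbolic `P0 + (A − P0)·t/(t + e^(−r))`; logistic and Gompertz as
standard sigmoid forms offset to start near `P0` (their fourth parameter is
a midpoint/displacement, kept positive); Weibull
`A + (P0 − A)·exp(−e^r·t^c)`, which differs from the modified Weibull only
in bookkeeping (the rate is not raised to the shape power) and reduces to
the exponential at `c = 1`. The three-parameter members and the `c = 1`
Weibulls are concave from the first trial (strictly shrinking increments);
the four-parameter members with `c > 1` are sigmoidal, with an early
acceleration phase before saturation — the fitted shape decides which
regime the data favor.

## Estimation

The marginal likelihood integrates the two random effects per subject. We
maximize its Laplace approximation: for each subject the joint negative log
density `q(u)` is minimized over `u = (a, ρ)` by a damped Newton iteration
(vectorized across subjects, warm-started between objective evaluations;
Gauss-Newton curvature for the steps, a central-difference Hessian of the
gradient for the Laplace determinant), and

    log L_i ≈ −q(û) + log 2π − ½ log det q''(û).

The outer optimization over fixed effects and log-scale standard deviations
uses L-BFGS-B with bound constraints (`c ∈ [10⁻³, 20]`, `r ∈ [−20, 20]`,
SDs ≥ 10⁻⁴), followed by a refinement pass with a finer finite-difference
step — this matters in the degenerate noise-free limit, where the surface
becomes arbitrarily steep as the residual SD approaches its floor.

Multistart: start 1 uses data-driven values (`P0` = mean first-trial score,
`A` = mean of the last three trials, `r = 0`, `c = 1`, SDs from the data);
start 2 (when `n_starts ≥ 2`) pins the random-effect SDs near zero so
boundary (singular) solutions are reachable; further starts jitter start 1
with fixed sub-seeds. The best log-likelihood wins. A random-effect SD
estimated below 10⁻² is treated as singular and the model is refitted with
that effect pinned at zero, noted on the fit.

Standard errors come from the observed information (central-difference
Hessian of the marginal log-likelihood over all parameters, inverted).
Degrees of freedom for coefficient t statistics use the containment
heuristic `n_subjects − n_fixed` (11 at the study design with the default
layout); no closed-form df exists for this model class and the heuristic is
deliberately conservative.

## Noninferiority

With reference (microscope) coefficient estimate `θ̂_ref` and new-device
estimate `θ̂_new`, the margin is `m = 0.2·|θ̂_ref|` (20% set a priori) and

    t = (θ̂_new − θ̂_ref + m) / √(SE_ref² + SE_new²)

is referred to the upper tail of Student's t at the coefficient df; p < α
(0.05) declares noninferiority. Lower is worse for both coefficients: a
lower plateau is poorer settled performance, a lower rate slower learning
under our parameterization; the test compares signed rates. The two device
estimates are treated as independent because the procedure consumes the
reported (estimate, SE, df) triples rather than a joint covariance; this is
slightly conservative when the estimates are positively correlated through
shared subjects.

The crossover analysis takes the final five trials of each phase (settled
performance; the first five post-crossover trials are available via
`settled_phase2=False`) and fits a linear mixed model with phase, starting-
device group, and their interaction as fixed effects and a random intercept
per subject (ML). Wald F statistics use containment denominators:
`n_subjects − 2` for the between-subject group effect, observations minus
subjects minus 2 for within-subject terms.

The TLX analysis is a classical mixed-design two-way ANOVA (device within
subject, group between; computed via pingouin), with Benjamini–Hochberg
adjustment across the seven responses within each effect. Zero-variance
tables are resolved explicitly (F = 0 when the effect sum of squares is
zero, F = ∞ when only the residual is zero) instead of 0/0.

## Score validation choices

- "Absolute novice" = first five attempts of phase 1 per novice; "absolute
  expert" = final five attempts per expert; discrimination is per-attempt.
- The "accuracy" candidate feature is `edge + flesh − perforations`,
  min-max rescaled (logistic discrimination is invariant to the affine
  rescale); it is isolated behind `ScoreModelSpec` and swappable.
- Outlier rule: 1.5×IQR fences on within-cohort median completion time.
- Expert threshold: Youden-optimal cutpoint (midpoint tie-break), reported
  raw and rounded to the nearest 5.

## The synthetic-data generator

`simulate_study` emulates the trial's structure: permuted blocked
randomization (blocks of 2 and 4) of 17 novices to a starting device, 20
trials per phase, 7 microscope-only experts, 820 repetitions in total. The
demonstration device truths use the published plateau and rate estimates
(A 64.89/65.93, r −0.94/−1.30 for exoscope/microscope) with `P0 = 25` (a
realistic first-attempt level well below the expert threshold) and
`c = 1.5` (mildly sigmoidal early learning); between-subject SDs default to
8 score points on the plateau and 0.25 on the log rate, residual SD 10
points, expert scores ~N(75, 8²) truncated to the scale. TLX domain means
(10.2 exoscope / 8.8 microscope, SD 3.5) put total workload medians near
the published 61/53.

Scores are generated as curve-plus-Gaussian noise clipped to [0, 100] and
then back-filled into rubric items by inverting the composite formula: the
edge score is drawn uniformly from the feasible integer set given the score
and the completeness cap, the time follows exactly (rounded to 0.1 s, hence
the 0.15-point round-trip tolerance), flesh tracks the score tertile, and
perforations are Poisson with mean `2(1 − score/100)`. Completion is
Bernoulli with probability increasing in the score, forced for scores above
95 where the no-star edge cap is infeasible. Experts are flat (no learning)
by design — their role is anchoring the score scale, not the curve.

What the generator does **not** emulate: rater disagreement, grape-to-grape
physical variability, fatigue or session effects, non-Gaussian or
autocorrelated residuals, and dropout. Passing tests therefore demonstrate
that the pipeline recovers the truth under its own model assumptions at the
study's size — not that those assumptions hold for the real cohort, whose
raw data are not deposited and whose published estimates are used here only
as simulation presets, never as recovery targets.

## Problem sizes used by the test suite

Calibration checks run at the study design (17 novices × 20 trials × 2
devices): 200 replicates for the 95% CI coverage of the plateau fixed
effect (single data-driven start per fit), 100 replicates for AIC selection
of the generating curve (shape 2) against the exponential, and 2,000
analytic-SE draws for the type-I error of the noninferiority test at the
margin, where the difference estimate carries Gaussian noise and its SE is
drawn from the scaled-chi-square sampling model at the fitted df (the
classical setup under which the one-tailed t test is exactly calibrated).
Oracle-equivalence checks (Laplace vs adaptive quadrature, logistic vs grid
search, ANOVA vs cell-means decomposition, BH vs step-up arithmetic) use
2–3-subject or 8-observation instances where the independent oracle is
itself exact.

## Known limitations

- Laplace (not adaptive quadrature) for the full fit: accurate here because
  the plateau enters the conditional mean linearly and rate deviations are
  moderate, but it can bias variance components when clusters are tiny.
- The AIC counts the boundary-pinned random-effect SD as an estimated
  parameter like any other; no boundary correction is applied.
- CI coverage relies on the containment df heuristic; alternatives
  (Satterthwaite, Kenward-Roger) are not implemented for this nonlinear
  model class.
- Score clipping at 0 and 100 truncates the residual distribution near the
  scale ends; with the default preset the plateau sits near 65, so the
  effect on fitted coefficients is negligible but grows if truths are moved
  toward the boundaries.
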