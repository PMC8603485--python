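# Methods

## The sequential design engine

The design treats the interim and final analyses as a bivariate problem in the
canonical group-sequential formulation: at information fractions
t₁ = 0.5 and t₂ = 1 the standardized statistics Z₁, Z₂ are jointly Gaussian
with Corr(Z₁, Z₂) = √(t₁/t₂) and E[Z_k] = Δ√t_k, where Δ = θ√n_max is the
drift at full information and θ the per-√n one-sample effect. Efficacy
boundaries spend the one-sided α = 0.025 under the null according to the
Hwang–Shih–DeCani schedule with γ = −4; futility boundaries spend β = 0.2
under the alternative with γ = −2. The futility bound is binding: the
continuation region used in the α recursion is truncated below it, which is
what lets the final efficacy bound sit slightly below Φ⁻¹(0.975).

Crossing probabilities are computed by the recursive sub-density method
(Armitage–McPherson–Rowe): the stage-1 density restricted to the continuation
interval is propagated through the Gaussian increment kernel on a trapezoid
grid. Numerical choices:

* grid: 601 nodes on each continuation interval (well past the point where
  results are stable to 10⁻⁶; a convergence test against 10⁶ Monte-Carlo
  draws is part of the suite);
* root-finding: Brent's method, tolerance 10⁻⁶ on probabilities and bounds;
* the drift Δ is root-found so that the final efficacy and futility bounds
  coincide (the standard closure: all of β is spent by the final stage, making
  total power exactly 1 − β); configurations where a spending increment is
  unattainable are treated as over-powered drifts during bracketing;
* the HSD spending function switches to its linear γ → 0 limit for
  |γ| < 10⁻⁵, keeping spending continuous in γ;
* per-group sample sizes are the rounded 16/32 of the published design; the
  solved continuous maximum (≈ 63.7 for n_fix = 62) is exposed as
  `n_max_continuous`.

The recursion is written for K stages generically but is validated only for
K ≤ 3; asymmetric multi-look designs beyond the two-stage pilot are out of
scope, as are binary/survival endpoints.

Two boundary parameterizations coexist deliberately. The solver's own bounds
(0.3993/2.7500 interim, 1.9609 final on the z scale) are what the error-
spending equations give; the published presentation rounds the interim bounds
to 0.40/2.75 and uses the fixed-design 1.96 at the final look, whose quantile
substitutions are 0.404/2.960/1.999. The operating-characteristics simulation
uses the latter triple so its estimates describe the procedure as actually
specified for the trial; both sets are available from `BoundarySet`.

Expected sample size is reported as N₁ + (N₂ − N₁)·P(continue) with the
rounded stage totals 32/64. With the continuous stage sizes the published
values (54.7 alternative, 42.8 null) are recovered almost exactly; with the
rounded totals the results are ~0.1–0.2 participants higher, well inside any
practical reading of the design.

## Operating-characteristics simulation

Each replicate draws unit-variance Gaussian outcomes with mean difference g
(32/group), computes the pooled-variance two-sample t on the first 16/group
at interim and on the full sample at final (stage-2 statistics accumulate the
stage-1 data rather than using an increment), and walks the decision tree.
Each replicate has its own RNG stream keyed by (seed, replicate index), so
enlarging the replicate count extends rather than reshuffles the set.
The published "one-sided type-I error at final analysis" of 0.024 is read as
the cumulative efficacy-claim probability across both analyses (its interim
component, 0.003, is reported separately, as is the final-only rate).

A normal-theory quadrature oracle cross-checks the simulation. One caution
discovered in testing and encoded there: quantile substitution equates the z-
and t-procedures under the null only. Under the alternative the normal
approximation to the interim noncentral-t success probability is off by about
0.04 at g = 0.714, so the alternative-drift cross-check uses the exact
noncentral-t distribution instead. No Welch variant or non-Gaussian outcome
simulation is provided.

## Endpoints

* Pill count: 100·(prescribed − remaining)/(days between dispensing and
  return). Late returns can exceed 100%; values are reported as computed and
  clamped to 100 only at the logit stage (the clamp is logged).
* MEMS on-schedule: events are reduced to the first opening per day
  (subsequent same-day openings are treated as curiosity openings), clock
  times are unwrapped around the daily median to avoid the midnight
  discontinuity, an ordinary least-squares line of time-of-day on day index
  gives the expected dosing time, and a scheduled day counts as adherent if an
  opening lies within ±6 h of the line, boundary inclusive (a 10⁻⁹ h guard
  absorbs floating-point ties). Days without openings are missed; fewer than
  two events yields 0% with a warning. The fit makes the measure invariant to
  a uniform shift of all dosing times.
* QIDS-SR: remission is score ≤ 5 (the threshold is a parameter, since
  "a score of 5" admits both readings); response is score ≤ ½·baseline.
* ITT: visits at or after the withdrawal week get both endpoints 0 and an
  `imputed` flag; after imputation every randomized participant has a record
  for every scheduled visit (20 participants × 3 visits = 60 rows).
* BMQ subscores are consumed as already-summed integers; item scoring and
  vendor MEMS file formats are out of scope.

## Synthetic trial generator

The generator is the package's stand-in for the undeposited clinical data and
is tuned to the *fitted* trial, not to an idealized one: logit-scale cell
means default to the posterior medians of the default-prior analysis
(placebo 2.69/2.56/2.54, MPH 2.75/1.96/1.53 at weeks 2/4/8 — about 94/93/93%
vs 94/88/82% adherence), random-intercept SD 0.75 and residual SD 0.6 logit
units (consistent with the reported credible-interval widths), QIDS
trajectories from the reported medians (week-8 change −8.77, MPH offsets
small), 4 of 20 participants withdrawing (weeks drawn from 3–7), and MEMS
dosing at a habitual time drawn from 07:00–22:00 with 1.5 h jitter — enough
spread for the ±6 h rule to be informative without saturating it. Dispensing
intervals are weeks 0→2, 2→4, 4→8 (14/14/28 days).

Adherence noise is Gaussian on the logit scale, matching the analysis model,
so parameter recovery is well-posed; pill counts are the *rounded*
deterministic consequence of the latent adherence probability, and MEMS doses
are daily Bernoulli draws from it. What the generator does **not** emulate:
beta-binomial overdispersion, informative dropout (withdrawal is independent
of adherence), digit preference in pill counts, device failures, or any
arm-imbalance in withdrawal risk. Passing recovery tests therefore show the
model recovers its own data-generating process measured through the endpoint
pipeline — including the discretization and boundary-censoring that pipeline
introduces — not that it is robust to misspecification.

Two quantifiable artefacts of realism are worth naming: rounding a 14-day
pill count quantizes adherence to ~7-point steps, and fully-adherent
intervals are boundary-censored by the logit shrink rule, which biases
high cells downward by ~0.1–0.2 logit units at the defaults. The recovery
contracts (95% CI coverage at n = 20; medians within 0.3 logit units at
n = 100) hold with these artefacts included. Recovery experiments disable
dropout, because ITT zero-imputation is a deliberate distortion of the
adherence scale rather than part of the generating truth; the ITT rule is
tested separately.

## The Bayesian mixed model

y_iw = x_iw'β + b_i + ε_iw with reference coding (placebo, earliest visit),
b_i ~ N(0, τ²), ε ~ N(0, σ²). Priors: β_j ~ N(m_j, s_j²) with defaults
m_j = 0 (intercept: sample mean of the outcome) and s_j = 2.5; σ ~ Exp(1);
τ² ~ Gamma(shape 1, scale 1). Autoscaling multiplies s_j by sd(y)/sd(x_j)
(intercept: by sd(y)) and divides the exponential rate by sd(y); it is the
documented contract of this package (the analogous feature in other software
is version-dependent). The informative-prior constructor maps an arm×week
adherence grid to cell means on the logit scale and then to reference-coded
coefficient means (double differences for the interactions), sets all s_j to
1 and disables autoscaling.

Sampling is Markov chain Monte Carlo tailored to this conjugate structure:

* β is drawn from its exact Gaussian full conditional with the random
  intercepts integrated out of the likelihood (block-diagonal Woodbury
  identity), which removes the intercept–random-effect coupling that slows
  plain Gibbs;
* σ and τ² are updated by univariate slice sampling on the log scale against
  the same marginal likelihood, again avoiding conditioning on b;
* b is then drawn exactly given everything else.

Four chains of 2000 sweeps (1000 warmup) give split R-hat ≤ 1.002 on the
synthetic fixtures (contract: ≤ 1.01, with warnings surfaced above 1.05); the
split R-hat implementation is cross-checked against arviz in the tests. With
the likelihood disabled the same interface returns exact independent prior
draws, used to verify prior calibration. Boundary percentages are shrunk
toward ½ by (p·(N−1) + 0.5)/N with N the scheduled doses of the interval
(a fixed-ε clamp is available). Missing visits simply drop out of the
likelihood — ITT zero-imputation happens upstream, as the trial specifies.
No multiplicity adjustment is applied across outcomes, and Bayes-factor model
comparison is out of scope.

One empirical property of the informative prior deserves note: because it
constrains the interactions as well as the treatment main effect, it is not
guaranteed to raise Pr(MPH > placebo) at *early* weeks on every dataset —
when the data demand a large week-8 interaction the constrained fit can
redistribute mass away from the main effect. At the week-8 contrast, the
trial's declared contrast of interest, the pro-MPH prior consistently raises
the exceedance probability, and that is the property the suite asserts.

## Problem sizes

The defaults used throughout the tests and scripts are the design's own
sizes: 10,000 operating-characteristic replicates, 20-participant trials for
coverage experiments (50 replications) and 100-participant trials for
accuracy experiments (20 replications), and 4 × 2000 MCMC iterations per fit.
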