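# gspilot

Design, simulation and Bayesian analysis tools for a two-arm medication-adherence
pilot trial: a placebo-controlled study of low-dose methylphenidate (MPH) added
to escitalopram in depressed outpatients, asking whether the stimulant helps
patients build the habit of taking their antidepressant.

The package is aimed at trial statisticians and methods researchers who want the
full computational chain of such a pilot — the group-sequential design engine,
its operating characteristics, the adherence endpoint definitions, and the
Bayesian longitudinal model — as tested, reusable code. Because participant-level
data from trials like this are rarely deposited, a synthetic-trial generator with
recorded ground truth stands in for the clinical dataset, which also makes the
model checkable by parameter recovery.

## What it computes

**Group-sequential design** (`gspilot.design`). A two-stage design with one
interim analysis at half the maximum sample size. Type-I error (two-sided
α = 0.05) and type-II error (β = 0.2) are allocated across the stages by
Hwang–Shih–DeCani spending functions,

    f(t; γ) = err · (1 − e^{−γt}) / (1 − e^{−γ}),

with γ = −4 for the efficacy bound and γ = −2 for the *binding* futility bound.
Boundaries are solved by the standard recursive numerical integration of the
sequential z-statistic's sub-density over the continuation region
(Corr(Z₁, Z₂) = √(t₁/t₂)), with the drift root-found so total power is 1 − β.
Because the trial analyses use two-sample t-tests, z-boundaries are converted to
the t scale by quantile substitution, t* = F⁻¹_ν(Φ(z)). The module also provides
the fixed-sample effect size θ = (z_{1−α/2} + z_{1−β})/√n_fix (Hedges' g = 2θ)
and pilot margin-of-error multipliers t_{df,0.975}·√(1/n₁ + 1/n₂).

**Operating characteristics** (`gspilot.ocsim`). Monte-Carlo simulation of the
two-stage procedure — pooled-variance t-tests on 16/group at interim and
32/group at final against the t-scale boundaries — giving futility-stop,
interim-success, overall type-I error and power, with an analytic quadrature
oracle for cross-checking.

**Endpoints** (`gspilot.endpoints`). Pill-count adherence
(100·(prescribed − remaining)/days), the MEMS ±6 h on-schedule rule with the
expected dosing time fitted by least squares to the participant's dosing
clock-times, QIDS-SR remission (≤ 5) and response (≥ 50% reduction), and the
intention-to-treat rule that scores withdrawn participants 0% adherent for the
rest of the schedule.

**Bayesian mixed model** (`gspilot.bayes`). Logit-scale adherence modeled as
treatment + visit + treatment×visit fixed effects with a per-participant random
intercept. Priors follow the weakly-informative default (N(0, 2.5²)
coefficients with sample-mean intercept centring, Exp(1) residual SD,
Gamma(1, 1) intercept variance, optional autoscaling) or an informative
construction that converts an arm×week adherence grid (96/90/82% MPH vs
90/79/66% placebo) into coefficient prior means. Sampling is by a collapsed
Gibbs/slice MCMC (4 chains × 2000 iterations, 1000 warmup) with split R-hat
convergence checks; summaries include estimated marginal means and
Pr(MPH > placebo) per week.

**Synthetic trials** (`gspilot.generate`), and a **pipeline/CLI**
(`gspilot.pipeline`, `gspilot` console command) that chains
design → simulate → generate → endpoints → fit → report with per-stage seeds
and a checksummed run manifest.

## Worked example

```python
from gspilot import DesignSpec, solve_boundaries, design_report
spec = DesignSpec()                     # the pilot design
print(design_report(spec, solve_boundaries(spec)))
```

```
stage  info  n/grp  z_fut   z_eff   t_fut   t_eff   df  cum_alpha  cum_beta
    1  0.50     16  0.3993  2.7500  0.4031  2.9599   30    0.00298   0.05379
    2  1.00     32  1.9609  1.9609  2.0000  2.0000   62    0.02500   0.20000
```

Reading stage 1: a trial whose interim t-statistic (30 df) falls below 0.403
stops for futility; above 2.960 it stops for success; otherwise it continues to
the full 32/group. Only 0.3% of the one-sided 2.5% error is spent at the
interim (γ = −4 back-loads spending). Running the operating-characteristics
simulation (`examples/02_operating_characteristics.py`) prints

```
null (no effect):
  stop for futility at interim:  65.4%
  claim success at interim:       0.2%
  claim success overall:          2.2%  (MC SE 0.0015)
alternative (g = 0.714):
  stop for futility at interim:   5.0%
  claim success at interim:      19.9%
  claim success overall:         79.1%  (MC SE 0.0041)
```

i.e. a futile trial usually stops early (two-thirds of null trials at the
interim, enrolling 32 instead of 64), while a real effect of g ≈ 0.71 is
detected with ~80% power. Fitting the Bayesian model to a synthetic
20-participant trial (`examples/04_bayesian_adherence_model.py`) ends with

```
Pr(MPH > placebo) at week 2: default 0.415  informative 0.680
Pr(MPH > placebo) at week 4: default 0.642  informative 0.707
Pr(MPH > placebo) at week 8: default 0.155  informative 0.294
```

— under data generated with lower MPH adherence by week 8, the posterior
probability that MPH beats placebo at the week-8 contrast stays well below ½
even under the deliberately pro-MPH prior.

Each script in `examples/` is a short narrative of one capability; the `gspilot`
command exposes the same steps as subcommands (`design`, `simulate-oc`,
`generate`, `endpoints`, `fit`, `run-all`, `report`).

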