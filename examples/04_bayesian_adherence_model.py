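"""Generate a synthetic 20-participant trial and fit the Bayesian model.

The generator reproduces the trial's structure (block randomization, pill
counts, MEMS events, withdrawals); the endpoints module derives % pill-count
adherence with the ITT rule; the mixed model is fit on the logit scale under
the default weakly-informative priors and under informative priors encoding
a pro-MPH belief (96/90/82% vs 90/79/66% adherence at weeks 2/4/8).
"""

from gspilot import (GeneratorConfig, ModelSpec, build_informative_priors,
                     default_priors, derive_adherence, fit_lmm,
                     generate_trial, logit_transform)

cfg = GeneratorConfig(seed=7)           # 20 participants, 4 withdrawals
ds = generate_trial(cfg)
adherence = derive_adherence(ds.visits, ds.mems_events)
print(f"{len(adherence)} visit records, "
      f"{int(adherence['imputed'].sum())} ITT-imputed")

n_doses = adherence["visit_week"].map({2: 14, 4: 14, 8: 28})
adherence["pill_logit"] = [
    logit_transform(v, "shrink", n_doses=int(n))
    for v, n in zip(adherence["pill_count_pct"], n_doses)]

model = ModelSpec(outcome="pill_logit")
fit_default = fit_lmm(adherence, model, default_priors(), seed=42)
print("\n--- default weakly-informative priors ---")
print(fit_default.report())

grid = {"placebo": {2: 90.0, 4: 79.0, 8: 66.0},
        "mph": {2: 96.0, 4: 90.0, 8: 82.0}}
fit_inf = fit_lmm(adherence, model, build_informative_priors(grid), seed=42)
print("\n--- informative pro-MPH priors ---")
for w in (2, 4, 8):
    print(f"Pr(MPH > placebo) at week {w}: "
          f"default {fit_default.pr_exceed[w]:.3f}  "
          f"informative {fit_inf.pr_exceed[w]:.3f}")
# The pro-treatment prior pulls the week-8 exceedance probability up, but
# the data (lower adherence under MPH) keep it well below one half.
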