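"""Solve the two-stage error-spending design and convert bounds to the t scale.

The design controls two-sided type-I error at 0.05 with 80% power using
Hwang-Shih-DeCani spending (gamma -4 for efficacy, -2 for the binding
futility bound) and one interim look at half the maximum sample size.
"""

from gspilot import (DesignSpec, design_report, fixed_sample_theta,
                     expected_sample_size, margin_of_error, solve_boundaries)

spec = DesignSpec()  # the pilot design: n_fix 62, interim at 16/group
bounds = solve_boundaries(spec)
print(design_report(spec, bounds))

es = fixed_sample_theta(spec.n_fix)
print(f"\nfixed-design effect size theta = {es.theta:.4f} "
      f"(Hedges' g = {es.hedges_g:.2f})")
# Expected enrolment: the interim stop (futility or early success) saves
# participants relative to the 64-participant maximum.
print(f"expected N under alternative: "
      f"{expected_sample_size(spec, bounds, es.theta):.1f}")
print(f"expected N under null:        "
      f"{expected_sample_size(spec, bounds, 0.0):.1f}")

# Stage-1 precision: with 10 per group, a 95% CI for each group mean spans
# +/-0.72 SD; for the between-group difference, +/-0.94 SD (or 1.07 SD after
# 20% dropout).
print(f"\nmargins of error at 95%: one group of 10 -> "
      f"{margin_of_error(10):.2f} SD; 10 vs 10 -> "
      f"{margin_of_error(10, n2=10):.2f} SD; 8 vs 8 -> "
      f"{margin_of_error(8, n2=8):.2f} SD")
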