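"""Bayesian random-intercept linear mixed model for longitudinal endpoints.

Model, for participant i at visit w (outcome y on the logit-adherence scale
or raw QIDS points):

    y_iw = x_iw' beta + b_i + e_iw,   b_i ~ N(0, tau^2),  e_iw ~ N(0, sigma^2)

with fixed effects treatment, visit, and treatment-by-visit interaction
under reference coding (placebo, earliest visit).  Priors:

* beta_j ~ N(m_j, s_j^2) — by default m_j = 0 (intercept: the sample mean of
  the outcome) and s_j = 2.5, optionally autoscaled by the data SDs;
* sigma ~ Exponential(rate), default rate 1 (autoscale divides by sd(y));
* tau^2 ~ Gamma(shape, scale), default shape = scale = 1.

Posterior sampling is by Markov chain Monte Carlo: the coefficient vector
and the random intercepts have conjugate Gaussian full conditionals (Gibbs
updates); sigma and tau^2 are updated with univariate slice sampling on the
log scale.  Convergence is summarized by split R-hat per parameter.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "PosteriorSummary",
    "logit_transform",
    "default_priors",
    "build_informative_priors",
    "fit_lmm",
    "sample_prior",
    "posterior_contrasts",
]

log = logging.getLogger(__name__)

ADHERENCE_VISITS = (2, 4, 8)
QIDS_VISITS = (0, 1, 2, 3, 4, 6, 8)
RHAT_WARN = 1.05


@dataclass
class ModelSpec:
    """Outcome and fixed-effect structure of the mixed model."""

    outcome: str = "pill_logit"           # pill_logit | mems_logit | qids
    visit_levels: tuple[int, ...] = ADHERENCE_VISITS
    treatment_arm: str = "mph"
    reference_arm: str = "placebo"

    @property
    def coef_names(self) -> tuple[str, ...]:
        ref, rest = self.visit_levels[0], self.visit_levels[1:]
        names = ["Intercept", "trt"]
        names += [f"visit_{w}" for w in rest]
        names += [f"trt:visit_{w}" for w in rest]
        return tuple(names)

    def design_matrix(self, data: pd.DataFrame) -> np.ndarray:
        trt = (data["arm"] == self.treatment_arm).to_numpy(float)
        cols = [np.ones(len(data)), trt]
        for w in self.visit_levels[1:]:
            cols.append((data["visit_week"] == w).to_numpy(float))
        for w in self.visit_levels[1:]:
            cols.append(trt * (data["visit_week"] == w).to_numpy(float))
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient: some arm/visit "
                             "cells are unobserved")
        return X


@dataclass
class PriorSpec:
    """Priors for the mixed model (see module docstring).

    ``coef_means``/``coef_sds`` may be scalars (broadcast) or dicts keyed by
    coefficient name.  With ``intercept_mean_rule`` the intercept prior mean
    is set to the sample mean of the outcome at fit time.  ``autoscale``
    multiplies each coefficient's prior SD by sd(y)/sd(x_j) (intercept: by
    sd(y)) and divides the error-SD exponential rate by sd(y).
    """

    coef_means: float | dict = 0.0
    coef_sds: float | dict = 2.5
    intercept_mean_rule: bool = True
    error_sd_rate: float = 1.0
    intercept_var_shape: float = 1.0
    intercept_var_scale: float = 1.0
    autoscale: bool = True

    def __post_init__(self) -> None:
        sds = (self.coef_sds.values() if isinstance(self.coef_sds, dict)
               else [self.coef_sds])
        if any(s <= 0 for s in sds):
            raise ValueError("prior SDs must be positive")
        if min(self.error_sd_rate, self.intercept_var_shape,
               self.intercept_var_scale) <= 0:
            raise ValueError("rate/shape/scale hyperparameters must be positive")

    def resolve(self, coef_names: Sequence[str], y: np.ndarray,
                X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        """Concrete (means, sds, error rate) for a design, applying the
        intercept rule and autoscaling."""
        p = len(coef_names)

        def expand(v, default):
            if isinstance(v, dict):
                return np.array([float(v.get(nm, default)) for nm in coef_names])
            return np.full(p, float(v))

        means = expand(self.coef_means, 0.0)
        sds = expand(self.coef_sds, 2.5)
        if self.intercept_mean_rule:
            means[0] = float(np.mean(y))
        rate = self.error_sd_rate
        if self.autoscale:
            sy = float(np.std(y))
            if sy > 0:
                sds = sds * sy
                rate = rate / sy
                for j in range(1, p):
                    sx = float(np.std(X[:, j]))
                    if sx > 0:
                        sds[j] = sds[j] / sx
        return means, sds, rate


def default_priors() -> PriorSpec:
    """The weakly-informative default: N(0, 2.5) coefficients (intercept
    centred at the sample mean), Exp(1) residual SD, Gamma(1, 1) intercept
    variance, all autoscaled."""
    return PriorSpec()


def logit_transform(pct, clamp_policy: str = "error",
                    n_doses: int | None = None, eps: float = 1e-3,
                    clamp_over_100: bool = True):
    """Logit of a percentage, with configurable boundary handling.

    Policies for pct == 0 or 100 (p == 0 or 1):

    * ``"error"`` — raise;
    * ``"shrink"`` — shrink toward 1/2 by (p*(N-1) + 0.5)/N with N =
      ``n_doses`` (the number of scheduled doses behind the percentage);
    * ``"eps"`` — clamp p into [eps, 1-eps].

    Pill-count percentages above 100 (late returns) are clamped to 100 first
    when ``clamp_over_100`` is set; the clamp is logged.
    """
    arr = np.atleast_1d(np.asarray(pct, dtype=float))
    if clamp_over_100 and np.any(arr > 100.0):
        log.info("clamping %d adherence value(s) above 100%% before logit",
                 int(np.sum(arr > 100.0)))
        arr = np.minimum(arr, 100.0)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("percentage outside [0, 100]")
    p = arr / 100.0
    boundary = (p <= 0.0) | (p >= 1.0)
    if np.any(boundary):
        if clamp_policy == "error":
            raise ValueError("boundary percentage with clamp_policy='error'")
        if clamp_policy == "shrink":
            if not n_doses or n_doses < 2:
                raise ValueError("shrink policy needs n_doses >= 2")
            p = (p * (n_doses - 1) + 0.5) / n_doses
        elif clamp_policy == "eps":
            p = np.clip(p, eps, 1 - eps)
        else:
            raise ValueError(f"unknown clamp policy {clamp_policy!r}")
    out = np.log(p / (1 - p))
    return float(out[0]) if np.isscalar(pct) or np.ndim(pct) == 0 else out


def build_informative_priors(target_adherence: dict[str, dict[int, float]],
                             coef_sd: float = 1.0,
                             visit_levels: Sequence[int] = ADHERENCE_VISITS,
                             ) -> PriorSpec:
    """Prior means encoding an arm x week adherence-percentage grid.

    The grid (percentages in (0, 100), keys ``"placebo"``/``"mph"`` by week)
    is mapped to logit cell means and then to reference-coded coefficient
    prior means: intercept = placebo at the first week; treatment main =
    MPH - placebo there; visit mains = placebo week differences;
    interactions = cell-mean double differences.  All coefficient SDs are
    ``coef_sd`` and autoscaling is off, matching the construction of a
    deliberately pro-treatment sensitivity prior.
    """
    cells = {}
    for arm in ("placebo", "mph"):
        cells[arm] = {}
        for w in visit_levels:
            pct = target_adherence[arm][w]
            if not 0 < pct < 100:
                raise ValueError("grid percentages must lie in (0, 100)")
            cells[arm][w] = math.log(pct / (100 - pct))
    ref = visit_levels[0]
    means = {"Intercept": cells["placebo"][ref],
             "trt": cells["mph"][ref] - cells["placebo"][ref]}
    for w in visit_levels[1:]:
        means[f"visit_{w}"] = cells["placebo"][w] - cells["placebo"][ref]
        means[f"trt:visit_{w}"] = (
            (cells["mph"][w] - cells["mph"][ref])
            - (cells["placebo"][w] - cells["placebo"][ref]))
    return PriorSpec(coef_means=means, coef_sds=coef_sd,
                     intercept_mean_rule=False, autoscale=False)


# ---------------------------------------------------------------------------
# sampling machinery
# ---------------------------------------------------------------------------

def _slice_sample(logf: Callable[[float], float], x0: float,
                  rng: np.random.Generator, w: float = 1.0,
                  max_steps: int = 64) -> float:
    """One univariate slice-sampling update (stepping out + shrinkage)."""
    y = logf(x0) - rng.exponential()
    lo = x0 - w * rng.random()
    hi = lo + w
    for _ in range(max_steps):
        if logf(lo) <= y:
            break
        lo -= w
    for _ in range(max_steps):
        if logf(hi) <= y:
            break
        hi += w
    for _ in range(max_steps):
        x = rng.uniform(lo, hi)
        if logf(x) > y:
            return x
        if x < x0:
            lo = x
        else:
            hi = x
    return x0


def _split_rhat(chains: np.ndarray) -> float:
    """Split potential-scale-reduction factor for draws shaped (chain, draw)."""
    m, n = chains.shape
    half = n // 2
    segs = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    k, n2 = segs.shape
    means = segs.mean(axis=1)
    W = segs.var(axis=1, ddof=1).mean()
    B = n2 * means.var(ddof=1)
    if W <= 0:
        return 1.0
    return float(math.sqrt((n2 - 1) / n2 + B / (W * n2)))


@dataclass
class PosteriorSummary:
    """Posterior draws and derived summaries for one model fit."""

    coef_names: tuple[str, ...]
    draws: dict                      # name -> array (chains, draws)
    medians: dict
    ci80: dict
    ci95: dict
    rhat: dict
    emm: pd.DataFrame                # arm x week posterior mean summaries
    pr_exceed: dict                  # week -> Pr(MPH > placebo)
    model: ModelSpec | None = None
    warnings: list = field(default_factory=list)

    def stacked(self, name: str) -> np.ndarray:
        return np.asarray(self.draws[name]).reshape(-1)

    def to_dict(self) -> dict:
        return {
            "medians": self.medians, "ci80": self.ci80, "ci95": self.ci95,
            "rhat": self.rhat, "pr_exceed": self.pr_exceed,
            "emm": self.emm.to_dict(orient="records"),
            "warnings": self.warnings,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def report(self) -> str:
        """Plain-text report: medians, 95% CI, Pr(MPH > placebo) per week."""
        lines = [f"{'parameter':<16} {'median':>8} {'95% CI':>18} {'R-hat':>6}"]
        for nm in list(self.coef_names) + ["sigma", "tau"]:
            lo, hi = self.ci95[nm]
            lines.append(f"{nm:<16} {self.medians[nm]:8.2f} "
                         f"[{lo:7.2f}, {hi:7.2f}] {self.rhat[nm]:6.3f}")
        lines.append("")
        lines.append("Estimated marginal means (posterior median [95% CI]):")
        for _, r in self.emm.iterrows():
            lines.append(f"  {r['arm']:<8} week {int(r['visit_week']):>2}: "
                         f"{r['median']:6.2f} [{r['lo95']:6.2f}, {r['hi95']:6.2f}]")
        lines.append("")
        for w, p in self.pr_exceed.items():
            lines.append(f"Pr(MPH > placebo) at week {w}: {p:.3f}")
        return "\n".join(lines)


def _prepare(data: pd.DataFrame, model: ModelSpec):
    cols = {"pill_logit", "mems_logit", "qids"} & set(data.columns)
    if model.outcome not in data.columns:
        raise ValueError(f"outcome column {model.outcome!r} not in data "
                         f"(available: {sorted(cols)})")
    d = data.dropna(subset=[model.outcome]).reset_index(drop=True)
    d = d[d["visit_week"].isin(model.visit_levels)].reset_index(drop=True)
    y = d[model.outcome].to_numpy(float)
    X = model.design_matrix(d)
    subj, subj_idx = np.unique(d["participant_id"], return_inverse=True)
    return d, y, X, subj, subj_idx


def fit_lmm(data: pd.DataFrame, model: ModelSpec, priors: PriorSpec,
            chains: int = 4, iterations: int = 2000, warmup: int = 1000,
            seed: int = 0) -> PosteriorSummary:
    """Fit the random-intercept mixed model by MCMC.

    ``data`` is long format with one row per participant-visit (columns
    ``participant_id``, ``arm``, ``visit_week`` and the outcome); missing
    visits are simply absent rows (observed-data likelihood).  Runs
    ``chains`` chains of ``iterations`` sweeps each, discarding ``warmup``;
    split R-hat is computed per parameter and a warning recorded if any
    exceeds 1.05.
    """
    d, y, X, subj, subj_idx = _prepare(data, model)
    names = model.coef_names
    n, p = X.shape
    n_subj = len(subj)
    m0, s0, rate = priors.resolve(names, y, X)
    prec0 = 1.0 / s0 ** 2
    XtX = X.T @ X
    Xty = X.T @ y
    Xt = X.T
    counts = np.bincount(subj_idx, minlength=n_subj).astype(float)
    # per-subject column sums of X and of y, for the collapsed beta update
    G = np.zeros((n_subj, p))
    np.add.at(G, subj_idx, X)
    gy = np.bincount(subj_idx, weights=y, minlength=n_subj)

    keep = iterations - warmup
    beta_draws = np.empty((chains, keep, p))
    sigma_draws = np.empty((chains, keep))
    tau_draws = np.empty((chains, keep))
    b_draws = np.empty((chains, keep, n_subj))

    shape_v, scale_v = priors.intercept_var_shape, priors.intercept_var_scale

    for c in range(chains):
        rng = np.random.default_rng([seed, c])
        beta = m0.copy()
        b = np.zeros(n_subj)
        sigma = max(float(np.std(y)), 0.5)
        tau2 = 1.0
        for it in range(iterations):
            # coefficients | sigma, tau (random intercepts marginalized out:
            # y ~ N(X beta, sigma^2 I + tau^2 Z Z'), whose inverse is block
            # diagonal with (I - c_i 1 1')/sigma^2, c_i = tau^2/(sigma^2 +
            # n_i tau^2) -- collapsing removes the beta/intercept coupling
            # that slows plain Gibbs mixing)
            shrink = tau2 / (sigma ** 2 + counts * tau2)
            XtVX = (XtX - G.T @ (shrink[:, None] * G)) / sigma ** 2
            XtVy = (Xty - G.T @ (shrink * gy)) / sigma ** 2
            prec = XtVX + np.diag(prec0)
            rhs = XtVy + prec0 * m0
            L = linalg.cholesky(prec, lower=True)
            mu = linalg.cho_solve((L, True), rhs)
            z = rng.standard_normal(p)
            beta = mu + linalg.solve_triangular(L, z, lower=True, trans="T")

            # variance components | beta (random intercepts marginalized
            # out, so sigma/tau mixing is not throttled by the latent b's):
            # per subject, log|V_i| = (n_i-1) log s2 + log(s2 + n_i t2) and
            # r'V^-1 r = (S2_i - t2 S1_i^2/(s2 + n_i t2))/s2
            resid_f = y - X @ beta
            s1 = np.bincount(subj_idx, weights=resid_f, minlength=n_subj)
            s2sum = np.bincount(subj_idx, weights=resid_f ** 2,
                                minlength=n_subj)

            def marginal_ll(s2, t2):
                denom = s2 + counts * t2
                logdet = np.sum((counts - 1) * math.log(s2)
                                + np.log(denom))
                quad = np.sum((s2sum - t2 * s1 ** 2 / denom) / s2)
                return -0.5 * (logdet + quad)

            def logf_sigma(ls):
                s = math.exp(ls)
                return marginal_ll(s * s, tau2) - rate * s + ls

            sigma = math.exp(_slice_sample(logf_sigma, math.log(sigma), rng))

            def logf_tau2(lt):
                t2 = math.exp(lt)
                return (marginal_ll(sigma ** 2, t2)
                        + (shape_v - 1) * lt - t2 / scale_v + lt)

            tau2 = math.exp(_slice_sample(logf_tau2, math.log(tau2), rng))

            # random intercepts | beta, sigma, tau
            prec_b = counts / sigma ** 2 + 1.0 / tau2
            mean_b = (s1 / sigma ** 2) / prec_b
            b = mean_b + rng.standard_normal(n_subj) / np.sqrt(prec_b)

            if it >= warmup:
                k = it - warmup
                beta_draws[c, k] = beta
                sigma_draws[c, k] = sigma
                tau_draws[c, k] = math.sqrt(tau2)
                b_draws[c, k] = b

    draws = {nm: beta_draws[:, :, j] for j, nm in enumerate(names)}
    draws["sigma"] = sigma_draws
    draws["tau"] = tau_draws
    for i, s in enumerate(subj):
        draws[f"b[{s}]"] = b_draws[:, :, i]

    return _summarize(model, names, draws, subj)


def sample_prior(model: ModelSpec, priors: PriorSpec, data: pd.DataFrame,
                 n_draws: int = 4000, chains: int = 4,
                 seed: int = 0) -> PosteriorSummary:
    """Prior-only sampling (likelihood disabled): exact independent draws
    from the PriorSpec, resolved against the data scale exactly as
    :func:`fit_lmm` would resolve it."""
    d, y, X, subj, subj_idx = _prepare(data, model)
    names = model.coef_names
    p = len(names)
    m0, s0, rate = priors.resolve(names, y, X)
    per = n_draws // chains
    rng = np.random.default_rng(seed)
    beta = m0 + s0 * rng.standard_normal((chains, per, p))
    sigma = rng.exponential(1.0 / rate, (chains, per))
    tau2 = rng.gamma(priors.intercept_var_shape,
                     priors.intercept_var_scale, (chains, per))
    draws = {nm: beta[:, :, j] for j, nm in enumerate(names)}
    draws["sigma"] = sigma
    draws["tau"] = np.sqrt(tau2)
    return _summarize(model, names, draws, subj)


def _cell_draws(model: ModelSpec, draws: dict, arm: str,
                week: int) -> np.ndarray:
    """Posterior draws of the arm x week estimated marginal mean."""
    ref = model.visit_levels[0]
    out = np.asarray(draws["Intercept"], float).reshape(-1).copy()
    if arm == model.treatment_arm:
        out += np.asarray(draws["trt"]).reshape(-1)
    if week != ref:
        out += np.asarray(draws[f"visit_{week}"]).reshape(-1)
        if arm == model.treatment_arm:
            out += np.asarray(draws[f"trt:visit_{week}"]).reshape(-1)
    return out


def _summarize(model: ModelSpec, names, draws, subj) -> PosteriorSummary:
    medians, ci80, ci95, rhat = {}, {}, {}, {}
    warnings_list = []
    scalar_names = list(names) + ["sigma", "tau"]
    for nm in scalar_names:
        flat = np.asarray(draws[nm]).reshape(-1)
        medians[nm] = float(np.median(flat))
        ci80[nm] = [float(q) for q in np.quantile(flat, [0.10, 0.90])]
        ci95[nm] = [float(q) for q in np.quantile(flat, [0.025, 0.975])]
        rhat[nm] = _split_rhat(np.asarray(draws[nm]))
        if rhat[nm] > RHAT_WARN:
            msg = f"R-hat {rhat[nm]:.3f} for {nm} exceeds {RHAT_WARN}"
            warnings_list.append(msg)
            log.warning(msg)

    emm_rows, pr_exceed = [], {}
    for week in model.visit_levels:
        diff = (_cell_draws(model, draws, model.treatment_arm, week)
                - _cell_draws(model, draws, model.reference_arm, week))
        pr_exceed[week] = float(np.mean(diff > 0))
        for arm in (model.reference_arm, model.treatment_arm):
            cell = _cell_draws(model, draws, arm, week)
            lo, hi = np.quantile(cell, [0.025, 0.975])
            emm_rows.append({"arm": arm, "visit_week": week,
                             "median": float(np.median(cell)),
                             "lo95": float(lo), "hi95": float(hi)})
    return PosteriorSummary(
        coef_names=tuple(names), draws=draws, medians=medians, ci80=ci80,
        ci95=ci95, rhat=rhat, emm=pd.DataFrame(emm_rows),
        pr_exceed=pr_exceed, model=model, warnings=warnings_list)


def posterior_contrasts(summary: PosteriorSummary, week: int
                        ) -> tuple[float, np.ndarray]:
    """Treatment-minus-reference EMM difference draws at one week.

    Returns ``(pr_exceed, diff_draws)`` where ``pr_exceed`` is the fraction
    of draws in which the treatment arm exceeds the reference arm.  For a
    change-from-baseline outcome (QIDS), the week difference in changes is
    exactly the treatment-by-week interaction draw.
    """
    model = summary.model
    if model is None or week not in model.visit_levels:
        raise ValueError(f"week {week} not a visit level of the fitted model")
    diff = (_cell_draws(model, summary.draws, model.treatment_arm, week)
            - _cell_draws(model, summary.draws, model.reference_arm, week))
    return float(np.mean(diff > 0)), diff
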