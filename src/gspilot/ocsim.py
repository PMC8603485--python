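"""Monte-Carlo operating characteristics of the two-stage t-test procedure.

The design engine works on the z scale; the trial itself analyses Gaussian
outcomes with pooled-variance two-sample t-tests against t-scale boundaries.
This module simulates that procedure replicate by replicate to estimate the
futility-stop probability, interim success probability, overall (cumulative)
one-sided type-I error or power, and the final-stage-only rejection rate,
together with binomial Monte-Carlo standard errors.

Each replicate draws from its own RNG stream keyed by (seed, replicate index)
so enlarging ``n_sims`` extends rather than reshuffles the replicate set.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .design import BoundarySet, _Recursion

__all__ = ["OCResult", "simulate_oc", "oc_analytic_check"]

log = logging.getLogger(__name__)


@dataclass
class OCResult:
    """Decision-path proportions from a simulated two-stage trial."""

    n_sims: int
    p_futility_interim: float
    p_success_interim: float
    p_reject_overall: float
    p_reject_final_only: float
    mc_se: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        for name in ("p_futility_interim", "p_success_interim",
                     "p_reject_overall", "p_reject_final_only"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if self.p_success_interim > self.p_reject_overall + 1e-12:
            raise ValueError("interim success cannot exceed overall rejection")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _pooled_t(x: np.ndarray, y: np.ndarray) -> float:
    """Pooled-variance two-sample t statistic (treatment minus control)."""
    n1, n2 = x.size, y.size
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    return float((y.mean() - x.mean()) / math.sqrt(s2 * (1 / n1 + 1 / n2)))


def simulate_oc(t_bounds: BoundarySet, effect_g: float,
                n_per_group_stages: tuple[int, int] = (16, 32),
                n_sims: int = 10_000, seed: int = 0) -> OCResult:
    """Simulate the two-stage trial against t-scale boundaries.

    Outcomes are unit-variance Gaussians with between-group mean difference
    ``effect_g`` (treatment higher).  Per replicate: stop for futility if the
    interim t falls below ``t_lower[0]``; claim success if above
    ``t_upper[0]``; otherwise accumulate to the stage-2 sample (stage-1 data
    retained) and claim success if the final t exceeds ``t_upper[1]``.
    """
    lower1, upper1 = t_bounds.t_lower[0], t_bounds.t_upper[0]
    final = t_bounds.t_upper[1]
    if not lower1 < upper1:
        raise ValueError("interim futility bound must sit below efficacy bound")
    if n_sims < 100:
        log.warning("n_sims=%d is very small; estimates will be noisy", n_sims)
    n1, n2 = n_per_group_stages
    if not 0 < n1 < n2:
        raise ValueError("need 0 < interim < final per-group counts")

    n_fut = n_succ1 = n_succ2 = 0
    for rep in range(n_sims):
        rng = np.random.default_rng([seed, rep])
        ctrl = rng.standard_normal(n2)
        trt = rng.standard_normal(n2) + effect_g
        t1 = _pooled_t(ctrl[:n1], trt[:n1])
        if t1 < lower1:
            n_fut += 1
        elif t1 > upper1:
            n_succ1 += 1
        elif _pooled_t(ctrl, trt) > final:
            n_succ2 += 1

    def prop(k):
        return k / n_sims

    def se(p):
        return math.sqrt(p * (1 - p) / n_sims)

    p_fut, p_s1, p_s2 = prop(n_fut), prop(n_succ1), prop(n_succ2)
    result = OCResult(
        n_sims=n_sims,
        p_futility_interim=p_fut,
        p_success_interim=p_s1,
        p_reject_overall=p_s1 + p_s2,
        p_reject_final_only=p_s2,
        mc_se={
            "p_futility_interim": se(p_fut),
            "p_success_interim": se(p_s1),
            "p_reject_overall": se(p_s1 + p_s2),
            "p_reject_final_only": se(p_s2),
        },
        seed=seed,
    )
    return result


def oc_analytic_check(z_lower1: float, z_upper1: float, z_final: float,
                      interim_drift: float,
                      info_fractions: tuple[float, float] = (0.5, 1.0),
                      n_grid: int = 601) -> dict[str, float]:
    """Normal-theory crossing probabilities for the two-stage design.

    Cross-validation oracle for :func:`simulate_oc` using the design module's
    sub-density recursion.  ``interim_drift`` is the mean of the stage-1 z
    statistic (0 under the null, theta*sqrt(N_interim) under the
    alternative); the final-stage mean scales as sqrt(t2/t1).
    """
    t1, t2 = info_fractions
    # _Recursion parameterizes E[Z_k] = Delta*sqrt(t_k); match stage 1.
    delta = interim_drift / math.sqrt(t1)
    rec = _Recursion(info_fractions, delta, n_grid)
    p_fut = rec.cross_lower(z_lower1)
    p_succ1 = rec.cross_upper(z_upper1)
    rec.condition(z_lower1, z_upper1)
    p_succ2 = rec.cross_upper(z_final)
    return {
        "p_futility_interim": p_fut,
        "p_success_interim": p_succ1,
        "p_continue": 1.0 - p_fut - p_succ1,
        "p_reject_final_only": p_succ2,
        "p_reject_overall": p_succ1 + p_succ2,
    }
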