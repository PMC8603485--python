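"""Group-sequential design engine with Hwang-Shih-DeCani error spending.

Implements the two-stage (generically, K-stage) design used to plan a pilot
trial with one interim look: error-spending boundaries computed by recursive
numerical integration of the sequential z-statistic's sub-density, a binding
futility bound, quantile substitution of z boundaries to the t scale, the
fixed-sample effect size, expected sample size, and pilot margin-of-error
multipliers.

The canonical construction: with information fractions ``t_1 < ... < t_K = 1``
the standardized statistics ``Z_k`` are jointly Gaussian with
``Corr(Z_j, Z_k) = sqrt(t_j / t_k)`` and ``E[Z_k] = Delta * sqrt(t_k)`` where
``Delta = theta * sqrt(n_max)`` is the drift at full information.  Efficacy
boundaries spend the one-sided type-I error per an HSD schedule under the
null (with the futility bound binding, i.e. the continuation region is
truncated below it); futility boundaries spend the type-II error under the
alternative.  The drift is solved so the two schedules close at the final
stage, which makes total power exactly ``1 - beta``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DesignSpec",
    "BoundarySet",
    "EffectSize",
    "hsd_spend",
    "solve_boundaries",
    "quantile_substitute",
    "fixed_sample_theta",
    "expected_sample_size",
    "margin_of_error",
    "design_report",
]

# Below this magnitude the HSD formula is numerically indistinguishable from
# its gamma -> 0 (linear) limit; branch explicitly so spending is continuous.
_GAMMA_LINEAR_EPS = 1e-5


@dataclass
class DesignSpec:
    """Parameters of a K-stage group-sequential design.

    Defaults are the two-stage pilot design: interim at half information,
    two-sided alpha 0.05, power 0.8, HSD gamma -4 efficacy / -2 binding
    futility spending, 16 then 32 participants per group.
    """

    n_stages: int = 2
    info_fractions: tuple[float, ...] = (0.5, 1.0)
    alpha_total: float = 0.05
    beta: float = 0.2
    gamma_upper: float = -4.0
    gamma_lower: float = -2.0
    n_fix: int = 62
    n_max: int = 64
    binding_futility: bool = True
    per_group_n: tuple[int, ...] = (16, 32)

    def __post_init__(self) -> None:
        self.info_fractions = tuple(float(t) for t in self.info_fractions)
        self.per_group_n = tuple(int(n) for n in self.per_group_n)
        if len(self.info_fractions) != self.n_stages:
            raise ValueError("info_fractions length must equal n_stages")
        fr = self.info_fractions
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError("info_fractions must be strictly increasing")
        if not math.isclose(fr[-1], 1.0):
            raise ValueError("last information fraction must be 1")
        if not (0.0 < self.alpha_total < 1.0 and 0.0 < self.beta < 1.0):
            raise ValueError("alpha_total and beta must lie in (0, 1)")
        if self.n_fix > self.n_max:
            raise ValueError("n_fix must not exceed n_max")

    @property
    def stage_totals(self) -> tuple[int, ...]:
        """Total (both-arm) sample size at each analysis."""
        return tuple(2 * n for n in self.per_group_n)

    @property
    def dfs(self) -> tuple[int, ...]:
        """Two-sample t degrees of freedom at each analysis."""
        return tuple(2 * n - 2 for n in self.per_group_n)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        return cls(**d)

    @classmethod
    def from_json(cls, path: str) -> "DesignSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class EffectSize:
    """Design effect size: one-sample z drift per sqrt(n) and Hedges' g."""

    theta: float
    hedges_g: float
    conversion_factor: float = 2.0


@dataclass
class BoundarySet:
    """Per-stage efficacy/futility boundaries on the z and t scales."""

    z_upper: tuple[float, ...]
    z_lower: tuple[float, ...]
    t_upper: tuple[float, ...]
    t_lower: tuple[float, ...]
    dfs: tuple[int, ...]
    drift: float | None = None          # Delta = theta * sqrt(n_max_continuous)
    n_max_continuous: float | None = None
    alpha_spent: tuple[float, ...] = ()  # cumulative one-sided alpha
    beta_spent: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        k = len(self.z_upper)
        for name in ("z_lower", "t_upper", "t_lower", "dfs"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} must have one entry per stage")
        for s in range(k - 1):
            if not self.z_lower[s] < self.z_upper[s]:
                raise ValueError("futility bound must sit below efficacy bound "
                                 "at interim stages")

    @classmethod
    def from_z(cls, z_lower: Sequence[float], z_upper: Sequence[float],
               dfs: Sequence[int], **kw) -> "BoundarySet":
        """Build a boundary set from z-scale bounds, converting to t."""
        t_up = tuple(quantile_substitute(z, d) for z, d in zip(z_upper, dfs))
        t_lo = tuple(quantile_substitute(z, d) for z, d in zip(z_lower, dfs))
        return cls(tuple(z_upper), tuple(z_lower), t_up, t_lo, tuple(dfs), **kw)

    @classmethod
    def from_t(cls, t_lower: Sequence[float], t_upper: Sequence[float],
               dfs: Sequence[int], **kw) -> "BoundarySet":
        """Build from t-scale bounds (e.g. published values), back-converting
        to the z scale by inverse quantile substitution."""
        def back(t, d):
            return float(stats.norm.ppf(stats.t.cdf(t, d)))
        z_up = tuple(back(t, d) for t, d in zip(t_upper, dfs))
        z_lo = tuple(back(t, d) for t, d in zip(t_lower, dfs))
        return cls(z_up, z_lo, tuple(t_upper), tuple(t_lower), tuple(dfs), **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def hsd_spend(t, gamma: float, err_total: float):
    """Hwang-Shih-DeCani cumulative error spent at information fraction t.

    ``err_total * (1 - exp(-gamma t)) / (1 - exp(-gamma))`` for gamma != 0,
    with the linear limit ``err_total * t`` at gamma == 0.  gamma < 0
    back-loads spending (little error used at the interim).
    """
    t = np.asarray(t, dtype=float)
    if np.any((t < 0) | (t > 1)):
        raise ValueError("information fraction must lie in [0, 1]")
    if abs(gamma) < _GAMMA_LINEAR_EPS:
        out = err_total * t
    else:
        out = err_total * np.expm1(-gamma * t) / np.expm1(-gamma)
    return float(out) if out.ndim == 0 else out


def quantile_substitute(z_bound: float, df: float) -> float:
    """Convert a normal-theory boundary to the t scale at ``df`` degrees of
    freedom by matching cumulative probabilities.

    Uses the survival function for positive bounds so extreme quantiles keep
    full precision.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if z_bound >= 0:
        return float(stats.t.isf(stats.norm.sf(z_bound), df))
    return float(stats.t.ppf(stats.norm.cdf(z_bound), df))


def fixed_sample_theta(n_fix: float, alpha_total: float = 0.05,
                       beta: float = 0.2) -> EffectSize:
    """Effect size detectable by a fixed one-sample z test of size n_fix.

    theta = (z_{1-alpha/2} + z_{1-beta}) / sqrt(n_fix); the two-sample
    standardized difference (Hedges' g) is twice theta.
    """
    if n_fix <= 0:
        raise ValueError("n_fix must be positive")
    if not (0 < alpha_total < 1 and 0 < beta < 1):
        raise ValueError("alpha_total and beta must lie in (0, 1)")
    za = stats.norm.isf(alpha_total / 2)
    zb = stats.norm.isf(beta)
    theta = float((za + zb) / math.sqrt(n_fix))
    return EffectSize(theta=theta, hedges_g=2 * theta)


def margin_of_error(n: int, confidence: float = 0.95,
                    n2: int | None = None) -> float:
    """Half-width of a confidence interval in units of the (common) SD.

    One group: ``t_{n-1} * sqrt(1/n)`` for the group mean.  Two groups:
    ``t_{n+n2-2} * sqrt(1/n + 1/n2)`` for the between-group difference.
    """
    if n < 2 or (n2 is not None and n2 < 2):
        raise ValueError("each group needs n >= 2")
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")
    q = 1 - (1 - confidence) / 2
    if n2 is None:
        return float(stats.t.ppf(q, n - 1) * math.sqrt(1 / n))
    return float(stats.t.ppf(q, n + n2 - 2) * math.sqrt(1 / n + 1 / n2))


# ---------------------------------------------------------------------------
# Sequential sub-density recursion
# ---------------------------------------------------------------------------

def _trapz_weights(grid: np.ndarray) -> np.ndarray:
    w = np.empty_like(grid)
    h = grid[1] - grid[0]
    w[:] = h
    w[0] = w[-1] = h / 2
    return w


class _Recursion:
    """Sub-density of the sequential z statistic over continuation regions.

    Maintains, stage by stage, the joint density of ``Z_k`` restricted to the
    event that all earlier statistics stayed inside their continuation
    intervals, evaluated on a trapezoid grid (Armitage-McPherson-Rowe
    recursion).
    """

    def __init__(self, info_fractions: Sequence[float], drift: float,
                 n_grid: int = 601):
        self.t = tuple(info_fractions)
        self.drift = drift
        self.n_grid = n_grid
        self.grid: np.ndarray | None = None   # stage-(k-1) continuation grid
        self.dens: np.ndarray | None = None   # sub-density on that grid
        self._w: np.ndarray | None = None     # trapezoid weights on grid
        self._stage = 0                       # stages absorbed so far

    def _increment_params(self):
        """Mean and SD of the scaled increment W_k - W_{k-1}."""
        t0 = 0.0 if self._stage == 0 else self.t[self._stage - 1]
        t1 = self.t[self._stage]
        dt = t1 - t0
        return t0, t1, dt

    def cross_upper(self, u: float) -> float:
        """P(statistic at the current stage exceeds u, given continuation)."""
        t0, t1, dt = self._increment_params()
        if self._stage == 0:
            return float(stats.norm.sf(u - self.drift * math.sqrt(t1)))
        arg = (u * math.sqrt(t1) - self.grid * math.sqrt(t0)
               - self.drift * dt) / math.sqrt(dt)
        return float(np.sum(self._w * self.dens * stats.norm.sf(arg)))

    def cross_lower(self, l: float) -> float:
        t0, t1, dt = self._increment_params()
        if self._stage == 0:
            return float(stats.norm.cdf(l - self.drift * math.sqrt(t1)))
        arg = (l * math.sqrt(t1) - self.grid * math.sqrt(t0)
               - self.drift * dt) / math.sqrt(dt)
        return float(np.sum(self._w * self.dens * stats.norm.cdf(arg)))

    def condition(self, lower: float, upper: float) -> None:
        """Restrict the current stage to [lower, upper] and advance."""
        t0, t1, dt = self._increment_params()
        new_grid = np.linspace(lower, upper, self.n_grid)
        if self._stage == 0:
            new_dens = stats.norm.pdf(new_grid - self.drift * math.sqrt(t1))
        else:
            arg = (new_grid[:, None] * math.sqrt(t1)
                   - self.grid[None, :] * math.sqrt(t0)
                   - self.drift * dt) / math.sqrt(dt)
            kern = stats.norm.pdf(arg) * math.sqrt(t1) / math.sqrt(dt)
            new_dens = kern @ (self._w * self.dens)
        self.grid, self.dens = new_grid, new_dens
        self._w = _trapz_weights(new_grid)
        self._stage += 1


def _spending_schedule(spec: DesignSpec):
    alpha1 = spec.alpha_total / 2  # one-sided
    a_cum = np.array([hsd_spend(t, spec.gamma_upper, alpha1)
                      for t in spec.info_fractions])
    b_cum = np.array([hsd_spend(t, spec.gamma_lower, spec.beta)
                      for t in spec.info_fractions])
    return a_cum, b_cum


def _bounds_for_drift(spec: DesignSpec, drift: float, n_grid: int,
                      tol: float):
    """Solve all boundaries for a given drift; return (lowers, uppers, gap).

    gap = final efficacy bound minus final futility bound; the design closes
    when gap == 0.
    """
    a_cum, b_cum = _spending_schedule(spec)
    rec0 = _Recursion(spec.info_fractions, 0.0, n_grid)     # null, for alpha
    rec1 = _Recursion(spec.info_fractions, drift, n_grid)   # alt, for beta
    lowers, uppers = [], []
    K = spec.n_stages
    for k in range(K):
        a_inc = a_cum[k] - (a_cum[k - 1] if k else 0.0)
        b_inc = b_cum[k] - (b_cum[k - 1] if k else 0.0)
        u = optimize.brentq(lambda x: rec0.cross_upper(x) - a_inc,
                            -10.0, 10.0, xtol=tol)
        l = optimize.brentq(lambda x: rec1.cross_lower(x) - b_inc,
                            -10.0, 10.0, xtol=tol)
        uppers.append(u)
        lowers.append(l)
        if k < K - 1:
            if not l < u:
                raise RuntimeError(
                    f"infeasible continuation region at stage {k + 1}: "
                    f"futility {l:.4f} >= efficacy {u:.4f} (drift {drift:.4f})")
            lo = l if spec.binding_futility else min(l, -8.0)
            rec0.condition(lo, u)
            rec1.condition(lo, u)
    return lowers, uppers, uppers[-1] - lowers[-1]


def solve_boundaries(spec: DesignSpec, n_grid: int = 601,
                     tol: float = 1e-6) -> BoundarySet:
    """Solve efficacy/futility z boundaries and the design drift.

    Efficacy bounds spend ``alpha_total/2`` under the null per the
    ``gamma_upper`` HSD schedule (continuation truncated at the binding
    futility bound); futility bounds spend ``beta`` under the alternative per
    ``gamma_lower``.  The drift ``Delta`` is root-found so the final efficacy
    and futility bounds coincide, making total power ``1 - beta``.  Raises a
    RuntimeError with diagnostics if the root-finder fails.
    """
    if spec.n_stages == 1:
        z = float(stats.norm.isf(spec.alpha_total / 2))
        es = fixed_sample_theta(spec.n_fix, spec.alpha_total, spec.beta)
        drift = es.theta * math.sqrt(spec.n_fix)
        return BoundarySet.from_z(
            [z], [z], spec.dfs, drift=drift,
            n_max_continuous=float(spec.n_fix),
            alpha_spent=(spec.alpha_total / 2,), beta_spent=(spec.beta,))

    def gap(drift):
        # Infeasible configurations (continuation region vanishing, or a
        # spending increment unattainable) occur when the drift is too large,
        # i.e. the design is overpowered: treat as a large negative gap so
        # bracketing still works.
        try:
            return _bounds_for_drift(spec, drift, n_grid, tol)[2]
        except (RuntimeError, ValueError):
            return -1e6

    es = fixed_sample_theta(spec.n_fix, spec.alpha_total, spec.beta)
    drift_fix = es.theta * math.sqrt(spec.n_fix)  # z_a + z_b
    lo, hi = 0.5 * drift_fix, drift_fix
    g_lo = gap(lo)
    for _ in range(40):
        if gap(hi) < 0:
            break
        lo, hi = hi, hi * 1.1
    else:
        raise RuntimeError("boundary drift solve failed: no sign change up to "
                           f"drift {hi:.3f} (gap at {lo:.3f} = {g_lo:.4g})")
    if not g_lo > 0:
        raise RuntimeError(
            f"boundary drift solve failed: gap at lower bracket {lo:.3f} is "
            f"{g_lo:.4g}, expected positive")
    try:
        drift = optimize.brentq(gap, lo, hi, xtol=tol)
    except ValueError as err:
        raise RuntimeError(
            f"boundary drift solve failed in [{lo:.3f}, {hi:.3f}]: "
            f"{err}") from None
    lowers, uppers, _ = _bounds_for_drift(spec, drift, n_grid, tol)
    # close the design: final futility == final efficacy
    final = 0.5 * (lowers[-1] + uppers[-1])
    lowers[-1] = uppers[-1] = final
    a_cum, b_cum = _spending_schedule(spec)
    n_max_cont = (drift / es.theta) ** 2
    return BoundarySet.from_z(
        lowers, uppers, spec.dfs, drift=drift, n_max_continuous=n_max_cont,
        alpha_spent=tuple(a_cum), beta_spent=tuple(b_cum))


def continuation_probability(z_lower: float, z_upper: float,
                             mean: float) -> float:
    """P(interim statistic falls strictly between the bounds) for a unit-
    variance Gaussian interim statistic with the given mean."""
    return float(stats.norm.cdf(z_upper - mean) - stats.norm.cdf(z_lower - mean))


def expected_sample_size(spec: DesignSpec, bounds: BoundarySet,
                         drift: float) -> float:
    """Expected total N of the two-stage design at a per-sqrt(n) drift.

    ``drift`` is the one-sample effect theta (0 under the null); the interim
    statistic has mean ``drift * sqrt(N_interim)``.  E[N] = N_interim +
    (N_max - N_interim) * P(continue).
    """
    if spec.n_stages != 2:
        raise ValueError("expected_sample_size implemented for 2-stage designs")
    n1, n2 = spec.stage_totals
    mean = drift * math.sqrt(n1)
    p_cont = continuation_probability(bounds.z_lower[0], bounds.z_upper[0], mean)
    return n1 + (n2 - n1) * p_cont


def design_report(spec: DesignSpec, bounds: BoundarySet) -> str:
    """Plain-text per-stage design table."""
    lines = [
        "Group-sequential design "
        f"(two-sided alpha={spec.alpha_total}, power={1 - spec.beta:.2f}, "
        f"HSD gamma {spec.gamma_upper:g}/{spec.gamma_lower:g}, "
        f"binding futility={spec.binding_futility})",
        f"n_fix={spec.n_fix}  n_max={spec.n_max}  "
        f"drift={bounds.drift:.4f}" if bounds.drift is not None else "",
        "stage  info  n/grp  z_fut   z_eff   t_fut   t_eff   df  "
        "cum_alpha  cum_beta",
    ]
    for k in range(spec.n_stages):
        a = bounds.alpha_spent[k] if bounds.alpha_spent else float("nan")
        b = bounds.beta_spent[k] if bounds.beta_spent else float("nan")
        lines.append(
            f"{k + 1:>5}  {spec.info_fractions[k]:4.2f}  "
            f"{spec.per_group_n[k]:>5}  "
            f"{bounds.z_lower[k]:6.4f}  {bounds.z_upper[k]:6.4f}  "
            f"{bounds.t_lower[k]:6.4f}  {bounds.t_upper[k]:6.4f}  "
            f"{bounds.dfs[k]:>3}  {a:9.5f}  {b:8.5f}")
    return "\n".join(ln for ln in lines if ln)
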