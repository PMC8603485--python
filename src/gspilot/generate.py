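"""Synthetic two-arm adherence trial generator.

Emulates the data structure of a 20-participant, 1:1 block-randomized,
placebo-controlled trial of methylphenidate (MPH)-augmented escitalopram:
per-visit pill counts (weeks 2/4/8), timestamped MEMS cap-opening streams
(one scheduled dose per day), QIDS-SR depression scores (weeks
0/1/2/3/4/6/8), and withdrawals.

The generative model matches the analysis model's assumptions: latent
adherence for participant i at visit week w is

    p_iw = inverse-logit(cell_mean[arm, w] + b_i + e_iw),

with a Gaussian random intercept b_i and Gaussian logit-scale residual e_iw.
Pill counts are the rounded deterministic consequence of p_iw; MEMS doses
are daily Bernoulli(p_iw) events at a participant-specific habitual time
plus Gaussian jitter.  Default cell means and QIDS trajectories are set to
the posterior medians a trial of this kind reports (high adherence in both
arms, slightly lower under MPH by week 8; ~8.8-point QIDS improvement with
a negligible arm difference).  The full generating truth is returned (and
written to ``truth.json``) for parameter-recovery testing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .endpoints import SCHEDULED_VISIT_WEEKS, VISIT_INTERVAL_DAYS

__all__ = ["GeneratorConfig", "TrialDataset", "block_randomize",
           "generate_trial", "write_trial"]

ARMS = ("placebo", "mph")
QIDS_WEEKS = (0, 1, 2, 3, 4, 6, 8)
TRIAL_START = pd.Timestamp("2018-01-08 00:00:00")


def _default_cell_means() -> dict[str, dict[int, float]]:
    # logit-scale adherence cell means (placebo ~93.6/92.8/92.7%,
    # MPH ~94.0/87.6/82.2% at weeks 2/4/8)
    return {
        "placebo": {2: 2.69, 4: 2.56, 8: 2.54},
        "mph": {2: 2.75, 4: 1.96, 8: 1.53},
    }


def _default_qids_week_effects() -> dict[int, float]:
    return {0: 0.0, 1: -8.74, 2: -9.09, 3: -9.21, 4: -7.32, 6: -9.44,
            8: -8.77}


def _default_qids_arm_offsets() -> dict[int, float]:
    # MPH-by-week interactions (points); week 0 is the reference
    return {0: 0.0, 1: 1.78, 2: 2.77, 3: 0.79, 4: 0.79, 6: 0.26, 8: -1.18}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic trial.

    All scales are the analysis scales: adherence cell means in logit units,
    QIDS effects in scale points, MEMS jitter in hours.
    """

    n_participants: int = 20
    block_size: int = 2
    logit_cell_means: dict = field(default_factory=_default_cell_means)
    random_intercept_sd: float = 0.75
    residual_sd: float = 0.6
    qids_baseline_mean: float = 17.3
    qids_baseline_sd: float = 2.4
    qids_mph_main: float = -1.62
    qids_week_effects: dict = field(default_factory=_default_qids_week_effects)
    qids_arm_week_offsets: dict = field(default_factory=_default_qids_arm_offsets)
    qids_residual_sd: float = 2.2
    n_dropouts: int = 4
    dropout_weeks: dict | None = None   # participant index -> week; overrides n_dropouts
    dropout_week_choices: tuple[int, ...] = (3, 4, 5, 6, 7)
    mems_jitter_sd: float = 1.5
    habitual_time_range: tuple[float, float] = (7.0, 22.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for arm, cells in self.logit_cell_means.items():
            for w, m in cells.items():
                p = 1 / (1 + np.exp(-m))
                if not 0 < p < 1:
                    raise ValueError(f"cell mean {arm}@{w} implies degenerate p")
        for name in ("random_intercept_sd", "residual_sd", "qids_baseline_sd",
                     "qids_residual_sd", "mems_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TrialDataset:
    """Long-format synthetic trial: visit table, MEMS event log, truth."""

    visits: pd.DataFrame
    mems_events: pd.DataFrame
    truth: dict


def block_randomize(n: int, block_size: int = 2,
                    seed: int | np.random.Generator = 0) -> np.ndarray:
    """1:1 block randomization; returns an array of arm labels.

    Every complete block contains each arm equally often, so the arm
    imbalance at any prefix never exceeds block_size/2.  A trailing partial
    block is a truncated permuted block.
    """
    if block_size % 2 != 0 or block_size < 2:
        raise ValueError("1:1 allocation requires an even block size >= 2")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    block = np.repeat(ARMS, block_size // 2)
    n_blocks = -(-n // block_size)
    seq = np.concatenate([rng.permutation(block) for _ in range(n_blocks)])
    return seq[:n]


def _logit_inv(x):
    return 1.0 / (1.0 + np.exp(-x))


def _coef_truth(cells: dict[str, dict[int, float]]) -> dict[str, float]:
    """Reference-coded fixed effects implied by the cell-mean grid
    (reference: placebo, earliest week)."""
    weeks = sorted(cells["placebo"])
    ref = weeks[0]
    out = {"Intercept": cells["placebo"][ref],
           "trt": cells["mph"][ref] - cells["placebo"][ref]}
    for w in weeks[1:]:
        out[f"visit_{w}"] = cells["placebo"][w] - cells["placebo"][ref]
        out[f"trt:visit_{w}"] = ((cells["mph"][w] - cells["mph"][ref])
                                 - (cells["placebo"][w] - cells["placebo"][ref]))
    return out


def generate_trial(cfg: GeneratorConfig) -> TrialDataset:
    """Generate one complete synthetic trial from the configured conditions."""
    rng = np.random.default_rng(cfg.seed)
    arms = block_randomize(cfg.n_participants, cfg.block_size, rng)
    pids = [f"P{i + 1:03d}" for i in range(cfg.n_participants)]

    intercepts = rng.normal(0.0, cfg.random_intercept_sd, cfg.n_participants)
    qids_base = rng.normal(cfg.qids_baseline_mean, cfg.qids_baseline_sd,
                           cfg.n_participants)
    habitual = rng.uniform(*cfg.habitual_time_range, cfg.n_participants)

    if cfg.dropout_weeks is not None:
        dropouts = {int(k): int(v) for k, v in cfg.dropout_weeks.items()}
    else:
        idx = rng.choice(cfg.n_participants, size=cfg.n_dropouts,
                         replace=False)
        weeks = rng.choice(cfg.dropout_week_choices, size=cfg.n_dropouts)
        dropouts = {int(i): int(w) for i, w in zip(idx, weeks)}

    visit_rows, mems_rows = [], []
    for i, (pid, arm) in enumerate(zip(pids, arms)):
        ww = dropouts.get(i)
        last_day = 56 if ww is None else min(56, 7 * ww)
        # latent per-interval adherence probability
        p_by_week = {}
        for w in SCHEDULED_VISIT_WEEKS:
            mu = cfg.logit_cell_means[arm][w] + intercepts[i]
            p_by_week[w] = float(_logit_inv(mu + rng.normal(0, cfg.residual_sd)))

        for w in SCHEDULED_VISIT_WEEKS:
            d0, d1 = VISIT_INTERVAL_DAYS[w]
            row = {"participant_id": pid, "arm": arm, "visit_week": w,
                   "withdrawal_week": ww if ww is not None else np.nan,
                   "n_prescribed": np.nan, "n_remaining": np.nan,
                   "dispense_date": "", "return_date": "", "qids": np.nan}
            if ww is None or w < ww:
                n_presc = d1 - d0
                n_taken = int(round(n_presc * p_by_week[w]))
                row.update({
                    "n_prescribed": n_presc,
                    "n_remaining": n_presc - n_taken,
                    "dispense_date": (TRIAL_START
                                      + pd.Timedelta(days=d0)).date().isoformat(),
                    "return_date": (TRIAL_START
                                    + pd.Timedelta(days=d1)).date().isoformat(),
                })
            visit_rows.append(row)

        # MEMS events: one scheduled dose a day until withdrawal
        for day in range(last_day):
            w = next(w for w in SCHEDULED_VISIT_WEEKS
                     if VISIT_INTERVAL_DAYS[w][0] <= day < VISIT_INTERVAL_DAYS[w][1])
            if rng.random() < p_by_week[w]:
                hour = habitual[i] + rng.normal(0, cfg.mems_jitter_sd)
                hour = float(np.clip(hour, 0.0, 23.983))
                ts = (TRIAL_START + pd.Timedelta(days=day)
                      + pd.Timedelta(hours=hour))
                mems_rows.append({"participant_id": pid,
                                  "timestamp": ts.isoformat()})

        # QIDS trajectory
        for w in QIDS_WEEKS:
            if ww is not None and w >= ww:
                continue
            mu = (qids_base[i] + cfg.qids_week_effects[w]
                  + (arm == "mph") * (cfg.qids_mph_main * (w > 0)
                                      + cfg.qids_arm_week_offsets[w]))
            score = int(np.clip(round(mu + rng.normal(0, cfg.qids_residual_sd)),
                                0, 27))
            for row in visit_rows[::-1]:
                if row["participant_id"] == pid and row["visit_week"] == w:
                    row["qids"] = score
                    break
            else:
                visit_rows.append({
                    "participant_id": pid, "arm": arm, "visit_week": w,
                    "withdrawal_week": ww if ww is not None else np.nan,
                    "n_prescribed": np.nan, "n_remaining": np.nan,
                    "dispense_date": "", "return_date": "", "qids": score})

    visits = pd.DataFrame(visit_rows).sort_values(
        ["participant_id", "visit_week"], kind="mergesort").reset_index(drop=True)
    mems = pd.DataFrame(mems_rows, columns=["participant_id", "timestamp"])
    mems = mems.sort_values(["participant_id", "timestamp"],
                            kind="mergesort").reset_index(drop=True)

    truth = {
        "seed": cfg.seed,
        "arms": {pid: arm for pid, arm in zip(pids, arms)},
        "logit_cell_means": cfg.logit_cell_means,
        "fixed_effects": _coef_truth(cfg.logit_cell_means),
        "random_intercept_sd": cfg.random_intercept_sd,
        "residual_sd": cfg.residual_sd,
        "qids": {
            "baseline_mean": cfg.qids_baseline_mean,
            "mph_main": cfg.qids_mph_main,
            "week_effects": cfg.qids_week_effects,
            "arm_week_offsets": cfg.qids_arm_week_offsets,
        },
        "dropouts": {pids[i]: w for i, w in sorted(dropouts.items())},
        "config": cfg.to_dict(),
    }
    return TrialDataset(visits=visits, mems_events=mems, truth=truth)


def write_trial(ds: TrialDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write visits.csv, mems_events.csv and truth.json; returns the paths.

    Output is byte-stable for a fixed config (fixed float format, fixed row
    order).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "visits": out / "visits.csv",
        "mems_events": out / "mems_events.csv",
        "truth": out / "truth.json",
    }
    ds.visits.to_csv(paths["visits"], index=False, float_format="%.6g")
    ds.mems_events.to_csv(paths["mems_events"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(ds.truth, fh, indent=2, sort_keys=True)
    return paths
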