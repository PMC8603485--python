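import numpy as np
import pandas as pd
import pytest

from gspilot.bayes import ModelSpec, default_priors, fit_lmm, logit_transform
from gspilot.design import BoundarySet, DesignSpec, solve_boundaries
from gspilot.endpoints import derive_adherence
from gspilot.generate import GeneratorConfig, generate_trial

N_DOSES_BY_WEEK = {2: 14, 4: 14, 8: 28}


def add_logit_columns(adherence: pd.DataFrame) -> pd.DataFrame:
    """Attach the analysis-scale outcomes used by the mixed model."""
    n = adherence["visit_week"].map(N_DOSES_BY_WEEK)
    return adherence.assign(
        pill_logit=[logit_transform(v, "shrink", n_doses=int(k))
                    for v, k in zip(adherence["pill_count_pct"], n)],
        mems_logit=[logit_transform(v, "shrink", n_doses=int(k))
                    for v, k in zip(adherence["mems_pct"], n)])


def adherence_from_seed(seed: int, n_participants: int = 20,
                        n_dropouts: int = 0):
    """Generate a trial and derive its analysis-ready adherence table."""
    cfg = GeneratorConfig(seed=seed, n_participants=n_participants,
                          n_dropouts=n_dropouts)
    ds = generate_trial(cfg)
    adh = add_logit_columns(derive_adherence(ds.visits, ds.mems_events))
    return adh, ds.truth


@pytest.fixture(scope="session")
def pilot_design():
    spec = DesignSpec()
    return spec, solve_boundaries(spec)


@pytest.fixture(scope="session")
def published_t_bounds():
    """The published t-scale boundaries: interim 0.404 (futility) / 2.960
    (efficacy) at 30 df, final 1.999 at 62 df."""
    return BoundarySet.from_t([0.404, 1.999], [2.960, 1.999], (30, 62))


@pytest.fixture(scope="session")
def small_trial():
    cfg = GeneratorConfig(seed=11, n_dropouts=0)
    return generate_trial(cfg)


@pytest.fixture(scope="session")
def small_fit(small_trial):
    adh = add_logit_columns(
        derive_adherence(small_trial.visits, small_trial.mems_events))
    return fit_lmm(adh, ModelSpec(), default_priors(), seed=3), small_trial
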