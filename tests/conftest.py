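"""Shared fixtures.

The three heavy simulation studies (OLS-oracle regime, three-group
parameter recovery, null network) are session-scoped so each multi-minute
MCMC fit runs once and is shared between the unit and acceptance layers.
"""

from __future__ import annotations

import numpy as np
import pytest

from bridgevar.catalog import default_catalog
from bridgevar.mlvar import MlvarSpec, fit_mlvar
from bridgevar.pipeline import PipelineConfig, run_pipeline
from bridgevar.preprocess import align_to_grid, reverse_code
from bridgevar.simulate import (GeneratorConfig, GroupSpec, ScheduleSpec,
                                default_config, default_innovation_cov,
                                simulate_panel)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def _grid_from(config):
    return align_to_grid(reverse_code(simulate_panel(config)), 180.0)


@pytest.fixture(scope="session")
def ols_study():
    """Single group, no random effects, complete data on a contiguous
    lattice (7 days x 8 prompts at 180 min => T=56): the regime where the
    hierarchical posterior must agree with pooled person-centred least
    squares."""
    base = default_config()
    gs = {"comorbid": GroupSpec(base.group_specs["comorbid"].phi_mean,
                                base.group_specs["comorbid"].mu_mean, 50)}
    cfg = GeneratorConfig(group_specs=gs, innovation_cov=default_innovation_cov(),
                          schedule=ScheduleSpec(days=7, prompts_per_day=8,
                                                interval_min=180.0),
                          re_sd_phi=0.0, re_sd_mu=0.0, miss_prob=0.0, seed=101)
    gridded = _grid_from(cfg)
    draws = fit_mlvar(gridded, chains=2, iterations=2000, seed=202)
    # pooled person-centred least squares on the same data
    Xs, Zs = [], []
    for pg in gridded.persons:
        z = pg.values - pg.values.mean(axis=0)
        Xs.append(z[:-1])
        Zs.append(z[1:])
    ols = np.linalg.lstsq(np.vstack(Xs), np.vstack(Zs), rcond=None)[0].T
    return {"config": cfg, "gridded": gridded, "draws": draws, "ols": ols,
            "truth": cfg.group_specs["comorbid"].phi_mean}


@pytest.fixture(scope="session")
def recovery_study():
    """Three groups x 30 persons on the full 5x14 design (jittered prompts,
    missed beeps, person random effects): group-lag recovery conditions."""
    cfg = default_config(seed=303, n_persons={"comorbid": 30,
                                              "depression_only": 30,
                                              "anxiety_only": 30})
    gridded = _grid_from(cfg)
    draws = fit_mlvar(gridded, chains=2, iterations=2000, seed=404)
    return {"config": cfg, "gridded": gridded, "draws": draws}


@pytest.fixture(scope="session")
def null_study():
    """All group lag matrices zero: calibration of CI pseudo-significance."""
    base = default_config()
    zero = np.zeros((7, 7))
    gs = {g: GroupSpec(zero, base.group_specs[g].mu_mean, 20)
          for g in base.group_specs}
    cfg = GeneratorConfig(group_specs=gs, innovation_cov=default_innovation_cov(),
                          schedule=ScheduleSpec(days=5, prompts_per_day=8,
                                                interval_min=180.0),
                          re_sd_phi=0.05, re_sd_mu=0.6, miss_prob=0.0, seed=505)
    gridded = _grid_from(cfg)
    draws = fit_mlvar(gridded, chains=2, iterations=1000, seed=606)
    return {"config": cfg, "gridded": gridded, "draws": draws}


def small_pipeline_config(seed: int = 7) -> PipelineConfig:
    return PipelineConfig(
        generator=default_config(
            n_persons={"comorbid": 4, "depression_only": 3, "anxiety_only": 3},
            schedule=ScheduleSpec(days=6, prompts_per_day=5, jitter_sd_min=10.0)),
        mlvar=MlvarSpec(chains=2, iterations=400, min_observed=8),
        seed=seed)


@pytest.fixture(scope="session")
def tiny_run(tmp_path_factory):
    """One full pipeline execution on a 10-person panel."""
    out = tmp_path_factory.mktemp("tiny_run")
    config = small_pipeline_config()
    manifest = run_pipeline(config, out)
    return {"config": config, "out": out, "manifest": manifest}
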