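"""Shared fixtures.

The expensive simulated-fit artifacts (random-intercept recovery fit,
within-area homogeneous/heterogeneous study fits, the 20-seed selection
experiment) are session-scoped so that module tests and the acceptance
checks reuse one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from synthprev import (
    ModelSpec,
    SurveyDataset,
    Variable,
    backward_select,
    fit_logistic,
    fit_random_intercept_logit,
    generate_population,
)
from synthprev.studies import (
    heterogeneous_areas_config,
    homogeneous_areas_config,
    recovery_config,
    selection_config,
    true_area_prevalence,
)


def make_dataset(df: pd.DataFrame, **variables) -> SurveyDataset:
    """Tiny helper: SurveyDataset from a frame plus kind declarations."""
    meta = {}
    for name, kind in variables.items():
        if isinstance(kind, tuple):
            meta[name] = Variable(name, "categorical", levels=list(kind[0]), reference=kind[1])
        else:
            meta[name] = Variable(name, kind)
    return SurveyDataset(df.copy(), meta)


@pytest.fixture(scope="session")
def recovery_dataset():
    """30 groups x 500, beta0=-1.5, beta_x=1.0, sigma_u=0.5."""
    return generate_population(recovery_config(seed=11))


@pytest.fixture(scope="session")
def recovery_fit(recovery_dataset):
    spec = ModelSpec.from_variables(
        "y", ["x"], recovery_dataset.variables, group="area_id"
    )
    return fit_random_intercept_logit(recovery_dataset, spec)


@pytest.fixture(scope="session")
def sigma0_dataset():
    """Same design with random_intercept_sd = 0."""
    return generate_population(recovery_config(sigma_u=0.0, seed=13))


@pytest.fixture(scope="session")
def homogeneous_study():
    """Within-area homogeneous covariates: config, data, pooled fit, truth."""
    cfg = homogeneous_areas_config(n_per_area=2000, seed=23)
    ds = generate_population(cfg)
    spec = ModelSpec.from_variables("y", ["x", "s"], ds.variables)
    model = fit_logistic(ds, spec)
    return cfg, ds, model, true_area_prevalence(cfg)


@pytest.fixture(scope="session")
def heterogeneous_study():
    """Within-area heterogeneous covariates (Jensen-gap regime)."""
    cfg = heterogeneous_areas_config(n_per_area=2000, seed=29)
    ds = generate_population(cfg)
    spec = ModelSpec.from_variables("y", ["x", "s"], ds.variables)
    model = fit_logistic(ds, spec)
    return cfg, ds, model, true_area_prevalence(cfg)


@pytest.fixture(scope="session")
def selection_experiment():
    """Backward selection under BIC, 20 seeds: per-seed retained term names."""
    retained = []
    for seed in range(20):
        ds = generate_population(selection_config(n=10_000, seed=100 + seed))
        spec = ModelSpec.from_variables("y", ["x1", "z1", "z2", "z3"], ds.variables)
        model = backward_select(ds, spec, criterion="bic")
        retained.append(set(model.spec.term_names))
    return retained
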