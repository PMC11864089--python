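"""Canned study conditions.

The bundled YAML configs (``examples/``) describe the desk-scale survey
emulation: ~28,600 respondents across 10 provinces and 28 health regions,
perceived-need prevalence ~18% and unmet-need prevalence ~3.9%, health-region
random intercepts with sd 0.3, unequal lognormal weights.  This module loads
them and also builds the smaller controlled designs used to probe specific
properties of the estimator: parameter recovery, selection consistency,
within-area covariate homogeneity (where the synthetic estimator is exact)
and within-area heterogeneity (where the Jensen gap appears).
"""

from __future__ import annotations

from importlib import resources

import yaml

from .simulate import OutcomeConfig, PredictorConfig, RegionConfig, SimulationConfig

EXAMPLE_LABELS = ("dev2018", "val2019", "val2020")


def example_config(label: str) -> SimulationConfig:
    """Load one of the bundled survey simulation configs by label."""
    if label not in EXAMPLE_LABELS:
        raise KeyError(f"unknown example config {label!r}; choose from {EXAMPLE_LABELS}")
    text = resources.files("synthprev").joinpath(f"examples/{label}.yaml").read_text()
    return SimulationConfig.from_dict(yaml.safe_load(text))


def example_run_config_path() -> str:
    """Filesystem path of the bundled end-to-end run configuration."""
    return str(resources.files("synthprev").joinpath("examples/study.yaml"))


def recovery_config(
    n_groups: int = 30,
    n_per_group: int = 500,
    beta0: float = -1.5,
    beta_x: float = 1.0,
    sigma_u: float = 0.5,
    seed: int = 11,
) -> SimulationConfig:
    """One binary predictor, known random-intercept sd: parameter recovery."""
    regions = [
        RegionConfig(area_id=f"g{i:02d}", province_id="p1", n=n_per_group)
        for i in range(n_groups)
    ]
    return SimulationConfig(
        predictors=[PredictorConfig("x", levels=["0", "1"], probs=[0.5, 0.5])],
        regions=regions,
        outcomes=[
            OutcomeConfig(
                "y",
                coefficients={"Intercept": beta0, "x[1]": beta_x},
                random_intercept_sd=sigma_u,
            )
        ],
        weight_sigma=0.0,
        cluster_size=1,
        seed=seed,
    )


def selection_config(n: int = 10_000, beta_true: float = 1.0, seed: int = 7) -> SimulationConfig:
    """One true binary predictor plus three null ones: selection consistency."""
    return SimulationConfig(
        predictors=[
            PredictorConfig("x1", levels=["0", "1"], probs=[0.5, 0.5]),
            PredictorConfig("z1", levels=["0", "1"], probs=[0.5, 0.5]),
            PredictorConfig("z2", levels=["0", "1"], probs=[0.5, 0.5]),
            PredictorConfig("z3", levels=["0", "1"], probs=[0.5, 0.5]),
        ],
        regions=[RegionConfig(area_id="a1", province_id="p1", n=n)],
        outcomes=[
            OutcomeConfig(
                "y", coefficients={"Intercept": -1.0, "x1[1]": beta_true}
            )
        ],
        weight_sigma=0.0,
        cluster_size=1,
        seed=seed,
    )


# Ten areas with distinct covariate mixes.  In the homogeneous design every
# respondent of an area sits in one covariate cell (degenerate level
# probabilities), so marginal-proportion synthetic estimation is exact; in
# the heterogeneous design areas mix the cells, which opens the Jensen gap.
_AREA_X_PROBS = [
    [1.0, 0.0], [0.0, 1.0], [1.0, 0.0], [0.0, 1.0], [1.0, 0.0],
    [0.0, 1.0], [1.0, 0.0], [0.0, 1.0], [1.0, 0.0], [0.0, 1.0],
]
_AREA_S_PROBS = [
    [1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0], [1.0, 0.0],
    [1.0, 0.0], [0.0, 1.0], [0.0, 1.0], [1.0, 0.0], [0.0, 1.0],
]


def homogeneous_areas_config(
    n_per_area: int = 2000,
    seed: int = 23,
    beta0: float = -3.5,
    beta_x: float = 0.4,
    beta_s: float = 0.7,
) -> SimulationConfig:
    """10 areas, each with a single within-area covariate pattern, sigma_u = 0.

    Defaults emulate the low-prevalence outcome (area prevalences ~3-8%):
    at that level the sampling noise of a 2000-respondent area (< ~0.7 pp at
    3 SEs) is small enough for observed-vs-predicted agreement to be
    informative about the estimator rather than about binomial noise.
    """
    regions = [
        RegionConfig(
            area_id=f"h{i:02d}",
            province_id=f"p{i % 2 + 1}",
            n=n_per_area,
            overrides={"x": _AREA_X_PROBS[i], "s": _AREA_S_PROBS[i]},
        )
        for i in range(10)
    ]
    return _two_predictor_config(regions, beta0, beta_x, beta_s, seed)


def heterogeneous_areas_config(
    n_per_area: int = 2000,
    seed: int = 29,
    beta0: float = -2.0,
    beta_x: float = 1.2,
    beta_s: float = 1.8,
) -> SimulationConfig:
    """10 areas mixing covariate cells in different shares, sigma_u = 0.

    Defaults use strong effects (risk spread comparable to the fitted
    survey models) so the Jensen gap between marginal-proportion synthetic
    estimation and individual-prediction aggregation is visible.
    """
    regions = [
        RegionConfig(
            area_id=f"h{i:02d}",
            province_id=f"p{i % 2 + 1}",
            n=n_per_area,
            overrides={
                "x": [1.0 - 0.05 * (i + 1), 0.05 * (i + 1)],
                "s": [0.9 - 0.06 * i, 0.1 + 0.06 * i],
            },
        )
        for i in range(10)
    ]
    return _two_predictor_config(regions, beta0, beta_x, beta_s, seed)


def _two_predictor_config(regions, beta0, beta_x, beta_s, seed) -> SimulationConfig:
    return SimulationConfig(
        predictors=[
            PredictorConfig("x", levels=["0", "1"], probs=[0.5, 0.5]),
            PredictorConfig("s", levels=["0", "1"], probs=[0.5, 0.5]),
        ],
        regions=regions,
        outcomes=[
            OutcomeConfig(
                "y",
                coefficients={"Intercept": beta0, "x[1]": beta_x, "s[1]": beta_s},
                random_intercept_sd=0.0,
            )
        ],
        weight_sigma=0.3,
        cluster_size=10,
        seed=seed,
    )


def true_area_prevalence(config: SimulationConfig, outcome: str = "y") -> dict[str, float]:
    """Exact per-area outcome probability implied by a config (sigma_u = 0 only).

    Enumerates the categorical cells of each area; percent scale.
    """
    import itertools

    import numpy as np
    from scipy.special import expit

    out = next(o for o in config.outcomes if o.name == outcome)
    if out.random_intercept_sd != 0:
        raise ValueError("exact area prevalences require random_intercept_sd = 0")
    result = {}
    for region in config.regions:
        total = 0.0
        axes = []
        for p in config.predictors:
            if p.kind != "categorical":
                raise ValueError("exact enumeration needs categorical predictors only")
            probs = region.overrides.get(p.name, p.probs)
            axes.append([(p.name, lv, pr) for lv, pr in zip(p.levels, probs)])
        for cell in itertools.product(*axes):
            pcell = float(np.prod([pr for _, _, pr in cell]))
            if pcell == 0.0:
                continue
            eta = out.coefficients["Intercept"] + sum(
                out.coefficients.get(f"{var}[{lv}]", 0.0) for var, lv, _ in cell
            )
            total += pcell * float(expit(eta))
        result[region.area_id] = 100.0 * total
    return result
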