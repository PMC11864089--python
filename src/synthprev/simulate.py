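"""Survey microdata simulator.

Generates respondent-level data with the nesting structure of a national
health survey: respondents within sampling clusters within health regions
(the ``area_id`` level) within provinces.  Binary outcomes are drawn from a
logistic model with a known fixed-effect vector and a health-region random
intercept, so every downstream stage (model fitting, performance metrics,
synthetic estimation) can be checked against ground truth.

Design weights are unequal (lognormal noise around an equal-probability
baseline, normalized to mean 1 within each province) and bootstrap replicate
weights follow the Rao-Wu-Yue rescaled cluster bootstrap, the standard
design-consistent scheme for surveys that ship replicate weights instead of
design variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import BSW_PREFIX, SurveyDataset, Variable
from .errors import ConfigurationError

_PROB_TOL = 1e-12


def term_name(variable: str, level: str | None = None) -> str:
    """Design-matrix term name: ``var[level]`` for a dummy, ``var`` otherwise."""
    return f"{variable}[{level}]" if level is not None else variable


@dataclass
class PredictorConfig:
    """One simulated predictor and its default distribution."""

    name: str
    kind: str = "categorical"  # or "continuous"
    levels: list[str] | None = None
    reference: str | None = None
    probs: list[float] | None = None  # categorical level probabilities
    mean: float = 0.0  # continuous
    sd: float = 1.0

    def __post_init__(self):
        if self.kind == "categorical":
            if not self.levels:
                raise ConfigurationError(f"categorical predictor {self.name!r} needs levels")
            if self.reference is None:
                self.reference = self.levels[0]
            if self.probs is None:
                self.probs = [1.0 / len(self.levels)] * len(self.levels)
            _check_probs(self.name, self.probs, len(self.levels))
        elif self.kind == "continuous":
            if self.sd < 0:
                raise ConfigurationError(f"predictor {self.name!r}: sd must be nonnegative")
        else:
            raise ConfigurationError(f"unknown predictor kind {self.kind!r}")

    def terms(self) -> list[str]:
        """Coefficient terms this predictor can produce (reference excluded)."""
        if self.kind == "continuous":
            return [self.name]
        return [term_name(self.name, lv) for lv in self.levels if lv != self.reference]


def _check_probs(name: str, probs: list[float], k: int) -> None:
    if len(probs) != k:
        raise ConfigurationError(f"predictor {name!r}: {len(probs)} probabilities for {k} levels")
    if any(p < 0 for p in probs):
        raise ConfigurationError(f"predictor {name!r}: negative level probability")
    if abs(sum(probs) - 1.0) > _PROB_TOL:
        raise ConfigurationError(
            f"predictor {name!r}: level probabilities sum to {sum(probs)!r}, not 1"
        )


@dataclass
class RegionConfig:
    """One health region: id, parent province and sample size.

    ``overrides`` replaces a predictor's default distribution in this region:
    categorical -> list of level probabilities, continuous -> {mean:, sd:}.
    """

    area_id: str
    province_id: str
    n: int
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        self.area_id = str(self.area_id)
        self.province_id = str(self.province_id)
        if self.n < 1:
            raise ConfigurationError(f"region {self.area_id!r}: size must be >= 1")


@dataclass
class OutcomeConfig:
    """A binary outcome's generative logistic model."""

    name: str
    coefficients: dict[str, float]
    random_intercept_sd: float = 0.0

    def __post_init__(self):
        if self.random_intercept_sd < 0:
            raise ConfigurationError(f"outcome {self.name!r}: random_intercept_sd must be >= 0")
        if "Intercept" not in self.coefficients:
            raise ConfigurationError(f"outcome {self.name!r}: coefficients must include 'Intercept'")


@dataclass
class SimulationConfig:
    """Full generative description of one survey dataset."""

    predictors: list[PredictorConfig]
    regions: list[RegionConfig]
    outcomes: list[OutcomeConfig]
    weight_sigma: float = 0.5  # sd of log weight noise
    cluster_size: int = 10  # respondents per synthetic dwelling cluster
    n_bootstrap: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_bootstrap < 0:
            raise ConfigurationError("n_bootstrap must be >= 0")
        if self.cluster_size < 1:
            raise ConfigurationError("cluster_size must be >= 1")
        if self.weight_sigma < 0:
            raise ConfigurationError("weight_sigma must be >= 0")
        names = [p.name for p in self.predictors]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate predictor names")
        producible = {t for p in self.predictors for t in p.terms()}
        for out in self.outcomes:
            for term in out.coefficients:
                if term != "Intercept" and term not in producible:
                    raise ConfigurationError(
                        f"outcome {out.name!r}: coefficient term {term!r} is not "
                        f"producible from the predictor descriptors"
                    )
        for region in self.regions:
            pred_by_name = {p.name: p for p in self.predictors}
            for pname, ov in region.overrides.items():
                if pname not in pred_by_name:
                    raise ConfigurationError(
                        f"region {region.area_id!r} overrides unknown predictor {pname!r}"
                    )
                p = pred_by_name[pname]
                if p.kind == "categorical":
                    _check_probs(f"{pname}@{region.area_id}", list(ov), len(p.levels))

    # ----------------------------------------------------------------- io
    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        predictors = [PredictorConfig(**p) for p in d["predictors"]]
        regions = [RegionConfig(**r) for r in d["regions"]]
        if "outcomes" in d:
            outcomes = [OutcomeConfig(**o) for o in d["outcomes"]]
        else:  # single-outcome shorthand
            outcomes = [
                OutcomeConfig(
                    name=d.get("outcome_name", "outcome"),
                    coefficients=d["coefficients"],
                    random_intercept_sd=d.get("random_intercept_sd", 0.0),
                )
            ]
        kwargs = {
            k: d[k]
            for k in ("weight_sigma", "cluster_size", "n_bootstrap", "seed")
            if k in d
        }
        return cls(predictors=predictors, regions=regions, outcomes=outcomes, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------- generation


def generate_population(config: SimulationConfig, seed: int | None = None) -> SurveyDataset:
    """Draw a full survey dataset from ``config``.

    For each health region one random intercept per outcome is drawn from
    Normal(0, random_intercept_sd^2); respondents' predictors come from the
    region's distributions; each outcome is Bernoulli(expit(eta)) with
    eta = beta0 + sum_j beta_j x_j + u_area.  Identical (config, seed) give a
    bit-identical dataset.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pred_by_name = {p.name: p for p in config.predictors}

    frames = []
    rid0 = 0
    for region in config.regions:
        n = region.n
        cols: dict[str, np.ndarray] = {
            "respondent_id": np.arange(rid0, rid0 + n),
            "area_id": np.repeat(region.area_id, n),
            "province_id": np.repeat(region.province_id, n),
            "cluster_id": np.array(
                [f"{region.area_id}-{i // config.cluster_size}" for i in range(n)]
            ),
        }
        rid0 += n
        for p in config.predictors:
            ov = region.overrides.get(p.name)
            if p.kind == "categorical":
                probs = np.asarray(ov if ov is not None else p.probs, float)
                idx = rng.choice(len(p.levels), size=n, p=probs / probs.sum())
                cols[p.name] = np.asarray(p.levels, object)[idx]
            else:
                mean, sd = p.mean, p.sd
                if ov is not None:
                    mean = ov.get("mean", mean)
                    sd = ov.get("sd", sd)
                cols[p.name] = rng.normal(mean, sd, size=n)
        frames.append(pd.DataFrame(cols))
    df = pd.concat(frames, ignore_index=True)

    # linear predictors and outcomes; one random intercept per (region, outcome)
    for out in config.outcomes:
        eta = np.full(len(df), out.coefficients["Intercept"], float)
        for term, beta in out.coefficients.items():
            if term == "Intercept":
                continue
            if "[" in term:
                var, level = term[:-1].split("[", 1)
                eta += beta * (df[var].to_numpy() == level)
            else:
                eta += beta * df[term].to_numpy(float)
        u_by_region = {
            r.area_id: rng.normal(0.0, out.random_intercept_sd) for r in config.regions
        }
        eta += df["area_id"].map(u_by_region).to_numpy(float)
        p = 1.0 / (1.0 + np.exp(-eta))
        df[out.name] = (rng.random(len(df)) < p).astype(int)

    # design weights: lognormal noise, normalized to mean 1 per province
    w = rng.lognormal(mean=0.0, sigma=config.weight_sigma, size=len(df))
    df["weight"] = w / df.groupby("province_id", observed=True)["respondent_id"].transform(
        lambda s: w[s.index].mean()
    )

    variables = {p.name: _predictor_variable(p) for p in config.predictors}
    for out in config.outcomes:
        variables[out.name] = Variable(out.name, "binary")
    dataset = SurveyDataset(df, variables)
    if config.n_bootstrap > 0:
        dataset = make_replicate_weights(
            dataset, config.n_bootstrap, seed=int(rng.integers(2**31))
        )
    dataset.validate()
    return dataset


def _predictor_variable(p: PredictorConfig) -> Variable:
    if p.kind == "categorical":
        return Variable(p.name, "categorical", levels=list(p.levels), reference=p.reference)
    return Variable(p.name, "continuous")


def make_replicate_weights(
    dataset: SurveyDataset, n_bootstrap: int, seed: int
) -> SurveyDataset:
    """Attach Rao-Wu-Yue rescaled cluster-bootstrap replicate weights.

    Within each province stratum, n_h - 1 of the n_h sampling clusters are
    resampled with replacement per replicate and design weights rescaled by
    (n_h / (n_h - 1)) * (times selected); a single-cluster stratum keeps its
    design weights (resampling a singleton is the identity).  Each replicate's
    weighted total equals the full-sample total in expectation.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    dataset.require_columns(["weight", "province_id"])
    df = dataset.df.drop(columns=dataset.replicate_columns)
    rng = np.random.default_rng(seed)

    if "cluster_id" in df.columns:
        cluster = df["cluster_id"].to_numpy()
    else:  # each respondent is its own cluster
        cluster = df.index.to_numpy().astype(str)

    w = df["weight"].to_numpy(float)
    mult = np.ones((len(df), n_bootstrap))
    for _, idx in df.groupby("province_id", observed=True).indices.items():
        clusters_h, inv = np.unique(cluster[idx], return_inverse=True)
        n_h = len(clusters_h)
        if n_h == 1:
            continue
        counts = rng.multinomial(n_h - 1, np.full(n_h, 1.0 / n_h), size=n_bootstrap)
        mult[idx, :] = (n_h / (n_h - 1)) * counts[:, inv].T

    bsw = pd.DataFrame(
        mult * w[:, None],
        columns=[f"{BSW_PREFIX}{b + 1}" for b in range(n_bootstrap)],
        index=df.index,
    )
    return SurveyDataset(pd.concat([df, bsw], axis=1), dataset.variables)
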