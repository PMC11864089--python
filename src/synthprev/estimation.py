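"""Regression synthetic estimation of area-level prevalence.

The estimator converts an individual-level logistic model into an area
prevalence forecast without refitting anything at the area level:

1. build the area's predictor profile — the weighted proportion of each
   non-reference categorical level and the weighted mean of each continuous
   term among the area's respondents;
2. apply the fitted coefficients to the profile,
   eta_a = beta_0 + sum_j beta_j * xbar_{aj}, with the random intercept set
   to 0 (new areas and new years carry no estimated intercept);
3. report 100 * expit(eta_a) as the predicted proportion.

Because expit is nonlinear, applying coefficients to marginal proportions
is not the same as averaging individual predictions (Jensen's inequality);
:func:`individual_aggregation_estimate` exposes the latter as an oracle so
the aggregation gap can be quantified.  Validation compares predicted with
observed weighted proportions; the comparison metric is the signed
difference predicted - observed, on the percent scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .dataset import SurveyDataset, WEIGHT_COLUMN
from .errors import EstimationError, SchemaError
from .fit import FittedModel
from .modelspec import INTERCEPT, ModelSpec, design_matrix
from .performance import predict_prob
from .survey import bootstrap_se, weighted_proportion

logger = logging.getLogger(__name__)


@dataclass
class AreaProfile:
    """Area-level values of every model term (the 'parallel predictor set')."""

    area_id: str
    term_values: dict[str, float]  # design column -> weighted proportion/mean
    n_respondents: int
    weight_total: float


@dataclass
class EstimateRecord:
    """One area's observed/predicted proportions on the percent scale."""

    area_id: str
    label: str = ""
    observed: float | None = None
    predicted: float | None = None
    difference: float | None = None
    observed_se: float | None = None
    predicted_se: float | None = None


def area_profile(
    dataset: SurveyDataset,
    spec: ModelSpec,
    area: str | None = None,
    by: str = "area_id",
    weights: str = WEIGHT_COLUMN,
) -> AreaProfile:
    """Weighted term values over one area's respondents (design weights).

    ``area=None`` profiles the whole dataset.  Term values are the weighted
    means of the design-matrix columns: the level proportion for a dummy,
    the mean for a continuous term, the mean product for an interaction.
    """
    data = dataset if area is None else dataset.subset((dataset.df[by].astype(str) == str(area)).to_numpy())
    if data.n == 0:
        raise EstimationError(f"area {area!r} has no respondents")
    X, names = design_matrix(data, spec, check_rank=False)
    w = data.df[weights].to_numpy(float)
    if w.sum() <= 0:
        raise EstimationError(f"area {area!r} has zero total weight")
    values = (w @ X) / w.sum()
    term_values = {nm: float(v) for nm, v in zip(names, values) if nm != INTERCEPT}
    return AreaProfile(
        area_id=str(area) if area is not None else "(all)",
        term_values=term_values,
        n_respondents=data.n,
        weight_total=float(w.sum()),
    )


def synthetic_logit(model: FittedModel, profile: AreaProfile) -> float:
    """eta_a = beta_0 + sum_j beta_j * term_value_j (random intercept 0)."""
    missing = [t for t in model.beta if t != INTERCEPT and t not in profile.term_values]
    if missing:
        raise SchemaError(f"area profile is missing model terms: {missing}")
    eta = model.beta[INTERCEPT]
    for term, beta in model.beta.items():
        if term != INTERCEPT:
            eta += beta * profile.term_values[term]
    return float(eta)


def synthetic_estimate(
    model: FittedModel, profile: AreaProfile, blup: float = 0.0
) -> EstimateRecord:
    """Predicted proportion 100 * expit(eta_a) for one area.

    ``blup`` optionally adds a known random-intercept prediction on the
    logit scale (development-data areas only).
    """
    eta = synthetic_logit(model, profile) + blup
    return EstimateRecord(area_id=profile.area_id, predicted=100.0 * float(expit(eta)))


def individual_aggregation_estimate(
    model: FittedModel,
    dataset: SurveyDataset,
    area: str | None = None,
    by: str = "area_id",
) -> float:
    """Oracle estimator: weighted mean of respondent-level expit(x_i' beta).

    Differs from the synthetic estimate exactly by the Jensen gap of expit
    over the area's covariate distribution; equals it when all respondents
    share one covariate pattern.
    """
    data = dataset if area is None else dataset.subset((dataset.df[by].astype(str) == str(area)).to_numpy())
    if data.n == 0:
        raise EstimationError(f"area {area!r} has no respondents")
    risk = predict_prob(model, data, mode="population_average")
    w = data.df[WEIGHT_COLUMN].to_numpy(float)
    if w.sum() <= 0:
        raise EstimationError(f"area {area!r} has zero total weight")
    return 100.0 * float(np.dot(w, risk) / w.sum())


def absolute_difference(predicted: float, observed: float) -> float:
    """Signed validation metric predicted - observed, both on the percent scale.

    (Called an 'absolute' difference in small-area validation tables, but the
    sign is kept; rounding to 2 decimals happens only at serialization.)
    """
    return predicted - observed


def validate(
    model: FittedModel,
    dataset: SurveyDataset,
    by: str = "province_id",
    label: str = "",
    use_blup: bool = False,
    bootstrap: bool = False,
) -> list[EstimateRecord]:
    """Observed vs synthetic-predicted proportions per area of ``dataset``.

    Profiles are computed from this dataset (the target year); areas with no
    respondents are skipped with a logged warning.  With ``bootstrap=True``
    both proportions get replicate-weight standard errors.
    """
    dataset.require_columns([by, model.spec.outcome, WEIGHT_COLUMN])
    records: list[EstimateRecord] = []
    for area in sorted(dataset.df[by].astype(str).unique()):
        sub = dataset.subset((dataset.df[by].astype(str) == area).to_numpy())
        if sub.n == 0:
            logger.warning("area %s has no respondents; skipped", area)
            continue
        try:
            rec = _validate_area(model, sub, area, label, use_blup, bootstrap)
        except (EstimationError, SchemaError) as exc:
            logger.warning("area %s skipped: %s", area, exc)
            continue
        records.append(rec)
    return records


def _validate_area(model, sub, area, label, use_blup, bootstrap) -> EstimateRecord:
    observed = weighted_proportion(sub, model.spec.outcome).value
    blup = model.blups.get(area, 0.0) if use_blup else 0.0
    profile = area_profile(sub, model.spec)
    profile.area_id = area
    predicted = synthetic_estimate(model, profile, blup=blup).predicted
    rec = EstimateRecord(
        area_id=area,
        label=label,
        observed=observed,
        predicted=predicted,
        difference=absolute_difference(predicted, observed),
    )
    if bootstrap:
        rec.observed_se = bootstrap_se(
            lambda ds, wcol: weighted_proportion(ds, model.spec.outcome, wcol).value, sub
        )
        rec.predicted_se = bootstrap_se(
            lambda ds, wcol: synthetic_estimate(
                model, area_profile(ds, model.spec, weights=wcol), blup=blup
            ).predicted,
            sub,
        )
    return rec


def records_to_frame(records: list[EstimateRecord]) -> pd.DataFrame:
    """Serializable validation table (proportions rounded to 2 decimals)."""
    rows = []
    for r in records:
        rows.append(
            {
                "area": r.area_id,
                "label": r.label,
                "observed_pct": None if r.observed is None else round(r.observed, 2),
                "predicted_pct": None if r.predicted is None else round(r.predicted, 2),
                "difference_pct": None if r.difference is None else round(r.difference, 2),
                "observed_se": None if r.observed_se is None else round(r.observed_se, 4),
                "predicted_se": None if r.predicted_se is None else round(r.predicted_se, 4),
            }
        )
    return pd.DataFrame(rows)
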