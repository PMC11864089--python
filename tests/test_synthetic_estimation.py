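"""Area profiles, synthetic estimation, the aggregation oracle, validation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from synthprev import (
    EstimationError,
    FittedModel,
    ModelSpec,
    absolute_difference,
    area_profile,
    fit_logistic,
    individual_aggregation_estimate,
    records_to_frame,
    synthetic_estimate,
    synthetic_logit,
    validate,
)
from synthprev.estimation import AreaProfile
from synthprev.modelspec import CategoricalTerm

from conftest import make_dataset


def _model(beta, terms=()):
    """Hand-built FittedModel around a coefficient map."""
    return FittedModel(
        beta=beta, sigma_u=0.0, loglik=0.0, aic=0.0, bic=0.0, n_obs=0,
        cov_beta=np.zeros((len(beta), len(beta))),
        spec=ModelSpec(outcome="y", terms=list(terms)),
    )


def _profile(values):
    return AreaProfile(area_id="a", term_values=values, n_respondents=1, weight_total=1.0)


# -------------------------------------------------------------- area profile


def test_area_profile_hand_values():
    df = pd.DataFrame(
        {"y": [0, 0, 1, 1], "g": ["A", "A", "B", "B"], "weight": [1.0, 1.0, 1.0, 1.0],
         "area_id": ["a"] * 4, "province_id": ["p"] * 4}
    )
    ds = make_dataset(df, y="binary", g=(["B", "A"], "B"))
    spec = ModelSpec.from_variables("y", ["g"], ds.variables)
    prof = area_profile(ds, spec, area="a")
    assert prof.term_values == {"g[A]": pytest.approx(0.5)}
    assert prof.n_respondents == 4
    # level shares including the implicit reference sum to 1
    assert prof.term_values["g[A]"] + 0.5 == pytest.approx(1.0)


def test_area_profile_reference_only_area_gives_zeros():
    df = pd.DataFrame(
        {"y": [0, 1, 0], "g": ["B", "B", "B"], "weight": [1.0, 2.0, 1.0],
         "area_id": ["a"] * 3, "province_id": ["p"] * 3}
    )
    ds = make_dataset(df, y="binary", g=(["B", "A"], "B"))
    spec = ModelSpec.from_variables("y", ["g"], ds.variables)
    assert area_profile(ds, spec, area="a").term_values["g[A]"] == 0.0


def test_area_profile_interaction_term_is_weighted_mean_product():
    df = pd.DataFrame(
        {"y": [0, 1, 0, 1], "x": ["0", "1", "0", "1"], "z": [1.0, 2.0, 3.0, 4.0],
         "weight": [1.0, 1.0, 1.0, 3.0], "area_id": ["a"] * 4, "province_id": ["p"] * 4}
    )
    ds = make_dataset(df, y="binary", x=(["0", "1"], "0"), z="continuous")
    spec = ModelSpec.from_variables("y", ["x", "z", "x:z"], ds.variables)
    prof = area_profile(ds, spec, area="a")
    # weighted mean of 1(x=1) * z: (0 + 2 + 0 + 3*4) / 6
    assert prof.term_values["x[1]:z"] == pytest.approx(14.0 / 6.0)
    assert prof.term_values["z"] == pytest.approx((1 + 2 + 3 + 12) / 6.0)


def test_area_profile_empty_area_raises():
    df = pd.DataFrame({"y": [0], "weight": [1.0], "area_id": ["a"], "province_id": ["p"]})
    ds = make_dataset(df, y="binary")
    with pytest.raises(EstimationError):
        area_profile(ds, ModelSpec(outcome="y", terms=[]), area="missing")


# --------------------------------------------------- synthetic logit/estimate


def test_synthetic_logit_closed_forms():
    term = CategoricalTerm("x", ("0", "1"), "0")
    assert synthetic_logit(_model({"Intercept": 0.0}), _profile({})) == 0.0
    m = _model({"Intercept": -2.0, "x[1]": 1.0}, terms=[term])
    assert synthetic_logit(m, _profile({"x[1]": 0.5})) == pytest.approx(-1.5)
    assert synthetic_logit(m, _profile({"x[1]": 0.0})) == pytest.approx(-2.0)


def test_synthetic_estimate_percent_scale():
    term = CategoricalTerm("x", ("0", "1"), "0")
    m = _model({"Intercept": -2.0, "x[1]": 1.0}, terms=[term])
    rec = synthetic_estimate(m, _profile({"x[1]": 0.5}))
    assert rec.predicted == pytest.approx(100 * expit(-1.5), abs=1e-10)
    assert rec.predicted == pytest.approx(18.2426, abs=1e-4)
    m0 = _model({"Intercept": float(logit(0.18))})
    assert synthetic_estimate(m0, _profile({})).predicted == pytest.approx(18.0)


def test_monotone_in_positive_coefficient_terms():
    term = CategoricalTerm("x", ("0", "1"), "0")
    m = _model({"Intercept": -1.0, "x[1]": 0.7}, terms=[term])
    vals = [synthetic_estimate(m, _profile({"x[1]": v})).predicted for v in (0.1, 0.4, 0.9)]
    assert vals[0] < vals[1] < vals[2]
    assert all(0 < v < 100 for v in vals)


# ------------------------------------------------------- aggregation oracle


def test_jensen_gap_two_pattern_toy_area():
    """Patterns eta=-2 and eta=0 with equal weight: individual aggregation
    gives 30.96%, the pooled-proportion synthetic estimate 26.89%."""
    df = pd.DataFrame(
        {"y": [0, 0], "x": ["0", "1"], "weight": [1.0, 1.0],
         "area_id": ["a", "a"], "province_id": ["p", "p"]}
    )
    ds = make_dataset(df, y="binary", x=(["0", "1"], "0"))
    term = CategoricalTerm("x", ("0", "1"), "0")
    m = _model({"Intercept": -2.0, "x[1]": 2.0}, terms=[term])
    indiv = individual_aggregation_estimate(m, ds, area="a")
    assert indiv == pytest.approx(100 * (expit(-2.0) + expit(0.0)) / 2, abs=1e-9)
    assert indiv == pytest.approx(30.96, abs=0.01)
    prof = area_profile(ds, m.spec, area="a")
    synth = synthetic_estimate(m, prof).predicted
    assert synth == pytest.approx(100 * expit(-1.0), abs=1e-9)
    assert synth == pytest.approx(26.89, abs=0.01)


def test_oracle_equivalence_under_homogeneity(homogeneous_study):
    """One covariate pattern per area: synthetic == individual aggregation."""
    _, ds, model, _ = homogeneous_study
    for area in ds.df["area_id"].unique():
        prof = area_profile(ds, model.spec, area=area)
        synth = synthetic_estimate(model, prof).predicted
        indiv = individual_aggregation_estimate(model, ds, area=area)
        assert synth == pytest.approx(indiv, abs=1e-9)


# ------------------------------------------------------------------ validate


def test_absolute_difference_published_pairs():
    assert absolute_difference(14.57, 14.9) == pytest.approx(-0.33)
    assert absolute_difference(19.94, 16.57) == pytest.approx(3.37)
    assert absolute_difference(7.3, 7.3) == 0.0


def test_validate_intercept_only_reproduces_weighted_mean():
    rng = np.random.default_rng(12)
    n = 500
    df = pd.DataFrame(
        {"y": rng.integers(0, 2, n), "weight": rng.lognormal(0, 0.4, n),
         "area_id": ["a"] * n, "province_id": ["p"] * n}
    )
    ds = make_dataset(df, y="binary")
    spec = ModelSpec(outcome="y", terms=[], use_weights=True)
    m = fit_logistic(ds, spec)
    (rec,) = validate(m, ds, by="province_id")
    assert rec.difference == pytest.approx(0.0, abs=1e-9)
    assert rec.difference == pytest.approx(rec.predicted - rec.observed, abs=1e-12)


def test_validate_homogeneous_areas_within_one_point(homogeneous_study):
    """Within-area homogeneity: max |predicted - observed| < 1 pp."""
    _, ds, model, _ = homogeneous_study
    records = validate(model, ds, by="area_id")
    assert len(records) == 10
    assert max(abs(r.difference) for r in records) < 1.0


def test_end_to_end_recovery_of_true_prevalence(homogeneous_study):
    """Synthetic estimates match the generative truth within 3 MC SEs in >= 9/10 areas."""
    cfg, ds, model, truth = homogeneous_study
    hits = 0
    for region in cfg.regions:
        prof = area_profile(ds, model.spec, area=region.area_id)
        pred = synthetic_estimate(model, prof).predicted
        p = truth[region.area_id] / 100.0
        se = 100 * np.sqrt(p * (1 - p) / region.n)
        hits += abs(pred - truth[region.area_id]) < 3 * se
    assert hits >= 9


def test_heterogeneity_opens_jensen_gap(heterogeneous_study):
    """Individual aggregation tracks observed prevalence better than the
    marginal-proportion synthetic estimator when areas mix covariate cells."""
    _, ds, model, _ = heterogeneous_study
    records = validate(model, ds, by="area_id")
    synth_err, indiv_err, gaps = [], [], []
    for r in records:
        indiv = individual_aggregation_estimate(model, ds, area=r.area_id)
        synth_err.append(abs(r.difference))
        indiv_err.append(abs(indiv - r.observed))
        gaps.append(abs(indiv - r.predicted))
    assert max(gaps) > 0.5  # the two estimators genuinely differ
    assert np.mean(indiv_err) < np.mean(synth_err)


def test_records_frame_rounding_self_consistent(homogeneous_study):
    _, ds, model, _ = homogeneous_study
    frame = records_to_frame(validate(model, ds, by="area_id"))
    recomputed = (frame["predicted_pct"] - frame["observed_pct"]).round(2)
    assert np.allclose(recomputed, frame["difference_pct"], atol=0.011)
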