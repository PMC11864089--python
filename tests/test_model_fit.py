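"""Logistic and random-intercept logistic fitting, selection, criteria."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from synthprev import (
    DesignMatrixError,
    ModelSpec,
    SeparationError,
    SpecificationError,
    backward_select,
    fit_logistic,
    fit_random_intercept_logit,
    generate_population,
)
from synthprev.fit import FittedModel
from synthprev.studies import recovery_config

from conftest import make_dataset


def test_intercept_only_closed_form():
    rng = np.random.default_rng(4)
    y = (rng.random(500) < 0.23).astype(int)
    ds = make_dataset(pd.DataFrame({"y": y, "weight": np.ones(500)}), y="binary")
    m = fit_logistic(ds, ModelSpec(outcome="y", terms=[]))
    assert m.beta["Intercept"] == pytest.approx(float(logit(y.mean())), abs=1e-6)
    assert m.sigma_u == 0.0


def test_perfect_separation_raises():
    df = pd.DataFrame(
        {"y": [0, 0, 0, 1, 1, 1], "x": list("aaabbb"), "weight": np.ones(6)}
    )
    ds = make_dataset(df, y="binary", x=(["a", "b"], "a"))
    spec = ModelSpec.from_variables("y", ["x"], ds.variables)
    with pytest.raises(SeparationError):
        fit_logistic(ds, spec)


def test_rank_deficiency_names_collinear_terms():
    df = pd.DataFrame(
        {"y": [0, 1, 0, 1, 1, 0], "x": [0.0, 1, 2, 3, 4, 5], "x2": [0.0, 2, 4, 6, 8, 10],
         "weight": np.ones(6)}
    )
    ds = make_dataset(df, y="binary", x="continuous", x2="continuous")
    spec = ModelSpec.from_variables("y", ["x", "x2"], ds.variables)
    with pytest.raises(DesignMatrixError) as err:
        fit_logistic(ds, spec)
    assert err.value.collinear_terms


def test_plain_logistic_parameter_recovery():
    """n = 20,000 with beta = (-2.0, 0.8): estimates within 3 SEs of truth."""
    cfg = recovery_config(n_groups=1, n_per_group=20_000, beta0=-2.0, beta_x=0.8,
                          sigma_u=0.0, seed=17)
    ds = generate_population(cfg)
    spec = ModelSpec.from_variables("y", ["x"], ds.variables)
    m = fit_logistic(ds, spec)
    for term, truth in [("Intercept", -2.0), ("x[1]", 0.8)]:
        assert abs(m.beta[term] - truth) < 3 * m.se(term), term


def test_information_criterion_identities(recovery_fit):
    k = len(recovery_fit.beta) + 1  # fixed effects + variance parameter
    assert recovery_fit.aic == pytest.approx(-2 * recovery_fit.loglik + 2 * k, abs=1e-9)
    assert recovery_fit.bic == pytest.approx(
        -2 * recovery_fit.loglik + k * np.log(recovery_fit.n_obs), abs=1e-9
    )


def test_random_intercept_parameter_recovery(recovery_fit):
    """30 groups x 500 with (beta0, beta_x, sigma_u) = (-1.5, 1.0, 0.5)."""
    m = recovery_fit
    for term, truth in [("Intercept", -1.5), ("x[1]", 1.0)]:
        assert abs(m.beta[term] - truth) < 3 * m.se(term), term
    assert m.sigma_u_se is not None
    assert abs(m.sigma_u - 0.5) < 3 * m.sigma_u_se
    assert len(m.blups) == 30
    # BLUPs shrink toward zero and correlate with the group effects' scale
    assert np.std(list(m.blups.values())) < 1.5 * m.sigma_u


def test_sigma_zero_limit_agrees_with_plain_logistic(sigma0_dataset):
    spec0 = ModelSpec.from_variables("y", ["x"], sigma0_dataset.variables)
    spec_g = ModelSpec.from_variables("y", ["x"], sigma0_dataset.variables, group="area_id")
    plain = fit_logistic(sigma0_dataset, spec0)
    mixed = fit_random_intercept_logit(sigma0_dataset, spec_g)
    assert mixed.sigma_u <= 0.05
    for term in plain.beta:
        assert mixed.beta[term] == pytest.approx(plain.beta[term], abs=1e-3)


def test_mixed_loglik_nests_plain_loglik(recovery_dataset, recovery_fit):
    spec0 = ModelSpec.from_variables("y", ["x"], recovery_dataset.variables)
    plain = fit_logistic(recovery_dataset, spec0)
    assert recovery_fit.loglik >= plain.loglik - 1e-6


def test_quadrature_convergence(recovery_dataset, recovery_fit):
    """Raising 9 -> 25 nodes changes the converged loglik by < 1e-3."""
    spec = ModelSpec.from_variables("y", ["x"], recovery_dataset.variables, group="area_id")
    m25 = fit_random_intercept_logit(recovery_dataset, spec, agq_nodes=25)
    assert abs(m25.loglik - recovery_fit.loglik) < 1e-3


def test_agreement_with_lme4_glmer(tmp_path):
    """Independent oracle: lme4::glmer with nAGQ=9 on a small fixture."""
    if shutil.which("Rscript") is None:
        raise RuntimeError("Rscript is required for the glmer cross-check")
    cfg = recovery_config(n_groups=10, n_per_group=200, seed=3)
    ds = generate_population(cfg)
    csv = tmp_path / "fixture.csv"
    ds.df[["y", "x", "area_id"]].to_csv(csv, index=False)
    script = (
        "suppressMessages(library(lme4));"
        f"d <- read.csv('{csv}');"
        "m <- glmer(y ~ factor(x) + (1|area_id), data=d, family=binomial, nAGQ=9);"
        "cat(fixef(m), sqrt(unlist(VarCorr(m))), as.numeric(logLik(m)), sep='\\n')"
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, check=True
    )
    b0, bx, sigma, ll = map(float, out.stdout.strip().split("\n"))
    spec = ModelSpec.from_variables("y", ["x"], ds.variables, group="area_id")
    m = fit_random_intercept_logit(ds, spec)
    assert m.beta["Intercept"] == pytest.approx(b0, abs=2e-3)
    assert m.beta["x[1]"] == pytest.approx(bx, abs=2e-3)
    assert m.sigma_u == pytest.approx(sigma, abs=2e-3)
    assert m.loglik == pytest.approx(ll, abs=1e-3)


def test_fewer_than_two_groups_rejected():
    cfg = recovery_config(n_groups=1, n_per_group=100, seed=1)
    ds = generate_population(cfg)
    spec = ModelSpec.from_variables("y", ["x"], ds.variables, group="area_id")
    with pytest.raises(SpecificationError):
        fit_random_intercept_logit(ds, spec)


def test_coefficients_invariant_to_level_reordering():
    rng = np.random.default_rng(8)
    lv = rng.choice(["a", "b", "c"], 600)
    y = (rng.random(600) < np.where(lv == "b", 0.6, 0.3)).astype(int)
    df = pd.DataFrame({"y": y, "g": lv, "weight": np.ones(600)})
    ds1 = make_dataset(df, y="binary", g=(["a", "b", "c"], "a"))
    ds2 = make_dataset(df, y="binary", g=(["a", "c", "b"], "a"))
    m1 = fit_logistic(ds1, ModelSpec.from_variables("y", ["g"], ds1.variables))
    m2 = fit_logistic(ds2, ModelSpec.from_variables("y", ["g"], ds2.variables))
    for term in ("g[b]", "g[c]"):
        assert m1.beta[term] == pytest.approx(m2.beta[term], abs=1e-6)


def test_weighted_fit_normalizes_weights():
    """Rescaling all weights leaves the weighted pseudo-likelihood fit unchanged."""
    rng = np.random.default_rng(10)
    n = 400
    x = rng.integers(0, 2, n).astype(str)
    y = (rng.random(n) < np.where(x == "1", 0.5, 0.2)).astype(int)
    w = rng.lognormal(0, 0.5, n)
    base = pd.DataFrame({"y": y, "x": x, "weight": w})
    scaled = base.assign(weight=w * 37.0)
    kinds = dict(y="binary", x=(["0", "1"], "0"))
    spec = lambda ds: ModelSpec.from_variables("y", ["x"], ds.variables, use_weights=True)
    m1 = fit_logistic(make_dataset(base, **kinds), spec(make_dataset(base, **kinds)))
    m2 = fit_logistic(make_dataset(scaled, **kinds), spec(make_dataset(scaled, **kinds)))
    assert m1.beta == pytest.approx(m2.beta)
    assert m1.aic == pytest.approx(m2.aic)


# ---------------------------------------------------------------- selection


def test_backward_selection_fixed_point(recovery_dataset):
    """A model whose only term is truly active is returned unchanged."""
    spec = ModelSpec.from_variables("y", ["x"], recovery_dataset.variables, group="area_id")
    m = backward_select(recovery_dataset, spec, criterion="aic")
    assert m.spec.term_names == ["x"]
    assert m.removal_log == []


def test_backward_selection_consistency(selection_experiment):
    """BIC keeps the true predictor and drops >= 2 of 3 nulls in >= 18/20 seeds."""
    ok = 0
    for retained in selection_experiment:
        nulls_kept = len(retained & {"z1", "z2", "z3"})
        ok += ("x1" in retained) and (nulls_kept <= 1)
    assert ok >= 18, f"only {ok}/20 seeds selected correctly"


def test_backward_selection_tie_break_removes_later_term():
    """Exactly tied removals drop the term later in the spec order.

    z1/z2 are exchangeable by construction (swapping them permutes rows),
    so both single-term removals give identical criteria.
    """
    block = pd.DataFrame(
        {"z1": ["0", "0", "1", "1"], "z2": ["0", "1", "0", "1"], "y": [0, 1, 1, 0]}
    )
    df = pd.concat([block] * 25, ignore_index=True)
    df["weight"] = 1.0
    ds = make_dataset(df, y="binary", z1=(["0", "1"], "0"), z2=(["0", "1"], "0"))
    spec = ModelSpec.from_variables("y", ["z1", "z2"], ds.variables)
    m = backward_select(ds, spec, criterion="aic")
    assert m.removal_log[0]["removed"] == "z2"


def test_fitted_model_json_roundtrip(tmp_path, recovery_fit):
    path = tmp_path / "fit.json"
    recovery_fit.to_json(path)
    back = FittedModel.from_json(path)
    assert back.beta == pytest.approx(recovery_fit.beta)
    assert back.sigma_u == pytest.approx(recovery_fit.sigma_u)
    assert back.spec.term_names == recovery_fit.spec.term_names
    assert back.blups == pytest.approx(recovery_fit.blups)
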