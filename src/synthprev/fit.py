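"""Individual-level logistic model fitting.

Two fitters share one interface:

* :func:`fit_logistic` — ordinary binary logistic regression (the sigma_u = 0
  reference model), delegated to statsmodels GLM/IRLS with a separation
  wrapper;
* :func:`fit_random_intercept_logit` — maximum-likelihood random-intercept
  logistic regression, integrating the group intercept by adaptive
  Gauss-Hermite quadrature centered at per-group posterior modes (1 node
  recovers the Laplace approximation).

Backward elimination over whole term blocks, driven by AIC or BIC, sits on
top of either fitter.

Survey weights enter, when requested, as a pseudo-likelihood with weights
normalized to mean 1; information criteria are not well defined under raw
expansion weights, and the mean-1 normalization keeps them on the
per-respondent scale.  Rows with missing values in any model variable are
dropped with a logged count.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import statsmodels.api as sm
from numpy.polynomial.hermite_e import hermegauss  # probabilists'; see _gh_nodes
from scipy.optimize import minimize
from scipy.special import expit
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .dataset import SurveyDataset, WEIGHT_COLUMN
from .errors import FitError, SeparationError, SpecificationError
from .modelspec import INTERCEPT, ModelSpec, design_matrix, spec_from_dict, spec_to_dict

logger = logging.getLogger(__name__)

LOGLIK_RTOL = 1e-10
MAX_ITER = 100
SIGMA_FLOOR = 1e-6
BOUNDARY_SIGMA = 1e-2
TIE_TOL = 1e-9


@dataclass
class FittedModel:
    """Estimated coefficients, variance component and fit statistics."""

    beta: dict[str, float]
    sigma_u: float
    loglik: float
    aic: float
    bic: float
    n_obs: int
    cov_beta: np.ndarray
    spec: ModelSpec
    blups: dict[str, float] = field(default_factory=dict)
    boundary: bool = False
    removal_log: list[dict] = field(default_factory=list)
    sigma_u_se: float | None = None  # delta-method SE; None for sigma_u = 0 fits

    @property
    def beta_names(self) -> list[str]:
        return list(self.beta.keys())

    @property
    def beta_vector(self) -> np.ndarray:
        return np.array(list(self.beta.values()))

    def se(self, term: str) -> float:
        i = self.beta_names.index(term)
        return float(np.sqrt(self.cov_beta[i, i]))

    # ------------------------------------------------------------- serialize
    def to_json(self, path: str | Path) -> None:
        payload = {
            "beta": self.beta,
            "sigma_u": self.sigma_u,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "cov_beta": np.asarray(self.cov_beta).tolist(),
            "blups": self.blups,
            "boundary": self.boundary,
            "removal_log": self.removal_log,
            "spec": spec_to_dict(self.spec),
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FittedModel":
        d = json.loads(Path(path).read_text())
        return cls(
            beta=d["beta"],
            sigma_u=d["sigma_u"],
            loglik=d["loglik"],
            aic=d["aic"],
            bic=d["bic"],
            n_obs=d["n_obs"],
            cov_beta=np.asarray(d["cov_beta"]),
            spec=spec_from_dict(d["spec"]),
            blups=d.get("blups", {}),
            boundary=d.get("boundary", False),
            removal_log=d.get("removal_log", []),
        )


# --------------------------------------------------------------- preparation


def _prepare(dataset: SurveyDataset, spec: ModelSpec):
    """Drop rows with missing model variables; build X, y, normalized weights."""
    cols = spec.variables_used() + [spec.outcome]
    if spec.group:
        cols.append(spec.group)
    if spec.use_weights:
        cols.append(WEIGHT_COLUMN)
    dataset.require_columns(cols)
    complete = dataset.df[cols].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropping %d rows with missing model variables", n_dropped)
    data = dataset.subset(complete.to_numpy())
    y = data.df[spec.outcome].to_numpy(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise SpecificationError(f"outcome {spec.outcome!r} is not binary")
    X, names = design_matrix(data, spec)
    if spec.use_weights:
        w = data.df[WEIGHT_COLUMN].to_numpy(float)
        w = w / w.mean()
    else:
        w = np.ones(len(y))
    return data, X, names, y, w


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray, w: np.ndarray) -> float:
    # y*eta - log(1 + e^eta), numerically stable
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def _check_separation(X, y, beta, eta):
    p = expit(eta)
    classified = (p > 0.5) == (y > 0.5)
    if np.max(np.abs(beta)) > 30 and classified.all():
        raise SeparationError(
            "perfect separation: coefficients diverge and the model classifies "
            "every observation correctly",
            diagnostics={"max_abs_beta": float(np.max(np.abs(beta)))},
        )


# ------------------------------------------------------------ plain logistic


def fit_logistic(dataset: SurveyDataset, spec: ModelSpec) -> FittedModel:
    """Maximum (pseudo-)likelihood logistic regression with sigma_u fixed at 0.

    IRLS with convergence at relative log-likelihood change < 1e-10 or 100
    iterations; k in AIC/BIC excludes the (absent) variance parameter.
    """
    data, X, names, y, w = _prepare(dataset, spec)
    try:
        model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w)
        with warnings.catch_warnings():
            # separation is diagnosed explicitly below
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            res = model.fit(method="IRLS", tol=LOGLIK_RTOL, maxiter=MAX_ITER)
    except PerfectSeparationError as exc:
        raise SeparationError(f"perfect separation detected by IRLS: {exc}") from exc
    beta = np.asarray(res.params)
    eta = X @ beta
    _check_separation(X, y, beta, eta)
    if not res.converged:
        raise FitError(
            "IRLS did not converge",
            diagnostics={"iterations": res.fit_history.get("iteration", MAX_ITER)},
        )
    ll = _bernoulli_loglik(y, eta, w)
    k = len(names)
    return FittedModel(
        beta=dict(zip(names, beta.tolist())),
        sigma_u=0.0,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * k,
        bic=-2.0 * ll + k * np.log(len(y)),
        n_obs=len(y),
        cov_beta=np.asarray(res.cov_params()),
        spec=spec,
    )


# ------------------------------------------------- random-intercept logistic


def _gh_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Physicists' Gauss-Hermite nodes/weights for integrals of e^{-z^2}f(z).

    Derived from the probabilists' rule (weight e^{-x^2/2}) by z = x/sqrt(2),
    which is better conditioned in numpy for moderate n; returns (z, log w).
    """
    x, w = hermegauss(n)
    return x / np.sqrt(2.0), np.log(w / np.sqrt(2.0))


class _AGQLoglik:
    """Marginal log-likelihood evaluator with warm-started group modes."""

    def __init__(self, X, y, w, group_idx, n_groups, nodes):
        self.X, self.y, self.w = X, y, w
        self.gi, self.G = group_idx, n_groups
        self.z, self.logw = _gh_nodes(nodes)
        self.u = np.zeros(n_groups)  # warm start across evaluations

    def _modes(self, eta0, inv_s2):
        """Per-group posterior modes of the random intercept (vector Newton)."""
        u = self.u.copy()
        for _ in range(50):
            eta = eta0 + u[self.gi]
            mu = expit(eta)
            score = np.bincount(self.gi, self.w * (self.y - mu), self.G) - u * inv_s2
            curv = np.bincount(self.gi, self.w * mu * (1 - mu), self.G) + inv_s2
            step = score / curv
            step = np.clip(step, -5.0, 5.0)
            u += step
            if np.max(np.abs(score)) < 1e-10:
                break
        return u, curv

    def loglik(self, beta, sigma):
        return self.value_and_grad(beta, sigma)[0]

    def value_and_grad(self, beta, sigma):
        """Marginal log-likelihood and its gradient over (beta, log sigma).

        The gradient is the posterior-weighted score, evaluated on the same
        quadrature grid with the adaptive centering held fixed (the extra
        terms from the theta-dependence of the nodes are of the order of the
        quadrature error itself).
        """
        eta0 = self.X @ beta
        inv_s2 = 1.0 / sigma**2
        u, curv = self._modes(eta0, inv_s2)
        self.u = u
        tau = 1.0 / np.sqrt(curv)
        K = len(self.z)
        # f_g(v) = sum_{i in g} w_i [y_i eta_i - log(1+e^eta_i)] - v^2/(2s^2) - log s - log(2 pi)/2
        # log integral_g ~= log sum_k w_k e^{z_k^2} e^{f_g(u_g + sqrt(2) tau_g z_k)} + log(sqrt(2) tau_g)
        terms = np.empty((K, self.G))
        resid = np.empty((K, len(self.y)))  # w_i (y_i - mu_i) at each node
        vmat = np.empty((K, self.G))
        for k, (z, lw) in enumerate(zip(self.z, self.logw)):
            v = u + np.sqrt(2.0) * tau * z
            eta = eta0 + v[self.gi]
            rows = self.w * (self.y * eta - np.logaddexp(0.0, eta))
            f = (
                np.bincount(self.gi, rows, self.G)
                - 0.5 * v**2 * inv_s2
                - np.log(sigma)
                - 0.5 * np.log(2.0 * np.pi)
            )
            terms[k] = lw + z**2 + f
            resid[k] = self.w * (self.y - expit(eta))
            vmat[k] = v
        m = terms.max(axis=0)
        sumexp = np.exp(terms - m).sum(axis=0)
        log_int = m + np.log(sumexp) + 0.5 * np.log(2.0) + np.log(tau)
        post = np.exp(terms - m) / sumexp  # (K, G) posterior node weights
        grad_beta = self.X.T @ (post[:, self.gi] * resid).sum(axis=0)
        grad_logsig = float(np.sum(post * (vmat**2 * inv_s2 - 1.0)))
        return float(log_int.sum()), np.append(grad_beta, grad_logsig)


def fit_random_intercept_logit(
    dataset: SurveyDataset,
    spec: ModelSpec,
    agq_nodes: int = 9,
    start: FittedModel | None = None,
) -> FittedModel:
    """ML random-intercept logistic regression via adaptive Gauss-Hermite.

    The group intercept u_g ~ Normal(0, sigma_u^2) is integrated out with
    ``agq_nodes`` quadrature nodes centered at each group's posterior mode
    (1 node = Laplace).  Starting values come from the sigma_u = 0 logistic
    fit (or ``start``); a fit driven to sigma_u ~ 0 is returned with
    ``boundary=True`` rather than raising.  k in AIC/BIC counts the fixed
    effects plus the variance parameter.
    """
    if not spec.group:
        raise SpecificationError("spec.group must name the random-intercept column")
    data, X, names, y, w = _prepare(dataset, spec)
    groups, group_idx = np.unique(data.df[spec.group].astype(str).to_numpy(), return_inverse=True)
    if len(groups) < 2:
        raise SpecificationError(f"random-intercept fit needs >= 2 groups, got {len(groups)}")

    if start is not None:
        beta0 = np.array([start.beta.get(nm, 0.0) for nm in names])
        sigma0 = max(start.sigma_u, 0.1)
    else:
        beta0 = np.array(list(fit_logistic(dataset, spec).beta.values()))
        sigma0 = 0.1

    evaluator = _AGQLoglik(X, y, w, group_idx, len(groups), agq_nodes)
    p = len(names)

    def negll(theta):
        return -evaluator.loglik(theta[:p], float(np.exp(theta[p])))

    def negll_grad(theta):
        val, grad = evaluator.value_and_grad(theta[:p], float(np.exp(theta[p])))
        return -val, -grad

    theta0 = np.append(beta0, np.log(sigma0))
    bounds = [(None, None)] * p + [(np.log(SIGMA_FLOOR), np.log(50.0))]
    res = minimize(
        negll_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
    )
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise FitError(
            f"random-intercept optimization failed: {res.message}",
            diagnostics={"iterations": res.nit},
        )
    beta = res.x[:p]
    sigma = float(np.exp(res.x[p]))
    ll = -res.fun
    _check_separation(X, y, beta, X @ beta)

    boundary = sigma <= BOUNDARY_SIGMA
    # BLUPs: posterior modes at the optimum
    u_hat, _ = evaluator._modes(X @ beta, 1.0 / sigma**2)
    blups = {g: float(u) for g, u in zip(groups, u_hat)}

    cov_beta, sigma_se = _covariances(negll, res.x, p, sigma, boundary)
    k = p + 1
    n = len(y)
    return FittedModel(
        beta=dict(zip(names, beta.tolist())),
        sigma_u=0.0 if sigma <= 10 * SIGMA_FLOOR else sigma,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * k,
        bic=-2.0 * ll + k * np.log(n),
        n_obs=n,
        cov_beta=cov_beta,
        spec=spec,
        blups=blups,
        boundary=boundary,
        sigma_u_se=sigma_se,
    )


def _covariances(negll, theta_hat, p, sigma, boundary):
    """(cov_beta, se of sigma_u) from the numerical Hessian at the optimum.

    sigma_u is optimized on the log scale, so its SE comes from the delta
    method.  At a sigma_u ~ 0 boundary the variance block is near-singular;
    the Hessian is then taken over the fixed effects only with sigma held
    fixed, and no sigma SE is reported.
    """
    from statsmodels.tools.numdiff import approx_hess

    if boundary:
        fixed_tail = theta_hat[p:]
        H = approx_hess(theta_hat[:p], lambda b: negll(np.append(b, fixed_tail)))
        return np.linalg.pinv(H), None
    H = approx_hess(theta_hat, negll)
    cov = np.linalg.pinv(H)
    sigma_se = sigma * float(np.sqrt(max(cov[p, p], 0.0)))
    return cov[:p, :p], sigma_se


# ---------------------------------------------------------- model selection


def _fit(dataset, spec, start=None):
    if spec.group:
        return fit_random_intercept_logit(dataset, spec, start=start)
    return fit_logistic(dataset, spec)


def backward_select(
    dataset: SurveyDataset, full_spec: ModelSpec, criterion: str = "aic"
) -> FittedModel:
    """Backward elimination of whole term blocks by AIC or BIC.

    At each step the single term whose removal most decreases the criterion
    is dropped; ties (within 1e-9) go to the term appearing later in the
    spec's term order.  Stops when no removal improves the criterion; the
    returned model carries an ordered ``removal_log``.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError(f"criterion must be 'aic' or 'bic', got {criterion!r}")
    current = _fit(dataset, full_spec)
    removal_log: list[dict] = []
    while current.spec.terms:
        cur_crit = getattr(current, criterion)
        best = None
        best_crit = np.inf
        for t in current.spec.terms:  # spec order; later term wins exact ties
            cand_spec = current.spec.drop_term(t.name)
            cand = _fit(dataset, cand_spec, start=current)
            crit = getattr(cand, criterion)
            if best is None or crit < best_crit - TIE_TOL or abs(crit - best_crit) <= TIE_TOL:
                best, best_crit, best_term = cand, min(crit, best_crit), t.name
        if best_crit < cur_crit - TIE_TOL:
            removal_log.append(
                {"removed": best_term, "criterion": criterion,
                 "before": float(cur_crit), "after": float(best_crit)}
            )
            current = best
        else:
            break
    current.removal_log = removal_log
    return current
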