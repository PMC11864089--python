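"""Discrimination and calibration of a fitted individual-level model.

The C statistic is the weighted probability that a randomly chosen case
receives a higher predicted risk than a randomly chosen non-case (ties
count one half); it equals the area under the ROC curve.  The calibration
slope is the coefficient on logit(risk) in a logistic refit of the outcome:
1 means perfectly calibrated, < 1 overconfident, > 1 underconfident.
Decile calibration compares mean predicted risk with the observed event
fraction within weighted tenths of the risk distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .dataset import SurveyDataset, Variable, WEIGHT_COLUMN
from .errors import SchemaError, UndefinedMetricError
from .fit import FittedModel, fit_logistic
from .modelspec import ContinuousTerm, ModelSpec, design_matrix


@dataclass
class PerformanceReport:
    c_statistic: float
    calibration_slope: float
    decile_table: pd.DataFrame  # decile, mean_predicted, observed_fraction, weight_share

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "c_statistic": self.c_statistic,
                    "calibration_slope": self.calibration_slope,
                    "decile_table": self.decile_table.to_dict(orient="records"),
                },
                indent=1,
            )
            + "\n"
        )


def predict_prob(
    model: FittedModel, dataset: SurveyDataset, mode: str = "population_average"
) -> np.ndarray:
    """Per-row predicted risk expit(x_i' beta [+ u_group]).

    ``population_average`` sets the random intercept to 0; ``group_specific``
    adds the estimated BLUP for groups seen in fitting and 0 for unseen ones.
    """
    if mode not in ("population_average", "group_specific"):
        raise ValueError(f"unknown prediction mode {mode!r}")
    X, names = design_matrix(dataset, model.spec, check_rank=False)
    beta = np.array([model.beta[nm] for nm in names])
    eta = X @ beta
    if mode == "group_specific" and model.spec.group:
        if model.spec.group not in dataset.df.columns:
            raise SchemaError(f"dataset is missing group column {model.spec.group!r}")
        u = dataset.df[model.spec.group].astype(str).map(model.blups).fillna(0.0)
        eta = eta + u.to_numpy(float)
    return expit(eta)


def _check_classes(y: np.ndarray) -> None:
    if y.min() == y.max():
        raise UndefinedMetricError("outcome has a single class; metric undefined")


def c_statistic(risk: np.ndarray, outcome: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted concordance over case-control pairs, O(n log n).

    sum_{i case, j control} w_i w_j [1(p_i > p_j) + 0.5 * 1(p_i = p_j)]
    normalized by the total case-control weight product.  Computed by
    sorting risks and accumulating control weight below / at each unique
    risk value; equals brute-force pair enumeration exactly.
    """
    risk = np.asarray(risk, float)
    y = np.asarray(outcome, float)
    w = np.ones_like(risk) if weights is None else np.asarray(weights, float)
    _check_classes(y)
    order = np.argsort(risk, kind="mergesort")
    r, yy, ww = risk[order], y[order], w[order]
    w_case = ww * yy
    w_ctrl = ww * (1.0 - yy)
    # group by unique risk value
    _, start = np.unique(r, return_index=True)
    case_g = np.add.reduceat(w_case, start)
    ctrl_g = np.add.reduceat(w_ctrl, start)
    ctrl_below = np.concatenate([[0.0], np.cumsum(ctrl_g)[:-1]])
    num = float(np.sum(case_g * (ctrl_below + 0.5 * ctrl_g)))
    denom = float(w_case.sum() * w_ctrl.sum())
    return num / denom


def c_statistic_bruteforce(risk, outcome, weights=None) -> float:
    """O(n^2) pair enumeration; the independent oracle for :func:`c_statistic`."""
    risk = np.asarray(risk, float)
    y = np.asarray(outcome, float)
    w = np.ones_like(risk) if weights is None else np.asarray(weights, float)
    _check_classes(y)
    cases, ctrls = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    num = 0.0
    for i in cases:
        gt = risk[i] > risk[ctrls]
        eq = risk[i] == risk[ctrls]
        num += w[i] * float(np.sum(w[ctrls] * (gt + 0.5 * eq)))
    return num / float(w[cases].sum() * w[ctrls].sum())


def calibration_slope(risk, outcome, weights=None) -> float:
    """Slope of a (weighted) logistic regression of outcome on logit(risk)."""
    risk = np.asarray(risk, float)
    y = np.asarray(outcome, float)
    _check_classes(y)
    if np.any((risk <= 0) | (risk >= 1)):
        raise UndefinedMetricError("risks must lie strictly inside (0, 1)")
    if np.ptp(risk) == 0:
        raise UndefinedMetricError("all risks identical; calibration slope undefined")
    df = pd.DataFrame({"lp": logit(risk), "y": y.astype(int)})
    if weights is not None:
        df[WEIGHT_COLUMN] = np.asarray(weights, float)
    ds = SurveyDataset(df, {"lp": Variable("lp", "continuous"), "y": Variable("y", "binary")})
    spec = ModelSpec(outcome="y", terms=[ContinuousTerm("lp")], use_weights=weights is not None)
    return fit_logistic(ds, spec).beta["lp"]


def calibration_deciles(risk, outcome, weights=None) -> pd.DataFrame:
    """Weighted decile calibration table.

    Rows are assigned to 10 groups by weighted deciles of predicted risk
    (ties broken by row order); each row reports the weighted mean predicted
    risk, the weighted observed event fraction and the group's weight share.
    """
    risk = np.asarray(risk, float)
    y = np.asarray(outcome, float)
    n = len(risk)
    if n < 10:
        raise ValueError(f"need at least 10 observations for deciles, got {n}")
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    order = np.argsort(risk, kind="stable")  # stable: ties broken by row order
    cum = np.cumsum(w[order])
    # group boundary: first rows whose cumulative weight reaches k/10 of total
    grp_sorted = np.minimum((10 * (cum - w[order] / 2) / cum[-1]).astype(int), 9)
    group = np.empty(n, int)
    group[order] = grp_sorted
    rows = []
    for g in range(10):
        m = group == g
        wg = w[m].sum()
        rows.append(
            {
                "decile": g + 1,
                "mean_predicted": float(np.average(risk[m], weights=w[m])) if wg > 0 else np.nan,
                "observed_fraction": float(np.average(y[m], weights=w[m])) if wg > 0 else np.nan,
                "weight_share": float(wg / w.sum()),
            }
        )
    return pd.DataFrame(rows)


def assess(
    model: FittedModel,
    dataset: SurveyDataset,
    weighted: bool = True,
    mode: str = "population_average",
) -> PerformanceReport:
    """Full performance report for ``model`` on ``dataset``."""
    risk = predict_prob(model, dataset, mode=mode)
    y = dataset.df[model.spec.outcome].to_numpy(float)
    w = dataset.df[WEIGHT_COLUMN].to_numpy(float) if weighted else None
    return PerformanceReport(
        c_statistic=c_statistic(risk, y, w),
        calibration_slope=calibration_slope(risk, y, w),
        decile_table=calibration_deciles(risk, y, w),
    )
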