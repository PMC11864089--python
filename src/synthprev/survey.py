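"""Survey-weighted descriptive estimation and bootstrap variance.

Proportions are reported on the percent scale throughout the package.
Bootstrap standard errors use the replicate-weight convention of surveys
that ship mean-bootstrap weights: deviations are taken from the full-sample
(design-weight) estimate, not from the replicate mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .dataset import SurveyDataset, WEIGHT_COLUMN
from .errors import ConfigurationError, EstimationError


@dataclass
class WeightedEstimate:
    """A weighted proportion (percent) or mean, with optional precision info."""

    value: float
    se: float | None = None
    n_effective: float | None = None


def _weights(dataset: SurveyDataset, weights: str) -> np.ndarray:
    dataset.require_columns([weights])
    w = dataset.df[weights].to_numpy(float)
    if len(w) == 0 or w.sum() <= 0:
        raise EstimationError("total weight is zero (empty dataset or all-zero weights)")
    return w


def weighted_proportion(
    dataset: SurveyDataset, indicator: str, weights: str = WEIGHT_COLUMN
) -> WeightedEstimate:
    """100 * sum(w_i * y_i) / sum(w_i) for a binary indicator column."""
    w = _weights(dataset, weights)
    dataset.require_columns([indicator])
    y = dataset.df[indicator].to_numpy(float)
    value = 100.0 * float(np.dot(w, y) / w.sum())
    return WeightedEstimate(value=value, n_effective=_kish_n(w))


def weighted_mean(
    dataset: SurveyDataset, column: str, weights: str = WEIGHT_COLUMN
) -> WeightedEstimate:
    """sum(w_i * x_i) / sum(w_i) for a numeric column."""
    w = _weights(dataset, weights)
    dataset.require_columns([column])
    x = dataset.df[column].to_numpy(float)
    return WeightedEstimate(value=float(np.dot(w, x) / w.sum()), n_effective=_kish_n(w))


def _kish_n(w: np.ndarray) -> float:
    """Kish effective sample size sum(w)^2 / sum(w^2)."""
    return float(w.sum() ** 2 / np.square(w).sum())


def bootstrap_se(
    statistic: Callable[[SurveyDataset, str], float], dataset: SurveyDataset
) -> float:
    """Replicate-weight bootstrap standard error of ``statistic``.

    ``statistic`` maps (dataset, weight column name) to a scalar.  Returns
    sqrt((1/B) * sum_b (theta_b - theta_hat)^2) where theta_hat uses the
    design weight column.
    """
    reps = dataset.replicate_columns
    if len(reps) < 2:
        raise ConfigurationError(
            "bootstrap_se needs >= 2 replicate weight columns (BSW1..BSWk)"
        )
    theta_hat = statistic(dataset, WEIGHT_COLUMN)
    devs = np.array([statistic(dataset, col) - theta_hat for col in reps])
    return float(np.sqrt(np.mean(np.square(devs))))
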