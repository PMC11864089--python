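"""Model specification and fixed-effect design matrices.

Categorical variables use reference-cell dummy coding; the reference level
is the first declared level unless the variable dictionary (or the spec)
names another.  Term/column naming follows the ``variable[level]``
convention so that a fitted coefficient vector, an area profile and a
simulation coefficient map all share one key space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .dataset import SurveyDataset, Variable
from .errors import ConfigurationError, DesignMatrixError, SchemaError, SpecificationError
from .simulate import term_name

INTERCEPT = "Intercept"


@dataclass(frozen=True)
class CategoricalTerm:
    variable: str
    levels: tuple[str, ...]
    reference: str

    def __post_init__(self):
        if self.reference not in self.levels:
            raise SpecificationError(
                f"reference level {self.reference!r} not among levels of {self.variable!r}"
            )

    @property
    def name(self) -> str:
        return self.variable

    def column_names(self) -> list[str]:
        return [term_name(self.variable, lv) for lv in self.levels if lv != self.reference]

    def columns(self, df: pd.DataFrame) -> np.ndarray:
        vals = df[self.variable].astype(str).to_numpy()
        return np.column_stack(
            [(vals == lv).astype(float) for lv in self.levels if lv != self.reference]
        )


@dataclass(frozen=True)
class ContinuousTerm:
    variable: str

    @property
    def name(self) -> str:
        return self.variable

    def column_names(self) -> list[str]:
        return [self.variable]

    def columns(self, df: pd.DataFrame) -> np.ndarray:
        return df[self.variable].to_numpy(float)[:, None]


@dataclass(frozen=True)
class InteractionTerm:
    """Product of two base terms (no automated screening; declared explicitly)."""

    left: Union[CategoricalTerm, ContinuousTerm]
    right: Union[CategoricalTerm, ContinuousTerm]

    @property
    def name(self) -> str:
        return f"{self.left.name}:{self.right.name}"

    def column_names(self) -> list[str]:
        return [f"{a}:{b}" for a in self.left.column_names() for b in self.right.column_names()]

    def columns(self, df: pd.DataFrame) -> np.ndarray:
        L, R = self.left.columns(df), self.right.columns(df)
        return np.column_stack([L[:, i] * R[:, j] for i in range(L.shape[1]) for j in range(R.shape[1])])


Term = Union[CategoricalTerm, ContinuousTerm, InteractionTerm]


@dataclass
class ModelSpec:
    """Outcome, ordered fixed-effect terms, optional random-intercept group."""

    outcome: str
    terms: list[Term]
    group: str | None = None  # area-id column for the random intercept
    use_weights: bool = False

    def __post_init__(self):
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise SpecificationError(f"duplicate model terms: {names}")

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def variables_used(self) -> list[str]:
        out: list[str] = []
        for t in self.terms:
            parts = (t.left, t.right) if isinstance(t, InteractionTerm) else (t,)
            for p in parts:
                if p.variable not in out:
                    out.append(p.variable)
        return out

    def drop_term(self, name: str) -> "ModelSpec":
        if name not in self.term_names:
            raise SpecificationError(f"cannot drop unknown term {name!r}")
        return ModelSpec(
            outcome=self.outcome,
            terms=[t for t in self.terms if t.name != name],
            group=self.group,
            use_weights=self.use_weights,
        )

    # ------------------------------------------------------------- builders
    @classmethod
    def from_variables(
        cls,
        outcome: str,
        predictors: list[str],
        variables: dict[str, Variable],
        group: str | None = None,
        use_weights: bool = False,
    ) -> "ModelSpec":
        """Build a spec from a variable dictionary, one main-effect term per name."""
        terms: list[Term] = []
        for name in predictors:
            if ":" in name:
                lname, rname = name.split(":", 1)
                terms.append(
                    InteractionTerm(
                        _base_term(lname, variables), _base_term(rname, variables)
                    )
                )
            else:
                terms.append(_base_term(name, variables))
        return cls(outcome=outcome, terms=terms, group=group, use_weights=use_weights)

    @classmethod
    def from_dict(cls, d: dict, variables: dict[str, Variable]) -> "ModelSpec":
        return cls.from_variables(
            outcome=d["outcome"],
            predictors=list(d["predictors"]),
            variables=variables,
            group=d.get("group"),
            use_weights=bool(d.get("use_weights", False)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path, variables: dict[str, Variable]) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh), variables)


def term_to_dict(t: Term) -> dict:
    if isinstance(t, CategoricalTerm):
        return {
            "type": "categorical",
            "variable": t.variable,
            "levels": list(t.levels),
            "reference": t.reference,
        }
    if isinstance(t, ContinuousTerm):
        return {"type": "continuous", "variable": t.variable}
    return {"type": "interaction", "left": term_to_dict(t.left), "right": term_to_dict(t.right)}


def term_from_dict(d: dict) -> Term:
    if d["type"] == "categorical":
        return CategoricalTerm(d["variable"], tuple(d["levels"]), d["reference"])
    if d["type"] == "continuous":
        return ContinuousTerm(d["variable"])
    return InteractionTerm(term_from_dict(d["left"]), term_from_dict(d["right"]))


def spec_to_dict(spec: ModelSpec) -> dict:
    """Self-contained spec serialization (embeds level sets and references)."""
    return {
        "outcome": spec.outcome,
        "terms": [term_to_dict(t) for t in spec.terms],
        "group": spec.group,
        "use_weights": spec.use_weights,
    }


def spec_from_dict(d: dict) -> ModelSpec:
    return ModelSpec(
        outcome=d["outcome"],
        terms=[term_from_dict(t) for t in d["terms"]],
        group=d.get("group"),
        use_weights=bool(d.get("use_weights", False)),
    )


def _base_term(name: str, variables: dict[str, Variable]) -> Term:
    if name not in variables:
        raise ConfigurationError(f"model predictor {name!r} not in the variable dictionary")
    var = variables[name]
    if var.kind == "categorical":
        return CategoricalTerm(name, tuple(var.levels), var.reference)
    return ContinuousTerm(name)


# ------------------------------------------------------------ design matrix


def design_matrix(
    dataset: SurveyDataset, spec: ModelSpec, check_rank: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design matrix with a leading intercept column.

    Returns (X, column names).  Raises SchemaError for missing columns and
    DesignMatrixError (naming the offending terms) for rank deficiency.
    """
    needed = spec.variables_used()
    missing = [v for v in needed if v not in dataset.df.columns]
    if missing:
        raise SchemaError(f"dataset is missing model variables: {missing}")
    blocks = [np.ones((len(dataset.df), 1))]
    names = [INTERCEPT]
    for t in spec.terms:
        blocks.append(t.columns(dataset.df))
        names.extend(t.column_names())
    X = np.hstack(blocks)
    if check_rank and len(names) > 1:
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            bad = _collinear_columns(X, names)
            raise DesignMatrixError(
                f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
                f"collinear columns: {bad}",
                collinear_terms=bad,
            )
    return X, names


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns pivoted last by a rank-revealing QR (the dependent ones)."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[piv[i]] for i in range(len(names)) if i >= len(diag) or diag[i] <= tol]
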