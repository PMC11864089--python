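"""Respondent-level survey microdata container.

A :class:`SurveyDataset` wraps a pandas DataFrame (one row per respondent)
together with a variable dictionary describing each analysis column.  The
expected layout mirrors public-use survey microdata files:

* identifier columns: ``respondent_id``, ``area_id`` (health region),
  ``province_id``, optionally ``cluster_id`` (sampling cluster);
* one column per predictor (categorical level labels or floats);
* one column per binary outcome (values in {0, 1});
* a positive design weight column (default name ``weight``);
* optional bootstrap replicate weight columns ``BSW1`` .. ``BSWk``.

Serialization is a plain CSV plus a JSON sidecar holding the variable
dictionary, so a round trip preserves types, category levels and the
reference level of each categorical variable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError

ID_COLUMNS = ("respondent_id", "area_id", "province_id", "cluster_id")
WEIGHT_COLUMN = "weight"
BSW_PREFIX = "BSW"


@dataclass
class Variable:
    """Entry of the variable dictionary."""

    name: str
    kind: str  # "categorical" | "continuous" | "binary"
    levels: list[str] | None = None
    reference: str | None = None

    def __post_init__(self):
        if self.kind not in ("categorical", "continuous", "binary"):
            raise ConfigurationError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical":
            if not self.levels:
                raise ConfigurationError(f"categorical variable {self.name!r} needs levels")
            if self.reference is None:
                self.reference = self.levels[0]
            if self.reference not in self.levels:
                raise ConfigurationError(
                    f"reference level {self.reference!r} not among levels of {self.name!r}"
                )

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.kind == "categorical":
            d["levels"] = list(self.levels)
            d["reference"] = self.reference
        return d

    @classmethod
    def from_dict(cls, name: str, d: dict) -> "Variable":
        return cls(name=name, kind=d["kind"], levels=d.get("levels"), reference=d.get("reference"))


@dataclass
class SurveyDataset:
    """Survey microdata plus its variable dictionary."""

    df: pd.DataFrame
    variables: dict[str, Variable] = field(default_factory=dict)

    # ------------------------------------------------------------------ api
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def replicate_columns(self) -> list[str]:
        cols = [c for c in self.df.columns if c.startswith(BSW_PREFIX) and c[len(BSW_PREFIX):].isdigit()]
        return sorted(cols, key=lambda c: int(c[len(BSW_PREFIX):]))

    @property
    def n_bootstrap(self) -> int:
        return len(self.replicate_columns)

    def require_columns(self, names: Iterable[str]) -> None:
        missing = [c for c in names if c not in self.df.columns]
        if missing:
            raise SchemaError(f"dataset is missing columns: {missing}")

    def subset(self, mask) -> "SurveyDataset":
        """Row subset sharing the variable dictionary (metadata is not copied)."""
        return SurveyDataset(self.df.loc[mask].reset_index(drop=True), self.variables)

    def validate(self) -> None:
        """Check container invariants; raise SchemaError on violation."""
        if WEIGHT_COLUMN in self.df.columns:
            w = self.df[WEIGHT_COLUMN].to_numpy(float)
            if not np.all(w > 0):
                raise SchemaError("design weights must be strictly positive")
        for name, var in self.variables.items():
            if name not in self.df.columns:
                continue
            col = self.df[name]
            if var.kind == "binary":
                vals = set(pd.unique(col.dropna()))
                if not vals <= {0, 1}:
                    raise SchemaError(f"binary column {name!r} has values outside {{0,1}}: {vals}")
            elif var.kind == "categorical":
                observed = set(col.dropna().astype(str).unique())
                unknown = observed - set(var.levels)
                if unknown:
                    raise SchemaError(f"column {name!r} has undeclared levels: {sorted(unknown)}")
        if "area_id" in self.df.columns and "province_id" in self.df.columns:
            nunique = self.df.groupby("area_id", observed=True)["province_id"].nunique()
            bad = nunique[nunique > 1]
            if len(bad):
                raise SchemaError(f"area ids mapped to multiple provinces: {list(bad.index)}")

    # ------------------------------------------------------------- serialize
    def to_csv(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>.csv`` and ``<prefix>.vars.json``; return both paths.

        Floats are written with repr-level precision so that identical
        datasets serialize byte-identically.
        """
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        csv_path = prefix.with_suffix(".csv")
        json_path = Path(str(prefix) + ".vars.json")
        self.df.to_csv(csv_path, index=False, float_format="%.12g")
        meta = {name: var.to_dict() for name, var in self.variables.items()}
        json_path.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
        return csv_path, json_path

    @classmethod
    def read_csv(cls, prefix: str | Path) -> "SurveyDataset":
        prefix = Path(prefix)
        csv_path = prefix if prefix.suffix == ".csv" else prefix.with_suffix(".csv")
        json_path = Path(str(csv_path)[: -len(".csv")] + ".vars.json")
        if not json_path.exists():
            raise ConfigurationError(f"variable dictionary sidecar not found: {json_path}")
        meta = json.loads(json_path.read_text())
        variables = {name: Variable.from_dict(name, d) for name, d in meta.items()}
        dtypes = {name: str for name, v in variables.items() if v.kind == "categorical"}
        df = pd.read_csv(csv_path, dtype=dtypes)
        for idc in ("area_id", "province_id", "cluster_id"):
            if idc in df.columns:
                df[idc] = df[idc].astype(str)
        return cls(df, variables)
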