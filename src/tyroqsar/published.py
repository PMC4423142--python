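"""The two published MMP-2 QSAR equations and the 30-compound reference table.

The general MLR equation (``eq1_mlr``) and the GA-PLS equation
(``eq2_gapls``) ship with their printed coefficients, standard errors and
calibration statistics, ready to predict pIC50 from descriptor values. The
compound table carries the substituent labels (R1/R2/R3 on the L-tyrosine
scaffold) with the experimental and model-predicted pIC50 of each of the 30
inhibitors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd

__all__ = [
    "PublishedEquation",
    "Table1Record",
    "load_equation",
    "predict_published",
    "predict_published_frame",
    "load_table1",
    "PUBLISHED_MODEL_IDS",
]

PUBLISHED_MODEL_IDS = ("eq1_mlr", "eq2_gapls")


@dataclass(frozen=True)
class PublishedEquation:
    model_id: str
    descriptors: tuple[str, ...]
    coefficients: tuple[float, ...]
    coef_se: tuple[float, ...]
    intercept: float
    intercept_se: float
    stats: dict

    def predict(self, values: Mapping[str, float]) -> float:
        total = self.intercept
        for name, coef in zip(self.descriptors, self.coefficients):
            if name not in values:
                raise KeyError(f"missing descriptor {name!r} for model {self.model_id}")
            total += coef * float(values[name])
        return total


_EQ_CACHE: dict[str, PublishedEquation] = {}


def load_equation(model_id: str) -> PublishedEquation:
    if model_id not in PUBLISHED_MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}; expected one of {PUBLISHED_MODEL_IDS}")
    if model_id not in _EQ_CACHE:
        with resources.files("tyroqsar.data").joinpath(f"{model_id}.json").open() as fh:
            d = json.load(fh)
        _EQ_CACHE[model_id] = PublishedEquation(
            model_id=d["model_id"],
            descriptors=tuple(d["descriptors"]),
            coefficients=tuple(d["coefficients"]),
            coef_se=tuple(d["coef_se"]),
            intercept=d["intercept"],
            intercept_se=d["intercept_se"],
            stats=d["stats"],
        )
    return _EQ_CACHE[model_id]


def predict_published(model_id: str, values: Mapping[str, float]) -> float:
    """Evaluate a published equation on descriptor values given by name."""
    return load_equation(model_id).predict(values)


def predict_published_frame(model_id: str, X: pd.DataFrame) -> pd.Series:
    """Row-wise prediction from a descriptor DataFrame."""
    eq = load_equation(model_id)
    missing = [c for c in eq.descriptors if c not in X.columns]
    if missing:
        raise KeyError(f"missing descriptor columns {missing} for model {model_id}")
    vals = X[list(eq.descriptors)].to_numpy(dtype=float)
    return pd.Series(vals @ list(eq.coefficients) + eq.intercept, index=X.index)


@dataclass(frozen=True)
class Table1Record:
    compound: str
    r1: str
    r2: str
    r3: str
    pic50_exp: float
    pic50_mlr: float
    pic50_gapls: float


def load_table1(as_frame: bool = False):
    """The 30 L-tyrosine derivatives with experimental and predicted pIC50."""
    with resources.files("tyroqsar.data").joinpath("table1.csv").open() as fh:
        frame = pd.read_csv(fh)
    if as_frame:
        return frame
    return [Table1Record(**row) for row in frame.to_dict(orient="records")]
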