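"""Logistic NTCP risk models with fixed, published coefficients.

A :class:`LogisticRiskModel` is a plain logistic model

    NTCP = [1 + exp(-LP)]^-1,   LP = beta0 + sum_j beta_j * x_j

whose coefficients are frozen at their published values rather than fitted.
The module ships a registry of the QUANTEC and Appelt radiation-pneumonitis
models and their locally updated descendants (intercept-recalibrated, fully
recalibrated, BIC-simplified, and the final simplified local "Model D"),
plus evaluation, (de)serialization and dose-response helpers.

Covariate values are supplied on their natural clinical scales (MLD in Gy,
V30 in % lung volume, age in years, ...); any standardization or
binarization a model expects is declared explicitly in its transforms so
that it is visible and reversible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CovariateTransform",
    "LogisticRiskModel",
    "registry",
    "linear_predictor",
    "predict_risk",
    "load_model",
    "save_model",
    "dose_response_curve",
    "CANONICAL_TERMS",
]

#: Canonical, case-sensitive term names emitted by the cohort encoder.
CANONICAL_TERMS = (
    "MLD",
    "V30",
    "smoke_former",
    "smoke_current",
    "comorbidity",
    "age",
    "stage",
    "NLR",
    "SII",
    "seq_chemo",
    "loc_midinf",
)

# LP magnitudes beyond this are clamped before exponentiation; expit(±700)
# is still strictly inside (0,1) in double precision.
_LP_CLAMP = 700.0


@dataclass(frozen=True)
class CovariateTransform:
    """Explicit, reversible preprocessing for one covariate.

    ``(x - center) / scale`` is applied before the coefficient; an optional
    ``indicator_threshold`` instead binarizes (``x >= threshold``), which is
    how the Appelt-family "old age" indicator is declared. ``encoding`` maps
    categorical levels to indicator-term names.
    """

    name: str
    center: float = 0.0
    scale: float = 1.0
    indicator_threshold: float | None = None
    encoding: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"transform {self.name!r}: scale must be > 0")

    def apply(self, value: float) -> float:
        if self.indicator_threshold is not None:
            return 1.0 if value >= self.indicator_threshold else 0.0
        return (value - self.center) / self.scale


@dataclass(frozen=True)
class LogisticRiskModel:
    """A logistic risk model with named, fixed coefficients.

    Parameters
    ----------
    name : str
        Registry identifier.
    intercept : float
        beta0 on the logit scale.
    terms : mapping of term name -> coefficient
        Insertion order is the model's canonical term order.
    transforms : list of CovariateTransform
        Declared preprocessing, keyed by term name.
    provenance : str
        Free-text note on where the coefficients come from.
    """

    name: str
    intercept: float
    terms: Mapping[str, float]
    transforms: Sequence[CovariateTransform] = field(default_factory=tuple)
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", dict(self.terms))
        object.__setattr__(self, "transforms", tuple(self.transforms))
        vals = [self.intercept, *self.terms.values()]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"model {self.name!r}: non-finite coefficient")

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(self.terms)

    def transform_for(self, term: str) -> CovariateTransform | None:
        for tr in self.transforms:
            if tr.name == term:
                return tr
        return None

    # -- evaluation ------------------------------------------------------

    def linear_predictor(self, record: Mapping[str, float]) -> float:
        return linear_predictor(self, record)

    def predict_risk(self, record: Mapping[str, float]) -> float:
        return predict_risk(self, record)


def _resolve(model: LogisticRiskModel, record: Mapping[str, float], term: str) -> float:
    if term not in record:
        raise KeyError(
            f"model {model.name!r} requires covariate {term!r}; "
            f"record provides {sorted(record)}"
        )
    value = record[term]
    if isinstance(value, bool):
        value = float(value)
    if not isinstance(value, (int, float, np.integer, np.floating)):
        raise TypeError(f"covariate {term!r} is non-numeric: {value!r}")
    tr = model.transform_for(term)
    return tr.apply(float(value)) if tr is not None else float(value)


def linear_predictor(model: LogisticRiskModel, record: Mapping[str, float]) -> float:
    """Evaluate LP = beta0 + sum beta_j x_j on the model's transformed scale."""
    lp = model.intercept
    for term, beta in model.terms.items():
        lp += beta * _resolve(model, record, term)
    return lp


def _expit_clamped(lp: float | np.ndarray) -> float | np.ndarray:
    # LP clamp prevents exp overflow; the probability clip keeps extreme
    # predictions strictly inside (0, 1) in double precision
    lp = np.clip(lp, -_LP_CLAMP, _LP_CLAMP)
    return np.clip(1.0 / (1.0 + np.exp(-lp)), 1e-12, 1.0 - 1e-12)


def predict_risk(model: LogisticRiskModel, record: Mapping[str, float]) -> float:
    """Predicted complication probability, strictly in (0, 1)."""
    return float(_expit_clamped(linear_predictor(model, record)))


def dose_response_curve(
    model: LogisticRiskModel,
    grid: Iterable[float],
    fixed: Mapping[str, float] | None = None,
    dose_term: str = "MLD",
) -> list[tuple[float, float]]:
    """Predicted risk over a grid of mean lung doses, other covariates fixed.

    With a positive dose coefficient the curve is strictly increasing; this
    is the dose-toxicity relationship commonly plotted for NTCP models.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("dose grid must be nonempty")
    if any(g < 0 for g in grid):
        raise ValueError("MLD values must be >= 0")
    fixed = dict(fixed or {})
    out = []
    for g in grid:
        rec = dict(fixed)
        rec[dose_term] = g
        out.append((float(g), predict_risk(model, rec)))
    return out


# -- serialization -------------------------------------------------------


def save_model(model: LogisticRiskModel, path) -> None:
    """Write a model-spec JSON file (full float precision, round-trip safe)."""
    doc = {
        "name": model.name,
        "intercept": model.intercept,
        "terms": dict(model.terms),
        "transforms": {
            tr.name: {
                "center": tr.center,
                "scale": tr.scale,
                "indicator_threshold": tr.indicator_threshold,
                "encoding": dict(tr.encoding) if tr.encoding else None,
            }
            for tr in model.transforms
        },
        "provenance": model.provenance,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_model(path) -> LogisticRiskModel:
    """Read a model-spec JSON file; raises on missing/malformed fields."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    problems = []
    for req in ("name", "intercept", "terms"):
        if req not in doc:
            problems.append(req)
    if problems:
        raise ValueError(f"model spec {path}: missing required field(s) {problems}")
    if not isinstance(doc["terms"], dict):
        raise ValueError(f"model spec {path}: 'terms' must be a name->coefficient map")
    transforms = []
    for name, spec in (doc.get("transforms") or {}).items():
        transforms.append(
            CovariateTransform(
                name=name,
                center=spec.get("center", 0.0),
                scale=spec.get("scale", 1.0),
                indicator_threshold=spec.get("indicator_threshold"),
                encoding=spec.get("encoding"),
            )
        )
    return LogisticRiskModel(
        name=doc["name"],
        intercept=float(doc["intercept"]),
        terms={k: float(v) for k, v in doc["terms"].items()},
        transforms=transforms,
        provenance=doc.get("provenance", ""),
    )


# -- registry ------------------------------------------------------------

_APPELT_TERMS = {
    "MLD": 0.138,
    "smoke_current": -0.48,
    "smoke_former": -0.37,
    "comorbidity": 0.82,
    "age": 0.51,
    "seq_chemo": 0.47,
    "loc_midinf": 0.63,
}

#: Printed calibration slope of the original Appelt model in the local
#: development cohort; model B's coefficients are the originals scaled by it.
APPELT_CALIBRATION_SLOPE = 0.6159

_OLD_AGE = CovariateTransform(name="age", indicator_threshold=63.0)


def _appelt(name: str, intercept: float, terms: Mapping[str, float], prov: str) -> LogisticRiskModel:
    return LogisticRiskModel(
        name=name, intercept=intercept, terms=terms, transforms=(_OLD_AGE,), provenance=prov
    )


def registry() -> dict[str, LogisticRiskModel]:
    """The eight published models, keyed by name.

    QUANTEC family (MLD-only): original, recalibrated (intercept + slope),
    and the ridge-shrunk final update. Appelt family: original,
    model A (intercept recalibration only), model B (full recalibration:
    every coefficient scaled by the calibration slope 0.6159), model C
    (BIC-simplified to MLD only), and the final simplified local model D.

    Model D is shipped on raw clinical scales (identity transforms): that is
    the only reading fully determined by the printed equation; users can
    attach center/scale via transforms without touching coefficients.
    """
    b = APPELT_CALIBRATION_SLOPE
    models = [
        LogisticRiskModel(
            "quantec_original", -3.87, {"MLD": 0.126},
            provenance="QUANTEC pooled analysis; MLD-only logistic model",
        ),
        LogisticRiskModel(
            "quantec_recalibrated", -1.742, {"MLD": 0.164},
            provenance="QUANTEC after intercept+slope recalibration in the development cohort",
        ),
        LogisticRiskModel(
            "quantec_final", -1.652, {"MLD": 0.155},
            provenance="QUANTEC after coefficient updating and ridge-based shrinkage",
        ),
        _appelt(
            "appelt_original", -4.76, _APPELT_TERMS,
            "Appelt multifactorial model; 'age' entered as an old-age indicator",
        ),
        _appelt(
            "appelt_a", -1.7575, _APPELT_TERMS,
            "Appelt model A: recalibration-in-the-large (intercept only)",
        ),
        _appelt(
            "appelt_b",
            -1.127,
            {
                "MLD": 0.085,
                "smoke_current": -0.2956,
                "smoke_former": -0.2279,
                "comorbidity": 0.5051,
                "age": 0.3141,
                "seq_chemo": 0.2895,
                "loc_midinf": 0.388,
            },
            f"Appelt model B: full recalibration; slopes = original x {b}",
        ),
        LogisticRiskModel(
            "appelt_c", -1.7422, {"MLD": 0.1637},
            provenance="Model C: BIC-guided simplification of the Appelt framework, MLD retained",
        ),
        LogisticRiskModel(
            "model_d",
            -0.8714,
            {
                "MLD": 0.1199,
                "smoke_former": -0.0572,
                "smoke_current": -2.15,
                "comorbidity": -0.0626,
                "age": 0.0405,
                "stage": -0.2493,
                "NLR": -0.1669,
                "SII": 0.0006,
                "V30": 0.0498,
            },
            provenance=(
                "Final simplified local model D; raw clinical scales assumed "
                "(standardization, if any, was not printed with the equation); "
                "age per year, stage numeric 1-4"
            ),
        ),
    ]
    return {m.name: m for m in models}


def registry_self_test(tol: float = 1e-3) -> None:
    """Check internal consistency of the shipped registry.

    Verifies that every Appelt-B slope equals the original Appelt
    coefficient times the printed calibration slope 0.6159 (within ``tol``),
    the recalibration construction behind model B.
    """
    reg = registry()
    orig, b_model = reg["appelt_original"], reg["appelt_b"]
    for term, beta in orig.terms.items():
        expected = beta * APPELT_CALIBRATION_SLOPE
        got = b_model.terms[term]
        if abs(got - expected) > tol:
            raise AssertionError(
                f"appelt_b[{term}] = {got}, but {beta} x {APPELT_CALIBRATION_SLOPE} "
                f"= {expected:.4f} (tol {tol})"
            )
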