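"""Patient-level cohort handling: reading, validation, coding, summaries.

A cohort is one row per patient with demographics, stage, smoking status,
pulmonary comorbidity, tumor location, pre-treatment hematology, DVH metrics
in physical dose (MLD in Gy; V5/V20/V30 as % of total bilateral lung),
treatment flags, and the radiation-pneumonitis grade. The binary endpoint is
grade >=2 pneumonitis within the follow-up window (``event``). Derived
inflammatory markers:

    NLR = neutrophils / lymphocytes
    SII = platelets * neutrophils / lymphocytes  (= platelets * NLR)

The encoder turns a cohort into the exact covariate columns a
:class:`~rpntcp.models.LogisticRiskModel` expects, using canonical
case-sensitive term names.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import CANONICAL_TERMS, LogisticRiskModel

__all__ = [
    "Cohort",
    "EncodingOptions",
    "read_cohort",
    "encode_for_model",
    "encode_terms",
    "summarize",
    "percentage",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "age", "sex", "stage", "ps", "smoking", "comorbidity", "location3",
    "histology", "neut", "lymph", "plt", "mld", "v5", "v20", "v30",
    "chemo", "immuno", "rp_grade",
)
#: optional columns derived when absent
DERIVED_COLUMNS = ("nlr", "sii", "event")
#: treatment-phase flags (not mutually exclusive); optional in files
PHASE_COLUMNS = (
    "chemo_induction", "chemo_concurrent", "chemo_adjuvant",
    "immuno_induction", "immuno_concurrent", "immuno_adjuvant",
)

SMOKING_LEVELS = ("never", "former", "current")

CONTINUOUS_SUMMARY = ("age", "neut", "lymph", "plt", "nlr", "sii",
                      "mld", "v5", "v20", "v30")
CATEGORICAL_SUMMARY = ("sex", "stage", "ps", "smoking", "comorbidity",
                       "location3", "histology", "chemo", "immuno")


@dataclass
class Cohort:
    """A validated patient table plus a label.

    ``true_model``/``drift`` are attached by the synthetic generator so that
    recovery experiments know the data-generating truth; they are ``None``
    for cohorts read from files.
    """

    df: pd.DataFrame
    label: str = "cohort"
    true_model: LogisticRiskModel | None = None
    drift: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if len(self.df) == 0:
            raise ValueError("cohort is empty")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def y(self) -> np.ndarray:
        return self.df["event"].to_numpy(dtype=float)

    @property
    def n_events(self) -> int:
        return int(self.df["event"].sum())

    def with_df(self, df: pd.DataFrame) -> "Cohort":
        return replace(self, df=df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def _derive(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "nlr" not in df.columns:
        df["nlr"] = df["neut"] / df["lymph"]
    if "sii" not in df.columns:
        df["sii"] = df["plt"] * df["neut"] / df["lymph"]
    if "event" not in df.columns:
        df["event"] = (df["rp_grade"] >= 2).astype(int)
    return df


def _validate(df: pd.DataFrame, label: str) -> None:
    problems = []
    for col in ("v5", "v20", "v30"):
        bad = ~df[col].between(0, 100)
        if bad.any():
            problems.append(f"{col} outside [0,100] in {int(bad.sum())} row(s)")
    if (df["mld"] < 0).any():
        problems.append("negative MLD")
    if (df["lymph"] <= 0).any():
        problems.append("non-positive lymphocyte count")
    bad_smoke = ~df["smoking"].isin(SMOKING_LEVELS)
    if bad_smoke.any():
        problems.append(f"unknown smoking level(s): {sorted(df.loc[bad_smoke, 'smoking'].unique())}")
    mism = df["event"] != (df["rp_grade"] >= 2).astype(int)
    if mism.any():
        problems.append(f"event != (rp_grade >= 2) in {int(mism.sum())} row(s)")
    if problems:
        raise ValueError(f"cohort {label!r} failed validation: " + "; ".join(problems))


def read_cohort(path, label: str | None = None, strict: bool = True) -> Cohort:
    """Read a cohort CSV with canonical headers and validate it.

    Derives ``nlr``, ``sii`` and ``event`` when absent. In strict mode
    (default, mirroring complete-case data) any missing cell in a required
    column is an error; in permissive mode incomplete rows are dropped and
    the count logged.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path}: missing required column(s) {missing}")
    na_rows = df[list(REQUIRED_COLUMNS)].isna().any(axis=1)
    if na_rows.any():
        if strict:
            cols = df[list(REQUIRED_COLUMNS)].isna().any(axis=0)
            raise ValueError(
                f"cohort file {path}: missing values in required column(s) "
                f"{list(cols.index[cols])} (strict mode)"
            )
        log.warning("dropping %d incomplete row(s) from %s", int(na_rows.sum()), path)
        df = df[~na_rows]
    df = _derive(df)
    label = label or str(path)
    _validate(df, label)
    return Cohort(df=df, label=label)


# -- encoding ------------------------------------------------------------


@dataclass(frozen=True)
class EncodingOptions:
    """Configurable codings the published equations do not pin down.

    ``age_cutoff``: threshold for the Appelt old-age indicator (the source
    model's cutoff is not printed; default 63, near the cohort median).
    ``midinf_levels``: which ``location3`` levels count as mid-or-inferior
    tumor location (three-level coding in the data, binary term in the
    model; default {1, 2}).
    """

    age_cutoff: float = 63.0
    midinf_levels: frozenset[int] = field(default_factory=lambda: frozenset({1, 2}))


def _seq_chemo(df: pd.DataFrame) -> pd.Series:
    """Sequential (non-concurrent) chemotherapy indicator."""
    if "chemo_concurrent" not in df.columns:
        raise KeyError(
            "term 'seq_chemo' needs the 'chemo_concurrent' phase flag; "
            "add chemo_induction/chemo_concurrent/chemo_adjuvant columns"
        )
    return ((df["chemo"] == 1) & (df["chemo_concurrent"] == 0)).astype(float)


def encode_terms(
    cohort: Cohort,
    terms,
    options: EncodingOptions | None = None,
    age_indicator: bool = False,
) -> pd.DataFrame:
    """Build the coded covariate matrix for the given canonical term names.

    Smoking is coded as two indicators with never-smoker as reference;
    stage enters numerically (1-4); ``age`` is continuous unless
    ``age_indicator`` asks for the old-age binarization.
    """
    opts = options or EncodingOptions()
    df = cohort.df
    out = {}
    for term in terms:
        if term == "MLD":
            out[term] = df["mld"].astype(float)
        elif term == "V30":
            out[term] = df["v30"].astype(float)
        elif term == "smoke_former":
            out[term] = (df["smoking"] == "former").astype(float)
        elif term == "smoke_current":
            out[term] = (df["smoking"] == "current").astype(float)
        elif term == "comorbidity":
            out[term] = df["comorbidity"].astype(float)
        elif term == "age":
            col = df["age"].astype(float)
            out[term] = (col >= opts.age_cutoff).astype(float) if age_indicator else col
        elif term == "stage":
            out[term] = df["stage"].astype(float)
        elif term == "NLR":
            out[term] = df["nlr"].astype(float)
        elif term == "SII":
            out[term] = df["sii"].astype(float)
        elif term == "seq_chemo":
            out[term] = _seq_chemo(df)
        elif term == "loc_midinf":
            out[term] = df["location3"].isin(opts.midinf_levels).astype(float)
        else:
            raise KeyError(
                f"cannot encode term {term!r}; known terms: {list(CANONICAL_TERMS)}"
            )
    return pd.DataFrame(out, index=df.index)


def encode_for_model(
    cohort: Cohort,
    model: LogisticRiskModel,
    options: EncodingOptions | None = None,
) -> pd.DataFrame:
    """Coded covariate matrix with exactly the model's term names/order.

    A declared ``indicator_threshold`` transform on ``age`` switches the age
    column to the old-age indicator at that threshold (the encoder option's
    cutoff is overridden by an explicit model transform); center/scale
    transforms are applied by the model at evaluation time, not here.
    """
    opts = options or EncodingOptions()
    age_tr = model.transform_for("age")
    age_indicator = age_tr is not None and age_tr.indicator_threshold is not None
    if age_indicator:
        opts = replace(opts, age_cutoff=float(age_tr.indicator_threshold))
    return encode_terms(cohort, model.term_names, opts, age_indicator=age_indicator)


def model_linear_predictor(
    cohort: Cohort, model: LogisticRiskModel, options: EncodingOptions | None = None
) -> np.ndarray:
    """Vectorized LP for every patient (transforms applied)."""
    X = encode_for_model(cohort, model, options)
    lp = np.full(len(X), model.intercept)
    for term, beta in model.terms.items():
        col = X[term].to_numpy(dtype=float)
        tr = model.transform_for(term)
        if tr is not None and tr.indicator_threshold is None:
            col = (col - tr.center) / tr.scale
        lp += beta * col
    return lp


def model_predictions(
    cohort: Cohort, model: LogisticRiskModel, options: EncodingOptions | None = None
) -> np.ndarray:
    """Vectorized predicted risks, strictly in (0, 1)."""
    lp = np.clip(model_linear_predictor(cohort, model, options), -700, 700)
    return np.clip(1.0 / (1.0 + np.exp(-lp)), 1e-12, 1.0 - 1e-12)


# -- summaries -----------------------------------------------------------


def percentage(k: int, n: int) -> float:
    """k/n as a percentage, rounded to 1 decimal (table style)."""
    return round(100.0 * k / n, 1)


def summarize(cohort: Cohort) -> pd.DataFrame:
    """Baseline-characteristics table: mean +/- SD or n (%).

    Continuous variables as mean and SD (2 decimals); categorical as count
    and percentage (1 decimal); plus the grade >=2 event rate. A
    single-patient cohort reports SD = 0 with a warning rather than NaN so
    the table stays total.
    """
    df = cohort.df
    rows = []
    for col in CONTINUOUS_SUMMARY:
        if col not in df.columns:
            continue
        x = df[col].astype(float)
        if len(x) < 2:
            warnings.warn(f"SD of {col!r} undefined for n=1; reporting 0", stacklevel=2)
            sd = 0.0
        else:
            sd = float(x.std(ddof=1))
        rows.append({"variable": col, "level": "", "kind": "continuous",
                     "mean": round(float(x.mean()), 2), "sd": round(sd, 2),
                     "n": len(x), "percent": np.nan})
    for col in CATEGORICAL_SUMMARY:
        if col not in df.columns:
            continue
        counts = df[col].value_counts().sort_index()
        for level, k in counts.items():
            rows.append({"variable": col, "level": str(level), "kind": "categorical",
                         "mean": np.nan, "sd": np.nan, "n": int(k),
                         "percent": percentage(int(k), len(df))})
    rows.append({"variable": "event", "level": "grade>=2", "kind": "categorical",
                 "mean": np.nan, "sd": np.nan, "n": cohort.n_events,
                 "percent": percentage(cohort.n_events, len(df))})
    return pd.DataFrame(rows)
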