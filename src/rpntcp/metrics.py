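"""Discrimination, calibration, and fit statistics for binary risk models.

Implements the standard external-validation panel for a logistic prediction
model: Mann-Whitney AUC (with bootstrap percentile CI), Brier score,
log-likelihood / AIC / BIC / Nagelkerke R^2, calibration-in-the-large and
calibration slope, the Hosmer-Lemeshow chi-square on quantile risk groups
(duplicate cut-points dropped), and grouped calibration curves.

Conventions that the literature leaves loose are explicit arguments here:

* CITL is the intercept of a maximum-likelihood logistic fit of outcomes on
  the model's linear predictor entered as a fixed offset; the calibration
  slope is the LP coefficient of a free intercept+slope refit. The
  intercept of that joint fit is also reported for transparency.
* Hosmer-Lemeshow degrees of freedom follow a named policy: ``"fitted"``
  (g - 2, model estimated on the evaluated data) or ``"external"`` (g,
  coefficients fixed elsewhere).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import logit as _logit

__all__ = [
    "ValidationReport",
    "CalibrationFit",
    "auc",
    "bootstrap_auc_ci",
    "brier",
    "fit_stats",
    "citl_and_slope",
    "hosmer_lemeshow",
    "calibration_curve",
    "validation_report",
]

log = logging.getLogger(__name__)

_CLIP = 1e-12  # probability clipping bound before logit


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary 0/1")
    return y


def _clip_probs(pred: np.ndarray) -> np.ndarray:
    pred = np.asarray(pred, dtype=float)
    if ((pred <= 0) | (pred >= 1)).any():
        log.info("clipping %d prediction(s) to [%g, 1-%g] before logit",
                 int(((pred <= _CLIP) | (pred >= 1 - _CLIP)).sum()), _CLIP, _CLIP)
    return np.clip(pred, _CLIP, 1 - _CLIP)


# -- discrimination ------------------------------------------------------


def auc(pred, y) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    Midrank tie handling; invariant under any strictly increasing transform
    of the predictions, so recalibration never changes it.
    """
    y = _check_binary(y)
    pred = np.asarray(pred, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both outcome classes must be present")
    ranks = stats.rankdata(pred)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def bootstrap_auc_ci(pred, y, B: int = 1000, seed: int | None = None,
                     level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC over paired patient resamples.

    Resamples that land on a single outcome class are redrawn (and logged);
    fully reproducible given ``seed``.
    """
    if B < 100:
        raise ValueError("use at least B=100 bootstrap resamples")
    y = _check_binary(y)
    pred = np.asarray(pred, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y)
    vals = np.empty(B)
    redrawn = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, n)
            if 0 < y[idx].sum() < n:
                break
            redrawn += 1
        vals[b] = auc(pred[idx], y[idx])
    if redrawn:
        log.info("redrew %d single-class bootstrap resample(s)", redrawn)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(vals, [alpha, 1 - alpha])
    return float(lo), float(hi)


def brier(pred, y) -> float:
    """Mean squared error between predicted probability and outcome."""
    y = _check_binary(y)
    return float(np.mean((np.asarray(pred, dtype=float) - y) ** 2))


# -- likelihood-based fit ------------------------------------------------


class FitStats(NamedTuple):
    log_likelihood: float
    aic: float
    bic: float
    nagelkerke_r2: float


def fit_stats(pred, y, k: int) -> FitStats:
    """Log-likelihood, AIC, BIC and Nagelkerke R^2 of fixed predictions.

    ``k`` is the number of model parameters charged by AIC/BIC (intercept
    included). Nagelkerke rescales the Cox-Snell R^2 against the
    intercept-only (prevalence) model so a perfect model reaches 1.
    """
    y = _check_binary(y)
    p = _clip_probs(pred)
    n = len(y)
    ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    pi = y.mean()
    ll0 = float(n * (pi * np.log(pi) + (1 - pi) * np.log(1 - pi))) if 0 < pi < 1 else 0.0
    r2_cs = 1.0 - np.exp(2.0 * (ll0 - ll) / n)
    r2_max = 1.0 - np.exp(2.0 * ll0 / n)
    nagelkerke = float(r2_cs / r2_max) if r2_max > 0 else 0.0
    return FitStats(ll, -2 * ll + 2 * k, -2 * ll + k * np.log(n), nagelkerke)


# -- calibration ---------------------------------------------------------


class CalibrationFit(NamedTuple):
    """CITL (offset-fit intercept), slope (free-fit LP coefficient), and the
    free fit's intercept, reported for transparency."""

    citl: float
    slope: float
    joint_intercept: float


def citl_and_slope(pred, y) -> CalibrationFit:
    """Calibration-in-the-large and calibration slope of predictions.

    CITL: ML intercept of ``y ~ 1`` with logit(pred) as a fixed offset; 0 is
    ideal, negative means the model overestimates risk. Slope: LP
    coefficient of ``y ~ 1 + logit(pred)``; 1 is ideal, below 1 indicates
    predictions more extreme than outcomes warrant.
    """
    y = _check_binary(y)
    lp = _logit(_clip_probs(pred))
    ones = np.ones((len(y), 1))
    try:
        offset_fit = sm.GLM(y, ones, family=sm.families.Binomial(), offset=lp).fit()
        joint_fit = sm.GLM(y, np.column_stack([np.ones_like(lp), lp]),
                           family=sm.families.Binomial()).fit()
    except Exception as exc:  # non-convergence / perfect separation
        raise RuntimeError(f"calibration fit failed: {exc}") from exc
    if not (offset_fit.converged and joint_fit.converged):
        raise RuntimeError("calibration fit did not converge")
    return CalibrationFit(float(offset_fit.params[0]),
                          float(joint_fit.params[1]),
                          float(joint_fit.params[0]))


def _quantile_groups(pred: np.ndarray, groups: int) -> np.ndarray:
    """Group index per observation from quantile cuts; duplicate cut-points
    dropped, so the realized number of groups can be below ``groups``."""
    edges = np.quantile(pred, np.linspace(0, 1, groups + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        raise ValueError(
            "fewer than 2 distinct risk groups after dropping duplicate "
            "cut-points; predictions are (nearly) constant"
        )
    # right-closed bins on unique edges; lowest edge made inclusive
    idx = np.searchsorted(edges, pred, side="left") - 1
    return np.clip(idx, 0, len(edges) - 2)


def hosmer_lemeshow(pred, y, groups: int = 10, df_policy: str = "fitted"
                    ) -> tuple[float, int, float, int]:
    """Hosmer-Lemeshow chi-square on quantile risk groups.

    Sums (O - E)^2 / E over both outcome classes within each group.
    Returns ``(chi2, df, p, groups_used)``; ``df_policy`` is ``"fitted"``
    (df = g - 2) or ``"external"`` (df = g).
    """
    if groups < 2:
        raise ValueError("need at least 2 risk groups")
    if df_policy not in ("fitted", "external"):
        raise ValueError("df_policy must be 'fitted' or 'external'")
    y = _check_binary(y)
    pred = np.asarray(pred, dtype=float)
    gidx = _quantile_groups(pred, groups)
    chi2 = 0.0
    used = 0
    for g in np.unique(gidx):
        sel = gidx == g
        e1 = pred[sel].sum()
        e0 = (1 - pred[sel]).sum()
        o1 = y[sel].sum()
        o0 = (1 - y[sel]).sum()
        chi2 += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
        used += 1
    df = used - 2 if df_policy == "fitted" else used
    df = max(df, 1)
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), p, int(used)


def calibration_curve(pred, y, groups: int = 10) -> pd.DataFrame:
    """Grouped calibration curve: per-quantile-bin mean prediction,
    observed event rate, and bin size.

    ``groups=10`` is the usual decile plot; small external cohorts commonly
    use 4 groups.
    """
    if groups < 2:
        raise ValueError("need at least 2 groups")
    y = _check_binary(y)
    pred = np.asarray(pred, dtype=float)
    gidx = _quantile_groups(pred, groups)
    rows = []
    for g in np.unique(gidx):
        sel = gidx == g
        rows.append({"mean_pred": float(pred[sel].mean()),
                     "observed_rate": float(y[sel].mean()),
                     "n": int(sel.sum())})
    return pd.DataFrame(rows)


# -- assembled report ----------------------------------------------------


@dataclass
class ValidationReport:
    """The full metric panel for one model evaluated on one cohort."""

    label: str
    n: int
    events: int
    auc: float
    auc_ci: tuple[float, float] | None
    brier: float
    log_likelihood: float
    aic: float
    bic: float
    nagelkerke_r2: float
    citl: float
    calibration_slope: float
    joint_intercept: float
    hl_chi2: float
    hl_df: int
    hl_p: float
    hl_groups_used: int
    calibration_curve: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        d = {
            "label": self.label, "n": self.n, "events": self.events,
            "auc": self.auc, "brier": self.brier,
            "log_likelihood": self.log_likelihood, "aic": self.aic,
            "bic": self.bic, "nagelkerke_r2": self.nagelkerke_r2,
            "citl": self.citl, "calibration_slope": self.calibration_slope,
            "joint_intercept": self.joint_intercept,
            "hl_chi2": self.hl_chi2, "hl_df": self.hl_df, "hl_p": self.hl_p,
            "hl_groups_used": self.hl_groups_used,
        }
        if self.auc_ci is not None:
            d["auc_ci_lower"], d["auc_ci_upper"] = self.auc_ci
        if self.calibration_curve is not None:
            d["calibration_curve"] = self.calibration_curve.to_dict(orient="records")
        return d


def validation_report(pred, y, k: int, label: str = "", groups: int = 10,
                      df_policy: str = "fitted", bootstrap: int = 0,
                      seed: int | None = None) -> ValidationReport:
    """Compute the whole panel in one call.

    ``bootstrap > 0`` adds a percentile bootstrap CI for the AUC (seed
    required then).
    """
    y = _check_binary(y)
    pred = np.asarray(pred, dtype=float)
    ci = None
    if bootstrap:
        if seed is None:
            raise ValueError("bootstrap AUC CI requires a seed")
        ci = bootstrap_auc_ci(pred, y, B=bootstrap, seed=seed)
    fs = fit_stats(pred, y, k)
    cal = citl_and_slope(pred, y)
    chi2, df, p, used = hosmer_lemeshow(pred, y, groups=groups, df_policy=df_policy)
    return ValidationReport(
        label=label, n=len(y), events=int(y.sum()),
        auc=auc(pred, y), auc_ci=ci, brier=brier(pred, y),
        log_likelihood=fs.log_likelihood, aic=fs.aic, bic=fs.bic,
        nagelkerke_r2=fs.nagelkerke_r2,
        citl=cal.citl, calibration_slope=cal.slope,
        joint_intercept=cal.joint_intercept,
        hl_chi2=chi2, hl_df=df, hl_p=p, hl_groups_used=used,
        calibration_curve=calibration_curve(pred, y, groups=groups),
    )
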