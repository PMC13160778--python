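"""Validation protocols: bootstrap optimism correction and fixed-coefficient
external validation.

Internal validation follows the standard bootstrap scheme: with the
predictor set held fixed (no per-resample selection), the model is refitted
in bootstrap samples of the original size, each refit is scored both on its
own bootstrap sample and on the original cohort, and the mean of that
difference (the optimism) is subtracted from the apparent performance.

External validation applies a model with locked coefficients to an
independent cohort and reports the full metric panel with the "external"
Hosmer-Lemeshow df policy and a small-cohort calibration grouping preset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .cohort import Cohort, EncodingOptions, encode_terms, model_predictions
from .metrics import ValidationReport, auc, brier, citl_and_slope, validation_report

__all__ = ["OptimismReport", "bootstrap_optimism", "external_validate"]

log = logging.getLogger(__name__)

_OPTIMISM_METRICS = ("auc", "brier", "slope")


@dataclass
class OptimismReport:
    """Apparent, optimism and corrected performance per metric.

    AUC is the primary optimism-corrected metric; Brier and calibration
    slope are reported as standard-practice extensions.
    """

    apparent: dict[str, float]
    optimism: dict[str, float]
    corrected: dict[str, float]
    B: int
    completed: int
    seed: int

    def to_dict(self) -> dict:
        return {"apparent": self.apparent, "optimism": self.optimism,
                "corrected": self.corrected, "B": self.B,
                "completed": self.completed, "seed": self.seed}


def _refit_predict(X: np.ndarray, y: np.ndarray, X_eval: np.ndarray) -> np.ndarray:
    Xc = sm.add_constant(X, has_constant="add")
    res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(maxiter=200)
    if not res.converged:
        raise RuntimeError("refit did not converge")
    lp = sm.add_constant(X_eval, has_constant="add") @ np.asarray(res.params)
    return 1.0 / (1.0 + np.exp(-np.clip(lp, -700, 700)))


def _panel(pred: np.ndarray, y: np.ndarray) -> dict[str, float]:
    return {"auc": auc(pred, y), "brier": brier(pred, y),
            "slope": citl_and_slope(pred, y).slope}


def bootstrap_optimism(
    cohort: Cohort,
    term_set,
    B: int = 1000,
    seed: int | None = None,
    options: EncodingOptions | None = None,
    age_indicator: bool = False,
) -> OptimismReport:
    """Optimism-corrected performance of a refitted model over fixed terms.

    Per resample: refit on the bootstrap sample, score on the bootstrap
    sample and on the original cohort; optimism is the mean score
    difference. Failed resamples are skipped (not redrawn, keeping the
    resample plan reproducible); more than 5% failures is an error.
    """
    if B < 100:
        raise ValueError("use at least B=100 resamples")
    if seed is None:
        raise ValueError("bootstrap_optimism requires a seed")
    X = encode_terms(cohort, term_set, options, age_indicator=age_indicator
                     ).to_numpy(dtype=float)
    y = cohort.y
    n = len(y)
    apparent = _panel(_refit_predict(X, y, X), y)

    rng = np.random.default_rng(seed)
    sums = dict.fromkeys(_OPTIMISM_METRICS, 0.0)
    completed = 0
    for b in range(B):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.sum() in (0, n):
            log.info("resample %d skipped: single outcome class", b)
            continue
        try:
            p_boot = _refit_predict(X[idx], yb, X[idx])
            p_orig = _refit_predict(X[idx], yb, X)
            perf_boot = _panel(p_boot, yb)
            perf_orig = _panel(p_orig, y)
        except Exception as exc:
            log.info("resample %d skipped: %s", b, exc)
            continue
        for m in _OPTIMISM_METRICS:
            sums[m] += perf_boot[m] - perf_orig[m]
        completed += 1
    if completed < 0.95 * B:
        raise RuntimeError(f"only {completed}/{B} bootstrap resamples completed")
    optimism = {m: sums[m] / completed for m in _OPTIMISM_METRICS}
    corrected = {m: apparent[m] - optimism[m] for m in _OPTIMISM_METRICS}
    return OptimismReport(apparent=apparent, optimism=optimism, corrected=corrected,
                          B=B, completed=completed, seed=seed)


def external_validate(
    model,
    cohort: Cohort,
    groups: int = 4,
    B: int = 1000,
    seed: int | None = None,
    options: EncodingOptions | None = None,
) -> ValidationReport:
    """Fixed-coefficient validation of a model on an independent cohort.

    No re-estimation is performed; the panel uses the external HL df policy
    and defaults to 4 calibration groups (the usual small-cohort preset).
    AIC/BIC are charged k = number of terms + 1 parameters for continuity
    with development-cohort tables, although no parameter was estimated here
    (a documented convention, not a likelihood-theory claim).
    """
    pred = model_predictions(cohort, model, options)
    return validation_report(
        pred, cohort.y, k=len(model.terms) + 1, label=f"{model.name} on {cohort.label}",
        groups=groups, df_policy="external", bootstrap=B, seed=seed,
    )
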