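"""Model updating: the closed-testing ladder and its building blocks.

When a published risk model is carried to a new population, the least
extensive update that fixes its misfit is preferred:

    none -> intercept recalibration -> intercept+slope recalibration
         -> full revision (re-estimate every coefficient)

The closed test walks this ladder with likelihood-ratio chi-square tests,
each more extensive level tested against the currently accepted one
(intercept vs none, df=1; slope vs intercept, df=1; revision vs slope,
df = #terms - 1), and stops at the first non-rejection.

Also here: penalized revision (ridge/lasso with cross-validated penalty),
deterministic backward elimination under BIC, and a restricted-cubic-spline
likelihood-ratio check for non-linearity of a continuous covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from .cohort import Cohort, EncodingOptions, encode_for_model, encode_terms, model_linear_predictor
from .models import CANONICAL_TERMS, CovariateTransform, LogisticRiskModel

__all__ = [
    "UpdateResult",
    "SelectionTrace",
    "recalibrate_intercept",
    "recalibrate",
    "revise",
    "closed_test",
    "bic_simplify",
    "rcs_basis",
    "rcs_nonlinearity_check",
]

LEVELS = ("none", "intercept", "intercept_slope", "revision")


@dataclass
class UpdateResult:
    """Outcome of the closed test: the chosen level, the fitted model at
    every level, and the full likelihood-ratio test trace."""

    selected_level: str
    models: dict[str, LogisticRiskModel]
    tests: list[tuple[str, float, int, float]]  # (comparison, LR, df, p)
    alpha: float
    log_likelihoods: dict[str, float] = field(default_factory=dict)

    @property
    def selected_model(self) -> LogisticRiskModel:
        return self.models[self.selected_level]


@dataclass
class SelectionTrace:
    """Accepted states of a backward-elimination search, in order."""

    steps: list[tuple[tuple[str, ...], float]]  # (term set, BIC)
    final_terms: tuple[str, ...]


def _bernoulli_ll(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _design_for_model(cohort: Cohort, model: LogisticRiskModel,
                      options: EncodingOptions | None) -> np.ndarray:
    """Covariates on the model's transformed scale (what the betas multiply)."""
    X = encode_for_model(cohort, model, options)
    cols = []
    for term in model.term_names:
        col = X[term].to_numpy(dtype=float)
        tr = model.transform_for(term)
        if tr is not None and tr.indicator_threshold is None:
            col = (col - tr.center) / tr.scale
        cols.append(col)
    return np.column_stack(cols)


def _fit_glm(y: np.ndarray, X: np.ndarray, offset: np.ndarray | None = None):
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial(), offset=offset).fit(maxiter=200)
    except Exception as exc:
        raise RuntimeError(f"logistic fit failed: {exc}") from exc
    if not res.converged:
        raise RuntimeError("logistic fit did not converge")
    return res


# -- recalibration -------------------------------------------------------


def recalibrate_intercept(model: LogisticRiskModel, cohort: Cohort,
                          options: EncodingOptions | None = None) -> LogisticRiskModel:
    """Recalibration-in-the-large: re-estimate the intercept only.

    Fits the ML offset correction ``logit(p) = alpha + LP`` and folds alpha
    into the intercept; every slope coefficient is untouched.
    """
    lp = model_linear_predictor(cohort, model, options)
    res = _fit_glm(cohort.y, np.ones((len(cohort), 1)), offset=lp)
    alpha = float(res.params[0])
    return LogisticRiskModel(
        name=f"{model.name}+intercept",
        intercept=model.intercept + alpha,
        terms=model.terms,
        transforms=model.transforms,
        provenance=f"{model.name} after intercept recalibration (alpha={alpha:.6g})",
    )


def recalibrate(model: LogisticRiskModel, cohort: Cohort,
                options: EncodingOptions | None = None) -> LogisticRiskModel:
    """Full (logistic) recalibration: fit ``logit(p) = a + b * LP``.

    The returned model has intercept ``a + b * beta0`` and every term
    coefficient scaled by the fitted slope ``b``, so its predictions equal
    the recalibrated ones and its LP remains a monotone transform of the
    original (discrimination unchanged by construction).
    """
    lp = model_linear_predictor(cohort, model, options)
    res = _fit_glm(cohort.y, np.column_stack([np.ones_like(lp), lp]))
    a, b = float(res.params[0]), float(res.params[1])
    return LogisticRiskModel(
        name=f"{model.name}+recal",
        intercept=a + b * model.intercept,
        terms={t: b * beta for t, beta in model.terms.items()},
        transforms=model.transforms,
        provenance=f"{model.name} after full recalibration (a={a:.6g}, b={b:.6g})",
    )


# -- revision ------------------------------------------------------------

_DEFAULT_LAMBDAS = np.logspace(-4, 2, 25)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


def _cv_deviance(Xs: np.ndarray, y: np.ndarray, penalty: str, lam: float,
                 cv: int, seed: int) -> float:
    kf = KFold(n_splits=cv, shuffle=True, random_state=seed)
    dev = 0.0
    for tr, te in kf.split(Xs):
        clf = _sk_logistic(penalty, lam).fit(Xs[tr], y[tr])
        p = clf.predict_proba(Xs[te])[:, 1]
        dev += -2.0 * _bernoulli_ll(p, y[te])
    return dev / len(y)


def _sk_logistic(penalty: str, lam: float) -> LogisticRegression:
    # sklearn minimizes C * sum(logloss) + 0.5||w||_2^2 (or ||w||_1); the
    # intercept is unpenalized with these solvers.
    common = dict(C=1.0 / lam, fit_intercept=True, max_iter=5000, tol=1e-8)
    if penalty == "ridge":
        return LogisticRegression(solver="lbfgs", **common)
    return LogisticRegression(solver="saga", l1_ratio=1.0, **common)


def revise(
    model_terms: Sequence[str],
    cohort: Cohort,
    penalty: str = "none",
    options: EncodingOptions | None = None,
    age_indicator: bool = False,
    lambdas: Sequence[float] | None = None,
    cv: int = 10,
    seed: int | None = None,
    relaxed: bool = False,
    name: str = "revised",
) -> LogisticRiskModel:
    """Re-estimate every coefficient over the given canonical terms.

    ``penalty="none"`` is a plain ML logistic fit (errors on separation,
    advising ridge). Ridge/lasso standardize covariates internally, pick the
    penalty weight by ``cv``-fold cross-validated deviance over ``lambdas``
    (default 25-point log grid, 1e-4..1e2; seed required), and report the
    coefficients back on the input scale with the intercept unpenalized.
    ``relaxed=True`` refits the lasso's selected support without penalty.
    """
    terms = list(model_terms)
    if not terms:
        raise ValueError("empty term set")
    X = encode_terms(cohort, terms, options, age_indicator=age_indicator).to_numpy(dtype=float)
    y = cohort.y
    if penalty == "none":
        try:
            res = _fit_glm(y, sm.add_constant(X, has_constant="add"))
        except RuntimeError as exc:
            raise RuntimeError(
                f"{exc}; if covariates separate the outcome, use penalty='ridge'"
            ) from exc
        params = np.asarray(res.params, dtype=float)
        intercept, coefs = float(params[0]), params[1:]
    elif penalty in ("ridge", "lasso"):
        if seed is None:
            raise ValueError("penalized revision requires a seed (CV fold shuffling)")
        Xs, mu, sd = _standardize(X)
        grid = np.asarray(lambdas if lambdas is not None else _DEFAULT_LAMBDAS, dtype=float)
        devs = [_cv_deviance(Xs, y, penalty, lam, cv, seed) for lam in grid]
        lam = float(grid[int(np.argmin(devs))])
        clf = _sk_logistic(penalty, lam).fit(Xs, y)
        coefs_std = clf.coef_.ravel()
        coefs = coefs_std / sd
        intercept = float(clf.intercept_[0] - np.sum(coefs_std * mu / sd))
        if penalty == "lasso" and relaxed:
            support = [t for t, c in zip(terms, coefs) if c != 0.0]
            if support:
                return revise(support, cohort, penalty="none", options=options,
                              age_indicator=age_indicator, name=f"{name}(relaxed)")
        name = f"{name}({penalty}, lambda={lam:.4g})"
    else:
        raise ValueError("penalty must be 'none', 'ridge' or 'lasso'")
    transforms = (CovariateTransform(name="age", indicator_threshold=(
        options or EncodingOptions()).age_cutoff),) if (age_indicator and "age" in terms) else ()
    return LogisticRiskModel(
        name=name, intercept=intercept,
        terms={t: float(c) for t, c in zip(terms, coefs)},
        transforms=transforms,
        provenance=f"refit on cohort {cohort.label!r} (penalty={penalty})",
    )


# -- closed testing ------------------------------------------------------


def closed_test(model: LogisticRiskModel, cohort: Cohort, alpha: float = 0.05,
                options: EncodingOptions | None = None) -> UpdateResult:
    """Select the least extensive update the data demand.

    Fits all four nested levels, computes the likelihood-ratio trace, and
    walks the ladder: a level is adopted only while the test against the
    currently accepted level rejects at ``alpha``. For a single-term model
    the revision level coincides with intercept+slope (zero extra df) and
    its test is reported with p = 1.
    """
    y = cohort.y
    Xt = _design_for_model(cohort, model, options)
    beta = np.array(list(model.terms.values()))
    lp = model.intercept + Xt @ beta

    m_int = recalibrate_intercept(model, cohort, options)
    m_slope = recalibrate(model, cohort, options)
    res_rev = _fit_glm(y, sm.add_constant(Xt, has_constant="add"))
    params = np.asarray(res_rev.params, dtype=float)
    m_rev = LogisticRiskModel(
        name=f"{model.name}+revision",
        intercept=float(params[0]),
        terms={t: float(c) for t, c in zip(model.term_names, params[1:])},
        transforms=model.transforms,
        provenance=f"{model.name} fully revised on {cohort.label!r}",
    )

    def _ll(m: LogisticRiskModel) -> float:
        # same terms/transforms as `model`, so the design matrix is reusable
        lp_m = m.intercept + Xt @ np.array(list(m.terms.values()))
        return _bernoulli_ll(1 / (1 + np.exp(-np.clip(lp_m, -700, 700))), y)

    ll = {
        "none": _bernoulli_ll(1 / (1 + np.exp(-np.clip(lp, -700, 700))), y),
        "intercept": _ll(m_int),
        "intercept_slope": _ll(m_slope),
        "revision": float(res_rev.llf),
    }

    df_rev = len(model.terms) - 1
    tests = []
    for lo, hi, df in (("none", "intercept", 1),
                       ("intercept", "intercept_slope", 1),
                       ("intercept_slope", "revision", df_rev)):
        lr = max(2.0 * (ll[hi] - ll[lo]), 0.0)
        p = float(stats.chi2.sf(lr, df)) if df > 0 else 1.0
        tests.append((f"{hi} vs {lo}", lr, df, p))

    selected = "none"
    for (comparison, lr, df, p), level in zip(tests, LEVELS[1:]):
        if p < alpha:
            selected = level
        else:
            break

    return UpdateResult(
        selected_level=selected,
        models={"none": model, "intercept": m_int,
                "intercept_slope": m_slope, "revision": m_rev},
        tests=tests, alpha=alpha, log_likelihoods=ll,
    )


# -- BIC-guided simplification ------------------------------------------


def _logit_bic(X: pd.DataFrame, y: np.ndarray) -> float:
    res = _fit_glm(y, sm.add_constant(X.to_numpy(dtype=float), has_constant="add"))
    k = X.shape[1] + 1
    return float(-2 * res.llf + k * np.log(len(y)))


def bic_simplify(
    cohort: Cohort,
    candidate_terms: Sequence[str],
    forced_terms: Sequence[str] = (),
    options: EncodingOptions | None = None,
    age_indicator: bool = False,
    name: str = "bic_simplified",
) -> tuple[LogisticRiskModel, SelectionTrace]:
    """Deterministic backward elimination under BIC.

    At each step the removal that lowers BIC most is taken; elimination
    stops when no removal lowers BIC. Ties are broken by canonical term
    order. ``forced_terms`` are never dropped.
    """
    terms = list(candidate_terms)
    if not terms:
        raise ValueError("empty candidate term set")
    forced = set(forced_terms)
    if not forced.issubset(terms):
        raise ValueError("forced_terms must be a subset of candidate_terms")
    y = cohort.y
    X = encode_terms(cohort, terms, options, age_indicator=age_indicator)

    order = {t: i for i, t in enumerate(CANONICAL_TERMS)}
    current = list(terms)
    bic = _logit_bic(X[current], y)
    steps = [(tuple(current), bic)]
    while True:
        droppable = sorted((t for t in current if t not in forced),
                           key=lambda t: order.get(t, len(order)))
        best = None
        for t in droppable:
            if len(current) == 1:
                break
            trial = [u for u in current if u != t]
            b = _logit_bic(X[trial], y)
            if b < bic and (best is None or b < best[1]):
                best = (t, b)
        if best is None:
            break
        current = [u for u in current if u != best[0]]
        bic = best[1]
        steps.append((tuple(current), bic))

    final = revise(current, cohort, penalty="none", options=options,
                   age_indicator=age_indicator, name=name)
    return final, SelectionTrace(steps=steps, final_terms=tuple(current))


# -- restricted cubic splines -------------------------------------------


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (linear-tail parametrization).

    For k knots returns k-1 columns: x itself plus k-2 non-linear terms

        [(x-t_j)+^3 - (x-t_{k-1})+^3 (t_k-t_j)/(t_k-t_{k-1})
                    + (x-t_k)+^3 (t_{k-1}-t_j)/(t_k-t_{k-1})] / (t_k-t_1)^2

    which is linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    t = np.sort(np.asarray(knots, dtype=float))
    k = len(t)
    if k < 3:
        raise ValueError("need at least 3 knots")
    norm = (t[-1] - t[0]) ** 2
    cols = [x]
    pos = lambda v: np.clip(v, 0, None) ** 3
    for j in range(k - 2):
        term = (pos(x - t[j])
                - pos(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
                + pos(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])) / norm
        cols.append(term)
    return np.column_stack(cols)


_KNOT_QUANTILES = {3: (0.1, 0.5, 0.9),
                   4: (0.05, 0.35, 0.65, 0.95),
                   5: (0.05, 0.275, 0.5, 0.725, 0.95)}


def rcs_nonlinearity_check(cohort: Cohort, covariate: str = "age", knots: int = 3,
                           alpha: float = 0.05) -> tuple[float, float, str]:
    """Likelihood-ratio test of spline terms beyond a linear effect.

    Knots at standard quantiles (3 knots at 0.1/0.5/0.9). Returns
    ``(LR, p, verdict)`` with verdict ``"linear"`` when p >= alpha.
    """
    if knots not in _KNOT_QUANTILES:
        raise ValueError("knots must be 3, 4 or 5")
    x = cohort.df[covariate].to_numpy(dtype=float)
    if len(np.unique(x)) < knots + 2:
        raise ValueError(f"too few distinct {covariate!r} values for {knots} knots")
    kq = np.quantile(x, _KNOT_QUANTILES[knots])
    if len(np.unique(kq)) < knots:
        raise ValueError("duplicate knots; covariate too discrete")
    y = cohort.y
    B = rcs_basis(x, kq)
    lin = _fit_glm(y, sm.add_constant(B[:, :1], has_constant="add"))
    spl = _fit_glm(y, sm.add_constant(B, has_constant="add"))
    lr = max(2.0 * (spl.llf - lin.llf), 0.0)
    df = knots - 2
    p = float(stats.chi2.sf(lr, df))
    return lr, p, ("linear" if p >= alpha else "non-linear")
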