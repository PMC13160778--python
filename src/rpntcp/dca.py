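"""Decision curve analysis: net benefit across threshold probabilities.

At a threshold probability t (the predicted risk above which intensified
management would be considered) the net benefit of acting on a model is

    NB(t) = TP/n - (FP/n) * t / (1 - t)

where TP and FP count predictions >= t among patients with and without the
event. Treat-none has NB = 0 everywhere; treat-all has
NB = pi - (1 - pi) * t / (1 - t) with pi the event prevalence. Classification
is closed on the left (pred >= t), so a patient whose prediction equals the
threshold is treated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DecisionCurve", "net_benefit", "decision_curve", "default_grid"]


def default_grid(start: float = 0.01, stop: float = 0.50, step: float = 0.01) -> np.ndarray:
    """Threshold grid covering the clinically relevant low-to-intermediate range."""
    return np.round(np.arange(start, stop + step / 2, step), 10)


@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray
    #: contiguous-scan (t_lo, t_hi) where the model beats both default
    #: strategies, or None when it never does
    positive_range: tuple[float, float] | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "nb_model": self.nb_model,
                             "nb_all": self.nb_all, "nb_none": self.nb_none})


def _check(pred, y):
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary 0/1")
    return pred, y


def net_benefit(pred, y, t: float) -> float:
    """Net benefit of treating patients with predicted risk >= t."""
    if not 0.0 < t < 1.0:
        raise ValueError("threshold must be strictly inside (0, 1)")
    pred, y = _check(pred, y)
    n = len(y)
    treat = pred >= t
    tp = float(np.sum(treat & (y == 1)))
    fp = float(np.sum(treat & (y == 0)))
    return tp / n - (fp / n) * t / (1.0 - t)


def decision_curve(pred, y, grid=None) -> DecisionCurve:
    """Net benefit of the model vs treat-all and treat-none over a grid."""
    pred, y = _check(pred, y)
    grid = np.asarray(default_grid() if grid is None else grid, dtype=float)
    if grid.size == 0 or ((grid <= 0) | (grid >= 1)).any():
        raise ValueError("grid must be nonempty and inside (0, 1)")
    if not (np.diff(grid) > 0).all():
        raise ValueError("grid must be strictly increasing")
    pi = y.mean()
    nb_model = np.array([net_benefit(pred, y, t) for t in grid])
    nb_all = pi - (1.0 - pi) * grid / (1.0 - grid)
    nb_none = np.zeros_like(grid)
    positive = nb_model > np.maximum(nb_all, 0.0)
    if positive.any():
        rng = (float(grid[positive][0]), float(grid[positive][-1]))
    else:
        rng = None
    return DecisionCurve(grid, nb_model, nb_all, nb_none, rng)
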