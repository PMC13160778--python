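"""Wide-table export of model coefficients and validation metrics.

Reproduces the familiar published layout: one column per model, with a
"Model parameters" block (coefficients, 4 decimals), a "Model performance"
block (LL/AIC/BIC/AUC/Brier, 3 decimals) and a "Calibration" block
(CITL/slope/Hosmer-Lemeshow). Rounding is fixed so re-exports are
byte-identical and diffs against printed tables are meaningful.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .metrics import ValidationReport
from .models import LogisticRiskModel

__all__ = ["table_export", "write_table"]

_METRIC_ROWS = (
    ("log_likelihood", "LL"),
    ("aic", "AIC"),
    ("bic", "BIC"),
    ("auc", "AUC"),
    ("brier", "Brier"),
    ("nagelkerke_r2", "Nagelkerke R2"),
)
_CAL_ROWS = (
    ("citl", "CITL"),
    ("calibration_slope", "Calibration slope"),
    ("hl_chi2", "Hosmer-Lemeshow chi2"),
    ("hl_p", "Hosmer-Lemeshow p"),
)


def table_export(results: dict[str, tuple[LogisticRiskModel, ValidationReport]]
                 ) -> pd.DataFrame:
    """Wide comparison table over ``{column name: (model, report)}``.

    Column order follows insertion order (pass a registry-ordered dict);
    coefficients are rounded to 4 decimals, metrics to 3.
    """
    if not results:
        raise ValueError("need at least one (model, report) pair")
    term_order: list[str] = []
    for model, _ in results.values():
        for t in model.term_names:
            if t not in term_order:
                term_order.append(t)
    rows: list[dict] = []

    def block(title):
        rows.append({"section": title, "row": title,
                     **{name: "" for name in results}})

    block("Model parameters")
    coef_rows = [("intercept", "Intercept")] + [(t, t) for t in term_order]
    for key, label in coef_rows:
        row = {"section": "Model parameters", "row": label}
        for name, (model, _) in results.items():
            if key == "intercept":
                row[name] = round(model.intercept, 4)
            else:
                row[name] = round(model.terms[key], 4) if key in model.terms else "-"
        rows.append(row)
    block("Model performance")
    for attr, label in _METRIC_ROWS:
        rows.append({"section": "Model performance", "row": label,
                     **{name: round(float(getattr(rep, attr)), 3)
                        for name, (_, rep) in results.items()}})
    block("Calibration")
    for attr, label in _CAL_ROWS:
        rows.append({"section": "Calibration", "row": label,
                     **{name: round(float(getattr(rep, attr)), 3)
                        for name, (_, rep) in results.items()}})
    return pd.DataFrame(rows)


def write_table(results, csv_path, json_path=None) -> pd.DataFrame:
    """Export the wide table as CSV (and optionally the raw panel as JSON)."""
    table = table_export(results)
    table.to_csv(csv_path, index=False)
    if json_path is not None:
        doc = {name: rep.to_dict() for name, (_, rep) in results.items()}
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, default=_jsonable)
            fh.write("\n")
    return table


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
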