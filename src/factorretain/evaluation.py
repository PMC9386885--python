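"""Summaries of trial records: accuracy/bias tables and the saturated-
regression verification.

The primary outputs are per-cell summaries — the proportion of
replications in which a criterion retained exactly the true number of
factors (accuracy) and the mean of (retained - true) (bias) — laid out as
one table pair per analysis arm with a row per (communality, interfactor
correlation, N) and a column per criterion.

The saturated-regression check fits a logistic model on the correctness
dummy and a linear model on the bias with full interactions of all design
factors, and verifies that the fitted values reproduce the empirical cell
means — i.e. that the regression framing adds nothing beyond cell
summaries.  Logistic cells with an empirical proportion of exactly 0 or 1
are separated; they are reported and excluded from the tolerance check.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .model import CRITERIA

__all__ = ["summarize_cells", "saturated_fit_check", "export_tables",
           "TABLE_NAMES"]

CELL_KEYS = ["communality", "theta", "N", "arm", "criterion"]

#: arm -> exported table stem (panel A = accuracy, panel B = bias)
TABLE_NAMES = {
    "cont_pearson": "table4",
    "d50_pearson": "table5",
    "d50_tetra": "table6",
    "d75_pearson": "table7",
    "d75_tetra": "table8",
}

_ROW_ORDER = ["communality", "theta", "N"]


def _ok(records: pd.DataFrame) -> pd.DataFrame:
    return records[records["status"] == "ok"]


def summarize_cells(records: pd.DataFrame) -> dict[str, dict[str, pd.DataFrame]]:
    """Per-arm accuracy and mean-bias tables.

    Returns ``{arm: {"accuracy": frame, "bias": frame}}`` with rows indexed
    by (communality, theta, N) and one column per criterion.  Missing-status
    rows are excluded from the denominators; a cell with no usable
    replication is flagged with NaN rather than silently zero.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    ok = _ok(records)
    grouped = ok.groupby(CELL_KEYS, sort=False).agg(
        accuracy=("correct", "mean"), bias=("bias", "mean"))
    out: dict[str, dict[str, pd.DataFrame]] = {}
    crit_order = [c for c in CRITERIA if c in records["criterion"].unique()]
    for arm in records["arm"].unique():
        sub = grouped.xs(arm, level="arm")
        panels = {}
        for panel in ("accuracy", "bias"):
            wide = sub[panel].unstack("criterion")
            wide = wide.reindex(columns=crit_order)
            wide = wide.sort_index(
                level=["communality", "theta", "N"],
                ascending=[True, True, True],
                key=lambda idx: idx.map(
                    {"low": 0, "high": 1}.get) if idx.name == "communality" else idx,
            )
            panels[panel] = wide
        out[arm] = panels
    return out


def saturated_fit_check(records: pd.DataFrame, tol_linear: float = 1e-8,
                        tol_logistic: float = 1e-6) -> dict:
    """Verify that saturated regressions reproduce the cell means.

    Fits OLS on bias and a binomial GLM on the correctness proportion with
    the full factorial interaction of criterion, N, theta, communality and
    arm, then compares per-cell fitted values with empirical means.
    """
    ok = _ok(records).copy()
    if ok.empty:
        raise ValueError("no usable records")
    counts = ok.groupby(CELL_KEYS).size()
    if (counts < 2).any():
        thin = counts[counts < 2].index.tolist()
        raise ValueError(f"cells with fewer than 2 observations: {thin[:5]}")

    factors = [f"C({k})" for k in CELL_KEYS]
    formula_rhs = "*".join(factors)

    # linear model on bias: saturated fit == cell means exactly
    ols = smf.ols(f"bias ~ {formula_rhs}", data=ok).fit()
    ok["_pred_bias"] = ols.predict(ok)
    cell = ok.groupby(CELL_KEYS).agg(
        mean_bias=("bias", "mean"), pred_bias=("_pred_bias", "mean"),
        prop=("correct", "mean"), n=("correct", "size"))
    linear_dev = float(np.max(np.abs(cell["mean_bias"] - cell["pred_bias"])))

    # logistic model on the correctness dummy, fitted on aggregated counts
    agg = cell.reset_index()
    agg["successes"] = agg["prop"] * agg["n"]
    agg["failures"] = agg["n"] - agg["successes"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = smf.glm(f"successes + failures ~ {formula_rhs}", data=agg,
                      family=sm.families.Binomial()).fit(maxiter=200)
        agg["pred_prop"] = glm.predict(agg)
    interior = (agg["prop"] > 0.0) & (agg["prop"] < 1.0)
    separated = agg.loc[~interior, CELL_KEYS + ["prop"]]
    logit_dev = (float(np.max(np.abs(agg.loc[interior, "prop"]
                                     - agg.loc[interior, "pred_prop"])))
                 if interior.any() else 0.0)

    return {
        "linear_max_dev": linear_dev,
        "linear_ok": linear_dev <= tol_linear,
        "logistic_max_dev_interior": logit_dev,
        "logistic_ok": logit_dev <= tol_logistic,
        "n_separated_cells": int((~interior).sum()),
        "separated_cells": separated,
        "n_cells": int(len(agg)),
    }


def export_tables(summary: dict, path) -> list[Path]:
    """Write one CSV per arm per panel (rounded to 2 decimals) plus an
    unrounded ``*_raw.csv`` copy; returns the rounded file paths."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for arm, panels in summary.items():
        stem = TABLE_NAMES.get(arm, arm)
        for panel_key, suffix in (("accuracy", "A"), ("bias", "B")):
            frame = panels[panel_key]
            raw = out / f"{stem}{suffix}_raw.csv"
            frame.to_csv(raw)
            rounded = out / f"{stem}{suffix}.csv"
            frame.round(2).to_csv(rounded, float_format="%.2f")
            written.append(rounded)
    return written
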