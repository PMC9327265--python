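"""Tree-table I/O, schema validation and the bivariate screening report."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .index import HARVEST_GRID, PROTECTION_GRID

#: Required columns of a field tree table and a per-column validator tag.
TREE_TABLE_COLUMNS: dict[str, str] = {
    "lon": "numeric",
    "lat": "numeric",
    "tree_age": "nonnegative",
    "dbh": "nonnegative",
    "ground_diameter": "nonnegative",
    "tree_height": "nonnegative",
    "crown_width": "nonnegative",
    "height_under_branch": "nonnegative",
    "growth_vigor": "vigor_grid",
    "harvest_intensity": "harvest_grid",
    "protection": "protection_grid",
    "output_kg": "nonnegative",
    "unit_price_rmb_per_kg": "nonnegative",
    "total_value_rmb": "nonnegative",
}

VIGOR_GRID = (1.0, 2.0, 3.0)
#: Relative tolerance for total_value == output * unit_price (absorbs price rounding)
VALUE_TOLERANCE = 0.01


class SchemaError(ValueError):
    """A tree table that cannot be validated at all (missing columns, empty)."""


def read_tree_table(path: str, required: list[str] | None = None,
                    ) -> tuple[pd.DataFrame, dict]:
    """Read and validate a tree-attribute CSV.

    Checks the required columns exist, ordinal scores sit on their field
    grids (growth vigor {1,2,3}, harvest {0,0.5,1}, protection
    {0,0.1,0.5,1}), measurements are nonnegative, and the total value
    equals output times unit price within 1% relative tolerance.  Rows
    violating a check are flagged, not dropped; the validation report
    counts them per rule.

    Returns ``(table, report)``; the table gains a boolean ``flagged``
    column.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return validate_tree_table(df, required)


def validate_tree_table(df: pd.DataFrame, required: list[str] | None = None,
                        ) -> tuple[pd.DataFrame, dict]:
    cols = list(TREE_TABLE_COLUMNS) if required is None else required
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = df.copy()
    flagged = np.zeros(len(df), dtype=bool)
    report: dict[str, int] = {}

    def flag(mask: np.ndarray, rule: str) -> None:
        nonlocal flagged
        n = int(np.sum(mask))
        if n:
            report[rule] = report.get(rule, 0) + n
            flagged |= np.asarray(mask, dtype=bool)

    grids = {"vigor_grid": VIGOR_GRID, "harvest_grid": HARVEST_GRID,
             "protection_grid": PROTECTION_GRID}
    for col in cols:
        kind = TREE_TABLE_COLUMNS.get(col, "numeric")
        vals = pd.to_numeric(df[col], errors="coerce")
        flag(vals.isna().to_numpy() & df[col].notna().to_numpy(),
             f"{col}: non-numeric")
        if kind == "nonnegative":
            flag((vals < 0).to_numpy(), f"{col}: negative")
        elif kind in grids:
            ok = np.isin(np.round(vals.to_numpy(dtype=float), 6), grids[kind])
            flag(~ok & vals.notna().to_numpy(), f"{col}: off-grid")
    if {"output_kg", "unit_price_rmb_per_kg", "total_value_rmb"}.issubset(cols):
        expect = df["output_kg"] * df["unit_price_rmb_per_kg"]
        denom = np.maximum(np.abs(expect.to_numpy(dtype=float)), 1e-9)
        rel = np.abs(df["total_value_rmb"].to_numpy(dtype=float)
                     - expect.to_numpy(dtype=float)) / denom
        flag(rel > VALUE_TOLERANCE, "total_value: inconsistent with output*price")
    df["flagged"] = flagged
    summary = {"n_rows": len(df), "n_flagged": int(flagged.sum()),
               "violations": report}
    return df, summary


def bivariate_report(table: pd.DataFrame, response: str = "total_value_rmb",
                     predictors: list[str] | None = None) -> pd.DataFrame:
    """OLS line and R^2 of the response against each predictor, untransformed.

    Returns one row per predictor with slope, intercept, r2 and n; a
    constant predictor reports NaN for all statistics.
    """
    if response not in table.columns:
        raise ValueError(f"response column {response!r} missing")
    if predictors is None:
        predictors = [c for c in table.columns
                      if c != response and c not in ("lon", "lat", "flagged")
                      and np.issubdtype(table[c].dtype, np.number)]
    rows = []
    for pred in predictors:
        pair = table[[pred, response]].dropna()
        if len(pair) < 3:
            raise ValueError(f"fewer than 3 complete rows for {pred!r}")
        x = pair[pred].to_numpy(dtype=float)
        yv = pair[response].to_numpy(dtype=float)
        if np.std(x) <= 1e-12:
            rows.append({"predictor": pred, "slope": np.nan,
                         "intercept": np.nan, "r2": np.nan, "n": len(pair)})
            continue
        res = stats.linregress(x, yv)
        rows.append({"predictor": pred, "slope": res.slope,
                     "intercept": res.intercept, "r2": res.rvalue ** 2,
                     "n": len(pair)})
    return pd.DataFrame(rows)
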