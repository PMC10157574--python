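"""Descriptive and comparative analyses of a fitted DW set.

Covers the distribution binning of the estimated disability weights,
the proportional difference against an external reference DW table,
the simultaneous eleven-symptom-category linear regression explaining
those differences, and the Pearson correlation between surveys.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .catalog import FLAG_COLUMNS, SYMPTOM_CATEGORIES, HealthState

__all__ = [
    "ReportingError",
    "bin_distribution",
    "proportional_difference",
    "build_comparison",
    "symptom_regression",
    "pearson_correlation",
]


class ReportingError(ValueError):
    """Raised for invalid inputs to the reporting operations."""


def bin_distribution(
    dws, bin_width: float = 0.1, denominator: int | None = None
) -> pd.DataFrame:
    """Bin DW values into half-open intervals [0, w), [w, 2w), ...

    Lower edges are inclusive; the top bin includes 1.0 exactly.  NaN
    entries (states with no estimable DW) are excluded from the counts.
    Percentages are computed against ``denominator`` when given —
    conventionally the full catalog size, even if some states carry no
    value — otherwise against the number of binned values.

    Returns a DataFrame with columns ``bin_low, bin_high, count, pct``.
    """
    vals = np.asarray(pd.Series(dws).dropna(), dtype=float)
    if len(vals) and (vals.min() < 0 or vals.max() > 1):
        raise ReportingError("DW values outside [0, 1]")
    n_bins = int(np.ceil(1.0 / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    edges[-1] = max(edges[-1], 1.0)
    idx = np.minimum((vals // bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins) if len(vals) else np.zeros(n_bins, int)
    denom = denominator if denominator is not None else max(len(vals), 1)
    return pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "count": counts,
            "pct": 100.0 * counts / denom,
        }
    )


def proportional_difference(local_dw: float, reference_dw: float) -> float:
    """Percent difference of a local DW against a reference DW:
    ``100 * (local - reference) / reference``.  Undefined for a zero
    reference."""
    if reference_dw == 0:
        raise ReportingError("proportional difference undefined for reference DW 0")
    return 100.0 * (local_dw - reference_dw) / reference_dw


def build_comparison(
    local_dws: dict[int, float],
    reference_dws: dict[int, float],
    catalog: list[HealthState],
) -> pd.DataFrame:
    """Per-state comparison rows over the intersection of both DW sets.

    Rows with a zero reference DW are excluded with a warning.  Columns:
    ``state_id, local_dw, reference_dw, d`` plus the eleven flag columns.
    """
    flags = {s.state_id: s.symptom_flags for s in catalog}
    rows, skipped = [], []
    for sid in sorted(set(local_dws) & set(reference_dws) & set(flags)):
        ref = reference_dws[sid]
        if ref == 0:
            skipped.append(sid)
            continue
        row = {
            "state_id": sid,
            "local_dw": local_dws[sid],
            "reference_dw": ref,
            "d": proportional_difference(local_dws[sid], ref),
        }
        row.update({c: int(f) for c, f in zip(FLAG_COLUMNS, flags[sid])})
        rows.append(row)
    if skipped:
        warnings.warn(
            f"excluded {len(skipped)} state(s) with reference DW 0: {skipped}",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def symptom_regression(comparison_rows: pd.DataFrame) -> pd.DataFrame:
    """OLS of the proportional difference on the eleven symptom flags.

    All eleven categories enter simultaneously alongside an intercept.
    Returns one row per term with the coefficient, its t-based 95%
    confidence interval and two-sided p-value.  A rank-deficient design
    (e.g. a category present in every row, confounded with the
    intercept) is an error naming the offending categories.
    """
    missing = [c for c in FLAG_COLUMNS if c not in comparison_rows.columns]
    if missing:
        raise ReportingError(f"comparison rows missing flag column(s): {missing}")
    if len(comparison_rows) < len(FLAG_COLUMNS) + 2:
        raise ReportingError(
            f"need at least {len(FLAG_COLUMNS) + 2} rows to fit the "
            "eleven-category regression"
        )
    X = sm.add_constant(
        comparison_rows[list(FLAG_COLUMNS)].astype(float), has_constant="add"
    )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        constant_cols = [
            c for c in FLAG_COLUMNS if comparison_rows[c].nunique() == 1
        ]
        raise ReportingError(
            "rank-deficient symptom design; collinear or constant "
            f"categories: {constant_cols or 'non-trivial collinearity'}"
        )
    fit = sm.OLS(comparison_rows["d"].astype(float), X).fit()
    ci = fit.conf_int(alpha=0.05)
    out = pd.DataFrame(
        {
            "term": ["intercept"] + list(SYMPTOM_CATEGORIES),
            "coefficient": fit.params.to_numpy(),
            "ci_low": ci[0].to_numpy(),
            "ci_high": ci[1].to_numpy(),
            "p_value": fit.pvalues.to_numpy(),
        }
    )
    return out


def pearson_correlation(local_dws, reference_dws) -> tuple[float, float]:
    """Pearson r (with two-sided t-test p-value) between two DW vectors.

    Accepts aligned sequences, or two state->DW maps whose intersection
    is used.  Needs at least 3 pairs and non-degenerate variances.
    """
    if isinstance(local_dws, dict) and isinstance(reference_dws, dict):
        common = sorted(set(local_dws) & set(reference_dws))
        x = np.array([local_dws[s] for s in common], dtype=float)
        y = np.array([reference_dws[s] for s in common], dtype=float)
    else:
        x = np.asarray(local_dws, dtype=float)
        y = np.asarray(reference_dws, dtype=float)
        if x.shape != y.shape:
            raise ReportingError("mismatched lengths for correlation")
    if len(x) < 3:
        raise ReportingError("need >= 3 paired values for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ReportingError("correlation undefined: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
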