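"""Descriptive summaries for the integrated injury/climate table.

Numeric variables get mean, sample SD, normal-approximation 95% CI, median,
inter-quartile range and bias-corrected sample skewness (G1); categorical
variables get count / percent-of-valid tables with half-up rounding to one
decimal, the convention used in surveillance reports.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

__all__ = [
    "NumericSummary",
    "FrequencyTable",
    "round_half_up",
    "summarize_numeric",
    "summarize_categorical",
    "summary_table",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (2.5 -> 3), unlike banker's rounding."""
    if not np.isfinite(x):
        return float(x)
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class NumericSummary:
    n_valid: int
    mean: float
    sd: float
    ci95_low: float
    ci95_high: float
    median: float
    iqr_low: float
    iqr_high: float
    skewness: float


@dataclass(frozen=True)
class FrequencyTable:
    """Counts and percents (of valid N) per category; missing kept aside."""

    table: pd.DataFrame  # index: category; columns: count, percent
    n_valid: int
    n_missing: int


def summarize_numeric(values, *, ci: str = "normal") -> NumericSummary:
    """Summary statistics of a numeric vector (missing values excluded).

    The CI is ``mean +/- 1.96 * sd / sqrt(n)`` by default (``ci="normal"``);
    ``ci="t"`` substitutes the Student-t quantile.  Quartiles use linear
    interpolation between closest ranks; skewness is the bias-corrected
    sample coefficient G1 (0 for a constant vector).
    """
    x = pd.to_numeric(pd.Series(values), errors="coerce").dropna().to_numpy(float)
    n = x.size
    if n < 2:
        raise ValidationError("need at least 2 non-missing values")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if ci == "normal":
        z = 1.959963984540054
    elif ci == "t":
        z = float(stats.t.ppf(0.975, n - 1))
    else:
        raise ValidationError(f"unknown ci convention {ci!r}")
    half = z * sd / np.sqrt(n)
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
    skew = 0.0 if sd == 0 else float(stats.skew(x, bias=False))
    return NumericSummary(
        n_valid=n,
        mean=mean,
        sd=sd,
        ci95_low=mean - half,
        ci95_high=mean + half,
        median=float(med),
        iqr_low=float(q1),
        iqr_high=float(q3),
        skewness=skew,
    )


def summarize_categorical(values) -> FrequencyTable:
    """Frequency table of a categorical vector.

    Percents are shares of valid (non-missing) N, half-up rounded to one
    decimal; missing values are excluded from N and reported separately.
    """
    s = pd.Series(values)
    if len(s) == 0:
        raise ValidationError("empty input")
    n_missing = int(s.isna().sum())
    valid = s.dropna().astype(str)
    n_valid = len(valid)
    if n_valid == 0:
        raise ValidationError("no valid (non-missing) values")
    counts = valid.value_counts().sort_index()
    pct = [round_half_up(100.0 * c / n_valid, 1) for c in counts]
    table = pd.DataFrame({"count": counts.astype(int), "percent": pct})
    table.index.name = "category"
    return FrequencyTable(table=table, n_valid=n_valid, n_missing=n_missing)


def summary_table(df: pd.DataFrame, numeric: list, categorical: list) -> pd.DataFrame:
    """Long-format summary of a dataset, one row per variable or category."""
    rows = []
    for v in numeric:
        s = summarize_numeric(df[v])
        rows.append(
            {
                "variable": v,
                "category": "",
                "n_valid": s.n_valid,
                "mean": s.mean,
                "sd": s.sd,
                "ci95_low": s.ci95_low,
                "ci95_high": s.ci95_high,
                "median": s.median,
                "iqr_low": s.iqr_low,
                "iqr_high": s.iqr_high,
                "skewness": s.skewness,
                "count": np.nan,
                "percent": np.nan,
            }
        )
    for v in categorical:
        ft = summarize_categorical(df[v])
        for cat, row in ft.table.iterrows():
            rows.append(
                {
                    "variable": v,
                    "category": cat,
                    "n_valid": ft.n_valid,
                    "count": int(row["count"]),
                    "percent": row["percent"],
                }
            )
    return pd.DataFrame(rows)
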