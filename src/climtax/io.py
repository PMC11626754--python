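"""Reading, validation and integration of the climate and injury tables.

Both inputs are plain CSV (UTF-8, header row, ISO-8601 dates).  Validation
is row-level: structurally broken files raise :class:`FormatError`, rows that
violate a field invariant are rejected with a recorded reason, and key
violations (duplicate school-year, duplicate case id) raise
:class:`ValidationError` naming the offending rows.

Integration joins every injury case to its school's climate record for the
injury's calendar year; when that year is missing, the school's most recent
*earlier* record is used (fallback), and cases with no same-or-earlier
record are flagged unmatched and excluded from clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError
from .synthetic import CATEGORY_LEVELS, CLIMATE_COLUMNS, CLIMATE_ITEMS, INJURY_COLUMNS

__all__ = [
    "ValidationReport",
    "IntegrationReport",
    "read_climate",
    "read_injuries",
    "write_climate",
    "write_injuries",
    "integrate",
]

#: categories that absorb unknown tokens when coercion is allowed
_COERCE_TARGET = {
    "event_place": "otherwise",
    "event_term": "otherwise",
    "anatomic_place": "other",
    "injury_cause": "otherwise",
    "injury_type": "otherwise",
}


@dataclass
class ValidationReport:
    n_input: int
    n_valid: int
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "reason"])
    )


def _reject_frame(reasons: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {"row": list(reasons), "reason": list(reasons.values())}
    ).astype({"row": int})


def read_climate(path) -> tuple:
    """Read and validate a climate CSV -> (DataFrame, ValidationReport).

    Row numbers in the report are 0-based data-row indices.  Duplicate
    (school_id, year) pairs among otherwise valid rows raise
    :class:`ValidationError` naming both rows.
    """
    df = pd.read_csv(path, dtype={"school_id": str})
    missing = [c for c in CLIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"climate file missing required column(s): {missing}")
    df = df[CLIMATE_COLUMNS].copy()
    reasons = {}
    year = pd.to_numeric(df["year"], errors="coerce")
    bad = df.index[year.isna() | (year != year.round())]
    for i in bad:
        reasons.setdefault(i, f"year {df.at[i, 'year']!r} is not an integer")
    for item in CLIMATE_ITEMS:
        col = pd.to_numeric(df[item], errors="coerce")
        df[item] = col
        lo, hi = (0.0, np.inf) if item == "violence" else (0.0, 100.0)
        bad = df.index[col.isna() | (col < lo) | (col > hi)]
        for i in bad:
            reasons.setdefault(i, f"{item}={df.at[i, item]!r} outside [{lo}, {hi}]")
    bad = df.index[df["school_id"].isna() | (df["school_id"].astype(str).str.len() == 0)]
    for i in bad:
        reasons.setdefault(i, "missing school_id")
    valid = df.drop(index=list(reasons)).copy()
    valid["year"] = pd.to_numeric(valid["year"]).astype(int)
    dup = valid.duplicated(subset=["school_id", "year"], keep=False)
    if dup.any():
        pairs = valid.loc[dup, ["school_id", "year"]].drop_duplicates()
        rows = valid.index[dup].tolist()
        raise ValidationError(
            f"duplicate (school_id, year) pairs {pairs.to_records(index=False).tolist()} "
            f"in rows {rows}"
        )
    report = ValidationReport(
        n_input=len(df), n_valid=len(valid), rejected=_reject_frame(reasons)
    )
    return valid.reset_index(drop=True), report


def read_injuries(path, coerce_unknown: bool = False) -> tuple:
    """Read and validate an injury CSV -> (DataFrame, ValidationReport).

    Unknown category tokens are rejected unless ``coerce_unknown`` is set, in
    which case descriptor tokens map to "otherwise"/"other" (gender is never
    coerced).  Duplicate case ids raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, dtype={"case_id": str, "school_id": str})
    missing = [c for c in INJURY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"injury file missing required column(s): {missing}")
    df = df[INJURY_COLUMNS].copy()
    reasons = {}

    date = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    for i in df.index[date.isna()]:
        reasons.setdefault(i, f"unparseable date {df.at[i, 'date']!r}")
    df["date"] = date

    hour = pd.to_numeric(df["hour"], errors="coerce")
    bad = df.index[hour.isna() | (hour != hour.round()) | (hour < 0) | (hour > 23)]
    for i in bad:
        reasons.setdefault(i, f"hour {df.at[i, 'hour']!r} outside 0-23")

    age = pd.to_numeric(df["age_group"], errors="coerce")
    bad = df.index[df["age_group"].notna() & age.isna()]
    for i in bad:
        reasons.setdefault(i, f"non-numeric age_group {df.at[i, 'age_group']!r}")
    df["age_group"] = age

    for col in ("n_regular_classes", "n_special_classes"):
        v = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[v.isna() | (v < 0) | (v != v.round())]
        for i in bad:
            reasons.setdefault(i, f"{col} {df.at[i, col]!r} is not a non-negative integer")
    for col in ("avg_students_regular", "avg_students_special"):
        v = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[v.isna() | (v < 0)]
        for i in bad:
            reasons.setdefault(i, f"{col} {df.at[i, col]!r} is not a non-negative number")

    for var, levels in CATEGORY_LEVELS.items():
        tokens = df[var].astype(str)
        unknown = df.index[~tokens.isin(levels)]
        if coerce_unknown and var in _COERCE_TARGET:
            df.loc[unknown, var] = _COERCE_TARGET[var]
        else:
            for i in unknown:
                reasons.setdefault(i, f"unknown {var} token {df.at[i, var]!r}")

    bad = df.index[df["case_id"].isna() | (df["case_id"].astype(str).str.len() == 0)]
    for i in bad:
        reasons.setdefault(i, "missing case_id")

    valid = df.drop(index=list(reasons)).copy()
    dup = valid.duplicated(subset=["case_id"], keep=False)
    if dup.any():
        raise ValidationError(
            f"duplicate case_id values {sorted(valid.loc[dup, 'case_id'].unique())[:5]} "
            f"in rows {valid.index[dup].tolist()}"
        )
    valid["hour"] = pd.to_numeric(valid["hour"]).astype(int)
    report = ValidationReport(
        n_input=len(df), n_valid=len(valid), rejected=_reject_frame(reasons)
    )
    return valid.reset_index(drop=True), report


def write_climate(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_injuries(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if np.issubdtype(out["date"].dtype, np.datetime64):
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


@dataclass
class IntegrationReport:
    n_cases: int
    n_same_year: int
    n_fallback: int
    n_unmatched: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "match_status": ["same_year", "fallback", "unmatched", "total"],
                "n_cases": [self.n_same_year, self.n_fallback, self.n_unmatched, self.n_cases],
            }
        )


def integrate(
    climate: pd.DataFrame, injuries: pd.DataFrame, allow_later_years: bool = False
) -> tuple:
    """Join each injury case to its school-year climate vector.

    Match order: the climate record of the same school and calendar year of
    the injury; otherwise the school's most recent earlier year (fallback);
    otherwise the case is unmatched (excluded from clustering downstream but
    retained here).  With ``allow_later_years`` a lenient third step borrows
    the school's earliest *later* record instead of leaving the case
    unmatched.  Output is sorted by case_id, so integration is
    order-independent.  Returns (integrated DataFrame, IntegrationReport).
    """
    cases = injuries.copy()
    cases["year"] = pd.to_datetime(cases["date"]).dt.year.astype(int)
    clim = climate.copy()
    clim["year"] = clim["year"].astype(int)
    clim_sorted = clim.sort_values("year", kind="mergesort")
    cases_sorted = cases.sort_values("year", kind="mergesort")

    merged = pd.merge_asof(
        cases_sorted,
        clim_sorted.rename(columns={"year": "climate_source_year"}),
        left_on="year",
        right_on="climate_source_year",
        by="school_id",
        direction="backward",
    )
    if allow_later_years:
        unmatched = merged["climate_source_year"].isna()
        if unmatched.any():
            fwd = pd.merge_asof(
                cases_sorted[unmatched.to_numpy()],
                clim_sorted.rename(columns={"year": "climate_source_year"}),
                left_on="year",
                right_on="climate_source_year",
                by="school_id",
                direction="forward",
            )
            merged.loc[unmatched.to_numpy(), fwd.columns] = fwd.to_numpy()

    status = np.where(
        merged["climate_source_year"].isna(),
        "unmatched",
        np.where(merged["climate_source_year"] == merged["year"], "same_year", "fallback"),
    )
    merged["match_status"] = status
    merged = merged.sort_values("case_id", kind="mergesort").reset_index(drop=True)
    report = IntegrationReport(
        n_cases=len(merged),
        n_same_year=int((merged["match_status"] == "same_year").sum()),
        n_fallback=int((merged["match_status"] == "fallback").sum()),
        n_unmatched=int((merged["match_status"] == "unmatched").sum()),
    )
    return merged, report
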