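"""Reading survey tables and deriving the analysis variables.

Derived variables:

* ``age_residual`` — residual of the OLS regression of glycemia on age
  (fitted on the retained complete-case rows).
* ``residual_category`` — ordered Normal / Outlier / Extreme on the absolute
  residual with lower-closed cuts at 40 and 80 mg/dL (Normal: |r| < 40;
  Outlier: 40 <= |r| < 80; Extreme: |r| >= 80).
* ``income_category`` — ordered D < C < B < A on monthly household income with
  lower-closed cuts at 10,000 / 20,000 / 40,000 (A: income >= 40,000;
  D: income < 10,000).
* ``glycemia_level`` — six ordered levels from configurable mg/dL bin edges
  (defaults 70/100/126/160/200: hypoglycemic, normal, prediabetic and three
  increasingly severe hyperglycemic ranges); half-open [edge, next_edge) bins.

All categorizations use lower-closed, upper-open intervals so boundary values
fall in the upper category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, SchemaError

__all__ = [
    "Variable",
    "VariableSchema",
    "default_schema",
    "read_survey",
    "FilterResult",
    "filter_complete",
    "AgeRegression",
    "age_regression",
    "categorize_residuals",
    "categorize_income",
    "categorize_glycemia",
    "coefficient_of_variation",
    "cv_by_group",
    "DerivedTable",
    "build_derived_table",
    "RESIDUAL_LABELS",
    "INCOME_LABELS",
]

RESIDUAL_LABELS = ("Normal", "Outlier", "Extreme")
INCOME_LABELS = ("D", "C", "B", "A")  # ordered low -> high


@dataclass(frozen=True)
class Variable:
    name: str
    role: str = "explanatory"          # response | explanatory
    scale: str = "continuous"          # continuous | ordinal | nominal
    levels: tuple | None = None        # ordered labels for categorical scales
    units: str = ""

    def validate(self) -> None:
        if self.role not in ("response", "explanatory"):
            raise SchemaError(f"variable {self.name!r}: unknown role {self.role!r}")
        if self.scale not in ("continuous", "ordinal", "nominal"):
            raise SchemaError(f"variable {self.name!r}: unknown scale {self.scale!r}")
        if self.levels is not None and len(set(self.levels)) != len(self.levels):
            raise SchemaError(f"variable {self.name!r}: duplicate level labels")
        if self.scale in ("ordinal", "nominal") and self.levels is None:
            raise SchemaError(f"variable {self.name!r}: categorical scale needs levels")


@dataclass(frozen=True)
class VariableSchema:
    variables: tuple[Variable, ...]

    def __post_init__(self) -> None:
        responses = [v for v in self.variables if v.role == "response"]
        if len(responses) != 1:
            raise SchemaError("schema must declare exactly one response variable")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("schema contains duplicate variable names")
        for v in self.variables:
            v.validate()

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def response(self) -> Variable:
        return next(v for v in self.variables if v.role == "response")

    @property
    def explanatory(self) -> list[Variable]:
        return [v for v in self.variables if v.role == "explanatory"]

    def __getitem__(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)


def default_schema() -> VariableSchema:
    """Schema matching the synthetic generator's default survey table."""
    return VariableSchema((
        Variable("glycemia", role="response", units="mg/dL"),
        Variable("age", units="years"),
        Variable("sex", scale="nominal", levels=(1, 2)),
        Variable("edu_interviewee", scale="ordinal", levels=(1, 2, 3)),
        Variable("edu_head", scale="ordinal", levels=(1, 2, 3)),
        Variable("income", units="currency/month"),
        Variable("working_hours", scale="ordinal", levels=(1, 2, 3, 4)),
        Variable("density", units="inhabitants/room"),
        Variable("utilities", units="index 0-1"),
        Variable("physical_activity", scale="ordinal", levels=(1, 2, 3)),
        Variable("sedentarism", units="min/day"),
        Variable("fruit_veg", units="portions/day"),
        Variable("salt", scale="ordinal", levels=(1, 2, 3, 4)),
        Variable("alcohol", scale="ordinal", levels=(1, 2, 3)),
    ))


def read_survey(path, schema: VariableSchema) -> pd.DataFrame:
    """Read a delimited respondent table (separator inferred from extension).

    Columns are matched by name (order-free); numeric and categorical cells
    that fail to parse (or categorical codes outside the declared levels)
    become missing.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    try:
        raw = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise InputError(f"input file is empty: {path}") from None
    missing = [n for n in schema.names if n not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    out = pd.DataFrame(index=raw.index)
    for var in schema.variables:
        col = pd.to_numeric(raw[var.name], errors="coerce")
        if var.levels is not None:
            col = col.where(col.isin(var.levels))
        out[var.name] = col
    return out


@dataclass(frozen=True)
class FilterResult:
    table: pd.DataFrame
    n_retained: int
    n_dropped: int


def filter_complete(table: pd.DataFrame, required: Sequence[str]) -> FilterResult:
    """Keep rows fully observed on the required variables (complete cases)."""
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(f"required variable(s) not in table: {', '.join(missing)}")
    keep = table[list(required)].notna().all(axis=1)
    out = table.loc[keep].reset_index(drop=True)
    if out.empty:
        import warnings

        warnings.warn("filter_complete: no complete records remain", stacklevel=2)
    return FilterResult(out, int(keep.sum()), int((~keep).sum()))


@dataclass(frozen=True)
class AgeRegression:
    intercept: float   # mg/dL
    slope: float       # mg/dL per year
    residuals: np.ndarray


def age_regression(glycemia, age) -> AgeRegression:
    """OLS fit of glycemia on age; residuals are observed minus fitted."""
    g = np.asarray(glycemia, dtype=float)
    a = np.asarray(age, dtype=float)
    ok = np.isfinite(g) & np.isfinite(a)
    if ok.sum() < 3:
        raise InputError("age_regression: need >= 3 complete (glycemia, age) pairs")
    if not ok.all():
        raise InputError("age_regression: missing values present; filter first")
    if np.ptp(a) == 0:
        raise InputError("age_regression: age is constant (degenerate design)")
    slope, intercept = np.polyfit(a, g, 1)
    residuals = g - (intercept + slope * a)
    return AgeRegression(float(intercept), float(slope), residuals)


def categorize_residuals(r, cut_outlier: float = 40.0, cut_extreme: float = 80.0) -> pd.Categorical:
    """Normal / Outlier / Extreme on |r| with lower-closed cuts."""
    if not (0 < cut_outlier < cut_extreme):
        raise ConfigError("cut_outlier: need 0 < cut_outlier < cut_extreme")
    a = np.abs(np.asarray(r, dtype=float))
    codes = np.searchsorted((cut_outlier, cut_extreme), a, side="right")
    codes = np.where(np.isfinite(a), codes, -1)
    return pd.Categorical.from_codes(codes, categories=list(RESIDUAL_LABELS), ordered=True)


def categorize_income(income, cuts: Sequence[float] = (10_000.0, 20_000.0, 40_000.0)) -> pd.Categorical:
    """D/C/B/A income bands, boundary values to the upper band (>= semantics)."""
    cuts = tuple(float(c) for c in cuts)
    if len(cuts) != 3 or not (0 < cuts[0] < cuts[1] < cuts[2]):
        raise ConfigError("cuts: need three strictly increasing positive cutoffs")
    x = np.asarray(income, dtype=float)
    if np.nanmin(x, initial=0.0) < 0:
        raise InputError("income: negative values present")
    codes = np.searchsorted(cuts, x, side="right")
    codes = np.where(np.isfinite(x), codes, -1)
    return pd.Categorical.from_codes(codes, categories=list(INCOME_LABELS), ordered=True)


def categorize_glycemia(glycemia, bin_edges: Sequence[float] = (70.0, 100.0, 126.0, 160.0, 200.0)):
    """Glycemia levels 1..6 from half-open [edge, next) mg/dL bins.

    Level 1 below the first edge, level 6 at/above the last.  Returns a
    nullable integer array (missing glycemia stays missing).
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size != 5 or np.any(np.diff(edges) <= 0) or edges[0] <= 0:
        raise ConfigError("bin_edges: need 5 strictly increasing positive edges")
    x = np.asarray(glycemia, dtype=float)
    levels = np.searchsorted(edges, np.nan_to_num(x), side="right") + 1
    out = pd.array(levels, dtype="Int64")
    out[~np.isfinite(x)] = pd.NA
    return out


def coefficient_of_variation(values) -> float:
    """CV = s / x-bar with the n-1 sample standard deviation."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise InputError("coefficient_of_variation: need >= 2 values")
    m = x.mean()
    if m == 0:
        raise InputError("coefficient_of_variation: mean is zero")
    return float(x.std(ddof=1) / m)


def cv_by_group(table: pd.DataFrame, group_cols: Sequence[str], value_col: str = "glycemia") -> pd.DataFrame:
    """Per-cell CV of a value column over a grouping; singleton cells get a
    missing CV but keep their reported n."""
    for c in (*group_cols, value_col):
        if c not in table.columns:
            raise SchemaError(f"cv_by_group: column {c!r} not in table")
    rows = []
    grouped = table.groupby(list(group_cols), observed=True, dropna=True)
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        vals = sub[value_col].dropna().to_numpy(dtype=float)
        n = vals.size
        mean = vals.mean() if n else np.nan
        sd = vals.std(ddof=1) if n >= 2 else np.nan
        cv = sd / mean if n >= 2 and mean != 0 else np.nan
        rows.append({**dict(zip(group_cols, key)), "n": n, "mean": mean, "sd": sd, "cv": cv})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DerivedTable:
    """Complete-case table with derived columns, plus the rules that made it."""

    table: pd.DataFrame
    regression: AgeRegression
    n_input: int
    n_retained: int
    residual_cuts: tuple[float, float]
    income_cuts: tuple[float, float, float]
    glycemia_edges: tuple[float, ...]


def build_derived_table(
    table: pd.DataFrame,
    schema: VariableSchema | None = None,
    *,
    required: Sequence[str] | None = None,
    residual_cuts: tuple[float, float] = (40.0, 80.0),
    income_cuts: Sequence[float] = (10_000.0, 20_000.0, 40_000.0),
    glycemia_edges: Sequence[float] = (70.0, 100.0, 126.0, 160.0, 200.0),
    income_col: str = "income",
) -> DerivedTable:
    """Filter to complete cases and append all derived analysis variables.

    Completeness is required on the response plus all explanatory variables
    (the full schema) unless ``required`` overrides it; the age regression is
    fitted on the retained rows only.
    """
    if schema is None:
        schema = default_schema()
    if required is None:
        required = schema.names
    filt = filter_complete(table, required)
    out = filt.table.copy()
    reg = age_regression(out["glycemia"], out["age"])
    out["age_residual"] = reg.residuals
    out["residual_category"] = categorize_residuals(reg.residuals, *residual_cuts)
    out["income_category"] = categorize_income(out[income_col], income_cuts)
    out["glycemia_level"] = categorize_glycemia(out["glycemia"], glycemia_edges)
    return DerivedTable(
        table=out,
        regression=reg,
        n_input=len(table),
        n_retained=filt.n_retained,
        residual_cuts=tuple(residual_cuts),
        income_cuts=tuple(float(c) for c in income_cuts),
        glycemia_edges=tuple(float(e) for e in glycemia_edges),
    )
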