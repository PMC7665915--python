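"""Descriptive user/nonuser cohort comparison.

Grouped counts, percentages (half-up rounding to one decimal, matching the
convention of published claims-database tables), and Pearson chi-square tests
of level x group contingency tables.

Two entry points exist for each summary: a row-level API operating on a
patient-level table (one row per patient) and a counts-level API operating on
grouped counts, so that published grouped tables can be re-verified exactly
without patient-level data.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import reference

__all__ = [
    "ChiSquareResult",
    "percent",
    "summarize_by_group",
    "summary_from_counts",
    "compare_groups",
    "chi_square",
    "pooled_share",
    "pooled_share_from_counts",
]

GROUP_COL = "chm_user"


def percent(count: int | float, total: int | float) -> float:
    """100*count/total, rounded half-up to one decimal.

    Computed with exact decimal arithmetic so that e.g. 4,178/33,507 rounds
    to 12.5 (12.4689... >= 12.45) regardless of binary float representation.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    count, total = (int(x) if float(x).is_integer() else float(x) for x in (count, total))
    frac = Decimal(100) * Decimal(count) / Decimal(total)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def chi_square(table: np.ndarray, correction: bool = False) -> ChiSquareResult:
    """Pearson chi-square on a level x group contingency table.

    No continuity correction by default (the published multi-level tables are
    consistent with the uncorrected statistic); Yates correction is available
    for 2x2 tables via ``correction=True``.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    expected = stats.contingency.expected_freq(table)
    if np.any(expected == 0):
        raise ValueError("degenerate table: an expected cell count is zero")
    stat, p, df, _ = stats.chi2_contingency(table, correction=correction)
    return ChiSquareResult(statistic=float(stat), df=int(df), p_value=float(p))


def _level_order(var: str, levels: Iterable) -> list:
    declared = reference.COHORT_COUNTS.get(var)
    if declared is not None and all(l in declared for l in levels):
        order = [l for l in declared if l in set(levels)]
        return order
    return sorted(levels, key=str)


def _flag_variable(series: pd.Series) -> bool:
    return series.dropna().isin([True, False, 0, 1]).all() and series.dtype != object


def summarize_by_group(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    group_col: str = GROUP_COL,
    flag_variables: Iterable[str] = reference.FLAG_VARIABLES,
) -> pd.DataFrame:
    """Per-level counts/percentages for users vs nonusers, plus chi-square p.

    Exhaustive categoricals contribute one row per level; flag variables
    contribute a single "yes" row (share of the group with the flag set).
    Denominators are always the group sizes.
    """
    unknown = [v for v in variables if v not in cohort.columns]
    if unknown:
        raise KeyError(
            f"unknown variable(s) {unknown}; valid names: {sorted(set(cohort.columns) - {group_col})}"
        )
    if group_col not in cohort.columns:
        raise KeyError(f"missing group column {group_col!r}")

    users = cohort[cohort[group_col].astype(bool)]
    nonusers = cohort[~cohort[group_col].astype(bool)]
    n_u, n_n = len(users), len(nonusers)
    flag_variables = set(flag_variables)

    rows = []
    for var in variables:
        if var in flag_variables or _flag_variable(cohort[var]):
            cu = int(users[var].astype(bool).sum())
            cn = int(nonusers[var].astype(bool).sum())
            table = np.array([[cu, n_u - cu], [cn, n_n - cn]]).T
            p = chi_square(table).p_value
            rows.append((var, "yes", cu, percent(cu, n_u), cn, percent(cn, n_n), p))
        else:
            levels = _level_order(var, cohort[var].unique())
            cu = users[var].value_counts()
            cn = nonusers[var].value_counts()
            table = np.array(
                [[int(cu.get(l, 0)) for l in levels], [int(cn.get(l, 0)) for l in levels]]
            ).T
            p = chi_square(table).p_value
            for lvl in levels:
                u, n = int(cu.get(lvl, 0)), int(cn.get(lvl, 0))
                rows.append((var, str(lvl), u, percent(u, n_u), n, percent(n, n_n), p))
    return pd.DataFrame(
        rows,
        columns=["variable", "level", "users_n", "users_pct", "nonusers_n", "nonusers_pct", "p"],
    )


def summary_from_counts(
    counts: Mapping[str, Mapping[str, tuple[int, int]]] | None = None,
    n_users: int | None = None,
    n_nonusers: int | None = None,
    flag_variables: Iterable[str] = reference.FLAG_VARIABLES,
) -> pd.DataFrame:
    """Summary table computed from grouped counts (no patient-level rows).

    Defaults to the published 2010 allergic-rhinitis cohort counts.  Group
    sizes are explicit denominators: published grouped tables occasionally
    carry small internal inconsistencies (a count column summing one off the
    group size), and percentages are defined against the stated group size.
    """
    counts = reference.COHORT_COUNTS if counts is None else counts
    n_users = reference.N_USERS if n_users is None else n_users
    n_nonusers = reference.N_NONUSERS if n_nonusers is None else n_nonusers
    flag_variables = set(flag_variables)

    rows = []
    for var, levels in counts.items():
        if var in flag_variables:
            (cu, cn) = next(iter(levels.values()))
            table = np.array([[cu, n_users - cu], [cn, n_nonusers - cn]]).T
        else:
            table = np.array([[u for (u, _) in levels.values()], [n for (_, n) in levels.values()]]).T
        p = chi_square(table).p_value
        for lvl, (u, n) in levels.items():
            rows.append((var, lvl, u, percent(u, n_users), n, percent(n, n_nonusers), p))
    return pd.DataFrame(
        rows,
        columns=["variable", "level", "users_n", "users_pct", "nonusers_n", "nonusers_pct", "p"],
    )


def compare_groups(
    cohort: pd.DataFrame,
    variable: str,
    group_col: str = GROUP_COL,
    correction: bool = False,
) -> ChiSquareResult:
    """Chi-square test of independence between ``variable`` and the group."""
    if variable not in cohort.columns:
        raise KeyError(
            f"unknown variable {variable!r}; valid names: {sorted(set(cohort.columns) - {group_col})}"
        )
    table = pd.crosstab(cohort[variable], cohort[group_col].astype(bool))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(f"variable {variable!r} needs >=2 levels with nonzero totals in both groups")
    return chi_square(table.to_numpy(), correction=correction)


def pooled_share(cohort: pd.DataFrame, predicate: Callable[[pd.DataFrame], pd.Series]) -> float:
    """Percent of all rows satisfying ``predicate`` (a vectorised row mask)."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    mask = predicate(cohort)
    return percent(int(np.asarray(mask, dtype=bool).sum()), len(cohort))


def pooled_share_from_counts(count: int, total: int) -> float:
    """Percent from grouped counts; identical rounding to the row-level API."""
    return percent(count, total)
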