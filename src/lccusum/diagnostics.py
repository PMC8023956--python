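"""Cohort-level diagnostic accuracy of a program pass/fail verdict.

Treats the program verdict as a binary test for a binary outcome (e.g.
still in the specialty at follow-up) and summarises the 2x2 table:

* predictive values and sensitivity/specificity with 95% confidence
  intervals (Wilson score by default; Clopper–Pearson and Wald
  available) — point estimates use exact rational arithmetic before
  floating;
* Fisher's exact test (two-sided, probability-mass ordering) and the
  Pearson chi-square test (Yates correction togglable, off by default);
* descriptive per-group summaries: mean with a t-based 95% CI, or
  median with range, per variable.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ContingencyTable",
    "DiagnosticSummary",
    "UndefinedMeasureError",
    "diagnostic_measures",
    "fisher_exact",
    "chi_square",
    "group_summary",
    "contingency_from_cohort",
]


class UndefinedMeasureError(ValueError):
    """A diagnostic measure has a zero denominator."""

    def __init__(self, measure: str) -> None:
        super().__init__(f"{measure} is undefined: its denominator is zero")
        self.measure = measure


@dataclass(frozen=True)
class ContingencyTable:
    """Pass/fail x stayed/left counts.

    Rows are the test (program passed / failed); columns are the outcome
    (stayed in the specialty / left).
    """

    passed_stayed: int
    passed_left: int
    failed_stayed: int
    failed_left: int

    def __post_init__(self) -> None:
        for name in ("passed_stayed", "passed_left", "failed_stayed", "failed_left"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.total == 0:
            raise ValueError("contingency table must have a positive total")

    @property
    def total(self) -> int:
        return self.passed_stayed + self.passed_left + self.failed_stayed + self.failed_left

    def to_array(self) -> np.ndarray:
        return np.array(
            [[self.passed_stayed, self.passed_left], [self.failed_stayed, self.failed_left]]
        )


@dataclass(frozen=True)
class DiagnosticSummary:
    """Point estimates and 95% CIs; ``None`` marks an undefined measure."""

    ppv: Optional[float]
    npv: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv_ci: Optional[tuple[float, float]]
    npv_ci: Optional[tuple[float, float]]
    sensitivity_ci: Optional[tuple[float, float]]
    specificity_ci: Optional[tuple[float, float]]
    ci_method: str = "wilson"


_CI_METHODS = {"wilson": "wilson", "clopper-pearson": "beta", "wald": "normal"}


def _proportion(
    count: int, nobs: int, measure: str, ci_method: str, strict: bool
) -> tuple[Optional[float], Optional[tuple[float, float]]]:
    if nobs == 0:
        if strict:
            raise UndefinedMeasureError(measure)
        return None, None
    point = float(Fraction(count, nobs))
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method=_CI_METHODS[ci_method])
    return point, (float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)))


def diagnostic_measures(
    table: ContingencyTable, ci_method: str = "wilson", strict: bool = True
) -> DiagnosticSummary:
    """PPV, NPV, sensitivity and specificity with 95% CIs.

    With the verdict as test and "stayed" as the condition:
    ``ppv = passed_stayed / passed``, ``npv = failed_left / failed``,
    ``sensitivity = passed_stayed / stayed``,
    ``specificity = failed_left / left``.

    ``strict=True`` raises :class:`UndefinedMeasureError` on a zero
    denominator; ``strict=False`` reports the measure as ``None``.
    """
    if ci_method not in _CI_METHODS:
        raise ValueError(
            f"unknown ci_method {ci_method!r}; expected one of {sorted(_CI_METHODS)}"
        )
    t = table
    ppv, ppv_ci = _proportion(
        t.passed_stayed, t.passed_stayed + t.passed_left, "ppv", ci_method, strict
    )
    npv, npv_ci = _proportion(
        t.failed_left, t.failed_stayed + t.failed_left, "npv", ci_method, strict
    )
    sens, sens_ci = _proportion(
        t.passed_stayed, t.passed_stayed + t.failed_stayed, "sensitivity", ci_method, strict
    )
    spec, spec_ci = _proportion(
        t.failed_left, t.passed_left + t.failed_left, "specificity", ci_method, strict
    )
    return DiagnosticSummary(
        ppv=ppv,
        npv=npv,
        sensitivity=sens,
        specificity=spec,
        ppv_ci=ppv_ci,
        npv_ci=npv_ci,
        sensitivity_ci=sens_ci,
        specificity_ci=spec_ci,
        ci_method=ci_method,
    )


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value (probability-mass ordering).

    The p-value is the total hypergeometric probability of all tables
    with the observed margins whose probability does not exceed that of
    the observed table.
    """
    _, p = stats.fisher_exact(table.to_array(), alternative="two-sided")
    return float(p)


def chi_square(
    table: ContingencyTable, continuity_correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square statistic and p-value (1 df), no Yates by default."""
    res = stats.chi2_contingency(table.to_array(), correction=continuity_correction)
    return float(res.statistic), float(res.pvalue)


def group_summary(
    df: pd.DataFrame,
    group_cols: Sequence[str] = ("passed_program", "career_stayed"),
    mean_cols: Optional[Sequence[str]] = None,
    median_cols: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-group descriptive summary in tidy form.

    For each group and variable: n, mean with t-based 95% CI (CI is NaN
    for a group of one, and degenerate for a constant column), and
    median with min–max for variables listed in ``median_cols``.
    """
    if mean_cols is None:
        mean_cols = [
            c
            for c in df.columns
            if c not in group_cols
            and c not in median_cols
            and pd.api.types.is_numeric_dtype(df[c])
        ]
    rows = []
    for key, g in df.groupby(list(group_cols), dropna=False, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        base = dict(zip(group_cols, key))
        for col in list(mean_cols) + list(median_cols):
            vals = g[col].dropna().to_numpy(dtype=float)
            n = len(vals)
            row = dict(base, variable=col, n=n)
            if n == 0:
                row.update(mean=np.nan, ci_lower=np.nan, ci_upper=np.nan)
            else:
                mean = float(np.mean(vals))
                if n > 1:
                    sem = float(np.std(vals, ddof=1) / np.sqrt(n))
                    tcrit = float(stats.t.ppf(0.975, n - 1))
                    ci = (mean - tcrit * sem, mean + tcrit * sem)
                else:
                    ci = (np.nan, np.nan)
                row.update(mean=mean, ci_lower=ci[0], ci_upper=ci[1])
            if col in median_cols and n > 0:
                row.update(
                    median=float(np.median(vals)),
                    min=float(np.min(vals)),
                    max=float(np.max(vals)),
                )
            rows.append(row)
    return pd.DataFrame(rows)


def contingency_from_cohort(summary: pd.DataFrame) -> ContingencyTable:
    """Build the 2x2 table from a cohort summary table.

    Expects binary columns ``passed_program`` and ``career_stayed``.
    """
    p = summary["passed_program"].astype(bool)
    s = summary["career_stayed"].astype(bool)
    return ContingencyTable(
        passed_stayed=int((p & s).sum()),
        passed_left=int((p & ~s).sum()),
        failed_stayed=int((~p & s).sum()),
        failed_left=int((~p & ~s).sum()),
    )
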