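"""Contingency-table statistics and descriptive summaries.

Crude odds ratios with Woolf confidence intervals, Pearson chi-square and
pooled-variance Student's t tests for case/control comparisons, allele
frequencies and the 1-df asymptotic Hardy-Weinberg equilibrium test, and
table-style descriptive summaries with complete-case denominators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import DomainError, ConfigError, round_half_up

__all__ = [
    "Table2x2",
    "GenotypeCounts",
    "TestResult",
    "CrudeOR",
    "crude_or",
    "chi_square_test",
    "student_t_test",
    "allele_frequency",
    "hwe_test",
    "describe_cohort",
    "DegenerateTableError",
]


class DegenerateTableError(DomainError):
    """A margin of the contingency table is zero."""


@dataclass(frozen=True)
class Table2x2:
    """2x2 counts: a=exposed cases, b=exposed controls, c=unexposed cases,
    d=unexposed controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise DomainError("cell counts must be non-negative")
        if sum(cells) == 0:
            raise DomainError("table total must be positive")


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts ordered homozygote-reference, heterozygote,
    homozygote-alternate."""

    n_homref: int
    n_het: int
    n_homalt: int

    def __post_init__(self) -> None:
        if min(self.n_homref, self.n_het, self.n_homalt) < 0:
            raise DomainError("genotype counts must be non-negative")
        if self.total == 0:
            raise DomainError("genotype counts must sum to a positive total")

    @property
    def total(self) -> int:
        return self.n_homref + self.n_het + self.n_homalt


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    note: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise DomainError("p_value outside [0, 1]")


@dataclass(frozen=True)
class CrudeOR:
    odds_ratio: float
    ci_low: float
    ci_high: float
    confidence: float
    corrected: bool  # True when 0.5 was added to every cell (zero cell)


def crude_or(table: Table2x2, confidence: float = 0.95) -> CrudeOR:
    """Cross-product odds ratio ad/(bc) with a Woolf (log-scale) CI.

    A zero cell triggers the standard continuity correction (0.5 added to
    all four cells); the result is flagged via ``corrected``.
    """
    if not 0.0 < confidence < 1.0:
        raise DomainError("confidence must lie in (0, 1)")
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_point = (a * d) / (b * c)
    z = stats.norm.ppf(1.0 - (1.0 - confidence) / 2.0)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(or_point)
    return CrudeOR(
        odds_ratio=float(or_point),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        confidence=confidence,
        corrected=corrected,
    )


def chi_square_test(counts: Sequence[Sequence[float]] | np.ndarray) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table."""
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 2 or obs.min() < 0:
        raise DomainError("counts must be a non-negative 2-D table")
    if obs.sum() <= 0:
        raise DegenerateTableError("table total must be positive")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero row or column margin")
    stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return TestResult(statistic=float(stat), df=float(df), p_value=float(p))


def student_t_test(group1: Sequence[float], group2: Sequence[float]) -> TestResult:
    """Two-sided pooled-variance (Student's) t-test; df = n1 + n2 - 2."""
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise DomainError("each group needs at least two observations")
    pooled = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (
        len(x) + len(y) - 2
    )
    if pooled <= 0:
        raise DomainError("pooled variance is zero; t statistic undefined")
    res = stats.ttest_ind(x, y, equal_var=True)
    return TestResult(
        statistic=float(res.statistic),
        df=float(len(x) + len(y) - 2),
        p_value=float(res.pvalue),
    )


def allele_frequency(counts: GenotypeCounts) -> float:
    """Alternate-allele frequency by allele counting:
    (2*n_homalt + n_het) / (2*total)."""
    return (2 * counts.n_homalt + counts.n_het) / (2 * counts.total)


def hwe_test(counts: GenotypeCounts) -> TestResult:
    """Asymptotic 1-df chi-square Hardy-Weinberg equilibrium test.

    Observed genotype counts are compared with n*((1-q)^2, 2q(1-q), q^2) at
    the allele-counting estimate of q; one degree of freedom because q is
    estimated. Monomorphic samples are reported as trivially conforming
    (statistic 0) with an explanatory note.
    """
    q = allele_frequency(counts)
    if q in (0.0, 1.0):
        return TestResult(statistic=0.0, df=1.0, p_value=1.0, note="monomorphic")
    n = counts.total
    expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2]) * n
    observed = np.array([counts.n_homref, counts.n_het, counts.n_homalt], dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    return TestResult(statistic=stat, df=1.0, p_value=float(stats.chi2.sf(stat, 1)))


#: Default typing of cohort variables for descriptive summaries.
_CONTINUOUS = {"age", "income", "age_menarche", "bmi", "wc", "whr"}


def describe_cohort(
    records: pd.DataFrame,
    variables: Sequence[str],
    kinds: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Case/control descriptive summary with complete-case denominators.

    For categorical variables, one row per level with counts and percentages
    (half-up, one decimal; denominators are the per-variable complete-case
    totals) plus a Pearson chi-square comparison; for continuous variables a
    single row with the group mean in ``*_n`` and SD in ``*_pct`` (level
    ``"mean_sd"``) compared by Student's t. Output columns: variable, level,
    cases_n, cases_pct, controls_n, controls_pct, statistic, p.
    """
    if records.empty:
        raise DomainError("records must be non-empty")
    kinds = kinds or {}
    cases = records[records["case_status"] == 1]
    controls = records[records["case_status"] == 0]
    rows: list[dict] = []
    for var in variables:
        if var not in records.columns:
            raise ConfigError(f"unknown variable {var!r}")
        kind = kinds.get(
            var, "continuous" if var in _CONTINUOUS else "categorical"
        )
        ca = cases[var].dropna()
        co = controls[var].dropna()
        if ca.empty and co.empty:
            warnings.warn(f"variable {var!r} is entirely missing; excluded", stacklevel=2)
            continue
        if kind == "continuous":
            test = student_t_test(ca.to_numpy(float), co.to_numpy(float))
            rows.append(
                {
                    "variable": var,
                    "level": "mean_sd",
                    "cases_n": float(ca.mean()),
                    "cases_pct": float(ca.std(ddof=1)),
                    "controls_n": float(co.mean()),
                    "controls_pct": float(co.std(ddof=1)),
                    "statistic": test.statistic,
                    "p": test.p_value,
                }
            )
        else:
            levels = sorted(pd.unique(pd.concat([ca, co])), key=str)
            table = np.array(
                [[int((ca == lv).sum()) for lv in levels],
                 [int((co == lv).sum()) for lv in levels]]
            )
            try:
                test = chi_square_test(table)
                stat, p = test.statistic, test.p_value
            except DegenerateTableError:
                stat, p = np.nan, np.nan
            n_ca, n_co = len(ca), len(co)
            for j, lv in enumerate(levels):
                rows.append(
                    {
                        "variable": var,
                        "level": str(lv),
                        "cases_n": int(table[0, j]),
                        "cases_pct": round_half_up(100.0 * table[0, j] / n_ca, 1)
                        if n_ca
                        else np.nan,
                        "controls_n": int(table[1, j]),
                        "controls_pct": round_half_up(100.0 * table[1, j] / n_co, 1)
                        if n_co
                        else np.nan,
                        "statistic": stat if j == 0 else np.nan,
                        "p": p if j == 0 else np.nan,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "variable",
            "level",
            "cases_n",
            "cases_pct",
            "controls_n",
            "controls_pct",
            "statistic",
            "p",
        ],
    )
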