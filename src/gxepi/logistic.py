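"""Unconditional logistic regression by Newton-Raphson maximum likelihood.

The estimation engine beneath all adjusted odds ratios: a design builder
with categorical/ordinal/continuous codings and complete-case handling, a
``LogisticModel`` fitted by iteratively reweighted Newton steps with
step-halving, and a ``LogisticResults`` object carrying the coefficient
vector, its covariance (inverse observed information at the MLE), Wald
odds-ratio intervals and a text summary. Trend tests across ordered
exposure categories are Wald tests of a single ordinal-score coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

from ._util import ConfigError, DomainError, EstimationError
from .tables import TestResult

__all__ = [
    "Term",
    "ModelSpec",
    "ADJUSTMENT_PRESETS",
    "DesignInfo",
    "build_design",
    "LogisticModel",
    "LogisticResults",
    "ORResult",
    "adjusted_or",
    "trend_test",
    "RankDeficiencyWarning",
]


class RankDeficiencyWarning(UserWarning):
    """A design column is constant or collinear."""


@dataclass(frozen=True)
class Term:
    """One model term: a field with its coding.

    coding: "continuous" (as-is), "categorical" (indicator columns against
    ``ref``), or "ordinal" (observed levels mapped to scores 0,1,2,... in
    ``levels`` order, default sorted).
    """

    field: str
    coding: str = "continuous"
    ref: str | None = None
    levels: tuple | None = None

    def __post_init__(self) -> None:
        if self.coding not in ("continuous", "categorical", "ordinal"):
            raise ConfigError(f"unknown coding {self.coding!r}")


#: Adjustment presets. model1 = stable socio-economic indicators; model2
#: additionally adjusts hormone-drug use, family history and moderate
#: exercise. Age, income and exercise score enter as continuous terms.
ADJUSTMENT_PRESETS: dict[str, tuple[Term, ...]] = {
    "none": (),
    "model1": (
        Term("age"),
        Term("education", "categorical", ref="primary_or_less"),
        Term("marital", "categorical", ref="married"),
        Term("residence", "categorical", ref="rural"),
        Term("income"),
    ),
}
ADJUSTMENT_PRESETS["model2"] = ADJUSTMENT_PRESETS["model1"] + (
    Term("hormone_drugs"),
    Term("family_history"),
    Term("exercise"),
)


@dataclass(frozen=True)
class ModelSpec:
    """Outcome plus ordered exposure terms plus an adjustment preset."""

    outcome: str = "case_status"
    terms: tuple[Term, ...] = ()
    adjustment: str = "none"

    def resolved_terms(self) -> tuple[Term, ...]:
        if self.adjustment not in ADJUSTMENT_PRESETS:
            raise ConfigError(f"unknown adjustment preset {self.adjustment!r}")
        extra = tuple(
            t
            for t in ADJUSTMENT_PRESETS[self.adjustment]
            if t.field not in {u.field for u in self.terms}
        )
        return tuple(self.terms) + extra


@dataclass
class DesignInfo:
    X: np.ndarray
    y: np.ndarray
    names: list[str]
    n_used: int
    n_dropped: int


def build_design(records: pd.DataFrame, spec: ModelSpec) -> DesignInfo:
    """Expand a model spec into a numeric design matrix.

    Intercept column first; categorical fields become indicator columns
    named ``field[level]`` against the reference level; ordinal fields map
    their ordered levels to integer scores. Rows with any missing referenced
    value are dropped (complete-case) and counted.
    """
    terms = spec.resolved_terms()
    fields = [spec.outcome] + [t.field for t in terms]
    missing_cols = [f for f in fields if f not in records.columns]
    if missing_cols:
        raise ConfigError(f"fields absent from records: {missing_cols}")
    sub = records[fields].dropna()
    n_dropped = len(records) - len(sub)
    if sub.empty:
        raise EstimationError("no complete-case rows for this model")
    y = sub[spec.outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise DomainError(f"outcome {spec.outcome!r} must be binary 0/1")

    cols: list[np.ndarray] = [np.ones(len(sub))]
    names: list[str] = ["intercept"]
    for t in terms:
        s = sub[t.field]
        if t.coding == "continuous":
            cols.append(s.to_numpy(dtype=float))
            names.append(t.field)
        elif t.coding == "ordinal":
            levels = list(t.levels) if t.levels else sorted(pd.unique(s), key=str)
            score = s.map({lv: i for i, lv in enumerate(levels)})
            if score.isna().any():
                raise ConfigError(f"values of {t.field!r} outside declared levels")
            cols.append(score.to_numpy(dtype=float))
            names.append(f"{t.field}_score")
        else:  # categorical
            levels = list(t.levels) if t.levels else sorted(pd.unique(s), key=str)
            ref = t.ref if t.ref is not None else levels[0]
            if ref not in levels:
                raise ConfigError(
                    f"reference {ref!r} not among observed levels of {t.field!r}"
                )
            for lv in levels:
                if lv == ref:
                    continue
                cols.append((s == lv).to_numpy(dtype=float))
                names.append(f"{t.field}[{lv}]")
    X = np.column_stack(cols)
    for j in range(1, X.shape[1]):
        if np.ptp(X[:, j]) == 0.0:
            warnings.warn(
                f"design column {names[j]!r} is constant", RankDeficiencyWarning,
                stacklevel=2,
            )
    return DesignInfo(X=X, y=y, names=names, n_used=len(sub), n_dropped=n_dropped)


@dataclass(frozen=True)
class ORResult:
    term: str
    or_point: float
    ci_low: float
    ci_high: float
    reference: str | None = None


class LogisticModel:
    """Bernoulli log-likelihood logistic model.

    Parameters
    ----------
    endog : array of 0/1 outcomes.
    exog : design matrix, intercept column included by the caller
        (``from_dataframe`` builds it from a :class:`ModelSpec`).
    names : column names aligned with ``exog``.
    """

    def __init__(
        self,
        endog: np.ndarray,
        exog: np.ndarray,
        names: Sequence[str] | None = None,
        n_dropped: int = 0,
    ) -> None:
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or len(self.endog) != self.exog.shape[0]:
            raise DomainError("endog/exog shapes incompatible")
        if not np.isin(self.endog, (0.0, 1.0)).all():
            raise DomainError("outcome must be binary 0/1")
        self.names = list(names) if names else [f"x{j}" for j in range(self.exog.shape[1])]
        self.n_dropped = n_dropped

    @classmethod
    def from_dataframe(cls, records: pd.DataFrame, spec: ModelSpec) -> "LogisticModel":
        d = build_design(records, spec)
        return cls(d.y, d.X, d.names, n_dropped=d.n_dropped)

    def loglike(self, beta: np.ndarray) -> float:
        eta = self.exog @ beta
        # numerically stable: sum y*eta - log(1+exp(eta))
        return float(np.sum(self.endog * eta - np.logaddexp(0.0, eta)))

    def score(self, beta: np.ndarray) -> np.ndarray:
        p = expit(self.exog @ beta)
        return self.exog.T @ (self.endog - p)

    def information(self, beta: np.ndarray) -> np.ndarray:
        p = expit(self.exog @ beta)
        w = p * (1.0 - p)
        return (self.exog * w[:, None]).T @ self.exog

    def fit(
        self, tol: float = 1e-10, maxiter: int = 50, start: np.ndarray | None = None
    ) -> "LogisticResults":
        """Newton-Raphson with step-halving; stops when max|score| < tol.

        The log-likelihood is non-decreasing across iterations by
        construction. Non-convergence or diverging coefficients (complete
        or quasi-complete separation) yield a flagged, non-converged result
        naming the offending terms.
        """
        beta = np.zeros(self.exog.shape[1]) if start is None else start.astype(float)
        ll = self.loglike(beta)
        history = [ll]
        converged = False
        message = ""
        it = 0
        for it in range(1, maxiter + 1):
            s = self.score(beta)
            if np.max(np.abs(s)) < tol:
                converged = True
                it -= 1
                break
            info = self.information(beta)
            try:
                delta = np.linalg.solve(info, s)
            except np.linalg.LinAlgError:
                delta, *_ = np.linalg.lstsq(info, s, rcond=None)
                message = "information matrix singular; least-squares step taken"
            step = 1.0
            while step >= 2.0**-12:
                cand = beta + step * delta
                ll_cand = self.loglike(cand)
                if ll_cand >= ll - 1e-12:
                    break
                step /= 2.0
            beta = beta + step * delta
            ll = self.loglike(beta)
            history.append(ll)
        else:
            message = message or f"maximum iterations ({maxiter}) reached"
        if converged and np.max(np.abs(s := self.score(beta))) >= tol:
            converged = False  # pragma: no cover - defensive
        big = np.abs(beta) > 15.0
        if big.any():
            converged = False
            offending = [self.names[j] for j in np.flatnonzero(big)]
            message = (
                "coefficients diverging (possible separation) for terms: "
                + ", ".join(offending)
            )
            warnings.warn(message, stacklevel=2)
        info = self.information(beta)
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
            converged = False
            message = message or "singular information at the optimum"
        return LogisticResults(
            model=self,
            params=pd.Series(beta, index=self.names),
            cov=pd.DataFrame(cov, index=self.names, columns=self.names),
            llf=ll,
            n_used=len(self.endog),
            n_iter=it,
            converged=converged,
            message=message,
            loglik_path=history,
        )


@dataclass
class LogisticResults:
    """MLE output: coefficients, covariance, convergence metadata."""

    model: LogisticModel
    params: pd.Series
    cov: pd.DataFrame
    llf: float
    n_used: int
    n_iter: int
    converged: bool
    message: str = ""
    loglik_path: list[float] = field(default_factory=list)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    def cov_params(self) -> pd.DataFrame:
        return self.cov

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = norm.ppf(1.0 - alpha / 2.0)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"low": lo, "high": hi})

    def odds_ratios(self, terms: Sequence[str] | None = None, alpha: float = 0.05) -> pd.DataFrame:
        """Wald odds ratios exp(beta +/- z*SE) for the named terms
        (default: every non-intercept term)."""
        terms = list(terms) if terms is not None else [
            t for t in self.params.index if t != "intercept"
        ]
        ci = self.conf_int(alpha)
        rows = []
        for t in terms:
            if t not in self.params.index:
                raise KeyError(f"term {t!r} not in model")
            rows.append(
                {
                    "term": t,
                    "or": float(np.exp(self.params[t])),
                    "ci_low": float(np.exp(ci.loc[t, "low"])),
                    "ci_high": float(np.exp(ci.loc[t, "high"])),
                }
            )
        return pd.DataFrame(rows)

    def wald_test(self, term: str) -> TestResult:
        """Wald z^2 (1-df chi-square) test of a single coefficient."""
        if term not in self.params.index:
            raise KeyError(f"term {term!r} not in model")
        z2 = float((self.params[term] / self.bse[term]) ** 2)
        return TestResult(statistic=z2, df=1.0, p_value=float(chi2.sf(z2, 1)))

    def summary(self) -> str:
        lines = [
            "Logistic regression (Newton-Raphson MLE)",
            f"  n = {self.n_used}  (dropped {self.model.n_dropped} incomplete rows)",
            f"  log-likelihood = {self.llf:.4f}  iterations = {self.n_iter}"
            f"  converged = {self.converged}",
        ]
        if self.message:
            lines.append(f"  note: {self.message}")
        lines.append(
            f"  {'term':<28}{'beta':>10}{'SE':>10}{'OR':>8}{'95% CI':>20}"
        )
        ci = self.conf_int()
        for t in self.params.index:
            b, se = self.params[t], self.bse[t]
            lines.append(
                f"  {t:<28}{b:>10.4f}{se:>10.4f}{np.exp(b):>8.2f}"
                f"   ({np.exp(ci.loc[t, 'low']):.2f}, {np.exp(ci.loc[t, 'high']):.2f})"
            )
        return "\n".join(lines)


def adjusted_or(fit: LogisticResults, term: str, alpha: float = 0.05) -> ORResult:
    """Adjusted odds ratio exp(beta) with Wald CI for one model term."""
    row = fit.odds_ratios([term], alpha=alpha).iloc[0]
    return ORResult(
        term=term, or_point=row["or"], ci_low=row["ci_low"], ci_high=row["ci_high"]
    )


def trend_test(
    records: pd.DataFrame,
    exposure: str,
    levels: Sequence | None = None,
    adjustment: str = "none",
    outcome: str = "case_status",
) -> TestResult:
    """Test for trend across ordered exposure categories.

    The exposure enters the adjusted logistic model as a single ordinal
    score (0, 1, 2, ...); the returned statistic is the Wald z^2 of that
    coefficient (1-df chi-square).
    """
    s = records[exposure].dropna()
    observed = list(levels) if levels else sorted(pd.unique(s), key=str)
    if len([lv for lv in observed if (s == lv).any()]) < 3:
        raise DomainError("trend test needs at least 3 observed ordered levels")
    spec = ModelSpec(
        outcome=outcome,
        terms=(Term(exposure, "ordinal", levels=tuple(observed)),),
        adjustment=adjustment,
    )
    fit = LogisticModel.from_dataframe(records, spec).fit()
    return fit.wald_test(f"{exposure}_score")
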