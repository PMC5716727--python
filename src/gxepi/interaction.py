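"""Gene-environment interaction on additive and multiplicative scales.

Joint-indicator coding of a dichotomized genotype and a binary adiposity
category against a common doubly-unexposed reference yields three odds
ratios OR10 (genotype only), OR01 (adiposity only) and OR11 (joint). The
additive-scale interaction measures are

    RERI = OR11 - OR10 - OR01 + 1        (0 under additivity)
    AP   = RERI / OR11                   (0 under additivity)
    S    = (OR11 - 1) / ((OR10 - 1) + (OR01 - 1))   (1 under additivity)

and the multiplicative-scale measure is the ratio of odds ratios
ROR = OR11/(OR10*OR01). Confidence intervals come from the delta method on
the fitted logistic coefficients and their covariance block: RERI and AP on
the natural scale, S on the log scale (standard for ratio measures), ROR as
a Wald interval on the linear combination b3 - b1 - b2. A case/control
stratified nonparametric bootstrap provides an independent percentile-CI
oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._util import ConfigError, DomainError, EstimationError
from .config import BINARY_CUTOFFS
from .logistic import LogisticModel, LogisticResults, ModelSpec, Term
from .simulate import genotype_high_indicator

__all__ = [
    "JointCoding",
    "joint_indicator_design",
    "reri",
    "attributable_proportion",
    "synergy_index",
    "ratio_of_odds_ratios",
    "Estimate",
    "InteractionResult",
    "interaction_from_fit",
    "JointEffectModel",
    "JointEffectResults",
    "bootstrap_interaction",
    "BootstrapInteraction",
]

_INDICATORS = ("g_only", "e_only", "joint")


class Estimate(NamedTuple):
    value: float
    ci_low: float
    ci_high: float


def _check_ors(or11: float, or10: float, or01: float) -> None:
    if min(or11, or10, or01) <= 0:
        raise DomainError("odds ratios must be strictly positive")


def reri(or11: float, or10: float, or01: float) -> float:
    """Relative excess risk due to interaction: OR11 - OR10 - OR01 + 1."""
    _check_ors(or11, or10, or01)
    return or11 - or10 - or01 + 1.0


def attributable_proportion(or11: float, or10: float, or01: float) -> float:
    """Attributable proportion due to interaction: RERI / OR11."""
    _check_ors(or11, or10, or01)
    return reri(or11, or10, or01) / or11


def synergy_index(or11: float, or10: float, or01: float) -> float:
    """Synergy index (OR11-1)/((OR10-1)+(OR01-1)).

    Returns ``nan`` when undefined: denominator <= 0 (no positive excess
    risk among the single exposures) or OR11 <= 1.
    """
    _check_ors(or11, or10, or01)
    denom = (or10 - 1.0) + (or01 - 1.0)
    if denom <= 0 or or11 <= 1.0:
        return math.nan
    return (or11 - 1.0) / denom


def ratio_of_odds_ratios(or11: float, or10: float, or01: float) -> float:
    """Multiplicative-scale interaction OR11/(OR10*OR01)."""
    _check_ors(or11, or10, or01)
    return or11 / (or10 * or01)


@dataclass(frozen=True)
class JointCoding:
    """How the 3-level genotype and a continuous adiposity index collapse to
    the four joint-exposure cells.

    ``grouping``: "dominant" (carriers high), "recessive" (minor homozygote
    high) or "homozygous" (both homozygotes high, heterozygote reference).
    The reference cell is (low genotype, index below cutoff).
    """

    snp: str
    grouping: str = "dominant"
    index: str = "bmi"
    cutoff: float | None = None

    def resolved_cutoff(self) -> float:
        if self.cutoff is not None:
            return self.cutoff
        if self.index not in BINARY_CUTOFFS:
            raise ConfigError(f"no default cutoff for index {self.index!r}")
        return BINARY_CUTOFFS[self.index]


def joint_indicator_design(
    records: pd.DataFrame, coding: JointCoding
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the three mutually exclusive joint-exposure indicators.

    Returns ``(design, cells)``: ``design`` has columns g_only (G+E-),
    e_only (G-E+) and joint (G+E+) aligned to the complete-case rows of
    ``records``; ``cells`` tabulates case/control counts of the four cells.
    An empty joint cell raises :class:`EstimationError` naming the cell.
    """
    for col in (coding.snp, coding.index, "case_status"):
        if col not in records.columns:
            raise ConfigError(f"column {col!r} absent from records")
    sub = records[[coding.snp, coding.index, "case_status"]].dropna()
    g = genotype_high_indicator(sub[coding.snp].to_numpy(), coding.grouping)
    e = (sub[coding.index].to_numpy(dtype=float) >= coding.resolved_cutoff()).astype(
        np.int8
    )
    design = pd.DataFrame(
        {
            "g_only": ((g == 1) & (e == 0)).astype(float),
            "e_only": ((g == 0) & (e == 1)).astype(float),
            "joint": ((g == 1) & (e == 1)).astype(float),
        },
        index=sub.index,
    )
    y = sub["case_status"].to_numpy()
    rows = []
    for name, gv, ev in (
        ("reference", 0, 0),
        ("g_only", 1, 0),
        ("e_only", 0, 1),
        ("joint", 1, 1),
    ):
        in_cell = (g == gv) & (e == ev)
        n_case = int(((y == 1) & in_cell).sum())
        n_ctrl = int(((y == 0) & in_cell).sum())
        if n_case + n_ctrl == 0:
            raise EstimationError(f"empty joint-exposure cell {name!r}")
        rows.append(
            {"cell": name, "genotype_high": gv, "adiposity_high": ev,
             "cases": n_case, "controls": n_ctrl}
        )
    return design, pd.DataFrame(rows)


@dataclass(frozen=True)
class InteractionResult:
    """RERI/AP/S/ROR with delta-method CIs and the source joint ORs."""

    reri: Estimate
    ap: Estimate
    s: Estimate
    s_defined: bool
    ror: Estimate
    or11: Estimate
    or10: Estimate
    or01: Estimate

    def summary(self) -> str:
        def fmt(name: str, e: Estimate, ok: bool = True) -> str:
            if not ok or math.isnan(e.value):
                return f"  {name:<6} undefined"
            return f"  {name:<6}{e.value:>8.3f}  ({e.ci_low:.3f}, {e.ci_high:.3f})"

        return "\n".join(
            [
                "Joint-exposure odds ratios (vs doubly-unexposed reference)",
                fmt("OR10", self.or10),
                fmt("OR01", self.or01),
                fmt("OR11", self.or11),
                "Additive interaction",
                fmt("RERI", self.reri),
                fmt("AP", self.ap),
                fmt("S", self.s, self.s_defined),
                "Multiplicative interaction",
                fmt("ROR", self.ror),
            ]
        )


def interaction_from_fit(
    fit: LogisticResults,
    terms: Sequence[str] = _INDICATORS,
    alpha: float = 0.05,
) -> InteractionResult:
    """Compute all interaction measures from a fitted joint-indicator model.

    ``terms`` names the G+E-, G-E+ and G+E+ indicator coefficients (in that
    order) within ``fit``; the delta method uses the corresponding 3x3
    covariance block. RERI and AP intervals are on the natural scale, the S
    interval on the log scale, and ROR is a Wald interval on b3 - b1 - b2.
    """
    t1, t2, t3 = terms
    for t in terms:
        if t not in fit.params.index:
            raise ConfigError(f"term {t!r} missing from fit")
    b = fit.params[[t1, t2, t3]].to_numpy()
    sigma = fit.cov.loc[[t1, t2, t3], [t1, t2, t3]].to_numpy()
    if not np.all(np.isfinite(sigma)):
        raise ConfigError("covariance block missing or non-finite")
    o10, o01, o11 = np.exp(b[0]), np.exp(b[1]), np.exp(b[2])
    z = norm.ppf(1.0 - alpha / 2.0)

    def delta_se(grad: np.ndarray) -> float:
        return float(np.sqrt(grad @ sigma @ grad))

    # Wald CIs for the three joint ORs
    se_b = np.sqrt(np.diag(sigma))
    or10 = Estimate(o10, *np.exp((b[0] - z * se_b[0], b[0] + z * se_b[0])))
    or01 = Estimate(o01, *np.exp((b[1] - z * se_b[1], b[1] + z * se_b[1])))
    or11 = Estimate(o11, *np.exp((b[2] - z * se_b[2], b[2] + z * se_b[2])))

    reri_hat = o11 - o10 - o01 + 1.0
    se = delta_se(np.array([-o10, -o01, o11]))
    reri_est = Estimate(reri_hat, reri_hat - z * se, reri_hat + z * se)

    ap_hat = reri_hat / o11
    grad_ap = np.array([-o10 / o11, -o01 / o11, (o10 + o01 - 1.0) / o11])
    se = delta_se(grad_ap)
    ap_est = Estimate(ap_hat, ap_hat - z * se, ap_hat + z * se)

    denom = (o10 - 1.0) + (o01 - 1.0)
    s_defined = denom > 0 and o11 > 1.0
    if s_defined:
        s_hat = (o11 - 1.0) / denom
        grad_lns = np.array([-o10 / denom, -o01 / denom, o11 / (o11 - 1.0)])
        se = delta_se(grad_lns)
        s_est = Estimate(
            s_hat, float(s_hat * np.exp(-z * se)), float(s_hat * np.exp(z * se))
        )
    else:
        s_est = Estimate(math.nan, math.nan, math.nan)

    a = np.array([-1.0, -1.0, 1.0])
    lror = b[2] - b[0] - b[1]
    se = delta_se(a)
    ror_est = Estimate(
        float(np.exp(lror)), float(np.exp(lror - z * se)), float(np.exp(lror + z * se))
    )

    return InteractionResult(
        reri=reri_est,
        ap=ap_est,
        s=s_est,
        s_defined=s_defined,
        ror=ror_est,
        or11=or11,
        or10=or10,
        or01=or01,
    )


class JointEffectModel:
    """Joint-effect logistic model for one SNP x adiposity pair.

    Builds the three joint-exposure indicators per ``coding``, appends the
    adjustment preset's covariate terms, and restricts to rows complete for
    every referenced field. ``fit()`` returns a :class:`JointEffectResults`
    carrying the logistic fit, cell counts and the interaction measures.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        coding: JointCoding,
        adjustment: str = "none",
        outcome: str = "case_status",
    ) -> None:
        self.records = records
        self.coding = coding
        self.adjustment = adjustment
        self.outcome = outcome
        design, cells = joint_indicator_design(records, coding)
        self.cells = cells
        aug = records.join(design, how="inner")
        # joint_indicator_design already dropped rows missing the exposure
        # pair; the model spec adds complete-case filtering on covariates.
        self._frame = aug
        self._spec = ModelSpec(
            outcome=outcome,
            terms=tuple(Term(t) for t in _INDICATORS),
            adjustment=adjustment,
        )

    def fit(self, **fit_kwargs) -> "JointEffectResults":
        lm = LogisticModel.from_dataframe(self._frame, self._spec)
        res = lm.fit(**fit_kwargs)
        measures = interaction_from_fit(res)
        return JointEffectResults(
            model=self, fit=res, cells=self.cells, measures=measures
        )


@dataclass
class JointEffectResults:
    model: JointEffectModel
    fit: LogisticResults
    cells: pd.DataFrame
    measures: InteractionResult

    def summary(self) -> str:
        head = (
            f"Joint effect: {self.model.coding.snp} "
            f"({self.model.coding.grouping}) x {self.model.coding.index} "
            f">= {self.model.coding.resolved_cutoff():g}, "
            f"adjustment={self.model.adjustment}, n={self.fit.n_used}"
        )
        return "\n".join([head, self.cells.to_string(index=False), self.measures.summary()])

    def bootstrap(
        self, n_boot: int = 2000, seed: int | np.random.Generator | None = None
    ) -> "BootstrapInteraction":
        return bootstrap_interaction(
            self.model.records,
            self.model.coding,
            adjustment=self.model.adjustment,
            n_boot=n_boot,
            seed=seed,
            outcome=self.model.outcome,
        )


@dataclass
class BootstrapInteraction:
    """Percentile CIs from case/control-stratified resampling."""

    point: InteractionResult
    reri: Estimate
    ap: Estimate
    s: Estimate
    ror: Estimate
    n_boot: int
    n_failed: int
    replicates: pd.DataFrame


def bootstrap_interaction(
    records: pd.DataFrame,
    coding: JointCoding,
    adjustment: str = "none",
    n_boot: int = 2000,
    seed: int | np.random.Generator | None = None,
    outcome: str = "case_status",
    alpha: float = 0.05,
) -> BootstrapInteraction:
    """Nonparametric bootstrap of the interaction measures.

    Cases and controls are resampled with replacement within their own
    stratum (preserving the case-control design), the adjusted joint model
    is refitted and every measure recomputed per replicate; CIs are the
    percentile intervals. Replicates that fail to converge are dropped; a
    failure rate above 10% triggers a warning.
    """
    if n_boot < 1:
        raise DomainError("n_boot must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = JointEffectModel(records, coding, adjustment=adjustment, outcome=outcome)
    point = base.fit().measures

    cases = records[records[outcome] == 1]
    controls = records[records[outcome] == 0]
    rows = []
    n_failed = 0
    for _ in range(n_boot):
        rc = cases.iloc[rng.integers(0, len(cases), size=len(cases))]
        rk = controls.iloc[rng.integers(0, len(controls), size=len(controls))]
        rep = pd.concat([rc, rk], ignore_index=True)
        try:
            res = JointEffectModel(
                rep, coding, adjustment=adjustment, outcome=outcome
            ).fit()
        except (EstimationError, DomainError):
            n_failed += 1
            continue
        if not res.fit.converged:
            n_failed += 1
            continue
        m = res.measures
        rows.append(
            {
                "reri": m.reri.value,
                "ap": m.ap.value,
                "s": m.s.value,
                "ror": m.ror.value,
            }
        )
    if n_failed > 0.10 * n_boot:
        warnings.warn(
            f"{n_failed} of {n_boot} bootstrap replicates failed to converge",
            stacklevel=2,
        )
    reps = pd.DataFrame(rows)
    if reps.empty:
        raise EstimationError("all bootstrap replicates failed")

    def pct(col: str, center: float) -> Estimate:
        vals = reps[col].dropna().to_numpy()
        lo, hi = np.quantile(vals, [alpha / 2.0, 1.0 - alpha / 2.0])
        return Estimate(center, float(lo), float(hi))

    return BootstrapInteraction(
        point=point,
        reri=pct("reri", point.reri.value),
        ap=pct("ap", point.ap.value),
        s=pct("s", point.s.value),
        ror=pct("ror", point.ror.value),
        n_boot=n_boot,
        n_failed=n_failed,
        replicates=reps,
    )
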