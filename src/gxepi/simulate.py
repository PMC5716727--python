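"""Synthetic case-control cohort generator.

Emulates the structure of a population-based breast-cancer case-control
study: a source population of women with three biallelic SNP genotypes drawn
under Hardy-Weinberg equilibrium, correlated adiposity indices (BMI, waist
circumference, waist-to-hip ratio) calibrated to configured "high" category
prevalences, socio-economic and reproductive covariates, a logistic disease
model, and control selection frequency-matched to cases within 5-year age
bands. Everything is driven by a :class:`~gxepi.config.SimulationConfig` and
a seed; identical configurations reproduce identical cohorts bit-for-bit.

Case-control sampling after a generative population model leaves odds ratios
invariant (outcome-dependent sampling changes only the intercept), so the
configured genotype/adiposity/joint ORs are recoverable downstream.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm, truncnorm

from ._util import ConfigError, DomainError
from .config import (
    ADIPOSITY_SD,
    BINARY_CUTOFFS,
    EDUCATION_LEVELS,
    MARITAL_LEVELS,
    SimulationConfig,
)

__all__ = [
    "assign_genotypes",
    "disease_probability",
    "generate_population",
    "sample_case_control",
    "inject_missingness",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "genotype_high_indicator",
    "SamplingReport",
    "MissingCovariateError",
    "COHORT_COLUMNS",
]

#: Fixed, documented header of the cohort CSV dialect (genotype columns are
#: appended in config order; missing values are written as empty fields).
COHORT_COLUMNS = [
    "id",
    "case_status",
    "age",
    "education",
    "marital",
    "residence",
    "income",
    "family_history",
    "hormone_drugs",
    "oral_contraceptive",
    "age_menarche",
    "menopause",
    "exercise",
    "bmi",
    "wc",
    "whr",
]

_NEVER_MISSING = ("id", "case_status")


class MissingCovariateError(KeyError):
    """A coefficient references a covariate absent from the record."""


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def assign_genotypes(
    freq: float, n: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Draw minor-allele counts for ``n`` subjects under HWE.

    Each subject draws two independent alleles with minor-allele frequency
    ``freq``; the genotype is the number of minor alleles, so genotype
    proportions converge to ((1-q)^2, 2q(1-q), q^2).
    """
    if not 0.0 <= freq <= 1.0:
        raise DomainError(f"minor-allele frequency must lie in [0, 1], got {freq}")
    if n < 0:
        raise DomainError("n must be non-negative")
    return _as_rng(rng).binomial(2, freq, size=n).astype(np.int8)


def genotype_high_indicator(genotypes: np.ndarray | pd.Series, coding: str) -> np.ndarray:
    """Dichotomize minor-allele counts: dominant (1,2 high), recessive (2),
    or homozygous (0,2 high, heterozygote reference)."""
    g = np.asarray(genotypes)
    if coding == "dominant":
        return (g >= 1).astype(np.int8)
    if coding == "recessive":
        return (g == 2).astype(np.int8)
    if coding == "homozygous":
        return (g != 1).astype(np.int8)
    raise ConfigError(f"unknown genotype coding {coding!r}")


def disease_probability(subject: Mapping, coefficients: Mapping[str, float]) -> float:
    """Logistic disease probability for one subject.

    ``coefficients`` maps term names to log-odds contributions; it must
    contain ``"intercept"`` and every other key names a numeric field of
    ``subject``. Returns ``1/(1+exp(-eta))``.
    """
    if "intercept" not in coefficients:
        raise ConfigError("coefficients must include an 'intercept' term")
    eta = 0.0
    for name, beta in coefficients.items():
        if name == "intercept":
            eta += beta
            continue
        try:
            value = subject[name]
        except (KeyError, IndexError) as exc:
            raise MissingCovariateError(name) from exc
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise MissingCovariateError(name)
        eta += beta * float(value)
    return float(expit(eta))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_population(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Generate a source population of women per the configuration.

    Returns one row per woman with covariates, adiposity indices, genotype
    columns (one per configured SNP, holding minor-allele counts) and
    ``case_status`` drawn from the logistic disease model. In large
    populations the joint-exposure-cell odds ratios converge to the
    configured ``or_geno`` / ``or_env`` / ``or_joint``.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_population
    cs = config.confounders
    snps = list(config.allele_freq)

    if n == 0:
        cols = COHORT_COLUMNS + snps
        return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})

    age = _truncated_normal(rng, cs.age_mean, cs.age_sd, cs.age_min, cs.age_max, n)
    education = rng.choice(EDUCATION_LEVELS, size=n, p=cs.education_probs)
    marital = rng.choice(MARITAL_LEVELS, size=n, p=cs.marital_probs)
    residence = np.where(rng.random(n) < cs.urban_prob, "urban", "rural")
    income = rng.lognormal(cs.income_log_mean, cs.income_log_sd, size=n)
    family_history = (rng.random(n) < cs.family_history_prob).astype(np.int8)
    hormone_drugs = (rng.random(n) < cs.hormone_drugs_prob).astype(np.int8)
    oral_contraceptive = (
        rng.random(n) < cs.oral_contraceptive_prob
    ).astype(np.int8)
    age_menarche = _truncated_normal(
        rng, cs.age_menarche_mean, cs.age_menarche_sd, 9.0, 22.0, n
    )
    menopause_age = rng.normal(cs.menopause_age_mean, cs.menopause_age_sd, size=n)
    menopause = np.where(age >= menopause_age, "post", "pre")
    exercise = rng.choice(len(cs.exercise_probs), size=n, p=cs.exercise_probs).astype(
        np.int8
    )

    genotypes = {snp: assign_genotypes(q, n, rng) for snp, q in config.allele_freq.items()}

    # Shared latent adiposity score, tilted by socio-economic position; the
    # shift is kept small so marginal "high" prevalences stay close to the
    # configured values.
    income_z = (np.log(income) - cs.income_log_mean) / cs.income_log_sd
    z = rng.normal(size=n)
    z = z + cs.adiposity_education_shift * (education == EDUCATION_LEVELS[0])
    z = z + cs.adiposity_income_slope * income_z
    rho = cs.adiposity_latent_corr
    adiposity: dict[str, np.ndarray] = {}
    for idx in ("bmi", "wc", "whr"):
        if idx not in config.adiposity_prevalence:
            adiposity[idx] = np.full(n, np.nan)
            continue
        p_high = config.adiposity_prevalence[idx]
        sd = ADIPOSITY_SD[idx]
        cutoff = BINARY_CUTOFFS[idx]
        s = rho * z + np.sqrt(1.0 - rho * rho) * rng.normal(size=n)
        # Location chosen so P(value >= cutoff) equals the configured
        # prevalence for a standard-normal latent score.
        if p_high in (0.0, 1.0):
            mu = cutoff - sd * (6.0 if p_high == 0.0 else -6.0)
        else:
            mu = cutoff - sd * norm.ppf(1.0 - p_high)
        values = mu + sd * s
        lo = {"bmi": 14.0, "wc": 50.0, "whr": 0.55}[idx]
        hi = {"bmi": 45.0, "wc": 130.0, "whr": 1.30}[idx]
        adiposity[idx] = np.clip(values, lo, hi)

    g_high = genotype_high_indicator(genotypes[config.disease_snp], config.genotype_high)
    e_high = (
        adiposity[config.disease_index] >= BINARY_CUTOFFS[config.disease_index]
    ).astype(np.int8)

    eta = np.full(n, logit(config.baseline_risk))
    eta += np.log(config.or_geno) * ((g_high == 1) & (e_high == 0))
    eta += np.log(config.or_env) * ((g_high == 0) & (e_high == 1))
    eta += np.log(config.or_joint) * ((g_high == 1) & (e_high == 1))
    if cs.disease_log_or:
        derived = {
            "family_history": family_history,
            "hormone_drugs": hormone_drugs,
            "education_low": (education == EDUCATION_LEVELS[0]).astype(float),
            "income_z": income_z,
            "age_z": (age - cs.age_mean) / cs.age_sd,
        }
        for name, beta in cs.disease_log_or.items():
            eta += beta * derived[name]
    case_status = (rng.random(n) < expit(eta)).astype(np.int8)

    df = pd.DataFrame(
        {
            "id": [f"S{i:07d}" for i in range(n)],
            "case_status": case_status,
            "age": age,
            "education": education,
            "marital": marital,
            "residence": residence,
            "income": income,
            "family_history": family_history,
            "hormone_drugs": hormone_drugs,
            "oral_contraceptive": oral_contraceptive,
            "age_menarche": age_menarche,
            "menopause": menopause,
            "exercise": exercise,
            "bmi": adiposity["bmi"],
            "wc": adiposity["wc"],
            "whr": adiposity["whr"],
        }
    )
    for snp in snps:
        df[snp] = genotypes[snp]
    return df


@dataclass
class SamplingReport:
    """Accounting of frequency-matched control selection."""

    anchor_age: float
    band_years: int
    bands: pd.DataFrame  # columns: band, age_lo, age_hi, cases, requested, drawn
    total_cases: int
    total_controls_requested: int
    total_controls_drawn: int
    refilled: int  # controls drawn outside their proportional band

    @property
    def shortfall(self) -> int:
        return self.total_controls_requested - self.total_controls_drawn


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation proportional to ``weights`` summing to ``total``."""
    if total <= 0 or weights.sum() == 0:
        return np.zeros_like(weights, dtype=int)
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    if rem > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:rem]] += 1
    return base


def sample_case_control(
    population: pd.DataFrame,
    control_ratio: float = 1.0,
    matching_band_years: int = 5,
    rng: np.random.Generator | int | None = None,
    target_cases: int | None = None,
) -> tuple[pd.DataFrame, SamplingReport]:
    """Draw a frequency-matched case-control sample from a population.

    All cases are retained (optionally thinned to ``target_cases``), then
    controls are drawn without replacement so that, within half-open age
    bands ``[anchor + k*w, anchor + (k+1)*w)`` anchored at the minimum case
    age, control counts are proportional to case counts times
    ``control_ratio`` (largest-remainder rounding). If a band has too few
    controls the remainder is refilled from neighbouring bands (best effort)
    and the event is recorded in the returned :class:`SamplingReport`.
    """
    rng = _as_rng(rng)
    if matching_band_years <= 0:
        raise ConfigError("matching_band_years must be positive")
    cases = population[population["case_status"] == 1]
    if cases.empty:
        raise DomainError("population contains no cases")
    controls = population[population["case_status"] == 0]

    if target_cases is not None and len(cases) > target_cases:
        keep = rng.choice(len(cases), size=target_cases, replace=False)
        cases = cases.iloc[np.sort(keep)]

    anchor = float(cases["age"].min())
    w = matching_band_years

    def band_of(age: pd.Series) -> np.ndarray:
        return np.floor((age.to_numpy(dtype=float) - anchor) / w).astype(int)

    case_band = band_of(cases["age"])
    ctrl_band = band_of(controls["age"])
    bands = np.unique(case_band)
    case_counts = np.array([(case_band == b).sum() for b in bands])
    total_controls = int(round(len(cases) * control_ratio))
    alloc = _largest_remainder(case_counts.astype(float), total_controls)

    chosen: list[pd.DataFrame] = []
    drawn = np.zeros(len(bands), dtype=int)
    available = []
    for i, b in enumerate(bands):
        pool = controls[ctrl_band == b]
        available.append(pool)
        take = min(alloc[i], len(pool))
        if take > 0:
            sel = rng.choice(len(pool), size=take, replace=False)
            chosen.append(pool.iloc[np.sort(sel)])
        drawn[i] = take

    shortfall = int((alloc - drawn).sum())
    refilled = 0
    if shortfall > 0:
        warnings.warn(
            f"{shortfall} matched controls unavailable in their age bands; "
            "refilling from remaining controls",
            stacklevel=2,
        )
        used = pd.concat(chosen).index if chosen else pd.Index([])
        spare = controls[~controls.index.isin(used)]
        # prefer controls inside any case band, closest bands first
        spare_band = band_of(spare["age"])
        in_band = spare[np.isin(spare_band, bands)]
        pool = in_band if len(in_band) >= shortfall else spare
        take = min(shortfall, len(pool))
        if take > 0:
            sel = rng.choice(len(pool), size=take, replace=False)
            chosen.append(pool.iloc[np.sort(sel)])
            refilled = take

    sample = pd.concat([cases] + chosen) if chosen else cases.copy()
    sample = sample.sort_values("id", kind="stable").reset_index(drop=True)
    sample["age_band"] = np.floor(
        (sample["age"].to_numpy(dtype=float) - anchor) / w
    ).astype(int)

    report = SamplingReport(
        anchor_age=anchor,
        band_years=w,
        bands=pd.DataFrame(
            {
                "band": bands,
                "age_lo": anchor + bands * w,
                "age_hi": anchor + (bands + 1) * w,
                "cases": case_counts,
                "requested": alloc,
                "drawn": drawn,
            }
        ),
        total_cases=len(cases),
        total_controls_requested=total_controls,
        total_controls_drawn=int(drawn.sum()) + refilled,
        refilled=refilled,
    )
    return sample, report


def inject_missingness(
    records: pd.DataFrame,
    rates: Mapping[str, float],
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Independently mask each maskable field at its configured rate.

    ``id`` and ``case_status`` can never be masked; a positive rate for
    either is a configuration error. Returns a copy.
    """
    rng = _as_rng(rng)
    out = records.copy()
    for field_name in sorted(rates):
        rate = rates[field_name]
        if not 0.0 <= rate <= 1.0:
            raise ConfigError(f"missing rate for {field_name!r} outside [0, 1]")
        if field_name in _NEVER_MISSING:
            if rate > 0:
                raise ConfigError(f"{field_name!r} may never be masked")
            continue
        if field_name not in out.columns:
            raise ConfigError(f"unknown field {field_name!r}")
        if rate == 0.0:
            continue
        mask = rng.random(len(out)) < rate
        if out[field_name].dtype.kind in "iub":
            out[field_name] = out[field_name].astype("Float64")
        out.loc[mask, field_name] = pd.NA
    return out


def simulate_cohort(
    config: SimulationConfig,
    missing_rates: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, SamplingReport]:
    """Generate a population and draw the matched case-control sample."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pop = generate_population(config, rng=rng)
    sample, report = sample_case_control(
        pop,
        control_ratio=config.control_ratio,
        matching_band_years=config.matching_band_years,
        rng=rng,
        target_cases=config.target_cases,
    )
    if missing_rates:
        sample = inject_missingness(sample, missing_rates, rng=rng)
    return sample, report


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write the cohort CSV: fixed core header, genotype/extra columns after,
    missing values as empty fields."""
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    cols = [c for c in COHORT_COLUMNS if c in df.columns] + extra
    df.to_csv(path, index=False, columns=cols, na_rep="")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort` (or the same dialect)."""
    df = pd.read_csv(path, dtype={"id": str})
    for col in df.columns:
        if col in ("case_status",):
            df[col] = df[col].astype(np.int8)
    return df


def sampling_report_dict(report: SamplingReport) -> dict:
    """JSON-serialisable form of a sampling report."""
    d = dataclasses.asdict(report)
    d["bands"] = report.bands.to_dict(orient="records")
    d["shortfall"] = report.shortfall
    return d
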