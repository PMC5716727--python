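"""Configuration objects for the cohort simulator and the study pipeline.

Both configurations map one-to-one onto a YAML/JSON document so that the CLI
(``gxepi simulate --config ...``) and library users share a single schema.
Defaults reproduce the structure of a population-based breast-cancer
case-control study in Chinese women: three biallelic SNPs in Hardy-Weinberg
equilibrium with control-derived minor-allele frequencies, Chinese-guideline
adiposity categories, ~818 cases frequency-matched to ~935 controls within
5-year age bands, and a logistic disease model with configurable
genotype-only / adiposity-only / joint odds ratios.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from ._util import ConfigError

#: Control-derived minor-allele frequencies (allele counting on control
#: genotype distributions: rasa2 502/365/51, cadm1 470/381/74,
#: hif1an 428/381/114).
DEFAULT_ALLELE_FREQ: dict[str, float] = {
    "rasa2": 0.2544,
    "cadm1": 0.2859,
    "hif1an": 0.3299,
}

#: Control prevalence of the "high" binary category for each adiposity index
#: (BMI >= 24 kg/m2, WC >= 80 cm, WHR >= 0.85).
DEFAULT_ADIPOSITY_PREVALENCE: dict[str, float] = {
    "bmi": 0.48,
    "wc": 0.62,
    "whr": 0.55,
}

#: Binary "high adiposity" cutoffs (Chinese guideline BMI, WHO WC/WHR).
BINARY_CUTOFFS: dict[str, float] = {"bmi": 24.0, "wc": 80.0, "whr": 0.85}

#: Marginal SD of each continuous adiposity index in the generator.
ADIPOSITY_SD: dict[str, float] = {"bmi": 3.3, "wc": 9.0, "whr": 0.06}

EDUCATION_LEVELS = ("primary_or_less", "junior_high", "senior_or_above")
MARITAL_LEVELS = ("unmarried", "married", "widowed_divorced")
RESIDENCE_LEVELS = ("rural", "urban")
MENOPAUSE_LEVELS = ("pre", "post")

#: Derived covariates that may carry a direct log-odds effect on disease in
#: the generative model (keys of ``ConfounderSpec.disease_log_or``).
DISEASE_EFFECT_COVARIATES = (
    "family_history",
    "hormone_drugs",
    "education_low",   # indicator of primary_or_less
    "income_z",        # standardised log income
    "age_z",           # standardised age
)


@dataclass
class ConfounderSpec:
    """Distributions of the non-exposure covariates.

    Location/scale defaults are calibrated to the control arm of the study
    population (mean age 54.3 y, mean income ~24.8k with SD ~22.6k, 5.6%
    first-degree family history, ...). ``adiposity_education_shift`` and
    ``adiposity_income_slope`` tilt the latent adiposity score so that lower
    socio-economic position carries more central/overall adiposity;
    ``disease_log_or`` adds direct covariate effects to the disease model
    (empty by default, so the configured exposure ORs are exactly the
    marginal ORs of the generated population).
    """

    age_mean: float = 54.3
    age_sd: float = 11.2
    age_min: float = 25.0
    age_max: float = 85.0
    education_probs: tuple[float, float, float] = (0.244, 0.366, 0.390)
    marital_probs: tuple[float, float, float] = (0.010, 0.909, 0.081)
    urban_prob: float = 0.552
    income_log_mean: float = 9.82
    income_log_sd: float = 0.78
    family_history_prob: float = 0.056
    hormone_drugs_prob: float = 0.038
    oral_contraceptive_prob: float = 0.178
    age_menarche_mean: float = 15.64
    age_menarche_sd: float = 1.9
    menopause_age_mean: float = 49.5
    menopause_age_sd: float = 3.0
    exercise_probs: tuple[float, ...] = (0.231, 0.254, 0.236, 0.279)
    adiposity_education_shift: float = 0.15
    adiposity_income_slope: float = -0.10
    adiposity_latent_corr: float = 0.70
    disease_log_or: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # YAML round trips deserialize tuples as lists; normalise
        for name in ("education_probs", "marital_probs", "exercise_probs"):
            setattr(self, name, tuple(getattr(self, name)))

    def validate(self) -> None:
        for name in ("education_probs", "marital_probs", "exercise_probs"):
            p = getattr(self, name)
            if any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-6:
                raise ConfigError(f"{name} must be non-negative and sum to 1")
        for name in (
            "urban_prob",
            "family_history_prob",
            "hormone_drugs_prob",
            "oral_contraceptive_prob",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        if not -1.0 < self.adiposity_latent_corr < 1.0:
            raise ConfigError("adiposity_latent_corr must lie in (-1, 1)")
        unknown = set(self.disease_log_or) - set(DISEASE_EFFECT_COVARIATES)
        if unknown:
            raise ConfigError(
                f"unknown disease_log_or covariates: {sorted(unknown)}; "
                f"allowed: {DISEASE_EFFECT_COVARIATES}"
            )


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-cohort generator.

    The disease model is logistic on the population: with G the configured
    genotype group (``genotype_high`` coding of ``disease_snp``) and E the
    high category of ``disease_index``,

        logit P(case) = logit(baseline_risk)
                        + ln(or_geno)  * 1[G, not E]
                        + ln(or_env)   * 1[not G, E]
                        + ln(or_joint) * 1[G, E]
                        + confounder effects (default none).

    An additive-null configuration satisfies
    ``or_joint == or_geno + or_env - 1``.
    """

    n_population: int = 30_000
    allele_freq: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ALLELE_FREQ)
    )
    adiposity_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ADIPOSITY_PREVALENCE)
    )
    baseline_risk: float = 0.05
    or_geno: float = 1.5
    or_env: float = 2.0
    or_joint: float = 2.5
    disease_snp: str = "rasa2"
    genotype_high: str = "dominant"  # "dominant" | "recessive" | "homozygous"
    disease_index: str = "bmi"
    confounders: ConfounderSpec = field(default_factory=ConfounderSpec)
    matching_band_years: int = 5
    control_ratio: float = 935.0 / 818.0
    target_cases: int | None = 818
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.confounders, Mapping):
            self.confounders = ConfounderSpec(**self.confounders)

    def validate(self) -> None:
        if self.n_population < 0:
            raise ConfigError("n_population must be non-negative")
        if not self.allele_freq:
            raise ConfigError("allele_freq must name at least one SNP")
        for snp, q in self.allele_freq.items():
            if not 0.0 <= q <= 1.0:
                raise ConfigError(f"allele_freq[{snp!r}]={q} outside [0, 1]")
        for idx, p in self.adiposity_prevalence.items():
            if idx not in BINARY_CUTOFFS:
                raise ConfigError(f"unknown adiposity index {idx!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"adiposity_prevalence[{idx!r}]={p} outside [0, 1]")
        if not 0.0 < self.baseline_risk < 1.0:
            raise ConfigError("baseline_risk must lie strictly in (0, 1)")
        for name in ("or_geno", "or_env", "or_joint"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.disease_snp not in self.allele_freq:
            raise ConfigError(f"disease_snp {self.disease_snp!r} not in allele_freq")
        if self.disease_index not in self.adiposity_prevalence:
            raise ConfigError(
                f"disease_index {self.disease_index!r} not in adiposity_prevalence"
            )
        if self.genotype_high not in ("dominant", "recessive", "homozygous"):
            raise ConfigError("genotype_high must be dominant/recessive/homozygous")
        if self.matching_band_years <= 0:
            raise ConfigError("matching_band_years must be a positive integer")
        if self.control_ratio <= 0:
            raise ConfigError("control_ratio must be positive")
        if self.target_cases is not None and self.target_cases <= 0:
            raise ConfigError("target_cases must be positive when given")
        self.confounders.validate()

    @property
    def is_additive_null(self) -> bool:
        return abs(self.or_joint - (self.or_geno + self.or_env - 1.0)) < 1e-12

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SimulationConfig keys: {sorted(unknown)}")
        cfg = cls(**dict(d))
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load from a YAML or JSON file (YAML is a JSON superset)."""
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text) or {})

    def to_file(self, path: str | Path) -> None:
        p = Path(path)
        d = self.to_dict()
        if p.suffix == ".json":
            p.write_text(json.dumps(d, indent=2))
        else:
            p.write_text(yaml.safe_dump(d, sort_keys=False))


#: Fine (table-style) adiposity categories; each list is the ascending cut
#: points, categories are [cut_i, cut_{i+1}). Underweight is merged into the
#: normal BMI group, so the BMI scale starts at "<24".
FINE_CUTOFFS: dict[str, list[float]] = {
    "bmi": [24.0, 28.0],
    "wc": [80.0, 90.0],
    "whr": [0.80, 0.85, 0.90],
}

#: Genotype grouping used in the joint-effect tables: RASA2 minor-allele
#: carriers high; CADM1 heterozygote-reference (homozygotes high); HIF1AN
#: minor-allele carriers high.
DEFAULT_GENOTYPE_GROUPING: dict[str, str] = {
    "rasa2": "dominant",
    "cadm1": "homozygous",
    "hif1an": "dominant",
}

#: Allele labels (major, minor) used only for rendering genotype rows.
DEFAULT_ALLELES: dict[str, tuple[str, str]] = {
    "rasa2": ("G", "T"),
    "cadm1": ("A", "G"),
    "hif1an": ("T", "C"),
}


@dataclass
class StudyConfig:
    """Configuration of the full study analysis pipeline."""

    input: str | None = None
    output_dir: str | None = None
    snps: list[str] = field(default_factory=lambda: list(DEFAULT_ALLELE_FREQ))
    fine_cutoffs: dict[str, list[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in FINE_CUTOFFS.items()}
    )
    binary_cutoffs: dict[str, float] = field(
        default_factory=lambda: dict(BINARY_CUTOFFS)
    )
    genotype_grouping: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE_GROUPING)
    )
    alleles: dict[str, tuple[str, str]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_ALLELES.items()}
    )
    adjustments: list[str] = field(default_factory=lambda: ["model1", "model2"])
    stratify: str | None = "menopause"
    interaction_adjustment: str = "model2"
    seed: int = 0

    def validate(self) -> None:
        for idx, cuts in self.fine_cutoffs.items():
            if sorted(cuts) != list(cuts) or len(set(cuts)) != len(cuts):
                raise ConfigError(f"fine_cutoffs[{idx!r}] must be strictly increasing")
        for snp, g in self.genotype_grouping.items():
            if g not in ("dominant", "recessive", "homozygous"):
                raise ConfigError(f"genotype_grouping[{snp!r}]={g!r} invalid")

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown StudyConfig keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.alleles:
            cfg.alleles = {k: tuple(v) for k, v in cfg.alleles.items()}
        cfg.validate()
        return cfg
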