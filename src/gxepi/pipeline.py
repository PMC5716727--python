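"""Configuration-driven study analysis: the full table set in one call.

``run_study`` takes a cohort table and a :class:`~gxepi.config.StudyConfig`
and emits the complete analysis bundle: case/control descriptives,
adiposity-category and genotype odds ratios under the Model 1 / Model 2
adjustment sets (overall and stratified by menopausal status, with trend
tests), and joint-effect interaction tables (RERI/AP/S/ROR with
delta-method CIs) for every SNP x adiposity-index pair. Also houses the
recruitment-accounting helpers and printed-table rendering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import ConfigError, DomainError, EstimationError, round_half_up
from .config import StudyConfig
from .interaction import JointCoding, JointEffectModel
from .logistic import LogisticModel, ModelSpec, Term, adjusted_or, trend_test
from .tables import describe_cohort

__all__ = [
    "RecruitmentLedger",
    "response_rate",
    "categorize",
    "run_study",
    "StudyReport",
    "render_tables",
]

_DESCRIBE_VARS = [
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
]


@dataclass(frozen=True)
class RecruitmentLedger:
    """Study-accounting counts from identification to analysis."""

    identified_cases: int
    selected_controls: int
    recruited_cases: int
    recruited_controls: int
    analyzed_cases: int
    analyzed_controls: int

    def __post_init__(self) -> None:
        if min(
            self.identified_cases,
            self.selected_controls,
            self.recruited_cases,
            self.recruited_controls,
            self.analyzed_cases,
            self.analyzed_controls,
        ) < 0:
            raise DomainError("ledger counts must be non-negative")
        if not (self.analyzed_cases <= self.recruited_cases <= self.identified_cases):
            raise DomainError("cases must satisfy analyzed <= recruited <= identified")
        if not (
            self.analyzed_controls <= self.recruited_controls <= self.selected_controls
        ):
            raise DomainError("controls must satisfy analyzed <= recruited <= selected")

    @property
    def case_response_rate(self) -> float:
        return response_rate(self.recruited_cases, self.identified_cases)

    @property
    def control_response_rate(self) -> float:
        return response_rate(self.recruited_controls, self.selected_controls)


def response_rate(recruited: int, eligible: int) -> float:
    """Response rate 100*recruited/eligible, half-up to one decimal."""
    if eligible <= 0:
        raise DomainError("eligible must be positive")
    if recruited > eligible:
        raise DomainError("recruited cannot exceed eligible")
    return round_half_up(100.0 * recruited / eligible, 1)


def categorize(values: pd.Series, cutoffs: Sequence[float]) -> pd.Series:
    """Bin a continuous index into ordered categories at the given ascending
    cut points; labels are "<c0", "c0-", ..., ">=c_last". Missing stays
    missing."""
    if sorted(cutoffs) != list(cutoffs):
        raise ConfigError("cutoffs must be strictly increasing")
    labels = [f"<{cutoffs[0]:g}"]
    labels += [f"{c:g}-" for c in cutoffs[:-1]]
    labels += [f">={cutoffs[-1]:g}"]
    edges = [-np.inf, *cutoffs, np.inf]
    out = pd.cut(values.astype(float), bins=edges, labels=labels, right=False)
    return out.astype(object).where(values.notna())


@dataclass
class StudyReport:
    """Bundle of analysis tables plus the run log."""

    descriptives: pd.DataFrame
    adiposity_or: pd.DataFrame
    genotype_or: pd.DataFrame
    interaction: pd.DataFrame
    run_log: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.descriptives.to_csv(out / "descriptives.csv", index=False)
        self.adiposity_or.to_csv(out / "adiposity_or.csv", index=False)
        self.genotype_or.to_csv(out / "genotype_or.csv", index=False)
        self.interaction.to_csv(out / "interaction.csv", index=False)
        (out / "run_log.json").write_text(json.dumps(self.run_log, indent=2))
        for name, text in render_tables(self).items():
            (out / f"{name}.txt").write_text(text)


def _strata(df: pd.DataFrame, stratify: str | None):
    yield "all", df
    if stratify and stratify in df.columns:
        for level in sorted(df[stratify].dropna().unique(), key=str):
            yield str(level), df[df[stratify] == level]


def _or_rows_for_exposure(
    df: pd.DataFrame,
    exposure_col: str,
    levels: list[str],
    adjustments: list[str],
    stratify: str | None,
    run_log: list[dict],
    exposure_label: str,
) -> list[dict]:
    rows: list[dict] = []
    for stratum, sub in _strata(df, stratify):
        observed = [lv for lv in levels if (sub[exposure_col] == lv).any()]
        if len(observed) < 2:
            run_log.append(
                {"analysis": exposure_label, "stratum": stratum,
                 "skipped": "fewer than 2 observed exposure levels"}
            )
            continue
        ref = observed[0]
        counts = {
            lv: (
                int(((sub[exposure_col] == lv) & (sub.case_status == 1)).sum()),
                int(((sub[exposure_col] == lv) & (sub.case_status == 0)).sum()),
            )
            for lv in observed
        }
        for adj in adjustments:
            spec = ModelSpec(
                terms=(Term(exposure_col, "categorical", ref=ref,
                            levels=tuple(observed)),),
                adjustment=adj,
            )
            try:
                fit = LogisticModel.from_dataframe(sub, spec).fit()
            except (EstimationError, DomainError) as exc:
                run_log.append(
                    {"analysis": exposure_label, "stratum": stratum,
                     "adjustment": adj, "skipped": str(exc)}
                )
                continue
            run_log.append(
                {"analysis": exposure_label, "stratum": stratum, "adjustment": adj,
                 "n_used": fit.n_used, "dropped": fit.model.n_dropped,
                 "converged": bool(fit.converged)}
            )
            for lv in observed:
                ca, co = counts[lv]
                if lv == ref:
                    rows.append(
                        {"exposure": exposure_label, "stratum": stratum,
                         "adjustment": adj, "level": lv, "cases": ca, "controls": co,
                         "or": 1.0, "ci_low": np.nan, "ci_high": np.nan,
                         "referent": True}
                    )
                    continue
                res = adjusted_or(fit, f"{exposure_col}[{lv}]")
                rows.append(
                    {"exposure": exposure_label, "stratum": stratum,
                     "adjustment": adj, "level": lv, "cases": ca, "controls": co,
                     "or": res.or_point, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "referent": False}
                )
            if len(observed) >= 3:
                try:
                    tt = trend_test(sub, exposure_col, levels=observed, adjustment=adj)
                    rows.append(
                        {"exposure": exposure_label, "stratum": stratum,
                         "adjustment": adj, "level": "p_trend", "cases": np.nan,
                         "controls": np.nan, "or": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "referent": False, "p_trend": tt.p_value}
                    )
                except (DomainError, EstimationError):
                    pass
    return rows


def run_study(records: pd.DataFrame, config: StudyConfig) -> StudyReport:
    """Run the full analysis bundle on a cohort table.

    Deterministic: the report is a pure function of the input table and the
    configuration. Analyses whose stratum lacks data (e.g. an empty joint
    cell) are skipped with a logged reason rather than aborting the run.
    """
    config.validate()
    if (records.case_status == 1).sum() == 0 or (records.case_status == 0).sum() == 0:
        raise DomainError("need at least one case and one control")
    log: dict = {
        "n_rows": int(len(records)),
        "n_cases": int((records.case_status == 1).sum()),
        "n_controls": int((records.case_status == 0).sum()),
        "seed": config.seed,
        "fits": [],
    }

    describe_vars = [v for v in _DESCRIBE_VARS if v in records.columns]
    descriptives = describe_cohort(records, describe_vars)

    df = records.copy()
    adip_rows: list[dict] = []
    for idx, cuts in config.fine_cutoffs.items():
        if idx not in df.columns:
            continue
        col = f"{idx}_cat"
        df[col] = categorize(df[idx], cuts)
        levels = [f"<{cuts[0]:g}"] + [f"{c:g}-" for c in cuts[:-1]] + [f">={cuts[-1]:g}"]
        adip_rows += _or_rows_for_exposure(
            df, col, levels, config.adjustments, config.stratify, log["fits"], idx
        )

    geno_rows: list[dict] = []
    for snp in config.snps:
        if snp not in df.columns:
            continue
        maj, mnr = config.alleles.get(snp, ("A", "B"))
        label = {0: f"{maj}/{maj}", 1: f"{maj}/{mnr}", 2: f"{mnr}/{mnr}"}
        col = f"{snp}_geno"
        df[col] = df[snp].map(label)
        geno_rows += _or_rows_for_exposure(
            df, col, [label[0], label[1], label[2]], config.adjustments,
            config.stratify, log["fits"], snp,
        )
        # dominant (carrier) contrast as its own binary fit
        dom_col = f"{snp}_dom"
        df[dom_col] = df[snp].map(
            {0: label[0], 1: f"{label[1]}+{label[2]}", 2: f"{label[1]}+{label[2]}"}
        )
        geno_rows += _or_rows_for_exposure(
            df, dom_col, [label[0], f"{label[1]}+{label[2]}"], config.adjustments,
            config.stratify, log["fits"], f"{snp}_dominant",
        )

    inter_rows: list[dict] = []
    for snp in config.snps:
        if snp not in df.columns:
            continue
        for idx, cutoff in config.binary_cutoffs.items():
            if idx not in df.columns:
                continue
            coding = JointCoding(
                snp=snp, grouping=config.genotype_grouping.get(snp, "dominant"),
                index=idx, cutoff=cutoff,
            )
            try:
                res = JointEffectModel(
                    df, coding, adjustment=config.interaction_adjustment
                ).fit()
            except (EstimationError, DomainError) as exc:
                log["fits"].append(
                    {"analysis": f"joint:{snp}x{idx}", "skipped": str(exc)}
                )
                continue
            log["fits"].append(
                {"analysis": f"joint:{snp}x{idx}", "n_used": res.fit.n_used,
                 "converged": bool(res.fit.converged)}
            )
            m = res.measures
            cells = res.cells.set_index("cell")
            inter_rows.append(
                {
                    "snp": snp, "adiposity_index": idx,
                    "coding": coding.grouping, "cutoff": cutoff,
                    "ref_cases": cells.loc["reference", "cases"],
                    "ref_controls": cells.loc["reference", "controls"],
                    "g_cases": cells.loc["g_only", "cases"],
                    "g_controls": cells.loc["g_only", "controls"],
                    "e_cases": cells.loc["e_only", "cases"],
                    "e_controls": cells.loc["e_only", "controls"],
                    "joint_cases": cells.loc["joint", "cases"],
                    "joint_controls": cells.loc["joint", "controls"],
                    "or10": m.or10.value, "or01": m.or01.value, "or11": m.or11.value,
                    "reri": m.reri.value, "reri_lo": m.reri.ci_low,
                    "reri_hi": m.reri.ci_high,
                    "ap": m.ap.value, "ap_lo": m.ap.ci_low, "ap_hi": m.ap.ci_high,
                    "s": m.s.value, "s_lo": m.s.ci_low, "s_hi": m.s.ci_high,
                    "s_defined": m.s_defined,
                    "ror": m.ror.value, "ror_lo": m.ror.ci_low,
                    "ror_hi": m.ror.ci_high,
                }
            )

    return StudyReport(
        descriptives=descriptives,
        adiposity_or=pd.DataFrame(adip_rows),
        genotype_or=pd.DataFrame(geno_rows),
        interaction=pd.DataFrame(inter_rows),
        run_log=log,
    )


def _fmt_or(or_point, lo, hi, referent=False) -> str:
    if referent:
        return "1.00 (referent)"
    if or_point is None or (isinstance(or_point, float) and np.isnan(or_point)):
        return "—"
    return (
        f"{round_half_up(or_point, 2):.2f} "
        f"({round_half_up(lo, 2):.2f}–{round_half_up(hi, 2):.2f})"
    )


def render_tables(report: StudyReport) -> dict[str, str]:
    """Render the bundle as fixed-layout text tables.

    Odds ratios print to two decimals (half-up), percentages to one; the
    reference row prints "1.00 (referent)" and empty cells print an em dash.
    """
    out: dict[str, str] = {}

    lines = [f"{'variable':<20}{'level':<22}{'cases':>14}{'controls':>14}{'p':>10}"]
    for _, r in report.descriptives.iterrows():
        if r["level"] == "mean_sd":
            ca = f"{r['cases_n']:.2f} ± {r['cases_pct']:.2f}"
            co = f"{r['controls_n']:.2f} ± {r['controls_pct']:.2f}"
        else:
            ca = f"{int(r['cases_n'])} ({r['cases_pct']:.1f})"
            co = f"{int(r['controls_n'])} ({r['controls_pct']:.1f})"
        p = "" if pd.isna(r["p"]) else f"{r['p']:.3f}"
        lines.append(f"{r['variable']:<20}{r['level']:<22}{ca:>14}{co:>14}{p:>10}")
    out["table_descriptives"] = "\n".join(lines)

    for name, frame in (
        ("table_adiposity", report.adiposity_or),
        ("table_genotype", report.genotype_or),
    ):
        lines = [
            f"{'exposure':<16}{'stratum':<10}{'model':<8}{'level':<14}"
            f"{'Case/Ctrl':>12}  OR (95% CI)"
        ]
        if not frame.empty:
            for _, r in frame.iterrows():
                if r["level"] == "p_trend":
                    lines.append(
                        f"{r['exposure']:<16}{r['stratum']:<10}{r['adjustment']:<8}"
                        f"{'P for trend':<14}{'':>12}  {r.get('p_trend', np.nan):.3f}"
                    )
                    continue
                cc = f"{int(r['cases'])}/{int(r['controls'])}"
                lines.append(
                    f"{r['exposure']:<16}{r['stratum']:<10}{r['adjustment']:<8}"
                    f"{str(r['level']):<14}{cc:>12}  "
                    f"{_fmt_or(r['or'], r['ci_low'], r['ci_high'], r['referent'])}"
                )
        out[name] = "\n".join(lines)

    lines = []
    for _, r in (report.interaction if not report.interaction.empty else pd.DataFrame()).iterrows():
        lines += [
            f"{r['snp']} ({r['coding']}) x {r['adiposity_index']} >= {r['cutoff']:g}",
            f"  reference {int(r['ref_cases'])}/{int(r['ref_controls'])}  1.00 (referent)",
            f"  genotype  {int(r['g_cases'])}/{int(r['g_controls'])}  "
            + _fmt_or(r["or10"], np.nan, np.nan).split(" ")[0],
            f"  adiposity {int(r['e_cases'])}/{int(r['e_controls'])}  "
            + _fmt_or(r["or01"], np.nan, np.nan).split(" ")[0],
            f"  joint     {int(r['joint_cases'])}/{int(r['joint_controls'])}  "
            + _fmt_or(r["or11"], np.nan, np.nan).split(" ")[0],
            "  Additive:       RERI = "
            + _fmt_or(r["reri"], r["reri_lo"], r["reri_hi"]),
            "                  AP = " + _fmt_or(r["ap"], r["ap_lo"], r["ap_hi"]),
            "                  S = "
            + (_fmt_or(r["s"], r["s_lo"], r["s_hi"]) if r["s_defined"] else "—"),
            "  Multiplicative: ROR = "
            + _fmt_or(r["ror"], r["ror_lo"], r["ror_hi"]),
        ]
    out["table_interaction"] = "\n".join(lines)
    return out
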