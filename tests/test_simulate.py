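"""Synthetic-cohort generator: genotypes, disease model, matching, missingness."""

import io

import numpy as np
import pandas as pd
import pytest

from gxepi import (
    GenotypeCounts,
    SimulationConfig,
    assign_genotypes,
    disease_probability,
    generate_population,
    hwe_test,
    inject_missingness,
    sample_case_control,
    simulate_cohort,
    write_cohort,
)
from gxepi._util import ConfigError, DomainError
from gxepi.simulate import MissingCovariateError
from gxepi.tables import chi_square_test


class TestAssignGenotypes:
    def test_zero_frequency(self):
        assert (assign_genotypes(0.0, 100, rng=0) == 0).all()

    def test_hwe_proportions_at_half(self):
        g = assign_genotypes(0.5, 1_000_000, rng=1)
        props = np.bincount(g, minlength=3) / len(g)
        # 3 Monte-Carlo SEs of a binomial proportion at n=1e6
        for p, expected in zip(props, (0.25, 0.5, 0.25)):
            se = np.sqrt(expected * (1 - expected) / 1e6)
            assert abs(p - expected) < 3 * se

    def test_minor_homozygote_rate_control_maf(self):
        # control minor-allele frequency implied by genotype counts 502/365/51
        g = assign_genotypes(0.2544, 1_000_000, rng=2)
        p_hom = (g == 2).mean()
        se = np.sqrt(0.0647 * (1 - 0.0647) / 1e6)
        assert p_hom == pytest.approx(0.0647, abs=3 * se + 1e-4)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            assign_genotypes(1.2, 10)


class TestDiseaseProbability:
    def test_logistic_symmetry(self):
        assert disease_probability({}, {"intercept": 0.0}) == 0.5

    def test_baseline_risk(self):
        p = disease_probability({}, {"intercept": np.log(0.05 / 0.95)})
        assert p == pytest.approx(0.05, rel=1e-12)

    def test_odds_doubling(self):
        coef = {"intercept": np.log(0.05 / 0.95), "exposed": np.log(2.0)}
        p = disease_probability({"exposed": 1}, coef)
        assert p == pytest.approx(2 / 21, rel=1e-12)  # odds 0.05/0.95 doubled

    def test_missing_covariate(self):
        with pytest.raises(MissingCovariateError):
            disease_probability({}, {"intercept": 0.0, "exposed": 1.0})


class TestGeneratePopulation:
    def test_empty_population(self):
        cfg = SimulationConfig(n_population=0)
        assert len(generate_population(cfg)) == 0

    def test_degenerate_baseline(self):
        with pytest.raises(ConfigError):
            SimulationConfig(baseline_risk=1.0).validate()

    @staticmethod
    def _cell_ors(pop, snp, coding, index, cutoff):
        from gxepi.simulate import genotype_high_indicator

        g = genotype_high_indicator(pop[snp].to_numpy(), coding)
        e = (pop[index] >= cutoff).astype(int).to_numpy()
        y = pop.case_status.to_numpy()

        def odds(mask):
            return ((y == 1) & mask).sum() / ((y == 0) & mask).sum()

        ref = odds((g == 0) & (e == 0))
        return (
            odds((g == 1) & (e == 0)) / ref,
            odds((g == 0) & (e == 1)) / ref,
            odds((g == 1) & (e == 1)) / ref,
        )

    def test_null_model_cell_ors(self):
        cfg = SimulationConfig(
            n_population=200_000, or_geno=1.0, or_env=1.0, or_joint=1.0, seed=11
        )
        pop = generate_population(cfg)
        ors = self._cell_ors(pop, "rasa2", "dominant", "bmi", 24.0)
        for o in ors:
            assert o == pytest.approx(1.0, abs=0.10)

    def test_additive_null_population_reri(self):
        # exhaustive cell counting is the oracle: with or_joint = or_geno +
        # or_env - 1 the population RERI is 0 up to Monte-Carlo error
        cfg = SimulationConfig(n_population=200_000, seed=12)
        assert cfg.is_additive_null
        pop = generate_population(cfg)
        o10, o01, o11 = self._cell_ors(pop, "rasa2", "dominant", "bmi", 24.0)
        assert o11 - o10 - o01 + 1 == pytest.approx(0.0, abs=0.15)

    def test_configured_or_recovery_in_population(self):
        cfg = SimulationConfig(n_population=400_000, seed=13)
        pop = generate_population(cfg)
        o10, o01, o11 = self._cell_ors(pop, "rasa2", "dominant", "bmi", 24.0)
        assert o10 == pytest.approx(1.5, abs=0.08)
        assert o01 == pytest.approx(2.0, abs=0.10)
        assert o11 == pytest.approx(2.5, abs=0.13)

    def test_control_genotypes_in_hwe(self):
        # generated control genotypes should pass the HWE test in ~95% of
        # replicates at alpha = 0.05
        rng = np.random.default_rng(5)
        passes = 0
        n_rep = 100
        for _ in range(n_rep):
            g = rng.binomial(2, 0.2544, size=1500)
            counts = np.bincount(g, minlength=3)
            if hwe_test(GenotypeCounts(*counts)).p_value > 0.05:
                passes += 1
        assert passes >= 90


class TestSampleCaseControl:
    def test_single_band(self):
        rng = np.random.default_rng(0)
        pop = pd.DataFrame(
            {
                "id": [f"S{i}" for i in range(300)],
                "case_status": [1] * 50 + [0] * 250,
                # ample controls inside the cases' single [52, 57) band
                "age": [52.0] * 50
                + list(rng.uniform(52, 56.9, 150))
                + list(rng.uniform(30, 50, 100)),
            }
        )
        sample, report = sample_case_control(pop, control_ratio=1.0, rng=1)
        ctrl = sample[sample.case_status == 0]
        assert ((ctrl.age >= 52) & (ctrl.age < 57)).all()
        assert report.shortfall == 0

    def test_rounding_bound(self):
        cfg = SimulationConfig(n_population=20_000, target_cases=None, seed=6)
        pop = generate_population(cfg)
        sample, report = sample_case_control(pop, control_ratio=1.0, rng=2)
        n_cases = (sample.case_status == 1).sum()
        n_ctrl = (sample.case_status == 0).sum()
        assert abs(n_ctrl - n_cases) <= len(report.bands)

    def test_no_cases_error(self):
        pop = pd.DataFrame({"id": ["a"], "case_status": [0], "age": [50.0]})
        with pytest.raises(DomainError):
            sample_case_control(pop)

    def test_shortfall_warns_and_refills(self):
        pop = pd.DataFrame(
            {
                "id": [f"S{i}" for i in range(40)],
                "case_status": [1] * 20 + [0] * 20,
                "age": [50.0] * 20 + [50.0] * 5 + [70.0] * 15,
            }
        )
        with pytest.warns(UserWarning, match="refilling"):
            sample, report = sample_case_control(pop, control_ratio=1.0, rng=3)
        assert report.refilled > 0
        assert (sample.case_status == 0).sum() == 20

    def test_age_band_distributions_match(self):
        # frequency matching should leave case/control age-band distributions
        # statistically indistinguishable in nearly all replicates
        cfg = SimulationConfig(n_population=12_000, target_cases=500, seed=0)
        ok = 0
        n_rep = 100
        for i in range(n_rep):
            rng = np.random.default_rng(1000 + i)
            pop = generate_population(cfg, rng=rng)
            sample, _ = sample_case_control(
                pop, control_ratio=1.0, rng=rng, target_cases=500
            )
            tab = (
                sample.groupby(["case_status", "age_band"]).size().unstack(fill_value=0)
            )
            p = chi_square_test(tab.to_numpy()).p_value
            ok += p > 0.05
        assert ok >= 95


class TestInjectMissingness:
    def test_zero_rates_identity(self, study_cohort):
        out = inject_missingness(study_cohort, {"bmi": 0.0}, rng=0)
        pd.testing.assert_frame_equal(out, study_cohort)

    def test_rate_one_masks_everything(self, study_cohort):
        out = inject_missingness(study_cohort, {"marital": 1.0}, rng=0)
        assert out.marital.isna().all()

    def test_protected_fields(self, study_cohort):
        with pytest.raises(ConfigError):
            inject_missingness(study_cohort, {"case_status": 0.1})

    def test_binomial_rate(self):
        df = pd.DataFrame(
            {"id": range(818), "case_status": 1, "marital": "married"}
        )
        out = inject_missingness(df, {"marital": 0.01}, rng=7)
        n_missing = out.marital.isna().sum()
        sd = np.sqrt(818 * 0.01 * 0.99)
        assert abs(n_missing - 8.18) <= 3 * sd


class TestDeterminism:
    def test_identical_seed_identical_bytes(self):
        cfg = SimulationConfig(n_population=5000, target_cases=200, seed=42)
        bufs = []
        for _ in range(2):
            sample, _ = simulate_cohort(cfg, missing_rates={"bmi": 0.01})
            buf = io.StringIO()
            write_cohort(sample, buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]
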