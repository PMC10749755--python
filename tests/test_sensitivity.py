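"""Measurement-error correction and sequential-mediation decomposition."""
import numpy as np
import pandas as pd
import pytest

from polymediate import (
    BootstrapSettings,
    IntermediateSpec,
    MediationError,
    MediationSpec,
    SensitivitySettings,
    SimulationConfig,
    bootstrap_mediation,
    reliability_adjusted_mediation,
    sequential_mediation,
    simulate_cohort,
)
from polymediate.mediation import prepare_analysis_frame
from polymediate.sensitivity import _eiv_outcome_coefs

FAST = BootstrapSettings(n_replicates=200, seed=0)

# raw-scale spec: the mediator keeps its measurement scale, so classical
# attenuation is exactly rho * b against a unit-variance true score
SPEC_RAW = MediationSpec("zgrs", "disinhibition", "bmi", standardize=())


def orthogonal_cohort(n, reliability, seed=31, b=0.5):
    """Mediator independent of the exposure (a_true = 0), no covariates."""
    cfg = SimulationConfig(
        n_individuals=n,
        n_variants=20,
        a_true=0.0,
        b_true=b,
        c_true=0.1,
        w_main=0.0,
        covariates=(),
        reliability=reliability,
        seed=seed,
    )
    return simulate_cohort(cfg).phenotypes


class TestReliabilityCorrection:
    def test_rho_one_is_identity(self, default_cohort, spec_age_sex):
        res = reliability_adjusted_mediation(
            default_cohort.phenotypes,
            spec_age_sex,
            SensitivitySettings(reliability=1.0),
            FAST,
        )
        for q in ("a", "b", "c_prime", "indirect", "total"):
            assert getattr(res.corrected, q) == pytest.approx(
                getattr(res.naive, q), abs=1e-10
            )
        assert res.delta_indirect == pytest.approx(0.0, abs=1e-10)

    def test_attenuation_factor_oracle(self):
        # classical error at rho = 0.8: naive slope = rho * b_true = 0.40,
        # the moment-corrected slope recovers b_true = 0.50
        pheno = orthogonal_cohort(100_000, reliability=0.8)
        res = reliability_adjusted_mediation(
            pheno, SPEC_RAW, SensitivitySettings(reliability=0.8), FAST
        )
        assert res.naive.b == pytest.approx(0.8 * 0.5, abs=0.01)
        assert res.corrected.b == pytest.approx(0.5, abs=0.01)
        # path a is untouched by the correction
        assert res.corrected.a == res.naive.a

    def test_corrected_b_matches_latent_truth_fit(self):
        # in simulation the hidden true-score column is available: the
        # corrected slope must agree with regressing on the truth directly
        pheno = orthogonal_cohort(100_000, reliability=0.8)
        res = reliability_adjusted_mediation(
            pheno, SPEC_RAW, SensitivitySettings(reliability=0.8), FAST
        )
        latent_spec = MediationSpec("zgrs", "disinhibition_true", "bmi", standardize=())
        from polymediate import fit_paths

        latent = fit_paths(pheno, latent_spec)
        assert res.corrected.b == pytest.approx(latent.b, abs=0.01)

    def test_correction_monotone_in_rho(self):
        pheno = orthogonal_cohort(20_000, reliability=0.8)
        df = prepare_analysis_frame(pheno, SPEC_RAW)
        bs = [
            abs(_eiv_outcome_coefs(df, SPEC_RAW, rho)[1])
            for rho in (1.0, 0.95, 0.9, 0.85, 0.8, 0.75)
        ]
        assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(bs, bs[1:]))

    def test_naive_and_corrected_bracket_truth_most_of_the_time(self):
        # the attenuated naive slope sits below b_true and the corrected
        # slope is centred on it, so [naive, corrected] widened by two
        # standard errors brackets the truth in nearly every replicate,
        # and on average the corrected estimate is unbiased while the
        # naive one is biased by the factor rho
        hits, naive_all, corr_all = 0, [], []
        n_rep = 30
        se = 1.0 / np.sqrt(20_000)  # upper bound on SE of the slope here
        for rep in range(n_rep):
            pheno = orthogonal_cohort(20_000, reliability=0.8, seed=600 + rep)
            df = prepare_analysis_frame(pheno, SPEC_RAW)
            naive_b = _eiv_outcome_coefs(df, SPEC_RAW, 1.0)[1]
            corr_b = _eiv_outcome_coefs(df, SPEC_RAW, 0.8)[1]
            naive_all.append(naive_b)
            corr_all.append(corr_b)
            if min(naive_b, corr_b) - 2 * se <= 0.5 <= max(naive_b, corr_b) + 2 * se:
                hits += 1
        assert hits / n_rep >= 0.9
        assert np.mean(naive_all) == pytest.approx(0.4, abs=3 * se / np.sqrt(n_rep))
        assert np.mean(corr_all) == pytest.approx(0.5, abs=3 * se / np.sqrt(n_rep))

    def test_infeasible_reliability_names_minimum(self):
        # mediator ~ 0.9 * exposure: the adjusted covariance goes singular
        # once rho < r^2 ~ 0.81
        rng = np.random.default_rng(5)
        n = 2000
        x = rng.normal(size=n)
        m = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=n)
        y = 0.3 * m + rng.normal(size=n)
        df = pd.DataFrame({"zgrs": x, "disinhibition": m, "bmi": y})
        with pytest.raises(MediationError, match="minimum feasible reliability"):
            reliability_adjusted_mediation(
                df, SPEC_RAW, SensitivitySettings(reliability=0.5), FAST
            )

    def test_delta_report_consistency(self, default_cohort, spec_age_sex):
        res = reliability_adjusted_mediation(
            default_cohort.phenotypes,
            spec_age_sex,
            SensitivitySettings(reliability=0.8),
            FAST,
        )
        assert res.delta_indirect == pytest.approx(
            res.corrected.indirect - res.naive.indirect
        )
        assert res.corrected.ci["b"][0] <= res.corrected.b <= res.corrected.ci["b"][1]

    def test_invalid_reliability_rejected(self):
        with pytest.raises(MediationError):
            SensitivitySettings(reliability=0.0).validate()
        with pytest.raises(MediationError):
            SensitivitySettings(reliability=1.0001).validate()


def sequential_chain_data(n=80, seed=2):
    """Noiseless exposure -> intermediate -> mediator -> outcome chain.

    Each link adds a component constructed exactly orthogonal (in sample)
    to everything upstream, so every equation's coefficients are exact
    while all designs stay full rank: the serial component p1 * p2 * b = 1
    and every other component is 0.
    """
    rng = np.random.default_rng(seed)

    def orthogonalize(v, basis):
        Q = np.column_stack(basis)
        return v - Q @ np.linalg.lstsq(Q, v, rcond=None)[0]

    ones = np.ones(n)
    x = orthogonalize(rng.normal(size=n), [ones])
    u1 = orthogonalize(rng.normal(size=n), [ones, x])
    i = x + u1
    u2 = orthogonalize(rng.normal(size=n), [ones, x, u1])
    m = i + u2
    y = m.copy()
    return pd.DataFrame({"x": x, "i": i, "m": m, "y": y})


class TestSequentialMediation:
    def test_noiseless_serial_chain(self):
        spec = MediationSpec("x", "m", "y", standardize=())
        res = sequential_mediation(sequential_chain_data(), spec, "i", FAST)
        assert res.components["via_both"] == pytest.approx(1.0, abs=1e-8)
        assert res.components["via_mediator"] == pytest.approx(0.0, abs=1e-8)
        assert res.components["via_intermediate"] == pytest.approx(0.0, abs=1e-8)
        assert res.components["direct"] == pytest.approx(0.0, abs=1e-8)
        assert res.total == pytest.approx(1.0, abs=1e-8)

    def test_collapses_to_plain_mediation_without_intermediate_paths(self):
        cfg = SimulationConfig(
            n_individuals=20_000,
            n_variants=20,
            intermediate=IntermediateSpec(from_exposure=0.0, to_mediator=0.0, to_outcome=0.0),
            seed=33,
        )
        pheno = simulate_cohort(cfg).phenotypes
        spec = MediationSpec(
            "zgrs", "disinhibition", "bmi", ("age", "sex"), ("age", "sex")
        )
        seq = sequential_mediation(pheno, spec, "depression", FAST)
        plain = bootstrap_mediation(pheno, spec, FAST)
        assert seq.components["via_mediator"] == pytest.approx(
            plain.indirect, abs=3 * plain.se["indirect"]
        )
        assert abs(seq.components["via_both"]) < 0.005
        assert abs(seq.components["via_intermediate"]) < 0.005

    def test_parameter_recovery_on_all_edges(self):
        inter = IntermediateSpec(from_exposure=0.2, to_mediator=0.25, to_outcome=0.15)
        cfg = SimulationConfig(
            n_individuals=5000, n_variants=20, intermediate=inter, seed=34
        )
        pheno = simulate_cohort(cfg).phenotypes
        spec = MediationSpec(
            "zgrs", "disinhibition", "bmi", ("age", "sex"), ("age", "sex")
        )
        res = sequential_mediation(
            pheno, spec, "depression", BootstrapSettings(400, seed=7)
        )
        truth = {
            "via_mediator": 0.10 * 0.43,
            "via_intermediate": 0.2 * 0.15,
            "via_both": 0.2 * 0.25 * 0.43,
            "direct": 0.16,
        }
        for comp, t in truth.items():
            assert res.components[comp] == pytest.approx(
                t, abs=3 * max(res.se[comp], 1e-3)
            ), comp

    def test_decomposition_identity_against_reduced_form(self):
        # common covariate sets: direct + all indirect components equals the
        # exposure coefficient of the reduced-form outcome regression
        rng = np.random.default_rng(35)
        n = 1500
        x = rng.normal(size=n)
        cov = rng.normal(size=n)
        i = 0.3 * x + 0.1 * cov + rng.normal(size=n)
        m = 0.2 * x + 0.4 * i + 0.1 * cov + rng.normal(size=n)
        y = 0.15 * x + 0.3 * i + 0.5 * m + 0.2 * cov + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "i": i, "m": m, "y": y, "cov": cov})
        spec = MediationSpec("x", "m", "y", ("cov",), ("cov",), standardize=())
        res = sequential_mediation(df, spec, "i", FAST)
        X = np.column_stack([np.ones(n), x, cov])
        reduced = np.linalg.lstsq(X, y, rcond=None)[0][1]
        total_decomposed = sum(res.components.values())
        assert total_decomposed == pytest.approx(reduced, abs=1e-8)
        assert res.total == pytest.approx(reduced, abs=1e-8)

    def test_intermediate_must_be_distinct(self, default_cohort, spec_age_sex):
        with pytest.raises(MediationError, match="distinct"):
            sequential_mediation(
                default_cohort.phenotypes, spec_age_sex, "disinhibition", FAST
            )
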