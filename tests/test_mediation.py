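"""Path estimation, bootstrap CIs, decomposition identities, model checks."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from polymediate import (
    BootstrapSettings,
    MediationError,
    MediationSpec,
    bootstrap_mediation,
    fit_paths,
    fit_paths_joint,
    indirect_effect,
    linearity_lrt,
    proportion_mediated,
    residual_diagnostics,
)

SPEC_PLAIN = MediationSpec("x", "m", "y")
SPEC_COVS = MediationSpec("x", "m", "y", ("c1", "c2"), ("c1", "c2"))
SPEC_RAW = MediationSpec("x", "m", "y", ("c1", "c2"), ("c1", "c2"), standardize=())


def chain_data(n=60, seed=0):
    """Deterministic chain completed through a path-a-only covariate.

    m = x + c exactly and y = m exactly, so both equations fit perfectly
    (zero residuals) while the designs stay full rank (c enters only the
    mediator equation): a=1, b=1, c'=0.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    c = rng.normal(size=n)
    m = x + c
    return pd.DataFrame({"x": x, "m": m, "y": m.copy(), "c": c})


CHAIN_SPEC = MediationSpec("x", "m", "y", ("c",), (), standardize=())


class TestFitPaths:
    def test_noiseless_chain_exact_paths(self):
        est = fit_paths(chain_data(), CHAIN_SPEC)
        assert est.a == pytest.approx(1.0, abs=1e-10)
        assert est.b == pytest.approx(1.0, abs=1e-10)
        assert est.c_prime == pytest.approx(0.0, abs=1e-10)
        assert est.indirect == pytest.approx(1.0, abs=1e-10)
        assert est.total == pytest.approx(1.0, abs=1e-10)
        assert est.proportion_mediated == pytest.approx(100.0, abs=1e-6)

    def test_ten_row_toy_table_against_normal_equations(self):
        # fixed tiny table; oracle solves the normal equations directly
        df = pd.DataFrame(
            {
                "x": [0.2, -1.1, 0.5, 1.7, -0.3, 0.9, -1.5, 0.1, 0.8, -0.6],
                "m": [0.5, -0.7, 0.1, 1.2, 0.3, 0.8, -1.1, -0.2, 0.9, -0.4],
                "y": [1.0, -0.9, 0.4, 1.5, 0.1, 1.1, -1.3, 0.2, 1.2, -0.8],
            }
        )
        spec = MediationSpec("x", "m", "y", standardize=())
        est = fit_paths(df, spec)
        Xa = np.column_stack([np.ones(10), df["x"]])
        beta_a = np.linalg.solve(Xa.T @ Xa, Xa.T @ df["m"])
        Xb = np.column_stack([np.ones(10), df["x"], df["m"]])
        beta_b = np.linalg.solve(Xb.T @ Xb, Xb.T @ df["y"])
        assert est.a == pytest.approx(beta_a[1], abs=1e-10)
        assert est.c_prime == pytest.approx(beta_b[1], abs=1e-10)
        assert est.b == pytest.approx(beta_b[2], abs=1e-10)

    def test_agrees_with_statsmodels_ols(self, random_linear_data):
        est = fit_paths(random_linear_data, SPEC_RAW)
        df = random_linear_data
        fa = sm.OLS(df["m"], sm.add_constant(df[["x", "c1", "c2"]])).fit()
        fb = sm.OLS(df["y"], sm.add_constant(df[["x", "m", "c1", "c2"]])).fit()
        assert est.a == pytest.approx(fa.params["x"], abs=1e-10)
        assert est.c_prime == pytest.approx(fb.params["x"], abs=1e-10)
        assert est.b == pytest.approx(fb.params["m"], abs=1e-10)

    def test_joint_equals_per_equation(self, random_linear_data):
        per_eq = fit_paths(random_linear_data, SPEC_COVS)
        joint = fit_paths_joint(random_linear_data, SPEC_COVS)
        for q in ("a", "b", "c_prime", "indirect", "total"):
            assert getattr(per_eq, q) == pytest.approx(getattr(joint, q), abs=1e-10)

    def test_exact_decomposition_with_common_covariates(self, random_linear_data):
        # OLS identity: coefficient of x in y ~ x + covs equals c' + a*b
        est = fit_paths(random_linear_data, SPEC_RAW)
        df = random_linear_data
        ft = sm.OLS(df["y"], sm.add_constant(df[["x", "c1", "c2"]])).fit()
        assert est.total == pytest.approx(ft.params["x"], abs=1e-12)

    def test_asymmetric_covariates_flag_refit_total(self, random_linear_data):
        spec = MediationSpec("x", "m", "y", ("c1", "c2"), ("c2",))
        est = fit_paths(random_linear_data, spec)
        assert est.total_refit is not None
        # the refit total is the x coefficient in y ~ x + c2, standardized
        assert est.total == pytest.approx(est.c_prime + est.indirect, abs=1e-12)

    def test_scale_equivariance(self, random_linear_data):
        df = random_linear_data
        scaled = df.assign(y=df["y"] * 7.0)
        raw, raw_scaled = fit_paths(df, SPEC_RAW), fit_paths(scaled, SPEC_RAW)
        assert raw_scaled.b == pytest.approx(7.0 * raw.b, rel=1e-10)
        assert raw_scaled.c_prime == pytest.approx(7.0 * raw.c_prime, rel=1e-10)
        std, std_scaled = fit_paths(df, SPEC_COVS), fit_paths(scaled, SPEC_COVS)
        assert std_scaled.b == pytest.approx(std.b, rel=1e-10)
        assert std_scaled.c_prime == pytest.approx(std.c_prime, rel=1e-10)

    def test_listwise_deletion_counts(self, random_linear_data):
        df = random_linear_data.copy()
        df.loc[:9, "m"] = np.nan
        est = fit_paths(df, SPEC_COVS)
        assert est.n_used == len(df) - 10

    def test_error_conditions(self, random_linear_data):
        with pytest.raises(MediationError, match="absent"):
            fit_paths(random_linear_data, MediationSpec("x", "m", "nope"))
        with pytest.raises(MediationError, match="distinct"):
            MediationSpec("x", "x", "y").validate()
        degenerate = random_linear_data.assign(m=1.0)
        with pytest.raises(MediationError, match="zero-variance"):
            fit_paths(degenerate, SPEC_PLAIN)
        collinear = random_linear_data.assign(c2=random_linear_data["c1"])
        with pytest.raises(MediationError, match="rank"):
            fit_paths(collinear, SPEC_RAW)


class TestEffectArithmetic:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(0.11, 0.17, 0.0187), (-0.06, -0.19, 0.0114), (0.0, 0.43, 0.0)],
    )
    def test_indirect_effect_products(self, a, b, expected):
        assert indirect_effect(a, b) == pytest.approx(expected)
        # these round to the published 2-decimal cells
        assert round(indirect_effect(0.11, 0.17), 2) == 0.02
        assert round(indirect_effect(-0.06, -0.19), 2) == 0.01

    @pytest.mark.parametrize(
        "indirect, total, expected",
        [
            (0.05, 0.22, 23),
            (0.02, 0.20, 10),
            (-0.002, 0.24, None),  # inconsistent mediation -> suppressed
            (0.002, -0.24, None),
            (0.05, 0.0, None),
            (0.0, 0.3, 0),
        ],
    )
    def test_proportion_mediated_rounding_and_suppression(self, indirect, total, expected):
        assert proportion_mediated(indirect, total) == expected

    def test_full_mediation_is_100_percent(self):
        # c' = 0 and nonzero indirect: total == indirect
        assert proportion_mediated(0.04, 0.04) == 100


class TestBootstrap:
    def test_degenerate_chain_gives_zero_width_cis(self):
        est = bootstrap_mediation(chain_data(), CHAIN_SPEC, BootstrapSettings(200, seed=1))
        for q, (lo, hi) in est.ci.items():
            assert hi - lo == pytest.approx(0.0, abs=1e-10), q
            assert est.se[q] == pytest.approx(0.0, abs=1e-10)

    def test_ci_equals_percentiles_of_replicates(self, random_linear_data):
        est = bootstrap_mediation(
            random_linear_data, SPEC_COVS, BootstrapSettings(300, seed=2)
        )
        for q, reps in est.replicates.items():
            lo, hi = np.percentile(reps, [2.5, 97.5])
            assert est.ci[q] == pytest.approx((lo, hi))
            assert est.ci[q][0] <= getattr(est, q) <= est.ci[q][1]

    def test_seed_reproducibility(self, random_linear_data):
        e1 = bootstrap_mediation(random_linear_data, SPEC_COVS, BootstrapSettings(100, seed=3))
        e2 = bootstrap_mediation(random_linear_data, SPEC_COVS, BootstrapSettings(100, seed=3))
        e3 = bootstrap_mediation(random_linear_data, SPEC_COVS, BootstrapSettings(100, seed=4))
        np.testing.assert_array_equal(e1.replicates["indirect"], e2.replicates["indirect"])
        assert not np.array_equal(e1.replicates["indirect"], e3.replicates["indirect"])

    def test_se_is_sd_of_replicates(self, random_linear_data):
        est = bootstrap_mediation(
            random_linear_data, SPEC_COVS, BootstrapSettings(150, seed=5)
        )
        assert est.se["a"] == pytest.approx(float(np.std(est.replicates["a"], ddof=1)))

    def test_invalid_settings_rejected(self):
        with pytest.raises(MediationError):
            BootstrapSettings(n_replicates=0).validate()
        with pytest.raises(MediationError):
            BootstrapSettings(ci_level=1.5).validate()


class TestLinearityLRT:
    def test_quadratic_alternative_detected(self):
        rng = np.random.default_rng(6)
        n = 2000
        x = rng.normal(size=n)
        m = 0.2 * x + 0.3 * x**2 + rng.normal(size=n)
        y = m + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "m": m, "y": y})
        stat, p = linearity_lrt(df, SPEC_PLAIN)
        assert p < 1e-6

    def test_statistic_nonnegative_under_null(self):
        rng = np.random.default_rng(7)
        for seed in range(5):
            r = np.random.default_rng(seed)
            df = pd.DataFrame(
                {"x": r.normal(size=50), "m": r.normal(size=50), "y": r.normal(size=50)}
            )
            stat, p = linearity_lrt(df, SPEC_PLAIN)
            assert stat >= 0.0
            assert 0.0 <= p <= 1.0


class TestResidualDiagnostics:
    def test_perfect_fit_residuals_zero(self):
        diag = residual_diagnostics(chain_data(), CHAIN_SPEC)
        for name, frame in diag.items():
            np.testing.assert_allclose(frame["residual"], 0.0, atol=1e-10)

    def test_residuals_sum_to_zero_and_quantiles_monotone(self, random_linear_data):
        diag = residual_diagnostics(random_linear_data, SPEC_COVS)
        for frame in diag.values():
            assert abs(frame["residual"].sum()) < 1e-8
            ordered = frame.sort_values("residual")
            assert ordered["theoretical_quantile"].is_monotonic_increasing

    def test_gaussian_residual_moments(self):
        rng = np.random.default_rng(8)
        n = 20_000
        x = rng.normal(size=n)
        m = 0.3 * x + rng.normal(size=n)
        y = 0.5 * m + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "m": m, "y": y})
        diag = residual_diagnostics(df, SPEC_PLAIN)
        from scipy import stats

        for frame in diag.values():
            assert abs(stats.skew(frame["residual"])) < 0.1
            assert abs(stats.kurtosis(frame["residual"], fisher=False) - 3.0) < 0.2
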