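"""Sensitivity analyses: mediator measurement error and intermediate confounding.

Two checks on the robustness of a mediation estimate:

**Fixed-reliability errors-in-variables correction.** Questionnaire
mediator scores are noisy. Under classical measurement error, the observed
mediator is the true score plus independent Gaussian noise, and a stated
reliability rho fixes the error variance at (1 - rho) * Var(observed).
The outcome-equation coefficients are corrected by the method-of-moments:
subtract the error variance from the mediator's diagonal entry of the
regressor covariance matrix before solving the normal equations. This is
deterministic and, in the linear-Gaussian case, equals the
single-indicator latent-variable SEM solution. Path a (observed mediator
as the dependent variable) is left unchanged — classical error in a
dependent variable inflates residual variance but does not bias the
slope.

**Sequential (intermediate-confounder) mediation.** A variable such as a
depression score may lie on the pathway between genetic risk and eating
behaviour while also affecting BMI. A recursive three-equation system
decomposes the total effect into a direct part and indirect components
through the mediator only, through the intermediate only, and through
both in sequence.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mediation import (
    BootstrapSettings,
    MediationError,
    MediationSpec,
    PathEstimates,
    _design,
    _solve_ols,
    bootstrap_mediation,
    bootstrap_system,
    indirect_effect,
    percentile_ci,
    prepare_analysis_frame,
    proportion_mediated,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SensitivitySettings",
    "ReliabilityAdjustedResult",
    "SequentialPathEstimates",
    "reliability_adjusted_mediation",
    "sequential_mediation",
]


@dataclass(frozen=True)
class SensitivitySettings:
    """Reliability of the observed mediator and the intermediate's name."""

    reliability: float = 0.8
    intermediate: str | None = None

    def validate(self) -> None:
        if not 0.0 < self.reliability <= 1.0:
            raise MediationError("reliability must be in (0, 1]")


@dataclass
class ReliabilityAdjustedResult:
    """Naive vs measurement-error-corrected mediation estimates."""

    naive: PathEstimates
    corrected: PathEstimates
    reliability: float
    delta_indirect: float
    delta_proportion_mediated: float | None  # percentage points; None if either suppressed


@dataclass
class SequentialPathEstimates:
    """Path decomposition for the exposure -> intermediate -> mediator -> outcome system.

    ``components`` holds the decomposed indirect effects:
    ``via_mediator`` (a_cond * b), ``via_intermediate`` (p1 * q),
    ``via_both`` (p1 * p2 * b); ``direct`` is c' from the full outcome
    equation and ``total`` their sum. ``paths`` keeps the raw equation
    coefficients; ``ci`` percentile intervals per component.
    """

    paths: dict[str, float]
    components: dict[str, float]
    total: float
    n_used: int
    se: dict[str, float] = field(default_factory=dict)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# errors-in-variables correction
# ---------------------------------------------------------------------------

def _eiv_outcome_coefs(
    df: pd.DataFrame, spec: MediationSpec, reliability: float
) -> tuple[float, float]:
    """(corrected c_prime, corrected b) from the moment-adjusted solve."""
    xcols = [spec.exposure, spec.mediator, *spec.covariates_b]
    X = np.column_stack([df[c].to_numpy(float) for c in xcols])
    y = df[spec.outcome].to_numpy(float)
    S = np.cov(X, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    cxy = np.array(
        [np.cov(X[:, j], y, ddof=1)[0, 1] for j in range(X.shape[1])]
    )
    m_idx = 1  # mediator position in xcols
    var_obs = S[m_idx, m_idx]
    err_var = (1.0 - reliability) * var_obs
    S_adj = S.copy()
    S_adj[m_idx, m_idx] -= err_var
    # feasibility: S_adj must stay positive definite
    eigmin = float(np.linalg.eigvalsh(S_adj).min())
    if eigmin <= 0:
        delta_max = 1.0 / float(np.linalg.inv(S)[m_idx, m_idx])
        rho_min = 1.0 - delta_max / var_obs
        raise MediationError(
            f"reliability {reliability:g} makes the adjusted regressor covariance "
            f"singular; minimum feasible reliability for these data is about {rho_min:.3f}"
        )
    beta = np.linalg.solve(S_adj, cxy)
    return float(beta[0]), float(beta[1])


def reliability_adjusted_mediation(
    data: pd.DataFrame,
    spec: MediationSpec,
    settings: SensitivitySettings = SensitivitySettings(),
    bootstrap: BootstrapSettings = BootstrapSettings(),
) -> ReliabilityAdjustedResult:
    """Mediation corrected for classical measurement error in the mediator.

    The error variance is anchored to the observed mediator variance on
    the analysis sample: Var(error) = (1 - rho) * Var(observed). Corrected
    b and c' come from the moment-adjusted normal equations; a is
    unchanged; the indirect effect becomes a * b_corrected. Both the naive
    and the corrected bundles are bootstrapped (same replicate draws), and
    the change in indirect effect and proportion mediated is reported.
    """
    settings.validate()
    naive = bootstrap_mediation(data, spec, bootstrap)
    df = prepare_analysis_frame(data, spec)

    c_corr, b_corr = _eiv_outcome_coefs(df, spec, settings.reliability)
    ind_corr = indirect_effect(naive.a, b_corr)
    total_corr = c_corr + ind_corr
    corrected = PathEstimates(
        a=naive.a,
        b=b_corr,
        c_prime=c_corr,
        indirect=ind_corr,
        total=total_corr,
        proportion_mediated=proportion_mediated(ind_corr, total_corr, ndigits=None),
        n_used=naive.n_used,
    )

    # bootstrap the corrected quantities with fresh resamples of the same size
    rng = np.random.default_rng(bootstrap.seed)
    B = bootstrap.n_replicates
    n = len(df)
    reps = {q: np.empty(B) for q in ("a", "b", "c_prime", "indirect", "total")}
    a_reps = naive.replicates["a"] if naive.replicates is not None else None
    attempts = 0
    for k in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            sub = df.iloc[idx]
            try:
                Xa = _design(sub, [spec.exposure, *spec.covariates_a])
                a_k = float(_solve_ols(Xa, sub[spec.mediator].to_numpy(float))[1])
                c_k, b_k = _eiv_outcome_coefs(sub, spec, settings.reliability)
                break
            except (MediationError, np.linalg.LinAlgError):
                attempts += 1
                if attempts > 10 * B:
                    raise MediationError(
                        "exceeded redraw budget in reliability-adjusted bootstrap"
                    )
        reps["a"][k] = a_k
        reps["b"][k] = b_k
        reps["c_prime"][k] = c_k
        reps["indirect"][k] = a_k * b_k
        reps["total"][k] = c_k + a_k * b_k
    corrected.replicates = reps
    corrected.se = {q: float(np.std(v, ddof=1)) if B > 1 else 0.0 for q, v in reps.items()}
    corrected.ci = {q: percentile_ci(v, bootstrap.ci_level) for q, v in reps.items()}

    if naive.proportion_mediated is None or corrected.proportion_mediated is None:
        delta_prop = None
    else:
        delta_prop = corrected.proportion_mediated - naive.proportion_mediated
    return ReliabilityAdjustedResult(
        naive=naive,
        corrected=corrected,
        reliability=settings.reliability,
        delta_indirect=corrected.indirect - naive.indirect,
        delta_proportion_mediated=delta_prop,
    )


# ---------------------------------------------------------------------------
# sequential (intermediate-confounder) mediation
# ---------------------------------------------------------------------------

def sequential_mediation(
    data: pd.DataFrame,
    spec: MediationSpec,
    intermediate: str,
    settings: BootstrapSettings = BootstrapSettings(),
) -> SequentialPathEstimates:
    """Three-equation recursive system with an intermediate confounder.

        intermediate ~ exposure + covariates_a          -> p1
        mediator     ~ exposure + intermediate + cov_a  -> a_cond, p2
        outcome      ~ exposure + intermediate + mediator + cov_b
                                                        -> c', q, b

    Indirect components: via_mediator = a_cond * b, via_intermediate =
    p1 * q, via_both = p1 * p2 * b; total = direct + all components (an
    algebraic identity with common covariate sets). All components get
    bootstrap SEs and percentile CIs.
    """
    if intermediate in (spec.exposure, spec.mediator, spec.outcome):
        raise MediationError("intermediate must be distinct from exposure/mediator/outcome")
    spec_std = spec
    if spec.standardize is None:
        spec_std = replace(
            spec, standardize=(spec.exposure, spec.mediator, spec.outcome, intermediate)
        )
    df = prepare_analysis_frame(data, spec_std, extra_columns=(intermediate,))

    equations = [
        ("intermediate_model", intermediate, [spec.exposure, *spec.covariates_a]),
        ("mediator_model", spec.mediator, [spec.exposure, intermediate, *spec.covariates_a]),
        (
            "outcome_model",
            spec.outcome,
            [spec.exposure, intermediate, spec.mediator, *spec.covariates_b],
        ),
    ]
    point: dict[str, dict[str, float]] = {}
    for name, ycol, xcols in equations:
        beta = _solve_ols(_design(df, xcols), df[ycol].to_numpy(float))
        point[name] = dict(zip(["_intercept", *xcols], beta))

    paths = {
        "exposure_to_intermediate": point["intermediate_model"][spec.exposure],
        "intermediate_to_mediator": point["mediator_model"][intermediate],
        "exposure_to_mediator": point["mediator_model"][spec.exposure],
        "mediator_to_outcome": point["outcome_model"][spec.mediator],
        "intermediate_to_outcome": point["outcome_model"][intermediate],
        "direct": point["outcome_model"][spec.exposure],
    }

    def _components(p1, p2, a_c, b, q, c):
        return {
            "direct": c,
            "via_mediator": a_c * b,
            "via_intermediate": p1 * q,
            "via_both": p1 * p2 * b,
        }

    comp = _components(
        paths["exposure_to_intermediate"],
        paths["intermediate_to_mediator"],
        paths["exposure_to_mediator"],
        paths["mediator_to_outcome"],
        paths["intermediate_to_outcome"],
        paths["direct"],
    )
    total = sum(comp.values())

    coefs = bootstrap_system(df, equations, settings)
    rep_comp = _components(
        coefs[("intermediate_model", spec.exposure)],
        coefs[("mediator_model", intermediate)],
        coefs[("mediator_model", spec.exposure)],
        coefs[("outcome_model", spec.mediator)],
        coefs[("outcome_model", intermediate)],
        coefs[("outcome_model", spec.exposure)],
    )
    rep_comp["total"] = sum(rep_comp.values())

    result = SequentialPathEstimates(
        paths={k: float(v) for k, v in paths.items()},
        components={k: float(v) for k, v in comp.items() if k != "direct"},
        total=float(total),
        n_used=len(df),
    )
    result.components["direct"] = float(comp["direct"])
    for k, v in rep_comp.items():
        result.se[k] = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        result.ci[k] = percentile_ci(v, settings.ci_level)
    return result
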