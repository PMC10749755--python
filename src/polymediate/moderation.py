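"""Moderation of the direct path, moderated-mediation, and stratified fits.

Three related questions about a continuous moderator W (flexible or rigid
restraint):

* does W moderate the *direct* exposure -> outcome path? (exposure x W
  interaction in the outcome equation);
* does W moderate the *mediated* path? (mediator x W interaction — the
  mediator -> outcome slope, and hence the indirect effect a*b(W), becomes
  a function of W: moderated-mediation);
* how does the mediation look within "low" (W <= 3) and "high" (W > 3)
  strata, the conventional dichotomisation of restraint scores?

The moderator is mean-centred before product terms are formed (numerical
conditioning only — estimates are invariant); reported simple slopes and
conditional effects undo the centring. Interaction p-values are Wald z
tests on the bootstrap SE.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

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
)

logger = logging.getLogger(__name__)

__all__ = [
    "StratificationRule",
    "ModerationResult",
    "StratifiedMediation",
    "test_direct_moderation",
    "moderated_mediation",
    "stratified_mediation",
]


@dataclass(frozen=True)
class StratificationRule:
    """Threshold dichotomisation of a moderator score.

    ``low`` is moderator <= threshold, ``high`` is moderator > threshold
    (default threshold 3, the recommended restraint cut).
    """

    moderator: str
    threshold: float = 3.0
    labels: tuple[str, str] = ("low", "high")

    def assign(self, values: pd.Series) -> pd.Series:
        """Stratum label per individual; NaN moderator stays NaN."""
        lab = np.where(values <= self.threshold, self.labels[0], self.labels[1])
        out = pd.Series(lab, index=values.index, dtype=object)
        out[values.isna()] = np.nan
        return out


@dataclass
class ModerationResult:
    """Interaction estimate plus conditional (simple-slope) summaries.

    ``conditional`` maps a descriptive moderator level ("at_threshold",
    "mean_minus_1sd", "mean_plus_1sd") to a dict with the moderator value,
    the conditional slope (of the exposure for direct moderation, of the
    mediator for moderated-mediation), the conditional indirect effect
    where applicable, and bootstrap CIs.
    """

    interaction: float
    interaction_se: float
    interaction_ci: tuple[float, float]
    interaction_p: float
    conditional: dict[str, dict] = field(default_factory=dict)
    a: float | None = None
    n_used: int = 0


@dataclass
class StratifiedMediation:
    """Bootstrap mediation per stratum, plus pooled references.

    ``percent_change_indirect`` is 100 * (indirect_high - indirect_low) /
    pooled total effect — the attenuation of mediation in the high stratum
    expressed against the overall effect. ``pooled_direct`` carries the
    pooled-sample direct effect for the pooled-direct presentation variant.
    """

    low: PathEstimates
    high: PathEstimates
    pooled: PathEstimates
    percent_change_indirect: float
    rule: StratificationRule

    @property
    def pooled_direct(self) -> float:
        return self.pooled.c_prime


def _check_moderator(df: pd.DataFrame, spec: MediationSpec, moderator: str) -> None:
    if moderator in (spec.exposure, spec.outcome):
        raise MediationError("moderator cannot be the exposure or outcome")
    if moderator == spec.mediator:
        # restraint is studied as a moderator, never simultaneously a mediator
        raise MediationError("moderator must differ from the mediator")
    if df[moderator].std(ddof=1) == 0:
        raise MediationError(f"moderator {moderator!r} has no variance")


def _wald_p(est: float, se: float) -> float:
    if se == 0:
        return 0.0 if est != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(est) / se))


def test_direct_moderation(
    data: pd.DataFrame,
    spec: MediationSpec,
    moderator: str,
    settings: BootstrapSettings = BootstrapSettings(),
) -> ModerationResult:
    """Exposure x moderator interaction on the direct exposure -> outcome path.

    Fits ``outcome ~ exposure + moderator_c + exposure*moderator_c +
    covariates_b`` (moderator mean-centred) and bootstraps the interaction
    coefficient. Simple slopes of the exposure are reported at the
    moderator mean -1 SD, the stratification threshold, and mean +1 SD.
    """
    df = prepare_analysis_frame(data, spec, extra_columns=(moderator,))
    _check_moderator(df, spec, moderator)
    w = df[moderator]
    w_mean, w_sd = float(w.mean()), float(w.std(ddof=1))
    df = df.copy()
    df["_w_c"] = w - w_mean
    df["_xw"] = df[spec.exposure] * df["_w_c"]
    xcols = [spec.exposure, "_w_c", "_xw", *spec.covariates_b]
    eq = [("direct_model", spec.outcome, xcols)]

    beta = _solve_ols(_design(df, xcols), df[spec.outcome].to_numpy(float))
    named = dict(zip(["_intercept", *xcols], beta))
    coefs = bootstrap_system(df, eq, settings)
    bx = coefs[("direct_model", spec.exposure)]
    bint = coefs[("direct_model", "_xw")]
    se = float(np.std(bint, ddof=1)) if len(bint) > 1 else 0.0

    result = ModerationResult(
        interaction=float(named["_xw"]),
        interaction_se=se,
        interaction_ci=percentile_ci(bint, settings.ci_level),
        interaction_p=_wald_p(float(named["_xw"]), se),
        n_used=len(df),
    )
    levels = {
        "mean_minus_1sd": w_mean - w_sd,
        "at_threshold": 3.0,
        "mean_plus_1sd": w_mean + w_sd,
    }
    for label, w0 in levels.items():
        slope_reps = bx + bint * (w0 - w_mean)
        result.conditional[label] = {
            "moderator_value": w0,
            "slope": float(named[spec.exposure] + named["_xw"] * (w0 - w_mean)),
            "slope_ci": percentile_ci(slope_reps, settings.ci_level),
        }
    return result


def moderated_mediation(
    data: pd.DataFrame,
    spec: MediationSpec,
    moderator: str,
    settings: BootstrapSettings = BootstrapSettings(),
    threshold: float = 3.0,
) -> ModerationResult:
    """Mediator x moderator interaction on path b (moderated-mediation).

    The outcome equation gains a mediator*moderator_c term, so the
    mediator -> outcome slope is b(W) = b0 + b_int * (W - mean) and the
    indirect effect a * b(W) is conditional on the moderator. Conditional
    b and conditional indirect effects (with bootstrap CIs) are reported
    at the threshold and at the moderator mean -/+ 1 SD.
    """
    df = prepare_analysis_frame(data, spec, extra_columns=(moderator,))
    _check_moderator(df, spec, moderator)
    w = df[moderator]
    w_mean, w_sd = float(w.mean()), float(w.std(ddof=1))
    df = df.copy()
    df["_w_c"] = w - w_mean
    df["_mw"] = df[spec.mediator] * df["_w_c"]
    eq_a = ("mediator_model", spec.mediator, [spec.exposure, *spec.covariates_a])
    eq_b = (
        "outcome_model",
        spec.outcome,
        [spec.exposure, spec.mediator, "_w_c", "_mw", *spec.covariates_b],
    )

    beta_a = _solve_ols(_design(df, eq_a[2]), df[spec.mediator].to_numpy(float))
    beta_b = _solve_ols(_design(df, eq_b[2]), df[spec.outcome].to_numpy(float))
    named_b = dict(zip(["_intercept", *eq_b[2]], beta_b))
    a_hat = float(beta_a[1])
    b0_hat = float(named_b[spec.mediator])
    bint_hat = float(named_b["_mw"])

    coefs = bootstrap_system(df, [eq_a, eq_b], settings)
    a_reps = coefs[("mediator_model", spec.exposure)]
    b0_reps = coefs[("outcome_model", spec.mediator)]
    bint_reps = coefs[("outcome_model", "_mw")]
    se = float(np.std(bint_reps, ddof=1)) if len(bint_reps) > 1 else 0.0

    result = ModerationResult(
        interaction=bint_hat,
        interaction_se=se,
        interaction_ci=percentile_ci(bint_reps, settings.ci_level),
        interaction_p=_wald_p(bint_hat, se),
        a=a_hat,
        n_used=len(df),
    )
    levels = {
        "mean_minus_1sd": w_mean - w_sd,
        "at_threshold": threshold,
        "mean_plus_1sd": w_mean + w_sd,
    }
    for label, w0 in levels.items():
        b_w = b0_hat + bint_hat * (w0 - w_mean)
        b_w_reps = b0_reps + bint_reps * (w0 - w_mean)
        ind_reps = a_reps * b_w_reps
        result.conditional[label] = {
            "moderator_value": w0,
            "b": b_w,
            "b_ci": percentile_ci(b_w_reps, settings.ci_level),
            "indirect": indirect_effect(a_hat, b_w),
            "indirect_ci": percentile_ci(ind_reps, settings.ci_level),
        }
    return result


def stratified_mediation(
    data: pd.DataFrame,
    spec: MediationSpec,
    rule: StratificationRule,
    settings: BootstrapSettings = BootstrapSettings(),
) -> StratifiedMediation:
    """Full bootstrap mediation within low/high moderator strata.

    Standardization happens inside each stratum's own analysis sample (as
    for any mediation fit). The pooled model supplies the denominator for
    the percent change in the indirect effect between strata, and the
    pooled direct effect reported alongside the fully stratified ones.
    """
    if rule.moderator not in data.columns:
        raise MediationError(f"moderator column {rule.moderator!r} absent")
    strata = rule.assign(data[rule.moderator])
    parts: dict[str, pd.DataFrame] = {}
    for lab in rule.labels:
        sub = data.loc[strata == lab]
        if sub.empty:
            raise MediationError(f"stratum {lab!r} is empty")
        parts[lab] = sub
    seeds = np.random.SeedSequence(settings.seed).generate_state(3) % (2**31)
    low = bootstrap_mediation(
        parts[rule.labels[0]], spec, replace(settings, seed=int(seeds[0]))
    )
    high = bootstrap_mediation(
        parts[rule.labels[1]], spec, replace(settings, seed=int(seeds[1]))
    )
    pooled = bootstrap_mediation(data, spec, replace(settings, seed=int(seeds[2])))
    if pooled.total == 0:
        raise MediationError("pooled total effect is zero; percent change undefined")
    pct = 100.0 * (high.indirect - low.indirect) / pooled.total
    return StratifiedMediation(
        low=low, high=high, pooled=pooled, percent_change_indirect=pct, rule=rule
    )
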