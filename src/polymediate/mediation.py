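"""Product-of-coefficients mediation with bootstrap confidence intervals.

The estimand decomposes the association between an exposure X (the
standardized genetic risk score) and an outcome Y (BMI) through a mediator
M (an eating-behaviour score) using two simultaneous linear regressions:

    M = i_a + a*X + (covariates_a)            -> path a
    Y = i_b + c'*X + b*M + (covariates_b)     -> paths b and c'

    indirect = a * b      total = c' + a * b
    proportion mediated = 100 * indirect / total

The two covariate sets may differ (the main adjusted model controls path a
additionally for smoking). Because the system is recursive with no
cross-equation constraints, equation-by-equation least squares equals the
joint "simultaneous" fit; both are provided and agree to machine
precision. Inference is by case-resampling bootstrap (individuals drawn
with replacement, all paths refit per replicate) with percentile
intervals, the standard approach for the product term a*b whose sampling
distribution is non-normal.

Continuous exposure/mediator/outcome are z-scored on the complete-case
analysis sample before fitting, so coefficients are standardized betas;
binary covariates enter untransformed.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MediationSpec",
    "BootstrapSettings",
    "PathEstimates",
    "MediationError",
    "fit_paths",
    "fit_paths_joint",
    "indirect_effect",
    "proportion_mediated",
    "bootstrap_mediation",
    "linearity_lrt",
    "residual_diagnostics",
]


class MediationError(ValueError):
    """Raised for invalid specifications or degenerate designs."""


@dataclass(frozen=True)
class MediationSpec:
    """Names the variables of one mediation model.

    ``standardize=None`` (default) z-scores exposure, mediator and outcome
    on the analysis sample; pass an explicit tuple (possibly empty) to
    control which columns are standardized.
    """

    exposure: str
    mediator: str
    outcome: str
    covariates_a: tuple[str, ...] = ()
    covariates_b: tuple[str, ...] = ()
    standardize: tuple[str, ...] | None = None

    def validate(self) -> None:
        core = (self.exposure, self.mediator, self.outcome)
        if len(set(core)) != 3:
            raise MediationError("exposure, mediator and outcome must be distinct")
        for cov in (*self.covariates_a, *self.covariates_b):
            if cov in core:
                raise MediationError(
                    f"covariate {cov!r} duplicates a core model variable"
                )

    @property
    def standardized_columns(self) -> tuple[str, ...]:
        if self.standardize is not None:
            return self.standardize
        return (self.exposure, self.mediator, self.outcome)


@dataclass(frozen=True)
class BootstrapSettings:
    """Case-resampling bootstrap configuration (percentile intervals)."""

    n_replicates: int = 1000
    ci_level: float = 0.95
    ci_method: str = "percentile"
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise MediationError("n_replicates must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise MediationError("ci_level must be in (0, 1)")
        if self.ci_method != "percentile":
            raise MediationError(f"unsupported ci_method {self.ci_method!r}")


@dataclass
class PathEstimates:
    """The a / b / c' / indirect / total bundle with optional bootstrap CIs.

    ``proportion_mediated`` holds the unrounded percentage, or None when
    mediation is inconsistent (indirect and total of opposite sign, or a
    zero total) and the ratio is suppressed. ``se`` and ``ci`` are filled
    by the bootstrap (SD of replicates; percentile intervals), keyed by
    quantity name; ``replicates`` retains the raw bootstrap draws.
    """

    a: float
    b: float
    c_prime: float
    indirect: float
    total: float
    proportion_mediated: float | None
    n_used: int
    se: dict[str, float] = field(default_factory=dict)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    replicates: dict[str, np.ndarray] | None = None
    total_refit: float | None = None

    QUANTITIES = ("a", "b", "c_prime", "indirect", "total")

    def as_dict(self) -> dict:
        out: dict = {q: getattr(self, q) for q in self.QUANTITIES}
        out["proportion_mediated"] = self.proportion_mediated
        out["n_used"] = self.n_used
        out["se"] = dict(self.se)
        out["ci"] = {k: list(v) for k, v in self.ci.items()}
        if self.total_refit is not None:
            out["total_refit"] = self.total_refit
        return out


# ---------------------------------------------------------------------------
# design preparation and plain least squares
# ---------------------------------------------------------------------------

def prepare_analysis_frame(
    data: pd.DataFrame,
    spec: MediationSpec,
    extra_columns: Sequence[str] = (),
) -> pd.DataFrame:
    """Complete-case, z-scored analysis frame for one model.

    Listwise deletion over every column the model touches (missing data
    are not imputed); the dropped count is logged. Columns flagged for
    standardization are z-scored on the retained sample.
    """
    spec.validate()
    cols: list[str] = []
    for c in (
        spec.exposure,
        spec.mediator,
        spec.outcome,
        *spec.covariates_a,
        *spec.covariates_b,
        *extra_columns,
    ):
        if c not in cols:
            cols.append(c)
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise MediationError(f"columns absent from data: {missing}")
    df = data[cols].apply(pd.to_numeric, errors="coerce").dropna()
    n_dropped = len(data) - len(df)
    if n_dropped:
        logger.info("listwise deletion removed %d of %d rows", n_dropped, len(data))
    n_regressors = 2 + max(len(spec.covariates_a), len(spec.covariates_b) + 1)
    if len(df) <= n_regressors + 2:
        raise MediationError(
            f"only {len(df)} complete cases for {n_regressors} regressors"
        )
    df = df.astype(float)
    for c in spec.standardized_columns:
        if c not in df.columns:
            continue
        sd = df[c].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise MediationError(f"zero-variance column {c!r} cannot be standardized")
        df[c] = (df[c] - df[c].mean()) / sd
    for c in (spec.mediator, spec.outcome):
        if df[c].std(ddof=1) == 0:
            raise MediationError(f"zero-variance column {c!r}")
    return df


def _design(df: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    return np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in cols]
    )


def _solve_ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise MediationError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def _equations(spec: MediationSpec) -> list[tuple[str, str, list[str]]]:
    """(equation name, response column, regressor columns) for both paths."""
    return [
        ("mediator_model", spec.mediator, [spec.exposure, *spec.covariates_a]),
        ("outcome_model", spec.outcome, [spec.exposure, spec.mediator, *spec.covariates_b]),
    ]


# ---------------------------------------------------------------------------
# point estimation
# ---------------------------------------------------------------------------

def indirect_effect(a: float, b: float) -> float:
    """The mediated (indirect) effect: the product a * b."""
    if not (np.isfinite(a) and np.isfinite(b)):
        raise MediationError("indirect effect requires finite a and b")
    return a * b


def proportion_mediated(
    indirect: float, total: float, ndigits: int | None = 0
) -> float | None:
    """Percentage of the total effect transmitted through the mediator.

    Returns ``round(100 * indirect / total)`` (to ``ndigits``; None skips
    rounding), or None — the suppression marker — when the direct and
    indirect effects counteract (opposite signs, "inconsistent mediation")
    or the total effect is zero.
    """
    if not (np.isfinite(indirect) and np.isfinite(total)):
        raise MediationError("proportion mediated requires finite inputs")
    if total == 0:
        return None
    pct = 100.0 * indirect / total
    if pct < 0:
        return None
    return pct if ndigits is None else round(pct, ndigits or None)


def _estimates_from_coefs(
    a: float, b: float, c_prime: float, n_used: int
) -> PathEstimates:
    ind = indirect_effect(a, b)
    total = c_prime + ind
    return PathEstimates(
        a=float(a),
        b=float(b),
        c_prime=float(c_prime),
        indirect=float(ind),
        total=float(total),
        proportion_mediated=proportion_mediated(ind, total, ndigits=None),
        n_used=int(n_used),
    )


def fit_paths(data: pd.DataFrame, spec: MediationSpec) -> PathEstimates:
    """Point estimates of all paths from equation-by-equation least squares."""
    df = prepare_analysis_frame(data, spec)
    coefs = {}
    for name, ycol, xcols in _equations(spec):
        beta = _solve_ols(_design(df, xcols), df[ycol].to_numpy(float))
        coefs[name] = dict(zip(["_intercept", *xcols], beta))
    est = _estimates_from_coefs(
        a=coefs["mediator_model"][spec.exposure],
        b=coefs["outcome_model"][spec.mediator],
        c_prime=coefs["outcome_model"][spec.exposure],
        n_used=len(df),
    )
    if set(spec.covariates_a) != set(spec.covariates_b):
        # With asymmetric covariate sets c' + a*b is no longer an algebraic
        # identity with the refit total; flag a material discrepancy.
        Xt = _design(df, [spec.exposure, *spec.covariates_b])
        beta_t = _solve_ols(Xt, df[spec.outcome].to_numpy(float))
        est.total_refit = float(beta_t[1])
        if abs(est.total_refit - est.total) > 0.01:
            logger.warning(
                "composed total %.4f differs from refit total %.4f by more than 0.01",
                est.total,
                est.total_refit,
            )
    return est


def fit_paths_joint(data: pd.DataFrame, spec: MediationSpec) -> PathEstimates:
    """Single simultaneous solve of both equations (block least squares).

    The recursive system has no cross-equation constraints, so stacking
    both equations into one block-diagonal design and solving once must
    reproduce the per-equation fit exactly; provided as an internal
    cross-check of the "simultaneous linear regressions" framing.
    """
    df = prepare_analysis_frame(data, spec)
    eqs = _equations(spec)
    blocks = [_design(df, xcols) for _, _, xcols in eqs]
    ys = [df[ycol].to_numpy(float) for _, ycol, _ in eqs]
    n = len(df)
    p = [B.shape[1] for B in blocks]
    X = np.zeros((2 * n, sum(p)))
    X[:n, : p[0]] = blocks[0]
    X[n:, p[0]:] = blocks[1]
    beta = _solve_ols(X, np.concatenate(ys))
    a = beta[1]
    c_prime = beta[p[0] + 1]
    b = beta[p[0] + 2]
    return _estimates_from_coefs(a, b, c_prime, len(df))


# ---------------------------------------------------------------------------
# bootstrap machinery (shared with the moderation module)
# ---------------------------------------------------------------------------

_CHUNK = 200  # replicates per vectorised solve; caps peak memory


def bootstrap_system(
    df: pd.DataFrame,
    equations: Sequence[tuple[str, str, Sequence[str]]],
    settings: BootstrapSettings,
) -> dict[tuple[str, str], np.ndarray]:
    """Case-resampling bootstrap of a set of linear equations.

    Draws individuals with replacement, refits every equation per
    replicate (vectorised normal-equation solves in chunks), and returns
    coefficient arrays keyed by ``(equation name, regressor name)`` with
    ``"_intercept"`` for the constant. Replicates with a singular design
    are redrawn, up to ``10 * n_replicates`` total attempts.
    """
    settings.validate()
    n = len(df)
    B = settings.n_replicates
    rng = np.random.default_rng(settings.seed)
    prepared = [
        (name, df[ycol].to_numpy(float), _design(df, list(xcols)), list(xcols))
        for name, ycol, xcols in equations
    ]
    out = {name: np.empty((B, len(xcols) + 1)) for name, _, _, xcols in prepared}
    attempts = 0
    max_attempts = 10 * B

    def _fit_one(idx_row: np.ndarray) -> dict[str, np.ndarray] | None:
        res = {}
        for name, y, X, _ in prepared:
            Xb = X[idx_row]
            G = Xb.T @ Xb
            try:
                beta = np.linalg.solve(G, Xb.T @ y[idx_row])
            except np.linalg.LinAlgError:
                return None
            res[name] = beta
        return res

    done = 0
    while done < B:
        size = min(_CHUNK, B - done)
        attempts += size
        if attempts > max_attempts + B:
            raise MediationError("too many singular bootstrap replicates")
        idx = rng.integers(0, n, size=(size, n))
        try:
            for name, y, X, _ in prepared:
                Xb = X[idx]  # (size, n, p)
                G = np.einsum("bni,bnj->bij", Xb, Xb)
                h = np.einsum("bni,bn->bi", Xb, y[idx])
                out[name][done : done + size] = np.linalg.solve(G, h[..., None])[..., 0]
            done += size
        except np.linalg.LinAlgError:
            # rare: at least one singular replicate in the chunk — fit one
            # at a time, redrawing singular replicates
            for row in idx:
                fitted = _fit_one(row)
                while fitted is None:
                    attempts += 1
                    if attempts > max_attempts:
                        raise MediationError(
                            "exceeded redraw budget for singular bootstrap replicates"
                        )
                    fitted = _fit_one(rng.integers(0, n, size=n))
                for name, beta in fitted.items():
                    out[name][done] = beta
                done += 1
                if done == B:
                    break

    keyed: dict[tuple[str, str], np.ndarray] = {}
    for name, _, _, xcols in prepared:
        for j, col in enumerate(["_intercept", *xcols]):
            keyed[(name, col)] = out[name][:, j]
    return keyed


def percentile_ci(draws: np.ndarray, level: float) -> tuple[float, float]:
    """Equal-tail percentile interval of a bootstrap replicate array."""
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(draws, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def bootstrap_mediation(
    data: pd.DataFrame,
    spec: MediationSpec,
    settings: BootstrapSettings = BootstrapSettings(),
) -> PathEstimates:
    """Full mediation fit with bootstrap SEs and percentile CIs.

    Point estimates come from the original sample; ``settings.n_replicates``
    case resamples supply the uncertainty for a, b, c', the indirect and
    the total effect. SEs are the SDs of the replicate draws.
    """
    est = fit_paths(data, spec)
    df = prepare_analysis_frame(data, spec)
    coefs = bootstrap_system(df, _equations(spec), settings)
    reps = {
        "a": coefs[("mediator_model", spec.exposure)],
        "b": coefs[("outcome_model", spec.mediator)],
        "c_prime": coefs[("outcome_model", spec.exposure)],
    }
    reps["indirect"] = reps["a"] * reps["b"]
    reps["total"] = reps["c_prime"] + reps["indirect"]
    est.replicates = reps
    est.se = {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for k, v in reps.items()}
    est.ci = {k: percentile_ci(v, settings.ci_level) for k, v in reps.items()}
    return est


# ---------------------------------------------------------------------------
# model checks
# ---------------------------------------------------------------------------

def linearity_lrt(data: pd.DataFrame, spec: MediationSpec) -> tuple[float, float]:
    """Likelihood-ratio test of linearity of the exposure -> mediator relation.

    Compares the Gaussian log-likelihood of ``mediator ~ exposure +
    covariates_a`` against the same model augmented with a squared-exposure
    term; the statistic 2*delta-loglik is referred to chi-square(1).
    Returns ``(statistic, p_value)``.
    """
    df = prepare_analysis_frame(data, spec)
    y = df[spec.mediator].to_numpy(float)
    x = df[spec.exposure].to_numpy(float)
    X0 = _design(df, [spec.exposure, *spec.covariates_a])
    X1 = np.column_stack([X0, x**2])
    n = len(y)
    rss0 = float(np.sum((y - X0 @ _solve_ols(X0, y)) ** 2))
    rss1 = float(np.sum((y - X1 @ _solve_ols(X1, y)) ** 2))
    if rss1 <= 0:
        return math.inf, 0.0
    stat = max(0.0, n * math.log(rss0 / rss1))
    return stat, float(stats.chi2.sf(stat, df=1))


def residual_diagnostics(
    data: pd.DataFrame, spec: MediationSpec
) -> dict[str, pd.DataFrame]:
    """Per-equation residuals paired with standard-normal rank quantiles.

    For each fitted equation, returns a DataFrame with the OLS residual
    and the theoretical normal quantile of its rank (Blom plotting
    positions), ready for Q-Q plotting or export.
    """
    df = prepare_analysis_frame(data, spec)
    out = {}
    n = len(df)
    for name, ycol, xcols in _equations(spec):
        y = df[ycol].to_numpy(float)
        X = _design(df, xcols)
        resid = y - X @ _solve_ols(X, y)
        ranks = stats.rankdata(resid, method="ordinal")
        theo = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
        out[name] = pd.DataFrame(
            {"residual": resid, "theoretical_quantile": theo}, index=df.index
        )
    return out
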