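"""Fixed-effect inverse-variance pooling of mediation estimates across cohorts.

Two independent cohorts measuring the same mediator construct can be
combined path by path: each path estimate is weighted by the inverse of
its squared (bootstrap) standard error, giving the minimum-variance linear
combination under a common-effect model. With only two cohorts a
random-effects variance is unidentifiable, so the fixed-effect model is
the appropriate precision-pooling choice; Cochran's Q and I^2 are reported
as heterogeneity descriptives.

Indirect effects are pooled directly on their own bootstrap SEs (not
recomposed as the product of pooled a and pooled b — the two operations do
not commute).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mediation import PathEstimates, proportion_mediated

logger = logging.getLogger(__name__)

__all__ = ["CohortEstimate", "MetaResult", "MetaError", "inverse_variance_meta", "meta_mediation"]


class MetaError(ValueError):
    """Raised for invalid meta-analysis inputs."""


@dataclass(frozen=True)
class CohortEstimate:
    """One quantity (a, b, c_prime, indirect or total) from one cohort."""

    cohort: str
    quantity: str
    estimate: float
    se: float
    n: int

    def validate(self) -> None:
        if not np.isfinite(self.estimate):
            raise MetaError(f"{self.cohort}/{self.quantity}: non-finite estimate")
        if not (np.isfinite(self.se) and self.se > 0):
            raise MetaError(f"{self.cohort}/{self.quantity}: SE must be positive")


@dataclass
class MetaResult:
    """Combined fixed-effect estimate with heterogeneity descriptives."""

    quantity: str
    estimate: float
    se: float
    ci: tuple[float, float]
    weights: dict[str, float]  # normalised, sum to 1
    q_statistic: float
    i_squared: float
    n_total: int


def inverse_variance_meta(
    estimates: list[CohortEstimate], ci_level: float = 0.95
) -> MetaResult:
    """Fixed-effect inverse-variance combination of one quantity.

    weights w_i = 1/SE_i^2; combined estimate = sum(w_i * est_i)/sum(w_i);
    combined SE = sqrt(1/sum(w_i)); CI = estimate +/- z * SE. Q is the
    weighted sum of squared deviations from the combined estimate and
    I^2 = max(0, (Q - (k-1))/Q) * 100.
    """
    if not estimates:
        raise MetaError("need at least one cohort estimate")
    quantities = {e.quantity for e in estimates}
    if len(quantities) != 1:
        raise MetaError(f"mixed quantities cannot be pooled: {sorted(quantities)}")
    for e in estimates:
        e.validate()
    w = np.array([1.0 / e.se**2 for e in estimates])
    theta = np.array([e.estimate for e in estimates])
    w_sum = w.sum()
    combined = float((w * theta).sum() / w_sum)
    se = float(np.sqrt(1.0 / w_sum))
    z = float(stats.norm.ppf(0.5 + ci_level / 2.0))
    q = float((w * (theta - combined) ** 2).sum())
    k = len(estimates)
    i2 = float(max(0.0, (q - (k - 1)) / q) * 100.0) if q > 0 else 0.0
    return MetaResult(
        quantity=estimates[0].quantity,
        estimate=combined,
        se=se,
        ci=(combined - z * se, combined + z * se),
        weights={e.cohort: float(wi / w_sum) for e, wi in zip(estimates, w)},
        q_statistic=q,
        i_squared=i2,
        n_total=sum(e.n for e in estimates),
    )


def meta_mediation(
    per_cohort: dict[str, PathEstimates], ci_level: float = 0.95
) -> dict[str, MetaResult | float | None]:
    """Pool a full set of path estimates across cohorts, quantity by quantity.

    ``per_cohort`` maps cohort label -> bootstrapped :class:`PathEstimates`
    (SEs required). Each of a, b, c_prime, indirect and total is combined
    separately by :func:`inverse_variance_meta`; the proportion mediated is
    recomputed from the combined indirect and combined total and returned
    under ``"proportion_mediated"`` (None when suppressed).
    """
    if not per_cohort:
        raise MetaError("no cohorts supplied")
    out: dict[str, MetaResult | float | None] = {}
    for q in PathEstimates.QUANTITIES:
        ests = []
        for label, pe in per_cohort.items():
            if q not in pe.se:
                raise MetaError(f"cohort {label!r} lacks a bootstrap SE for {q!r}")
            ests.append(
                CohortEstimate(
                    cohort=label,
                    quantity=q,
                    estimate=getattr(pe, q),
                    se=pe.se[q],
                    n=pe.n_used,
                )
            )
        out[q] = inverse_variance_meta(ests, ci_level=ci_level)
    out["proportion_mediated"] = proportion_mediated(
        out["indirect"].estimate, out["total"].estimate, ndigits=None
    )
    return out
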