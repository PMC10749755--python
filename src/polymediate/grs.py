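"""Weighted polygenic risk scores from allele dosages.

A genetic risk score (GRS) aggregates many small additive variant effects
into one exposure variable: for individual *i*,

    GRS_i = sum_j w_j * d_ij

where ``d_ij`` in [0, 2] counts copies of the effect allele of variant *j*
and ``w_j`` is its per-allele effect size from GWAS summary statistics.
Scores are internally z-standardized before analysis so that path
coefficients downstream are on a per-SD-of-genetic-risk scale and
comparable across cohorts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantWeightTable",
    "RiskScoreVector",
    "GRSError",
    "validate_weight_table",
    "compute_grs",
    "standardize",
    "risk_scores",
    "variance_explained",
]

#: Strand-ambiguous allele pairs (palindromic SNPs). Alignment by allele
#: identity cannot detect strand flips for these; they are scored as-is
#: with a warning.
AMBIGUOUS_PAIRS = {frozenset({"A", "T"}), frozenset({"C", "G"})}

WEIGHT_COLUMNS = ("variant_id", "effect_allele", "other_allele", "weight")


class GRSError(ValueError):
    """Raised for malformed weight tables or dosage/weight mismatches."""


@dataclass(frozen=True)
class RiskScoreVector:
    """Per-individual raw and internally standardized risk scores."""

    raw: pd.Series
    z: pd.Series

    def __post_init__(self) -> None:
        if not self.raw.index.equals(self.z.index):
            raise GRSError("raw and standardized scores must share an index")


# Alias for documentation purposes: a weight table is a plain DataFrame with
# the four canonical GWAS summary-statistic columns.
VariantWeightTable = pd.DataFrame


def validate_weight_table(weights: pd.DataFrame) -> pd.DataFrame:
    """Check a variant-weight table and return it unchanged.

    Requires columns ``variant_id, effect_allele, other_allele, weight``
    with unique variant ids, differing alleles and finite weights.
    """
    missing = [c for c in WEIGHT_COLUMNS if c not in weights.columns]
    if missing:
        raise GRSError(f"weight table is missing columns: {missing}")
    if weights["variant_id"].duplicated().any():
        dups = weights.loc[weights["variant_id"].duplicated(), "variant_id"]
        raise GRSError(f"duplicate variant ids in weight table: {sorted(set(dups))}")
    same = weights["effect_allele"] == weights["other_allele"]
    if same.any():
        raise GRSError(
            "effect and other allele identical for: "
            f"{sorted(weights.loc[same, 'variant_id'])}"
        )
    w = pd.to_numeric(weights["weight"], errors="coerce").to_numpy(float)
    if not np.all(np.isfinite(w)):
        raise GRSError("weight table contains non-finite weights")
    ambiguous = [
        vid
        for vid, ea, oa in zip(
            weights["variant_id"], weights["effect_allele"], weights["other_allele"]
        )
        if frozenset({str(ea).upper(), str(oa).upper()}) in AMBIGUOUS_PAIRS
    ]
    if ambiguous:
        logger.warning(
            "%d strand-ambiguous (A/T or C/G) variants scored as-is: %s%s",
            len(ambiguous),
            ambiguous[:5],
            "..." if len(ambiguous) > 5 else "",
        )
    return weights


def compute_grs(
    dosages: pd.DataFrame,
    weights: pd.DataFrame,
    counted_alleles: Mapping[str, str] | None = None,
) -> pd.Series:
    """Raw weighted risk score: sum over variants of weight x effect-allele dosage.

    Parameters
    ----------
    dosages
        Individuals x variants matrix of allele dosages in [0, 2]; column
        names are variant ids. Individuals with a missing dosage at any
        scored variant are dropped (complete-case scoring), with the count
        logged.
    weights
        Variant-weight table (see :func:`validate_weight_table`).
    counted_alleles
        Optional map variant id -> the allele the dosage column counts.
        When the counted allele equals the table's *other* allele the
        dosage is flipped to ``2 - d`` before weighting; an allele matching
        neither table allele is a hard error (no strand guessing). When
        omitted, dosages are assumed to count the effect allele.
    """
    validate_weight_table(weights)
    missing = [v for v in weights["variant_id"] if v not in dosages.columns]
    if missing:
        raise GRSError(f"variants in weight table absent from dosages: {missing}")

    mat = dosages[list(weights["variant_id"])].to_numpy(dtype=float)
    if np.nanmin(mat, initial=0.0) < 0 or np.nanmax(mat, initial=0.0) > 2:
        raise GRSError("dosages must lie in [0, 2]")

    w = weights["weight"].to_numpy(dtype=float).copy()
    offset = 0.0
    if counted_alleles is not None:
        for j, (vid, ea, oa) in enumerate(
            zip(weights["variant_id"], weights["effect_allele"], weights["other_allele"])
        ):
            counted = str(counted_alleles.get(vid, ea)).upper()
            if counted == str(ea).upper():
                continue
            if counted == str(oa).upper():
                # d counts the other allele: effect dosage is 2 - d, i.e.
                # contribution w*(2 - d) = 2w - w*d.
                offset += 2.0 * w[j]
                w[j] = -w[j]
            else:
                raise GRSError(
                    f"variant {vid}: counted allele {counted!r} matches neither "
                    f"effect ({ea}) nor other ({oa}) allele"
                )

    complete = ~np.isnan(mat).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info(
            "dropping %d of %d individuals with missing dosages among scored variants",
            n_dropped,
            len(dosages),
        )
    scores = mat[complete] @ w + offset
    return pd.Series(scores, index=dosages.index[complete], name="grs_raw")


def standardize(raw: pd.Series | np.ndarray) -> pd.Series:
    """Internally standardized z-scores, (x - mean) / sd with the n-1 sd."""
    s = pd.Series(np.asarray(raw, dtype=float)) if not isinstance(raw, pd.Series) else raw
    if len(s) < 2:
        raise GRSError("standardization needs at least 2 individuals")
    sd = s.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise GRSError("cannot standardize a zero-variance score vector")
    z = (s - s.mean()) / sd
    return z.rename("zgrs")


def risk_scores(
    dosages: pd.DataFrame,
    weights: pd.DataFrame,
    counted_alleles: Mapping[str, str] | None = None,
) -> RiskScoreVector:
    """Convenience wrapper: raw score plus its z-standardized version."""
    raw = compute_grs(dosages, weights, counted_alleles)
    return RiskScoreVector(raw=raw, z=standardize(raw))


def variance_explained(
    zgrs: Sequence[float],
    outcome: Sequence[float],
    covariates: pd.DataFrame | None = None,
) -> float:
    """R^2 of a least-squares fit of the outcome on the risk score.

    Optional covariate columns enter the design alongside the score; the
    returned value is the overall model R^2, the usual "variance explained
    by the GRS" summary when covariates are omitted.
    """
    import statsmodels.api as sm

    z = np.asarray(zgrs, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if z.shape[0] != y.shape[0]:
        raise GRSError("zgrs and outcome lengths differ")
    X = z.reshape(-1, 1)
    if covariates is not None:
        X = np.column_stack([X, np.asarray(covariates, dtype=float)])
    if X.shape[0] <= X.shape[1] + 1:
        raise GRSError("need more individuals than regressors")
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise GRSError("rank-deficient design in variance_explained")
    return float(sm.OLS(y, X).fit().rsquared)
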