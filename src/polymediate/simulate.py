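"""Synthetic genotype-phenotype cohorts with a known mediation structure.

The generator produces the data structure the downstream estimators assume:
many independent biallelic variants acting additively on a continuous
outcome (BMI-like), a questionnaire-style eating-behaviour mediator that
depends linearly on the standardized genetic risk score, and an outcome
that depends on the score directly, on the mediator, on a continuous
moderator (restraint-like, centred at the conventional threshold of 3) and
on their product. Structural equations are written on a standardized scale
(unit-variance exposure/mediator/outcome by default) so the generating path
coefficients are directly comparable to standardized betas recovered by the
estimators. Classical measurement error can be added to the mediator at a
stated reliability, and an optional intermediate variable (depression-like)
sits on the exposure -> mediator pathway for sequential-mediation studies.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import grs as grs_mod

logger = logging.getLogger(__name__)

__all__ = [
    "Covariate",
    "IntermediateSpec",
    "SimulationConfig",
    "SyntheticCohort",
    "SimulationError",
    "simulate_genotypes",
    "simulate_weights",
    "simulate_cohort",
    "implied_moments",
]

_BASES = ("A", "C", "G", "T")


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class Covariate:
    """A baseline covariate with its effects on mediator and outcome.

    Binary covariates are Bernoulli(prevalence); continuous ones are
    Normal(mean, sd). Structural equations use the centred covariate so
    that generated mediator/outcome stay zero-mean.
    """

    name: str
    kind: str = "binary"  # "binary" | "continuous"
    prevalence: float = 0.5
    mean: float = 0.0
    sd: float = 1.0
    beta_mediator: float = 0.0
    beta_outcome: float = 0.0

    def variance(self) -> float:
        if self.kind == "binary":
            return self.prevalence * (1.0 - self.prevalence)
        return self.sd**2

    def validate(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise SimulationError(f"covariate {self.name}: unknown kind {self.kind!r}")
        if self.kind == "binary" and not 0.0 < self.prevalence < 1.0:
            raise SimulationError(f"covariate {self.name}: prevalence must be in (0,1)")
        if self.kind == "continuous" and self.sd <= 0:
            raise SimulationError(f"covariate {self.name}: sd must be positive")


@dataclass(frozen=True)
class IntermediateSpec:
    """An intermediate confounder on the exposure -> mediator -> outcome chain.

    Generates ``i = from_exposure * zGRS + noise`` and adds ``to_mediator * i``
    to the mediator equation and ``to_outcome * i`` to the outcome equation.
    ``noise_sd=None`` sizes the residual for unit variance of ``i``.
    """

    name: str = "depression"
    from_exposure: float = 0.1
    to_mediator: float = 0.1
    to_outcome: float = 0.1
    noise_sd: float | None = None

    def resolved_noise_sd(self) -> float:
        if self.noise_sd is not None:
            if self.noise_sd < 0:
                raise SimulationError("intermediate noise_sd must be >= 0")
            return float(self.noise_sd)
        v = 1.0 - self.from_exposure**2
        if v <= 0:
            raise SimulationError(
                "intermediate from_exposure too large for unit variance; "
                "set noise_sd explicitly"
            )
        return math.sqrt(v)

    def variance(self) -> float:
        return self.from_exposure**2 + self.resolved_noise_sd() ** 2


DEFAULT_COVARIATES: tuple[Covariate, ...] = (
    Covariate("sex", "binary", prevalence=0.6, beta_mediator=0.05, beta_outcome=0.10),
    Covariate("age", "continuous", mean=0.0, sd=1.0, beta_mediator=0.05, beta_outcome=0.10),
)


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters for a synthetic cohort.

    Path defaults mirror the scale of published standardized estimates for
    a disinhibition-type mediator (a=0.10, b=0.43, c'=0.16). The moderator
    is drawn around the conventional restraint threshold of 3 and enters
    the outcome equation centred at that threshold, so ``w_interaction``
    is the change in the mediator->outcome slope per unit of moderator
    above the threshold. ``reliability`` is the fraction of observed
    mediator variance that is true-score variance (classical error);
    1.0 means the observed mediator equals the true one.
    """

    n_individuals: int = 2000
    n_variants: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    weight_loc: float = 0.02
    weight_scale: float = 0.01
    a_true: float = 0.10
    b_true: float = 0.43
    c_true: float = 0.16
    w_main: float = -0.04
    w_interaction: float = 0.0
    xw_interaction: float = 0.0  # exposure x moderator effect on the outcome
    moderator_mean: float = 3.0
    moderator_sd: float = 1.0
    moderator_name: str = "flexible_restraint"
    mediator_name: str = "disinhibition"
    outcome_name: str = "bmi"
    covariates: tuple[Covariate, ...] = DEFAULT_COVARIATES
    intermediate: IntermediateSpec | None = None
    reliability: float = 1.0
    noise_sd_mediator: float | None = None
    noise_sd_outcome: float | None = None
    outcome_rescale_mean: float | None = None  # e.g. 25.4 for BMI-like units
    outcome_rescale_sd: float = 4.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1 or self.n_variants < 1:
            raise SimulationError("n_individuals and n_variants must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimulationError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0.0 < self.reliability <= 1.0:
            raise SimulationError("reliability must be in (0, 1]")
        if self.moderator_sd <= 0:
            raise SimulationError("moderator_sd must be positive")
        for c in self.covariates:
            c.validate()
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise SimulationError("covariate names must be unique")
        for sd in (self.noise_sd_mediator, self.noise_sd_outcome):
            if sd is not None and sd < 0:
                raise SimulationError("noise sds must be >= 0")
        # verify unit-variance defaults are feasible
        self.resolved_noise_sds()

    # -- closed-form second moments ------------------------------------
    def _mediator_variance_parts(self) -> tuple[float, float]:
        """(explained variance of mediator, Cov(zGRS, mediator))."""
        t_x = t_m = 0.0
        var_i = 0.0
        if self.intermediate is not None:
            t_x = self.intermediate.from_exposure
            t_m = self.intermediate.to_mediator
            var_i = self.intermediate.variance()
        explained = (
            self.a_true**2
            + t_m**2 * var_i
            + 2.0 * self.a_true * t_m * t_x
            + sum(c.beta_mediator**2 * c.variance() for c in self.covariates)
        )
        cov_zm = self.a_true + t_m * t_x
        return explained, cov_zm

    def resolved_noise_sds(self) -> tuple[float, float]:
        """Residual sds for mediator and outcome, defaulting to unit variance."""
        explained_m, cov_zm = self._mediator_variance_parts()
        if self.noise_sd_mediator is not None:
            sd_m = float(self.noise_sd_mediator)
        else:
            if explained_m >= 1.0:
                raise SimulationError(
                    "mediator paths explain >= 100% variance; set noise_sd_mediator"
                )
            sd_m = math.sqrt(1.0 - explained_m)
        var_m = explained_m + sd_m**2

        t_x = t_m = t_y = 0.0
        var_i = 0.0
        if self.intermediate is not None:
            t_x = self.intermediate.from_exposure
            t_m = self.intermediate.to_mediator
            t_y = self.intermediate.to_outcome
            var_i = self.intermediate.variance()
        cov_mi = self.a_true * t_x + t_m * var_i
        v_w = self.moderator_sd**2
        explained_y = (
            self.c_true**2
            + self.b_true**2 * var_m
            + t_y**2 * var_i
            + self.w_main**2 * v_w
            + self.w_interaction**2 * var_m * v_w
            + self.xw_interaction**2 * v_w
            + sum(c.beta_outcome**2 * c.variance() for c in self.covariates)
            + 2.0 * self.c_true * self.b_true * cov_zm
            + 2.0 * self.c_true * t_y * t_x
            + 2.0 * self.b_true * t_y * cov_mi
            + 2.0
            * self.b_true
            * sum(c.beta_mediator * c.beta_outcome * c.variance() for c in self.covariates)
        )
        if self.noise_sd_outcome is not None:
            sd_y = float(self.noise_sd_outcome)
        else:
            if explained_y >= 1.0:
                raise SimulationError(
                    "outcome paths explain >= 100% variance; set noise_sd_outcome"
                )
            sd_y = math.sqrt(1.0 - explained_y)
        return sd_m, sd_y


def implied_moments(config: SimulationConfig) -> dict[str, float]:
    """Closed-form means/variances of the generated mediator and outcome.

    Both variables are zero-mean by construction (covariates enter
    centred); variances follow from independence of the structural inputs.
    """
    sd_m, sd_y = config.resolved_noise_sds()
    explained_m, _ = config._mediator_variance_parts()
    var_m = explained_m + sd_m**2
    var_y = _outcome_variance(config, var_m) + sd_y**2
    return {"mean_mediator": 0.0, "mean_outcome": 0.0, "var_mediator": var_m, "var_outcome": var_y}


def _outcome_variance(config: SimulationConfig, var_m: float) -> float:
    t_x = t_m = t_y = 0.0
    var_i = 0.0
    if config.intermediate is not None:
        t_x = config.intermediate.from_exposure
        t_m = config.intermediate.to_mediator
        t_y = config.intermediate.to_outcome
        var_i = config.intermediate.variance()
    cov_zm = config.a_true + t_m * t_x
    cov_mi = config.a_true * t_x + t_m * var_i
    v_w = config.moderator_sd**2
    return (
        config.c_true**2
        + config.b_true**2 * var_m
        + t_y**2 * var_i
        + config.w_main**2 * v_w
        + config.w_interaction**2 * var_m * v_w
        + config.xw_interaction**2 * v_w
        + sum(c.beta_outcome**2 * c.variance() for c in config.covariates)
        + 2.0 * config.c_true * config.b_true * cov_zm
        + 2.0 * config.c_true * t_y * t_x
        + 2.0 * config.b_true * t_y * cov_mi
        + 2.0
        * config.b_true
        * sum(c.beta_mediator * c.beta_outcome * c.variance() for c in config.covariates)
    )


@dataclass
class SyntheticCohort:
    """A simulated cohort: genotypes, weights, phenotypes and ground truth."""

    genotypes: pd.DataFrame  # individuals x variants, dosages in {0,1,2}
    weights: pd.DataFrame  # variant-weight table
    phenotypes: pd.DataFrame  # one row per individual
    grs_raw: pd.Series
    grs_z: pd.Series
    config: SimulationConfig

    @property
    def truth(self) -> dict:
        """Ground-truth parameter record (the config, as a plain dict)."""
        return dataclasses.asdict(self.config)

    def write(self, outdir: str | Path, vcf: bool = False) -> dict[str, Path]:
        """Write genotypes/phenotypes/weights/ground truth under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genotypes": outdir / "genotypes.csv",
            "phenotypes": outdir / "phenotypes.csv",
            "weights": outdir / "weights.tsv",
            "truth": outdir / "ground_truth.json",
        }
        self.genotypes.to_csv(paths["genotypes"], index_label="individual_id")
        self.phenotypes.to_csv(paths["phenotypes"], index=False)
        self.weights.to_csv(paths["weights"], sep="\t", index=False)
        truth = self.truth
        truth["maf_range"] = list(truth["maf_range"])
        paths["truth"].write_text(json.dumps(truth, indent=2, default=str) + "\n")
        if vcf:
            paths["vcf"] = outdir / "genotypes.vcf"
            write_dosage_vcf(paths["vcf"], self.genotypes, self.weights)
        return paths


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_genotypes(config: SimulationConfig) -> pd.DataFrame:
    """Additive genotype dosages: binomial(2, MAF) per variant, independent loci.

    Per-variant MAFs are drawn uniformly within ``config.maf_range``
    (Hardy-Weinberg, no linkage disequilibrium).
    """
    config.validate()
    rng = _rngs(config.seed, 3)[0]
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_variants)
    dosages = rng.binomial(2, mafs, size=(config.n_individuals, config.n_variants))
    ids = [f"id{i:06d}" for i in range(config.n_individuals)]
    cols = [f"rs{j + 1:06d}" for j in range(config.n_variants)]
    return pd.DataFrame(dosages, index=pd.Index(ids, name="individual_id"), columns=cols)


def simulate_weights(config: SimulationConfig) -> pd.DataFrame:
    """Per-variant effect weights with non-palindromic allele pairs."""
    config.validate()
    rng = _rngs(config.seed, 3)[1]
    w = rng.normal(config.weight_loc, config.weight_scale, size=config.n_variants)
    # draw allele pairs that differ and are not strand-ambiguous (A/T, C/G)
    pairs = [
        (a, b)
        for a in _BASES
        for b in _BASES
        if a != b and frozenset({a, b}) not in grs_mod.AMBIGUOUS_PAIRS
    ]
    chosen = rng.integers(0, len(pairs), size=config.n_variants)
    return pd.DataFrame(
        {
            "variant_id": [f"rs{j + 1:06d}" for j in range(config.n_variants)],
            "effect_allele": [pairs[k][0] for k in chosen],
            "other_allele": [pairs[k][1] for k in chosen],
            "weight": w,
        }
    )


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full cohort under the linear mediation/moderation model.

    Structure (all structural inputs independent, covariates centred):

        mediator = a_true * zGRS [+ intermediate, covariate terms] + e_m
        outcome  = c_true * zGRS + b_true * mediator + w_main * (W - mean)
                   + w_interaction * mediator * (W - mean)
                   [+ intermediate, covariate terms] + e_y
        observed mediator = mediator + classical error such that
                   Var(true) / Var(observed) = reliability
    """
    config.validate()
    genotypes = simulate_genotypes(config)
    weights = simulate_weights(config)
    rng = _rngs(config.seed, 3)[2]

    raw = pd.Series(
        genotypes.to_numpy(float) @ weights["weight"].to_numpy(float),
        index=genotypes.index,
        name="grs_raw",
    )
    if raw.std(ddof=1) == 0:
        # degenerate (e.g. MAF ~ 0): keep zeros rather than failing
        z = pd.Series(np.zeros(len(raw)), index=raw.index, name="zgrs")
    else:
        z = grs_mod.standardize(raw)
    zv = z.to_numpy()
    n = config.n_individuals

    cov_values: dict[str, np.ndarray] = {}
    cov_centred: dict[str, np.ndarray] = {}
    for c in config.covariates:
        if c.kind == "binary":
            x = rng.binomial(1, c.prevalence, size=n).astype(float)
            cov_values[c.name] = x
            cov_centred[c.name] = x - c.prevalence
        else:
            x = rng.normal(c.mean, c.sd, size=n)
            cov_values[c.name] = x
            cov_centred[c.name] = x - c.mean

    inter_vals: np.ndarray | None = None
    if config.intermediate is not None:
        spec = config.intermediate
        inter_vals = spec.from_exposure * zv + rng.normal(
            0.0, spec.resolved_noise_sd(), size=n
        )

    sd_m, sd_y = config.resolved_noise_sds()
    mediator = config.a_true * zv + rng.normal(0.0, 1.0, size=n) * sd_m
    if inter_vals is not None:
        mediator = mediator + config.intermediate.to_mediator * inter_vals
    for c in config.covariates:
        mediator = mediator + c.beta_mediator * cov_centred[c.name]

    moderator = rng.normal(config.moderator_mean, config.moderator_sd, size=n)
    w_c = moderator - config.moderator_mean

    outcome = (
        config.c_true * zv
        + config.b_true * mediator
        + config.w_main * w_c
        + config.w_interaction * mediator * w_c
        + config.xw_interaction * zv * w_c
        + rng.normal(0.0, 1.0, size=n) * sd_y
    )
    if inter_vals is not None:
        outcome = outcome + config.intermediate.to_outcome * inter_vals
    for c in config.covariates:
        outcome = outcome + c.beta_outcome * cov_centred[c.name]

    if config.reliability < 1.0:
        var_true = float(np.var(mediator, ddof=1))
        err_sd = math.sqrt(var_true * (1.0 - config.reliability) / config.reliability)
        observed = mediator + rng.normal(0.0, err_sd, size=n)
    else:
        observed = mediator.copy()

    if config.outcome_rescale_mean is not None:
        outcome_out = config.outcome_rescale_mean + config.outcome_rescale_sd * outcome
    else:
        outcome_out = outcome

    pheno = pd.DataFrame({"individual_id": genotypes.index})
    pheno[config.outcome_name] = outcome_out
    pheno[config.mediator_name] = observed
    pheno[config.mediator_name + "_true"] = mediator
    pheno[config.moderator_name] = moderator
    if inter_vals is not None:
        pheno[config.intermediate.name] = inter_vals
    for name, vals in cov_values.items():
        pheno[name] = vals
    pheno["grs_raw"] = raw.to_numpy()
    pheno["zgrs"] = zv

    return SyntheticCohort(
        genotypes=genotypes,
        weights=weights,
        phenotypes=pheno,
        grs_raw=raw,
        grs_z=z,
        config=config,
    )


def write_dosage_vcf(path: str | Path, genotypes: pd.DataFrame, weights: pd.DataFrame) -> Path:
    """Write dosages as a minimal single-field VCF (FORMAT ``DS``).

    One record per variant on a synthetic contig, REF = other allele,
    ALT = effect allele, so the counted (ALT-dosage) allele is the effect
    allele. Readable by any VCF parser that honours FORMAT fields.
    """
    path = Path(path)
    by_id = weights.set_index("variant_id")
    samples = list(genotypes.index)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the ALT (effect) allele">',
        "##contig=<ID=1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for pos, vid in enumerate(genotypes.columns, start=1):
        ref = by_id.loc[vid, "other_allele"] if vid in by_id.index else "N"
        alt = by_id.loc[vid, "effect_allele"] if vid in by_id.index else "N"
        ds = "\t".join(f"{v:g}" for v in genotypes[vid].to_numpy(float))
        lines.append(f"1\t{pos}\t{vid}\t{ref}\t{alt}\t.\t.\t.\tDS\t{ds}")
    path.write_text("\n".join(lines) + "\n")
    return path
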