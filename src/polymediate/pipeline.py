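"""End-to-end run configuration and publication-style results tables.

``run_pipeline`` ties the stages together the way the analysis is meant to
be reported: for every eating-behaviour mediator (each tested separately,
never pooled) it fits the minimally adjusted model ("model1": age and sex)
and the fully adjusted model ("model2": adds smoking, ethnicity,
depression and anxiety, with smoking adjusting path a only), then any
requested moderation and sensitivity stages, and writes both a
display-rounded TSV and a full-precision JSON. All randomness descends
deterministically from the single run seed.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import grs as grs_mod
from .io import read_dosage_csv, read_phenotypes, read_weight_table
from .mediation import (
    BootstrapSettings,
    MediationError,
    MediationSpec,
    PathEstimates,
    bootstrap_mediation,
    linearity_lrt,
)
from .moderation import StratificationRule, moderated_mediation, stratified_mediation
from .sensitivity import SensitivitySettings, reliability_adjusted_mediation

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "MODEL_COVARIATES", "run_pipeline", "build_spec", "results_to_tsv"]

#: Covariate schemes of the two reported models. The fully adjusted model
#: controls path a additionally for smoking; path b omits it.
MODEL_COVARIATES: dict[str, dict[str, tuple[str, ...]]] = {
    "model1": {"a": ("age", "sex"), "b": ("age", "sex")},
    "model2": {
        "a": ("smoking", "ethnicity", "depression", "anxiety", "sex", "age"),
        "b": ("ethnicity", "depression", "anxiety", "sex", "age"),
    },
}


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    phenotypes: str
    mediators: tuple[str, ...]
    outcome: str = "bmi"
    exposure: str = "zgrs"
    dosages: str | None = None  # dosage CSV; with weights, recomputes the exposure
    weights: str | None = None
    models: tuple[str, ...] = ("model1", "model2")
    moderator: str | None = None
    threshold: float = 3.0
    n_replicates: int = 1000
    ci_level: float = 0.95
    reliability: float | None = None  # run the measurement-error sensitivity if set
    intermediate: str | None = None  # run sequential mediation if set (unused here; CLI)
    outdir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        self.mediators = tuple(self.mediators)
        self.models = tuple(self.models)
        if not self.mediators:
            raise MediationError("mediator list must be non-empty")
        for m in self.models:
            if m not in MODEL_COVARIATES:
                raise MediationError(f"unknown model {m!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def build_spec(
    config: RunConfig, mediator: str, model: str, available: set[str]
) -> MediationSpec:
    """Mediation spec for one mediator x model row.

    Covariates named by the model but absent from the data raise, so a
    row fails loudly rather than silently dropping an adjustment.
    """
    scheme = MODEL_COVARIATES[model]
    missing = [c for c in {*scheme["a"], *scheme["b"]} if c not in available]
    if missing:
        raise MediationError(f"model {model!r} needs missing columns {sorted(missing)}")
    return MediationSpec(
        exposure=config.exposure,
        mediator=mediator,
        outcome=config.outcome,
        covariates_a=scheme["a"],
        covariates_b=scheme["b"],
    )


def _stage_seed(base_seed: int, label: str) -> int:
    """Deterministic per-stage seed below 2^31, independent of stage order."""
    h = np.frombuffer(label.encode(), dtype=np.uint8).astype(np.uint64)
    mix = int(h.sum() + 1000003 * len(h))
    return int(np.random.SeedSequence([base_seed, mix]).generate_state(1)[0] % (2**31))


def _estimates_record(est: PathEstimates) -> dict:
    rec = est.as_dict()
    if rec["proportion_mediated"] is None:
        rec["proportion_mediated_display"] = "suppressed (inconsistent mediation)"
    else:
        rec["proportion_mediated_display"] = f"{round(rec['proportion_mediated'])}%"
    return rec


def run_pipeline(config: RunConfig) -> dict:
    """Run every requested stage and write results.tsv / results.json.

    Returns the full results dictionary (what results.json contains). A
    stage failure aborts that mediator's row with a logged reason and the
    remaining mediators continue.
    """
    pheno = read_phenotypes(
        config.phenotypes, required_columns=(config.outcome, *config.mediators)
    )
    if config.dosages and config.weights:
        dosages = read_dosage_csv(config.dosages)
        weights = read_weight_table(config.weights)
        scores = grs_mod.risk_scores(dosages, weights)
        pheno = pheno.set_index("individual_id") if "individual_id" in pheno.columns else pheno
        pheno[config.exposure] = scores.z
        pheno = pheno.reset_index()
    elif config.exposure not in pheno.columns:
        raise MediationError(
            f"exposure column {config.exposure!r} absent and no dosages/weights given"
        )

    available = set(pheno.columns)
    results: dict = {"config": dataclasses.asdict(config), "rows": [], "errors": []}

    for mediator in config.mediators:
        for model in config.models:
            label = f"{mediator}/{model}"
            try:
                spec = build_spec(config, mediator, model, available)
                settings = BootstrapSettings(
                    n_replicates=config.n_replicates,
                    ci_level=config.ci_level,
                    seed=_stage_seed(config.seed, f"mediate:{label}"),
                )
                est = bootstrap_mediation(pheno, spec, settings)
                lrt_stat, lrt_p = linearity_lrt(pheno, spec)
                row = {
                    "mediator": mediator,
                    "model": model,
                    **_estimates_record(est),
                    "linearity_lrt_stat": lrt_stat,
                    "linearity_lrt_p": lrt_p,
                }
                logger.info("%s: n_used=%d", label, est.n_used)

                if config.moderator and config.moderator in available:
                    mm = moderated_mediation(
                        pheno,
                        spec,
                        config.moderator,
                        BootstrapSettings(
                            n_replicates=config.n_replicates,
                            ci_level=config.ci_level,
                            seed=_stage_seed(config.seed, f"modmed:{label}"),
                        ),
                        threshold=config.threshold,
                    )
                    strat = stratified_mediation(
                        pheno,
                        spec,
                        StratificationRule(config.moderator, config.threshold),
                        BootstrapSettings(
                            n_replicates=config.n_replicates,
                            ci_level=config.ci_level,
                            seed=_stage_seed(config.seed, f"strat:{label}"),
                        ),
                    )
                    row["moderation"] = {
                        "moderator": config.moderator,
                        "interaction": mm.interaction,
                        "interaction_p": mm.interaction_p,
                        "conditional": mm.conditional,
                        "stratified": {
                            "low": _estimates_record(strat.low),
                            "high": _estimates_record(strat.high),
                            "percent_change_indirect": strat.percent_change_indirect,
                            "pooled_direct": strat.pooled_direct,
                        },
                    }

                if config.reliability is not None:
                    adj = reliability_adjusted_mediation(
                        pheno,
                        spec,
                        SensitivitySettings(reliability=config.reliability),
                        BootstrapSettings(
                            n_replicates=config.n_replicates,
                            ci_level=config.ci_level,
                            seed=_stage_seed(config.seed, f"reliability:{label}"),
                        ),
                    )
                    row["reliability_sensitivity"] = {
                        "reliability": adj.reliability,
                        "corrected": _estimates_record(adj.corrected),
                        "delta_indirect": adj.delta_indirect,
                        "delta_proportion_mediated": adj.delta_proportion_mediated,
                    }

                results["rows"].append(row)
            except MediationError as exc:
                logger.error("%s failed: %s", label, exc)
                results["errors"].append({"row": label, "reason": str(exc)})

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "results.json").write_text(
        json.dumps(results, indent=2, sort_keys=True, default=_jsonable) + "\n"
    )
    results_to_tsv(results, outdir / "results.tsv")
    return results


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _fmt_ci(ci: list[float] | tuple[float, float]) -> str:
    return f"({ci[0]:.2f} to {ci[1]:.2f})"


def results_to_tsv(results: dict, path: str | Path) -> pd.DataFrame:
    """Display-rounded table mirroring the published layout.

    Coefficients to 2 decimals with 95% CIs, proportion mediated as an
    integer percent (or the suppression marker). Rounding happens only
    here; results.json keeps full precision.
    """
    rows = []
    for r in results["rows"]:
        ci = r.get("ci", {})
        out = {"mediator": r["mediator"], "model": r["model"], "n": r["n_used"]}
        for q in ("a", "b", "c_prime", "indirect", "total"):
            cell = f"{r[q]:.2f}"
            if q in ci:
                cell += f" {_fmt_ci(ci[q])}"
            out[q] = cell
        out["proportion_mediated"] = r["proportion_mediated_display"]
        if "moderation" in r:
            out["interaction_p"] = f"{r['moderation']['interaction_p']:.3g}"
        rows.append(out)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
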