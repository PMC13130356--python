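"""Study orchestration: exclusions, KDM scoring, index construction, the
Model 1 / Model 2 survey-logistic suites, and stratified effect modification.

Order of operations: exclusions -> KDM fit/score -> dietary-index scoring ->
median splits -> models. Index medians and splits are computed on the
age-restricted analytic sample; stratified and unstratified analyses reuse
the same KDM and index values (computed once).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diet import (
    CDAI_NUTRIENTS,
    compute_cdai,
    compute_digm,
    compute_sex_references,
    default_digm_config,
    joint_diet_groups,
    median_split,
)
from .kdm import KDMModel, fit_kdm, score_cohort
from .simulate import KDM_BIOMARKERS
from .survey import SurveyDesign, fit_survey_logistic

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "ExclusionStep",
    "ExclusionReport",
    "apply_exclusions",
    "build_analytic_cohort",
    "run_primary_analysis",
    "run_effect_modification",
]

#: Model 1 adjustment set: sociodemographic and lifestyle covariates
DEFAULT_MODEL1 = (
    "age",
    "sex",
    "race",
    "marital_status",
    "income_poverty_ratio",
    "smoking",
    "alcohol",
    "energy_intake",
    "bmi",
)
#: Model 2 additionally adjusts for the inflammatory markers CRP and WBC
DEFAULT_MODEL2 = DEFAULT_MODEL1 + ("crp", "wbc_count")


@dataclass
class AnalysisConfig:
    biomarkers: tuple[str, ...] = KDM_BIOMARKERS
    model1_covariates: tuple[str, ...] = DEFAULT_MODEL1
    model2_covariates: tuple[str, ...] = DEFAULT_MODEL2
    exposure: str = "antibiotic_use"
    outcomes: tuple[str, ...] = ("accelerated", "diarrhea")
    age_min: float = 45.0  # analytic sample restricted to age > age_min
    accel_threshold: float = 0.0
    cdai_scale: str = "se"
    weighted_median: bool = True
    ci_method: str = "normal"
    design: SurveyDesign = field(default_factory=SurveyDesign)

    def __post_init__(self) -> None:
        if not set(self.model1_covariates) <= set(self.model2_covariates):
            raise ValueError("Model 1 covariates must be a subset of Model 2")

    def covariates(self, model: str) -> tuple[str, ...]:
        if model == "model1":
            return self.model1_covariates
        if model == "model2":
            return self.model2_covariates
        raise ValueError(f"unknown model {model!r}")


@dataclass(frozen=True)
class ExclusionStep:
    name: str
    n_before: int
    n_removed: int
    n_after: int


@dataclass
class ExclusionReport:
    steps: list[ExclusionStep] = field(default_factory=list)

    def add(self, name: str, n_before: int, n_after: int) -> None:
        step = ExclusionStep(name, n_before, n_before - n_after, n_after)
        if self.steps and self.steps[-1].n_after != n_before:
            raise ValueError("exclusion counts do not telescope")
        self.steps.append(step)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])

    def to_text(self) -> str:
        lines = ["Participant flow"]
        for s in self.steps:
            lines.append(f"  {s.name}: {s.n_before} -> {s.n_after} (removed {s.n_removed})")
        return "\n".join(lines)


def apply_exclusions(
    cohort: pd.DataFrame, config: AnalysisConfig
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Sequential filters: age restriction, complete exposure/outcome,
    complete covariates, complete KDM biomarkers. Counts telescope exactly."""
    required = (
        [config.exposure, "diarrhea", "age", "sex"]
        + list(config.model2_covariates)
        + list(config.biomarkers)
        + [config.design.stratum, config.design.psu, config.design.weight]
    )
    for col in dict.fromkeys(required):
        if col not in cohort.columns:
            raise KeyError(f"required column missing: {col}")

    report = ExclusionReport()
    df = cohort

    n0 = len(df)
    df = df[df["age"] > config.age_min]
    report.add(f"age_over_{config.age_min:g}", n0, len(df))

    n0 = len(df)
    df = df[df[[config.exposure, "diarrhea"]].notna().all(axis=1)]
    report.add("complete_exposure_outcome", n0, len(df))

    n0 = len(df)
    df = df[df[list(config.model2_covariates)].notna().all(axis=1)]
    report.add("complete_covariates", n0, len(df))

    n0 = len(df)
    df = df[df[list(config.biomarkers)].notna().all(axis=1)]
    report.add("complete_kdm_biomarkers", n0, len(df))

    return df.copy(), report


def build_analytic_cohort(
    cohort: pd.DataFrame, config: AnalysisConfig
) -> tuple[pd.DataFrame, KDMModel, ExclusionReport]:
    """Exclusions, KDM training + scoring, and dietary-index columns
    (digm, cdai, digm_group, cdai_group, joint_group) in one pass."""
    df, report = apply_exclusions(cohort, config)
    model = fit_kdm(df, list(config.biomarkers))
    scores = score_cohort(model, df, threshold=config.accel_threshold)
    df = df.join(scores)

    weights = df[config.design.weight] if config.weighted_median else None
    df["digm"] = compute_digm(df, default_digm_config(), weights=weights)
    cdai_cfg = compute_sex_references(df, CDAI_NUTRIENTS, scale_kind=config.cdai_scale)
    df["cdai"] = compute_cdai(df, cdai_cfg)
    df["digm_group"], digm_med = median_split(df["digm"], weights)
    df["cdai_group"], cdai_med = median_split(df["cdai"], weights)
    df["joint_group"] = joint_diet_groups(df["digm_group"], df["cdai_group"])
    logger.info("median splits: digm at %.3f, cdai at %.3f", digm_med, cdai_med)
    return df, model, report


def _formula(outcome: str, exposure: str, covariates: tuple[str, ...]) -> str:
    # same adjustment set for both outcomes; the outcome is never a covariate
    terms = [exposure] + [c for c in covariates if c != outcome]
    return f"{outcome} ~ " + " + ".join(terms)


def _fit_row(df: pd.DataFrame, outcome: str, model: str, stratum: str, config: AnalysisConfig):
    formula = _formula(outcome, config.exposure, config.covariates(model))
    try:
        res = fit_survey_logistic(formula, df, design=config.design, ci_method=config.ci_method)
        i = res.term_index(config.exposure)
        return {
            "outcome": outcome,
            "model": model,
            "stratum": stratum,
            "or": float(res.or_[i]),
            "ci_low": float(res.ci_low[i]),
            "ci_high": float(res.ci_high[i]),
            "p": float(res.p_values[i]),
            "n": res.n_used,
            "estimable": True,
        }
    except (ValueError, KeyError, RuntimeError) as exc:
        logger.warning("stratum %s / outcome %s not estimable: %s", stratum, outcome, exc)
        return {
            "outcome": outcome,
            "model": model,
            "stratum": stratum,
            "or": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p": np.nan,
            "n": len(df),
            "estimable": False,
        }


def run_primary_analysis(analytic: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Exposure ORs for each outcome under Model 1 and Model 2 (forest rows).

    Expects the prepared analytic cohort from :func:`build_analytic_cohort`.
    """
    rows = [
        _fit_row(analytic, outcome, model, "overall", config)
        for outcome in config.outcomes
        for model in ("model1", "model2")
    ]
    forest = pd.DataFrame(rows)
    forest["display"] = [
        f"{r['or']:.2f} ({r['ci_low']:.2f}-{r['ci_high']:.2f})" if r["estimable"] else "NE"
        for r in rows
    ]
    return forest


def run_effect_modification(
    analytic: pd.DataFrame,
    config: AnalysisConfig,
    model: str = "model1",
) -> pd.DataFrame:
    """Per-stratum exposure ORs across the DI-GM and CDAI median splits and
    the joint double-low / single-low / double-high grouping."""
    groupings = {
        "digm": ("digm_group", ["low", "high"]),
        "cdai": ("cdai_group", ["low", "high"]),
        "joint": ("joint_group", ["double_low", "single_low", "double_high"]),
    }
    rows = []
    for modifier, (col, levels) in groupings.items():
        for level in levels:
            sub = analytic[analytic[col] == level]
            label = f"{modifier}_{level}" if modifier != "joint" else level
            if len(sub) == 0:
                for outcome in config.outcomes:
                    rows.append(
                        {
                            "outcome": outcome,
                            "model": model,
                            "stratum": label,
                            "or": np.nan,
                            "ci_low": np.nan,
                            "ci_high": np.nan,
                            "p": np.nan,
                            "n": 0,
                            "estimable": False,
                        }
                    )
                continue
            for outcome in config.outcomes:
                rows.append(_fit_row(sub, outcome, model, label, config))
    forest = pd.DataFrame(rows)
    forest["display"] = [
        f"{r['or']:.2f} ({r['ci_low']:.2f}-{r['ci_high']:.2f})" if r["estimable"] else "NE"
        for r in rows
    ]
    return forest
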