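"""Synthetic NHANES-like cohort generation with known generative parameters.

Every downstream stage (KDM fitting, dietary-index scoring, survey-weighted
logistic regression, stratified effect modification) is validated by
parameter recovery against the quantities planted here.

Generative model
----------------
* Biomarkers follow linear-Gaussian trajectories on chronological age,
  ``x_i = q_true + k_true * (CA + delta) + N(0, s_true)``, where ``delta`` is
  a latent biological-age shift of ``+/- latent_shift_years`` whose sign is
  the participant's true accelerated-aging status. Planting the exposure
  effect on that latent shift lets the downstream binary "KDM accelerated"
  inherit a known odds ratio without circular use of the estimator.
* Exposure (30-day antibiotic use) and diarrhea are Bernoulli draws from
  logistic models with configurable coefficients and planted exposure
  log-odds ratios, optionally stratum-specific (effect modification by the
  DI-GM / CDAI median splits, which the generator computes with the same
  deterministic scoring code the analysis pipeline uses).
* The survey design is stratified with a fixed number of PSUs per stratum
  and i.i.d. lognormal weights independent of outcomes given covariates, so
  weighted estimators remain consistent and recovery tests are valid.
* Missingness is MCAR, matching the complete-case analysis assumption.

One pseudorandom stream per purpose (demographics, design, diet, exposure,
outcomes, biomarkers, missingness), each derived from the single seed, keeps
column-level reproducibility under config edits.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .diet import (
    CDAI_NUTRIENTS,
    DIGMConfig,
    compute_cdai,
    compute_component_medians,
    compute_digm,
    compute_sex_references,
    default_digm_config,
    joint_diet_groups,
    median_split,
)

__all__ = [
    "ConfigurationError",
    "BiomarkerSpec",
    "ExposureModel",
    "OutcomeModel",
    "DietIntakeSpec",
    "SimulationConfig",
    "KDM_BIOMARKERS",
    "default_config",
    "digm_modification_config",
    "cdai_modification_config",
    "joint_modification_config",
    "generate_cohort",
    "inject_missingness",
    "true_effect_summary",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the offending field."""


#: the ten KDM biomarker columns
KDM_BIOMARKERS = (
    "systolic_bp",
    "albumin",
    "alkaline_phosphatase",
    "blood_urea_nitrogen",
    "creatinine",
    "glycohemoglobin",
    "total_cholesterol",
    "lymphocyte_pct",
    "wbc_count",
    "mean_cell_volume",
)

# purpose-keyed substream codes (stable across config edits)
_STREAMS = {
    "demographics": 11,
    "design": 12,
    "diet": 13,
    "exposure": 14,
    "outcomes": 15,
    "biomarkers": 16,
    "missingness": 17,
}


def _rng(seed: int, purpose: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[purpose], seed])


@dataclass(frozen=True)
class BiomarkerSpec:
    """Linear trajectory of one biomarker on age: q + k*age, residual SD s."""

    name: str
    q_true: float
    k_true: float
    s_true: float


@dataclass(frozen=True)
class ExposureModel:
    """Logistic model for 30-day antibiotic use (age centered at 60 years)."""

    baseline_prev: float = 0.12
    beta_age: float = 0.0
    beta_female: float = 0.0


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic outcome model with a planted exposure log-OR.

    With ``modifier`` set ('digm' | 'cdai' | 'joint'), ``stratum_log_ors``
    replaces the overall ``log_or_exposure`` per modifier stratum
    ('low'/'high', or 'double_low'/'single_low'/'double_high').
    """

    intercept: float
    beta_age: float = 0.0
    beta_female: float = 0.0
    log_or_exposure: float = 0.0
    modifier: str | None = None
    stratum_log_ors: tuple[tuple[str, float], ...] | None = None

    def stratum_map(self) -> dict[str, float]:
        return dict(self.stratum_log_ors or ())


@dataclass(frozen=True)
class DietIntakeSpec:
    """Sex-specific lognormal intake distribution (median parameterization)."""

    name: str
    median_female: float
    median_male: float
    sigma: float = 0.6


def _default_biomarker_specs() -> tuple[BiomarkerSpec, ...]:
    # Residual SDs chosen so the ten-marker panel pins the latent deviation
    # to ~ +/- 2 years (sum k^2/s^2 ~ 0.25); a strongly informative panel.
    return (
        BiomarkerSpec("systolic_bp", 95.0, 0.55, 3.5),
        BiomarkerSpec("albumin", 4.9, -0.005, 0.032),
        BiomarkerSpec("alkaline_phosphatase", 55.0, 0.25, 1.6),
        BiomarkerSpec("blood_urea_nitrogen", 8.0, 0.12, 0.76),
        BiomarkerSpec("creatinine", 0.75, 0.0035, 0.022),
        BiomarkerSpec("glycohemoglobin", 4.7, 0.018, 0.115),
        BiomarkerSpec("total_cholesterol", 160.0, 0.65, 4.1),
        BiomarkerSpec("lymphocyte_pct", 38.0, -0.13, 0.82),
        BiomarkerSpec("wbc_count", 7.8, -0.01, 0.063),
        BiomarkerSpec("mean_cell_volume", 85.0, 0.07, 0.44),
    )


def _default_diet_specs() -> tuple[DietIntakeSpec, ...]:
    # DI-GM components (servings or g per day; green tea defined, unscorable)
    return (
        DietIntakeSpec("avocado", 0.08, 0.06, 1.0),
        DietIntakeSpec("broccoli", 0.12, 0.10, 1.0),
        DietIntakeSpec("chickpeas", 0.05, 0.05, 1.0),
        DietIntakeSpec("coffee", 1.5, 1.6, 0.8),
        DietIntakeSpec("cranberries", 0.03, 0.03, 1.0),
        DietIntakeSpec("fermented_dairy", 0.6, 0.5, 0.9),
        DietIntakeSpec("fiber", 16.0, 18.0, 0.45),
        DietIntakeSpec("green_tea", 0.2, 0.15, 1.0),
        DietIntakeSpec("soybean", 0.1, 0.1, 1.0),
        DietIntakeSpec("whole_grains", 0.9, 1.0, 0.8),
        DietIntakeSpec("red_meat", 0.5, 0.8, 0.8),
        DietIntakeSpec("processed_meat", 0.3, 0.5, 0.9),
        DietIntakeSpec("refined_grains", 4.5, 5.5, 0.5),
    )


def _default_cdai_specs() -> tuple[DietIntakeSpec, ...]:
    # daily antioxidant intakes: vit A ug, vit C mg, vit E mg,
    # beta-carotene ug, selenium ug, zinc mg
    return (
        DietIntakeSpec("vitamin_a", 520.0, 600.0, 0.55),
        DietIntakeSpec("vitamin_c", 75.0, 85.0, 0.6),
        DietIntakeSpec("vitamin_e", 7.5, 9.0, 0.5),
        DietIntakeSpec("beta_carotene", 1800.0, 2000.0, 0.8),
        DietIntakeSpec("selenium", 95.0, 120.0, 0.45),
        DietIntakeSpec("zinc", 9.0, 12.0, 0.45),
    )


@dataclass
class SimulationConfig:
    n_participants: int = 5000
    n_strata: int = 15
    psus_per_stratum: int = 2
    weight_lognorm_mu: float = math.log(1000.0)
    weight_lognorm_sigma: float = 0.5
    age_range: tuple[float, float] = (20.0, 85.0)
    prop_female: float = 0.52
    biomarker_specs: tuple[BiomarkerSpec, ...] = field(default_factory=_default_biomarker_specs)
    latent_shift_years: float = 10.0
    exposure_model: ExposureModel = field(default_factory=ExposureModel)
    outcome_models: dict[str, OutcomeModel] = field(default_factory=dict)
    diet_specs: tuple[DietIntakeSpec, ...] = field(default_factory=_default_diet_specs)
    cdai_specs: tuple[DietIntakeSpec, ...] = field(default_factory=_default_cdai_specs)
    fat_share_mean: float = 0.34
    fat_share_sd: float = 0.06
    modifier_age_floor: float = 45.0  # modifier splits computed on age > floor
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.outcome_models:
            self.outcome_models = {
                "accelerated": OutcomeModel(
                    intercept=0.0,
                    beta_age=0.0,
                    beta_female=0.05,
                    log_or_exposure=math.log(1.64),
                ),
                "diarrhea": OutcomeModel(
                    intercept=float(logit(0.08)),
                    beta_age=0.01,
                    beta_female=0.1,
                    log_or_exposure=math.log(2.66),
                ),
            }

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be positive")
        if self.n_strata < 1 or self.psus_per_stratum < 1:
            raise ConfigurationError("n_strata and psus_per_stratum must be positive")
        if self.n_strata * self.psus_per_stratum < 2:
            raise ConfigurationError("design needs at least 2 PSUs in total (psus_per_stratum)")
        if self.n_participants < self.n_strata * self.psus_per_stratum:
            raise ConfigurationError(
                "n_participants must be at least n_strata * psus_per_stratum"
            )
        if not self.age_range[0] < self.age_range[1]:
            raise ConfigurationError("age_range must satisfy min < max")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ConfigurationError("prop_female must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if not self.weight_lognorm_sigma >= 0:
            raise ConfigurationError("weight_lognorm_sigma must be nonnegative")
        for spec in self.biomarker_specs:
            if spec.s_true < 0:
                raise ConfigurationError(f"biomarker_specs: s_true < 0 for {spec.name}")
        if not 0.0 < self.exposure_model.baseline_prev < 1.0:
            raise ConfigurationError("exposure_model.baseline_prev must lie in (0, 1)")
        for name, model in self.outcome_models.items():
            if model.modifier not in (None, "digm", "cdai", "joint"):
                raise ConfigurationError(f"outcome_models[{name!r}].modifier unknown")
            if model.modifier is not None and not model.stratum_map():
                raise ConfigurationError(
                    f"outcome_models[{name!r}]: modifier set but stratum_log_ors empty"
                )

    @classmethod
    def from_dict(cls, payload: dict) -> "SimulationConfig":
        kwargs = dict(payload)
        if "biomarker_specs" in kwargs:
            kwargs["biomarker_specs"] = tuple(BiomarkerSpec(**b) for b in kwargs["biomarker_specs"])
        for key in ("diet_specs", "cdai_specs"):
            if key in kwargs:
                kwargs[key] = tuple(DietIntakeSpec(**d) for d in kwargs[key])
        if "exposure_model" in kwargs:
            kwargs["exposure_model"] = ExposureModel(**kwargs["exposure_model"])
        if "outcome_models" in kwargs:
            models = {}
            for name, m in kwargs["outcome_models"].items():
                m = dict(m)
                if m.get("stratum_log_ors"):
                    m["stratum_log_ors"] = tuple(dict(m["stratum_log_ors"]).items())
                models[name] = OutcomeModel(**m)
            kwargs["outcome_models"] = models
        if "age_range" in kwargs:
            kwargs["age_range"] = tuple(kwargs["age_range"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)


def default_config(**overrides) -> SimulationConfig:
    """The default study conditions: overall planted ORs 1.64 (accelerated
    aging) and 2.66 (diarrhea) for recent antibiotic use."""
    return SimulationConfig(**overrides)


def _modified(
    modifier: str,
    accel_strata: dict[str, float],
    diarrhea_strata: dict[str, float],
    **overrides,
) -> SimulationConfig:
    cfg = SimulationConfig(**overrides)
    cfg.outcome_models = {
        "accelerated": OutcomeModel(
            intercept=0.0,
            beta_age=0.0,
            beta_female=0.05,
            modifier=modifier,
            stratum_log_ors=tuple((k, math.log(v)) for k, v in accel_strata.items()),
        ),
        "diarrhea": OutcomeModel(
            intercept=float(logit(0.08)),
            beta_age=0.01,
            beta_female=0.1,
            modifier=modifier,
            stratum_log_ors=tuple((k, math.log(v)) for k, v in diarrhea_strata.items()),
        ),
    }
    return cfg


def digm_modification_config(
    accel_or_low: float = 3.32,
    accel_or_high: float = 1.0,
    diarrhea_or_low: float = 3.77,
    diarrhea_or_high: float = 1.0,
    **overrides,
) -> SimulationConfig:
    """Effect modification by DI-GM: the low-diet-quality stratum carries the
    exposure effect for both outcomes, the high stratum defaults to null."""
    return _modified(
        "digm",
        {"low": accel_or_low, "high": accel_or_high},
        {"low": diarrhea_or_low, "high": diarrhea_or_high},
        **overrides,
    )


def cdai_modification_config(
    accel_or_low: float = 2.37,
    accel_or_high: float = 1.0,
    diarrhea_or_low: float = 3.60,
    diarrhea_or_high: float = 1.0,
    **overrides,
) -> SimulationConfig:
    """Effect modification by CDAI (antioxidant capacity) for both outcomes."""
    return _modified(
        "cdai",
        {"low": accel_or_low, "high": accel_or_high},
        {"low": diarrhea_or_low, "high": diarrhea_or_high},
        **overrides,
    )


def joint_modification_config(
    accel_or_double_low: float = 3.76,
    diarrhea_or_double_low: float = 4.39,
    or_other: float = 1.0,
    **overrides,
) -> SimulationConfig:
    """Joint DI-GM x CDAI modification: only the double-low group carries an
    exposure effect by default."""
    return _modified(
        "joint",
        {"double_low": accel_or_double_low, "single_low": or_other, "double_high": or_other},
        {"double_low": diarrhea_or_double_low, "single_low": or_other, "double_high": or_other},
        **overrides,
    )


def _draw_design(config: SimulationConfig, rng: np.random.Generator):
    n = config.n_participants
    # cyclic assignment then shuffle: every stratum holds exactly
    # psus_per_stratum PSUs whenever n >= n_strata * psus_per_stratum
    stratum = rng.permutation(np.arange(n) % config.n_strata)
    psu = np.empty(n, dtype=int)
    for s in range(config.n_strata):
        idx = np.flatnonzero(stratum == s)
        psu[idx] = rng.permutation(np.arange(idx.size) % config.psus_per_stratum)
    weight = rng.lognormal(config.weight_lognorm_mu, config.weight_lognorm_sigma, n)
    return stratum, psu, weight


def _draw_intakes(
    specs: tuple[DietIntakeSpec, ...], female: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    out = {}
    for spec in specs:
        med = np.where(female, spec.median_female, spec.median_male)
        out[spec.name] = np.exp(rng.normal(np.log(med), spec.sigma))
    return out


def _modifier_strata(
    df: pd.DataFrame, config: SimulationConfig
) -> dict[str, pd.Series]:
    """DI-GM / CDAI / joint group labels for every record, using component
    medians, CDAI references and index split points from the weighted
    age-restricted subsample — exactly what the analysis pipeline computes."""
    restricted = df[df["age"] > config.modifier_age_floor]
    weights = df["weight"]
    digm_cfg: DIGMConfig = default_digm_config()
    comp_medians = compute_component_medians(restricted, digm_cfg, weights=weights.loc[restricted.index])
    digm = compute_digm(df, digm_cfg, sex_medians=comp_medians)
    cdai_cfg = compute_sex_references(restricted, CDAI_NUTRIENTS, scale_kind="se")
    cdai = compute_cdai(df, cdai_cfg)
    _, digm_med = median_split(digm.loc[restricted.index], weights.loc[restricted.index])
    _, cdai_med = median_split(cdai.loc[restricted.index], weights.loc[restricted.index])
    digm_labels = pd.Series(
        np.where(digm >= digm_med, "high", "low"), index=df.index, name="digm_group"
    )
    cdai_labels = pd.Series(
        np.where(cdai >= cdai_med, "high", "low"), index=df.index, name="cdai_group"
    )
    return {
        "digm": digm_labels,
        "cdai": cdai_labels,
        "joint": joint_diet_groups(digm_labels, cdai_labels),
    }


def _outcome_draw(
    model: OutcomeModel,
    df: pd.DataFrame,
    strata: dict[str, pd.Series],
    rng: np.random.Generator,
) -> np.ndarray:
    age_c = df["age"].to_numpy() - 60.0
    female = (df["sex"] == "female").to_numpy().astype(float)
    exposure = df["antibiotic_use"].to_numpy().astype(float)
    if model.modifier is None:
        lor = np.full(len(df), model.log_or_exposure)
    else:
        lors = model.stratum_map()
        labels = strata[model.modifier]
        lor = labels.map(lors).to_numpy(dtype=float)
    lp = model.intercept + model.beta_age * age_c + model.beta_female * female + lor * exposure
    return (rng.random(len(df)) < expit(lp)).astype(int)


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw a full synthetic cohort; identical config + seed gives an
    identical table.

    The returned frame carries, besides the analysis columns, the
    ground-truth column ``true_accelerated`` (the generative accelerated
    status whose sign drives the latent biological-age shift).
    """
    config.validate()
    n = config.n_participants
    seed = config.seed

    rng_demo = _rng(seed, "demographics")
    age = rng_demo.uniform(config.age_range[0], config.age_range[1], n)
    female = rng_demo.random(n) < config.prop_female
    sex = np.where(female, "female", "male")
    race = rng_demo.choice(
        ["non_hispanic_white", "non_hispanic_black", "mexican_american", "other"],
        size=n,
        p=[0.45, 0.20, 0.20, 0.15],
    )
    marital = rng_demo.choice(
        ["married", "previously_married", "never_married"], size=n, p=[0.55, 0.25, 0.20]
    )
    income_poverty_ratio = rng_demo.uniform(0.3, 5.0, n)
    smoking = rng_demo.choice(["never", "former", "current"], size=n, p=[0.50, 0.25, 0.25])
    alcohol = (rng_demo.random(n) < 0.6).astype(int)
    energy_intake = np.clip(
        rng_demo.normal(np.where(female, 1850.0, 2350.0), np.where(female, 500.0, 600.0)),
        600.0,
        None,
    )
    bmi = np.clip(rng_demo.normal(28.5, 6.0, n), 15.0, None)
    crp = np.exp(rng_demo.normal(np.log(0.2), 1.0, n))  # mg/dL

    rng_design = _rng(seed, "design")
    stratum, psu, weight = _draw_design(config, rng_design)

    rng_diet = _rng(seed, "diet")
    diet = _draw_intakes(config.diet_specs, female, rng_diet)
    cdai_intakes = _draw_intakes(config.cdai_specs, female, rng_diet)
    fat_energy_share = np.clip(
        rng_diet.normal(config.fat_share_mean, config.fat_share_sd, n), 0.05, 0.70
    )

    rng_exp = _rng(seed, "exposure")
    em = config.exposure_model
    lp_exp = (
        float(logit(em.baseline_prev))
        + em.beta_age * (age - 60.0)
        + em.beta_female * female.astype(float)
    )
    antibiotic_use = (rng_exp.random(n) < expit(lp_exp)).astype(int)

    df = pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "age": age,
            "sex": sex,
            "race": race,
            "marital_status": marital,
            "income_poverty_ratio": income_poverty_ratio,
            "smoking": smoking,
            "alcohol": alcohol,
            "energy_intake": energy_intake,
            "bmi": bmi,
            "crp": crp,
            **diet,
            "fat_energy_share": fat_energy_share,
            **cdai_intakes,
            "antibiotic_use": antibiotic_use,
            "stratum_id": stratum,
            "psu_id": psu,
            "weight": weight,
        }
    )

    needs_strata = any(m.modifier for m in config.outcome_models.values())
    strata = _modifier_strata(df, config) if needs_strata else {}

    rng_out = _rng(seed, "outcomes")
    accel_model = config.outcome_models["accelerated"]
    true_accel = _outcome_draw(accel_model, df, strata, rng_out)
    df["diarrhea"] = _outcome_draw(config.outcome_models["diarrhea"], df, strata, rng_out)
    df["true_accelerated"] = true_accel

    # biomarkers track CA shifted by the latent accelerated/decelerated offset
    rng_bio = _rng(seed, "biomarkers")
    delta = config.latent_shift_years * (2.0 * true_accel - 1.0)
    for spec in config.biomarker_specs:
        noise = rng_bio.normal(0.0, spec.s_true, n) if spec.s_true > 0 else 0.0
        df[spec.name] = spec.q_true + spec.k_true * (age + delta) + noise

    df = df[
        [c for c in df.columns if c != "true_accelerated"] + ["true_accelerated"]
    ]

    if config.missing_rate > 0:
        targets = list(KDM_BIOMARKERS) + ["crp"]
        df = inject_missingness(df, config.missing_rate, targets, seed=seed)
    return df


def inject_missingness(
    cohort: pd.DataFrame, rate: float, columns: list[str], seed: int
) -> pd.DataFrame:
    """Independently blank each targeted cell with probability ``rate`` (MCAR)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    unknown = [c for c in columns if c not in cohort.columns]
    if unknown:
        raise KeyError(f"unknown column: {unknown[0]}")
    out = cohort.copy()
    if rate == 0.0:
        return out
    rng = _rng(seed, "missingness")
    for col in columns:
        mask = rng.random(len(out)) < rate
        out.loc[mask, col] = np.nan
    return out


def true_effect_summary(config: SimulationConfig) -> pd.DataFrame:
    """Planted exposure odds ratios, overall and per modifier stratum."""
    config.validate()
    rows = []
    for outcome, model in config.outcome_models.items():
        if model.modifier is None:
            rows.append(
                {
                    "outcome": outcome,
                    "modifier": "none",
                    "stratum": "overall",
                    "log_or": model.log_or_exposure,
                    "or": math.exp(model.log_or_exposure),
                }
            )
        else:
            for stratum, lor in model.stratum_map().items():
                rows.append(
                    {
                        "outcome": outcome,
                        "modifier": model.modifier,
                        "stratum": stratum,
                        "log_or": lor,
                        "or": math.exp(lor),
                    }
                )
    return pd.DataFrame(rows)
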