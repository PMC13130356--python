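"""Dietary indices: DI-GM (gut-microbiota diet index) and CDAI (composite
dietary antioxidant index).

The DI-GM is a sum of binary component scores over food groups / nutrients
classified as beneficial or unfavorable for the gut microbiota.  Beneficial
components score 1 when intake reaches the sex-specific median, unfavorable
components score 1 when intake stays below it; the high-fat-diet component
uses a fixed rule (energy share from fat < 40%).  With the default roster of
14 components, 13 of which are scorable in NHANES-like inputs, the score
ranges from 0 to 13 and higher values indicate a more gut-friendly diet.

The CDAI sums, over six antioxidant nutrients (vitamins A, C, E,
beta-carotene, selenium, zinc), the deviation of individual intake from the
sex-specific reference mean divided by the sex-specific scale:

    CDAI = sum_i (intake_i - Mean_i) / Scale_i

where the default scale is the standard error of the mean (``scale_kind="se"``)
with the standard deviation available via ``scale_kind="sd"``.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DietComponentRule",
    "DIGMConfig",
    "CDAIConfig",
    "default_digm_config",
    "CDAI_NUTRIENTS",
    "compute_sex_references",
    "compute_cdai",
    "compute_component_medians",
    "compute_digm",
    "weighted_median",
    "median_split",
    "joint_diet_groups",
]

#: the six CDAI nutrients, in scoring order
CDAI_NUTRIENTS = (
    "vitamin_a",
    "vitamin_c",
    "vitamin_e",
    "beta_carotene",
    "selenium",
    "zinc",
)


@dataclass(frozen=True)
class DietComponentRule:
    """Scoring rule for one DI-GM component.

    rule is one of:

    - ``"median_ge"``   score 1 when intake >= sex-specific median (beneficial)
    - ``"median_lt"``   score 1 when intake <  sex-specific median (unfavorable)
    - ``"fat_share_lt"`` score 1 when the energy share from fat < ``threshold``
      (the fixed-cutoff high-fat-diet component)
    """

    name: str
    direction: str  # 'beneficial' | 'unfavorable'
    rule: str  # 'median_ge' | 'median_lt' | 'fat_share_lt'
    scorable: bool = True
    threshold: float = 0.40

    def __post_init__(self) -> None:
        if self.direction not in ("beneficial", "unfavorable"):
            raise ValueError(f"unknown direction {self.direction!r} for {self.name}")
        if self.rule not in ("median_ge", "median_lt", "fat_share_lt"):
            raise ValueError(f"unknown rule {self.rule!r} for {self.name}")


@dataclass
class DIGMConfig:
    components: list[DietComponentRule] = field(default_factory=list)

    @property
    def scorable_components(self) -> list[DietComponentRule]:
        return [c for c in self.components if c.scorable]

    @property
    def max_score(self) -> int:
        """Attainable maximum: the number of scorable components."""
        return len(self.scorable_components)


def default_digm_config() -> DIGMConfig:
    """Default 14-component roster (13 scorable; green tea lacks intake data
    in NHANES-like inputs and is defined but not scored)."""
    beneficial = [
        "avocado",
        "broccoli",
        "chickpeas",
        "coffee",
        "cranberries",
        "fermented_dairy",
        "fiber",
        "green_tea",
        "soybean",
        "whole_grains",
    ]
    unfavorable = ["red_meat", "processed_meat", "refined_grains"]
    comps = [
        DietComponentRule(n, "beneficial", "median_ge", scorable=(n != "green_tea"))
        for n in beneficial
    ]
    comps += [DietComponentRule(n, "unfavorable", "median_lt") for n in unfavorable]
    comps.append(
        DietComponentRule("high_fat_diet", "unfavorable", "fat_share_lt", threshold=0.40)
    )
    return DIGMConfig(components=comps)


@dataclass
class CDAIConfig:
    """Reference table for CDAI scoring.

    ``reference`` maps (sex, nutrient) -> (mean, scale).
    """

    nutrients: tuple[str, ...] = CDAI_NUTRIENTS
    reference: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    scale_kind: str = "se"  # 'se' | 'sd'

    def validate(self) -> None:
        if self.scale_kind not in ("se", "sd"):
            raise ValueError(f"scale_kind must be 'se' or 'sd', got {self.scale_kind!r}")
        for key, (_, scale) in self.reference.items():
            if not scale > 0:
                raise ValueError(f"degenerate nutrient: nonpositive scale for {key}")


def compute_sex_references(
    cohort: pd.DataFrame,
    nutrient_names: tuple[str, ...] = CDAI_NUTRIENTS,
    scale_kind: str = "se",
    sex_col: str = "sex",
) -> CDAIConfig:
    """Sex-specific reference (mean, scale) per nutrient from the analytic sample.

    Scale is the standard error of the mean (SD/sqrt(n), SD with divisor n-1)
    for ``scale_kind='se'`` or the SD itself for ``'sd'``.
    """
    if scale_kind not in ("se", "sd"):
        raise ValueError(f"scale_kind must be 'se' or 'sd', got {scale_kind!r}")
    reference: dict[tuple[str, str], tuple[float, float]] = {}
    sexes = cohort[sex_col].dropna().unique()
    if len(sexes) < 2:
        raise ValueError("both sexes must be represented to build sex-specific references")
    for sex, grp in cohort.groupby(sex_col, observed=True):
        for nutrient in nutrient_names:
            vals = grp[nutrient].dropna().to_numpy(dtype=float)
            if vals.size < 2:
                raise ValueError(f"fewer than 2 records for sex={sex!r}, {nutrient}")
            sd = vals.std(ddof=1)
            scale = sd / np.sqrt(vals.size) if scale_kind == "se" else sd
            if not scale > 0:
                raise ValueError(f"degenerate nutrient: {nutrient} is constant for sex={sex!r}")
            reference[(sex, nutrient)] = (float(vals.mean()), float(scale))
    return CDAIConfig(nutrients=tuple(nutrient_names), reference=reference, scale_kind=scale_kind)


def compute_cdai(cohort: pd.DataFrame, config: CDAIConfig, sex_col: str = "sex") -> pd.Series:
    """Per-record CDAI; records missing any nutrient get NaN (complete-case)."""
    config.validate()
    cdai = pd.Series(np.nan, index=cohort.index, name="cdai")
    complete = cohort[list(config.nutrients)].notna().all(axis=1) & cohort[sex_col].notna()
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("compute_cdai: %d records incomplete on nutrients, excluded", n_dropped)
    for sex, grp in cohort[complete].groupby(sex_col, observed=True):
        total = np.zeros(len(grp))
        for nutrient in config.nutrients:
            mean, scale = config.reference[(sex, nutrient)]
            total += (grp[nutrient].to_numpy(dtype=float) - mean) / scale
        cdai.loc[grp.index] = total
    return cdai


def compute_component_medians(
    cohort: pd.DataFrame,
    config: DIGMConfig,
    weights: pd.Series | None = None,
    sex_col: str = "sex",
) -> dict[tuple[str, str], float]:
    """Sex-specific medians of median-ruled component intakes (weighted if
    weights given)."""
    medians: dict[tuple[str, str], float] = {}
    for sex, grp in cohort.groupby(sex_col, observed=True):
        for comp in config.scorable_components:
            if comp.rule == "fat_share_lt":
                continue
            vals = grp[comp.name]
            mask = vals.notna()
            if weights is not None:
                medians[(sex, comp.name)] = weighted_median(
                    vals[mask].to_numpy(dtype=float),
                    weights.loc[grp.index[mask]].to_numpy(dtype=float),
                )
            else:
                medians[(sex, comp.name)] = float(vals[mask].median())
    return medians


def compute_digm(
    cohort: pd.DataFrame,
    config: DIGMConfig | None = None,
    sex_medians: dict[tuple[str, str], float] | None = None,
    weights: pd.Series | None = None,
    sex_col: str = "sex",
    fat_share_col: str = "fat_energy_share",
) -> pd.Series:
    """Per-record DI-GM integer score in [0, max_score].

    Sex-specific component medians are computed from the cohort itself when not
    supplied. Records missing any scorable component are excluded (NaN score).
    """
    if config is None:
        config = default_digm_config()
    if sex_medians is None:
        sex_medians = compute_component_medians(cohort, config, weights=weights, sex_col=sex_col)

    needed = [
        fat_share_col if c.rule == "fat_share_lt" else c.name for c in config.scorable_components
    ]
    complete = cohort[needed].notna().all(axis=1) & cohort[sex_col].notna()
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("compute_digm: %d records incomplete on components, excluded", n_dropped)

    score = pd.Series(np.nan, index=cohort.index, name="digm")
    sub = cohort[complete]
    total = np.zeros(len(sub))
    sex = sub[sex_col].to_numpy()
    for comp in config.scorable_components:
        if comp.rule == "fat_share_lt":
            total += (sub[fat_share_col].to_numpy(dtype=float) < comp.threshold).astype(int)
            continue
        med = np.array([sex_medians[(s, comp.name)] for s in sex])
        vals = sub[comp.name].to_numpy(dtype=float)
        if comp.rule == "median_ge":
            total += (vals >= med).astype(int)
        else:
            total += (vals < med).astype(int)
    score.loc[sub.index] = total
    return score


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Classic weighted median.

    The smallest value whose cumulative weight reaches half the total; when a
    value's cumulative weight equals the half exactly, the average of that
    value and the next is returned (so equal weights reproduce the ordinary
    sample median).
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("no values to take a median of")
    if np.any(weights <= 0):
        raise ValueError("weights must be strictly positive")
    order = np.argsort(values, kind="mergesort")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    half = cum[-1] / 2.0
    idx = int(np.searchsorted(cum, half, side="left"))
    if np.isclose(cum[idx], half):
        if idx + 1 < v.size:
            return float((v[idx] + v[idx + 1]) / 2.0)
        return float(v[idx])
    return float(v[idx])


def median_split(
    values: pd.Series,
    weights: pd.Series | None = None,
) -> tuple[pd.Series, float]:
    """Dichotomize at the (survey-weighted) median: 'high' iff value >= median.

    Returns (labels, median). Missing values get missing labels. With all
    values identical everyone is 'high' and a warning is emitted.
    """
    mask = values.notna()
    if int(mask.sum()) < 2:
        raise ValueError("median_split needs at least 2 non-missing values")
    vals = values[mask].to_numpy(dtype=float)
    if weights is not None:
        med = weighted_median(vals, weights.loc[values.index[mask]].to_numpy(dtype=float))
    else:
        med = float(np.median(vals))
    if np.all(vals == vals[0]):
        warnings.warn("median_split: all values identical; everyone labeled 'high'")
    labels = pd.Series(pd.NA, index=values.index, dtype="object", name=f"{values.name}_group")
    labels[mask] = np.where(vals >= med, "high", "low")
    return labels, med


def joint_diet_groups(digm_labels: pd.Series, cdai_labels: pd.Series) -> pd.Series:
    """Joint DI-GM x CDAI grouping: double_low (both low), single_low (exactly
    one low), double_high (both high). Mutually exclusive and exhaustive on
    records labeled for both indices."""
    groups = pd.Series(pd.NA, index=digm_labels.index, dtype="object", name="joint_group")
    both = digm_labels.notna() & cdai_labels.notna()
    n_low = (digm_labels[both] == "low").astype(int) + (cdai_labels[both] == "low").astype(int)
    groups[both] = n_low.map({2: "double_low", 1: "single_low", 0: "double_high"})
    return groups
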