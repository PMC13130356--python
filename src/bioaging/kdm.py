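"""Klemera-Doubal biological age (KDM) estimation and age acceleration.

The estimator combines per-biomarker ordinary least squares regressions on
chronological age (CA) into a precision-weighted composite anchored by CA:

    KDM = [ sum_i (x_i - q_i) k_i / s_i^2  +  CA / s_BA^2 ]
          / [ sum_i k_i^2 / s_i^2  +  1 / s_BA^2 ]

where q_i, k_i, s_i are the intercept, slope and root mean squared error of
the regression of biomarker x_i on CA, and s_BA scales how strongly CA
anchors the estimate (semantically, the SD of true biological-age deviation
from CA).  Age acceleration is the residual of KDM age regressed on CA;
"accelerated" is residual above a configurable threshold (default 0).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "BiomarkerFit",
    "KDMModel",
    "fit_biomarker_regressions",
    "estimate_sba",
    "fit_kdm",
    "compute_kdm",
    "compute_age_acceleration",
    "score_cohort",
]

#: floor applied to s_i when evaluating KDM weights (guards noiseless fits)
_S_FLOOR = 1e-8
#: floor inside the s_BA variance decomposition
_SBA_VAR_FLOOR = 1e-6


@dataclass(frozen=True)
class BiomarkerFit:
    """OLS fit of one biomarker on chronological age."""

    name: str
    q: float  # intercept, biomarker units
    k: float  # slope, biomarker units per year
    s: float  # root mean squared error, biomarker units
    n_train: int

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError(f"{self.name}: negative RMSE")
        if self.n_train < 3:
            raise ValueError(f"{self.name}: fewer than 3 training records")


@dataclass
class KDMModel:
    fits: list[BiomarkerFit]
    s_ba: float
    sba_method: str = "variance_decomposition"
    rmse_divisor: str = "n"

    def __post_init__(self) -> None:
        if not self.s_ba > 0:
            raise ValueError("s_ba must be positive")
        if not any(f.k != 0 for f in self.fits):
            raise ValueError("no informative biomarkers: all slopes are zero")

    @property
    def biomarker_names(self) -> list[str]:
        return [f.name for f in self.fits]

    def to_file(self, path) -> None:
        payload = {
            "s_ba": float(self.s_ba),
            "sba_method": self.sba_method,
            "rmse_divisor": self.rmse_divisor,
            "biomarkers": [
                {
                    "name": f.name,
                    "q": float(f.q),
                    "k": float(f.k),
                    "s": float(f.s),
                    "n_train": int(f.n_train),
                }
                for f in self.fits
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "KDMModel":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        fits = [BiomarkerFit(**b) for b in payload["biomarkers"]]
        return cls(
            fits=fits,
            s_ba=payload["s_ba"],
            sba_method=payload.get("sba_method", "file"),
            rmse_divisor=payload.get("rmse_divisor", "n"),
        )


def _ols_line(ca: np.ndarray, x: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Closed-form simple OLS of x on ca; returns (intercept, slope, residuals)."""
    ca_mean, x_mean = ca.mean(), x.mean()
    sxx = float(np.sum((ca - ca_mean) ** 2))
    if sxx == 0.0:
        raise ValueError("degenerate age column: chronological age is constant")
    slope = float(np.sum((ca - ca_mean) * (x - x_mean)) / sxx)
    intercept = float(x_mean - slope * ca_mean)
    resid = x - (intercept + slope * ca)
    return intercept, slope, resid


def fit_biomarker_regressions(
    cohort: pd.DataFrame,
    biomarker_names: list[str],
    age_col: str = "age",
    rmse_divisor: str = "n",
) -> list[BiomarkerFit]:
    """Regress each biomarker on chronological age (complete cases per marker).

    RMSE uses divisor n by default (``rmse_divisor='n'``); the unbiased-variance
    flavour sqrt(RSS/(n-2)) is available with ``'n-2'``.
    """
    if rmse_divisor not in ("n", "n-2"):
        raise ValueError("rmse_divisor must be 'n' or 'n-2'")
    fits = []
    for name in biomarker_names:
        if name not in cohort.columns:
            raise KeyError(f"required column missing: {name}")
        sub = cohort[[age_col, name]].dropna()
        n = len(sub)
        if n < 3:
            raise ValueError(f"{name}: fewer than 3 complete records")
        ca = sub[age_col].to_numpy(dtype=float)
        x = sub[name].to_numpy(dtype=float)
        q, k, resid = _ols_line(ca, x)
        denom = n if rmse_divisor == "n" else n - 2
        s = float(np.sqrt(np.sum(resid**2) / denom))
        if k == 0.0:
            warnings.warn(f"biomarker {name} has zero slope on age and carries zero KDM weight")
        fits.append(BiomarkerFit(name=name, q=q, k=k, s=s, n_train=n))
    return fits


def _kdm_weights(fits: list[BiomarkerFit]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    q = np.array([f.q for f in fits])
    k = np.array([f.k for f in fits])
    s = np.maximum(np.array([f.s for f in fits]), _S_FLOOR)
    return q, k, s


def _ba_e(cohort: pd.DataFrame, fits: list[BiomarkerFit]) -> pd.Series:
    """Unscaled biomarker-only estimate BA_E = sum((x-q)k/s^2) / sum(k^2/s^2)."""
    q, k, s = _kdm_weights(fits)
    names = [f.name for f in fits]
    X = cohort[names].to_numpy(dtype=float)
    num = ((X - q) * (k / s**2)).sum(axis=1)
    den = float(np.sum(k**2 / s**2))
    if den == 0.0:
        raise ValueError("no informative biomarkers: all slopes are zero")
    return pd.Series(num / den, index=cohort.index, name="ba_e")


def estimate_sba(
    cohort: pd.DataFrame,
    fits: list[BiomarkerFit],
    age_col: str = "age",
) -> float:
    """Variance-decomposition estimate of the chronological-age scaling factor.

    s_BA^2 is the variance of BA_E - CA in excess of the estimation-noise
    variance 1 / sum(k_i^2/s_i^2) of BA_E, floored at 1e-6. The excess is the
    part attributable to true biological-age deviation from CA.
    """
    names = [f.name for f in fits]
    sub = cohort[[age_col] + names].dropna()
    ba_e = _ba_e(sub, fits)
    dev = ba_e.to_numpy() - sub[age_col].to_numpy(dtype=float)
    _, k, s = _kdm_weights(fits)
    noise_var = 1.0 / float(np.sum(k**2 / s**2))
    excess = float(np.var(dev, ddof=1)) - noise_var
    if excess <= _SBA_VAR_FLOOR:
        warnings.warn(
            "estimate_sba: variance of BA_E - CA does not exceed estimation noise; "
            "s_ba floored"
        )
        excess = _SBA_VAR_FLOOR
    return float(np.sqrt(excess))


def fit_kdm(
    cohort: pd.DataFrame,
    biomarker_names: list[str],
    age_col: str = "age",
    rmse_divisor: str = "n",
    s_ba: float | None = None,
) -> KDMModel:
    """Train a KDM model: per-biomarker regressions plus the s_BA scale.

    A fixed ``s_ba`` may be supplied for strict reproduction of external
    models; otherwise the variance-decomposition estimator is used.
    """
    fits = fit_biomarker_regressions(cohort, biomarker_names, age_col, rmse_divisor)
    if s_ba is None:
        s_ba_val = estimate_sba(cohort, fits, age_col)
        method = "variance_decomposition"
    else:
        if not s_ba > 0:
            raise ValueError("s_ba must be positive")
        s_ba_val, method = float(s_ba), "fixed"
    return KDMModel(fits=fits, s_ba=s_ba_val, sba_method=method, rmse_divisor=rmse_divisor)


def compute_kdm(model: KDMModel, cohort: pd.DataFrame, age_col: str = "age") -> pd.DataFrame:
    """Evaluate the KDM formula per record; incomplete records are excluded
    (count logged)."""
    names = model.biomarker_names
    missing_cols = [c for c in names + [age_col] if c not in cohort.columns]
    if missing_cols:
        raise KeyError(f"required column missing: {missing_cols[0]}")
    complete = cohort[names + [age_col]].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("compute_kdm: %d records incomplete on biomarkers/age, excluded", n_dropped)
    sub = cohort[complete]
    q, k, s = _kdm_weights(model.fits)
    X = sub[names].to_numpy(dtype=float)
    ca = sub[age_col].to_numpy(dtype=float)
    num = ((X - q) * (k / s**2)).sum(axis=1) + ca / model.s_ba**2
    den = float(np.sum(k**2 / s**2)) + 1.0 / model.s_ba**2
    return pd.DataFrame({"kdm_age": num / den}, index=sub.index)


def compute_age_acceleration(
    scores: pd.DataFrame,
    cohort: pd.DataFrame,
    age_col: str = "age",
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Residual of KDM age on CA (OLS with intercept, fit on the scored
    sample); ``accelerated`` flags residuals above ``threshold``."""
    if len(scores) < 3:
        raise ValueError("need at least 3 scored records to residualize")
    ca = cohort.loc[scores.index, age_col].to_numpy(dtype=float)
    kdm_age = scores["kdm_age"].to_numpy(dtype=float)
    intercept, slope, resid = _ols_line(ca, kdm_age)
    out = scores.copy()
    out["acceleration"] = resid
    out["accelerated"] = (resid > threshold).astype(int)
    logger.debug("acceleration regression: intercept=%.4f slope=%.4f", intercept, slope)
    return out


def score_cohort(
    model: KDMModel,
    cohort: pd.DataFrame,
    age_col: str = "age",
    threshold: float = 0.0,
) -> pd.DataFrame:
    """KDM age, acceleration residual and accelerated flag in one call."""
    scores = compute_kdm(model, cohort, age_col=age_col)
    return compute_age_acceleration(scores, cohort, age_col=age_col, threshold=threshold)
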