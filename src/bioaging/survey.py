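"""Design-based logistic regression for stratified cluster samples.

Point estimates maximize the survey-weighted pseudo-log-likelihood (Newton /
iteratively reweighted least squares).  The covariance is the Taylor
linearization sandwich: between-PSU variability of weighted score totals
within strata, with the customary n_h/(n_h - 1) small-sample factor per
stratum, pre- and post-multiplied by the inverse pseudo-information.  A
stratum holding a single PSU is handled with the "adjust" convention: its
score total is centered at the grand mean of all PSU totals (factor 1) and a
warning is logged rather than raising.

Confidence intervals are on the log-odds scale with the normal 0.975
quantile by default; Student t with the design degrees of freedom
(total PSUs - total strata) is available via ``ci_method='t'``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy.special import expit
from scipy.stats import norm, t as student_t

logger = logging.getLogger(__name__)

__all__ = [
    "SurveyDesign",
    "SurveyLogisticResult",
    "SeparationError",
    "combine_cycle_weights",
    "fit_survey_logistic",
    "odds_ratio_table",
]

_MAX_ITER = 100
_GRAD_TOL = 1e-8  # sup-norm on the gradient with weights normalized to mean 1
_SEPARATION_BETA = 15.0


class SeparationError(RuntimeError):
    """Raised when a coefficient diverges (perfect or quasi-separation)."""


def _check_separation(beta: np.ndarray, col_sd: np.ndarray, terms: list[str]) -> None:
    beta_std = np.abs(beta) * col_sd
    if np.max(beta_std) > _SEPARATION_BETA:
        worst = terms[int(np.argmax(beta_std))]
        raise SeparationError(f"separation detected: coefficient for {worst!r} diverging")


@dataclass(frozen=True)
class SurveyDesign:
    """Column names identifying the complex-sample design in a data frame."""

    stratum: str = "stratum_id"
    psu: str = "psu_id"
    weight: str = "weight"
    n_cycles: int = 1


def combine_cycle_weights(weights, n_cycles: int):
    """Adjust weights for pooling survey cycles: divide each by n_cycles."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    out = w / n_cycles
    if isinstance(weights, pd.Series):
        return pd.Series(out, index=weights.index, name=weights.name)
    return out


@dataclass
class SurveyLogisticResult:
    terms: list[str]
    beta: np.ndarray
    cov: np.ndarray  # design-based covariance of beta
    n_used: int
    n_dropped: int
    design_df: int
    n_iter: int
    converged: bool
    ci_method: str = "normal"
    formula: str = ""
    warnings_: list[str] = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def or_(self) -> np.ndarray:
        return np.exp(self.beta)

    def _quantile(self) -> float:
        if self.ci_method == "t":
            return float(student_t.ppf(0.975, max(self.design_df, 1)))
        return float(norm.ppf(0.975))

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.beta - self._quantile() * self.se)

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.beta + self._quantile() * self.se)

    @property
    def p_values(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.beta / self.se
        return 2 * norm.sf(np.abs(z))

    def term_index(self, term: str) -> int:
        matches = [i for i, name in enumerate(self.terms) if name == term or term in name]
        if not matches:
            raise KeyError(f"term {term!r} not in model: {self.terms}")
        return matches[0]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "or": self.or_,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p_values,
            },
            index=pd.Index(self.terms, name="term"),
        )


def _pll(X: np.ndarray, y: np.ndarray, w: np.ndarray, beta: np.ndarray) -> float:
    eta = np.clip(X @ beta, -30.0, 30.0)
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def _irls(X: np.ndarray, y: np.ndarray, w: np.ndarray, terms: list[str]):
    """Newton maximization of the weighted pseudo-log-likelihood with
    step-halving when a full Newton step would decrease the objective.

    Divergence is judged on the scale-free coefficient |beta_j| * sd(x_j),
    invariant to covariate units; the intercept is exempt (its magnitude
    tracks the centering of uncentred covariates, not separation).
    """
    n, p = X.shape
    beta = np.zeros(p)
    col_sd = X.std(axis=0)  # 0 for the intercept/constant columns, exempting them
    ll = _pll(X, y, w, beta)
    grad_norm = np.inf
    for it in range(1, _MAX_ITER + 1):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = expit(eta)
        grad = X.T @ (w * (y - mu))
        grad_norm = float(np.max(np.abs(grad)))
        if grad_norm < _GRAD_TOL:
            _check_separation(beta, col_sd, terms)
            return beta, mu, it, True
        v = w * mu * (1.0 - mu)
        H = (X * v[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            H = H + 1e-10 * np.eye(p)
            step = np.linalg.solve(H, grad)
        scale = 1.0
        for _ in range(30):
            candidate = beta + scale * step
            ll_new = _pll(X, y, w, candidate)
            if ll_new >= ll - 1e-12 * abs(ll):
                break
            scale /= 2.0
        beta = beta + scale * step
        ll = _pll(X, y, w, beta)
        if grad_norm > 1e-4:
            _check_separation(beta, col_sd, terms)
    _check_separation(beta, col_sd, terms)
    eta = np.clip(X @ beta, -30.0, 30.0)
    return beta, expit(eta), _MAX_ITER, grad_norm < _GRAD_TOL


def _taylor_cov(
    X: np.ndarray,
    y: np.ndarray,
    mu: np.ndarray,
    w: np.ndarray,
    strata: np.ndarray,
    psus: np.ndarray,
    warnings_out: list[str],
) -> tuple[np.ndarray, int]:
    """Stratified-cluster linearization sandwich and design df."""
    p = X.shape[1]
    U = X * (w * (y - mu))[:, None]  # per-record weighted score contributions

    # PSU totals of the score, grouped by (stratum, psu)
    totals = (
        pd.DataFrame(U)
        .groupby([pd.Series(strata), pd.Series(psus)], sort=False)
        .sum()
    )
    stratum_of_psu = totals.index.get_level_values(0).to_numpy()
    Z = totals.to_numpy()
    grand_mean = Z.mean(axis=0)

    G = np.zeros((p, p))
    n_psu_total = 0
    unique_strata = pd.unique(stratum_of_psu)
    for h in unique_strata:
        Zh = Z[stratum_of_psu == h]
        n_h = Zh.shape[0]
        n_psu_total += n_h
        if n_h == 1:
            dev = Zh[0] - grand_mean
            G += np.outer(dev, dev)
            warnings_out.append(f"stratum {h!r} has a single PSU; centered at the grand mean")
        else:
            dev = Zh - Zh.mean(axis=0)
            G += (n_h / (n_h - 1)) * dev.T @ dev

    if warnings_out:
        logger.warning(
            "%d strata have a single PSU; scores centered at the grand mean",
            len(warnings_out),
        )
    v = w * mu * (1.0 - mu)
    B = (X * v[:, None]).T @ X
    Binv = np.linalg.inv(B)
    cov = Binv @ G @ Binv
    cov = (cov + cov.T) / 2.0
    design_df = int(n_psu_total - len(unique_strata))
    return cov, design_df


def fit_survey_logistic(
    formula: str,
    data: pd.DataFrame,
    design: SurveyDesign = SurveyDesign(),
    ci_method: str = "normal",
) -> SurveyLogisticResult:
    """Fit ``outcome ~ terms`` by weighted pseudo-likelihood with
    design-based (Taylor linearization) covariance.

    The model frame is strict complete-case: rows with a missing value in any
    model variable or design column are dropped and counted.
    """
    for col in (design.stratum, design.psu, design.weight):
        if col not in data.columns:
            raise KeyError(f"required column missing: {col}")
    y_mat, X_mat = patsy.dmatrices(formula, data, return_type="dataframe", NA_action="drop")
    keep = X_mat.index[
        data.loc[X_mat.index, [design.stratum, design.psu, design.weight]].notna().all(axis=1)
    ]
    X_mat, y_mat = X_mat.loc[keep], y_mat.loc[keep]
    n_used = len(X_mat)
    n_dropped = len(data) - n_used
    if n_dropped:
        logger.info("fit_survey_logistic: %d records dropped (incomplete model frame)", n_dropped)
    if n_used == 0:
        raise ValueError("empty model frame after complete-case filtering")

    y = y_mat.to_numpy(dtype=float).ravel()
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValueError(f"outcome must be binary 0/1, found values {uniq[:5]}")

    w_raw = data.loc[keep, design.weight].to_numpy(dtype=float)
    if np.any(w_raw <= 0):
        raise ValueError("weights must be strictly positive")
    if design.n_cycles > 1:
        w_raw = combine_cycle_weights(w_raw, design.n_cycles)
    w = w_raw / w_raw.mean()  # scale-invariant; keeps the gradient tolerance meaningful

    X = X_mat.to_numpy(dtype=float)
    terms = list(X_mat.columns)
    beta, mu, n_iter, converged = _irls(X, y, w, terms)

    warn_list: list[str] = []
    strata = data.loc[keep, design.stratum].to_numpy()
    psus = data.loc[keep, design.psu].to_numpy()
    cov, design_df = _taylor_cov(X, y, mu, w, strata, psus, warn_list)

    return SurveyLogisticResult(
        terms=terms,
        beta=beta,
        cov=cov,
        n_used=n_used,
        n_dropped=n_dropped,
        design_df=design_df,
        n_iter=n_iter,
        converged=converged,
        ci_method=ci_method,
        formula=formula,
        warnings_=warn_list,
    )


def odds_ratio_table(
    results: list[SurveyLogisticResult],
    focus_term: str,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Forest-style table: one row per fitted model for the focal exposure term.

    Rows preserve input order. Full-precision columns plus 2-decimal display.
    """
    if labels is None:
        labels = [f"model_{i + 1}" for i in range(len(results))]
    if len(labels) != len(results):
        raise ValueError("labels must match results in length")
    rows = []
    for label, res in zip(labels, results):
        i = res.term_index(focus_term)
        or_, lo, hi = res.or_[i], res.ci_low[i], res.ci_high[i]
        rows.append(
            {
                "label": label,
                "term": res.terms[i],
                "or": or_,
                "ci_low": lo,
                "ci_high": hi,
                "p": res.p_values[i],
                "n": res.n_used,
                "display": f"{or_:.2f} ({lo:.2f}-{hi:.2f})",
            }
        )
    return pd.DataFrame(rows)
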