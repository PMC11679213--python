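"""Age-adjusted linear and logistic dose–response models.

Sex-stratified fits of each renal endpoint on urinary cadmium (μg/g Cr) and
age, with the significance gate that decides whether benchmark-dose
estimation proceeds.  OLS uses t-based confidence intervals (small-sample
study); logistic maximum likelihood uses Newton iterations with Wald
normal-based intervals on the log-odds scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import lstsq
from scipy.special import expit
from scipy.stats import norm, t as t_dist

__all__ = [
    "LinearFit",
    "LogisticFit",
    "SeparationError",
    "ConvergenceError",
    "fit_linear_age_adjusted",
    "fit_logistic_age_adjusted",
    "significance_gate",
    "CONTINUOUS_ENDPOINTS",
    "FLAG_ENDPOINTS",
]

CONTINUOUS_ENDPOINTS = ("crcl", "egfr", "ln_b2mg")
FLAG_ENDPOINTS = ("tr_below_95", "tr_below_90")
PARAM_NAMES = ("intercept", "u_cd", "age")

MIN_RECORDS = 10
SIGNIFICANCE_LEVEL = 0.05


class SeparationError(RuntimeError):
    """Complete/quasi-complete separation: the logistic MLE does not exist."""


class ConvergenceError(RuntimeError):
    """Newton iterations failed to reach the gradient tolerance."""


@dataclass
class LinearFit:
    """OLS fit of endpoint ~ 1 + u_cd + age with normal residuals."""

    endpoint: str
    sex: str
    params: np.ndarray          # (intercept, beta_dose, beta_age)
    cov: np.ndarray             # 3x3 coefficient covariance
    residual_sd: float          # sqrt(RSS / (n - 3))
    n: int
    pvalues: np.ndarray
    conf_int: np.ndarray        # 3x2, 95% t-based
    n_excluded: dict = field(default_factory=dict)
    design: np.ndarray | None = None    # retained for profile-likelihood BMDLs
    response: np.ndarray | None = None

    kind = "linear"

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def beta_dose(self) -> float:
        return float(self.params[1])

    @property
    def beta_age(self) -> float:
        return float(self.params[2])

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def p_dose(self) -> float:
        return float(self.pvalues[1])

    def to_dict(self) -> dict:
        return {
            "kind": "linear",
            "endpoint": self.endpoint,
            "sex": self.sex,
            "params": self.params.tolist(),
            "cov": self.cov.tolist(),
            "residual_sd": self.residual_sd,
            "n": self.n,
            "pvalues": self.pvalues.tolist(),
            "conf_int": self.conf_int.tolist(),
            "n_excluded": self.n_excluded,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearFit":
        d = dict(d)
        d.pop("kind", None)
        for key in ("params", "cov", "pvalues", "conf_int"):
            d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit of a dichotomous flag ~ 1 + u_cd + age."""

    endpoint: str
    sex: str
    params: np.ndarray
    cov: np.ndarray
    n: int
    pvalues: np.ndarray
    conf_int: np.ndarray        # 3x2 on the log-odds scale, Wald
    converged: bool
    n_excluded: dict = field(default_factory=dict)
    design: np.ndarray | None = None
    response: np.ndarray | None = None

    kind = "logistic"

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def beta_dose(self) -> float:
        return float(self.params[1])

    @property
    def beta_age(self) -> float:
        return float(self.params[2])

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def p_dose(self) -> float:
        return float(self.pvalues[1])

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    @property
    def or_conf_int(self) -> np.ndarray:
        return np.exp(self.conf_int)

    def to_dict(self) -> dict:
        return {
            "kind": "logistic",
            "endpoint": self.endpoint,
            "sex": self.sex,
            "params": self.params.tolist(),
            "cov": self.cov.tolist(),
            "n": self.n,
            "pvalues": self.pvalues.tolist(),
            "conf_int": self.conf_int.tolist(),
            "converged": self.converged,
            "n_excluded": self.n_excluded,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticFit":
        d = dict(d)
        d.pop("kind", None)
        for key in ("params", "cov", "pvalues", "conf_int"):
            d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


def _model_frame(markers: pd.DataFrame, value_col: str, sex: str):
    """Listwise-complete (y, dose, age) arrays for one sex, with exclusion counts."""
    if sex not in ("man", "woman"):
        raise ValueError("sex must be man|woman")
    sub = markers.loc[markers["sex"] == sex, ["u_cd", "age", value_col]]
    n_total = len(sub)
    complete = sub.dropna()
    excluded = {"missing": int(n_total - len(complete)), "total": int(n_total)}
    return complete, excluded


def fit_linear_age_adjusted(markers: pd.DataFrame, endpoint: str, sex: str) -> LinearFit:
    """OLS of a continuous endpoint on [1, U-Cd, age] within one sex.

    ``ln_b2mg`` takes the natural log of the creatinine-corrected urinary
    β2-MG; non-positive values are excluded with a logged count (no
    pseudo-count policy exists for this assay).
    """
    if endpoint not in CONTINUOUS_ENDPOINTS:
        raise ValueError(f"endpoint must be one of {CONTINUOUS_ENDPOINTS}")

    df = markers
    excluded_nonpos = 0
    if endpoint == "ln_b2mg":
        if "ln_b2mg" in df.columns:
            value_col = "ln_b2mg"
        else:
            df = df.copy()
            nonpos = df["u_b2mg"].notna() & (df["u_b2mg"] <= 0) & (df["sex"] == sex)
            excluded_nonpos = int(nonpos.sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                df["ln_b2mg"] = np.where(df["u_b2mg"] > 0, np.log(df["u_b2mg"]), np.nan)
            value_col = "ln_b2mg"
    else:
        value_col = endpoint

    complete, excluded = _model_frame(df, value_col, sex)
    excluded["nonpositive_b2mg"] = excluded_nonpos
    n = len(complete)
    if n < MIN_RECORDS:
        raise ValueError(f"{endpoint}/{sex}: only {n} usable records (< {MIN_RECORDS})")

    y = complete[value_col].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(n), complete["u_cd"].to_numpy(float), complete["age"].to_numpy(float)]
    )
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError(f"{endpoint}/{sex}: rank-deficient design matrix")

    beta, _, _, _ = lstsq(X, y)
    resid = y - X @ beta
    dof = n - 3
    rss = float(resid @ resid)
    sigma = np.sqrt(rss / dof)
    xtx_inv = np.linalg.inv(X.T @ X)
    cov = sigma**2 * xtx_inv
    se = np.sqrt(np.diag(cov))
    tstat = beta / se
    pvalues = 2.0 * t_dist.sf(np.abs(tstat), dof)
    tcrit = t_dist.ppf(0.975, dof)
    conf = np.column_stack([beta - tcrit * se, beta + tcrit * se])

    return LinearFit(
        endpoint=endpoint,
        sex=sex,
        params=beta,
        cov=cov,
        residual_sd=float(sigma),
        n=n,
        pvalues=pvalues,
        conf_int=conf,
        n_excluded=excluded,
        design=X,
        response=y,
    )


def logistic_loglik(params: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Bernoulli log-likelihood, numerically stable via log1p(exp)."""
    eta = X @ params
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic_age_adjusted(
    markers: pd.DataFrame,
    flag: str,
    sex: str,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Logistic ML fit of a reabsorption flag on [1, U-Cd, age] within one sex.

    Newton iterations with step halving until the score norm drops below
    ``tol``.  Monotone likelihood (complete separation) raises
    :class:`SeparationError`; hitting ``max_iter`` raises
    :class:`ConvergenceError`.
    """
    if flag not in FLAG_ENDPOINTS:
        raise ValueError(f"flag must be one of {FLAG_ENDPOINTS}")
    complete, excluded = _model_frame(markers, flag, sex)
    n = len(complete)
    if n < MIN_RECORDS:
        raise ValueError(f"{flag}/{sex}: only {n} usable records (< {MIN_RECORDS})")
    y = complete[flag].to_numpy(dtype=float)
    if not set(np.unique(y)).issubset({0.0, 1.0}):
        raise ValueError(f"{flag}/{sex}: outcome must be 0/1")
    if y.min() == y.max():
        raise SeparationError(
            f"{flag}/{sex}: outcome is constant ({int(y[0])} for all records); "
            "logistic MLE does not exist"
        )
    X = np.column_stack(
        [np.ones(n), complete["u_cd"].to_numpy(float), complete["age"].to_numpy(float)]
    )
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError(f"{flag}/{sex}: rank-deficient design matrix")

    beta = np.zeros(3)
    ll = logistic_loglik(beta, X, y)
    converged = False
    hess = None
    for _ in range(max_iter):
        p = expit(X @ beta)
        grad = X.T @ (y - p)
        if np.linalg.norm(grad, ord=np.inf) < tol:
            converged = True
            break
        w = p * (1.0 - p)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                f"{flag}/{sex}: singular information matrix (separation suspected)"
            ) from exc
        # Step-halving to guarantee likelihood ascent.
        scale = 1.0
        for _ in range(60):
            candidate = beta + scale * step
            ll_new = logistic_loglik(candidate, X, y)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll = logistic_loglik(beta, X, y)
        if np.abs(beta).max() > 1e2:
            raise SeparationError(
                f"{flag}/{sex}: diverging coefficients (|beta| > 100); "
                "complete separation suspected"
            )
    if not converged:
        raise ConvergenceError(f"{flag}/{sex}: no convergence in {max_iter} iterations")

    p = expit(X @ beta)
    w = p * (1.0 - p)
    hess = (X * w[:, None]).T @ X
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvalues = 2.0 * norm.sf(np.abs(z))
    zcrit = norm.ppf(0.975)
    conf = np.column_stack([beta - zcrit * se, beta + zcrit * se])

    return LogisticFit(
        endpoint=flag,
        sex=sex,
        params=beta,
        cov=cov,
        n=n,
        pvalues=pvalues,
        conf_int=conf,
        converged=converged,
        n_excluded=excluded,
        design=X,
        response=y,
    )


def significance_gate(fit) -> str:
    """``proceed`` iff the two-sided dose p-value is below 0.05, else ``skip``."""
    return "proceed" if fit.p_dose < SIGNIFICANCE_LEVEL else "skip"
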