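"""Benchmark-dose estimation: hybrid approach and logistic additional risk.

Continuous endpoints use the hybrid approach under a normal residual model
around the age-adjusted linear fit: the cut-off is the endpoint level whose
background tail probability equals P(0), and the BMD is the dose at which
the adverse-tail probability rises from P(0) by the benchmark response
(additional risk) or by BMR·(1−P(0)) (extra risk).  Dichotomous
reabsorption flags use the logistic model, with the background prevalence
estimated from the fit at zero dose and a reference age.

BMDLs are one-sided lower 95% confidence limits, by profile likelihood
(default; requires the fit to retain its data), the delta method on
ln BMD, or a one-sided bound on the dose slope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import norm, t as t_dist

from .association_models import LinearFit, LogisticFit, significance_gate

__all__ = [
    "BmdSpec",
    "BmdResult",
    "ADVERSITY",
    "hybrid_cutoff",
    "hybrid_bmd",
    "hybrid_bmd_closed",
    "hybrid_bmd_numeric",
    "hybrid_bmdl",
    "logistic_background",
    "logistic_bmd",
    "logistic_bmdl",
    "bmd_table",
]

log = logging.getLogger(__name__)

#: Direction in which each endpoint becomes adverse.
ADVERSITY = {
    "crcl": "low",
    "egfr": "low",
    "ln_b2mg": "high",
    "tr_below_95": "high",  # flags: probability rises with dose
    "tr_below_90": "high",
}

PROFILE_CHI2_90 = 2.705543454095404  # chi2(1) 90th percentile; one-sided 95%


@dataclass(frozen=True)
class BmdSpec:
    """Risk definition and methods for one benchmark-dose computation.

    ``p0`` is the fixed background probability for hybrid endpoints; ``None``
    means estimate it from the logistic fit at zero dose and
    ``reference_age``.
    """

    endpoint: str
    model_kind: str = "hybrid_continuous"   # or "logistic"
    p0: float | None = 0.05
    bmr: float = 0.05
    risk_type: str = "additional"           # or "extra"
    adversity: str | None = None            # default from ADVERSITY[endpoint]
    reference_age: float = 70.0
    bmdl_method: str = "profile"            # profile | delta | slope_bound
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if self.model_kind not in ("hybrid_continuous", "logistic"):
            raise ValueError("model_kind must be hybrid_continuous|logistic")
        if self.risk_type not in ("additional", "extra"):
            raise ValueError("risk_type must be additional|extra")
        if self.bmdl_method not in ("profile", "delta", "slope_bound"):
            raise ValueError("bmdl_method must be profile|delta|slope_bound")
        if not (0.0 < self.bmr < 1.0):
            raise ValueError("bmr must lie in (0, 1)")
        if self.p0 is not None and not (0.0 < self.p0 and self.p0 + self.bmr < 1.0):
            raise ValueError("require 0 < p0 and p0 + bmr < 1")

    def adversity_for(self) -> str:
        adv = self.adversity or ADVERSITY.get(self.endpoint)
        if adv not in ("low", "high"):
            raise ValueError(f"unknown adversity for endpoint {self.endpoint!r}")
        return adv


@dataclass(frozen=True)
class BmdResult:
    """One row of the benchmark-dose table."""

    endpoint: str
    sex: str
    bmr: float
    bmd: float | None = None
    bmdl: float | None = None
    cutoff: float | None = None
    p0_used: float | None = None
    risk_type: str = "additional"
    bmdl_method_used: str | None = None
    model_kind: str = "hybrid_continuous"
    status: str = "ok"
    reason: str | None = None


def _effective_bmr(p0: float, bmr: float, risk_type: str) -> float:
    return bmr * (1.0 - p0) if risk_type == "extra" else bmr


def _check_adverse_sign(beta_dose: float, adversity: str, what: str) -> None:
    ok = beta_dose < 0 if adversity == "low" else beta_dose > 0
    if beta_dose == 0 or not ok:
        raise ValueError(
            f"{what}: dose slope {beta_dose:g} is not signed toward adversity "
            f"({adversity}); BMD undefined"
        )


# ---------------------------------------------------------------------------
# Hybrid approach (continuous endpoints)

def hybrid_cutoff(fit: LinearFit, spec: BmdSpec) -> float:
    """Adversity cut-off: the P(0) background quantile at zero dose.

    For ln-scale endpoints the returned value is on the ln scale; the report
    layer exponentiates.
    """
    if spec.p0 is None:
        raise ValueError("hybrid endpoints require a fixed p0")
    if fit.residual_sd <= 0:
        raise ValueError("residual SD must be positive")
    mu0 = fit.intercept + fit.beta_age * spec.reference_age
    z = norm.ppf(1.0 - spec.p0)
    if spec.adversity_for() == "low":
        return float(mu0 - z * fit.residual_sd)
    return float(mu0 + z * fit.residual_sd)


def hybrid_bmd_closed(
    beta_dose: float,
    residual_sd: float,
    p0: float,
    bmr: float,
    risk_type: str = "additional",
) -> float:
    """Closed-form hybrid BMD: (z(1−p0) − z(1−p0−BMR*)) · σ / |β|."""
    if residual_sd <= 0:
        raise ValueError("residual SD must be positive")
    if beta_dose == 0:
        raise ValueError("dose slope must be nonzero")
    if not (0.0 < p0 and p0 + bmr < 1.0 and bmr >= 0.0):
        raise ValueError("require 0 < p0 and p0 + bmr < 1")
    b = _effective_bmr(p0, bmr, risk_type)
    k = norm.ppf(1.0 - p0) - norm.ppf(1.0 - p0 - b)
    return float(k * residual_sd / abs(beta_dose))


def hybrid_bmd(fit: LinearFit, spec: BmdSpec) -> float:
    """Hybrid BMD from an age-adjusted linear fit (μg/g Cr)."""
    _check_adverse_sign(fit.beta_dose, spec.adversity_for(), f"{fit.endpoint}/{fit.sex}")
    return hybrid_bmd_closed(
        fit.beta_dose, fit.residual_sd, spec.p0, spec.bmr, spec.risk_type
    )


def hybrid_bmd_numeric(
    beta_dose: float,
    residual_sd: float,
    p0: float,
    bmr: float,
    risk_type: str = "additional",
) -> float:
    """Root-find of the adverse-tail probability equation (independent route).

    Solves P(d) − P(0) = BMR (additional) or (P(d) − P(0))/(1 − P(0)) = BMR
    (extra), where P(d) = Φ(z(p0) + |β|·d/σ) is the adverse-tail probability
    under the normal residual model.
    """
    b = _effective_bmr(p0, bmr, risk_type)
    target = p0 + b

    def tail_prob(d: float) -> float:
        return float(norm.cdf(norm.ppf(p0) + abs(beta_dose) * d / residual_sd))

    hi = 1.0
    while tail_prob(hi) < target and hi < 1e12:
        hi *= 2.0
    return float(optimize.brentq(lambda d: tail_prob(d) - target, 0.0, hi, xtol=1e-12))


def _hybrid_profile_bmdl(fit: LinearFit, spec: BmdSpec, bmd: float) -> float | None:
    """Profile-likelihood lower limit, treating the BMD as the parameter.

    The constraint BMD = d0 pins β_dose = s·K·σ/d0 (s the adverse sign); the
    remaining parameters (intercept, age slope, σ) are profiled out with ML
    σ (denominator n).  Returns None when the bracketing fails.
    """
    X, y = fit.design, fit.response
    if X is None or y is None:
        return None
    n = len(y)
    b = _effective_bmr(spec.p0, spec.bmr, spec.risk_type)
    k = norm.ppf(1.0 - spec.p0) - norm.ppf(1.0 - spec.p0 - b)
    sign = -1.0 if spec.adversity_for() == "low" else 1.0
    dose = X[:, 1]
    Xa = X[:, [0, 2]]
    qa, _ = np.linalg.qr(Xa)

    def loglik_at(sigma: float, d0: float) -> float:
        beta_dose = sign * k * sigma / d0
        r = y - beta_dose * dose
        r = r - qa @ (qa.T @ r)  # profile out intercept and age by projection
        rss = float(r @ r)
        return -0.5 * n * math.log(2.0 * math.pi * sigma * sigma) - rss / (2.0 * sigma * sigma)

    sigma_hat = fit.residual_sd
    def profile_ll(d0: float) -> float:
        res = optimize.minimize_scalar(
            lambda s: -loglik_at(s, d0),
            bounds=(sigma_hat * 1e-2, sigma_hat * 1e2),
            method="bounded",
            options={"xatol": sigma_hat * 1e-8},
        )
        return -res.fun

    # Unconstrained ML log-likelihood (OLS with ML variance).
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ beta) ** 2).sum())
    sig_ml = math.sqrt(rss / n)
    ll_hat = -0.5 * n * math.log(2.0 * math.pi * sig_ml * sig_ml) - n / 2.0
    d_hat = k * sig_ml / abs(beta[1]) if beta[1] != 0 else bmd

    def lr_gap(d0: float) -> float:
        return 2.0 * (ll_hat - profile_ll(d0)) - PROFILE_CHI2_90

    lo = d_hat * 1e-4
    try:
        if lr_gap(d_hat) > 0 or lr_gap(lo) < 0:
            return None
        return float(optimize.brentq(lr_gap, lo, d_hat, xtol=d_hat * 1e-8))
    except (ValueError, RuntimeError):
        return None


def hybrid_bmdl(fit: LinearFit, spec: BmdSpec) -> float:
    """One-sided lower confidence limit of the hybrid BMD."""
    bmd = hybrid_bmd(fit, spec)
    method = spec.bmdl_method
    if method == "profile":
        value = _hybrid_profile_bmdl(fit, spec, bmd)
        if value is not None:
            return value
        log.warning(
            "%s/%s: profile BMDL bracketing failed; falling back to delta method",
            fit.endpoint,
            fit.sex,
        )
        method = "delta"
    if method == "delta":
        dof = fit.n - 3
        var_ln = fit.cov[1, 1] / fit.beta_dose**2 + 1.0 / (2.0 * dof)
        z = norm.ppf(spec.confidence)
        return float(bmd * math.exp(-z * math.sqrt(var_ln)))
    # slope_bound: one-sided bound on the dose slope in the adverse direction.
    dof = fit.n - 3
    tcrit = t_dist.ppf(spec.confidence, dof)
    se = math.sqrt(fit.cov[1, 1])
    sign = -1.0 if spec.adversity_for() == "low" else 1.0
    beta_bound = fit.beta_dose + sign * tcrit * se
    _check_adverse_sign(beta_bound, spec.adversity_for(), f"{fit.endpoint}/{fit.sex} bound")
    b = _effective_bmr(spec.p0, spec.bmr, spec.risk_type)
    k = norm.ppf(1.0 - spec.p0) - norm.ppf(1.0 - spec.p0 - b)
    return float(k * fit.residual_sd / abs(beta_bound))


# ---------------------------------------------------------------------------
# Logistic model (dichotomous endpoints)

def logistic_background(fit: LogisticFit, spec: BmdSpec) -> float:
    """Model-estimated background prevalence at zero dose and the reference age."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    return float(expit(fit.intercept + fit.beta_age * spec.reference_age))


def logistic_bmd(
    beta_dose: float,
    p0: float,
    bmr: float,
    risk_type: str = "additional",
) -> float:
    """Closed-form logistic BMD: [logit(target) − logit(p0)] / β_dose.

    The target prevalence is p0 + BMR (additional risk) or
    p0 + BMR·(1 − p0) (extra risk).  Independent of the age slope once p0
    is given.
    """
    if beta_dose <= 0:
        raise ValueError("dose slope must be positive for a rising flag prevalence")
    if not (0.0 < p0 and p0 + bmr < 1.0 and bmr > 0.0):
        raise ValueError("require 0 < p0 and p0 + bmr < 1")
    target = p0 + _effective_bmr(p0, bmr, risk_type)
    return float((logit(target) - logit(p0)) / beta_dose)


def _logistic_bmd_from_params(params: np.ndarray, spec: BmdSpec) -> float:
    p0 = float(expit(params[0] + params[2] * spec.reference_age))
    return logistic_bmd(float(params[1]), p0, spec.bmr, spec.risk_type)


def _logistic_delta_bmdl(fit: LogisticFit, spec: BmdSpec, bmd: float) -> float:
    """Delta method on ln BMD, propagating the full coefficient covariance
    (background prevalence uncertainty included) by numeric gradient."""
    theta = fit.params.astype(float)

    def ln_bmd(p: np.ndarray) -> float:
        return math.log(_logistic_bmd_from_params(p, spec))

    grad = np.zeros(3)
    for i in range(3):
        h = 1e-6 * (1.0 + abs(theta[i]))
        up, dn = theta.copy(), theta.copy()
        up[i] += h
        dn[i] -= h
        grad[i] = (ln_bmd(up) - ln_bmd(dn)) / (2.0 * h)
    var_ln = float(grad @ fit.cov @ grad)
    z = norm.ppf(spec.confidence)
    return float(bmd * math.exp(-z * math.sqrt(max(var_ln, 0.0))))


def _logistic_profile_bmdl(fit: LogisticFit, spec: BmdSpec, bmd: float) -> float | None:
    """Profile-likelihood lower limit with BMD as the parameter of interest."""
    X, y = fit.design, fit.response
    if X is None or y is None:
        return None

    def negll(params: np.ndarray) -> float:
        eta = X @ params
        return float(np.logaddexp(0.0, eta).sum() - y @ eta)

    ll_hat = -negll(fit.params)

    def profile_ll(d0: float) -> float:
        res = optimize.minimize(
            negll,
            fit.params,
            method="SLSQP",
            constraints=[
                {
                    "type": "eq",
                    "fun": lambda p: _logistic_bmd_from_params(p, spec) - d0,
                }
            ],
            options={"maxiter": 200, "ftol": 1e-12},
        )
        if not res.success:
            raise RuntimeError(res.message)
        return -float(res.fun)

    def lr_gap(d0: float) -> float:
        return 2.0 * (ll_hat - profile_ll(d0)) - PROFILE_CHI2_90

    lo = bmd * 1e-3
    try:
        if lr_gap(bmd * (1.0 - 1e-9)) > 0 or lr_gap(lo) < 0:
            return None
        return float(optimize.brentq(lr_gap, lo, bmd, xtol=bmd * 1e-7))
    except (ValueError, RuntimeError):
        return None


def logistic_bmdl(fit: LogisticFit, spec: BmdSpec) -> float:
    """One-sided lower confidence limit of the logistic BMD."""
    p0 = spec.p0 if spec.p0 is not None else logistic_background(fit, spec)
    bmd = logistic_bmd(fit.beta_dose, p0, spec.bmr, spec.risk_type)
    method = spec.bmdl_method
    if method == "profile":
        value = _logistic_profile_bmdl(fit, spec, bmd)
        if value is not None:
            return value
        log.warning(
            "%s/%s: profile BMDL failed; falling back to delta method",
            fit.endpoint,
            fit.sex,
        )
        method = "delta"
    if method == "delta":
        return _logistic_delta_bmdl(fit, spec, bmd)
    # slope_bound: upper one-sided bound of the dose slope.
    z = norm.ppf(spec.confidence)
    beta_upper = fit.beta_dose + z * math.sqrt(fit.cov[1, 1])
    return logistic_bmd(beta_upper, p0, spec.bmr, spec.risk_type)


# ---------------------------------------------------------------------------
# Table assembly

def bmd_table(
    fits,
    bmrs=(0.05, 0.10),
    specs: dict | None = None,
    reference_age: float = 70.0,
    bmdl_method: str = "profile",
    risk_type: str = "additional",
) -> list[BmdResult]:
    """One BmdResult per fit × BMR; gate failures become explicit skip rows.

    ``specs`` optionally maps endpoint id → BmdSpec overrides (applied before
    the per-BMR replacement).
    """
    results: list[BmdResult] = []
    for fit in fits:
        is_linear = fit.kind == "linear"
        base = BmdSpec(
            endpoint=fit.endpoint,
            model_kind="hybrid_continuous" if is_linear else "logistic",
            p0=0.05 if is_linear else None,
            reference_age=reference_age,
            bmdl_method=bmdl_method,
            risk_type=risk_type,
        )
        if specs and fit.endpoint in specs:
            base = specs[fit.endpoint]
        gate = significance_gate(fit)
        for bmr in bmrs:
            spec = replace(base, bmr=bmr)
            if gate == "skip":
                results.append(
                    BmdResult(
                        endpoint=fit.endpoint,
                        sex=fit.sex,
                        bmr=bmr,
                        model_kind=spec.model_kind,
                        risk_type=spec.risk_type,
                        status="skipped",
                        reason=f"skipped (p >= 0.05; p = {fit.p_dose:.3f})",
                    )
                )
                continue
            if is_linear:
                cutoff = hybrid_cutoff(fit, spec)
                bmd = hybrid_bmd(fit, spec)
                bmdl = hybrid_bmdl(fit, spec)
                p0_used = spec.p0
            else:
                p0_used = spec.p0 if spec.p0 is not None else logistic_background(fit, spec)
                cutoff = None
                bmd = logistic_bmd(fit.beta_dose, p0_used, spec.bmr, spec.risk_type)
                bmdl = logistic_bmdl(fit, spec)
            results.append(
                BmdResult(
                    endpoint=fit.endpoint,
                    sex=fit.sex,
                    bmr=bmr,
                    bmd=bmd,
                    bmdl=bmdl,
                    cutoff=cutoff,
                    p0_used=p0_used,
                    risk_type=spec.risk_type,
                    bmdl_method_used=spec.bmdl_method,
                    model_kind=spec.model_kind,
                )
            )
    return results
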