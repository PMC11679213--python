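"""Synthetic cohort generator with the study's statistical structure.

Strata sizes, age distributions and lognormal urinary-cadmium exposure are
calibrated to the published participant characteristics; dose–response
coefficients default to the published age-adjusted estimates, with residual
SDs and intercepts frozen from a one-off moment-matching calibration
(``scripts/calibrate_defaults.py`` reproduces them).

Two generation modes:

* ``endpoint`` — draws the modelled endpoints directly from the linear /
  logistic truth (fast; used for fitting and recovery tests);
* ``analyte`` — back-solves raw analytes so that
  :func:`cdbmd.renal_markers.derive_panel_frame` reproduces the drawn
  endpoint values exactly, and the dichotomous reabsorption flags arise
  mechanistically from the β2-microglobulin model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .renal_markers import (
    AREAS,
    JAFFE_OFFSET_MG_DL,
    SEXES,
    bsa_du_bois,
)

__all__ = [
    "Stratum",
    "TrueDoseResponse",
    "CohortConfig",
    "default_config",
    "sample_cohort",
    "true_bmd",
    "config_to_yaml",
    "config_from_yaml",
]

CONTINUOUS_ENDPOINTS = ("crcl", "egfr", "ln_b2mg")
FLAG_ENDPOINTS = ("tr_below_95", "tr_below_90")


@dataclass(frozen=True)
class Stratum:
    """One sex × area cell: size, age distribution, exposure distribution."""

    sex: str
    area: str
    n: int
    age_mean: float
    age_sd: float
    ucd_gm: float   # geometric mean, μg/g Cr
    ucd_gsd: float  # geometric SD (> 1)

    def __post_init__(self) -> None:
        if self.sex not in SEXES or self.area not in AREAS:
            raise ValueError("invalid sex/area")
        if self.n < 0:
            raise ValueError("stratum n must be >= 0")
        if self.ucd_gsd <= 1:
            raise ValueError("ucd_gsd must be > 1")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be > 0")


@dataclass(frozen=True)
class TrueDoseResponse:
    """Ground-truth dose–response for one endpoint × sex.

    ``kind`` is ``linear`` (continuous endpoint, normal residuals; ln scale
    for β2-MG) or ``logistic`` (log-odds scale, no residual SD).
    ``adverse`` gives the adversity direction of the endpoint.
    """

    endpoint: str
    sex: str
    kind: str
    intercept: float
    beta_dose: float
    beta_age: float
    residual_sd: float | None = None
    adverse: str = "low"

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "logistic"):
            raise ValueError("kind must be linear|logistic")
        if self.kind == "linear" and (self.residual_sd is None or self.residual_sd <= 0):
            raise ValueError("linear truth requires residual_sd > 0")
        if self.adverse not in ("low", "high"):
            raise ValueError("adverse must be low|high")

    def background_mean(self, reference_age: float = 70.0) -> float:
        """Endpoint mean (or log-odds) at zero dose and the reference age."""
        return self.intercept + self.beta_age * reference_age


# Frozen calibration (see scripts/calibrate_defaults.py):
#  - slopes are the published age-adjusted coefficients;
#  - residual SDs back out the published BMR-5% benchmark doses;
#  - intercepts moment-match the sex-specific marginal endpoint means at the
#    sex-specific mean age and mean exposure.
_DEFAULT_STRATA = (
    Stratum("man", "polluted", 30, 74.1, 7.8, 9.0, 1.6),
    Stratum("woman", "polluted", 44, 73.2, 7.2, 11.6, 1.7),
    Stratum("man", "non_polluted", 18, 62.9, 9.9, 1.9, 1.7),
    Stratum("woman", "non_polluted", 18, 63.9, 9.0, 4.8, 1.5),
)

_DEFAULT_LINEAR = (
    TrueDoseResponse("crcl", "man", "linear", 171.2979, -1.37, -1.32, 19.45, "low"),
    TrueDoseResponse("crcl", "woman", "linear", 183.8022, -1.24, -1.55, 19.45, "low"),
    TrueDoseResponse("egfr", "man", "linear", 133.1472, -1.02, -0.97, 16.00, "low"),
    TrueDoseResponse("egfr", "woman", "linear", 175.2233, -0.65, -1.56, 16.00, "low"),
    TrueDoseResponse("ln_b2mg", "man", "linear", -6.2182, 0.30, 0.15, 2.3121, "high"),
    TrueDoseResponse("ln_b2mg", "woman", "linear", -5.3958, 0.18, 0.16, 1.7836, "high"),
)

_DEFAULT_LOGISTIC = (
    TrueDoseResponse("tr_below_95", "man", "logistic", -4.7570, 0.157004, 0.039221, None, "high"),
    TrueDoseResponse("tr_below_95", "woman", "logistic", -7.8161, 0.157004, 0.076961, None, "high"),
    TrueDoseResponse("tr_below_90", "man", "logistic", -8.0829, 0.190620, 0.067659, None, "high"),
    TrueDoseResponse("tr_below_90", "woman", "logistic", -8.6823, 0.113329, 0.086178, None, "high"),
)


@dataclass
class CohortConfig:
    """Everything needed to generate a reproducible synthetic cohort."""

    strata: tuple[Stratum, ...] = _DEFAULT_STRATA
    linear_truth: tuple[TrueDoseResponse, ...] = _DEFAULT_LINEAR
    logistic_truth: tuple[TrueDoseResponse, ...] = _DEFAULT_LOGISTIC
    mode: str = "analyte"
    seed: int = 0
    scale: int = 1
    age_floor: float = 50.0
    # Nuisance analyte distributions (analyte mode only).
    u_cr_gm: float = 1.0       # mg/mL
    u_cr_gsd: float = 1.4
    s_b2mg_gm: float = 2000.0  # μg/L
    s_b2mg_gsd: float = 1.3
    height_mean: dict = field(default_factory=lambda: {"man": 160.0, "woman": 148.0})
    height_sd: float = 6.0
    weight_mean: dict = field(default_factory=lambda: {"man": 60.0, "woman": 51.0})
    weight_sd: float = 8.0
    max_resample: int = 100

    def __post_init__(self) -> None:
        if self.mode not in ("endpoint", "analyte"):
            raise ValueError("mode must be endpoint|analyte")
        if self.scale < 1:
            raise ValueError("scale must be >= 1")

    def truth_for(self, endpoint: str, sex: str) -> TrueDoseResponse:
        for t in (*self.linear_truth, *self.logistic_truth):
            if t.endpoint == endpoint and t.sex == sex:
                return t
        raise KeyError(f"no truth for {endpoint!r}/{sex!r}")


def default_config(mode: str = "analyte", seed: int = 0, scale: int = 1) -> CohortConfig:
    return CohortConfig(mode=mode, seed=seed, scale=scale)


def _truncated_normal(rng, mean, sd, size, floor):
    """Rejection sampling from N(mean, sd) truncated below at ``floor``."""
    out = rng.normal(mean, sd, size=size)
    for _ in range(1000):
        bad = out < floor
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    raise RuntimeError("age truncation rejection sampling did not terminate")


def _positive_normal(rng, mean, sd, size):
    out = rng.normal(mean, sd, size=size)
    for _ in range(1000):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    raise RuntimeError("positivity rejection sampling did not terminate")


def _draw_linear(rng, truth, ucd, age, max_resample, positive):
    """Endpoint draw with bounded resampling of the residual when positivity
    is required (analyte back-solve needs crcl, egfr > 0)."""
    mean = truth.intercept + truth.beta_dose * ucd + truth.beta_age * age
    y = mean + rng.normal(0.0, truth.residual_sd, size=ucd.shape)
    if not positive:
        return y
    for _ in range(max_resample):
        bad = y <= 0
        if not bad.any():
            return y
        y[bad] = mean[bad] + rng.normal(0.0, truth.residual_sd, size=int(bad.sum()))
    raise RuntimeError(
        f"analyte back-solve unsatisfiable for {truth.endpoint}/{truth.sex}: "
        f"could not draw positive endpoint values in {max_resample} retries"
    )


def sample_cohort(config: CohortConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a cohort table plus the ground-truth dose–response sidecar.

    Endpoint mode columns: subject_id, sex, area, age, u_cd (μg/g Cr),
    crcl, egfr, ln_b2mg, tr_below_95, tr_below_90.
    Analyte mode columns: the raw-analyte schema of
    :data:`cdbmd.renal_markers.REQUIRED_COLUMNS`.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    counter = 0
    for st in config.strata:
        n = st.n * config.scale
        if n == 0:
            continue
        age = _truncated_normal(rng, st.age_mean, st.age_sd, n, config.age_floor)
        ucd = rng.lognormal(np.log(st.ucd_gm), np.log(st.ucd_gsd), size=n)
        ids = [f"S{counter + i:05d}" for i in range(n)]
        counter += n
        base = pd.DataFrame(
            {
                "subject_id": ids,
                "sex": st.sex,
                "area": st.area,
                "age": age,
            }
        )
        if config.mode == "endpoint":
            base["u_cd"] = ucd
            for ep in CONTINUOUS_ENDPOINTS:
                t = config.truth_for(ep, st.sex)
                base[ep] = _draw_linear(rng, t, ucd, age, config.max_resample, False)
            for ep in FLAG_ENDPOINTS:
                t = config.truth_for(ep, st.sex)
                eta = t.intercept + t.beta_dose * ucd + t.beta_age * age
                p = 1.0 / (1.0 + np.exp(-eta))
                base[ep] = (rng.uniform(size=n) < p).astype(float)
        else:
            crcl = _draw_linear(
                rng, config.truth_for("crcl", st.sex), ucd, age, config.max_resample, True
            )
            egfr = _draw_linear(
                rng, config.truth_for("egfr", st.sex), ucd, age, config.max_resample, True
            )
            ln_b2 = _draw_linear(
                rng, config.truth_for("ln_b2mg", st.sex), ucd, age, config.max_resample, False
            )
            u_cr = rng.lognormal(np.log(config.u_cr_gm), np.log(config.u_cr_gsd), size=n)
            s_b2 = rng.lognormal(np.log(config.s_b2mg_gm), np.log(config.s_b2mg_gsd), size=n)
            height = _positive_normal(rng, config.height_mean[st.sex], config.height_sd, n)
            weight = _positive_normal(rng, config.weight_mean[st.sex], config.weight_sd, n)

            # Invert the eGFR equation for serum creatinine (enzymatic scale),
            # then shift back to the Jaffe scale used by the instruments.
            sexf = 0.739 if st.sex == "woman" else 1.0
            s_cr_enz = (egfr / (194.0 * age ** (-0.287) * sexf)) ** (-1.0 / 1.094)
            s_cr_jaffe = s_cr_enz + JAFFE_OFFSET_MG_DL
            # Invert the 2-h clearance formula for urine volume.
            bsa = bsa_du_bois(height, weight)
            uv = crcl * (s_cr_jaffe * 0.01 * 120.0) / u_cr * bsa / 1.73
            base["s_cr_jaffe"] = s_cr_jaffe
            base["u_cr"] = u_cr
            base["urine_volume_2h"] = uv
            base["u_cd_per_L"] = ucd * u_cr
            base["u_b2mg_per_L"] = np.exp(ln_b2) * u_cr
            base["s_b2mg"] = s_b2
            base["height"] = height
            base["weight"] = weight
        frames.append(base)

    cohort = pd.concat(frames, ignore_index=True)
    truth = {
        "seed": config.seed,
        "mode": config.mode,
        "scale": config.scale,
        "truths": [dataclasses.asdict(t) for t in (*config.linear_truth, *config.logistic_truth)],
    }
    return cohort, truth


def true_bmd(
    truth: TrueDoseResponse,
    p0: float,
    bmr: float,
    risk_type: str = "additional",
) -> float:
    """Closed-form benchmark dose implied by a linear truth (oracle).

    Additional risk: ``(z(1−p0) − z(1−p0−bmr)) · σ / |β_dose|``; extra risk
    rescales the benchmark response to ``bmr·(1−p0)`` first.
    """
    if truth.kind != "linear":
        raise ValueError("true_bmd is defined for linear (continuous) truths")
    if not (0.0 < p0 and p0 + bmr < 1.0 and bmr >= 0.0):
        raise ValueError("require 0 < p0 and p0 + bmr < 1")
    sign_ok = truth.beta_dose < 0 if truth.adverse == "low" else truth.beta_dose > 0
    if truth.beta_dose == 0 or not sign_ok:
        raise ValueError("beta_dose must be nonzero and adverse-signed")
    if risk_type == "extra":
        bmr = bmr * (1.0 - p0)
    elif risk_type != "additional":
        raise ValueError("risk_type must be additional|extra")
    k = norm.ppf(1.0 - p0) - norm.ppf(1.0 - p0 - bmr)
    return float(k * truth.residual_sd / abs(truth.beta_dose))


# ---------------------------------------------------------------------------
# YAML round-trip for CLI configuration.

def config_to_yaml(config: CohortConfig) -> str:
    doc = {
        "mode": config.mode,
        "seed": config.seed,
        "scale": config.scale,
        "age_floor": config.age_floor,
        "strata": [dataclasses.asdict(s) for s in config.strata],
        "linear_truth": [dataclasses.asdict(t) for t in config.linear_truth],
        "logistic_truth": [dataclasses.asdict(t) for t in config.logistic_truth],
        "u_cr_gm": config.u_cr_gm,
        "u_cr_gsd": config.u_cr_gsd,
        "s_b2mg_gm": config.s_b2mg_gm,
        "s_b2mg_gsd": config.s_b2mg_gsd,
        "height_mean": config.height_mean,
        "height_sd": config.height_sd,
        "weight_mean": config.weight_mean,
        "weight_sd": config.weight_sd,
    }
    return yaml.safe_dump(doc, sort_keys=False)


def config_from_yaml(text: str) -> CohortConfig:
    doc = yaml.safe_load(text) or {}
    kwargs = {}
    if "strata" in doc:
        kwargs["strata"] = tuple(Stratum(**s) for s in doc.pop("strata"))
    for key in ("linear_truth", "logistic_truth"):
        if key in doc:
            kwargs[key] = tuple(TrueDoseResponse(**t) for t in doc.pop(key))
    kwargs.update(doc)
    return CohortConfig(**kwargs)
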