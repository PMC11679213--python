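"""Recompute the frozen defaults of cdbmd.synthetic_cohort.

Moment-matching calibration of the generator defaults from the published
summary statistics:

* residual SDs back out the published BMR-5% hybrid benchmark doses from
  the published age-adjusted slopes (sigma = BMD5 * |beta| / (z0.95 - z0.90));
* linear intercepts match the sex-specific marginal endpoint means at the
  sex-specific mean age and the mixture-mean exposure implied by the
  stratum lognormal parameters;
* logistic intercepts match the published background prevalences at zero
  dose and age 70, given the published age odds ratios.

Run from the repository root:  python scripts/calibrate_defaults.py
The printed values are the ones frozen in _DEFAULT_LINEAR/_DEFAULT_LOGISTIC.
"""

import numpy as np
from scipy.stats import norm

ln = np.log

# Stratum summaries: (sex, area, n, age_mean, ucd_gm, ucd_gsd)
STRATA = [
    ("man", "polluted", 30, 74.1, 9.0, 1.6),
    ("woman", "polluted", 44, 73.2, 11.6, 1.7),
    ("man", "non_polluted", 18, 62.9, 1.9, 1.7),
    ("woman", "non_polluted", 18, 63.9, 4.8, 1.5),
]

# Sex-specific marginal summaries (all areas pooled).
MEAN_AGE = {"man": 69.9, "woman": 70.5}
MEAN_ENDPOINT = {
    ("crcl", "man"): 69.3,
    ("crcl", "woman"): 60.9,
    ("egfr", "man"): 58.1,
    ("egfr", "woman"): 58.1,
    ("ln_b2mg", "man"): ln(600.3),     # geometric mean on the ln scale
    ("ln_b2mg", "woman"): ln(2597.5),
}

# Published age-adjusted slopes (dose per μg/g Cr, age per year).
SLOPES = {
    ("crcl", "man"): (-1.37, -1.32),
    ("crcl", "woman"): (-1.24, -1.55),
    ("egfr", "man"): (-1.02, -0.97),
    ("egfr", "woman"): (-0.65, -1.56),
    ("ln_b2mg", "man"): (0.30, 0.15),
    ("ln_b2mg", "woman"): (0.18, 0.16),
}

# Published BMR-5% hybrid BMDs used to pin residual SDs (only the
# significant endpoints were published; the other sex inherits its
# counterpart's SD).
BMD5 = {
    ("crcl", "woman"): 5.7,
    ("egfr", "man"): 5.7,
    ("ln_b2mg", "man"): 2.8,
    ("ln_b2mg", "woman"): 3.6,
}

# Published logistic odds ratios and model-estimated background
# prevalences at age 70.
LOGISTIC = {
    ("tr_below_95", "man"): (1.17, 1.04, 0.118),
    ("tr_below_95", "woman"): (1.17, 1.08, 0.081),
    ("tr_below_90", "man"): (1.21, 1.07, 0.034),
    ("tr_below_90", "woman"): (1.12, 1.09, 0.066),
}

REFERENCE_AGE = 70.0


def lognormal_mean(gm, gsd):
    return gm * np.exp(ln(gsd) ** 2 / 2.0)


def mean_ucd(sex):
    rows = [(n, lognormal_mean(gm, gsd)) for s, _, n, _, gm, gsd in STRATA if s == sex]
    total = sum(n for n, _ in rows)
    return sum(n * m for n, m in rows) / total


def logit(p):
    return ln(p / (1.0 - p))


def main():
    k5 = norm.ppf(0.95) - norm.ppf(0.90)
    print("# residual SDs (sigma = BMD5 * |beta_dose| / K5)")
    sigmas = {}
    for (ep, sex), bmd5 in BMD5.items():
        beta = SLOPES[(ep, sex)][0]
        sigmas[(ep, sex)] = bmd5 * abs(beta) / k5
        print(f"  {ep}/{sex}: {sigmas[(ep, sex)]:.4f}")

    print("# linear intercepts (mean_y - b_dose*mean_ucd - b_age*mean_age)")
    for (ep, sex), (bd, ba) in SLOPES.items():
        icpt = MEAN_ENDPOINT[(ep, sex)] - bd * mean_ucd(sex) - ba * MEAN_AGE[sex]
        print(f"  {ep}/{sex}: {icpt:.4f}")

    print("# logistic coefficients (ln OR) and intercepts at age 70")
    for (ep, sex), (or_dose, or_age, p0) in LOGISTIC.items():
        icpt = logit(p0) - ln(or_age) * REFERENCE_AGE
        print(
            f"  {ep}/{sex}: beta_dose={ln(or_dose):.6f} "
            f"beta_age={ln(or_age):.6f} intercept={icpt:.4f}"
        )


if __name__ == "__main__":
    main()
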