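"""Study-shaped fit objects (published p-value patterns) for gate tests."""

import numpy as np

from cdbmd.association_models import LinearFit, LogisticFit


def _linear(endpoint, sex, beta_dose, p_dose, sigma, n):
    return LinearFit(
        endpoint=endpoint,
        sex=sex,
        params=np.array([150.0, beta_dose, -1.2]),
        cov=0.05 * np.eye(3),
        residual_sd=sigma,
        n=n,
        pvalues=np.array([1e-6, p_dose, 1e-4]),
        conf_int=np.zeros((3, 2)),
    )


def _logistic(endpoint, sex, beta_dose, p_dose, n):
    return LogisticFit(
        endpoint=endpoint,
        sex=sex,
        params=np.array([-4.8, beta_dose, 0.04]),
        cov=0.002 * np.eye(3),
        n=n,
        pvalues=np.array([1e-4, p_dose, 0.28]),
        conf_int=np.zeros((3, 2)),
        converged=True,
    )


def study_shaped_fits():
    """Fits whose dose p-values follow the published significance pattern."""
    return [
        _linear("crcl", "man", -1.37, 0.118, 23.0, 48),     # not significant
        _linear("crcl", "woman", -1.24, 0.002, 19.45, 62),
        _linear("egfr", "man", -1.02, 0.041, 16.0, 48),
        _linear("egfr", "woman", -0.65, 0.082, 16.0, 62),   # not significant
        _linear("ln_b2mg", "man", 0.30, 0.0005, 2.31, 48),
        _linear("ln_b2mg", "woman", 0.18, 0.0005, 1.78, 62),
        _logistic("tr_below_95", "man", np.log(1.17), 0.022, 48),
        _logistic("tr_below_95", "woman", np.log(1.17), 0.003, 62),
        _logistic("tr_below_90", "man", np.log(1.21), 0.021, 48),
        _logistic("tr_below_90", "woman", np.log(1.12), 0.017, 62),
    ]
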