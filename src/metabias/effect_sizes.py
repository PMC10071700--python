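"""Effect-size metrics, their sampling variances, and bias-test predictors.

Three metrics are supported, the ones that dominate ecological and
evolutionary meta-analysis because they are unit-less, asymptotically
normal, and have closed-form sampling variances:

* ``SMD`` — standardized mean difference as Hedges' *g* (small-sample
  corrected Cohen's *d*), variance
  ``(n_e + n_c)/(n_e n_c) + g^2 / (2 (n_e + n_c))``.
* ``lnRR`` — log response ratio ``ln(mean_e / mean_c)`` with the
  delta-method variance ``sd_e^2/(n_e mean_e^2) + sd_c^2/(n_c mean_c^2)``.
* ``Zr`` — Fisher's z-transformed correlation ``atanh(r)`` with variance
  ``1/(n - 3)``.

Because the point estimates of SMD and lnRR are algebraically coupled with
their sampling variances, regression tests for small-study effects that use
the standard error as predictor suffer an artefactual correlation.  The
module therefore also provides the effective-sample-size predictor
``sqrt((n_e + n_c)/(n_e n_c))`` (and its square), which depends on the group
sizes only and breaks that coupling.
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np

__all__ = [
    "METRICS",
    "compute_effect_size",
    "hedges_g",
    "log_response_ratio",
    "fisher_z",
    "effective_sample_predictor",
]

METRICS = ("SMD", "lnRR", "Zr")


def hedges_g(mean_e, sd_e, n_e, mean_c, sd_c, n_c) -> tuple[float, float]:
    """Hedges' g and its sampling variance from two-group summary statistics.

    Applies the small-sample correction J = 1 - 3/(4 df - 1), df = n_e+n_c-2.
    """
    n_e, n_c = int(n_e), int(n_c)
    if n_e < 2 or n_c < 2:
        raise ValueError("SMD requires at least 2 observations per group")
    if sd_e < 0 or sd_c < 0 or (sd_e == 0 and sd_c == 0):
        raise ValueError("group SDs must be non-negative and not both zero")
    df = n_e + n_c - 2
    s_pool = math.sqrt(((n_e - 1) * sd_e**2 + (n_c - 1) * sd_c**2) / df)
    if s_pool == 0:
        raise ValueError("pooled SD is zero; SMD undefined")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * (mean_e - mean_c) / s_pool
    var = (n_e + n_c) / (n_e * n_c) + g**2 / (2.0 * (n_e + n_c))
    return g, var


def log_response_ratio(mean_e, sd_e, n_e, mean_c, sd_c, n_c) -> tuple[float, float]:
    """Log response ratio ln(mean_e/mean_c) with delta-method variance."""
    if mean_e <= 0 or mean_c <= 0:
        raise ValueError("lnRR requires strictly positive group means")
    if n_e < 2 or n_c < 2:
        raise ValueError("lnRR requires at least 2 observations per group")
    es = math.log(mean_e / mean_c)
    var = sd_e**2 / (n_e * mean_e**2) + sd_c**2 / (n_c * mean_c**2)
    if var <= 0:
        raise ValueError("lnRR sampling variance must be positive")
    return es, var


def fisher_z(r, n) -> tuple[float, float]:
    """Fisher's z = atanh(r) with variance 1/(n-3)."""
    if not -1.0 < r < 1.0:
        raise ValueError("correlation must lie strictly inside (-1, 1)")
    if n <= 3:
        raise ValueError("Fisher's z requires n > 3")
    return math.atanh(r), 1.0 / (n - 3.0)


def compute_effect_size(metric: str, **summary_stats) -> tuple[float, float]:
    """Compute (effect size, sampling variance) for one record.

    Parameters
    ----------
    metric : {"SMD", "lnRR", "Zr"}
    **summary_stats
        For SMD / lnRR: ``mean_e, sd_e, n_e, mean_c, sd_c, n_c``.
        For Zr: ``r, n``.
    """
    if metric == "SMD":
        return hedges_g(**summary_stats)
    if metric == "lnRR":
        return log_response_ratio(**summary_stats)
    if metric == "Zr":
        return fisher_z(**summary_stats)
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def effective_sample_predictor(
    n_e, n_c, order: Literal["linear", "quadratic"] = "linear"
):
    """Effective-sample-size predictor for small-study-effect regressions.

    With the effective sample ñ = n_e n_c / (n_e + n_c), returns
    ``sqrt(1/ñ)`` (order="linear", the standard-error analogue) or ``1/ñ``
    (order="quadratic", the sampling-variance analogue).  Accepts scalars or
    arrays; any missing (NaN) group size yields NaN, signalling the caller
    to fall back to the standard error itself.
    """
    n_e = np.asarray(n_e, dtype=float)
    n_c = np.asarray(n_c, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        valid = (n_e >= 1) & (n_c >= 1)
        inv_n_tilde = np.where(valid, (n_e + n_c) / (n_e * n_c), np.nan)
    if order == "linear":
        out = np.sqrt(inv_n_tilde)
    elif order == "quadratic":
        out = inv_n_tilde
    else:
        raise ValueError("order must be 'linear' or 'quadratic'")
    return out if out.ndim else float(out)
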