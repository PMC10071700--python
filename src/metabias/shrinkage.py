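"""Folded-normal shrinkage: how much do corrected effects drop?

The absolute difference ``D = |eta_uncorrected - eta_corrected|`` between a
meta-analysis' standardized overall effect and its bias-corrected version
is a folded-normal variable: treating the underlying difference as Gaussian
with mean D and variance Var(D), its absolute value has mean::

    D_f = sqrt(2 Var(D) / pi) * exp(-D^2 / (2 Var(D)))
          + D * (1 - 2 * Phi(-D / sqrt(Var(D))))

and variance ``Var(D_f) = D^2 + Var(D) - D_f^2`` (the second raw moment is
preserved under folding).  Var(D) is computed from the two standard errors
with their correlation r, fixed at 1 by default because the two intercepts
are estimated from the same data — giving ``Var(D) = (SE_c - SE_u)^2``.

The folded means are pooled across meta-analyses by a random-effects model
with Var(D_f) as sampling variance, and can be mapped back to each
metric's original units by multiplying with the per-case response SD that
was divided out during standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .pooling import SecondOrderSummary, pool_coefficients

__all__ = [
    "FoldedDifference",
    "folded_normal_moments",
    "difference_and_fold",
    "pool_differences",
    "backtransform",
]


def folded_normal_moments(mu, var):
    """Mean and variance of |X| for X ~ Normal(mu, var).

    The degenerate case var = 0 returns (|mu|, 0) analytically.
    Accepts scalars or arrays.
    """
    mu = np.asarray(mu, dtype=float)
    var = np.asarray(var, dtype=float)
    if np.any(var < 0):
        raise ValueError("variance must be non-negative")
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sd > 0, mu / np.where(sd > 0, sd, 1.0), np.inf * np.sign(mu))
        mean_f = np.where(
            sd > 0,
            np.sqrt(2.0 / np.pi) * sd * np.exp(-(mu**2) / np.where(var > 0, 2.0 * var, 1.0))
            + mu * (1.0 - 2.0 * stats.norm.cdf(-ratio)),
            np.abs(mu),
        )
    var_f = mu**2 + var - mean_f**2
    var_f = np.maximum(var_f, 0.0)
    if mean_f.ndim == 0:
        return float(mean_f), float(var_f)
    return mean_f, var_f


@dataclass
class FoldedDifference:
    """Folded absolute difference between uncorrected and corrected effects."""

    meta_id: str
    metric: str
    d: float
    var_d: float
    r: float
    d_folded: float
    var_d_folded: float
    sd_response: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def difference_and_fold(
    eta_uncorrected: float,
    se_uncorrected: float,
    eta_corrected: float,
    se_corrected: float,
    r: float = 1.0,
    meta_id: str = "",
    metric: str = "",
    sd_response: float | None = None,
) -> FoldedDifference:
    """Folded mean/variance of the standardized effect-size reduction."""
    if se_uncorrected < 0 or se_corrected < 0:
        raise ValueError("standard errors must be non-negative")
    d = abs(eta_uncorrected - eta_corrected)
    var_d = se_corrected**2 + se_uncorrected**2 - 2.0 * r * se_corrected * se_uncorrected
    var_d = max(var_d, 0.0)
    d_f, var_f = folded_normal_moments(d, var_d)
    return FoldedDifference(
        meta_id=meta_id, metric=metric, d=d, var_d=var_d, r=r,
        d_folded=d_f, var_d_folded=var_f, sd_response=sd_response,
    )


def pool_differences(
    cases: pd.DataFrame | list,
    moderator: bool = True,
    inference: str = "z",
    min_var: float = 1e-10,
) -> SecondOrderSummary:
    """Random-effects pooling of folded differences across meta-analyses.

    `cases` is a DataFrame with columns d_folded / var_d_folded / metric
    (or a list of FoldedDifference).  Folded variances are floored at
    `min_var` so a perfectly degenerate case cannot carry infinite weight.
    """
    if not isinstance(cases, pd.DataFrame):
        cases = pd.DataFrame([c.to_dict() for c in cases])
    ses = np.sqrt(np.maximum(cases["var_d_folded"].to_numpy(float), min_var))
    return pool_coefficients(
        cases["d_folded"].to_numpy(float),
        ses,
        moderator=cases["metric"] if moderator else None,
        coefficient="d_folded",
        inference=inference,
    )


def backtransform(cases: pd.DataFrame, value_col: str = "d_folded") -> pd.DataFrame:
    """Map standardized differences back to each metric's original units.

    Adds a per-case original-units column (standardized value times the
    response SD divided out during standardization) and returns per-metric
    unweighted averages alongside the per-case table.
    """
    if "sd_response" not in cases.columns or cases["sd_response"].isna().any():
        raise ValueError("per-case sd_response required for back-transformation")
    out = cases.copy()
    out["d_original"] = out[value_col] * out["sd_response"]
    return out


def backtransform_summary(cases: pd.DataFrame, value_col: str = "d_folded") -> pd.Series:
    """Per-metric unweighted mean of back-transformed differences."""
    out = backtransform(cases, value_col)
    return out.groupby("metric")["d_original"].mean()
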