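"""Standardization of per-meta-analysis models and second-order pooling.

Regression coefficients estimated inside single meta-analyses live on the
scale of their effect-size metric, so they cannot be averaged across
meta-analyses directly.  Each case is therefore refitted on a standardized
scale: the response is divided by its standard deviation (no centring, so
the intercept stays interpretable), and the uncertainty and centred-year
predictors are z-scaled and then *shifted* so that zero uncertainty and the
latest publication year map to predictor value zero — making the intercept
the standardized bias-corrected effect.  Note that the shifted z-scores
reduce to ``error_i / SD(error)`` and ``(year_i - year_latest) / SD(year)``.

The standardized coefficients are then pooled across meta-analyses with a
random-effects model weighted by inverse squared standard errors (a
second-order meta-analysis), optionally moderated by effect-size type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .bias import _error_predictors, _fit_case_models, apply_decision_tree, expected_signs, _slope
from .multilevel import MultilevelMetaRegression, typical_sampling_variance

__all__ = [
    "RandomEffectsMeta",
    "SecondOrderSummary",
    "StandardizedCase",
    "standardize_case",
    "pool_coefficients",
]


class RandomEffectsMeta(BaseEstimator):
    """Classic random-effects meta-analysis of independent estimates.

    A thin single-component specialisation of the multilevel REML engine:
    the marginal variance of case *i* is ``se_i^2 + tau2``.  With a
    categorical moderator the model is fitted cell-means style (one mean
    per level, shared tau2) and a marginal R^2 for the moderator is
    reported.

    Attributes
    ----------
    estimate_, se_ : pooled mean and its standard error (intercept model).
    tau2_, i2_ : between-case heterogeneity and the Higgins-style I^2.
    level_means_ : per-level coefficient table when a moderator was given.
    r2_marginal_ : variance of moderator-fitted values over (that + tau2).
    """

    def __init__(self, inference: str = "z", ci_level: float = 0.95):
        self.inference = inference
        self.ci_level = ci_level

    def fit(self, y, se, moderator=None):
        y = np.asarray(y, dtype=float)
        se = np.asarray(se, dtype=float)
        if np.any(se <= 0):
            raise ValueError("standard errors must be strictly positive")
        if y.shape[0] < 2:
            raise ValueError("need at least 2 cases to pool")
        v = se**2
        core = MultilevelMetaRegression(
            inference=self.inference, ci_level=self.ci_level, single_component=True
        ).fit(None, y, v=v)
        self.model_ = core
        tab = core.coef_table()
        self.estimate_ = float(tab.loc["intercept", "estimate"])
        self.se_ = float(tab.loc["intercept", "se"])
        self.pval_ = float(tab.loc["intercept", "pval"])
        self.ci_ = (float(tab.loc["intercept", "ci_low"]), float(tab.loc["intercept", "ci_high"]))
        self.tau2_ = core.sigma2_obs_
        v_typ = typical_sampling_variance(v)
        self.i2_ = self.tau2_ / (self.tau2_ + v_typ) if (self.tau2_ + v_typ) > 0 else 0.0
        self.k_ = y.shape[0]

        self.level_means_ = None
        self.r2_marginal_ = None
        if moderator is not None:
            moderator = pd.Series(np.asarray(moderator), name="level")
            levels = sorted(moderator.unique())
            if len(levels) >= 2 and all((moderator == l).sum() >= 2 for l in levels):
                dummies = np.column_stack([(moderator == l).to_numpy(float) for l in levels])
                mod = MultilevelMetaRegression(
                    fit_intercept=False,
                    inference=self.inference,
                    ci_level=self.ci_level,
                    single_component=True,
                ).fit(dummies, y, v=v, names=[str(l) for l in levels])
                self.moderated_model_ = mod
                self.level_means_ = mod.coef_table()
                fitted = dummies @ mod.coef_
                var_fit = float(np.var(fitted))
                denom = var_fit + mod.sigma2_obs_
                self.r2_marginal_ = var_fit / denom if denom > 0 else 0.0
            else:
                warnings.warn(
                    "moderator needs >= 2 levels with >= 2 cases each; skipped",
                    stacklevel=2,
                )
        return self


@dataclass
class SecondOrderSummary:
    """Pooled second-order meta-analytic summary of one coefficient."""

    coefficient: str
    n_cases: int
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    tau2_among: float
    i2_among: float
    by_level: dict = field(default_factory=dict)
    r2_marginal: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def pool_coefficients(
    estimates,
    ses,
    moderator=None,
    coefficient: str = "coef",
    inference: str = "z",
    ci_level: float = 0.95,
) -> SecondOrderSummary:
    """Random-effects pooling of (estimate, SE) cases across meta-analyses."""
    estimates = np.asarray(estimates, dtype=float)
    ses = np.asarray(ses, dtype=float)
    keep = np.isfinite(estimates) & np.isfinite(ses) & (ses > 0)
    estimates, ses = estimates[keep], ses[keep]
    if moderator is not None:
        moderator = np.asarray(moderator)[keep]
    if estimates.shape[0] == 1:
        warnings.warn("single case: returning it as-is with undefined tau2", stacklevel=2)
        from scipy import stats as _st

        crit = _st.norm.ppf(0.5 + ci_level / 2.0)
        e, s = float(estimates[0]), float(ses[0])
        return SecondOrderSummary(
            coefficient, 1, e, s, e - crit * s, e + crit * s,
            float(2 * _st.norm.sf(abs(e / s))), float("nan"), float("nan"),
        )
    pool = RandomEffectsMeta(inference=inference, ci_level=ci_level).fit(
        estimates, ses, moderator=moderator
    )
    by_level = {}
    if pool.level_means_ is not None:
        for name, row in pool.level_means_.iterrows():
            by_level[name] = {
                "estimate": float(row["estimate"]),
                "se": float(row["se"]),
                "ci_low": float(row["ci_low"]),
                "ci_high": float(row["ci_high"]),
                "pval": float(row["pval"]),
                "n": int((np.asarray(moderator) == name).sum()),
            }
    return SecondOrderSummary(
        coefficient=coefficient,
        n_cases=pool.k_,
        estimate=pool.estimate_,
        se=pool.se_,
        ci_low=pool.ci_[0],
        ci_high=pool.ci_[1],
        pval=pool.pval_,
        tau2_among=pool.tau2_,
        i2_among=pool.i2_,
        by_level=by_level,
        r2_marginal=pool.r2_marginal_,
    )


@dataclass
class StandardizedCase:
    """One meta-analysis' standardized (scale-free) model coefficients."""

    meta_id: str
    metric: str
    k: int
    sd_response: float
    eta0_overall: float
    se_eta0_overall: float
    p_eta0_overall: float
    eta0_corrected_type1: float
    se_eta0_corrected_type1: float
    p_eta0_corrected_type1: float
    eta0_corrected_type2: float
    se_eta0_corrected_type2: float
    p_eta0_corrected_type2: float
    eta1_small_effect: float | None
    se_eta1: float | None
    p_eta1: float | None
    eta2_time_lag: float | None
    se_eta2: float | None
    p_eta2: float | None
    scenario: str
    expected_sign_eta1: int
    expected_sign_eta2: int
    z_error0: float | None
    z_year_latest: float | None
    dropped_terms: str

    def to_dict(self) -> dict:
        return asdict(self)


def standardize_case(
    df: pd.DataFrame,
    predictor_mode: str = "auto",
    variant: str = "main_text",
    inference: str = "z",
) -> StandardizedCase:
    """Refit one meta-analysis on the standardized scale.

    The response is divided by its (unweighted, ddof=1) SD without
    centring; sampling variances are divided by the squared SD.  The
    uncertainty predictor and centred year are replaced by their shifted
    z-scores so the intercept is conditional on zero uncertainty at the
    latest year.  The quadratic correction model squares the shifted
    uncertainty z-score.  The decision tree is re-applied on the
    standardized linear fit to produce the type-2 corrected intercept.
    """
    if len(df) < 4:
        raise ValueError(f"standardization needs k >= 4 effect sizes, got {len(df)}")
    y_raw = df["es"].to_numpy(dtype=float)
    sd = float(np.std(y_raw, ddof=1))
    if sd <= 0:
        raise ValueError("response standard deviation is zero; cannot standardize")
    y = y_raw / sd
    v = df["var"].to_numpy(dtype=float) / sd**2
    groups = df["study_id"].to_numpy()

    err_lin_raw, _, mode = _error_predictors(df, predictor_mode)
    sd_err = float(np.std(err_lin_raw, ddof=1))
    z_error0 = None
    if sd_err > 0:
        err_lin = err_lin_raw / sd_err          # z(error_i) - z(error_0)
        z_error0 = float(-np.mean(err_lin_raw) / sd_err)
    else:
        err_lin = np.zeros(len(df))
    err_quad = err_lin**2

    z_year_latest = None
    if "year" in df.columns and df["year"].notna().all():
        year = df["year"].to_numpy(dtype=float)
        sd_year = float(np.std(year, ddof=1))
        if sd_year > 0:
            year_c = (year - year.max()) / sd_year   # z(year_i) - z(year_latest)
            z_year_latest = float((year.max() - np.mean(year)) / sd_year)
        else:
            year_c = np.zeros(len(df))
    else:
        year_c = np.zeros(len(df))

    fits = _fit_case_models(y, v, groups, err_lin, err_quad, year_c, inference)
    null_tab = fits["null"].coef_table()
    eta0 = float(null_tab.loc["intercept", "estimate"])
    expected = expected_signs(eta0)
    scenario, corrected = apply_decision_tree(fits, expected, variant=variant)
    lin_tab = fits["linear"].coef_table()
    quad_tab = fits["quadratic"].coef_table()
    corr_tab = corrected.coef_table()

    e1, s1, p1 = _slope(lin_tab, "error")
    e2, s2, p2 = _slope(lin_tab, "year")
    return StandardizedCase(
        meta_id=str(df["meta_id"].iloc[0]),
        metric=str(df["metric"].iloc[0]),
        k=len(df),
        sd_response=sd,
        eta0_overall=eta0,
        se_eta0_overall=float(null_tab.loc["intercept", "se"]),
        p_eta0_overall=float(null_tab.loc["intercept", "pval"]),
        eta0_corrected_type1=float(quad_tab.loc["intercept", "estimate"]),
        se_eta0_corrected_type1=float(quad_tab.loc["intercept", "se"]),
        p_eta0_corrected_type1=float(quad_tab.loc["intercept", "pval"]),
        eta0_corrected_type2=float(corr_tab.loc["intercept", "estimate"]),
        se_eta0_corrected_type2=float(corr_tab.loc["intercept", "se"]),
        p_eta0_corrected_type2=float(corr_tab.loc["intercept", "pval"]),
        eta1_small_effect=e1,
        se_eta1=s1,
        p_eta1=p1,
        eta2_time_lag=e2,
        se_eta2=s2,
        p_eta2=p2,
        scenario=scenario,
        expected_sign_eta1=expected[0],
        expected_sign_eta2=expected[1],
        z_error0=z_error0,
        z_year_latest=z_year_latest,
        dropped_terms=",".join(fits["dropped"]),
    )
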