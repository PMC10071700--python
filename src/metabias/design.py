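"""Retrodesign calculus: statistical power, Type S and Type M errors.

Given a true effect, a standard error and a two-sided significance level,
an estimate is modelled as Normal(true_effect, se^2).  With
``z_c = Phi^{-1}(1 - alpha/2)`` and the signal-to-noise ratio
``lambda = true_effect / se``:

* power  = P(|est| / se > z_c) = 1 - Phi(z_c - lambda) + Phi(-z_c - lambda)
* Type S = P(sign(est) != sign(true) | significant)
         = Phi(-z_c - |lambda|) / power
* Type M = E[|est| | significant] / |true_effect|, from truncated-normal
  moments (the exaggeration ratio).

All three depend on (lambda, alpha) only.  At lambda = 0 the definitions
force power = alpha, Type S = 1/2 and Type M undefined (reported as inf).
A seeded Monte-Carlo version is provided as an independent oracle.

Aggregation mirrors the two levels of a meta-analytic corpus: per-effect
metrics are averaged by a study-random-intercept mixed model at the
sampling level, and per-meta-analysis metrics by a regression weighted by
the number of effect sizes k; medians are always reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .multilevel import MultilevelMetaRegression

__all__ = [
    "DesignMetrics",
    "design_metrics",
    "retrodesign_mc",
    "AggregateDesignSummary",
    "aggregate_sampling_level",
    "aggregate_meta_level",
]

METRIC_COLS = ("power", "type_s", "type_m")


@dataclass
class DesignMetrics:
    """Power / Type S / Type M at one (true effect, se, alpha) design point."""

    true_effect: float
    se: float
    alpha: float
    power: float
    type_s: float
    type_m: float  # inf when the true effect is zero
    snr: float     # lambda = true_effect / se

    def to_dict(self) -> dict:
        return asdict(self)


def design_metrics(true_effect: float, se: float, alpha: float = 0.05) -> DesignMetrics:
    """Closed-form power, Type S and Type M errors."""
    if se <= 0:
        raise ValueError("se must be strictly positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    lam = true_effect / se
    a = abs(lam)
    z_c = stats.norm.ppf(1.0 - alpha / 2.0)
    power = stats.norm.sf(z_c - a) + stats.norm.cdf(-z_c - a)
    if true_effect == 0.0:
        return DesignMetrics(true_effect, se, alpha, float(power), 0.5, float("inf"), lam)
    type_s = float(stats.norm.cdf(-z_c - a) / power)
    # E[|est| ; significant] for a positive true effect t = a*se:
    #   t*(1 - Phi(z_c - lam)) + se*phi(z_c - lam) - t*Phi(-z_c - lam) + se*phi(z_c + lam)
    t = a * se
    e_abs_sig = (
        t * stats.norm.sf(z_c - a)
        + se * stats.norm.pdf(z_c - a)
        - t * stats.norm.cdf(-z_c - a)
        + se * stats.norm.pdf(z_c + a)
    )
    type_m = float(e_abs_sig / (t * power))
    return DesignMetrics(true_effect, se, alpha, float(power), type_s, type_m, lam)


def retrodesign_mc(
    true_effect: float,
    se: float,
    alpha: float = 0.05,
    n_sims: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> DesignMetrics:
    """Monte-Carlo retrodesign; independent oracle for the closed forms."""
    if se <= 0:
        raise ValueError("se must be strictly positive")
    if n_sims < 10_000:
        raise ValueError("n_sims must be at least 10_000")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z_c = stats.norm.ppf(1.0 - alpha / 2.0)
    est = rng.normal(true_effect, se, size=n_sims)
    sig = np.abs(est) > z_c * se
    power = float(sig.mean())
    if not sig.any():
        warnings.warn("no significant draws; Type S/M unavailable", stacklevel=2)
        return DesignMetrics(true_effect, se, alpha, power, float("nan"), float("nan"),
                             true_effect / se)
    sig_est = est[sig]
    if true_effect == 0.0:
        type_s = float((sig_est < 0).mean())
        type_m = float("inf")
    else:
        type_s = float((np.sign(sig_est) != np.sign(true_effect)).mean())
        type_m = float(np.abs(sig_est).mean() / abs(true_effect))
    return DesignMetrics(true_effect, se, alpha, power, type_s, type_m, true_effect / se)


@dataclass
class AggregateDesignSummary:
    """Aggregated power / Type S / Type M at one level of the corpus."""

    level: str                   # "sampling" or "meta"
    truth_mode: str              # "uncorrected" or "corrected"
    post_hoc_filter: bool
    n_units: int
    mean: dict                   # metric name -> model-based mean
    median: dict                 # metric name -> median
    by_metric: dict              # effect-size metric -> {mean: {...}, median: {...}, n}

    def to_dict(self) -> dict:
        return asdict(self)


def _lmm_mean(values: np.ndarray, groups: np.ndarray) -> float:
    """Intercept of a study-random-intercept variance-components model."""
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    values, groups = values[ok], np.asarray(groups)[ok]
    if values.size == 0:
        return float("nan")
    if values.size < 3 or np.unique(groups).size < 2 or np.ptp(values) == 0:
        return float(values.mean())
    try:
        fit = MultilevelMetaRegression().fit(None, values, v=None, groups=groups)
        return float(fit.coef_[0])
    except Exception:  # degenerate grouping; fall back to the plain mean
        warnings.warn("mixed-model aggregation failed; using plain mean", stacklevel=2)
        return float(values.mean())


def aggregate_sampling_level(
    table: pd.DataFrame,
    truth_mode: str = "uncorrected",
    post_hoc_filter: bool = False,
) -> AggregateDesignSummary:
    """Aggregate per-effect-size metrics with a study-random-effect model.

    `table` needs columns power / type_s / type_m, study_uid, metric, and —
    when `post_hoc_filter` — a boolean overall_significant column used to
    drop effect sizes from meta-analyses with non-significant mean effects.
    """
    df = table
    if post_hoc_filter:
        df = df[df["overall_significant"]]
        if df.empty:
            raise ValueError("post hoc filter removed every effect size")

    def _block(sub: pd.DataFrame) -> tuple[dict, dict]:
        mean = {m: _lmm_mean(sub[m].to_numpy(), sub["study_uid"].to_numpy())
                for m in METRIC_COLS}
        finite = {m: sub[m].replace([np.inf, -np.inf], np.nan) for m in METRIC_COLS}
        med = {m: float(finite[m].median()) for m in METRIC_COLS}
        return mean, med

    mean, med = _block(df)
    by_metric = {}
    for metric, sub in df.groupby("metric"):
        m_mean, m_med = _block(sub)
        by_metric[metric] = {"mean": m_mean, "median": m_med, "n": len(sub)}
    return AggregateDesignSummary(
        level="sampling",
        truth_mode=truth_mode,
        post_hoc_filter=post_hoc_filter,
        n_units=len(df),
        mean=mean,
        median=med,
        by_metric=by_metric,
    )


def aggregate_meta_level(
    table: pd.DataFrame,
    truth_mode: str = "uncorrected",
    post_hoc_filter: bool = False,
) -> AggregateDesignSummary:
    """Aggregate per-meta-analysis metrics by a k-weighted regression.

    `table` needs power / type_s / type_m, k, metric and — when filtering —
    overall_significant (mean-effect p < alpha before correction).
    """
    df = table
    if post_hoc_filter:
        df = df[df["overall_significant"]]
        if df.empty:
            raise ValueError("post hoc filter removed every meta-analysis")

    def _wmean(sub: pd.DataFrame, col: str) -> float:
        vals = sub[col].to_numpy(float)
        w = sub["k"].to_numpy(float)
        ok = np.isfinite(vals)
        if not ok.any():
            return float("nan")
        return float(np.average(vals[ok], weights=w[ok]))

    def _block(sub: pd.DataFrame) -> tuple[dict, dict]:
        mean = {m: _wmean(sub, m) for m in METRIC_COLS}
        finite = {m: sub[m].replace([np.inf, -np.inf], np.nan) for m in METRIC_COLS}
        med = {m: float(finite[m].median()) for m in METRIC_COLS}
        return mean, med

    mean, med = _block(df)
    by_metric = {}
    for metric, sub in df.groupby("metric"):
        m_mean, m_med = _block(sub)
        by_metric[metric] = {"mean": m_mean, "median": m_med, "n": len(sub)}
    return AggregateDesignSummary(
        level="meta",
        truth_mode=truth_mode,
        post_hoc_filter=post_hoc_filter,
        n_units=len(df),
        mean=mean,
        median=med,
        by_metric=by_metric,
    )
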