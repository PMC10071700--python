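"""Three-level random-effects meta-analysis / meta-regression by REML.

The model for effect size ``y_ji`` (effect *i* of study *j*) with known
sampling variance ``v_i`` is::

    y_ji = x_ji' beta + s_j + o_ji + m_ji
    s_j  ~ N(0, sigma2_study),  o_ji ~ N(0, sigma2_obs),  m_ji ~ N(0, v_i)

so the marginal covariance is ``diag(v + sigma2_obs)`` plus a
``sigma2_study`` compound-symmetric block per study.  Variance components
are estimated by restricted maximum likelihood (the fixed effects are
profiled out by GLS), coefficients by GLS at the REML optimum, and
inference is Wald-type (normal by default, Student-t optional).

The restricted log-likelihood is evaluated in O(k) per call using the
rank-one Woodbury identity within each study block, which keeps the
simulation-heavy calibration workloads cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "MultilevelMetaRegression",
    "MultilevelFit",
    "ConvergenceWarning",
    "reml_loglik",
    "fit_multilevel",
    "wald_inference",
    "heterogeneity_stats",
    "typical_sampling_variance",
]

_VAR_FLOOR = 1e-10
_LOG_FLOOR = np.log(_VAR_FLOOR)


class ConvergenceWarning(UserWarning):
    """Raised when the REML optimizer fails to converge cleanly."""


def _prepare(y, X, v, groups):
    y = np.asarray(y, dtype=float)
    k = y.shape[0]
    if X is None:
        X = np.ones((k, 1))
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    if v is None:
        v = np.zeros(k)
    else:
        v = np.asarray(v, dtype=float)
    if groups is None:
        groups = np.arange(k)
    groups = np.asarray(groups)
    if not (y.shape[0] == X.shape[0] == v.shape[0] == groups.shape[0]):
        raise ValueError("y, X, v and groups must have aligned first dimensions")
    if np.any(v < 0):
        raise ValueError("sampling variances must be non-negative")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("moderator matrix is rank deficient")
    # sort by group so per-study blocks are contiguous for reduceat
    order = np.argsort(groups, kind="stable")
    g_sorted = groups[order]
    starts = np.flatnonzero(np.r_[True, g_sorted[1:] != g_sorted[:-1]])
    return y[order], X[order], v[order], starts, order


def _reml_core(sigma2_s, sigma2_o, y, X, v, starts):
    """Restricted log-likelihood plus GLS by-products, blockwise Woodbury.

    Inputs must already be sorted by group; `starts` are the block offsets.
    Returns (loglik, beta, XtVX_inv, rss).
    """
    k, p = X.shape
    d = v + sigma2_o
    if np.any(d <= 0):
        return -np.inf, None, None, None
    a = 1.0 / d
    s1 = np.add.reduceat(a, starts)
    u = sigma2_s / (1.0 + sigma2_s * s1)
    logdet_v = np.sum(np.log(d)) + np.sum(np.log1p(sigma2_s * s1))
    xa = X * a[:, None]
    xa_g = np.add.reduceat(xa, starts, axis=0)          # per-block sums of a_i x_i
    ya_g = np.add.reduceat(y * a, starts)
    xtvx = X.T @ xa - (xa_g * u[:, None]).T @ xa_g
    xtvy = xa.T @ y - xa_g.T @ (u * ya_g)
    ytvy = y @ (y * a) - u @ ya_g**2
    try:
        chol = np.linalg.cholesky(xtvx)
    except np.linalg.LinAlgError:
        return -np.inf, None, None, None
    beta = np.linalg.solve(xtvx, xtvy)
    rss = ytvy - beta @ xtvy
    logdet_xtvx = 2.0 * np.sum(np.log(np.diag(chol)))
    ll = -0.5 * ((k - p) * np.log(2.0 * np.pi) + logdet_v + logdet_xtvx + rss)
    return ll, beta, np.linalg.inv(xtvx), rss


def reml_loglik(sigma2_study, sigma2_obs, y, X=None, v=None, groups=None) -> float:
    """Restricted log-likelihood at the given variance components.

    Exposed so the REML optimum can be verified by brute-force grid search.
    """
    if sigma2_study < 0 or sigma2_obs < 0:
        raise ValueError("variance components must be non-negative")
    ys, Xs, vs, starts, _ = _prepare(y, X, v, groups)
    ll, _, _, _ = _reml_core(sigma2_study, sigma2_obs, ys, Xs, vs, starts)
    if not np.isfinite(ll):
        raise FloatingPointError(
            "singular marginal covariance; check sampling variances and components"
        )
    return float(ll)


@dataclass
class MultilevelFit:
    """Container for a fitted multilevel meta-analytic model."""

    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    sigma2_study: float
    sigma2_obs: float
    loglik: float
    converged: bool
    identifiable: bool
    k: int
    n_studies: int
    names: list[str] = field(default_factory=list)
    dropped_terms: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "coef": self.coef.tolist(),
            "se": self.se.tolist(),
            "sigma2_study": self.sigma2_study,
            "sigma2_obs": self.sigma2_obs,
            "loglik": self.loglik,
            "converged": self.converged,
            "identifiable": self.identifiable,
            "k": self.k,
            "n_studies": self.n_studies,
            "names": list(self.names),
            "dropped_terms": list(self.dropped_terms),
        }


class MultilevelMetaRegression(BaseEstimator):
    """Three-level random-effects meta-regression estimator.

    Parameters
    ----------
    fit_intercept : bool, default True
        Prepend an intercept column to the moderator matrix.
    inference : {"z", "t"}, default "z"
        Wald inference flavour; "t" uses k - p residual degrees of freedom.
    ci_level : float, default 0.95
        Confidence level for ``conf_int`` / ``coef_table``.
    n_starts : int, default 3
        Deterministic multi-starts for the variance-component optimizer.
    tol : float, default 1e-8
        Convergence tolerance on the restricted log-likelihood.
    single_component : bool, default False
        Estimate only the observation-level component (classic
        random-effects model; used for second-order pooling).

    Attributes
    ----------
    coef_, se_, cov_ : GLS coefficients at the REML optimum and their
        covariance (first entry is the intercept when fitted).
    sigma2_study_, sigma2_obs_ : REML variance components.
    loglik_, converged_, identifiable_, k_, n_studies_ : fit diagnostics.
    """

    def __init__(
        self,
        fit_intercept: bool = True,
        inference: str = "z",
        ci_level: float = 0.95,
        n_starts: int = 3,
        tol: float = 1e-8,
        single_component: bool = False,
    ):
        self.fit_intercept = fit_intercept
        self.inference = inference
        self.ci_level = ci_level
        self.n_starts = n_starts
        self.tol = tol
        self.single_component = single_component

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y, *, v=None, groups=None, names=None):
        """Fit by REML.

        Parameters
        ----------
        X : array-like of shape (k, p) or None
            Moderators (without intercept column); None for intercept-only.
        y : array-like of shape (k,)
            Effect sizes.
        v : array-like of shape (k,), optional
            Known sampling variances (zeros give a pure variance-components
            mixed model).
        groups : array-like of shape (k,), optional
            Study labels; None treats every record as its own study.
        names : list of str, optional
            Moderator names for the coefficient table.
        """
        y = np.asarray(y, dtype=float)
        k = y.shape[0]
        if X is not None:
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            if X.size == 0:
                X = None
        p_mod = 0 if X is None else X.shape[1]
        if names is None:
            names = [f"x{i}" for i in range(p_mod)]
        if self.fit_intercept:
            design = (
                np.ones((k, 1))
                if X is None
                else np.hstack([np.ones((k, 1)), X])
            )
            names = ["intercept"] + list(names)
        else:
            if X is None:
                raise ValueError("need moderators when fit_intercept=False")
            design = X
            names = list(names)
        p = design.shape[1]
        min_k = p + 1 if self.single_component else (3 if p == 1 else p + 2)
        if k < min_k:
            raise ValueError(f"need at least {min_k} effect sizes, got {k}")

        ys, Xs, vs, starts, _ = _prepare(y, design, v, groups)
        n_studies = starts.shape[0]
        singleton = n_studies == k
        one_component = self.single_component or singleton
        if singleton and not self.single_component:
            warnings.warn(
                "one effect size per study: between- and within-study variances "
                "are jointly unidentifiable; reporting a single total "
                "heterogeneity component as sigma2_obs_",
                ConvergenceWarning,
                stacklevel=2,
            )

        scale = float(np.var(ys)) + float(np.mean(vs)) + 1e-10
        upper = np.log(max(10.0 * scale, 1e-6))

        def _neg_ll(s2s, s2o):
            ll, *_ = _reml_core(s2s, s2o, ys, Xs, vs, starts)
            return -ll if np.isfinite(ll) else 1e12

        def _search(fun, x0s, ndim):
            best = None
            for x0 in x0s:
                res = optimize.minimize(
                    fun, x0, method="L-BFGS-B",
                    bounds=[(_LOG_FLOOR, upper)] * ndim,
                    options={"ftol": self.tol, "gtol": 1e-10},
                )
                if best is None or res.fun < best.fun - 1e-12:
                    best = res
            if not best.success:
                nm = optimize.minimize(
                    fun, best.x, method="Nelder-Mead",
                    options={"fatol": self.tol, "xatol": 1e-10},
                )
                if nm.fun <= best.fun:
                    nm.success = nm.success or best.success
                    best = nm
            return best

        # starts span the total scale so the flat low-variance region of the
        # log parameterization cannot trap every run
        splits = [(0.25, 0.25), (0.5, 0.01), (0.01, 0.5)][: max(self.n_starts, 1)]
        starts_1d = [[np.log(0.3 * scale)], [np.log(0.01 * scale)]]
        all_v_positive = bool(np.all(vs > 0))
        # candidate optima: interior plus each boundary; a boundary wins ties
        # so degenerate components are reported as exactly zero
        candidates = []  # (neg_ll, n_zero_components, s2s, s2o, success)
        if one_component:
            best = _search(lambda t: _neg_ll(0.0, np.exp(t[0])), starts_1d, 1)
            candidates.append((best.fun, 0, 0.0, float(np.exp(best.x[0])), best.success))
        else:
            best = _search(
                lambda t: _neg_ll(np.exp(t[0]), np.exp(t[1])),
                [[np.log(fs * scale), np.log(fo * scale)] for fs, fo in splits],
                2,
            )
            candidates.append(
                (best.fun, 0, float(np.exp(best.x[0])), float(np.exp(best.x[1])), best.success)
            )
            b_obs = _search(lambda t: _neg_ll(0.0, np.exp(t[0])), starts_1d, 1)
            candidates.append((b_obs.fun, 1, 0.0, float(np.exp(b_obs.x[0])), b_obs.success))
            if all_v_positive:
                b_stu = _search(lambda t: _neg_ll(np.exp(t[0]), 0.0), starts_1d, 1)
                candidates.append((b_stu.fun, 1, float(np.exp(b_stu.x[0])), 0.0, b_stu.success))
                candidates.append((_neg_ll(0.0, 0.0), 2, 0.0, 0.0, True))
        best_fun = min(c[0] for c in candidates)
        # among candidates within tolerance of the optimum prefer the most
        # boundary-constrained (deterministic tie-break)
        fun, _, s2s, s2o, converged = max(
            (c for c in candidates if c[0] <= best_fun + 1e-7), key=lambda c: c[1]
        )
        s2s = 0.0 if s2s <= 2 * _VAR_FLOOR else s2s
        s2o = 0.0 if s2o <= 2 * _VAR_FLOOR else s2o
        converged = bool(converged)
        s2o_eval = s2o if (s2o > 0 or np.all(vs > 0)) else _VAR_FLOOR
        ll, beta, cov, _ = _reml_core(s2s, s2o_eval, ys, Xs, vs, starts)
        if not converged:
            warnings.warn(
                "REML optimizer did not report clean convergence; "
                "returning best point found",
                ConvergenceWarning,
                stacklevel=2,
            )

        self.coef_ = beta
        self.cov_ = cov
        self.se_ = np.sqrt(np.diag(cov))
        self.sigma2_study_ = s2s
        self.sigma2_obs_ = s2o
        self.loglik_ = float(ll)
        self.converged_ = converged
        self.identifiable_ = not singleton or self.single_component
        self.k_ = k
        self.n_studies_ = n_studies
        self.names_ = names
        self.v_ = vs
        return self

    # -- inference -------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise AttributeError("estimator is not fitted; call fit first")

    def predict(self, X=None):
        self._check_fitted()
        if X is None:
            if len(self.coef_) != 1:
                raise ValueError("moderators required for prediction")
            return np.full(1, self.coef_[0])
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.fit_intercept:
            X = np.hstack([np.ones((X.shape[0], 1)), X])
        return X @ self.coef_

    def coef_table(self, level=None) -> pd.DataFrame:
        """Wald coefficient table: estimate, SE, statistic, p, CI."""
        self._check_fitted()
        level = self.ci_level if level is None else level
        est, se = self.coef_, self.se_
        stat = np.divide(est, se, out=np.zeros_like(est), where=se > 0)
        if self.inference == "t":
            df = max(self.k_ - len(est), 1)
            pval = 2.0 * stats.t.sf(np.abs(stat), df)
            crit = stats.t.ppf(0.5 + level / 2.0, df)
        else:
            pval = 2.0 * stats.norm.sf(np.abs(stat))
            crit = stats.norm.ppf(0.5 + level / 2.0)
        return pd.DataFrame(
            {
                "estimate": est,
                "se": se,
                "stat": stat,
                "pval": pval,
                "ci_low": est - crit * se,
                "ci_high": est + crit * se,
            },
            index=self.names_,
        )

    def conf_int(self, level=None) -> np.ndarray:
        tab = self.coef_table(level)
        return tab[["ci_low", "ci_high"]].to_numpy()

    def to_fit(self) -> MultilevelFit:
        self._check_fitted()
        return MultilevelFit(
            coef=self.coef_,
            se=self.se_,
            cov=self.cov_,
            sigma2_study=self.sigma2_study_,
            sigma2_obs=self.sigma2_obs_,
            loglik=self.loglik_,
            converged=self.converged_,
            identifiable=self.identifiable_,
            k=self.k_,
            n_studies=self.n_studies_,
            names=list(self.names_),
        )


# -- thin functional wrappers ------------------------------------------------

def fit_multilevel(y, X=None, v=None, groups=None, **kwargs) -> MultilevelMetaRegression:
    """Fit a multilevel meta-regression; thin wrapper over the estimator."""
    return MultilevelMetaRegression(**kwargs).fit(X, y, v=v, groups=groups)


def wald_inference(model: MultilevelMetaRegression, level: float = 0.95) -> pd.DataFrame:
    return model.coef_table(level)


def typical_sampling_variance(v) -> float:
    """Higgins-style typical sampling variance.

    v_typ = (k - 1) * sum(w) / ((sum(w))^2 - sum(w^2)), with w = 1/v.
    """
    v = np.asarray(v, dtype=float)
    v = v[v > 0]
    k = v.shape[0]
    if k < 2:
        return float(v[0]) if k == 1 else 0.0
    w = 1.0 / v
    return float((k - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum()))


def heterogeneity_stats(model: MultilevelMetaRegression) -> dict:
    """Multilevel I-squared decomposition at the fitted components."""
    model._check_fitted()
    s2s, s2o = model.sigma2_study_, model.sigma2_obs_
    v_typ = typical_sampling_variance(model.v_)
    total = s2s + s2o + v_typ
    if total <= 0:
        i2_total = i2_study = i2_obs = 0.0
    else:
        i2_total = (s2s + s2o) / total
        i2_study = s2s / total
        i2_obs = s2o / total
    return {
        "sigma2_study": s2s,
        "sigma2_obs": s2o,
        "v_typical": v_typ,
        "i2_total": i2_total,
        "i2_study": i2_study,
        "i2_obs": i2_obs,
    }
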