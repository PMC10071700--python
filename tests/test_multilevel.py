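import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metabias import (
    MultilevelMetaRegression,
    fit_multilevel,
    heterogeneity_stats,
    reml_loglik,
    typical_sampling_variance,
    wald_inference,
)
from metabias.multilevel import ConvergenceWarning, _prepare, _reml_core


def _gls_two_points():
    y = np.array([0.0, 1.0])
    X = np.ones((2, 1))
    v = np.array([1.0, 1.0])
    ys, Xs, vs, starts, _ = _prepare(y, X, v, np.array(["a", "b"]))
    return _reml_core(0.0, 0.0, ys, Xs, vs, starts)


def test_gls_two_point_inverse_variance_average():
    """With zero heterogeneity the GLS mean of (0, 1) at unit variances is
    0.5 with standard error sqrt(0.5)."""
    _, beta, cov, _ = _gls_two_points()
    assert beta[0] == pytest.approx(0.5)
    assert np.sqrt(cov[0, 0]) == pytest.approx(np.sqrt(0.5))


def test_location_equivariance(fix12):
    base = fit_multilevel(fix12["y"], v=fix12["v"], groups=fix12["g"])
    shifted = fit_multilevel(fix12["y"] + 3.7, v=fix12["v"], groups=fix12["g"])
    assert shifted.coef_[0] == pytest.approx(base.coef_[0] + 3.7, abs=1e-6)
    assert shifted.sigma2_study_ == pytest.approx(base.sigma2_study_, abs=1e-6)
    assert shifted.sigma2_obs_ == pytest.approx(base.sigma2_obs_, abs=1e-6)


def test_scale_equivariance(fix12):
    c = 2.5
    base = fit_multilevel(fix12["y"], v=fix12["v"], groups=fix12["g"])
    scaled = fit_multilevel(c * fix12["y"], v=c**2 * fix12["v"], groups=fix12["g"])
    assert scaled.coef_[0] == pytest.approx(c * base.coef_[0], rel=1e-5)
    assert scaled.se_[0] == pytest.approx(c * base.se_[0], rel=1e-5)
    assert scaled.sigma2_study_ == pytest.approx(c**2 * base.sigma2_study_, rel=1e-3, abs=1e-6)
    assert scaled.sigma2_obs_ == pytest.approx(c**2 * base.sigma2_obs_, rel=1e-3, abs=1e-6)


def test_moderator_centering_invariance(fix12):
    x = fix12["x"].to_numpy()
    base = fit_multilevel(fix12["y"], X=x[:, None], v=fix12["v"], groups=fix12["g"])
    cent = fit_multilevel(
        fix12["y"], X=(x - x.mean())[:, None], v=fix12["v"], groups=fix12["g"]
    )
    assert cent.coef_[1] == pytest.approx(base.coef_[1], rel=1e-5)
    assert cent.sigma2_study_ == pytest.approx(base.sigma2_study_, abs=1e-6)
    assert cent.coef_[0] == pytest.approx(
        base.coef_[0] + base.coef_[1] * x.mean(), rel=1e-5
    )


def test_homogeneous_fixture_collapses_to_fixed_effect():
    """With responses tighter than their sampling variance the variance
    components vanish and the fit is the plain inverse-variance mean."""
    y = 0.3 + np.array([-2, -1, 0, 1, 2, 1, -1, 0]) * 1e-3
    v = np.full(8, 0.04)
    groups = np.array(["a", "a", "b", "b", "c", "c", "d", "d"])
    fit = fit_multilevel(y, v=v, groups=groups)
    assert fit.sigma2_study_ == pytest.approx(0.0, abs=1e-6)
    assert fit.sigma2_obs_ == pytest.approx(0.0, abs=1e-6)
    assert fit.coef_[0] == pytest.approx(y.mean(), abs=1e-6)
    assert fit.se_[0] == pytest.approx(np.sqrt(0.04 / 8), rel=1e-3)


def test_one_effect_per_study_warns_and_reports_total_heterogeneity():
    rng = np.random.default_rng(3)
    y = rng.normal(0.3, 0.3, 10)
    v = np.full(10, 0.02)
    with pytest.warns(ConvergenceWarning, match="unidentifiable"):
        fit = fit_multilevel(y, v=v, groups=np.arange(10))
    assert not fit.identifiable_
    assert fit.sigma2_study_ == 0.0
    assert fit.sigma2_obs_ > 0


def test_singleton_structure_matches_two_level_model():
    """With one effect per study the three-level fit must agree with an
    explicit one-component random-effects fit."""
    rng = np.random.default_rng(4)
    y = rng.normal(0.2, 0.25, 12)
    v = rng.uniform(0.01, 0.05, 12)
    with pytest.warns(ConvergenceWarning):
        three = fit_multilevel(y, v=v, groups=np.arange(12))
    two = fit_multilevel(y, v=v, single_component=True)
    assert three.coef_[0] == pytest.approx(two.coef_[0], rel=1e-6)
    assert three.sigma2_obs_ == pytest.approx(two.sigma2_obs_, rel=1e-4, abs=1e-8)


def test_rank_deficient_moderators_rejected(fix12):
    X = np.column_stack([fix12["x"], fix12["x"] * 2.0])
    with pytest.raises(ValueError, match="rank"):
        fit_multilevel(fix12["y"], X=X, v=fix12["v"], groups=fix12["g"])


def test_too_few_records_rejected():
    with pytest.raises(ValueError, match="at least"):
        fit_multilevel([0.1, 0.2], v=[0.01, 0.01], groups=["a", "b"])


class TestWaldInference:
    def _fake_fit(self, est, se):
        m = MultilevelMetaRegression()
        m.coef_ = np.array([est])
        m.se_ = np.array([se])
        m.cov_ = np.array([[se**2]])
        m.names_ = ["intercept"]
        m.k_ = 10
        m.v_ = np.full(10, 0.01)
        m.sigma2_study_ = m.sigma2_obs_ = 0.0
        return m

    def test_z_two_gives_known_p_and_ci(self):
        tab = wald_inference(self._fake_fit(1.0, 0.5))
        row = tab.loc["intercept"]
        assert row["stat"] == pytest.approx(2.0)
        assert row["pval"] == pytest.approx(0.0455, abs=2e-4)
        assert row["ci_low"] == pytest.approx(0.020, abs=1e-3)
        assert row["ci_high"] == pytest.approx(1.980, abs=1e-3)

    def test_zero_estimate_gives_p_one_symmetric_ci(self):
        tab = wald_inference(self._fake_fit(0.0, 0.5))
        row = tab.loc["intercept"]
        assert row["pval"] == pytest.approx(1.0)
        assert row["ci_low"] == pytest.approx(-row["ci_high"])

    def test_null_p_values_are_uniform(self):
        """Wald p-values under the null agree with simulated z statistics."""
        rng = np.random.default_rng(8)
        z = rng.standard_normal(200_000)
        p_sim = (np.abs(z) > stats.norm.ppf(0.975)).mean()
        tab = wald_inference(self._fake_fit(1.0, 0.5))
        # the nominal 5% level the table's p-values refer to
        assert p_sim == pytest.approx(0.05, abs=0.002)
        assert (tab["pval"] < 0.05).iloc[0] == (abs(tab["stat"].iloc[0]) > 1.96)


class TestHeterogeneity:
    def _fit_with(self, s2s, s2o, v):
        m = MultilevelMetaRegression()
        m.coef_ = np.array([0.0])
        m.se_ = np.array([1.0])
        m.cov_ = np.eye(1)
        m.names_ = ["intercept"]
        m.k_ = len(v)
        m.v_ = np.asarray(v, float)
        m.sigma2_study_ = s2s
        m.sigma2_obs_ = s2o
        return m

    def test_zero_components_zero_i2(self):
        st_ = heterogeneity_stats(self._fit_with(0.0, 0.0, [0.1] * 5))
        assert st_["i2_total"] == 0.0

    def test_components_equal_typical_variance_gives_half(self):
        v = [0.1] * 5
        v_typ = typical_sampling_variance(v)
        st_ = heterogeneity_stats(self._fit_with(v_typ / 2, v_typ / 2, v))
        assert st_["i2_total"] == pytest.approx(0.5)

    def test_typical_variance_rules_agree_on_standard_fixture(self, fix12):
        """Higgins-style formula vs harmonic-mean rule differ by <5% on the
        frozen fixture's variances."""
        v = fix12["v"].to_numpy()
        formula = typical_sampling_variance(v)
        harmonic = len(v) / np.sum(1.0 / v)
        assert formula == pytest.approx(harmonic, rel=0.05)


def test_reml_optimum_matches_grid_on_fixture(fix12):
    """The optimizer's variance components maximise the same restricted
    likelihood surface a coarse grid search explores (fine grid lives in
    the acceptance suite)."""
    y, v, g = fix12["y"].to_numpy(), fix12["v"].to_numpy(), fix12["g"].to_numpy()
    fit = fit_multilevel(y, v=v, groups=g)
    grid = np.linspace(0.0, 0.3, 61)
    best = max(
        ((s2s, s2o, reml_loglik(s2s, s2o, y, v=v, groups=g)) for s2s in grid for s2o in grid),
        key=lambda t: t[2],
    )
    assert fit.loglik_ >= best[2] - 1e-6
    assert abs(fit.sigma2_study_ - best[0]) <= (grid[1] - grid[0])
    assert abs(fit.sigma2_obs_ - best[1]) <= (grid[1] - grid[0])


def test_multilevel_fit_matches_metafor(fix12, tmp_path):
    """Independent cross-check of coefficients, SEs and variance components
    against the rma.mv reference implementation."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not available for the metafor cross-check")
    csv = tmp_path / "fix.csv"
    fix12.to_csv(csv, index=False)
    script = textwrap.dedent(
        f"""
        suppressMessages(library(metafor))
        d <- read.csv("{csv}")
        d$obs <- seq_len(nrow(d))
        f <- rma.mv(y, v, mods = ~x, random = list(~1 | g, ~1 | obs),
                    data = d, method = "REML")
        cat(coef(f), f$se, f$sigma2, sep = ",")
        """
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, check=True
    )
    ref = np.array([float(t) for t in out.stdout.strip().split(",")])
    fit = fit_multilevel(fix12["y"], X=fix12[["x"]], v=fix12["v"], groups=fix12["g"])
    np.testing.assert_allclose(fit.coef_, ref[:2], atol=1e-4)
    np.testing.assert_allclose(fit.se_, ref[2:4], atol=1e-4)
    np.testing.assert_allclose(
        [fit.sigma2_study_, fit.sigma2_obs_], ref[4:6], atol=1e-4
    )


def test_estimator_is_sklearn_compatible(fix12):
    est = MultilevelMetaRegression(inference="t")
    params = est.get_params()
    assert params["inference"] == "t"
    est.set_params(inference="z").fit(
        None, fix12["y"], v=fix12["v"], groups=fix12["g"]
    )
    assert est.coef_.shape == (1,)
    assert est.predict()[0] == pytest.approx(est.coef_[0])
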