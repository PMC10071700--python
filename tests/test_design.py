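import numpy as np
import pandas as pd
import pytest

from metabias import (
    aggregate_meta_level,
    aggregate_sampling_level,
    design_metrics,
    retrodesign_mc,
)


class TestClosedForms:
    def test_null_effect_forces_definitional_values(self):
        dm = design_metrics(0.0, 0.2, alpha=0.05)
        assert dm.power == pytest.approx(0.05, abs=1e-12)
        assert dm.type_s == 0.5
        assert np.isinf(dm.type_m)

    def test_huge_signal_limits(self):
        dm = design_metrics(5.0, 0.25)  # lambda = 20
        assert dm.power == pytest.approx(1.0, abs=1e-9)
        assert dm.type_s == pytest.approx(0.0, abs=1e-12)
        assert dm.type_m == pytest.approx(1.0, abs=1e-6)

    def test_sign_symmetry(self):
        a = design_metrics(0.3, 0.2)
        b = design_metrics(-0.3, 0.2)
        assert a.power == pytest.approx(b.power)
        assert a.type_s == pytest.approx(b.type_s)
        assert a.type_m == pytest.approx(b.type_m)

    def test_metrics_depend_only_on_snr_and_alpha(self):
        a = design_metrics(0.3, 0.1)
        b = design_metrics(0.6, 0.2)
        assert a.power == pytest.approx(b.power)
        assert a.type_m == pytest.approx(b.type_m)

    def test_monotone_in_signal_to_noise(self):
        lams = np.linspace(0.1, 4.0, 25)
        out = [design_metrics(l, 1.0) for l in lams]
        powers = [o.power for o in out]
        type_s = [o.type_s for o in out]
        type_m = [o.type_m for o in out]
        assert np.all(np.diff(powers) > 0)
        assert np.all(np.diff(type_s) < 0)
        assert np.all(np.diff(type_m) < 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            design_metrics(0.3, 0.0)
        with pytest.raises(ValueError):
            design_metrics(0.3, 0.1, alpha=1.5)


class TestMonteCarloOracle:
    def test_closed_form_agrees_with_simulation(self):
        """Spot-check at moderate signal; the full grid at 1e7 draws lives
        in the acceptance suite."""
        dm = design_metrics(0.25, 0.25, alpha=0.05)
        mc = retrodesign_mc(0.25, 0.25, alpha=0.05, n_sims=400_000, seed=6)
        assert mc.power == pytest.approx(dm.power, abs=0.004)
        assert mc.type_s == pytest.approx(dm.type_s, abs=0.01)
        assert mc.type_m == pytest.approx(dm.type_m, rel=0.02)

    def test_fixed_seed_reproducible(self):
        a = retrodesign_mc(0.3, 0.2, n_sims=50_000, seed=11)
        b = retrodesign_mc(0.3, 0.2, n_sims=50_000, seed=11)
        assert a == b

    def test_minimum_draws_enforced(self):
        with pytest.raises(ValueError):
            retrodesign_mc(0.3, 0.2, n_sims=100)


def _sampling_table(values, studies, metric="SMD"):
    return pd.DataFrame(
        {
            "power": values,
            "type_s": values,
            "type_m": values,
            "study_uid": studies,
            "metric": [metric] * len(values),
            "overall_significant": [True] * len(values),
        }
    )


class TestSamplingAggregation:
    def test_constant_values_aggregate_to_constant(self):
        tab = _sampling_table([0.4] * 6, ["a", "a", "b", "b", "c", "c"])
        agg = aggregate_sampling_level(tab)
        assert agg.mean["power"] == pytest.approx(0.4)
        assert agg.median["power"] == pytest.approx(0.4)

    def test_balanced_design_matches_grand_mean_of_study_means(self):
        """With equal cluster sizes the random-intercept aggregate equals
        the unweighted mean of study means (balanced one-way layout)."""
        rng = np.random.default_rng(7)
        study_means = rng.uniform(0.1, 0.8, 10)
        rows, studies = [], []
        for j, m in enumerate(study_means):
            for _ in range(4):
                rows.append(m + rng.normal(0, 1e-3))
                studies.append(f"s{j}")
        agg = aggregate_sampling_level(_sampling_table(rows, studies))
        assert agg.mean["power"] == pytest.approx(study_means.mean(), abs=1e-3)

    def test_post_hoc_filter_drops_rows(self):
        tab = _sampling_table([0.2, 0.2, 0.8, 0.8], ["a", "a", "b", "b"])
        tab["overall_significant"] = [False, False, True, True]
        agg = aggregate_sampling_level(tab, post_hoc_filter=True)
        assert agg.n_units == 2
        assert agg.mean["power"] == pytest.approx(0.8)


def _meta_table(values, ks, metric="SMD", sig=None):
    n = len(values)
    return pd.DataFrame(
        {
            "power": values,
            "type_s": values,
            "type_m": values,
            "k": ks,
            "metric": [metric] * n,
            "overall_significant": sig if sig is not None else [True] * n,
        }
    )


class TestMetaAggregation:
    def test_equal_weights_reduce_to_plain_mean(self):
        agg = aggregate_meta_level(_meta_table([0.2, 0.4, 0.6], [5, 5, 5]))
        assert agg.mean["power"] == pytest.approx(0.4)

    def test_dominant_weight_pulls_the_aggregate(self):
        agg = aggregate_meta_level(_meta_table([0.2, 0.9], [1, 100_000]))
        assert agg.mean["power"] == pytest.approx(0.9, abs=1e-4)

    def test_filter_changes_membership_not_values(self):
        tab = _meta_table([0.2, 0.4, 0.9], [4, 4, 4], sig=[False, True, True])
        full = aggregate_meta_level(tab, post_hoc_filter=False)
        filt = aggregate_meta_level(tab, post_hoc_filter=True)
        assert full.n_units == 3 and filt.n_units == 2
        assert filt.mean["power"] == pytest.approx((0.4 + 0.9) / 2)

    def test_all_filtered_raises(self):
        tab = _meta_table([0.2], [4], sig=[False])
        with pytest.raises(ValueError, match="post hoc"):
            aggregate_meta_level(tab, post_hoc_filter=True)

    def test_infinite_type_m_excluded_from_weighted_mean(self):
        tab = _meta_table([0.2, 0.4], [5, 5])
        tab.loc[0, "type_m"] = np.inf
        agg = aggregate_meta_level(tab)
        assert agg.mean["type_m"] == pytest.approx(0.4)
        assert np.isfinite(agg.median["type_m"])
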